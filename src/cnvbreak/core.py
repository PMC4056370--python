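"""Shared containers and sequence utilities.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conventions appear only at FASTA/BED/GFF boundaries, handled by the I/O
helpers in :mod:`cnvbreak.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """i.i.d. DNA of length ``n`` at the requested GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def lcp(a: str, b: str) -> int:
    """Length of the longest common prefix."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def lcs(a: str, b: str) -> int:
    """Length of the longest common suffix."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


@dataclass
class Interval:
    """Half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def coverage_fraction(iv: Interval, others: list[Interval]) -> float:
    """Fraction of ``iv`` covered by the union of ``others`` (same chromosome)."""
    if len(iv) == 0:
        return 0.0
    pieces = sorted(
        (max(o.start, iv.start), min(o.end, iv.end))
        for o in others
        if o.chrom == iv.chrom and o.start < iv.end and o.end > iv.start
    )
    covered = 0
    cursor = iv.start
    for s, e in pieces:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered / len(iv)


@dataclass
class SimGenome:
    """A genome as an ordered map of chromosome name -> sequence.

    ``euchromatin_mask`` and ``te_annotation`` are per-chromosome interval
    lists; the mask marks regions where CNV calling is trusted (the analogue
    of restricting analysis to assembled chromosome-arm euchromatin).
    """

    chromosomes: dict[str, str]
    euchromatin_mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    te_annotation: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        for name, seq in self.chromosomes.items():
            if seq.strip("ACGT"):
                raise ValueError(f"{name}: sequence contains non-ACGT characters")
        for anno in (self.euchromatin_mask, self.te_annotation):
            for name, ivs in anno.items():
                n = len(self.chromosomes[name])
                for s, e in ivs:
                    if not (0 <= s <= e <= n):
                        raise ValueError(f"{name}:{s}-{e} outside chromosome bounds")

    def seq(self, chrom: str, start: int, end: int) -> str:
        return self.chromosomes[chrom][max(start, 0) : end]

    def size(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def in_mask(self, chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.euchromatin_mask.get(chrom, []))


@dataclass
class CNVCall:
    """A detected copy-number variant with single-nucleotide breakpoints.

    For deletions and tandem duplications ``(start, end)`` is the affected
    reference interval; for insertions ``start == end`` is the insertion
    point.  ``inserted_seq`` holds the inserted bases for insertions and any
    junction extra bases for deletions (complex ends).
    """

    chrom: str
    start: int
    end: int
    kind: str  # deletion | insertion | tandem_dup
    inserted_seq: str = ""
    support: list[tuple[str, str]] = field(default_factory=list)  # (read_id, strain)
    filters_passed: frozenset = frozenset()

    @property
    def n_strains(self) -> int:
        return len({s for _, s in self.support})

    @property
    def size(self) -> int:
        if self.kind == "insertion":
            return len(self.inserted_seq)
        return self.end - self.start

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.kind, self.inserted_seq)
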