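"""Synthetic genomes with implanted CNVs of known mechanistic signature.

The generator builds a random multi-chromosome reference, edits it so that
each planned CNV site carries an exactly controlled breakpoint signature
(blunt junction, k bp of microhomology, junction filler bases, flanking
high-identity repeats, an adjacent short-repeat tract, or a planted non-B
motif), derives per-strain genomes carrying the variants, an outgroup genome
at configurable divergence for polarization, and shotgun reads.  Everything
is recorded in a machine-readable truth ledger so that every downstream
stage can be scored against known truth.

Signatures are *enforced*, not merely sampled: after placement the reference
bases adjacent to each junction are adjusted so that, e.g., a "blunt"
deletion has exactly zero bases of breakpoint microhomology and a
"microhomology(k)" deletion has exactly k.  This keeps the truth ledger
verifiable from sequence alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BASES, SimGenome, random_dna, revcomp

# Flanking windows used downstream; implant sites keep at least twice this
# distance apart so per-event analyses never overlap.
FLANK_WINDOW = 500
SITE_MARGIN = 600

# Short planted non-B motif sequences (each fits inside the 25 bp
# breakpoint-proximal window used by the enrichment analysis).
NONB_PLANT = {
    "G4": "GGGTTAGGGTTAGGGTTAGGG",
    "ZDNA": "GCGTGCACGCGCGTGC",
    "INVERTED_REPEAT": "ACGTGATCGTAC" + "GTACGATCACGT",
    "MIRROR_REPEAT": "ACGTGATCGTAC" + "CATGCTAGTGCA"[::-1],
    "DIRECT_REPEAT": "ACGTGATCGTAC" * 2,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class CNVSpec:
    """One CNV to implant.

    ``signature`` selects the junction geometry:

    - ``blunt``: no microhomology, no junction extras
    - ``microhomology``: ``mh_k`` bp of breakpoint microhomology (type I)
    - ``complex``: ``extras_len`` untemplated bases at the junction
    - ``complex_mh``: both microhomology and junction extras
    - ``filler``: insertion of novel sequence absent from the reference
    - ``repeat_expansion``: insertion extending an adjacent short-repeat tract
    - ``nahr_flanks``: deletion flanked by two high-identity repeats
    """

    kind: str  # deletion | insertion | tandem_dup
    size: int
    signature: str = "blunt"
    mh_k: int = 0
    extras_len: int = 0
    unit: str = "CA"
    copies: int = 0
    repeat_len: int = 0
    repeat_identity: float = 100.0
    strains: tuple[str, ...] = ()
    planted_nonb: str | None = None
    chrom: str | None = None

    def __post_init__(self):
        if self.size < 25:
            raise ConfigError("CNV size floor is 25 bp")
        if self.kind not in ("deletion", "insertion", "tandem_dup"):
            raise ConfigError(f"unknown CNV kind {self.kind!r}")
        if self.mh_k < 0:
            raise ConfigError("microhomology length must be >= 0")
        if self.signature == "nahr_flanks" and self.repeat_len < 30:
            raise ConfigError("NAHR flanking repeats must be >= 30 bp")
        if self.signature == "microhomology" and self.mh_k < 1:
            raise ConfigError("microhomology signature needs mh_k >= 1")
        if self.signature in ("complex", "complex_mh") and self.extras_len < 1:
            raise ConfigError("complex signature needs extras_len >= 1")


@dataclass
class SimEvent:
    """Truth-ledger record of one implanted CNV (0-based half-open)."""

    chrom: str
    start: int
    end: int
    kind: str
    signature: str
    mh_k: int = 0
    inserted_seq: str = ""
    strains: tuple[str, ...] = ()
    polarity: str | None = None  # set by generate_outgroup
    planted_nonb: str | None = None

    @property
    def size(self) -> int:
        if self.kind == "insertion":
            return len(self.inserted_seq)
        return self.end - self.start


@dataclass
class SimTruth:
    """Ground truth for one simulation: all events plus strain names."""

    events: list[SimEvent]
    strains: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            [e.__dict__ for e in self.events], indent=1, default=list
        )


@dataclass
class SimRead:
    read_id: str
    strain: str
    seq: str
    chrom: str
    start: int  # origin on the strain genome, forward coordinates
    end: int
    strand: str


@dataclass
class ReadSet:
    reads: list[SimRead]
    mean_length: float
    error_rate: float

    def by_strain(self) -> dict[str, list[SimRead]]:
        out: dict[str, list[SimRead]] = {}
        for r in self.reads:
            out.setdefault(r.strain, []).append(r)
        return out


# ---------------------------------------------------------------------------
# reference genome


def generate_genome(
    n_chrom: int,
    lengths: list[int],
    gc: float = 0.42,
    seed: int = 0,
    mask_margin: int = 2000,
    n_te: int = 0,
    te_len: int = 500,
) -> SimGenome:
    """Random reference genome with a euchromatin mask and optional TE islands.

    Bases are i.i.d. at the requested GC; the mask covers everything except
    ``mask_margin`` bp at each chromosome end (the analogue of excluding
    repeat-rich chromosome ends).  TE islands share a common consensus so the
    annotation marks genuinely repetitive sequence.
    """
    if len(lengths) != n_chrom:
        raise ConfigError("lengths must list one size per chromosome")
    if any(l < 10_000 for l in lengths):
        raise ConfigError("chromosomes must be >= 10 kb")
    if not 0 < gc < 1:
        raise ConfigError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chroms: dict[str, str] = {}
    mask: dict[str, list[tuple[int, int]]] = {}
    te: dict[str, list[tuple[int, int]]] = {}
    consensus = random_dna(rng, te_len, gc) if n_te else ""
    for i, length in enumerate(lengths):
        name = f"chr{i + 1}"
        seq = bytearray(random_dna(rng, length, gc), "ascii")
        ivs = []
        for _ in range(n_te):
            pos = int(rng.integers(mask_margin, length - mask_margin - te_len))
            seq[pos : pos + te_len] = consensus.encode()
            ivs.append((pos, pos + te_len))
        chroms[name] = seq.decode()
        mask[name] = [(mask_margin, length - mask_margin)]
        te[name] = sorted(ivs)
    return SimGenome(chroms, mask, te, seed=seed)


# ---------------------------------------------------------------------------
# CNV implanting


def _set_base(seq: bytearray, pos: int, *, differ_from: str, rng) -> None:
    """Force ``seq[pos]`` to differ from every base in ``differ_from``."""
    choices = [b for b in BASES if b not in differ_from]
    if chr(seq[pos]) in differ_from:
        seq[pos] = ord(choices[int(rng.integers(len(choices)))])


def _mutate_copy(seq: str, identity: float, rng) -> str:
    """Copy of ``seq`` carrying exactly the substitutions implied by identity %."""
    n_sub = int(round(len(seq) * (1 - identity / 100.0)))
    out = bytearray(seq, "ascii")
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        cur = chr(out[pos])
        alts = [b for b in BASES if b != cur]
        out[pos] = ord(alts[int(rng.integers(3))])
    return out.decode()


def _novel_kmer(rng, n: int, genome_seqs: list[str]) -> str:
    """Random n-mer with no exact full-length match anywhere in the genome."""
    for _ in range(200):
        cand = random_dna(rng, n)
        rc = revcomp(cand)
        if not any(cand in s or rc in s for s in genome_seqs):
            return cand
    raise ConfigError(f"could not draw a novel {n}-mer")


def _left_normalize_insertion(ref: str, pos: int, ins: str) -> tuple[int, str]:
    while pos > 0 and ins[-1] == ref[pos - 1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def _place_sites(genome: SimGenome, specs: list[CNVSpec], rng) -> list[tuple[str, int]]:
    """Choose one start position per spec, respecting mask and separation.

    Sites are laid down along each masked interval with a moving cursor and
    random jitter (separation >= 2x the flank window), cycling chromosomes;
    this guarantees placement whenever capacity allows, even at high event
    density.
    """
    lanes = []  # [chrom, cursor, hi]
    for chrom, ivs in genome.euchromatin_mask.items():
        for lo, hi in ivs:
            lanes.append([chrom, lo + SITE_MARGIN, hi - SITE_MARGIN])
    if not lanes:
        raise ConfigError("genome has no euchromatin mask to place CNVs in")
    order = rng.permutation(len(lanes))
    lanes = [lanes[i] for i in order]
    out = []
    lane_ix = 0
    for spec in specs:
        span = spec.size if spec.kind != "insertion" else 0
        extra = spec.repeat_len if spec.signature == "nahr_flanks" else 0
        placed = None
        for _ in range(len(lanes)):
            lane = lanes[lane_ix % len(lanes)]
            lane_ix += 1
            if spec.chrom and lane[0] != spec.chrom:
                continue
            s = lane[1] + extra + int(rng.integers(0, 150))
            if s + span + extra <= lane[2]:
                placed = (lane[0], s)
                lane[1] = s + span + extra + 2 * FLANK_WINDOW
                break
        if placed is None:
            raise ConfigError("could not place all CNV specs (genome too small?)")
        out.append(placed)
    return out


def implant_cnvs(
    genome: SimGenome,
    specs: list[CNVSpec],
    strains: list[str],
    seed: int = 0,
) -> tuple[SimGenome, dict[str, SimGenome], SimTruth]:
    """Implant CNVs, returning the (edited) reference, strain genomes and truth.

    The reference is edited *before* strain derivation so that each junction
    carries its exact intended signature; the same edited reference must be
    used for mapping and classification.
    """
    rng = np.random.default_rng(seed)
    sites = _place_sites(genome, specs, rng)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}
    events: list[SimEvent] = []

    for spec, (chrom, s) in zip(specs, sites):
        seq = seqs[chrom]
        e = s + (spec.size if spec.kind != "insertion" else 0)
        mh_k = 0
        inserted = ""
        sig = spec.signature

        if spec.planted_nonb:
            plant = NONB_PLANT[spec.planted_nonb]
            if spec.kind == "insertion":
                seq[s - len(plant) - 2 : s - 2] = plant.encode()
            else:
                seq[s + 2 : s + 2 + len(plant)] = plant.encode()

        if spec.kind == "deletion":
            if sig == "nahr_flanks":
                rep = random_dna(rng, spec.repeat_len)
                seq[s - spec.repeat_len : s] = rep.encode()
                seq[e : e + spec.repeat_len] = _mutate_copy(
                    rep, spec.repeat_identity, rng
                ).encode()
            if sig in ("microhomology", "complex_mh"):
                mh_k = spec.mh_k
                seq[e : e + mh_k] = seq[s : s + mh_k]
                _set_base(seq, e + mh_k, differ_from=chr(seq[s + mh_k]), rng=rng)
            else:
                _set_base(seq, s, differ_from=chr(seq[e]), rng=rng)
            _set_base(seq, e - 1, differ_from=chr(seq[s - 1]), rng=rng)
            if sig in ("complex", "complex_mh"):
                # extras must not extend either flank match: the first base
                # differs from the reference base the left flank would read
                # next, the last from the base preceding the right flank
                ext = random_dna(rng, spec.extras_len)
                if spec.extras_len == 1:
                    opts = [
                        b
                        for b in BASES
                        if b not in (chr(seq[s]), chr(seq[e - 1]), chr(seq[e]))
                    ]
                    ext = opts[int(rng.integers(len(opts)))]
                else:
                    first = [
                        b for b in BASES if b not in (chr(seq[s]), chr(seq[e]))
                    ]
                    last = [b for b in BASES if b != chr(seq[e - 1])]
                    ext = (
                        first[int(rng.integers(len(first)))]
                        + ext[1:-1]
                        + last[int(rng.integers(len(last)))]
                    )
                inserted = ext

        elif spec.kind == "insertion":
            if sig == "repeat_expansion":
                unit = spec.unit
                tract = unit * 3
                seq[s - len(tract) : s] = tract.encode()
                _set_base(seq, s - len(tract) - 1, differ_from=unit[-1], rng=rng)
                copies = spec.copies or max(2, spec.size // len(unit))
                inserted = (unit * copies)[: max(spec.size, 2 * len(unit))]
            else:  # filler
                ins = _novel_kmer(rng, spec.size, [b.decode() for b in seqs.values()])
                while ins[0] == chr(seq[s]) or ins[-1] == chr(seq[s - 1]):
                    ins = _novel_kmer(
                        rng, spec.size, [b.decode() for b in seqs.values()]
                    )
                inserted = ins

        else:  # tandem_dup
            _set_base(seq, s, differ_from=chr(seq[e]), rng=rng)
            _set_base(seq, e - 1, differ_from=chr(seq[s - 1]), rng=rng)

        strain_subset = tuple(spec.strains) or tuple(strains)
        if not set(strain_subset) <= set(strains):
            raise ConfigError("spec strains not a subset of the cohort")
        events.append(
            SimEvent(
                chrom,
                s,
                e,
                spec.kind,
                sig,
                mh_k=mh_k,
                inserted_seq=inserted,
                strains=strain_subset,
                planted_nonb=spec.planted_nonb,
            )
        )

    reference = SimGenome(
        {c: b.decode() for c, b in seqs.items()},
        genome.euchromatin_mask,
        genome.te_annotation,
        seed=genome.seed,
    )

    # left-normalize repeat expansions against the edited reference so the
    # truth ledger stores the canonical (leftmost) representation
    for ev in events:
        if ev.kind == "insertion" and ev.signature == "repeat_expansion":
            pos, ins = _left_normalize_insertion(
                reference.chromosomes[ev.chrom], ev.start, ev.inserted_seq
            )
            ev.start = ev.end = pos
            ev.inserted_seq = ins

    strain_genomes = {
        name: _apply_events(reference, [e for e in events if name in e.strains])
        for name in strains
    }
    return reference, strain_genomes, SimTruth(events, tuple(strains))


def _apply_events(reference: SimGenome, events: list[SimEvent]) -> SimGenome:
    chroms = {}
    for chrom, ref in reference.chromosomes.items():
        parts = []
        cursor = 0
        for ev in sorted(
            (e for e in events if e.chrom == chrom), key=lambda e: e.start
        ):
            parts.append(ref[cursor : ev.start])
            if ev.kind == "deletion":
                parts.append(ev.inserted_seq)  # junction extras, if any
                cursor = ev.end
            elif ev.kind == "insertion":
                parts.append(ev.inserted_seq)
                cursor = ev.start
            else:  # tandem_dup
                parts.append(ref[ev.start : ev.end] * 2)
                cursor = ev.end
        parts.append(ref[cursor:])
        chroms[chrom] = "".join(parts)
    return SimGenome(chroms)


# Observed breakpoint-class frequencies used as the default cohort mix.
CLASS_MIX = {"blunt": 0.35, "microhomology": 0.41, "complex": 0.22, "complex_mh": 0.02}


def cohort_specs(
    n_events: int,
    seed: int = 0,
    class_mix: dict | None = None,
    insertion_fraction: float = 0.0,
    nahr_fraction: float = 0.0,
    size_log_median: float = 35.0,
    size_log_sigma: float = 0.7,
    size_range: tuple[int, int] = (25, 500),
    ins_size_range: tuple[int, int] = (25, 60),
) -> list[CNVSpec]:
    """Build a cohort of CNV specs with a controlled breakpoint-class mix.

    Junction-class signatures (blunt / microhomology / complex /
    complex+microhomology) are implanted on deletions; an optional fraction
    of events are insertions (filler or repeat expansions, sized to fit
    within a read) and an optional fraction of the deletions carry
    NAHR-style flanking repeats.  Sizes are log-normal around the stated
    median, clipped to ``size_range``.
    """
    mix = dict(class_mix or CLASS_MIX)
    rng = np.random.default_rng(seed)
    n_ins = int(round(insertion_fraction * n_events))
    n_nahr = int(round(nahr_fraction * (n_events - n_ins)))
    n_del = n_events - n_ins - n_nahr
    labels = list(mix)
    weights = np.array([mix[l] for l in labels], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * n_del).astype(int)
    while counts.sum() < n_del:
        counts[int(rng.choice(len(labels), p=weights))] += 1
    specs: list[CNVSpec] = []

    def _del_size():
        s = rng.lognormal(np.log(size_log_median), size_log_sigma)
        return int(np.clip(round(s), *size_range))

    for label, cnt in zip(labels, counts):
        for _ in range(cnt):
            mh_k = int(2 + rng.geometric(0.5) - 1) if "mh" in label or label == "microhomology" else 0
            mh_k = min(mh_k, 10)
            extras = int(rng.integers(1, 16)) if label.startswith("complex") else 0
            specs.append(
                CNVSpec(
                    "deletion",
                    _del_size(),
                    signature=label,
                    mh_k=mh_k,
                    extras_len=extras,
                )
            )
    for _ in range(n_nahr):
        # repeats sized within the 200 bp precise-mode flank and at SSA-scale
        # identity so every implant is detectable by the type I filter
        specs.append(
            CNVSpec(
                "deletion",
                _del_size(),
                signature="nahr_flanks",
                repeat_len=int(rng.integers(40, 180)),
                repeat_identity=float(rng.uniform(98.5, 100)),
            )
        )
    for _ in range(n_ins):
        size = int(rng.integers(ins_size_range[0], ins_size_range[1] + 1))
        if rng.uniform() < 0.2:
            specs.append(
                CNVSpec("insertion", size, signature="repeat_expansion",
                        unit=["CA", "AT", "CAG"][int(rng.integers(3))])
            )
        else:
            specs.append(CNVSpec("insertion", size, signature="filler"))
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


# ---------------------------------------------------------------------------
# outgroup


def generate_outgroup(
    reference: SimGenome,
    truth: SimTruth,
    divergence: float = 0.05,
    share: float = 0.0,
    seed: int = 0,
    guard: int = 20,
) -> SimGenome:
    """Outgroup genome for parsimony polarization.

    A ``share`` fraction of events (chosen at random) have their derived
    allele written into the outgroup; the rest stay ancestral.  Substitutions
    are applied uniformly at the given rate, sparing ``guard`` bp around
    every junction so polarization errors reflect logic rather than noise.
    The intended polarity of every event is recorded in the truth ledger.
    """
    if not 0 <= share <= 1:
        raise ConfigError("share must be in [0, 1]")
    if divergence >= 0.2:
        raise ConfigError("divergence must be < 0.2")
    rng = np.random.default_rng(seed)
    n_events = len(truth.events)
    n_shared = int(round(share * n_events))
    shared_ix = set(
        rng.choice(n_events, size=n_shared, replace=False).tolist()
    ) if n_shared else set()

    guard_zones: dict[str, set[int]] = {c: set() for c in reference.chromosomes}
    for ev in truth.events:
        for j in (ev.start, ev.end):
            guard_zones[ev.chrom].update(range(j - guard, j + guard))

    chroms = {}
    for chrom, ref in reference.chromosomes.items():
        seq = bytearray(ref, "ascii")
        if divergence > 0:
            n_sub = rng.binomial(len(ref), divergence)
            for pos in rng.choice(len(ref), size=n_sub, replace=False):
                if int(pos) in guard_zones[chrom]:
                    continue
                cur = chr(seq[pos])
                alts = [b for b in BASES if b != cur]
                seq[pos] = ord(alts[int(rng.integers(3))])
        chroms[chrom] = seq.decode()

    shared_events = []
    for i, ev in enumerate(truth.events):
        if i in shared_ix:
            shared_events.append(ev)
            ev.polarity = (
                "INSERTION_IN_REFERENCE"
                if ev.kind == "deletion"
                else "DELETION_IN_REFERENCE"
            )
        else:
            ev.polarity = (
                "DELETION_IN_STRAIN" if ev.kind == "deletion" else "INSERTION_IN_STRAIN"
            )

    out = SimGenome(chroms)
    return _apply_events(out, shared_events)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    strain_genomes: dict[str, SimGenome],
    coverage: float,
    mean_len: int = 105,
    len_sd: float = 20.0,
    error: float = 0.0,
    seed: int = 0,
    both_strands: bool = True,
) -> ReadSet:
    """Uniform shotgun reads from each strain genome.

    Read lengths are drawn from a normal truncated to [50, 2 x mean]; total
    bases per strain approximate ``coverage`` times the genome size.
    """
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    if mean_len < 50:
        raise ConfigError("mean read length must be >= 50 bp")
    rng = np.random.default_rng(seed)
    reads: list[SimRead] = []
    for strain in sorted(strain_genomes):
        genome = strain_genomes[strain]
        size = genome.size()
        n_reads = int(round(coverage * size / mean_len))
        names = list(genome.chromosomes)
        lens = np.array([len(genome.chromosomes[c]) for c in names], dtype=float)
        probs = lens / lens.sum()
        chrom_ix = rng.choice(len(names), size=n_reads, p=probs)
        raw_lens = np.clip(
            rng.normal(mean_len, len_sd, size=n_reads), 50, 2 * mean_len
        ).astype(int)
        strands = (
            rng.integers(2, size=n_reads) if both_strands else np.zeros(n_reads, int)
        )
        for i in range(n_reads):
            chrom = names[chrom_ix[i]]
            L = min(int(raw_lens[i]), int(lens[chrom_ix[i]]))
            start = int(rng.integers(0, lens[chrom_ix[i]] - L + 1))
            seq = genome.chromosomes[chrom][start : start + L]
            if error > 0:
                n_err = rng.binomial(L, error)
                if n_err:
                    b = bytearray(seq, "ascii")
                    for pos in rng.choice(L, size=n_err, replace=False):
                        cur = chr(b[pos])
                        alts = [x for x in BASES if x != cur]
                        b[pos] = ord(alts[int(rng.integers(3))])
                    seq = b.decode()
            strand = "+" if strands[i] == 0 else "-"
            if strand == "-":
                seq = revcomp(seq)
            reads.append(
                SimRead(
                    f"{strain}.r{i}", strain, seq, chrom, start, start + L, strand
                )
            )
    return ReadSet(reads, float(mean_len), float(error))
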