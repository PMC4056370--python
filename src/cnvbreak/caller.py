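"""Split-read CNV calling.

Reads are anchored to the reference by exact k-mer seeds.  A read that
aligns contiguously (one block, full length, mismatches under the
configured rate) is *concordant* and excluded from split analysis.  The
remainder are decomposed into a maximal exact prefix block and a maximal
exact suffix block; the geometry of the two blocks yields the split
signature:

- blocks colinear with a reference gap        -> deletion
- blocks adjacent on the reference with
  unaligned read bases between them           -> insertion
- 3' block mapping 5' of the 5' block         -> tandem duplication
- reference gap plus unaligned junction bases -> deletion with a complex end

Junctions ambiguous under microhomology are left-normalized so identical
events from different reads cluster on one canonical key.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .core import CNVCall, Interval, SimGenome, coverage_fraction, revcomp
from .simulate import ReadSet

log = logging.getLogger(__name__)


@dataclass
class Block:
    """One gap-free alignment block: read[r_start:r_end] == ref[g_start:g_end]."""

    r_start: int
    r_end: int
    g_start: int
    g_end: int

    def __post_init__(self):
        if self.r_end - self.r_start != self.g_end - self.g_start:
            raise ValueError("block length mismatch between read and reference")


@dataclass
class ReadAlignment:
    read_id: str
    strain: str
    chrom: str
    strand: str
    read_len: int
    blocks: list[Block]
    mismatches: int = 0
    concordant: bool = False
    seq: str = ""  # read bases in alignment orientation (may be empty for PSL)

    @property
    def start_key(self) -> tuple:
        """Alignment start used for the PCR-duplicate rule (5'-most sequenced base)."""
        if self.strand == "+":
            return (self.chrom, self.strand, self.blocks[0].g_start)
        return (self.chrom, self.strand, self.blocks[-1].g_end)


@dataclass
class SplitSignature:
    kind: str  # read_gap_deletion | ref_gap_insertion | flipped_tandem_dup
    chrom: str
    ref_start: int
    ref_end: int
    inserted_seq: str
    read_id: str
    strain: str
    junction_read_offsets: tuple[int, int]
    read_len: int
    start_key: tuple


# ---------------------------------------------------------------------------
# mapping


class GenomeIndex:
    """Exact k-mer index over all chromosomes."""

    def __init__(self, genome: SimGenome, k: int = 13, max_hits: int = 50):
        if k < 11:
            raise ValueError("seed length must be >= 11")
        self.genome = genome
        self.k = k
        self.max_hits = max_hits
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.chromosomes.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((chrom, i))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        h = self.index.get(kmer, ())
        return list(h) if len(h) <= self.max_hits else []


def _hamming(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def _extend_fwd(seq: str, ref: str, r0: int, g0: int) -> int:
    """Maximal exact extension length starting at read r0 / ref g0."""
    n = 0
    rl, gl = len(seq), len(ref)
    while r0 + n < rl and g0 + n < gl and seq[r0 + n] == ref[g0 + n]:
        n += 1
    return n


def _extend_back(seq: str, ref: str, r1: int, g1: int) -> int:
    """Maximal exact extension length ending at read r1 / ref g1 (exclusive)."""
    n = 0
    while r1 - n > 0 and g1 - n > 0 and seq[r1 - n - 1] == ref[g1 - n - 1]:
        n += 1
    return n


def _best_anchor(index, seq, from_end, tie_margin=2):
    """Longest unique maximal exact match anchored at one read end.

    Returns (chrom, ref_pos, length) where ref_pos is the block start
    (from_end=False) or block end (from_end=True).  Placements whose
    extension lengths differ by less than ``tie_margin`` are treated as
    ambiguous (returns None): around near-identical repeats a chance
    one-base extension can otherwise slip the anchor onto the wrong copy.
    """
    k = index.k
    kmer = seq[-k:] if from_end else seq[:k]
    best = None
    runner_up = 0
    for chrom, pos in index.hits(kmer):
        ref = index.genome.chromosomes[chrom]
        if from_end:
            n = _extend_back(seq, ref, len(seq), pos + k)
            cand = (n, chrom, pos + k)
        else:
            n = _extend_fwd(seq, ref, 0, pos)
            cand = (n, chrom, pos)
        if best is None:
            best = cand
        elif (cand[1], cand[2]) != (best[1], best[2]):
            if cand[0] > best[0]:
                runner_up = best[0]
                best = cand
            else:
                runner_up = max(runner_up, cand[0])
    if best is None or runner_up >= best[0] - tie_margin:
        return None
    n, chrom, pos = best
    return chrom, pos, n


def _try_concordant(index, seq, max_mm):
    L, k = len(seq), index.k
    best = None
    tie = False
    seen = set()
    for off in (0, L // 2, max(0, L - k)):
        for chrom, pos in index.hits(seq[off : off + k]):
            start = pos - off
            if start < 0 or (chrom, start) in seen:
                continue
            seen.add((chrom, start))
            ref = index.genome.chromosomes[chrom]
            if start + L > len(ref):
                continue
            mm = _hamming(seq, ref[start : start + L], max_mm)
            if mm <= max_mm:
                if best is None or mm < best[0]:
                    best, tie = (mm, chrom, start), False
                elif mm == best[0] and (chrom, start) != best[1:]:
                    tie = True
    if best is None or tie:
        return None
    return best


def _try_split(index, seq, max_gap):
    L = len(seq)
    pa = _best_anchor(index, seq, from_end=False)
    sa = _best_anchor(index, seq, from_end=True)
    if pa is None or sa is None or pa[0] != sa[0]:
        return None
    chrom = pa[0]
    s, p = pa[1], pa[2]
    e, q = sa[1], sa[2]
    m = L - p - q  # unaligned middle (negative = blocks overlap on the read)

    if m <= 0:
        # full cover: D > 0 is a colinear reference gap (deletion); D < 0
        # means the suffix block re-maps upstream of the prefix block's end
        # (the flipped pattern of a tandem-duplication junction)
        D = (e - L) - s
        if 1 <= abs(D) <= max_gap and D != 0:
            j = L - q  # leftmost junction placement within the ambiguity range
            return chrom, [
                Block(0, j, s, s + j),
                Block(j, L, e - (L - j), e),
            ]
        return None

    t = e - q
    gr = t - (s + p)  # reference gap between the blocks
    if gr <= 0:  # blocks adjacent/overlapping on reference: insertion
        o = -gr
        ilen = m + o
        j = t - s  # read offset of the (leftmost) insertion point
        if j < 0 or j + ilen > L:
            return None
        return chrom, [
            Block(0, j, s, t),
            Block(j + ilen, L, t, e),
        ]
    if gr <= max_gap:  # deletion with unaligned junction bases (complex end)
        return chrom, [
            Block(0, p, s, s + p),
            Block(p + m, L, t, e),
        ]
    return None


def map_reads(
    reads: ReadSet,
    genome: SimGenome,
    k: int = 13,
    max_gap: int = 10_000,
    max_mismatch_rate: float = 0.05,
    index: GenomeIndex | None = None,
) -> list[ReadAlignment]:
    """Map every read; unmappable reads are dropped (counted in the log)."""
    if index is None:
        index = GenomeIndex(genome, k=k)
    out: list[ReadAlignment] = []
    n_unmapped = n_ambiguous = 0
    for read in reads.reads:
        aln = None
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            L = len(seq)
            max_mm = int(max_mismatch_rate * L)
            hit = _try_concordant(index, seq, max_mm)
            if hit is not None:
                mm, chrom, start = hit
                aln = ReadAlignment(
                    read.read_id,
                    read.strain,
                    chrom,
                    strand,
                    L,
                    [Block(0, L, start, start + L)],
                    mismatches=mm,
                    concordant=True,
                )
                break
            split = _try_split(index, seq, max_gap)
            if split is not None:
                chrom, blocks = split
                aln = ReadAlignment(
                    read.read_id, read.strain, chrom, strand, L, blocks, seq=seq
                )
                break
        if aln is None:
            n_unmapped += 1
        else:
            out.append(aln)
    if n_unmapped:
        log.info("map_reads: %d reads unmapped or ambiguous", n_unmapped)
    return out


# ---------------------------------------------------------------------------
# signatures


def _left_norm_interval(ref: str, start: int, end: int) -> tuple[int, int]:
    while start > 0 and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def _left_norm_insertion(ref: str, pos: int, ins: str) -> tuple[int, str]:
    while pos > 0 and ins and ins[-1] == ref[pos - 1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def detect_split_signatures(
    alignments: list[ReadAlignment],
    genome: SimGenome,
    min_size: int = 25,
) -> list[SplitSignature]:
    """Emit one signature per qualifying two-block alignment.

    Geometry rule on the two reference blocks: a gap between them is a
    deletion; abutting blocks with unaligned read bases in between are an
    insertion; block 2 re-mapping upstream of block 1's end is the flipped
    pattern of a tandem-duplication junction.
    """
    out = []
    for aln in alignments:
        if aln.concordant or len(aln.blocks) != 2:
            continue
        b1, b2 = aln.blocks
        if b1.r_end > b2.r_start or b1.r_start != 0 or b2.r_end != aln.read_len:
            raise ValueError(f"malformed block list for read {aln.read_id}")
        ref = genome.chromosomes[aln.chrom]
        middle_seq = (
            aln.seq[b1.r_end : b2.r_start] if aln.seq else "N" * (b2.r_start - b1.r_end)
        )
        midpoints = (b1.r_end, b2.r_start)
        if b2.g_start < b1.g_end:  # tandem duplication
            if middle_seq:
                continue  # duplication junctions with extras are not called
            start, end = _left_norm_interval(ref, b2.g_start, b1.g_end)
            if end - start < min_size:
                continue
            kind, ins = "flipped_tandem_dup", ""
        elif b2.g_start > b1.g_end:  # deletion (extras allowed: complex end)
            if b2.g_start - b1.g_end < min_size:
                continue
            start, end = b1.g_end, b2.g_start
            ins = middle_seq
            if not ins:
                start, end = _left_norm_interval(ref, start, end)
            kind = "read_gap_deletion"
        else:  # insertion
            if len(middle_seq) < min_size:
                continue
            pos, ins = _left_norm_insertion(ref, b1.g_end, middle_seq)
            start = end = pos
            kind = "ref_gap_insertion"
        out.append(
            SplitSignature(
                kind,
                aln.chrom,
                start,
                end,
                ins,
                aln.read_id,
                aln.strain,
                midpoints,
                aln.read_len,
                aln.start_key,
            )
        )
    return out


# ---------------------------------------------------------------------------
# clustering and filtering


FILTERS = ("min_support", "pcr_duplicates", "read_end_margin", "mask", "te")


def cluster_and_filter(
    signatures: list[SplitSignature],
    genome: SimGenome,
    te: dict[str, list[tuple[int, int]]] | None = None,
    mask: dict[str, list[tuple[int, int]]] | None = None,
    read_end_margin: int = 10,
    min_support: int = 2,
    te_frac: float = 0.8,
    min_size: int = 25,
    exclude_tandem: bool = False,
    discard_log: list | None = None,
) -> list[CNVCall]:
    """Group signatures on identical breakpoints and apply the filter chain.

    A group survives iff it has >= ``min_support`` distinct reads whose
    junction sits >= ``read_end_margin`` bp from both read ends, the reads do
    not all share one alignment start (PCR-duplicate rule), both breakpoints
    fall in the euchromatin mask, and less than ``te_frac`` of the mutated
    sequence lies in annotated TEs.  Discards are logged with the failing
    filter.
    """
    if te is None:
        te = genome.te_annotation
    if mask is None:
        mask = genome.euchromatin_mask

    def in_mask(chrom, pos):
        ivs = mask.get(chrom)
        if not ivs:
            return not mask  # no mask at all: accept
        return any(s <= pos <= e for s, e in ivs)

    groups: dict[tuple, list[SplitSignature]] = defaultdict(list)
    for sig in signatures:
        j1, j2 = sig.junction_read_offsets
        if j1 < read_end_margin or sig.read_len - j2 < read_end_margin:
            continue  # junction too close to a read end to be trusted
        kind = {
            "read_gap_deletion": "deletion",
            "ref_gap_insertion": "insertion",
            "flipped_tandem_dup": "tandem_dup",
        }[sig.kind]
        groups[(sig.chrom, sig.ref_start, sig.ref_end, kind, sig.inserted_seq)].append(
            sig
        )

    calls = []
    for key in sorted(groups):
        chrom, start, end, kind, ins = key
        sigs = groups[key]
        reads_ids = {s.read_id for s in sigs}
        reason = None
        if len(reads_ids) < min_support:
            reason = "min_support"
        elif len({s.start_key for s in sigs}) < 2:
            reason = "pcr_duplicates"
        elif not (in_mask(chrom, start) and in_mask(chrom, end)):
            reason = "mask"
        else:
            iv = Interval(chrom, start, max(end, start + 1))
            te_ivs = [Interval(chrom, s, e) for s, e in te.get(chrom, [])]
            if kind == "insertion":
                frac = 1.0 if any(
                    t.start <= start < t.end for t in te_ivs
                ) else 0.0
            else:
                frac = coverage_fraction(iv, te_ivs)
            if frac >= te_frac:
                reason = "te"
        if reason is None and kind == "tandem_dup" and exclude_tandem:
            reason = "tandem_excluded"
        if reason is not None:
            if discard_log is not None:
                discard_log.append((key, reason))
            continue
        calls.append(
            CNVCall(
                chrom,
                start,
                end,
                kind,
                inserted_seq=ins,
                support=sorted((s.read_id, s.strain) for s in sigs),
                filters_passed=frozenset(FILTERS),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.kind))
    return calls


# ---------------------------------------------------------------------------
# PSL interoperability


PSL_HEADER_FIRST = "psLayout"
_PSL_NCOLS = 21


def import_psl(path: str) -> list[ReadAlignment]:
    """Read alignments from a PSL file (BLAT's tab-separated format).

    Handles the optional 5-line header; negative-strand block coordinates
    follow the PSL convention (query coordinates on the reversed query),
    which matches this package's internal representation.
    """
    out = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 5 if lines and lines[0].startswith(PSL_HEADER_FIRST) else 0
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != _PSL_NCOLS:
            raise ValueError(
                f"{path}:{lineno}: expected {_PSL_NCOLS} PSL columns, got {len(cols)}"
            )
        try:
            mismatches = int(cols[1])
            strand = cols[8]
            qname, qsize = cols[9], int(cols[10])
            tname = cols[13]
            nblocks = int(cols[17])
            sizes = [int(x) for x in cols[18].rstrip(",").split(",")]
            qstarts = [int(x) for x in cols[19].rstrip(",").split(",")]
            tstarts = [int(x) for x in cols[20].rstrip(",").split(",")]
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: malformed PSL field ({err})") from None
        if not (len(sizes) == len(qstarts) == len(tstarts) == nblocks):
            raise ValueError(f"{path}:{lineno}: block count mismatch")
        blocks = [
            Block(q, q + sz, t, t + sz) for sz, q, t in zip(sizes, qstarts, tstarts)
        ]
        concordant = nblocks == 1 and blocks[0].r_start == 0 and blocks[0].r_end == qsize
        out.append(
            ReadAlignment(
                qname,
                qname.split(".")[0],
                tname,
                strand[0],
                qsize,
                blocks,
                mismatches=mismatches,
                concordant=concordant,
            )
        )
    return out


def export_psl(alignments: list[ReadAlignment], genome: SimGenome, path: str) -> None:
    """Write alignments as PSL (no header)."""
    with open(path, "w") as fh:
        for a in alignments:
            matches = sum(b.r_end - b.r_start for b in a.blocks) - a.mismatches
            qgap = sum(
                b2.r_start - b1.r_end for b1, b2 in zip(a.blocks, a.blocks[1:])
            )
            tgap = sum(
                max(0, b2.g_start - b1.g_end)
                for b1, b2 in zip(a.blocks, a.blocks[1:])
            )
            tsize = len(genome.chromosomes[a.chrom])
            row = [
                matches,
                a.mismatches,
                0,
                0,
                sum(1 for b1, b2 in zip(a.blocks, a.blocks[1:]) if b2.r_start > b1.r_end),
                qgap,
                sum(1 for b1, b2 in zip(a.blocks, a.blocks[1:]) if b2.g_start > b1.g_end),
                tgap,
                a.strand,
                a.read_id,
                a.read_len,
                a.blocks[0].r_start,
                a.blocks[-1].r_end,
                a.chrom,
                tsize,
                a.blocks[0].g_start,
                a.blocks[-1].g_end,
                len(a.blocks),
                ",".join(str(b.r_end - b.r_start) for b in a.blocks) + ",",
                ",".join(str(b.r_start) for b in a.blocks) + ",",
                ",".join(str(b.g_start) for b in a.blocks) + ",",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")
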