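"""Detection of SSA/NAHR-capable homology between a CNV and its flanks.

Two filters mirror the hallmarks of the homology-driven pathways:

- type I: stretches >= 30 bp at >= 98% identity (single-strand annealing);
- type II: stretches >= 200 bp at >= 95% identity (non-allelic homologous
  recombination, or SSA).

Identity is measured over alignment columns, so gaps count against it.
The engine is seed-and-extend: exact 11-mer seeds are clustered, clusters
confined to one diagonal are resolved by an exact longest-qualifying-
segment scan, and clusters spanning several diagonals fall back to a local
affine-gap alignment (match +1, mismatch -1, gap open -2, extend -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import SimGenome

SEED_K = 11

TYPE_I = {"min_len": 30, "min_identity": 98.0}
TYPE_II = {"min_len": 200, "min_identity": 95.0}


@dataclass
class HomologyHit:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int  # alignment columns
    identity: float  # percent, gaps count against
    geometry: str = ""

    def overlaps(self, other: "HomologyHit") -> bool:
        return (
            self.a_start < other.a_end
            and other.a_start < self.a_end
            and self.b_start < other.b_end
            and other.b_start < self.b_end
        )


@dataclass
class FlankTriplet:
    cnv_seq: str
    five_flank: str
    three_flank: str
    provenance: str  # precise | imprecise
    coords: dict[str, tuple[str, int, int]]
    truncated: bool = False


# ---------------------------------------------------------------------------
# flank extraction


def extract_flanks(
    chrom: str,
    start: int,
    end: int,
    genome: SimGenome,
    mode: str = "precise",
    precise_flank: int = 200,
    imprecise_reach: int = 500,
    inward_frac: float = 0.25,
) -> FlankTriplet:
    """Extract CNV sequence plus 5'/3' flanks.

    Precise (split-read) coordinates take fixed flanks outside the event;
    imprecise (array-style) coordinates take flanks reaching
    ``imprecise_reach`` bp outward and ``inward_frac`` of the CNV length
    inward past each nominal breakpoint, overlapping the CNV ends.
    """
    ref = genome.chromosomes[chrom]
    if not 0 <= start <= end <= len(ref):
        raise ValueError("interval outside chromosome")
    if mode == "precise":
        f_lo, f_hi = max(0, start - precise_flank), start
        t_lo, t_hi = end, min(len(ref), end + precise_flank)
        truncated = (start - precise_flank < 0) or (end + precise_flank > len(ref))
    elif mode == "imprecise":
        inward = int(round(inward_frac * (end - start)))
        f_lo, f_hi = max(0, start - imprecise_reach), min(start + inward, end)
        t_lo, t_hi = max(end - inward, start), min(len(ref), end + imprecise_reach)
        truncated = (start - imprecise_reach < 0) or (
            end + imprecise_reach > len(ref)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FlankTriplet(
        ref[start:end],
        ref[f_lo:f_hi],
        ref[t_lo:t_hi],
        mode,
        {
            "cnv": (chrom, start, end),
            "five": (chrom, f_lo, f_hi),
            "three": (chrom, t_lo, t_hi),
        },
        truncated,
    )


# ---------------------------------------------------------------------------
# alignment engine


def _seed_matches(a: str, b: str, k: int = SEED_K):
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    out = []
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            out.append((i, j))
    return out


def _cluster_seeds(seeds, band=15, gap=100):
    """Group seeds into candidate regions by diagonal proximity."""
    seeds = sorted(seeds, key=lambda s: (s[1] - s[0], s[0]))
    clusters = []
    cur = []
    for s in seeds:
        if cur and (
            (s[1] - s[0]) - (cur[-1][1] - cur[-1][0]) > band
            or s[0] - cur[-1][0] > gap
        ):
            clusters.append(cur)
            cur = []
        cur.append(s)
    if cur:
        clusters.append(cur)
    return clusters


def _longest_qualifying_segment(mismatch, min_len, min_identity):
    """Longest segment with identity >= min_identity (ungapped boolean scan).

    ``mismatch`` is a boolean sequence; identity of a segment is the match
    fraction.  Weights matches 1-q and mismatches -q so qualifying segments
    are exactly those with non-negative weight sum; returns (start, end) of
    the longest one of length >= min_len, else None.
    """
    q = min_identity / 100.0
    n = len(mismatch)
    if n < min_len:
        return None
    prefix = [0.0] * (n + 1)
    for t, mm in enumerate(mismatch):
        prefix[t + 1] = prefix[t] + (-q if mm else 1.0 - q)
    # classic longest (r - l) with prefix[r] >= prefix[l]
    stack = [0]
    for l in range(1, n + 1):
        if prefix[l] < prefix[stack[-1]] - 1e-12:
            stack.append(l)
    best = None
    r = n
    while r > 0 and stack:
        if prefix[r] >= prefix[stack[-1]] - 1e-12:
            l = stack.pop()
            if r - l >= min_len and (best is None or r - l > best[1] - best[0]):
                best = (l, r)
        else:
            r -= 1
    return best


def _diagonal_hit(a, b, cluster, min_len, min_identity):
    d = cluster[0][1] - cluster[0][0]
    lo_i = max(0, -d)
    hi_i = min(len(a), len(b) - d)
    if hi_i - lo_i < min_len:
        return None
    mismatch = [a[i] != b[i + d] for i in range(lo_i, hi_i)]
    seg = _longest_qualifying_segment(mismatch, min_len, min_identity)
    if seg is None:
        return None
    l, r = seg
    matches = (r - l) - sum(mismatch[l:r])
    return HomologyHit(
        lo_i + l,
        lo_i + r,
        lo_i + l + d,
        lo_i + r + d,
        r - l,
        100.0 * matches / (r - l),
    )


MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -2, -1


def _sw_hit(a, b, box, min_len, min_identity):
    """Best local affine-gap alignment inside a bounding box."""
    ai, aj, bi, bj = box
    sa, sb = a[ai:aj], b[bi:bj]
    n, m = len(sa), len(sb)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up moves)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left moves)
    ptr = [[0] * (m + 1) for _ in range(n + 1)]
    best, bpos = 0.0, None
    for i in range(1, n + 1):
        ci = sa[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        Pi = ptr[i]
        for j in range(1, m + 1):
            Xi[j] = max(Mi1[j] + GAP_OPEN, Xi1[j] + GAP_EXTEND)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND)
            s = MATCH if ci == sb[j - 1] else MISMATCH
            diag = max(Mi1[j - 1], Xi1[j - 1], Yi1j1 := Y[i - 1][j - 1]) + s
            val = max(0.0, diag, Xi[j], Yi[j])
            Mi[j] = val
            if val == 0:
                Pi[j] = 0
            elif val == diag:
                Pi[j] = 1
            elif val == Xi[j]:
                Pi[j] = 2
            else:
                Pi[j] = 3
            if val > best:
                best, bpos = val, (i, j)
    if bpos is None:
        return None
    i, j = bpos
    cols = matches = 0
    end_i, end_j = i, j
    while i > 0 and j > 0 and ptr[i][j]:
        move = ptr[i][j]
        cols += 1
        if move == 1:
            matches += sa[i - 1] == sb[j - 1]
            i, j = i - 1, j - 1
        elif move == 2:
            i -= 1
        else:
            j -= 1
    if cols < min_len:
        return None
    identity = 100.0 * matches / cols
    if identity < min_identity:
        return None
    return HomologyHit(ai + i, ai + end_i, bi + j, bi + end_j, cols, identity)


def find_homology(
    a: str,
    b: str,
    min_len: int = 30,
    min_identity: float = 98.0,
    a_coord: tuple[str, int] | None = None,
    b_coord: tuple[str, int] | None = None,
) -> list[HomologyHit]:
    """Maximal non-redundant high-identity stretches shared by a and b.

    When both coordinates are known, hits lying on the genomic identity
    diagonal (the two pieces covering the same genomic bases) are removed
    as self-hits.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    hits: list[HomologyHit] = []
    for cluster in _cluster_seeds(_seed_matches(a, b)):
        diagonals = {j - i for i, j in cluster}
        if len(diagonals) == 1:
            hit = _diagonal_hit(a, b, cluster, min_len, min_identity)
        else:
            pad = 25
            box = (
                max(0, min(i for i, _ in cluster) - pad),
                min(len(a), max(i for i, _ in cluster) + SEED_K + pad),
                max(0, min(j for _, j in cluster) - pad),
                min(len(b), max(j for _, j in cluster) + SEED_K + pad),
            )
            hit = _sw_hit(a, b, box, min_len, min_identity)
        if hit is None:
            continue
        if a_coord is not None and b_coord is not None:
            ca, oa = a_coord
            cb, ob = b_coord
            if ca == cb and oa + hit.a_start == ob + hit.b_start:
                continue  # self-hit: same genomic bases in both pieces
        hits.append(hit)
    hits.sort(key=lambda h: (-h.length * h.identity, h.a_start))
    kept: list[HomologyHit] = []
    for h in hits:
        if not any(h.overlaps(k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.a_start, h.b_start))
    return kept


# ---------------------------------------------------------------------------
# mechanism support


GEOMETRIES = ("five_vs_cnv", "three_vs_cnv", "five_vs_three")


def low_complexity_fraction(seq: str, k: int = 5) -> float:
    """1 - (distinct k-mers / possible k-mers): high values flag repetitive
    or low-complexity sequence (a descriptive annotation, never a filter)."""
    if len(seq) < k:
        return 0.0
    total = len(seq) - k + 1
    distinct = len({seq[i : i + k] for i in range(total)})
    return 1.0 - distinct / total


@dataclass
class MechanismSupport:
    type_I: bool
    type_II: bool
    hits: list[tuple[str, str, HomologyHit]] = field(default_factory=list)
    # (geometry, filter name, hit); low-complexity annotation in hit order
    low_complexity: list[bool] = field(default_factory=list)


def classify_mechanism_support(
    chrom: str,
    start: int,
    end: int,
    genome: SimGenome,
    mode: str = "precise",
) -> MechanismSupport:
    """Scan the three geometries with both homology filters and set flags."""
    trip = extract_flanks(chrom, start, end, genome, mode=mode)
    pieces = {
        "five": (trip.five_flank, trip.coords["five"]),
        "three": (trip.three_flank, trip.coords["three"]),
        "cnv": (trip.cnv_seq, trip.coords["cnv"]),
    }
    pairs = [
        ("five_vs_cnv", "five", "cnv"),
        ("three_vs_cnv", "three", "cnv"),
        ("five_vs_three", "five", "three"),
    ]
    support = MechanismSupport(False, False)
    for filt_name, filt in (("type_I", TYPE_I), ("type_II", TYPE_II)):
        for geom, pa, pb in pairs:
            seq_a, (ca, sa_lo, _) = pieces[pa]
            seq_b, (cb, sb_lo, _) = pieces[pb]
            if not seq_a or not seq_b:
                continue
            found = find_homology(
                seq_a,
                seq_b,
                filt["min_len"],
                filt["min_identity"],
                a_coord=(ca, sa_lo),
                b_coord=(cb, sb_lo),
            )
            for h in found:
                h.geometry = geom
                support.hits.append((geom, filt_name, h))
                support.low_complexity.append(
                    low_complexity_fraction(seq_a[h.a_start : h.a_end]) > 0.5
                )
                if filt_name == "type_I":
                    support.type_I = True
                else:
                    support.type_II = True
    return support
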