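"""Breakpoint classification, microhomology quantification, and polarization.

Each call's supporting reads are realigned across the junction to recover
any inserted/deleted junction bases; breakpoint microhomology is measured
in three geometries:

- type I (mechanistically relevant): identity between the event-internal
  sequence and the breakpoint-adjacent external sequence on either side —
  the geometry in which one copy of the shared stretch becomes part of the
  event, the hallmark of microhomology-mediated repair;
- type II (control): identity between the two external flanks across the
  junction;
- type III (control): identity between the event's 5'-internal end and the
  5'-external flank end.

Types II and III cannot mediate the event and serve as the empirical
expectation for finding n identical nucleotides near a junction by chance.
Breakpoints are then assigned to four classes (blunt / microhomology /
complex / complex with microhomology) and polarized against an outgroup
genome under parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .core import CNVCall, SimGenome, lcp, lcs, revcomp
from .simulate import ReadSet
from .stats import two_proportion_test


@dataclass
class BreakpointAlignment:
    call: CNVCall
    per_read_extras: dict[str, str]
    junction_extra_bases: str
    inconsistent: bool
    n_anchored: int


@dataclass
class MicrohomologyProfile:
    type_I: int
    type_II: int
    type_III: int
    junction_extra_bases: str = ""


@dataclass
class BreakpointClass:
    label: str  # BLUNT | MICROHOMOLOGY | COMPLEX | COMPLEX_MH
    long_identity: bool  # type I microhomology > 20 bp (SSA-scale)


@dataclass
class Polarity:
    state: str
    # DELETION_IN_STRAIN / INSERTION_IN_STRAIN: the variant is real in the
    # sequenced strain; INSERTION_IN_REFERENCE / DELETION_IN_REFERENCE: the
    # outgroup shares the derived allele, so under parsimony the variant
    # belongs to the reference lineage.  UNPOLARIZED when the outgroup
    # alignment fails the quality gates.


# ---------------------------------------------------------------------------
# junction realignment


def _extend_with_budget(read: str, ref: str, r0: int, g0: int, direction: int,
                        per: int = 20) -> int:
    """Extend an anchored alignment allowing <=1 mismatch per ``per`` bp."""
    n = mism = 0
    while True:
        ri = r0 + direction * n if direction > 0 else r0 - 1 - n
        gi = g0 + direction * n if direction > 0 else g0 - 1 - n
        if ri < 0 or ri >= len(read) or gi < 0 or gi >= len(ref):
            break
        if read[ri] != ref[gi]:
            if (mism + 1) * per > n + 1:
                mism += 1
            else:
                break
        n += 1
    return n


def realign_junction(
    call: CNVCall, reads: ReadSet, genome: SimGenome, anchor_k: int = 15
) -> BreakpointAlignment:
    """Re-derive the junction content of each supporting read.

    Each read is anchored to the reference flanks on both sides of the
    junction (maximal extension with <=1 mismatch per 20 bp); the bases left
    unexplained by either flank are the junction extras.  Reads that imply
    different extras mark the call inconsistent.
    """
    if len({r for r, _ in call.support}) < 2:
        raise ValueError("realign_junction requires >=2 supporting reads")
    ref = genome.chromosomes[call.chrom]
    start, end = call.start, call.end
    seq_by_id = {r.read_id: r.seq for r in reads.reads}
    extras_by_read: dict[str, str] = {}
    for read_id, _strain in call.support:
        raw = seq_by_id.get(read_id)
        if raw is None:
            continue
        for seq in (raw, revcomp(raw)):
            L = len(seq)
            # anchor the read start inside the 5' flank
            window_lo = max(0, start - L - 20)
            a = ref.rfind(seq[:anchor_k], window_lo, start)
            if a < 0:
                continue
            left = _extend_with_budget(seq, ref, 0, a, +1)
            if a + left < start:  # flank anchor fails to reach the junction
                continue
            left_used = start - a  # read bases explained by the 5' flank
            b = ref.find(seq[-anchor_k:], end, end + L + 20)
            if b < 0:
                continue
            right = _extend_with_budget(seq, ref, L, b + anchor_k, -1)
            if (b + anchor_k) - right > end:  # anchor fails to reach junction
                continue
            # read index aligned to the reference position `end`
            idx_end = L - (b + anchor_k) + end
            extras_by_read[read_id] = seq[left_used : max(left_used, idx_end)]
            break
    variants = set(extras_by_read.values())
    consensus = max(variants, key=lambda v: sum(
        1 for e in extras_by_read.values() if e == v
    )) if variants else ""
    return BreakpointAlignment(
        call,
        extras_by_read,
        consensus,
        inconsistent=len(variants) > 1,
        n_anchored=len(extras_by_read),
    )


# ---------------------------------------------------------------------------
# microhomology


def measure_microhomology(
    call: CNVCall, genome: SimGenome, max_k: int = 50
) -> MicrohomologyProfile:
    """Measure breakpoint microhomology in the three junction geometries.

    Type I is max(prefix, suffix) identity between the event-internal
    segment and the adjacent external sequence — the two orientations a
    junction can shift through, not their sum.  All lengths are capped at
    ``max_k`` and at the available flank.
    """
    ref = genome.chromosomes[call.chrom]
    if call.kind == "insertion":
        seg = call.inserted_seq
        if not seg:
            raise ValueError("insertion call without sequence")
    else:
        seg = ref[call.start : call.end]
    before = ref[max(0, call.start - max_k) : call.start]
    after = ref[call.end : call.end + max_k]
    cap = min(max_k, len(seg))
    t1 = min(cap, max(lcp(seg, after), lcs(seg, before)))
    t2 = min(max_k, _anchored_cross(before, after))
    t3 = min(cap, _anchored_cross(before, seg))
    extras = call.inserted_seq if call.kind == "deletion" else ""
    return MicrohomologyProfile(t1, t2, t3, extras)


def _anchored_cross(before: str, after: str) -> int:
    """Longest k with before[-k:] == after[:k] (junction-anchored identity)."""
    n = min(len(before), len(after))
    k = 0
    while k < n and before[-1 - k] == after[k]:
        k += 1
    return k


MIN_MICROHOMOLOGY = 2  # below this, identical junction bases are noise


def classify_breakpoint(profile: MicrohomologyProfile) -> BreakpointClass:
    """Assign one of the four breakpoint classes.

    Microhomology requires >= 2 bp of type I identity (1 bp shows no excess
    over the chance geometries); complex ends are junctions carrying extra
    bases unexplained by either flank.
    """
    has_mh = profile.type_I >= MIN_MICROHOMOLOGY
    has_extra = bool(profile.junction_extra_bases)
    if has_extra:
        label = "COMPLEX_MH" if has_mh else "COMPLEX"
    else:
        label = "MICROHOMOLOGY" if has_mh else "BLUNT"
    return BreakpointClass(label, long_identity=profile.type_I > 20)


@dataclass
class ExcessTestResult:
    per_k: dict[int, tuple[int, int, float]]  # k -> (nI, nII+nIII, p)
    smallest_significant_k: int | None
    alpha: float


def microhomology_excess_test(
    profiles: list[MicrohomologyProfile], alpha: float = 0.05, max_k: int = 20
) -> ExcessTestResult:
    """Smallest microhomology length showing excess of type I over controls.

    For each k, compares the proportion of breakpoints with type I >= k
    against the pooled proportion of type II / type III >= k (two chance
    geometries per breakpoint) with a two-proportion test.
    """
    n = len(profiles)
    if n < 30:
        raise ValueError("excess test needs >= 30 profiles")
    per_k = {}
    smallest = None
    for k in range(1, max_k + 1):
        n1 = sum(p.type_I >= k for p in profiles)
        n23 = sum(p.type_II >= k for p in profiles) + sum(
            p.type_III >= k for p in profiles
        )
        if n1 == 0 and n23 == 0:
            break
        res = two_proportion_test(n1, n, n23, 2 * n)
        per_k[k] = (n1, n23, res.p_value)
        if (
            smallest is None
            and res.p_value < alpha
            and n1 / n > n23 / (2 * n)
        ):
            smallest = k
    return ExcessTestResult(per_k, smallest, alpha)


# ---------------------------------------------------------------------------
# polarization


def _identity(query: str, target: str) -> tuple[float, int]:
    res = edlib.align(query, target, mode="HW", task="distance")
    d = res["editDistance"]
    return 1.0 - d / len(query), d


def polarize(
    call: CNVCall,
    outgroup: SimGenome | None,
    genome: SimGenome,
    window: int = 500,
    junction_tol: int = 10,
    min_identity: float = 0.70,
) -> Polarity:
    """Assign ancestral/derived state by parsimony against an outgroup.

    If the outgroup carries the reference (ancestral-present) allele the
    call stands; if it shares the derived junction with similar breakpoints
    the variant is re-assigned to the reference lineage.  Calls whose flank
    alignment drops below ``min_identity``, or where both alleles align
    equally well, stay unpolarized.
    """
    if call.kind == "insertion":
        stands, flipped = "INSERTION_IN_STRAIN", "DELETION_IN_REFERENCE"
    else:
        stands, flipped = "DELETION_IN_STRAIN", "INSERTION_IN_REFERENCE"
    if outgroup is None:
        return Polarity("UNPOLARIZED")
    ref = genome.chromosomes[call.chrom]
    start, end = call.start, call.end
    left = ref[max(0, start - window) : start]
    right = ref[end : end + window]
    segment = ref[start:end] if call.kind != "insertion" else ""
    anc = left + segment + right
    der = left + call.inserted_seq + right

    target = None
    for chrom_seq in outgroup.chromosomes.values():
        res = edlib.align(left, chrom_seq, mode="HW", task="locations")
        ident = 1.0 - res["editDistance"] / max(1, len(left))
        if ident >= min_identity:
            loc = res["locations"][0]
            lo = max(0, loc[0] - 50)
            hi = loc[1] + 1 + len(segment) + len(call.inserted_seq) + window + 50
            target = chrom_seq[lo:hi]
            break
    if target is None:
        return Polarity("UNPOLARIZED")

    id_anc, d_anc = _identity(anc, target)
    id_der, d_der = _identity(der, target)
    if max(id_anc, id_der) < min_identity or d_anc == d_der:
        return Polarity("UNPOLARIZED")
    if d_der < d_anc:
        # outgroup looks derived; require similar breakpoints via a short
        # junction-spanning probe (edit distance bounds the junction offset)
        probe = ref[max(0, start - 25) : start] + call.inserted_seq + ref[end : end + 25]
        _, d_probe = _identity(probe, target)
        if d_probe <= junction_tol:
            return Polarity(flipped)
        return Polarity("UNPOLARIZED")
    return Polarity(stands)


# ---------------------------------------------------------------------------
# recurrence and complexity


@dataclass
class RegionReport:
    chrom: str
    start: int
    end: int
    calls: list[CNVCall]
    recurrent: bool
    complex_strains: list[str] = field(default_factory=list)


def find_recurrent_and_complex(
    calls: list[CNVCall], proximity: int = 500
) -> list[RegionReport]:
    """Group calls into regions; flag recurrence and within-strain complexity.

    A region is recurrent when different strains carry independent but
    overlapping CNVs (distinct junctions); complex when one strain carries
    several distinct junctions within ``proximity`` bp (one mutational event
    with multiple breakpoints).
    """
    reports = []
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in sorted(by_chrom.items()):
        cs.sort(key=lambda c: (c.start, c.end))
        cluster: list[CNVCall] = []
        hi = None
        for c in cs + [None]:
            if c is not None and (hi is None or c.start <= hi + proximity):
                cluster.append(c)
                hi = max(hi if hi is not None else c.end, c.end)
                continue
            if cluster:
                reports.append(_analyse_cluster(chrom, cluster, proximity))
            if c is not None:
                cluster, hi = [c], c.end
    return reports


def _strains(c: CNVCall) -> frozenset:
    return frozenset(s for _, s in c.support)


def _analyse_cluster(chrom, cluster, proximity) -> RegionReport:
    recurrent = False
    for i, a in enumerate(cluster):
        for b in cluster[i + 1 :]:
            if a.key() == b.key():
                continue
            overlap = a.start < max(b.end, b.start + 1) and b.start < max(
                a.end, a.start + 1
            )
            if overlap and _strains(a) != _strains(b) and (_strains(a) | _strains(b)):
                recurrent = True
    complex_strains = []
    strains = set().union(*(_strains(c) for c in cluster))
    for s in sorted(strains):
        junctions = sorted(
            {c.key() for c in cluster if s in _strains(c)},
            key=lambda k: k[1],
        )
        for j1, j2 in zip(junctions, junctions[1:]):
            if j2[1] - j1[2] <= proximity:
                complex_strains.append(s)
                break
    return RegionReport(
        chrom,
        min(c.start for c in cluster),
        max(max(c.end, c.start) for c in cluster),
        cluster,
        recurrent,
        complex_strains,
    )
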