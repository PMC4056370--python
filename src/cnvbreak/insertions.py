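"""Origin of inserted sequence: tandem duplication, repeat expansion, filler.

An insertion is a *tandem duplication* when a full-length high-identity copy
of the inserted sequence exists in the nearby reference, a *repeat
expansion* when it extends an adjacent short-repeat tract in phase, and
*filler DNA* otherwise — novel sequence attributed to untemplated synthesis
and/or the copying of short stretches from the neighbourhood during
end-joining repair.  The neighbourhood matcher quantifies how many inserted
nucleotides can be attributed to short direct or inverted repeats in
windows of 30/60/90/120 bp around the insertion point, and the shuffle
machinery builds size-matched coordinate-shuffled controls for the
enrichment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .core import CNVCall, SimGenome, revcomp
from .stats import TestResult, fisher_exact, wilcoxon_rank_sum

WINDOWS = (30, 60, 90, 120)


@dataclass
class InsertionOrigin:
    label: str  # TANDEM_DUP | REPEAT_EXPANSION | FILLER
    evidence: dict = field(default_factory=dict)


@dataclass
class MatchSegment:
    ins_start: int
    ins_end: int
    flank: str  # five | three
    flank_start: int
    flank_end: int
    orientation: str  # forward | reverse


@dataclass
class NeighborhoodMatch:
    window: int
    matched_nt: int
    length: int
    segments: list[MatchSegment]

    @property
    def matched_fraction(self) -> float:
        return self.matched_nt / self.length if self.length else 0.0


# ---------------------------------------------------------------------------
# origin classification


def _is_repeat_of(seq: str, unit: str) -> bool:
    """True if seq is >=2 copies of unit, allowing a truncated final copy."""
    if len(seq) < 2 * len(unit):
        return False
    reps = (unit * (len(seq) // len(unit) + 1))[: len(seq)]
    return seq == reps


def classify_insertion_origin(
    ins: CNVCall,
    genome: SimGenome,
    search_radius: int = 1000,
    min_identity: float = 0.90,
    max_unit: int = 6,
) -> InsertionOrigin:
    """Classify one insertion, checking tandem duplication first, then
    repeat expansion, then falling back to filler."""
    seq = ins.inserted_seq
    if not seq:
        raise ValueError("insertion call has no inserted sequence")
    ref = genome.chromosomes[ins.chrom]
    # short-unit expansions are checked first: an insertion extending an
    # adjacent tract in phase is also, trivially, a full-length local copy,
    # so testing tandem duplication first would shadow every expansion
    for u_len in range(1, max_unit + 1):
        unit = seq[:u_len]
        if not _is_repeat_of(seq, unit):
            continue
        right = ref[ins.end : ins.end + u_len]
        left = ref[max(0, ins.start - u_len) : ins.start]
        if right == unit or left == unit:
            return InsertionOrigin(
                "REPEAT_EXPANSION",
                {"unit": unit, "copies": len(seq) / u_len},
            )
    lo = max(0, ins.start - search_radius)
    # search the two flanking windows separately: reference-resident events
    # (polarized insertions in the reference, shuffled controls) occupy
    # [start, end) and must never match their own footprint
    windows = [
        (lo, ref[lo : ins.start]),
        (ins.end, ref[ins.end : ins.end + search_radius]),
    ]
    max_dist = int(len(seq) * (1 - min_identity))
    for w_lo, window in windows:
        for orientation, query in (("forward", seq), ("reverse", revcomp(seq))):
            if len(window) < len(seq) - max_dist:
                continue
            res = edlib.align(query, window, mode="HW", task="locations", k=max_dist)
            if res["editDistance"] != -1:
                s, e = res["locations"][0]
                return InsertionOrigin(
                    "TANDEM_DUP",
                    {
                        "copy_interval": (w_lo + s, w_lo + e + 1),
                        "identity": 1 - res["editDistance"] / len(seq),
                        "orientation": orientation,
                    },
                )
    return InsertionOrigin("FILLER", {})


# ---------------------------------------------------------------------------
# neighbourhood matching


def _maximal_matches(a: str, b: str, min_match: int):
    """All maximal exact matches >= min_match between a and b (forward)."""
    out = []
    la, lb = len(a), len(b)
    if la < min_match or lb < min_match:
        return out
    # run[j] = length of the common suffix of a[:i+1], b[:j+1] (rolled row DP)
    prev = [0] * (lb + 1)
    for i in range(la):
        cur = [0] * (lb + 1)
        ai = a[i]
        for j in range(lb):
            if ai == b[j]:
                cur[j + 1] = prev[j] + 1
        prev = cur
        for j in range(lb):
            n = cur[j + 1]
            if n >= min_match and (
                i == la - 1 or j == lb - 1 or a[i + 1] != b[j + 1]
            ):
                out.append((i - n + 1, i + 1, j - n + 1, j + 1))  # half-open
    return out


def match_neighborhood(
    ins_seq: str,
    five_flank: str,
    three_flank: str,
    min_match: int = 7,
    both_strands: bool = True,
) -> NeighborhoodMatch:
    """Coverage of the insertion by maximal exact matches to its flanks.

    ``matched_nt`` is the union coverage (no double counting); the recorded
    segments are a greedy longest-first non-overlapping tiling of the
    insertion.  With ``both_strands`` the reverse complement of the
    insertion is matched as well (inverted repeats).
    """
    window = max(len(five_flank), len(three_flank))
    raw: list[tuple[int, MatchSegment]] = []
    for flank_name, flank in (("five", five_flank), ("three", three_flank)):
        queries = [("forward", ins_seq)]
        if both_strands:
            queries.append(("reverse", revcomp(ins_seq)))
        for orientation, query in queries:
            for qs, qe, fs, fe in _maximal_matches(query, flank, min_match):
                if orientation == "reverse":
                    qs, qe = len(ins_seq) - qe, len(ins_seq) - qs
                raw.append(
                    (
                        qe - qs,
                        MatchSegment(qs, qe, flank_name, fs, fe, orientation),
                    )
                )
    covered = np.zeros(len(ins_seq), dtype=bool)
    for _, seg in raw:
        covered[seg.ins_start : seg.ins_end] = True
    segments = []
    tiled = np.zeros(len(ins_seq), dtype=bool)
    for _, seg in sorted(raw, key=lambda t: (-t[0], t[1].ins_start)):
        if not tiled[seg.ins_start : seg.ins_end].any():
            tiled[seg.ins_start : seg.ins_end] = True
            segments.append(seg)
    return NeighborhoodMatch(
        window, int(covered.sum()), len(ins_seq), segments
    )


def neighborhood_flanks(
    call: CNVCall, genome: SimGenome, window: int
) -> tuple[str, str, str]:
    """Insertion sequence plus its 5'/3' flanks trimmed to ``window`` bp.

    Works for real insertions (zero-length footprint) and shuffled controls
    (whose pseudo-inserted sequence occupies ``[start, end)``; flanks are
    taken outside the footprint).
    """
    ref = genome.chromosomes[call.chrom]
    five = ref[max(0, call.start - window) : call.start]
    three = ref[call.end : call.end + window]
    return call.inserted_seq, five, three


# ---------------------------------------------------------------------------
# shuffled controls


def shuffle_controls(
    insertions: list[CNVCall],
    genome: SimGenome,
    factor: int = 10,
    seed: int = 0,
    margin: int = 200,
) -> list[CNVCall]:
    """Size-preserving coordinate-shuffled pseudo-insertions.

    For each real insertion, ``factor`` pseudo-insertions of identical size
    are placed uniformly at random on the same chromosome inside the
    euchromatin mask; the pseudo-inserted sequence is the reference sequence
    at the shuffled location.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for ins in insertions:
        size = len(ins.inserted_seq)
        ref = genome.chromosomes[ins.chrom]
        mask = genome.euchromatin_mask.get(ins.chrom) or [(0, len(ref))]
        spans = [
            (max(s, margin), min(e, len(ref) - margin) - size)
            for s, e in mask
        ]
        spans = [(lo, hi) for lo, hi in spans if hi > lo]
        if not spans:
            import logging

            logging.getLogger(__name__).warning(
                "shuffle_controls: no room for a %d bp control on %s",
                size,
                ins.chrom,
            )
            continue
        widths = np.array([hi - lo for lo, hi in spans], dtype=float)
        for _ in range(factor):
            si = int(rng.choice(len(spans), p=widths / widths.sum()))
            lo, hi = spans[si]
            p = int(rng.integers(lo, hi))
            out.append(
                CNVCall(
                    ins.chrom, p, p + size, "insertion", inserted_seq=ref[p : p + size]
                )
            )
    return out


# ---------------------------------------------------------------------------
# enrichment tests


@dataclass
class WindowTestResult:
    window: int
    rank_sum: TestResult
    count_test: TestResult
    real_with_match: int
    control_with_match: int
    n_real: int
    n_control: int


def filler_enrichment_tests(
    real: list[NeighborhoodMatch], controls: list[NeighborhoodMatch]
) -> WindowTestResult:
    """Compare real insertions against shuffled controls for one window.

    (a) rank-sum test on matched fractions; (b) exact 2x2 test on the counts
    of insertions with at least one neighbourhood match.
    """
    if not real or not controls:
        raise ValueError("both real and control match lists must be non-empty")
    windows = {m.window for m in real} | {m.window for m in controls}
    if len(windows) != 1:
        raise ValueError("mixed window sizes in one test")
    rf = [m.matched_fraction for m in real]
    cf = [m.matched_fraction for m in controls]
    if all(v == 0 for v in rf + cf):
        flat = TestResult(
            "degenerate", 0.0, 1.0, sizes=(len(rf), len(cf)),
            flagged="all matched fractions zero",
        )
        return WindowTestResult(
            windows.pop(), flat, flat, 0, 0, len(real), len(controls)
        )
    rank = wilcoxon_rank_sum(rf, cf)
    r_with = sum(m.matched_nt > 0 for m in real)
    c_with = sum(m.matched_nt > 0 for m in controls)
    count = fisher_exact(
        [[r_with, len(real) - r_with], [c_with, len(controls) - c_with]]
    )
    return WindowTestResult(
        windows.pop(), rank, count, r_with, c_with, len(real), len(controls)
    )
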