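"""Non-B DNA detectors, breakpoint regions, and enrichment machinery."""

import numpy as np
import pytest
from scipy import stats as sps

from cnvbreak.core import CNVCall, SimGenome, random_dna
from cnvbreak.nonb import (
    BreakpointRegion,
    breakpoint_regions,
    enrichment_test,
    scan_direct_repeats,
    scan_g4,
    scan_inverted_repeats,
    scan_mirror_repeats,
    scan_nonb,
    scan_zdna,
    shuffle_regions,
)

from conftest import make_seq

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# brute-force oracles (independent enumeration; see also test_acceptance)


def oracle_zdna(seq, min_tract=10):
    dinucs = {"GC", "CG", "GT", "TG", "AC", "CA"}
    found = []
    n = len(seq)
    for i in range(n):
        j = i + min_tract
        while j <= n:
            ok = all(seq[t : t + 2] in dinucs for t in range(i, j - 1))
            if not ok:
                break
            found.append((i, j))
            j += 1
    # maximal, non-nested
    out = []
    for i, j in sorted(found, key=lambda x: (x[0], -(x[1] - x[0]))):
        if not any(a <= i and j <= b for a, b in out if (a, b) != (i, j)):
            out.append((i, j))
    return sorted(set(out) - {x for x in out for y in out if x != y and y[0] <= x[0] and x[1] <= y[1]})


def oracle_palindromic(seq, min_arm, max_spacer, mirror):
    found = set()
    n = len(seq)
    for i in range(n):
        for arm in range(min_arm, (n - i) // 2 + 1):
            for g in range(max_spacer + 1):
                j = i + 2 * arm + g
                if j > n:
                    break
                a1 = seq[i : i + arm]
                a2 = seq[i + arm + g : j]
                target = a1[::-1] if mirror else "".join(
                    COMP[c] for c in reversed(a1)
                )
                if a2 == target:
                    # maximality: cannot extend outward
                    ext = (
                        i > 0
                        and j < n
                        and (
                            seq[i - 1] == seq[j]
                            if mirror
                            else seq[i - 1] == COMP[seq[j]]
                        )
                    )
                    if not ext:
                        found.add((i, j))
    return _nonnested(found)


def oracle_direct(seq, min_unit=10, max_spacer=8):
    found = set()
    n = len(seq)
    for i in range(n):
        for unit in range(min_unit, (n - i) // 2 + 1):
            for g in range(max_spacer + 1):
                j = i + 2 * unit + g
                if j > n:
                    break
                if seq[i : i + unit] == seq[i + unit + g : j]:
                    found.add((i, j))
    return _nonnested(found)


def _nonnested(found):
    out = []
    for i, j in sorted(found, key=lambda x: (x[0], -(x[1] - x[0]))):
        if not any(a <= i and j <= b for a, b in found if (a, b) != (i, j)):
            out.append((i, j))
    return sorted(out)


class TestDetectors:
    def test_g4_example(self):
        (m,) = scan_g4("GGGTTGGGTTGGGTTGGG")
        assert (m.start, m.end, m.strand) == (0, 18, "+")

    def test_g4_minus_strand(self):
        (m,) = scan_g4("CCCTTCCCTTCCCTTCCC")
        assert m.strand == "-"

    def test_g4_long_loop_breaks_chain(self):
        assert scan_g4("GGG" + "A" * 8 + "GGGTTGGGTTGGG") == []

    def test_zdna_example(self):
        (m,) = scan_zdna("GCGCGCGCGCGC")
        assert (m.start, m.end) == (0, 12)

    def test_zdna_short_tract_ignored(self):
        assert scan_zdna("GCGCGCGC") == []  # 8 < 10

    def test_at_alternation_is_not_zdna(self):
        assert scan_zdna("ATATATATATATAT") == []

    def test_scan_rejects_ambiguous_bases(self):
        with pytest.raises(ValueError):
            scan_nonb("ACGTNACGT")

    @pytest.mark.parametrize("seed", range(40))
    def test_ir_matches_bruteforce(self, seed):
        seq = make_seq(3000 + seed, 150)
        got = [(m.start, m.end) for m in scan_inverted_repeats(seq)]
        assert got == oracle_palindromic(seq, 10, 8, mirror=False)

    @pytest.mark.parametrize("seed", range(40))
    def test_mr_matches_bruteforce(self, seed):
        seq = make_seq(4000 + seed, 150)
        got = [(m.start, m.end) for m in scan_mirror_repeats(seq)]
        assert got == oracle_palindromic(seq, 10, 8, mirror=True)

    @pytest.mark.parametrize("seed", range(40))
    def test_dr_matches_bruteforce(self, seed):
        seq = make_seq(5000 + seed, 150)
        got = [(m.start, m.end) for m in scan_direct_repeats(seq)]
        assert got == oracle_direct(seq)

    def test_planted_ir_found(self):
        arm = make_seq(6001, 12)
        seq = make_seq(6002, 50) + arm + "ACG" + "".join(
            COMP[c] for c in reversed(arm)
        ) + make_seq(6003, 50)
        hits = scan_inverted_repeats(seq)
        assert any(m.descriptor["arm"] >= 12 for m in hits)


class TestRegions:
    def test_two_225bp_regions_per_deletion(self, mixed_sim):
        call = CNVCall("chr1", 30_000, 30_100, "deletion")
        regions = breakpoint_regions([call], mixed_sim["reference"])
        assert len(regions) == 2
        for r in regions:
            lo, hi = r.span
            assert hi - lo == 225
            wlo, whi = r.test_window
            assert whi - wlo == 50

    def test_short_deletion_truncates_inner(self, mixed_sim):
        call = CNVCall("chr1", 30_000, 30_030, "deletion")
        regions = breakpoint_regions([call], mixed_sim["reference"])
        assert all(r.inner == 15 and r.truncated for r in regions)

    def test_insertions_skipped(self, mixed_sim):
        call = CNVCall("chr1", 30_000, 30_000, "insertion", inserted_seq="A" * 30)
        assert breakpoint_regions([call], mixed_sim["reference"]) == []

    def test_span_coordinate_orientation(self):
        r = BreakpointRegion("chr1", 1000, True, 25, 200)
        assert r.span_coord(1000) == 25.0  # the junction itself
        assert r.span_coord(1024) == 1.0  # deep inside the CNV
        assert r.span_coord(801) == 224.0  # far into the flank


@pytest.fixture(scope="module")
def motif_genome():
    rng = np.random.default_rng(77)
    seq = list(random_dna(rng, 120_000))
    motif = "GGGTTAGGGTTAGGGTTAGGG"
    for _ in range(250):
        p = int(rng.integers(500, len(seq) - 500))
        seq[p : p + len(motif)] = motif
    return SimGenome({"chr1": "".join(seq)})


class TestEnrichment:

    def test_planted_everywhere_gives_infinite_odds(self):
        rng = np.random.default_rng(78)
        motif = "GGGTTAGGGTTAGGGTTAGGG"
        seq = list(random_dna(rng, 120_000))
        calls = []
        for i in range(35):
            s = 2000 + i * 3000
            # plant a G4 straddling each 5' junction test window
            seq[s - 10 : s - 10 + len(motif)] = motif
            calls.append(CNVCall("chr1", s, s + 100, "deletion"))
        genome = SimGenome({"chr1": "".join(seq)})
        regions = [
            r for r in breakpoint_regions(calls, genome) if r.inside_right
        ]
        res = enrichment_test(
            regions, genome, control_factor=10, seed=1, classes=("G4",),
            histograms=False,
        )
        assert res.odds_ratio == float("inf")
        assert res.p_value < 1e-6

    def test_control_counts(self, motif_genome):
        calls = [
            CNVCall("chr1", 3000 + 2500 * i, 3100 + 2500 * i, "deletion")
            for i in range(20)
        ]
        regions = breakpoint_regions(calls, motif_genome)
        rng = np.random.default_rng(5)
        controls = shuffle_regions(regions, motif_genome, 10, rng)
        assert len(controls) == 10 * len(regions)

    def test_determinism(self, motif_genome):
        calls = [
            CNVCall("chr1", 3000 + 2500 * i, 3100 + 2500 * i, "deletion")
            for i in range(10)
        ]
        regions = breakpoint_regions(calls, motif_genome)
        a = enrichment_test(regions, motif_genome, seed=9, histograms=False)
        b = enrichment_test(regions, motif_genome, seed=9, histograms=False)
        assert a.table == b.table and a.p_value == b.p_value

    def test_shuffled_controls_flat_histogram(self, motif_genome):
        calls = [
            CNVCall("chr1", 3000 + 2300 * i, 3100 + 2300 * i, "deletion")
            for i in range(45)
        ]
        regions = breakpoint_regions(calls, motif_genome)
        res = enrichment_test(
            regions, motif_genome, control_factor=10, seed=13, classes=("G4",)
        )
        hist = res.histogram_control
        assert hist.sum() > 30
        chi = sps.chisquare(hist)
        assert chi.pvalue > 0.01  # uniform positional distribution
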