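"""Microhomology measurement, class assignment, polarization, recurrence."""

import numpy as np
import pytest

from cnvbreak.classify import (
    MicrohomologyProfile,
    classify_breakpoint,
    find_recurrent_and_complex,
    measure_microhomology,
    microhomology_excess_test,
    polarize,
    realign_junction,
)
from cnvbreak.core import CNVCall, SimGenome, lcp, lcs, random_dna
from cnvbreak.simulate import ReadSet, SimRead, generate_outgroup

from conftest import make_seq


def oracle_type_I(ref, start, end, ins="", max_k=50):
    """Brute-force junction scan, independent of the implementation."""
    seg = ins if start == end else ref[start:end]
    best = 0
    for k in range(1, min(max_k, len(seg)) + 1):
        if end + k <= len(ref) and seg[:k] == ref[end : end + k]:
            best = max(best, k)
        if start - k >= 0 and seg[-k:] == ref[start - k : start]:
            best = max(best, k)
    return best


class TestMeasure:
    def test_worked_example(self):
        genome = SimGenome({"chr1": "TTTTACGGGGACTTTT"})
        call = CNVCall("chr1", 4, 10, "deletion")
        prof = measure_microhomology(call, genome)
        assert prof.type_I == 2  # "AC" shared between segment start and 3' flank

    def test_blunt_implant_measures_zero(self, mixed_sim):
        ref = mixed_sim["reference"]
        for ev in mixed_sim["truth"].events:
            if ev.kind == "deletion" and ev.signature == "blunt":
                call = CNVCall(ev.chrom, ev.start, ev.end, "deletion")
                assert measure_microhomology(call, ref).type_I == 0

    def test_implanted_k_recovered(self):
        from cnvbreak.simulate import CNVSpec, generate_genome, implant_cnvs

        base = generate_genome(1, [40_000], seed=51)
        ref, _, truth = implant_cnvs(
            base, [CNVSpec("deletion", 50, "microhomology", mh_k=7)], ["sA"], seed=52
        )
        ev = truth.events[0]
        prof = measure_microhomology(
            CNVCall(ev.chrom, ev.start, ev.end, "deletion"), ref
        )
        assert prof.type_I == 7

    def test_matches_oracle_on_random_junctions(self):
        rng = np.random.default_rng(60)
        ref = random_dna(rng, 5000)
        genome = SimGenome({"chr1": ref})
        for _ in range(300):
            start = int(rng.integers(100, 4000))
            end = start + int(rng.integers(25, 400))
            call = CNVCall("chr1", start, end, "deletion")
            assert measure_microhomology(call, genome).type_I == oracle_type_I(
                ref, start, end
            )

    def test_insertion_microhomology(self):
        rng = np.random.default_rng(61)
        ref = random_dna(rng, 2000)
        genome = SimGenome({"chr1": ref})
        pos = 800
        ins = ref[pos : pos + 4] + "A" + (
            "C" if ref[pos + 4] != "C" else "G"
        ) + random_dna(rng, 20)
        call = CNVCall("chr1", pos, pos, "insertion", inserted_seq=ins)
        assert measure_microhomology(call, genome).type_I >= 4

    def test_edge_event_uses_available_flank(self):
        genome = SimGenome({"chr1": make_seq(3, 200)})
        call = CNVCall("chr1", 10, 60, "deletion")
        prof = measure_microhomology(call, genome, max_k=50)
        assert prof.type_I >= 0  # truncated flank, no crash


class TestClassRules:
    @pytest.mark.parametrize(
        "t1,extra,label",
        [
            (0, "", "BLUNT"),
            (1, "", "BLUNT"),
            (2, "", "MICROHOMOLOGY"),
            (0, "GAT", "COMPLEX"),
            (1, "GAT", "COMPLEX"),
            (3, "GATTC", "COMPLEX_MH"),
        ],
    )
    def test_four_classes(self, t1, extra, label):
        bc = classify_breakpoint(MicrohomologyProfile(t1, 0, 0, extra))
        assert bc.label == label

    def test_long_identity_flag(self):
        assert classify_breakpoint(MicrohomologyProfile(21, 0, 0)).long_identity
        assert not classify_breakpoint(MicrohomologyProfile(20, 0, 0)).long_identity


class TestExcessTest:
    def test_no_excess_when_all_zero(self):
        profiles = [MicrohomologyProfile(0, 0, 0) for _ in range(50)]
        res = microhomology_excess_test(profiles)
        assert res.smallest_significant_k is None

    def test_identical_counts_give_p_near_one(self):
        profiles = [MicrohomologyProfile(3, 3, 3) for _ in range(60)]
        res = microhomology_excess_test(profiles)
        assert all(p > 0.5 for _, _, p in res.per_k.values())
        assert res.smallest_significant_k is None

    def test_planted_excess_detected_at_or_below_k(self):
        rng = np.random.default_rng(62)
        genome = SimGenome({"chr1": random_dna(rng, 300_000)})
        profiles = []
        ref = genome.chromosomes["chr1"]
        pos = 500
        while len(profiles) < 200 and pos < 295_000:
            start, end = pos, pos + 60
            seg = ref[start:end]
            # plant type I = 3 by rewriting the 3' flank
            genome.chromosomes["chr1"] = (
                ref[:end] + seg[:3] + ref[end + 3 :]
            )
            ref = genome.chromosomes["chr1"]
            call = CNVCall("chr1", start, end, "deletion")
            profiles.append(measure_microhomology(call, genome))
            pos += 1000
        res = microhomology_excess_test(profiles)
        assert res.smallest_significant_k is not None
        assert res.smallest_significant_k <= 3

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            microhomology_excess_test([MicrohomologyProfile(0, 0, 0)] * 10)


class TestRealign:
    def _mk_reads(self, genome, call, extras_list):
        ref = genome.chromosomes[call.chrom]
        reads, support = [], []
        for i, extras in enumerate(extras_list):
            seq = ref[call.start - 50 : call.start] + extras + ref[
                call.end : call.end + 50
            ]
            reads.append(SimRead(f"r{i}", "sA", seq, call.chrom, 0, len(seq), "+"))
            support.append((f"r{i}", "sA"))
        call.support = support
        return ReadSet(reads, 105.0, 0.0)

    def test_clean_deletion_empty_extras(self, mixed_sim):
        ref = mixed_sim["reference"]
        for ev in mixed_sim["truth"].events:
            if ev.signature == "blunt" and ev.kind == "deletion":
                call = CNVCall(ev.chrom, ev.start, ev.end, "deletion")
                reads = self._mk_reads(ref, call, ["", ""])
                ra = realign_junction(call, reads, ref)
                assert ra.junction_extra_bases == "" and not ra.inconsistent

    def test_inserted_bases_recovered(self, mixed_sim):
        ref = mixed_sim["reference"]
        ev = next(e for e in mixed_sim["truth"].events if e.signature == "blunt")
        call = CNVCall(ev.chrom, ev.start, ev.end, "deletion")
        reads = self._mk_reads(ref, call, ["GATCC", "GATCC"])
        ra = realign_junction(call, reads, ref)
        assert len(ra.junction_extra_bases) == 5

    def test_disagreeing_reads_flagged(self, mixed_sim):
        ref = mixed_sim["reference"]
        ev = next(e for e in mixed_sim["truth"].events if e.signature == "blunt")
        call = CNVCall(ev.chrom, ev.start, ev.end, "deletion")
        reads = self._mk_reads(ref, call, ["GATCC", "TTTAA"])
        assert realign_junction(call, reads, ref).inconsistent

    def test_requires_two_reads(self, mixed_sim):
        ref = mixed_sim["reference"]
        call = CNVCall("chr1", 100, 160, "deletion", support=[("r1", "sA")])
        with pytest.raises(ValueError):
            realign_junction(call, ReadSet([], 105.0, 0.0), ref)


class TestPolarize:
    def test_ancestral_outgroup_keeps_call(self, mixed_sim):
        ref = mixed_sim["reference"]
        og = generate_outgroup(
            ref, mixed_sim["truth"], divergence=0.0, share=0.0, seed=1
        )
        for ev in mixed_sim["truth"].events:
            if ev.kind != "deletion":
                continue
            call = CNVCall(ev.chrom, ev.start, ev.end, "deletion",
                           inserted_seq=ev.inserted_seq)
            assert polarize(call, og, ref).state == "DELETION_IN_STRAIN"

    def test_derived_outgroup_flips_call(self, mixed_sim, outgroup_shared):
        ref = mixed_sim["reference"]
        for ev in mixed_sim["truth"].events:
            if ev.kind != "deletion" or ev.signature == "nahr_flanks":
                continue
            call = CNVCall(ev.chrom, ev.start, ev.end, "deletion",
                           inserted_seq=ev.inserted_seq)
            assert polarize(call, outgroup_shared, ref).state == (
                "INSERTION_IN_REFERENCE"
            )

    def test_heavily_diverged_flank_unpolarized(self, mixed_sim, rng):
        ref = mixed_sim["reference"]
        ev = next(e for e in mixed_sim["truth"].events if e.kind == "deletion")
        call = CNVCall(ev.chrom, ev.start, ev.end, "deletion")
        scrambled = SimGenome(
            {c: random_dna(rng, len(s)) for c, s in ref.chromosomes.items()}
        )
        assert polarize(call, scrambled, ref).state == "UNPOLARIZED"

    def test_missing_outgroup_unpolarized(self, mixed_sim):
        ref = mixed_sim["reference"]
        call = CNVCall("chr1", 1000, 1060, "deletion")
        assert polarize(call, None, ref).state == "UNPOLARIZED"


class TestRecurrence:
    def _call(self, start, end, strains, ins=""):
        return CNVCall(
            "chr1", start, end, "deletion", inserted_seq=ins,
            support=[(f"r{start}-{s}", s) for s in strains],
        )

    def test_shared_junction_not_recurrent(self):
        calls = [self._call(100, 160, ["s1", "s2"])]
        (rep,) = find_recurrent_and_complex(calls)
        assert not rep.recurrent

    def test_overlapping_distinct_junctions_recurrent(self):
        calls = [
            self._call(100, 160, ["s1"]),
            self._call(120, 180, ["s2"]),
        ]
        (rep,) = find_recurrent_and_complex(calls)
        assert rep.recurrent

    def test_same_strain_nearby_junctions_complex(self):
        calls = [
            self._call(1000, 1040, ["s1"]),
            self._call(1140, 1180, ["s1"]),  # 100 bp apart
        ]
        (rep,) = find_recurrent_and_complex(calls)
        assert rep.complex_strains == ["s1"]
        assert not rep.recurrent

    def test_distant_junctions_separate_regions(self):
        calls = [
            self._call(1000, 1040, ["s1"]),
            self._call(9000, 9040, ["s2"]),
        ]
        assert len(find_recurrent_and_complex(calls)) == 2
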