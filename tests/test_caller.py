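"""Split-read mapping, signature detection, clustering filters, PSL I/O."""

import numpy as np
import pytest

from cnvbreak.caller import (
    Block,
    GenomeIndex,
    ReadAlignment,
    SplitSignature,
    cluster_and_filter,
    detect_split_signatures,
    export_psl,
    import_psl,
    map_reads,
)
from cnvbreak.core import SimGenome, random_dna
from cnvbreak.simulate import ReadSet, SimRead

from conftest import make_seq


@pytest.fixture(scope="module")
def flat_genome():
    return SimGenome({"chr1": make_seq(77, 20_000)})


def one_read(seq, rid="r1", strain="sA"):
    return ReadSet([SimRead(rid, strain, seq, "chr1", 0, len(seq), "+")], 105.0, 0.0)


class TestMapping:
    def test_exact_read_is_concordant_single_block(self, flat_genome):
        seq = flat_genome.chromosomes["chr1"][4000:4105]
        (aln,) = map_reads(one_read(seq), flat_genome)
        assert aln.concordant and len(aln.blocks) == 1
        assert aln.blocks[0].g_start == 4000

    def test_deletion_read_two_blocks_with_gap(self, flat_genome):
        ref = flat_genome.chromosomes["chr1"]
        seq = ref[1000:1030] + ref[1060:1090]
        (aln,) = map_reads(one_read(seq), flat_genome)
        b1, b2 = aln.blocks
        assert b2.g_start - b1.g_end == 30

    def test_random_read_is_unmapped(self, flat_genome):
        # a read of fresh random sequence shares no 13-mer with the genome
        seq = make_seq(123456, 105)
        assert seq not in flat_genome.chromosomes["chr1"]
        assert map_reads(one_read(seq), flat_genome) == []

    def test_reverse_strand_read_maps(self, flat_genome):
        from cnvbreak.core import revcomp

        seq = revcomp(flat_genome.chromosomes["chr1"][6000:6100])
        (aln,) = map_reads(one_read(seq), flat_genome)
        assert aln.concordant and aln.strand == "-"

    def test_seed_length_floor(self, flat_genome):
        with pytest.raises(ValueError):
            GenomeIndex(flat_genome, k=9)


class TestSignatures:
    def test_concordant_alignment_yields_no_signature(self, flat_genome):
        seq = flat_genome.chromosomes["chr1"][4000:4105]
        alns = map_reads(one_read(seq), flat_genome)
        assert detect_split_signatures(alns, flat_genome) == []

    @pytest.mark.parametrize("gap,expected", [(24, 0), (25, 1), (40, 1)])
    def test_min_size_boundary(self, flat_genome, gap, expected):
        ref = flat_genome.chromosomes["chr1"]
        seq = ref[2000:2050] + ref[2050 + gap : 2100 + gap]
        alns = map_reads(one_read(seq), flat_genome)
        sigs = detect_split_signatures(alns, flat_genome, min_size=25)
        assert len(sigs) == expected
        if sigs:
            assert sigs[0].kind == "read_gap_deletion"
            assert (sigs[0].ref_end - sigs[0].ref_start) == gap

    def test_flipped_blocks_are_tandem_dup(self):
        # junction bases forced distinct so the duplication is unambiguous
        raw = list(make_seq(42, 10_000))
        raw[4959], raw[5039] = "A", "C"
        genome = SimGenome({"chr1": "".join(raw)})
        aln = ReadAlignment(
            "r1", "sA", "chr1", "+", 80,
            [Block(0, 40, 5000, 5040), Block(40, 80, 4960, 5000)],
        )
        (sig,) = detect_split_signatures([aln], genome)
        assert sig.kind == "flipped_tandem_dup"
        assert (sig.ref_start, sig.ref_end) == (4960, 5040)

    def test_malformed_blocks_raise(self, flat_genome):
        aln = ReadAlignment(
            "r1", "sA", "chr1", "+", 80,
            [Block(0, 50, 5000, 5050), Block(40, 80, 5100, 5140)],
        )
        with pytest.raises(ValueError):
            detect_split_signatures([aln], flat_genome)

    def test_deletion_left_normalized(self):
        # deletion of one of two identical 30-mers is ambiguous; the caller
        # must report the leftmost interval
        unit = make_seq(9, 30)
        left = make_seq(10, 400)
        right = make_seq(11, 400)
        if left[-1] == unit[-1]:  # keep the leftmost placement at 400
            left = left[:-1] + ("A" if unit[-1] != "A" else "C")
        ref = left + unit + unit + right
        genome = SimGenome({"chr1": ref})
        derived = left + unit + right  # one copy deleted
        seq = derived[370:475]
        (aln,) = map_reads(one_read(seq), genome)
        (sig,) = detect_split_signatures([aln], genome)
        assert (sig.ref_start, sig.ref_end) == (400, 430)


def _sig(start, end, kind="read_gap_deletion", rid="r1", strain="sA",
         read_start=1000, offsets=(50, 50), read_len=105, ins=""):
    return SplitSignature(
        kind, "chr1", start, end, ins, rid, strain, offsets, read_len,
        ("chr1", "+", read_start),
    )


class TestClusterFilter:
    def test_single_read_filtered(self, flat_genome):
        log = []
        calls = cluster_and_filter(
            [_sig(1000, 1040)], flat_genome, discard_log=log
        )
        assert calls == [] and log[0][1] == "min_support"

    def test_pcr_duplicates_filtered(self, flat_genome):
        log = []
        sigs = [
            _sig(1000, 1040, rid="r1", read_start=990),
            _sig(1000, 1040, rid="r2", read_start=990),
        ]
        assert cluster_and_filter(sigs, flat_genome, discard_log=log) == []
        assert log[0][1] == "pcr_duplicates"

    def test_two_independent_reads_pass(self, flat_genome):
        sigs = [
            _sig(1000, 1040, rid="r1", read_start=990),
            _sig(1000, 1040, rid="r2", read_start=985),
        ]
        (call,) = cluster_and_filter(sigs, flat_genome)
        assert (call.start, call.end, call.kind) == (1000, 1040, "deletion")

    def test_read_end_margin(self, flat_genome):
        sigs = [
            _sig(1000, 1040, rid="r1", read_start=990, offsets=(5, 5)),
            _sig(1000, 1040, rid="r2", read_start=985, offsets=(50, 50)),
        ]
        assert cluster_and_filter(sigs, flat_genome) == []

    def test_te_filter(self, flat_genome):
        te = {"chr1": [(990, 1050)]}
        sigs = [
            _sig(1000, 1040, rid="r1", read_start=990),
            _sig(1000, 1040, rid="r2", read_start=985),
        ]
        log = []
        assert cluster_and_filter(sigs, flat_genome, te=te, discard_log=log) == []
        assert log[0][1] == "te"

    def test_mask_filter(self, flat_genome):
        mask = {"chr1": [(5000, 6000)]}
        sigs = [
            _sig(1000, 1040, rid="r1", read_start=990),
            _sig(1000, 1040, rid="r2", read_start=985),
        ]
        assert cluster_and_filter(sigs, flat_genome, mask=mask) == []

    def test_tandem_exclusion_switch(self, flat_genome):
        sigs = [
            _sig(1000, 1040, kind="flipped_tandem_dup", rid="r1", read_start=990),
            _sig(1000, 1040, kind="flipped_tandem_dup", rid="r2", read_start=985),
        ]
        assert len(cluster_and_filter(sigs, flat_genome)) == 1
        assert cluster_and_filter(sigs, flat_genome, exclude_tandem=True) == []


class TestEndToEndProperties:
    def test_monotonicity_min_size_and_support(self, mixed_sim, mixed_calls):
        ref = mixed_sim["reference"]
        alns = mixed_calls["alignments"]
        keys = lambda calls: {c.key() for c in calls}
        base = keys(
            cluster_and_filter(
                detect_split_signatures(alns, ref, min_size=25), ref
            )
        )
        lower = keys(
            cluster_and_filter(
                detect_split_signatures(alns, ref, min_size=20), ref, min_size=20
            )
        )
        assert base <= lower  # lowering min_size never removes a call
        stricter = keys(
            cluster_and_filter(
                detect_split_signatures(alns, ref, min_size=25), ref, min_support=3
            )
        )
        assert stricter <= base  # raising support never adds one

    def test_deterministic_ordering(self, mixed_sim):
        ref = mixed_sim["reference"]
        a = map_reads(mixed_sim["reads"], ref)
        sigs = detect_split_signatures(a, ref)
        c1 = cluster_and_filter(sigs, ref)
        c2 = cluster_and_filter(sigs, ref)
        assert [c.key() for c in c1] == [c.key() for c in c2]
        assert c1 == sorted(c1, key=lambda c: (c.chrom, c.start, c.kind))


class TestPSL:
    def test_roundtrip(self, tmp_path, mixed_sim, mixed_calls):
        ref = mixed_sim["reference"]
        alns = [a for a in mixed_calls["alignments"] if not a.concordant][:20]
        p = tmp_path / "out.psl"
        export_psl(alns, ref, p)
        back = import_psl(p)
        assert len(back) == len(alns)
        for a, b in zip(alns, back):
            assert [
                (x.r_start, x.r_end, x.g_start, x.g_end) for x in a.blocks
            ] == [(x.r_start, x.r_end, x.g_start, x.g_end) for x in b.blocks]
            assert (a.read_id, a.chrom, a.strand) == (b.read_id, b.chrom, b.strand)

    def test_header_skipped(self, tmp_path):
        line = "\t".join(
            ["50", "0", "0", "0", "0", "0", "0", "0", "+", "r1", "50", "0",
             "50", "chr1", "1000", "100", "150", "1", "50,", "0,", "100,"]
        )
        p = tmp_path / "h.psl"
        p.write_text(
            "psLayout version 3\n\nmatch\tmis\n----\n----\n" + line + "\n"
        )
        (aln,) = import_psl(p)
        assert aln.blocks[0].g_start == 100 and aln.concordant

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "bad.psl"
        p.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match=":1"):
            import_psl(p)
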