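"""End-to-end orchestration: simulate -> call -> classify -> downstream tests.

``run_pipeline`` executes the full analysis on either a simulated cohort
(the default; ground truth enables confusion matrices) or user-supplied
files, writing every stage's tables plus a replayable config into one
report directory.  All randomness derives from the single master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import caller, classify, homology, insertions, io, nonb, stats
from .core import CNVCall, SimGenome
from .simulate import (
    CLASS_MIX,
    cohort_specs,
    generate_genome,
    generate_outgroup,
    implant_cnvs,
    simulate_reads,
)

log = logging.getLogger("cnvbreak")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


DEFAULT_CONFIG = {
    "seed": 11,
    "outdir": "cnvbreak_report",
    "mode": "simulate",  # simulate | user
    "simulate": {
        "n_chrom": 2,
        "chrom_length": 60_000,
        "gc": 0.42,
        "n_strains": 9,
        "coverage": 1.2,  # per strain; nine strains give ~10x combined
        "read_length": 105,
        "read_sd": 20,
        "error_rate": 0.0,
        "n_events": 40,
        "class_mix": dict(CLASS_MIX),
        "insertion_fraction": 0.2,
        "nahr_fraction": 0.05,
        "outgroup_divergence": 0.03,
        "outgroup_share": 0.25,
    },
    "user": {"reference": None, "reads": [], "te": None, "mask": None,
             "outgroup": None, "gene_models": None},
    "call": {"min_size": 25, "min_support": 2, "end_margin": 10,
             "te_frac": 0.8, "exclude_tandem": False, "seed_k": 13},
    "insertion_origin": {"windows": [30, 60, 90, 120], "min_match": 7,
                         "control_factor": 10},
    "nonb": {"control_factor": 10},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class ReportBundle:
    outdir: Path
    config: dict
    results: dict = field(default_factory=dict)


def as_insertion_events(calls_with_polarity) -> list[CNVCall]:
    """The post-polarization insertion set.

    Insertion calls that stand, plus deletion calls re-assigned as
    insertions in the reference (their inserted sequence is the reference
    segment, with the interval as footprint — matched by the control
    convention).
    """
    out = []
    for c, pol, ref_seq in calls_with_polarity:
        if c.kind == "insertion" and pol != "DELETION_IN_REFERENCE":
            out.append(c)
        elif c.kind == "deletion" and pol == "INSERTION_IN_REFERENCE":
            out.append(
                CNVCall(c.chrom, c.start, c.end, "insertion",
                        inserted_seq=ref_seq, support=c.support)
            )
    return out


def run_pipeline(config: dict | None = None) -> ReportBundle:
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    bundle = ReportBundle(outdir, cfg)
    res = bundle.results
    stage = "setup"
    t0 = time.time()
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        sim = cfg["simulate"]
        truth = None
        if cfg["mode"] == "simulate":
            base = generate_genome(
                sim["n_chrom"],
                [sim["chrom_length"]] * sim["n_chrom"],
                gc=sim["gc"],
                seed=seed,
            )
            strains = [f"s{i}" for i in range(1, sim["n_strains"] + 1)]
            specs = cohort_specs(
                sim["n_events"],
                seed=seed + 1,
                class_mix=sim["class_mix"],
                insertion_fraction=sim["insertion_fraction"],
                nahr_fraction=sim["nahr_fraction"],
            )
            genome, strain_genomes, truth = implant_cnvs(
                base, specs, strains, seed=seed + 2
            )
            outgroup = generate_outgroup(
                genome, truth,
                divergence=sim["outgroup_divergence"],
                share=sim["outgroup_share"],
                seed=seed + 3,
            )
            reads = simulate_reads(
                strain_genomes,
                coverage=sim["coverage"],
                mean_len=sim["read_length"],
                len_sd=sim["read_sd"],
                error=sim["error_rate"],
                seed=seed + 4,
            )
            io.write_fasta(genome, outdir / "reference.fasta")
            io.write_fasta(outgroup, outdir / "outgroup.fasta")
            io.write_fastq(reads, outdir / "reads")
            io.write_truth(truth, outdir / "truth.tsv", outdir / "truth.json")
            io.write_bed(genome.euchromatin_mask, outdir / "mask.bed", "euchromatin")
            io.write_te_gff3(genome.te_annotation, outdir / "te.gff3")
            gene_models = None
        else:
            user = cfg["user"]
            if not user.get("reference"):
                raise ValueError("user-data mode requires a reference path")
            genome = io.read_fasta(user["reference"])
            if user.get("mask"):
                genome.euchromatin_mask = io.read_bed(user["mask"])
            if user.get("te"):
                genome.te_annotation = io.read_te_annotation(user["te"])
            reads = io.read_fastq(user["reads"])
            outgroup = io.read_fasta(user["outgroup"]) if user.get("outgroup") else None
            gene_models = (
                io.read_gene_models(user["gene_models"])
                if user.get("gene_models")
                else None
            )
        res["n_reads"] = len(reads.reads)

        # ------------------------------------------------------------------
        stage = "call"
        ccfg = cfg["call"]
        alignments = caller.map_reads(reads, genome, k=ccfg["seed_k"])
        signatures = caller.detect_split_signatures(
            alignments, genome, min_size=ccfg["min_size"]
        )
        discards: list = []
        calls = caller.cluster_and_filter(
            signatures,
            genome,
            read_end_margin=ccfg["end_margin"],
            min_support=ccfg["min_support"],
            te_frac=ccfg["te_frac"],
            min_size=ccfg["min_size"],
            exclude_tandem=ccfg["exclude_tandem"],
            discard_log=discards,
        )
        io.write_calls(calls, outdir / "calls.tsv", outdir / "calls.json")
        with open(outdir / "call_discards.tsv", "w") as fh:
            for key, reason in discards:
                fh.write("\t".join(map(str, key)) + f"\t{reason}\n")
        res["n_calls"] = len(calls)

        # ------------------------------------------------------------------
        stage = "classify"
        rows = []
        classified = []
        with_polarity = []
        for c in calls:
            ra = classify.realign_junction(c, reads, genome)
            if ra.inconsistent:
                rows.append((c, None, None, "inconsistent"))
                continue
            prof = classify.measure_microhomology(c, genome)
            bc = classify.classify_breakpoint(prof)
            pol = (
                classify.polarize(c, outgroup, genome).state
                if c.kind != "tandem_dup"
                else "."
            )
            classified.append((c, prof, bc, pol))
            ref_seq = genome.chromosomes[c.chrom][c.start : c.end]
            with_polarity.append((c, pol, ref_seq))
            rows.append((c, prof, bc, pol))
        regions = classify.find_recurrent_and_complex(calls)
        with open(outdir / "classification.tsv", "w") as fh:
            fh.write(
                "#CHROM\tSTART\tEND\tSVTYPE\tCLASS\tTYPE_I\tTYPE_II\tTYPE_III\t"
                "EXTRAS\tLONG_IDENTITY\tPOLARITY\n"
            )
            for c, prof, bc, pol in rows:
                if prof is None:
                    fh.write(
                        f"{c.chrom}\t{c.start}\t{c.end}\t{c.kind}\t"
                        f"INCONSISTENT\t.\t.\t.\t.\t.\t.\n"
                    )
                else:
                    fh.write(
                        f"{c.chrom}\t{c.start}\t{c.end}\t{c.kind}\t{bc.label}\t"
                        f"{prof.type_I}\t{prof.type_II}\t{prof.type_III}\t"
                        f"{prof.junction_extra_bases or '.'}\t"
                        f"{int(bc.long_identity)}\t{pol}\n"
                    )
        profiles = [p for _, p, _, _ in classified]
        if len(profiles) >= 30:
            excess = classify.microhomology_excess_test(profiles)
            res["mh_excess_smallest_k"] = excess.smallest_significant_k
        if classified:
            table = stats.summarize_breakpoint_classes([b for _, _, b, _ in classified])
            res["class_table"] = {
                label: {"count": cnt, "pct": pct} for label, cnt, pct in table.rows
            }
        res["n_recurrent_regions"] = sum(r.recurrent for r in regions)
        res["n_complex_regions"] = sum(bool(r.complex_strains) for r in regions)
        res["size_summary"] = stats.size_summary(calls)
        if gene_models is not None:
            _, ctx = stats.annotate_context(calls, gene_models)
            res["context"] = {r[0]: r[1] for r in ctx.rows}

        # ------------------------------------------------------------------
        stage = "insertion_origin"
        icfg = cfg["insertion_origin"]
        ins_events = as_insertion_events(with_polarity)
        origins = []
        for ins in ins_events:
            origins.append(insertions.classify_insertion_origin(ins, genome))
        res["insertion_origins"] = {
            lab: sum(o.label == lab for o in origins)
            for lab in ("TANDEM_DUP", "REPEAT_EXPANSION", "FILLER")
        }
        fillers = [
            i for i, o in zip(ins_events, origins) if o.label == "FILLER"
        ]
        if fillers:
            controls = insertions.shuffle_controls(
                fillers, genome, factor=icfg["control_factor"], seed=seed + 5
            )
            window_tests = {}
            for w in icfg["windows"]:
                real_m = [
                    insertions.match_neighborhood(
                        *insertions.neighborhood_flanks(i, genome, w),
                        min_match=icfg["min_match"],
                    )
                    for i in fillers
                ]
                ctrl_m = [
                    insertions.match_neighborhood(
                        *insertions.neighborhood_flanks(i, genome, w),
                        min_match=icfg["min_match"],
                    )
                    for i in controls
                ]
                wt = insertions.filler_enrichment_tests(real_m, ctrl_m)
                window_tests[w] = {
                    "rank_sum_p": wt.rank_sum.p_value,
                    "count_p": wt.count_test.p_value,
                    "real_with_match": wt.real_with_match,
                    "control_with_match": wt.control_with_match,
                }
            res["filler_window_tests"] = window_tests

        # ------------------------------------------------------------------
        stage = "homology"
        flags = []
        for c in calls:
            if c.kind != "deletion":
                continue
            sup = homology.classify_mechanism_support(
                c.chrom, c.start, c.end, genome, mode="precise"
            )
            flags.append((c, sup))
        res["homology"] = {
            "n_deletions": len(flags),
            "type_I": sum(s.type_I for _, s in flags),
            "type_II": sum(s.type_II for _, s in flags),
        }
        with open(outdir / "homology.tsv", "w") as fh:
            fh.write("#CHROM\tSTART\tEND\tTYPE_I\tTYPE_II\tN_HITS\n")
            for c, s in flags:
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{int(s.type_I)}\t"
                    f"{int(s.type_II)}\t{len(s.hits)}\n"
                )

        # ------------------------------------------------------------------
        stage = "nonb"
        ncfg = cfg["nonb"]
        del_calls = [c for c in calls if c.kind == "deletion"]
        if del_calls:
            regions_nb = nonb.breakpoint_regions(del_calls, genome)
            enr = nonb.enrichment_test(
                regions_nb,
                genome,
                control_factor=ncfg["control_factor"],
                seed=seed + 6,
            )
            res["nonb"] = {
                "table": enr.table,
                "odds_ratio": enr.odds_ratio if np.isfinite(enr.odds_ratio) else "inf",
                "p_value": enr.p_value,
            }
            with open(outdir / "nonb_histogram.tsv", "w") as fh:
                fh.write("#bin_lo\tbin_hi\tbreakpoints\tcontrols\n")
                for i in range(len(enr.histogram_real)):
                    fh.write(
                        f"{enr.bin_edges[i]:.0f}\t{enr.bin_edges[i + 1]:.0f}\t"
                        f"{enr.histogram_real[i]:.0f}\t{enr.histogram_control[i]:.0f}\n"
                    )

        # ------------------------------------------------------------------
        stage = "summarize"
        if truth is not None:
            res["truth_comparison"] = compare_to_truth(calls, truth)
        res["elapsed_s"] = round(time.time() - t0, 2)
        with open(outdir / "report.json", "w") as fh:
            json.dump(res, fh, indent=1, default=_jsonable)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
    except Exception as err:  # persist partial results, then re-raise
        with open(outdir / "report.partial.json", "w") as fh:
            json.dump(res, fh, indent=1, default=_jsonable)
        raise PipelineError(stage, err) from err
    return bundle


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def compare_to_truth(calls: list[CNVCall], truth) -> dict:
    """Confusion summary of calls against the implanted-event ledger."""
    def ev_key(e):
        return (e.chrom, e.start, e.end, e.kind)

    truth_keys = {ev_key(e) for e in truth.events}
    call_keys = {(c.chrom, c.start, c.end, c.kind) for c in calls}
    tp = truth_keys & call_keys
    return {
        "n_truth": len(truth_keys),
        "n_calls": len(call_keys),
        "exact_matches": len(tp),
        "recall_exact": len(tp) / len(truth_keys) if truth_keys else None,
        "precision_exact": len(tp) / len(call_keys) if call_keys else None,
        "missed": sorted(map(list, truth_keys - call_keys)),
        "spurious": sorted(map(list, call_keys - truth_keys)),
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
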