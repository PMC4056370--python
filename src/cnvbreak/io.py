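"""File-format boundaries: FASTA/FASTQ/BED/GFF3, truth ledgers, call tables.

Internally everything is 0-based half-open; 1-based conventions are applied
only here (GFF3).  Call tables are written as a VCF-like TSV (SVTYPE / END /
SEQ columns) plus a JSON sidecar carrying full support details.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CNVCall, SimGenome
from .simulate import ReadSet, SimEvent, SimRead, SimTruth


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(genome: SimGenome | dict, path) -> None:
    chroms = genome.chromosomes if isinstance(genome, SimGenome) else genome
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> SimGenome:
    chroms = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return SimGenome(chroms)


def write_fastq(reads: ReadSet, directory, prefix: str = "reads") -> list[Path]:
    """One FASTQ per strain; read origin is kept in the description."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for strain, rs in sorted(reads.by_strain().items()):
        p = directory / f"{prefix}.{strain}.fastq"
        with open(p, "w") as fh:
            for r in rs:
                fh.write(
                    f"@{r.read_id} {r.chrom}:{r.start}-{r.end}({r.strand})\n"
                    f"{r.seq}\n+\n{'I' * len(r.seq)}\n"
                )
        paths.append(p)
    return paths


def read_fastq(paths, strain_from_id: bool = True) -> ReadSet:
    reads = []
    if isinstance(paths, (str, Path)):
        paths = [paths]
    for p in paths:
        for rec in SeqIO.parse(str(p), "fastq"):
            strain = rec.id.split(".")[0] if strain_from_id else Path(p).stem
            reads.append(SimRead(rec.id, strain, str(rec.seq).upper(), "", 0, 0, "+"))
    mean = sum(len(r.seq) for r in reads) / max(1, len(reads))
    return ReadSet(reads, mean, 0.0)


# ---------------------------------------------------------------------------
# BED / GFF3


def write_bed(intervals: dict[str, list[tuple[int, int]]], path, name="region"):
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            out.setdefault(cols[0], []).append((int(cols[1]), int(cols[2])))
    return out


def write_te_gff3(te: dict[str, list[tuple[int, int]]], path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(te):
            for i, (s, e) in enumerate(te[chrom]):
                fh.write(
                    f"{chrom}\tcnvbreak\ttransposable_element\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID=TE_{chrom}_{i}\n"
                )


def read_gene_models(path) -> dict:
    """Gene and exon intervals from a GFF3 file (0-based half-open)."""
    models: dict[str, dict[str, list]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _, ftype, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
            entry = models.setdefault(chrom, {"genes": [], "exons": []})
            iv = (int(start) - 1, int(end))
            if ftype == "gene":
                entry["genes"].append(iv)
            elif ftype in ("exon", "CDS"):
                entry["exons"].append(iv)
    return models


def read_te_annotation(path) -> dict[str, list[tuple[int, int]]]:
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        out: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    continue
                out.setdefault(cols[0], []).append((int(cols[3]) - 1, int(cols[4])))
        return out
    return read_bed(path)


# ---------------------------------------------------------------------------
# truth ledger


def write_truth(truth: SimTruth, tsv_path, json_path=None):
    cols = (
        "chrom start end kind signature mh_k inserted_seq strains polarity "
        "planted_nonb"
    ).split()
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in truth.events:
            fh.write(
                "\t".join(
                    [
                        e.chrom,
                        str(e.start),
                        str(e.end),
                        e.kind,
                        e.signature,
                        str(e.mh_k),
                        e.inserted_seq or ".",
                        ",".join(e.strains),
                        e.polarity or ".",
                        e.planted_nonb or ".",
                    ]
                )
                + "\n"
            )
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "strains": list(truth.strains),
                    "events": [
                        {**e.__dict__, "strains": list(e.strains)}
                        for e in truth.events
                    ],
                },
                fh,
                indent=1,
            )


def read_truth(json_path) -> SimTruth:
    with open(json_path) as fh:
        data = json.load(fh)
    events = [
        SimEvent(**{**d, "strains": tuple(d["strains"])}) for d in data["events"]
    ]
    return SimTruth(events, tuple(data["strains"]))


# ---------------------------------------------------------------------------
# call tables


CALL_COLS = "CHROM START END SVTYPE SEQ N_READS N_STRAINS".split()


def write_calls(calls: list[CNVCall], tsv_path, json_path=None):
    with open(tsv_path, "w") as fh:
        fh.write("#" + "\t".join(CALL_COLS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        c.kind,
                        c.inserted_seq or ".",
                        str(len({r for r, _ in c.support})),
                        str(c.n_strains),
                    ]
                )
                + "\n"
            )
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(
                [
                    {
                        "chrom": c.chrom,
                        "start": c.start,
                        "end": c.end,
                        "kind": c.kind,
                        "inserted_seq": c.inserted_seq,
                        "support": [list(s) for s in c.support],
                    }
                    for c in calls
                ],
                fh,
                indent=1,
            )


def read_calls(json_path) -> list[CNVCall]:
    with open(json_path) as fh:
        data = json.load(fh)
    return [
        CNVCall(
            d["chrom"],
            d["start"],
            d["end"],
            d["kind"],
            inserted_seq=d.get("inserted_seq", ""),
            support=[tuple(s) for s in d.get("support", [])],
        )
        for d in data
    ]
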