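"""Readers and writers for the pipeline's on-disk formats.

Peaks travel as 6+2-column BED (chrom, start, end, name, score, strand,
signal, q-value), gene models as BED12, sequences as FASTA (via Biopython),
gene sets as GMT lines, ranked lists as two-column RNK, and everything
tabular as TSV with a header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionTable, MultireadGroup, RankedList
from .peaks import PEAK_COLUMNS, GeneModel, peak_frame


# ---------------------------------------------------------------- BED 6+2

def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS,
                     dtype={"chrom": str, "name": str, "strand": str})
    return peak_frame(df)


# ----------------------------------------------------------------- BED12

def write_genes_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons) + ","
        starts = ",".join(str(s - g.tx_start) for s, _ in g.exons) + ","
        rows.append((g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                     g.tx_start, g.tx_end, "0,0,0", len(g.exons), sizes, starts))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not f or not f[0] or f[0].startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


# ----------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=str(name), description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------- GMT

def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "tfcoreg") -> None:
    with open(path, "w") as fh:
        for set_id, genes in gene_sets.items():
            fh.write("\t".join([set_id, description, *sorted(map(str, genes))]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = set(f[2:])
    return sets


# ------------------------------------------------------------------- RNK

def write_rnk(ranked: RankedList, path: str | Path) -> None:
    ranked.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_rnk(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"],
                     dtype={"gene_id": str})
    df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="stable")
    return RankedList(df["gene_id"].to_numpy(object), df["score"].to_numpy(float))


# ------------------------------------------------------ expression tables

def write_expression(table: ExpressionTable, values_path: str | Path,
                     design_path: str | Path) -> None:
    table.values.to_csv(values_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": list(table.values.columns),
         "condition": [table.conditions[s] for s in table.values.columns]}
    ).to_csv(design_path, sep="\t", index=False)


def read_expression(values_path: str | Path, design_path: str | Path) -> ExpressionTable:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    conditions = dict(zip(design["sample_id"], design["condition"]))
    return ExpressionTable(values=values, conditions=conditions)


# ------------------------------------------------------- multiread groups

def write_multiread_groups(groups: Sequence[MultireadGroup], path: str | Path) -> None:
    pd.DataFrame(
        {"group_id": [f"mr{i:06d}" for i in range(len(groups))],
         "count": [g.count for g in groups],
         "exons": [",".join(g.exons) for g in groups]}
    ).to_csv(path, sep="\t", index=False)


def read_multiread_groups(path: str | Path) -> list[MultireadGroup]:
    df = pd.read_csv(path, sep="\t", dtype={"exons": str})
    return [MultireadGroup(exons=tuple(r.exons.split(",")), count=float(r.count))
            for r in df.itertuples()]


# ------------------------------------------------------------------ JSON

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
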