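"""RPKM quantification, multiread allocation, differential calls, ranking.

Expression is measured in RPKM (reads per kilobase of exonic transcript per
million mapped reads). Reads mapping to several exons ("multireads") are
allocated fractionally, proportional to the unique-read counts of their
candidate exons. Differential genes are called by a pure fold-change rule
with a minimum-expression floor, and ranked lists for enrichment analysis
are ordered by log2 fold change between the two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_MIN_RPKM = 2.0
#: pseudocount (RPKM units) added before log ratios / log2 display transforms
LOG_PSEUDOCOUNT = 0.5

UP_IN_A = "up_in_a"
UP_IN_B = "up_in_b"
UNCHANGED = "unchanged"


@dataclass
class ExpressionTable:
    """Gene x sample RPKM matrix with a sample -> condition mapping."""

    values: pd.DataFrame            # index gene_id, columns sample_id, RPKM
    conditions: dict[str, str]      # sample_id -> condition label

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if (self.values.to_numpy(float) < 0).any():
            raise ValueError("RPKM values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")

    @property
    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        cols = [s for s in self.values.columns if self.conditions[s] == condition]
        if not cols:
            raise ValueError(f"condition {condition!r} has no samples")
        return cols

    def condition_mean(self, condition: str) -> pd.Series:
        return self.values[self.samples_of(condition)].mean(axis=1)


@dataclass(frozen=True)
class MultireadGroup:
    """A set of reads mapping ambiguously to 2+ candidate exons."""

    exons: tuple[str, ...]
    count: float

    def __post_init__(self) -> None:
        if len(self.exons) < 2:
            raise ValueError("a multiread group needs >= 2 candidate exons")
        if self.count < 0:
            raise ValueError("negative multiread count")


def allocate_multireads(
    unique_exon_counts: Mapping[str, float] | pd.Series,
    multiread_groups: Sequence[MultireadGroup],
) -> pd.Series:
    """Split each multiread group across its exons, proportional to unique counts.

    Returns total fractional counts per exon (unique + allocated share).
    Groups whose candidate exons all have zero unique counts are split
    uniformly. Total read mass is conserved.
    """
    counts = pd.Series(unique_exon_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative unique counts")
    out = counts.copy()
    for group in multiread_groups:
        missing = [e for e in group.exons if e not in counts.index]
        if missing:
            raise ValueError(f"multiread group references unknown exons: {missing}")
        u = counts[list(group.exons)].to_numpy(float)
        total = u.sum()
        weights = u / total if total > 0 else np.full(len(u), 1.0 / len(u))
        out[list(group.exons)] += group.count * weights
    return out


def compute_rpkm(
    per_gene_counts: Mapping[str, float] | pd.Series,
    exonic_length_bp: Mapping[str, int] | pd.Series,
    total_mapped_reads: float,
) -> pd.Series:
    """RPKM = count / (exonic kb) / (million mapped reads).

    ``exonic_length_bp`` is the union of the gene's exons, not its genomic
    span. Fractional counts from multiread allocation pass through unchanged.
    """
    counts = pd.Series(per_gene_counts, dtype=float)
    lengths = pd.Series(exonic_length_bp, dtype=float).reindex(counts.index)
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if lengths.isna().any():
        raise ValueError(f"genes without length: {list(counts.index[lengths.isna()])[:5]}")
    zero = lengths <= 0
    if zero.any():
        raise ValueError(f"zero exonic length for gene(s): {list(counts.index[zero])[:5]}")
    return counts / (lengths / 1000.0) / (total_mapped_reads / 1e6)


def _two_conditions(table: ExpressionTable, condition_a: str | None, condition_b: str | None) -> tuple[str, str]:
    labels = table.condition_labels
    if condition_a is None and condition_b is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 conditions, found {labels}")
        return labels[0], labels[1]
    if condition_a is None or condition_b is None:
        raise ValueError("specify both conditions or neither")
    for c in (condition_a, condition_b):
        if c not in labels:
            raise ValueError(f"condition {c!r} not present in table")
    return condition_a, condition_b


def call_differential(
    table: ExpressionTable,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_rpkm: float = DEFAULT_MIN_RPKM,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> pd.DataFrame:
    """Fold-change differential call with a minimum-expression floor.

    A gene is differential iff max(meanA, meanB)/min(meanA, meanB) >=
    ``fold_threshold`` AND both condition means are >= ``min_rpkm``.
    Replicates are summarised by the arithmetic mean per condition.

    Returns a frame indexed by gene with columns ``mean_a``, ``mean_b``,
    ``fold_change`` (A over B), ``passes_min_expression``, ``direction``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    ca, cb = _two_conditions(table, condition_a, condition_b)
    mean_a = table.condition_mean(ca)
    mean_b = table.condition_mean(cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
        hi = np.maximum(mean_a, mean_b)
        lo = np.minimum(mean_a, mean_b)
        ratio = np.where(lo > 0, hi / lo, np.inf)
    ratio = np.where((hi == 0) & (lo == 0), 1.0, ratio)
    passes_min = (mean_a >= min_rpkm) & (mean_b >= min_rpkm)
    is_de = (ratio >= fold_threshold) & passes_min
    direction = np.where(~is_de, UNCHANGED, np.where(mean_a > mean_b, UP_IN_A, UP_IN_B))
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "passes_min_expression": passes_min,
            "direction": direction,
        },
        index=mean_a.index,
    )


def de_summary(de: pd.DataFrame) -> dict[str, int]:
    """Counts of up/down/total differential genes from a differential table."""
    n_up = int((de["direction"] == UP_IN_A).sum())
    n_down = int((de["direction"] == UP_IN_B).sum())
    return {"n_up_in_a": n_up, "n_up_in_b": n_down, "n_changed": n_up + n_down}


def zscore_transform(table: ExpressionTable, pseudocount: float = LOG_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-gene Z score of log2 expression across samples, Z = (x - mu) / sigma.

    x is log2(RPKM + pseudocount); mu and sigma are the per-gene mean and
    sample standard deviation (ddof=1) across samples. Constant genes
    (sigma = 0) map to all-zero rows. Display transform only.
    """
    x = np.log2(table.values.to_numpy(float) + pseudocount)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True) if x.shape[1] > 1 else np.zeros_like(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    return pd.DataFrame(z, index=table.values.index, columns=table.values.columns)


@dataclass
class RankedList:
    """Genes strictly ordered by a ranking score (non-increasing)."""

    genes: np.ndarray   # object array of gene ids
    scores: np.ndarray  # float, non-increasing

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.genes, "score": self.scores})


def rank_by_fold_change(
    table: ExpressionTable,
    condition_a: str | None = None,
    condition_b: str | None = None,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> RankedList:
    """Rank genes by log2((meanA + eps)/(meanB + eps)), descending.

    The most up-regulated genes in condition A sit at the top. Ties are
    broken lexicographically by gene id so the order is deterministic.
    """
    ca, cb = _two_conditions(table, condition_a, condition_b)
    mean_a = table.condition_mean(ca)
    mean_b = table.condition_mean(cb)
    score = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    frame = pd.DataFrame({"gene_id": score.index.astype(str), "score": score.to_numpy(float)})
    frame = frame.sort_values(["score", "gene_id"], ascending=[False, True], kind="stable")
    return RankedList(frame["gene_id"].to_numpy(object), frame["score"].to_numpy(float))
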