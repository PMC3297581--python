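"""Peak filtering and peak-to-gene target assignment.

Binding peaks are intervals in 0-based half-open (BED) coordinates with a
per-peak significance q-value. A gene is a *target* of a factor when at least
one significant peak overlaps the gene body or a fixed window upstream of the
transcription start site (default 3000 bp). Upstream is strand-aware: for a
``+`` gene the TSS is ``tx_start`` and the window extends left; for a ``-``
gene the TSS is ``tx_end`` and the window extends right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "signal", "q_value"]

#: q-value cutoff used to call a peak significant (Benjamini-Hochberg scale).
DEFAULT_Q_THRESHOLD = 0.001
#: upstream window, in bp, within which a peak is assigned to a gene's TSS.
DEFAULT_UPSTREAM_BP = 3000


class CapacityError(ValueError):
    """Raised when requested objects cannot be placed in the available space."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with exon structure.

    Exons are 0-based half-open intervals, sorted, non-overlapping and
    contained in ``[tx_start, tx_end)``.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if len(self.exons) == 0:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript bounds")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted, non-overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (tx_end for minus-strand genes)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def exonic_length(self) -> int:
        """Total exon length in bp (union of exons, not the genomic span)."""
        return sum(e - s for s, e in self.exons)

    def assignment_window(self, upstream_bp: int = DEFAULT_UPSTREAM_BP) -> tuple[int, int]:
        """Half-open interval a peak must overlap to be assigned to this gene."""
        if self.strand == "+":
            return max(0, self.tx_start - upstream_bp), self.tx_end
        return self.tx_start, self.tx_end + upstream_bp


@dataclass
class TargetAssignment:
    """Result of mapping a peak set onto gene models.

    ``assignments`` has one row per (peak, gene) pair with a ``relation``
    column: ``inside`` when the peak overlaps the gene body, else
    ``upstream``. A peak may hit several genes; the per-factor target set is
    the union of assigned genes.
    """

    assignments: pd.DataFrame
    target_genes: frozenset[str]
    n_peaks: int
    n_assigned: int
    unassigned_peaks: list[str] = field(default_factory=list)
    upstream_bp: int = DEFAULT_UPSTREAM_BP

    @property
    def fraction_assigned(self) -> float:
        return self.n_assigned / self.n_peaks if self.n_peaks else float("nan")


def peak_frame(records: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Normalise peak records into the canonical 6+2-column frame."""
    df = pd.DataFrame(records)
    for col, default in (("name", None), ("score", 0.0), ("strand", "."),
                         ("signal", 0.0), ("q_value", 0.0)):
        if col not in df.columns:
            if col == "name":
                df["name"] = [f"peak_{i}" for i in range(len(df))]
            else:
                df[col] = default
    df = df[PEAK_COLUMNS].copy()
    validate_peaks(df)
    return df


def validate_peaks(peaks: pd.DataFrame) -> None:
    if len(peaks) == 0:
        return
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks.loc[peaks["start"] >= peaks["end"], "name"].tolist()[:5]
        raise ValueError(f"peaks with start >= end: {bad}")
    q = peaks["q_value"].to_numpy(float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q_value must lie in [0, 1]")


def filter_peaks(peaks: pd.DataFrame, q_threshold: float = DEFAULT_Q_THRESHOLD) -> pd.DataFrame:
    """Retain peaks whose q-value is at or below ``q_threshold``, preserving order."""
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must lie in (0, 1]")
    validate_peaks(peaks)
    return peaks.loc[peaks["q_value"] <= q_threshold].copy()


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: Sequence[GeneModel],
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
) -> TargetAssignment:
    """Assign each peak to every gene whose assignment window it overlaps.

    Overlap means >= 1 bp intersection under half-open coordinates. A peak
    overlapping the gene body is recorded as ``inside`` (the more specific
    relation wins over ``upstream``). Peaks on chromosomes absent from the
    annotation raise a warning and are counted unassigned.
    """
    validate_peaks(peaks)
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be non-negative")

    gene_chroms = {g.chrom for g in genes}
    known = peaks["chrom"].isin(gene_chroms) if len(peaks) else pd.Series([], dtype=bool)
    if len(peaks) and (~known).any():
        missing = sorted(peaks.loc[~known, "chrom"].unique())
        warnings.warn(
            f"{int((~known).sum())} peaks on chromosomes absent from the "
            f"annotation ({missing[:5]}); counted unassigned",
            stacklevel=2,
        )

    starts = peaks["start"].to_numpy(np.int64) if len(peaks) else np.array([], dtype=np.int64)
    ends = peaks["end"].to_numpy(np.int64) if len(peaks) else np.array([], dtype=np.int64)
    names = peaks["name"].to_numpy(object) if len(peaks) else np.array([], dtype=object)
    chrom_index: dict[str, np.ndarray] = {}
    if len(peaks):
        for chrom, sub in peaks.groupby("chrom", sort=False):
            chrom_index[str(chrom)] = sub.index.to_numpy()
    pos_of = {idx: i for i, idx in enumerate(peaks.index)} if len(peaks) else {}

    rows: list[tuple[str, str, str]] = []
    assigned_mask = np.zeros(len(peaks), dtype=bool)
    for gene in genes:
        idxs = chrom_index.get(gene.chrom)
        if idxs is None:
            continue
        pos = np.array([pos_of[i] for i in idxs])
        ws, we = gene.assignment_window(upstream_bp)
        hit = (starts[pos] < we) & (ends[pos] > ws)
        if not hit.any():
            continue
        hit_pos = pos[hit]
        assigned_mask[hit_pos] = True
        inside = (starts[hit_pos] < gene.tx_end) & (ends[hit_pos] > gene.tx_start)
        for p, ins in zip(hit_pos, inside):
            rows.append((names[p], gene.gene_id, "inside" if ins else "upstream"))

    assignments = pd.DataFrame(rows, columns=["peak_id", "gene_id", "relation"])
    unassigned = [str(n) for n in names[~assigned_mask]]
    return TargetAssignment(
        assignments=assignments,
        target_genes=frozenset(assignments["gene_id"]) if len(rows) else frozenset(),
        n_peaks=len(peaks),
        n_assigned=int(assigned_mask.sum()),
        unassigned_peaks=unassigned,
        upstream_bp=upstream_bp,
    )
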