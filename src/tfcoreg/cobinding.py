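"""Co-binding statistics for two transcription factors.

Three complementary views of whether two factors act on shared targets:

1. *Target-set overlap*: the intersection of the two factors' target gene
   sets, its share of each set (reported as whole percents, truncated toward
   zero) and a hypergeometric upper-tail p-value against a gene universe.
2. *Peak proximity*: for every peak of factor A, the distance to the nearest
   peak of factor B (0 for overlapping peaks, else the edge gap), summarised
   as the fraction of A-peaks with a B-peak within a window (default 500 bp,
   inclusive).
3. A combined machine-readable report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PROXIMITY_WINDOW_BP = 500


def hypergeom_tail(k, N: int, K: int, n: int):
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Drawing ``n`` items from a universe of ``N`` containing ``K`` marked
    items, the probability of seeing at least ``k`` marked ones. Computed in
    log space (``logsf``) so extreme tails underflow gracefully rather than
    losing precision term-by-term. ``k`` may be a scalar or an array.

    Parameters follow the sampling convention: ``N`` universe size, ``K``
    marked (successes in the universe), ``n`` draws.
    """
    k_arr = np.asarray(k)
    if N < 0 or K < 0 or n < 0 or K > N or n > N:
        raise ValueError(f"infeasible hypergeometric parameters N={N}, K={K}, n={n}")
    if (k_arr < 0).any() or (k_arr > np.minimum(K, n)).any():
        raise ValueError("k must satisfy 0 <= k <= min(K, n)")
    with np.errstate(divide="ignore"):
        logp = stats.hypergeom.logsf(k_arr - 1, N, K, n)
    p = np.exp(logp)
    return float(p) if np.isscalar(k) or k_arr.ndim == 0 else p


def log10_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """log10 of the hypergeometric upper tail; finite far beyond float underflow."""
    if not 0 <= k <= min(K, n):
        raise ValueError("k must satisfy 0 <= k <= min(K, n)")
    return float(stats.hypergeom.logsf(k - 1, N, K, n) / math.log(10))


def truncated_percent(part: int, whole: int) -> int:
    """Whole-number percent truncated toward zero (3915/5393 -> 72, not 73)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return int((100 * part) // whole) if part >= 0 else -int((100 * -part) // whole)


@dataclass
class OverlapResult:
    """Target-set overlap between two factors against a gene universe."""

    n_targets_a: int
    n_targets_b: int
    n_common: int
    universe_size: int
    pct_of_a: int          # common as truncated percent of set A
    pct_of_b: int          # common as truncated percent of set B
    pct_of_a_raw: float
    pct_of_b_raw: float
    hypergeom_p: float
    log10_hypergeom_p: float
    common_genes: frozenset = field(default_factory=frozenset, repr=False)


def target_overlap(set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]) -> OverlapResult:
    """Intersection size, truncated percents and hypergeometric significance.

    The tail is P(|A ∩ B| >= k) for random draws of |B| genes from the
    universe containing the |A| targets of the other factor.
    """
    a, b, uni = frozenset(set_a), frozenset(set_b), frozenset(universe)
    offenders = sorted((a | b) - uni)
    if offenders:
        raise ValueError(f"set elements outside universe: {offenders[:10]}")
    common = a & b
    k = len(common)
    return OverlapResult(
        n_targets_a=len(a),
        n_targets_b=len(b),
        n_common=k,
        universe_size=len(uni),
        pct_of_a=truncated_percent(k, len(a)) if a else 0,
        pct_of_b=truncated_percent(k, len(b)) if b else 0,
        pct_of_a_raw=100.0 * k / len(a) if a else 0.0,
        pct_of_b_raw=100.0 * k / len(b) if b else 0.0,
        hypergeom_p=hypergeom_tail(k, len(uni), len(a), len(b)),
        log10_hypergeom_p=log10_hypergeom_tail(k, len(uni), len(a), len(b)),
        common_genes=common,
    )


def nearest_peak_distances(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame) -> np.ndarray:
    """Distance from each A-peak to its nearest B-peak.

    Distance is 0 when any B-peak overlaps (or touches) the A-peak, else the
    minimum edge gap to a B-peak on the same chromosome. A-peaks on
    chromosomes with no B-peaks get ``inf``. Returned in A's row order.
    """
    if len(peaks_a) == 0:
        raise ValueError("peak set A is empty")
    if len(peaks_b) == 0:
        raise ValueError("peak set B is empty")
    out = np.full(len(peaks_a), np.inf)
    b_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in peaks_b.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy(np.int64), kind="stable")
        s = sub["start"].to_numpy(np.int64)[order]
        e = sub["end"].to_numpy(np.int64)[order]
        b_by_chrom[str(chrom)] = (s, e, np.maximum.accumulate(e))

    a_pos = {idx: i for i, idx in enumerate(peaks_a.index)}
    for chrom, sub in peaks_a.groupby("chrom", sort=False):
        entry = b_by_chrom.get(str(chrom))
        if entry is None:
            continue
        bs, _be, pmax = entry
        a_s = sub["start"].to_numpy(np.int64)
        a_e = sub["end"].to_numpy(np.int64)
        rows = np.array([a_pos[i] for i in sub.index])
        # B-peaks starting left of A's end: overlap iff their max end > A start
        idx = np.searchsorted(bs, a_e, side="left")
        left_max_end = np.where(idx > 0, pmax[np.maximum(idx - 1, 0)], np.iinfo(np.int64).min)
        overlap = (idx > 0) & (left_max_end > a_s)
        left_gap = np.where(idx > 0, a_s - left_max_end, np.iinfo(np.int64).max).astype(float)
        left_gap[left_gap < 0] = 0.0  # touching/overlapping handled by overlap mask
        right_gap = np.where(idx < len(bs), bs[np.minimum(idx, len(bs) - 1)] - a_e,
                             np.inf).astype(float)
        d = np.minimum(left_gap, right_gap)
        d[overlap] = 0.0
        out[rows] = d
    return out


def windowed_fraction(distances: np.ndarray, window_bp: int = DEFAULT_PROXIMITY_WINDOW_BP) -> tuple[int, float]:
    """Count and fraction of A-peaks within ``window_bp`` (inclusive) of a B-peak.

    Infinite distances (no B-peak on the chromosome) count in the denominator
    but never the numerator.
    """
    n_within = int(np.sum(distances <= window_bp))
    return n_within, n_within / len(distances)


def distance_histogram(distances: np.ndarray, bin_bp: int = 100, max_bp: int = 5000) -> pd.DataFrame:
    """Binned counts of nearest-peak distances; a final open bin collects the rest."""
    edges = np.arange(0, max_bp + bin_bp, bin_bp)
    finite = distances[np.isfinite(distances)]
    counts, _ = np.histogram(np.minimum(finite, max_bp + 0.5), bins=np.append(edges, np.inf))
    labels = [f"[{edges[i]},{edges[i + 1]})" for i in range(len(edges) - 1)] + [f">={max_bp}"]
    return pd.DataFrame({"bin": labels, "count": counts.astype(int)})


@dataclass
class CoBindingReport:
    """Combined overlap + proximity summary for two factors."""

    overlap: OverlapResult
    n_peaks_a: int
    n_within_window: int
    window_bp: int
    fraction_within: float
    pct_within: int
    distance_histogram: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        o = self.overlap
        return {
            "n_targets_a": o.n_targets_a,
            "n_targets_b": o.n_targets_b,
            "n_common": o.n_common,
            "universe_size": o.universe_size,
            "pct_of_a": o.pct_of_a,
            "pct_of_b": o.pct_of_b,
            "pct_of_a_raw": o.pct_of_a_raw,
            "pct_of_b_raw": o.pct_of_b_raw,
            "hypergeom_p": o.hypergeom_p,
            "log10_hypergeom_p": o.log10_hypergeom_p,
            "n_peaks_a": self.n_peaks_a,
            "n_within_window": self.n_within_window,
            "window_bp": self.window_bp,
            "fraction_within": self.fraction_within,
            "pct_within": self.pct_within,
        }


def cobinding_report(
    targets_a: Iterable[str],
    targets_b: Iterable[str],
    universe: Iterable[str],
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    window_bp: int = DEFAULT_PROXIMITY_WINDOW_BP,
) -> CoBindingReport:
    """Run both co-binding approaches and assemble the combined report."""
    overlap = target_overlap(targets_a, targets_b, universe)
    d = nearest_peak_distances(peaks_a, peaks_b)
    n_within, frac = windowed_fraction(d, window_bp)
    return CoBindingReport(
        overlap=overlap,
        n_peaks_a=len(peaks_a),
        n_within_window=n_within,
        window_bp=window_bp,
        fraction_within=frac,
        pct_within=truncated_percent(n_within, len(peaks_a)),
        distance_histogram=distance_histogram(d),
    )
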