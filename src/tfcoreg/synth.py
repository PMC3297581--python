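"""Synthetic-data generator with planted ground truth.

Every downstream stage of the analysis — peak filtering and assignment,
co-binding statistics, motif occurrence, de novo discovery, differential
expression and gene-set enrichment — is exercised against data in which the
relevant structure is planted with known parameters:

* two peak sets with a controllable co-bound fraction whose partner peaks
  sit at half-normal edge distances,
* peak sequences with motif instances planted at controllable per-peak
  occurrence rates,
* an expression matrix in which a designated target gene set is enriched
  among the up-regulated genes of condition A with controllable effect size,
* per-exon read counts with a controllable multiread fraction.

All generators are pure functions of the configuration: randomness flows
from ``cfg.seed`` through per-stage seed streams, so outputs are
byte-identical across reruns and independent of call order. Planted events
are recorded in first-class truth tables; tests never re-infer ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import DEFAULT_PWMS, PWM, _COMPLEMENT, decode, encode
from .peaks import CapacityError, GeneModel, peak_frame

# per-stage seed stream offsets (spawn keys under cfg.seed)
_STAGE_ANNOTATION = 1
_STAGE_PEAKS = 2
_STAGE_MOTIFS = 3
_STAGE_EXPRESSION = 4
_STAGE_COUNTS = 5

MIN_INTERGENIC_GAP = 3000  # bp; also leaves room for the upstream window


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults emulate the scale of the analysed system, scaled to one
    synthetic chromosome: thousands of peaks for each factor with roughly
    half of factor A's peaks co-bound at near-zero edge distances, motif
    occurrence rates in the 0.4-0.6 range, and a two-condition expression
    matrix (2 replicates each) in which most up-regulated genes come from
    the designated target set with a 2 log2-unit effect.
    """

    seed: int = 0
    n_genes: int = 2000
    chrom_length: int = 200_000_000
    n_chromosomes: int = 1
    gc_content: float = 0.5
    # peaks
    n_peaks_a: int = 5000
    n_peaks_b: int = 7000
    cobind_fraction: float = 0.48
    cobind_distance_sd: float = 150.0
    peak_width: int = 250
    decoy_fraction: float = 0.05
    # motifs
    motif_occurrence: dict[str, float] = field(
        default_factory=lambda: {"TCF7_v1": 0.44, "RUNX1_v1": 0.54}
    )
    #: planted instances are conditioned to score >= this fraction of the
    #: motif's maximum log-odds, so a scan at the same threshold recovers them
    plant_threshold_fraction: float = 0.8
    # expression
    n_up: int = 300
    n_down: int = 300
    target_up_bias: float = 0.8
    fold_change_magnitude: float = 2.0
    noise_sd: float = 0.25
    n_replicates: int = 2
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    condition_a: str = "CD34pos"
    condition_b: str = "CD34neg"
    # read counts
    multiread_fraction: float = 0.2
    library_size: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("cobind_fraction", "decoy_fraction", "target_up_bias",
                     "multiread_fraction", "gc_content"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.multiread_fraction >= 1:
            raise ValueError("multiread_fraction must be < 1")
        for name, v in self.motif_occurrence.items():
            if not 0 <= v <= 1:
                raise ValueError(f"motif_occurrence[{name!r}] must lie in [0, 1]")
        for name in ("chrom_length", "n_chromosomes", "peak_width", "n_replicates",
                     "library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_peaks_a", "n_peaks_b", "n_up", "n_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down must be <= n_genes")
        if self.cobind_distance_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


class Genome:
    """In-memory genome: chromosome name -> int8 base codes (0..3 = A,C,G,T)."""

    def __init__(self, chroms: dict[str, np.ndarray]):
        self.chroms = chroms

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def sequence(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > len(self.chroms[chrom]) or start >= end:
            raise ValueError(f"interval [{start},{end}) outside {chrom}")
        return decode(self.chroms[chrom][start:end])

    def items(self):
        return self.chroms.items()


def generate_annotation(cfg: SynthConfig) -> tuple[list[GeneModel], Genome]:
    """Place non-overlapping stranded genes with >= 3 kb flanks; emit the genome.

    Genes are placed constructively: lengths are drawn first and the
    remaining slack distributed as random inter-gene gaps on top of the
    mandatory 3 kb minimum, so placement either succeeds deterministically
    or raises a :class:`CapacityError` up front. The genome is i.i.d.
    background sequence at the configured GC content.
    """
    rng = cfg._rng(_STAGE_ANNOTATION)
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cum = np.cumsum(p)

    def _random_bases(n: int, chunk: int = 20_000_000) -> np.ndarray:
        out = np.empty(n, dtype=np.int8)
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            out[lo:hi] = np.searchsorted(cum, rng.random(hi - lo)).astype(np.int8)
        return out

    chroms = {name: _random_bases(cfg.chrom_length) for name in cfg.chrom_names}
    genome = Genome(chroms)
    if cfg.n_genes == 0:
        return [], genome

    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_here in zip(cfg.chrom_names, per_chrom):
        if n_here == 0:
            continue
        lengths = rng.integers(2000, 10001, size=n_here)
        required = lengths.sum() + (n_here + 1) * MIN_INTERGENIC_GAP
        if required > cfg.chrom_length:
            raise CapacityError(
                f"cannot place {n_here} genes with {MIN_INTERGENIC_GAP} bp flanks "
                f"in {cfg.chrom_length} bp ({required} bp required)"
            )
        slack = cfg.chrom_length - required
        cuts = np.sort(rng.integers(0, slack + 1, size=n_here + 1))
        extra = np.diff(np.concatenate([[0], cuts]))  # random split of the slack
        pos = MIN_INTERGENIC_GAP + extra[0]
        for i in range(n_here):
            tx_start = int(pos)
            tx_end = int(pos + lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=_random_exons(rng, tx_start, tx_end),
                )
            )
            gid += 1
            pos = tx_end + MIN_INTERGENIC_GAP + extra[i + 1]
    return genes, genome


def _random_exons(rng: np.random.Generator, tx_start: int, tx_end: int) -> tuple[tuple[int, int], ...]:
    """1-6 exons; the first starts at tx_start and the last ends at tx_end."""
    span = tx_end - tx_start
    n_exons = int(rng.integers(1, 7))
    if n_exons == 1 or span < 2 * n_exons * 50:
        return ((tx_start, tx_end),)
    # 2*(k-1) interior breakpoints define alternating exon/intron segments
    inner = np.sort(rng.choice(np.arange(1, span), size=2 * (n_exons - 1), replace=False))
    bounds = np.concatenate([[0], inner, [span]])
    return tuple(
        (tx_start + int(bounds[2 * i]), tx_start + int(bounds[2 * i + 1]))
        for i in range(n_exons)
    )


def generate_peak_sets(
    cfg: SynthConfig, genes: Sequence[GeneModel] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two peak sets with a planted co-bound fraction, plus the truth table.

    Exactly ``round(cobind_fraction * n_peaks_a)`` A-peaks receive a partner
    B-peak whose edge distance is drawn from |Normal(0, cobind_distance_sd)|
    on a random side; remaining peaks of both sets are uniform. Planted
    ("true") peaks get q-values <= 0.001; an extra ``decoy_fraction`` of
    each set size is appended as uniform decoy peaks with q > 0.001, so the
    significance filter is exercised without disturbing the planted counts.
    The truth table lists each co-bound (peak_a, peak_b) pair with its
    planted gap.
    """
    rng = cfg._rng(_STAGE_PEAKS)
    n_co = round(cfg.cobind_fraction * cfg.n_peaks_a)
    if n_co > cfg.n_peaks_b:
        raise ValueError(
            f"cobind_fraction * n_peaks_a = {n_co} exceeds n_peaks_b = {cfg.n_peaks_b}"
        )
    w = cfg.peak_width
    L = cfg.chrom_length
    chrom_of = lambda i, n: cfg.chrom_names[i * cfg.n_chromosomes // max(n, 1)]

    a_starts = rng.integers(0, L - w, size=cfg.n_peaks_a) if cfg.n_peaks_a else np.array([], int)
    a_chroms = [chrom_of(i, cfg.n_peaks_a) for i in range(cfg.n_peaks_a)]
    a_names = [f"A_{i:05d}" for i in range(cfg.n_peaks_a)]

    co_idx = np.sort(rng.choice(cfg.n_peaks_a, size=n_co, replace=False)) if n_co else np.array([], int)
    gaps = np.rint(np.abs(rng.normal(0.0, cfg.cobind_distance_sd, size=n_co))).astype(int)
    sides = rng.random(n_co) < 0.5

    b_chroms: list[str] = []
    b_starts_list: list[int] = []
    truth_rows = []
    for j, (ai, gap, left) in enumerate(zip(co_idx, gaps, sides)):
        a_s = int(a_starts[ai])
        if left:
            b_s = a_s - gap - w
            if b_s < 0:
                b_s = a_s + w + gap  # flip side at the chromosome edge
        else:
            b_s = a_s + w + gap
            if b_s + w > L:
                b_s = a_s - gap - w
        b_s = int(np.clip(b_s, 0, L - w))
        name_b = f"B_{j:05d}"
        b_chroms.append(a_chroms[ai])
        b_starts_list.append(b_s)
        truth_rows.append((a_names[ai], name_b, int(gap)))

    n_rest = cfg.n_peaks_b - n_co
    rest_starts = rng.integers(0, L - w, size=n_rest) if n_rest else np.array([], int)
    for j in range(n_rest):
        b_chroms.append(chrom_of(n_co + j, cfg.n_peaks_b))
        b_starts_list.append(int(rest_starts[j]))
    b_names = [f"B_{j:05d}" for j in range(cfg.n_peaks_b)]

    def _finish(chroms, starts, names, prefix, n_true):
        n_decoys = round(cfg.decoy_fraction * n_true)
        d_starts = rng.integers(0, L - w, size=n_decoys) if n_decoys else np.array([], int)
        all_chroms = list(chroms) + [chrom_of(i, max(n_decoys, 1)) for i in range(n_decoys)]
        all_starts = list(starts) + [int(s) for s in d_starts]
        all_names = list(names) + [f"{prefix}dec_{i:05d}" for i in range(n_decoys)]
        q_true = rng.uniform(0.0, 0.001, size=n_true)
        q_decoy = rng.uniform(0.0011, 0.05, size=n_decoys)
        q = np.concatenate([q_true, q_decoy])
        signal = rng.lognormal(3.0, 0.5, size=n_true + n_decoys)
        return peak_frame(
            pd.DataFrame(
                {
                    "chrom": all_chroms,
                    "start": all_starts,
                    "end": [s + w for s in all_starts],
                    "name": all_names,
                    "score": np.round(signal, 3),
                    "strand": ".",
                    "signal": np.round(signal, 3),
                    "q_value": q,
                }
            )
        )

    peaks_a = _finish(a_chroms, a_starts, a_names, "A", cfg.n_peaks_a)
    peaks_b = _finish(b_chroms, b_starts_list, b_names, "B", cfg.n_peaks_b)
    truth = pd.DataFrame(truth_rows, columns=["peak_a", "peak_b", "planted_gap"])
    return peaks_a, peaks_b, truth


def plant_motifs(
    cfg: SynthConfig,
    peaks: pd.DataFrame,
    genome: Genome,
    pwms: Mapping[str, PWM] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Extract peak sequences and plant motif instances at the configured rates.

    For each motif id in ``cfg.motif_occurrence``, an exact
    ``round(rate * n_peaks)`` subset of peaks (seeded sampling without
    replacement) receives one instance sampled from the PWM, written at a
    uniform position on a uniform strand. Instances are rejection-sampled
    until they score at least ``plant_threshold_fraction`` of the motif's
    maximum log-odds, so a scan at the planting threshold detects every
    planted site. Returns (peak name -> sequence, truth table of edits).
    """
    rng = cfg._rng(_STAGE_MOTIFS)
    if pwms is None:
        pwms = DEFAULT_PWMS
    names = peaks["name"].tolist()
    seqs: dict[str, np.ndarray] = {}
    for _, row in peaks.iterrows():
        if row["end"] > genome.length(row["chrom"]):
            raise ValueError(f"peak {row['name']} outside genome bounds")
        seqs[row["name"]] = genome.chroms[row["chrom"]][row["start"]:row["end"]].copy()

    truth_rows = []
    for motif_id in sorted(cfg.motif_occurrence):
        rate = cfg.motif_occurrence[motif_id]
        pwm = pwms[motif_id]
        n_plant = round(rate * len(names))
        chosen = rng.choice(len(names), size=n_plant, replace=False) if n_plant else np.array([], int)
        log_odds = pwm.log_odds
        min_score = cfg.plant_threshold_fraction * pwm.max_score
        cum = np.cumsum(pwm.matrix, axis=1)
        for i in chosen:
            name = names[int(i)]
            seq = seqs[name]
            if pwm.width > len(seq):
                raise ValueError(f"motif {motif_id} wider than peak {name}")
            for _ in range(1000):
                u = rng.random(pwm.width)
                instance = np.array([np.searchsorted(cum[k], u[k]) for k in range(pwm.width)],
                                    dtype=np.int8)
                if log_odds[np.arange(pwm.width), instance].sum() >= min_score:
                    break
            else:
                instance = pwm.matrix.argmax(axis=1).astype(np.int8)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                instance = _COMPLEMENT[instance[::-1]]
            pos = int(rng.integers(0, len(seq) - pwm.width + 1))
            seq[pos:pos + pwm.width] = instance
            truth_rows.append((name, motif_id, pos, strand))
    truth = pd.DataFrame(truth_rows, columns=["peak_id", "motif_id", "position", "strand"])
    return {n: decode(s) for n, s in seqs.items()}, truth


def generate_expression(
    cfg: SynthConfig,
    genes: Sequence[GeneModel] | Sequence[str],
    target_set: Iterable[str],
) -> tuple["ExpressionTable", pd.DataFrame]:
    """Two-condition expression matrix with planted up/down genes.

    Baseline log2 expression is i.i.d. normal; ``n_up`` genes gain
    ``fold_change_magnitude`` log2 units in condition A (a
    ``target_up_bias`` fraction of them drawn from the target set) and
    ``n_down`` genes lose the same amount. Replicate noise is
    Normal(0, noise_sd) in log2 space; RPKM is the back-transform, hence
    non-negative. Returns the table and a truth frame (gene_id, direction,
    is_target).
    """
    from .expression import ExpressionTable

    rng = cfg._rng(_STAGE_EXPRESSION)
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    targets = sorted(set(target_set))
    unknown = set(targets) - set(gene_ids)
    if unknown:
        raise ValueError(f"target genes absent from annotation: {sorted(unknown)[:5]}")
    n = len(gene_ids)
    if cfg.n_up + cfg.n_down > n:
        raise ValueError("n_up + n_down exceeds number of genes")
    n_target_up = round(cfg.target_up_bias * cfg.n_up)
    if n_target_up > len(targets):
        raise ValueError(
            f"target_up_bias * n_up = {n_target_up} exceeds |target_set| = {len(targets)}"
        )

    target_arr = np.array(targets, dtype=object)
    non_targets = np.array([g for g in gene_ids if g not in set(targets)], dtype=object)
    if cfg.n_up - n_target_up > len(non_targets):
        raise ValueError("not enough non-target genes for the requested n_up")
    up_t = rng.choice(target_arr, size=n_target_up, replace=False) if n_target_up else np.array([], object)
    up_nt = (rng.choice(non_targets, size=cfg.n_up - n_target_up, replace=False)
             if cfg.n_up - n_target_up else np.array([], object))
    up = set(up_t.tolist()) | set(up_nt.tolist())
    remaining = np.array([g for g in gene_ids if g not in up], dtype=object)
    down = set(rng.choice(remaining, size=cfg.n_down, replace=False).tolist()) if cfg.n_down else set()

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    delta = np.array([
        cfg.fold_change_magnitude if g in up else (-cfg.fold_change_magnitude if g in down else 0.0)
        for g in gene_ids
    ])
    samples, conditions, data = [], {}, []
    for cond, offset in ((cfg.condition_a, delta), (cfg.condition_b, np.zeros(n))):
        for rep in range(1, cfg.n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            samples.append(sample)
            conditions[sample] = cond
            noise = rng.normal(0.0, cfg.noise_sd, size=n)
            data.append(2.0 ** (baseline + offset + noise))
    values = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "direction": ["up" if g in up else ("down" if g in down else "null") for g in gene_ids],
            "is_target": [g in set(targets) for g in gene_ids],
        }
    )
    return ExpressionTable(values=values, conditions=conditions), truth


def generate_read_counts(
    cfg: SynthConfig, genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, list]:
    """Per-exon unique counts plus multiread groups summing to the library size.

    Exon weights combine a per-gene lognormal expression level with exon
    length. ``round(multiread_fraction * library_size)`` reads are emitted
    as multiread groups of 2-4 candidate exons; the remainder are unique.
    """
    from .expression import MultireadGroup

    rng = cfg._rng(_STAGE_COUNTS)
    if not genes:
        raise ValueError("no genes with exons")
    exon_ids, exon_gene, exon_len, gene_w = [], [], [], []
    for g in genes:
        level = rng.lognormal(0.0, 1.0)
        for k, (s, e) in enumerate(g.exons):
            exon_ids.append(f"{g.gene_id}:e{k}")
            exon_gene.append(g.gene_id)
            exon_len.append(e - s)
            gene_w.append(level)
    weights = np.asarray(gene_w) * np.asarray(exon_len, dtype=float)
    weights /= weights.sum()

    n_multi = round(cfg.multiread_fraction * cfg.library_size)
    n_unique = cfg.library_size - n_multi
    unique = rng.multinomial(n_unique, weights)
    table = pd.DataFrame({"exon_id": exon_ids, "gene_id": exon_gene,
                          "length": exon_len, "unique_count": unique})

    groups: list[MultireadGroup] = []
    if n_multi > 0:
        n_groups = max(1, n_multi // 20)
        group_counts = rng.multinomial(n_multi, np.full(n_groups, 1.0 / n_groups))
        for c in group_counts:
            size = int(rng.integers(2, min(5, len(exon_ids) + 1)))
            members = rng.choice(len(exon_ids), size=size, replace=False, p=weights)
            groups.append(MultireadGroup(
                exons=tuple(exon_ids[int(i)] for i in members), count=int(c)))
    return table, groups
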