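"""End-to-end orchestration: synthesize-or-load, quantify, assign, co-bind,
motif, enrich, and a machine-readable report.

The pipeline runs the full integrative analysis from a single validated
configuration. In *synth* mode every input is generated with planted ground
truth (annotation and genome, two peak sets, peak sequences with motifs,
read counts, a two-condition expression matrix whose up-regulated genes are
biased toward factor A's binding targets). In *paths* mode the same stages
run on user-supplied BED/BED12/FASTA/TSV files. Exactly one of the two
modes must be configured.

Every output is stamped with the configuration hash and root seed; reruns
with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as tio
from .cobinding import cobinding_report
from .enrichment import gsea_preranked, results_frame
from .expression import (ExpressionTable, allocate_multireads, call_differential,
                         compute_rpkm, de_summary, rank_by_fold_change, zscore_transform)
from .motif import (DEFAULT_PWMS, compare_motifs, discover_motif,
                    peak_motif_occurrence, sample_bound_sequences)
from .peaks import assign_peaks_to_genes, filter_peaks
from .synth import Genome, SynthConfig, generate_annotation, generate_expression, \
    generate_peak_sets, generate_read_counts, plant_motifs

logger = logging.getLogger("tfcoreg")


class Thresholds(BaseModel):
    q_value: float = Field(0.001, gt=0, le=1)
    fold_change: float = Field(2.0, gt=1)
    min_rpkm: float = Field(2.0, ge=0)
    proximity_window: int = Field(500, ge=0)
    motif_threshold: float = Field(0.8, gt=0, le=1)
    upstream_bp: int = Field(3000, ge=0)


class EnrichmentSettings(BaseModel):
    n_permutations: int = Field(1000, ge=100)


class InputPaths(BaseModel):
    peaks_a: str
    peaks_b: str
    genes: str
    genome: str
    expression: str
    design: str


class MotifSettings(BaseModel):
    sample_size: int = Field(600, ge=50)
    discovery_width: int = Field(12, ge=4)
    n_restarts: int = Field(10, ge=1)
    run_discovery: bool = True


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: str = "tfcoreg_out"
    synth: Optional[dict] = None
    inputs: Optional[InputPaths] = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    enrichment: EnrichmentSettings = Field(default_factory=EnrichmentSettings)
    motif: MotifSettings = Field(default_factory=MotifSettings)
    factor_a: str = "TCF7"
    factor_b: str = "RUNX1"
    write_genome_fasta: bool = False

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "PipelineConfig":
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("configure exactly one of 'synth' and 'inputs'")
        return self

    def synth_config(self) -> SynthConfig:
        assert self.synth is not None
        return SynthConfig(**{"seed": self.seed, **self.synth})

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ------------------------------------------------------------- report schema

class AssignSection(BaseModel):
    n_peaks_input: int
    n_peaks_significant: int
    n_assigned: int
    fraction_assigned: float
    n_target_genes: int


class CobindSection(BaseModel):
    n_targets_a: int
    n_targets_b: int
    n_common: int
    universe_size: int
    pct_of_a: int
    pct_of_b: int
    pct_of_a_raw: float
    pct_of_b_raw: float
    hypergeom_p: float
    log10_hypergeom_p: float
    n_peaks_a: int
    n_within_window: int
    window_bp: int
    fraction_within: float
    pct_within: int


class MotifSection(BaseModel):
    threshold_fraction: float
    occurrence: dict[str, dict[str, float]]  # peak set -> factor -> fraction
    discovered_consensus: Optional[str] = None
    discovery_converged: Optional[bool] = None
    best_match_motif: Optional[str] = None
    best_match_orientation: Optional[str] = None
    best_match_n_aligned: Optional[int] = None
    best_match_similarity: Optional[float] = None
    best_match_consensus_matches: Optional[int] = None


class ExpressionSection(BaseModel):
    n_genes: int
    fold_threshold: float
    min_rpkm: float
    n_up_in_a: int
    n_up_in_b: int
    n_changed: int


class QuantSection(BaseModel):
    total_reads: float
    n_exons: int
    n_multiread_groups: int
    mass_conserved: bool


class EnrichSection(BaseModel):
    permutation_mode: str = "gene_set"
    n_permutations: int
    results: list[dict]


class Report(BaseModel):
    package: str = "tfcoreg"
    seed: int
    config_hash: str
    mode: str
    quantify: Optional[QuantSection] = None
    assign_a: AssignSection
    assign_b: AssignSection
    cobinding: CobindSection
    motif: Optional[MotifSection] = None
    expression: ExpressionSection
    enrichment: EnrichSection


def _log(stage: str, event: str, **fields) -> None:
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s event=%s %s", stage, event, payload)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the report dict (also written to outdir).

    Stage order: synthesize-or-load -> assign -> expression (planted toward
    factor A's targets in synth mode) -> quantify -> co-bind -> motif ->
    enrich -> report. A stage failure is logged with the stage name and
    re-raised; outputs written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    stage = "setup"
    try:
        thr = config.thresholds
        if config.synth is not None:
            stage = "synth"
            scfg = config.synth_config()
            _log(stage, "start", seed=scfg.seed, n_genes=scfg.n_genes)
            genes, genome = generate_annotation(scfg)
            peaks_a, peaks_b, cobind_truth = generate_peak_sets(scfg, genes)
            tio.write_genes_bed12(genes, outdir / "genes.bed12")
            tio.write_peaks_bed(peaks_a, outdir / "peaks_a.bed")
            tio.write_peaks_bed(peaks_b, outdir / "peaks_b.bed")
            cobind_truth.to_csv(outdir / "truth_cobinding.tsv", sep="\t", index=False)
            if config.write_genome_fasta:
                tio.write_fasta({c: genome.sequence(c, 0, genome.length(c))
                                 for c in genome.chroms}, outdir / "genome.fa")
            mode = "synth"
        else:
            stage = "load"
            inp = config.inputs
            assert inp is not None
            genes = tio.read_genes_bed12(inp.genes)
            genome = Genome({name: np.asarray(_encode_fasta(seq))
                             for name, seq in tio.read_fasta(inp.genome).items()})
            peaks_a = tio.read_peaks_bed(inp.peaks_a)
            peaks_b = tio.read_peaks_bed(inp.peaks_b)
            mode = "paths"
        _log(stage, "done", n_genes=len(genes), n_peaks_a=len(peaks_a), n_peaks_b=len(peaks_b))

        stage = "assign"
        sig_a = filter_peaks(peaks_a, thr.q_value)
        sig_b = filter_peaks(peaks_b, thr.q_value)
        asg_a = assign_peaks_to_genes(sig_a, genes, thr.upstream_bp)
        asg_b = assign_peaks_to_genes(sig_b, genes, thr.upstream_bp)
        asg_a.assignments.to_csv(outdir / "assignments_a.tsv", sep="\t", index=False)
        asg_b.assignments.to_csv(outdir / "assignments_b.tsv", sep="\t", index=False)
        tio.write_gmt({f"{config.factor_a}_targets": asg_a.target_genes,
                       f"{config.factor_b}_targets": asg_b.target_genes},
                      outdir / "target_sets.gmt")
        _log(stage, "done", targets_a=len(asg_a.target_genes), targets_b=len(asg_b.target_genes),
             frac_a=f"{asg_a.fraction_assigned:.3f}", frac_b=f"{asg_b.fraction_assigned:.3f}")

        stage = "expression"
        if config.synth is not None:
            table, expr_truth = generate_expression(scfg, genes, asg_a.target_genes)
            expr_truth.to_csv(outdir / "truth_expression.tsv", sep="\t", index=False)
            tio.write_expression(table, outdir / "expression.tsv", outdir / "design.tsv")
        else:
            table = tio.read_expression(inp.expression, inp.design)
        de = call_differential(table, thr.fold_change, thr.min_rpkm)
        de.to_csv(outdir / "differential.tsv", sep="\t", index_label="gene_id")
        zscore_transform(table).to_csv(outdir / "zscores.tsv", sep="\t", index_label="gene_id")
        summary = de_summary(de)
        _log(stage, "done", **summary)

        quant_section = None
        if config.synth is not None:
            stage = "quantify"
            exon_table, groups = generate_read_counts(scfg, genes)
            tio.write_multiread_groups(groups, outdir / "multiread_groups.tsv")
            unique = pd.Series(exon_table["unique_count"].to_numpy(float),
                               index=exon_table["exon_id"])
            allocated = allocate_multireads(unique, groups)
            gene_counts = allocated.groupby(
                exon_table.set_index("exon_id")["gene_id"]).sum()
            lengths = pd.Series({g.gene_id: g.exonic_length for g in genes})
            rpkm = compute_rpkm(gene_counts, lengths.loc[gene_counts.index],
                                float(scfg.library_size))
            pd.DataFrame({"count": gene_counts, "rpkm": rpkm}).to_csv(
                outdir / "quantification.tsv", sep="\t", index_label="gene_id")
            conserved = bool(np.isclose(allocated.sum(), scfg.library_size, atol=1e-6))
            quant_section = QuantSection(
                total_reads=float(scfg.library_size), n_exons=len(exon_table),
                n_multiread_groups=len(groups), mass_conserved=conserved)
            _log(stage, "done", n_exons=len(exon_table), conserved=conserved)

        stage = "cobind"
        universe = [g.gene_id for g in genes]
        cb = cobinding_report(asg_a.target_genes, asg_b.target_genes, universe,
                              sig_a, sig_b, thr.proximity_window)
        cb.distance_histogram.to_csv(outdir / "distance_histogram.tsv", sep="\t", index=False)
        _log(stage, "done", n_common=cb.overlap.n_common,
             fraction_within=f"{cb.fraction_within:.3f}")

        stage = "motif"
        motif_section = None
        pwms_by_factor = {
            config.factor_a: [p for k, p in DEFAULT_PWMS.items() if k.startswith(config.factor_a)],
            config.factor_b: [p for k, p in DEFAULT_PWMS.items() if k.startswith(config.factor_b)],
        }
        if config.synth is not None:
            seqs_a, mtruth_a = plant_motifs(scfg, sig_a, genome)
            seqs_b, mtruth_b = plant_motifs(scfg, sig_b, genome)
            mtruth_a.to_csv(outdir / "truth_motifs_a.tsv", sep="\t", index=False)
            mtruth_b.to_csv(outdir / "truth_motifs_b.tsv", sep="\t", index=False)
        else:
            seqs_a = {r["name"]: genome.sequence(r["chrom"], r["start"], r["end"])
                      for _, r in sig_a.iterrows()}
            seqs_b = {r["name"]: genome.sequence(r["chrom"], r["start"], r["end"])
                      for _, r in sig_b.iterrows()}
        occ = {}
        for label, seqs in (("peaks_a", seqs_a), ("peaks_b", seqs_b)):
            res = peak_motif_occurrence(seqs, pwms_by_factor, thr.motif_threshold)
            occ[label] = res.fractions
            res.hits.to_csv(outdir / f"motif_hits_{label}.tsv", sep="\t")
        motif_section = MotifSection(threshold_fraction=thr.motif_threshold, occurrence=occ)
        if config.motif.run_discovery and len(sig_a) >= config.motif.sample_size:
            sample = sample_bound_sequences(sig_a, seqs_a, config.motif.sample_size,
                                            seed=config.seed)
            disc = discover_motif(list(sample.values()), config.motif.discovery_width,
                                  n_restarts=config.motif.n_restarts, seed=config.seed)
            best_id, best_aln = None, None
            for motif_id, pwm in DEFAULT_PWMS.items():
                aln = compare_motifs(pwm, disc.pwm)
                if best_aln is None or aln.similarity > best_aln.similarity:
                    best_id, best_aln = motif_id, aln
            motif_section.discovered_consensus = disc.pwm.consensus
            motif_section.discovery_converged = disc.converged
            motif_section.best_match_motif = best_id
            motif_section.best_match_orientation = best_aln.orientation
            motif_section.best_match_n_aligned = best_aln.n_aligned
            motif_section.best_match_similarity = best_aln.similarity
            motif_section.best_match_consensus_matches = best_aln.consensus_matches
        _log(stage, "done", **{f"occ_{k}": v for k, v in occ.get("peaks_a", {}).items()})

        stage = "enrich"
        ranked = rank_by_fold_change(table)
        tio.write_rnk(ranked, outdir / "ranked.rnk")
        gene_sets = {f"{config.factor_a}_targets": set(asg_a.target_genes),
                     f"{config.factor_b}_targets": set(asg_b.target_genes)}
        enr = gsea_preranked(ranked, gene_sets,
                             n_permutations=config.enrichment.n_permutations,
                             seed=config.seed)
        results_frame(enr).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        _log(stage, "done", **{r.gene_set_id: f"p={r.nominal_p:.4g}" for r in enr})

        stage = "report"
        report = Report(
            seed=config.seed,
            config_hash=config.config_hash(),
            mode=mode,
            quantify=quant_section,
            assign_a=AssignSection(
                n_peaks_input=len(peaks_a), n_peaks_significant=len(sig_a),
                n_assigned=asg_a.n_assigned, fraction_assigned=asg_a.fraction_assigned,
                n_target_genes=len(asg_a.target_genes)),
            assign_b=AssignSection(
                n_peaks_input=len(peaks_b), n_peaks_significant=len(sig_b),
                n_assigned=asg_b.n_assigned, fraction_assigned=asg_b.fraction_assigned,
                n_target_genes=len(asg_b.target_genes)),
            cobinding=CobindSection(**cb.to_dict()),
            motif=motif_section,
            expression=ExpressionSection(
                n_genes=len(table.values), fold_threshold=thr.fold_change,
                min_rpkm=thr.min_rpkm, **summary),
            enrichment=EnrichSection(
                n_permutations=config.enrichment.n_permutations,
                results=[json.loads(results_frame(enr).to_json(orient="records"))
                         ][0] if enr else []),
        )
        report_dict = report.model_dump()
        tio.write_json(report_dict, outdir / "report.json")
        tio.write_json(Report.model_json_schema(), outdir / "report.schema.json")
        _log(stage, "done", seconds=f"{time.time() - t0:.1f}")
        return report_dict
    except Exception:
        logger.error("stage=%s event=failed", stage)
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()


def _encode_fasta(seq: str) -> np.ndarray:
    from .motif import encode
    return encode(seq)
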