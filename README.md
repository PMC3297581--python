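# tfcoreg

Integrative ChIP-seq + RNA-seq analysis of transcription-factor
co-regulation, built for the question of how two factors (for example TCF7
and RUNX1 in CD34+ multipotential hematopoietic progenitors) jointly control
a self-renewal expression program. The package takes binding peaks for two
factors, gene models, a genome and an expression matrix, and answers: which
genes does each factor target, do the two factors co-bind, do their binding
motifs co-occur in each other's peaks, and are their targets enriched among
the genes that distinguish two cell states?

It is a library plus a `tfcoreg` command-line pipeline, intended for
regulatory-genomics analysts who have peak calls and expression tables and
want the full co-regulation workflow — including a synthetic-data generator
that plants every structure the analysis assumes, with ground-truth tables,
so each stage can be validated against known parameters.

## What it computes

**Targets.** Peaks are filtered at a q-value threshold (default
q ≤ 0.001) and assigned to every gene whose window they overlap: 3000 bp
upstream of the TSS (strand-aware) through the gene body, exons and introns
alike, in 0-based half-open coordinates. A peak may hit several genes.

**Co-binding.** Three complementary views:

1. *Target overlap.* For target sets A and B in a universe of N genes, the
   intersection k = |A ∩ B| is scored with the hypergeometric upper tail
   P(X ≥ k), X ~ Hypergeom(N, |A|, |B|), computed in log space so extreme
   tails remain meaningful. Percent overlaps are reported truncated toward
   zero (3915/5393 → 72%), matching how such tables are conventionally
   printed.
2. *Peak proximity.* For every A-peak, the distance to the nearest B-peak
   (0 if overlapping, else the edge gap), summarised as the fraction of
   A-peaks with a B-peak within 500 bp (inclusive).
3. *Motif occurrence.* Peaks are scanned with position-weight matrices on
   both strands using log2-odds scores Σᵢ log2(pᵢ(base)/bg(base)); a peak
   counts once per factor if any motif version hits (non-duplicate union).
   De novo motifs are discovered from a seeded sample of bound sequences by
   ZOOPS (zero-or-one occurrence per sequence) expectation-maximisation and
   compared to known motifs by sliding-window column correlation in both
   orientations.

**Expression.** RPKM = count / (exonic kb) / (million mapped reads), with
multireads allocated across candidate exons proportional to unique-read
counts. Differential genes require a fold change ≥ 2 between condition
means and ≥ 2 RPKM in both conditions (both thresholds configurable).
Display Z-scores are (x − μ)/σ on log2 expression.

**Enrichment.** Genes are ranked by log2 fold change; a gene set's
enrichment score ES is the extremum of a weighted running sum (hits add
|score|/Σ|score|, misses subtract 1/(N − N_hits)). Significance comes from a
seeded gene-set permutation null: nominal p with the +1-corrected
estimator, NES = ES / mean |same-sign null ES|, and an NES-ratio FDR q.

## Worked example

Run the synthetic demo pipeline (all inputs generated with planted ground
truth — here 250 genes on a 20 Mb chromosome, 600 + 800 peaks with a planted
co-bound fraction of 0.48, motifs planted at rates 0.44/0.54, and 40 + 40
differential genes biased toward factor A's targets):

```bash
cat > demo.json <<'EOF'
{
  "seed": 7,
  "outdir": "demo_out",
  "synth": {"n_genes": 250, "chrom_length": 20000000, "n_peaks_a": 600,
            "n_peaks_b": 800, "n_up": 40, "n_down": 40, "library_size": 100000},
  "enrichment": {"n_permutations": 500},
  "motif": {"sample_size": 300, "n_restarts": 5}
}
EOF
tfcoreg run --config demo.json
```

`demo_out/report.json` then contains (abridged):

```text
cobinding:  61 A-targets, 67 B-targets, 33 common (54% of A, 49% of B),
            hypergeometric p = 1.15e-07; 50% of A-peaks within 500 bp of a B-peak
motif:      occurrence in A-peaks: TCF7 0.44, RUNX1 0.525 (threshold 0.8 of max score)
            de novo 12-mer consensus AAAGATCAAAGG, best match TCF7_v1
            (complementary orientation, 12/12 consensus positions)
expression: 57 differential genes (36 up in condition A, 21 up in B)
enrichment: TCF7_targets  ES 0.754, nominal p 0.002, FDR q 0.00
            RUNX1_targets ES 0.490, nominal p 0.012, FDR q 0.019
```

Reading it: the planted co-binding shows up as a highly significant target
overlap and half of A's peaks sitting within 500 bp of a B-peak; the
planted motif rates are recovered at the scan threshold; the de novo search
finds the planted motif (as its reverse complement — strands are
indistinguishable to the model); and because the up-regulated genes were
drawn preferentially from factor A's targets, that target set is enriched
at the top of the fold-change-ranked list while the co-bound B set inherits
a weaker enrichment.

Every stage is also exposed as a subcommand (`synth`, `quantify`, `assign`,
`cobind`, `motif`, `enrich`) over standard formats: BED 6+2 peaks, BED12
gene models, FASTA, GMT gene sets, RNK ranked lists, TSV tables.

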