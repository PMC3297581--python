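"""Generators: determinism, planted structure, truth-table conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tfcoreg import (CapacityError, DEFAULT_PWMS, ExpressionTable, SynthConfig,
                     call_differential, de_summary, filter_peaks,
                     generate_annotation, generate_expression, generate_peak_sets,
                     generate_read_counts, nearest_peak_distances,
                     peak_motif_occurrence, plant_motifs, relative_threshold,
                     scan_pwm)

SMALL = dict(n_genes=40, chrom_length=1_500_000, n_peaks_a=120, n_peaks_b=160,
             n_up=8, n_down=8, library_size=20_000)


def small_cfg(**over):
    return SynthConfig(**{**SMALL, **over})


class TestAnnotation:
    def test_empty_case_still_emits_genome(self):
        genes, genome = generate_annotation(small_cfg(n_genes=0, n_up=0, n_down=0))
        assert genes == []
        assert genome.length("chr1") == SMALL["chrom_length"]

    def test_determinism_byte_identical(self):
        g1, gen1 = generate_annotation(small_cfg(seed=1))
        g2, gen2 = generate_annotation(small_cfg(seed=1))
        assert g1 == g2
        assert np.array_equal(gen1.chroms["chr1"], gen2.chroms["chr1"])

    def test_pairwise_gaps_at_least_3kb_by_interval_sweep(self):
        cfg = SynthConfig(seed=5, n_genes=100, chrom_length=2_000_000, n_up=0, n_down=0)
        genes, _ = generate_annotation(cfg)
        assert len(genes) == 100
        intervals = sorted((g.tx_start, g.tx_end) for g in genes)
        for (s1, e1), (s2, e2) in itertools.combinations(intervals, 2):
            lo, hi = ((s1, e1), (s2, e2)) if s1 <= s2 else ((s2, e2), (s1, e1))
            assert hi[0] - lo[1] >= 3000
        for g in genes:
            assert g.exons[0][0] == g.tx_start and g.exons[-1][1] == g.tx_end

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_annotation(small_cfg(n_genes=40, chrom_length=100_000))

    def test_gc_content_respected(self):
        _, genome = generate_annotation(small_cfg(n_genes=0, n_up=0, n_down=0,
                                                  gc_content=0.7))
        gc = np.isin(genome.chroms["chr1"], [1, 2]).mean()
        assert gc == pytest.approx(0.7, abs=0.01)


class TestPeakSets:
    def test_degenerate_full_cobinding_zero_distance(self):
        cfg = small_cfg(cobind_fraction=1.0, cobind_distance_sd=0.0,
                        n_peaks_b=200, decoy_fraction=0.0)
        pa, pb, truth = generate_peak_sets(cfg)
        assert len(truth) == cfg.n_peaks_a
        d = nearest_peak_distances(pa, pb)
        assert (d == 0).all()

    def test_zero_cobinding_empty_truth(self):
        _, _, truth = generate_peak_sets(small_cfg(cobind_fraction=0.0))
        assert len(truth) == 0

    def test_truth_table_accounts_each_pair_once(self):
        cfg = small_cfg(cobind_fraction=0.5)
        _, _, truth = generate_peak_sets(cfg)
        assert len(truth) == round(0.5 * cfg.n_peaks_a)
        assert truth["peak_a"].is_unique and truth["peak_b"].is_unique

    def test_q_values_mark_true_and_decoy_peaks(self):
        cfg = small_cfg(decoy_fraction=0.1)
        pa, _, _ = generate_peak_sets(cfg)
        sig = filter_peaks(pa, 0.001)
        assert len(sig) == cfg.n_peaks_a
        assert len(pa) == cfg.n_peaks_a + round(0.1 * cfg.n_peaks_a)

    def test_infeasible_cobind_fraction_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_peak_sets(small_cfg(n_peaks_a=100, n_peaks_b=30, cobind_fraction=0.9))

    def test_determinism(self):
        a1, b1, t1 = generate_peak_sets(small_cfg(seed=9))
        a2, b2, t2 = generate_peak_sets(small_cfg(seed=9))
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(t1, t2)


class TestPlantMotifs:
    def test_full_occurrence_every_peak_hit_at_planting_threshold(self):
        cfg = small_cfg(motif_occurrence={"TCF7_v1": 1.0}, decoy_fraction=0.0)
        genes, genome = generate_annotation(cfg)
        pa, _, _ = generate_peak_sets(cfg, genes)
        seqs, truth = plant_motifs(cfg, pa, genome)
        pwm = DEFAULT_PWMS["TCF7_v1"]
        thr = relative_threshold(pwm, cfg.plant_threshold_fraction)
        assert len(truth) == len(pa)
        assert all(len(scan_pwm(s, pwm, thr)) >= 1 for s in seqs.values())

    def test_zero_occurrence_hit_rate_bounded_by_background_fpr(self, rng):
        cfg = small_cfg(motif_occurrence={"TCF7_v1": 0.0}, n_peaks_a=400, n_peaks_b=400)
        genes, genome = generate_annotation(cfg)
        pa, _, _ = generate_peak_sets(cfg, genes)
        seqs, truth = plant_motifs(cfg, pa, genome)
        assert len(truth) == 0
        pwm = DEFAULT_PWMS["TCF7_v1"]
        occ = peak_motif_occurrence(seqs, {"TCF7": [pwm]})
        # empirical per-peak scanner FPR from 2000 independent background sequences
        bg = {f"b{i}": "".join("ACGT"[c] for c in rng.integers(0, 4, cfg.peak_width))
              for i in range(2000)}
        fpr = peak_motif_occurrence(bg, {"TCF7": [pwm]}).fractions["TCF7"]
        margin = 3 * np.sqrt(max(fpr, 0.005) * (1 / len(seqs) + 1 / len(bg)))
        assert occ.fractions["TCF7"] <= fpr + margin

    def test_motif_wider_than_peak_raises(self):
        cfg = small_cfg(peak_width=8, motif_occurrence={"TCF7_v1": 1.0})
        genes, genome = generate_annotation(cfg)
        pa, _, _ = generate_peak_sets(cfg, genes)
        with pytest.raises(ValueError, match="wider than peak"):
            plant_motifs(cfg, pa, genome)


class TestExpression:
    def test_full_bias_all_up_genes_are_targets(self):
        gene_ids = [f"G{i:03d}" for i in range(400)]
        targets = gene_ids[:150]
        cfg = small_cfg(n_genes=400, n_up=100, n_down=50, target_up_bias=1.0)
        _, truth = generate_expression(cfg, gene_ids, targets)
        up = truth.loc[truth["direction"] == "up", "gene_id"]
        assert len(up) == 100
        assert set(up) <= set(targets)

    def test_null_effect_de_count_within_permutation_bound(self):
        gene_ids = [f"G{i:03d}" for i in range(600)]
        cfg = small_cfg(n_genes=600, n_up=50, n_down=50, fold_change_magnitude=0.0)
        table, _ = generate_expression(cfg, gene_ids, gene_ids[:100])
        n_de = de_summary(call_differential(table))["n_changed"]
        # permutation oracle: every balanced relabelling of the 4 samples
        counts = []
        samples = list(table.values.columns)
        for combo in itertools.combinations(range(4), 2):
            conds = {s: ("A" if i in combo else "B") for i, s in enumerate(samples)}
            t2 = ExpressionTable(values=table.values, conditions=conds)
            counts.append(de_summary(call_differential(t2, condition_a="A",
                                                       condition_b="B"))["n_changed"])
        assert n_de <= max(counts)

    def test_rpkm_non_negative_and_bias_error(self):
        gene_ids = [f"G{i}" for i in range(50)]
        cfg = small_cfg(n_genes=50, n_up=20, n_down=5, target_up_bias=1.0)
        with pytest.raises(ValueError, match="exceeds"):
            generate_expression(cfg, gene_ids, gene_ids[:10])
        cfg2 = small_cfg(n_genes=50, n_up=5, n_down=5)
        table, _ = generate_expression(cfg2, gene_ids, gene_ids[:10])
        assert (table.values.to_numpy() >= 0).all()


class TestReadCounts:
    def test_zero_multiread_fraction_no_groups(self):
        cfg = small_cfg(multiread_fraction=0.0)
        genes, _ = generate_annotation(cfg)
        table, groups = generate_read_counts(cfg, genes)
        assert groups == []
        assert table["unique_count"].sum() == cfg.library_size

    def test_total_mass_equals_library_size(self):
        cfg = small_cfg(multiread_fraction=0.3)
        genes, _ = generate_annotation(cfg)
        table, groups = generate_read_counts(cfg, genes)
        total = table["unique_count"].sum() + sum(g.count for g in groups)
        assert total == cfg.library_size
        assert all(len(g.exons) >= 2 for g in groups)

    def test_determinism(self):
        cfg = small_cfg(seed=3)
        genes, _ = generate_annotation(cfg)
        t1, g1 = generate_read_counts(cfg, genes)
        t2, g2 = generate_read_counts(cfg, genes)
        pd.testing.assert_frame_equal(t1, t2)
        assert g1 == g2

    def test_invalid_multiread_fraction(self):
        with pytest.raises(ValueError):
            small_cfg(multiread_fraction=1.0)
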