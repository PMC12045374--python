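"""Generator determinism, analytic expectations, and peak recovery."""

import numpy as np
import pandas as pd
import pytest

from pausekit import (
    GeneModel,
    GeneratorConfig,
    GenomicInterval,
    ValidationError,
    build_windows,
    consensus,
    generate_genome,
    simulate_coverage,
    simulate_peaks,
    window_density,
)
from pausekit.synthetic import CLASS_PAUSED, CLASS_UNCHANGED, make_gene_sets


class TestGenome:
    def test_same_seed_reproduces_exactly(self):
        cfg = GeneratorConfig(n_genes=50, chrom_length=1_000_000, seed=5)
        g1, t1 = generate_genome(cfg)
        g2, t2 = generate_genome(cfg)
        assert [g.interval for g in g1] == [g.interval for g in g2]
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        g1, _ = generate_genome(GeneratorConfig(n_genes=50, chrom_length=1_000_000, seed=5))
        g2, _ = generate_genome(GeneratorConfig(n_genes=50, chrom_length=1_000_000, seed=6))
        assert [g.interval for g in g1] != [g.interval for g in g2]

    def test_no_paused_labels_when_fraction_zero(self):
        _, truth = generate_genome(
            GeneratorConfig(n_genes=80, chrom_length=1_500_000,
                            fraction_paused=0.0, seed=1)
        )
        assert (truth["true_class"] == CLASS_UNCHANGED).all()

    def test_label_counts_near_binomial(self):
        _, truth = generate_genome(
            GeneratorConfig(n_genes=100, chrom_length=2_000_000,
                            fraction_paused=0.3, seed=3)
        )
        n_paused = (truth["true_class"] == CLASS_PAUSED).sum()
        # within 4 binomial SDs of 30
        assert abs(n_paused - 30) < 4 * np.sqrt(100 * 0.3 * 0.7)

    def test_genes_non_overlapping(self):
        genes, _ = generate_genome(
            GeneratorConfig(n_genes=100, chrom_length=2_000_000, seed=2)
        )
        for a, b in zip(genes, genes[1:]):
            assert a.interval.end < b.interval.start

    def test_overfull_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="chrom_length"):
            generate_genome(GeneratorConfig(n_genes=500, chrom_length=100_000))

    def test_paused_fold_change_is_release_fold(self):
        _, truth = generate_genome(
            GeneratorConfig(n_genes=200, chrom_length=4_000_000,
                            release_fold=3.0, seed=4)
        )
        prr = lambda t, c: (t[f"body_rate_{c}"] / t[f"promoter_rate_{c}"])
        fc = prr(truth, "treat") / prr(truth, "ctrl")
        paused = truth["true_class"] == CLASS_PAUSED
        assert np.allclose(fc[paused], 3.0)
        assert np.allclose(fc[~paused], 1.0)

    def test_treatment_conserves_expected_gene_signal(self):
        cfg = GeneratorConfig(n_genes=200, chrom_length=4_000_000, seed=4)
        genes, truth = generate_genome(cfg)
        span = cfg.promoter_up + cfg.promoter_down
        body_len = np.array([g.length - cfg.promoter_down for g in genes])
        total = lambda c: (
            truth[f"promoter_rate_{c}"] * span + truth[f"body_rate_{c}"] * body_len
        )
        assert np.allclose(total("ctrl"), total("treat"))


def one_gene_setup(prom_rate, body_rate, length=2350, strand="+"):
    cfg = GeneratorConfig(
        n_genes=1, chrom_length=100_000, background_rate=0.0, seed=0
    )
    start = 10_000
    g = GeneModel("g0000", GenomicInterval(cfg.chrom, start, start + length, strand))
    truth = pd.DataFrame(
        {
            "gene_id": ["g0000"],
            "true_class": [CLASS_UNCHANGED],
            "promoter_rate_ctrl": [prom_rate],
            "body_rate_ctrl": [body_rate],
            "promoter_rate_treat": [prom_rate],
            "body_rate_treat": [body_rate],
            "seed": [0],
        }
    )
    return cfg, [g], truth


class TestCoverage:
    def test_monte_carlo_prr_matches_analytic_ratio(self):
        """Promoter 5/bp vs body 0.5/bp with 350 bp / 2 kb windows: the
        measured density ratio concentrates on 0.1."""
        prom_rate, body_rate = 5.0, 0.5
        cfg, genes, truth = one_gene_setup(prom_rate, body_rate)
        (w,) = build_windows(genes)
        ratios = []
        for seed in range(50):
            cfg2 = GeneratorConfig(**{**vars(cfg), "seed": seed})
            tracks = simulate_coverage(genes, truth, cfg2, "ctrl")
            t = tracks["+"]
            dp = window_density(t, w.promoter, 1e6)
            db = window_density(t, w.body, 1e6)
            ratios.append(db / dp)
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - body_rate / prom_rate) < 3 * se + 1e-4

    def test_window_sums_match_rates(self):
        cfg, genes, truth = one_gene_setup(4.0, 1.0, length=5000)
        tracks = simulate_coverage(genes, truth, cfg, "ctrl")
        (w,) = build_windows(genes)
        prom_sum = tracks["+"].window_sum(cfg.chrom, w.promoter.start, w.promoter.end)
        lam = 4.0 * 350
        assert abs(prom_sum - lam) < 4 * np.sqrt(lam)

    def test_minus_strand_gene_signal_on_minus_track(self):
        cfg, genes, truth = one_gene_setup(5.0, 0.5, strand="-")
        tracks = simulate_coverage(genes, truth, cfg, "ctrl")
        assert tracks["-"].total_signal > 0
        assert tracks["+"].total_signal == 0.0

    def test_coverage_deterministic_per_condition_stream(self):
        cfg, genes, truth = one_gene_setup(2.0, 0.5)
        a = simulate_coverage(genes, truth, cfg, "ctrl")
        b = simulate_coverage(genes, truth, cfg, "ctrl")
        c = simulate_coverage(genes, truth, cfg, "treat")
        assert a["+"] == b["+"]
        assert not (a["+"] == c["+"])

    def test_body_tiles_preserve_total_signal_distribution(self):
        """Tiled and per-base body simulation agree in window-sum moments."""
        cfg, genes, truth = one_gene_setup(3.0, 1.0, length=6000)
        (w,) = build_windows(genes)
        sums = {"tiled": [], "per_base": []}
        for seed in range(30):
            for label, tile in (("tiled", 25), ("per_base", 1)):
                c = GeneratorConfig(**{**vars(cfg), "seed": seed, "body_tile_bp": tile})
                t = simulate_coverage(genes, truth, c, "ctrl")["+"]
                sums[label].append(t.window_sum(c.chrom, w.body.start, w.body.end))
        lam = 1.0 * w.body.length
        for label, vals in sums.items():
            assert abs(np.mean(vals) - lam) < 4 * np.sqrt(lam / 30), label


class TestPeaks:
    def test_consensus_recovers_true_promoters(self, small_config, small_study):
        genes, truth, _, _ = small_study
        reps = simulate_peaks(genes, truth, small_config)
        cps = consensus(reps, min_sets=len(reps), fdr_max=0.05)
        assert len(cps) == len(genes)
        # each consensus peak covers its gene's TSS-centred true interval
        # to within the +/- 20 bp boundary jitter
        tss = sorted(
            (g.tss if g.strand == "+" else g.tss - 1) for g in genes
        )
        for p, center in zip(cps.peaks, tss):
            assert p.interval.start == pytest.approx(center - 200, abs=21)
            assert p.interval.end == pytest.approx(center + 200, abs=21)

    def test_fdr_filter_removes_all_decoys(self, small_config, small_study):
        genes, truth, _, _ = small_study
        reps = simulate_peaks(genes, truth, small_config)
        n_true = len(genes)
        for rep in reps:
            kept = [p for p in rep if p.fdr <= 0.05]
            assert len(kept) == n_true

    def test_replicates_jitter_but_share_promoters(self, small_config, small_study):
        genes, truth, _, _ = small_study
        r1, r2, _ = simulate_peaks(genes, truth, small_config)
        starts1 = [p.interval.start for p in r1 if p.fdr <= 0.05]
        starts2 = [p.interval.start for p in r2 if p.fdr <= 0.05]
        assert starts1 != starts2
        assert np.abs(np.array(starts1) - np.array(starts2)).max() <= 40


def test_gene_sets_cover_truth_classes(small_config, small_study):
    genes, truth, _, _ = small_study
    sets = make_gene_sets(truth, small_config)
    names = {s.name for s in sets}
    assert "paused_enriched" in names and "unchanged_enriched" in names
    paused = set(truth.loc[truth["true_class"] == CLASS_PAUSED, "gene_id"])
    enriched = next(s for s in sets if s.name == "paused_enriched")
    frac_paused = len(enriched.members & paused) / len(enriched.members)
    assert frac_paused > 0.5
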