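"""Replication-vs-power models, excess counting, permutation, LD pruning."""

import numpy as np
import pandas as pd
import pytest

import powerrep as pr
from powerrep.enrichment import (
    excess_by_power,
    excess_from_counts,
    fit_model,
    ld_prune,
    permutation_control,
    spline_summary,
)
from powerrep.pipeline import RunConfig, powered_records_from_pair
from powerrep.simulator import simulate_ld_block_genotypes
from conftest import make_records


class TestFitModel:
    def test_model_term_structure(self, enriched_records):
        terms = {
            "I": {"intercept", "power"},
            "II": {"intercept", "power", "near_exon", "power_x_near_exon"},
            "III": {"intercept", "power"},
            "IV": {"intercept", "power", "near_exon", "power_x_near_exon"},
            "M1": {"intercept", "same_direction"},
            "M2": {"intercept", "power", "same_direction", "power_x_same_direction"},
        }
        for tag, expected in terms.items():
            thr = 2000 if tag in ("II", "IV") else None
            fit = fit_model(enriched_records, tag, near_exon_threshold_bp=thr)
            assert set(fit.coefficients) == expected, tag
            assert fit.converged

    def test_enriched_pair_detected_by_model_i(self, enriched_records):
        fit = fit_model(enriched_records, "I")
        est, se, pv = fit.term("power")
        assert est > 0 and pv < 1e-10

    def test_same_direction_subset_sharpens_the_signal(self, enriched_records):
        """Restricting to same-direction SNPs concentrates true effects, so
        the power term strengthens (per-unit-SE) relative to the all-SNP fit."""
        fit_all = fit_model(enriched_records, "I")
        fit_sd = fit_model(enriched_records, "III")
        assert fit_sd.n_snps < fit_all.n_snps
        z_all = fit_all.term("power")[0] / fit_all.term("power")[1]
        z_sd = fit_sd.term("power")[0] / fit_sd.term("power")[1]
        assert z_sd > 0 and z_all > 0

    def test_direction_models_on_enriched_pair(self, enriched_records):
        m1 = fit_model(enriched_records, "M1")
        assert m1.term("same_direction")[0] > 0
        assert m1.term("same_direction")[2] < 1e-6
        m2 = fit_model(enriched_records, "M2")
        assert set(m2.coefficients) >= {"power", "same_direction"}

    def test_constant_outcome_rejected(self):
        df = make_records(100, power=0.5, replicated=True)
        with pytest.raises(ValueError, match="constant"):
            fit_model(df, "I")

    def test_missing_near_exon_column_rejected(self):
        df = make_records(100, power=0.5, replicated=[True, False] * 50)
        with pytest.raises(ValueError, match="annotate"):
            fit_model(df, "II", near_exon_threshold_bp=9999)

    def test_lrt_switch_gives_comparable_pvalue(self, enriched_records):
        wald = fit_model(enriched_records, "I").term("power")[2]
        lrt = fit_model(enriched_records, "I", use_lrt=True).term("power")[2]
        assert lrt < 1e-10 and wald < 1e-10

    def test_separation_flagged_with_pvalues_withheld(self):
        rng = np.random.default_rng(0)
        power = rng.uniform(size=200)
        df = make_records(200, power=power, replicated=power > 0.5)
        fit = fit_model(df, "I")
        assert not fit.converged
        assert fit.term("power")[2] is None


class TestExcess:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(50, 500))
            power = rng.uniform(size=n)
            rep = rng.uniform(size=n) < 0.3
            df = make_records(n, power=power, replicated=rep)
            thr = float(rng.uniform(0.2, 0.9))
            report = excess_by_power(df, thr)
            # brute force
            high = [i for i in range(n) if power[i] >= thr]
            n_rep_high = sum(bool(rep[i]) for i in high)
            expected = len(high) * (rep.sum() / n)
            assert report.n_high == len(high)
            assert report.n_replicated_high == n_rep_high
            assert report.expected == pytest.approx(expected)
            assert report.excess == pytest.approx(n_rep_high - expected)
            assert sum(c[1] for c in report.per_decile_counts) == n
            assert sum(c[2] for c in report.per_decile_counts) == rep.sum()

    def test_rate_equal_in_and_out_of_stratum_gives_zero_excess(self):
        df = make_records(
            200,
            power=np.r_[np.full(100, 0.9), np.full(100, 0.1)],
            replicated=np.r_[
                np.tile([True, False], 50), np.tile([True, False], 50)
            ],
        )
        report = excess_by_power(df, 0.6)
        assert report.excess == pytest.approx(0.0)

    def test_all_records_above_threshold(self):
        df = make_records(100, power=0.95, replicated=[True] * 30 + [False] * 70)
        report = excess_by_power(df, 0.5)
        assert report.expected == report.n_replicated_high
        assert report.excess == 0.0

    def test_no_high_power_records(self):
        df = make_records(100, power=0.2, replicated=[True, False] * 50)
        report = excess_by_power(df, 0.9)
        assert report.n_high == 0 and report.excess == 0.0

    def test_counts_helper_arithmetic(self):
        report = excess_from_counts(364_259, 7_277, 503, 0.0569)
        assert report.expected == pytest.approx(7_277 * 0.0569)
        assert report.excess_rounded == 89


class TestPermutation:
    def test_single_permutation_deterministic(self, enriched_records):
        a = permutation_control(enriched_records, 1, seed=9)
        b = permutation_control(enriched_records, 1, seed=9)
        assert a == b

    def test_labels_exchangeable_under_permutation(self, enriched_records):
        pvals = permutation_control(enriched_records, 60, seed=4)
        # permuted fits are null fits: rejection near nominal, not enriched
        assert (pvals < 0.05).mean() < 0.2
        assert pvals.min() > 1e-4

    def test_observed_fit_beats_permutation_distribution(self, enriched_records):
        observed = fit_model(enriched_records, "I").term("power")[2]
        pvals = permutation_control(enriched_records, 60, seed=12)
        assert observed < np.quantile(pvals, 0.01)


class TestLdPrune:
    def test_duplicate_snps_collapse_to_one(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        G = np.hstack([g, g])
        assert ld_prune(G, ["a", "b"]) == ["a"]

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.3, size=(500, 30)).astype(float)
        ids = [f"rs{i}" for i in range(30)]
        assert ld_prune(G, ids) == ids

    def test_within_window_pairs_below_threshold_after_pruning(self):
        """Exhaustive check on a block-correlated 200-SNP panel."""
        dos = simulate_ld_block_genotypes(400, 200, block_size=8, rho=0.95, seed=3)
        kept = ld_prune(dos, window=50, step=5, r2_max=0.5)
        assert 0 < len(kept) < 200
        sub = dos[kept].to_numpy()
        pos = {s: i for i, s in enumerate(dos.columns)}
        order = [pos[s] for s in kept]
        r2 = np.corrcoef(sub, rowvar=False) ** 2
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if order[b] - order[a] < 46:  # guaranteed to share a window
                    assert r2[a, b] < 0.5

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            ld_prune(np.zeros((10, 3)), window=1)


class TestDistanceSweep:
    def test_interaction_peaks_at_the_planting_scale(self):
        """Causal SNPs planted within 10 kb of exons: sweeping the near-exon
        cutoff, the power x near-exon interaction is strongest at a mid-range
        threshold, not at the narrowest or widest."""
        grid = (2000, 10_000, 25_000, 100_000)
        cfg = RunConfig(exon_thresholds=grid)
        peaks = []
        for seed in range(5):
            pair = pr.generate_study_pair(
                n_snps=10_000, frac_causal=0.3, effect_scale=0.08,
                exon_frac_near=1.0, near_bp=10_000, seed=700 + seed,
            )
            records = powered_records_from_pair(pair, cfg)
            neglogp = []
            for thr in grid:
                pv = fit_model(records, "II", near_exon_threshold_bp=thr).term(
                    "power_x_near_exon"
                )[2]
                neglogp.append(-np.log10(max(pv, 1e-300)) if pv is not None else 0.0)
            peaks.append(grid[int(np.argmax(neglogp))])
        mid_range = sum(p in (10_000, 25_000) for p in peaks)
        assert mid_range >= 4


class TestSplineSummary:
    def test_constant_indicator_gives_flat_line(self):
        df = make_records(100, power=np.linspace(0, 1, 100), replicated=True)
        grid, prop = spline_summary(df)
        assert np.allclose(prop, 1.0)

    def test_grid_covers_unit_interval_monotonically(self, enriched_records):
        grid, prop = spline_summary(enriched_records)
        assert grid[0] == 0.0 and grid[-1] == 1.0
        assert np.all(np.diff(grid) > 0)
        assert np.all((prop >= 0) & (prop <= 1))

    def test_calibrated_pair_tracks_identity(self):
        """With a huge discovery sample the analytic power is essentially the
        true replication probability, so the smoothed curve hugs y = x."""
        pair = pr.generate_study_pair(
            n_snps=20_000, frac_causal=1.0, effect_scale=0.15,
            trait_kind="quantitative", n_disc=500_000, n_test=37_052,
            sd_trait=9.2, seed=21,
        )
        records = powered_records_from_pair(pair, RunConfig(trait_kind="quantitative"))
        grid, prop = spline_summary(records)
        sel = (grid >= 0.1) & (grid <= 0.9)
        assert np.abs(prop[sel] - grid[sel]).max() < 0.1

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            spline_summary(make_records(10, power=0.5, replicated=True))
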