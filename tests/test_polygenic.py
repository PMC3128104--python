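"""Polygenic scoring and score-phenotype association."""

import numpy as np
import pandas as pd
import pytest

import powerrep as pr
from powerrep.polygenic import (
    SeparationError,
    compute_scores,
    nagelkerke_r2,
    progressive_thresholds,
    score_association,
)
from powerrep.simulator import generate_study_pair, simulate_case_control_cohort


def make_dosages(matrix, snps=None, inds=None):
    matrix = np.asarray(matrix, dtype=float)
    snps = snps or [f"rs{i}" for i in range(matrix.shape[1])]
    inds = inds or [f"ind{i}" for i in range(matrix.shape[0])]
    return pd.DataFrame(matrix, columns=snps, index=inds)


class TestComputeScores:
    def test_single_snp_arithmetic(self):
        dos = make_dosages([[2.0], [1.0], [0.0]])
        (a, b, c) = compute_scores(dos, {"rs0": 0.2}, {"rs0": 0.01}, 0.05)
        assert a.score == pytest.approx(0.4)  # mean over one SNP = lnOR * dosage
        assert b.score == pytest.approx(0.2)
        assert c.score == 0.0
        assert a.n_snps_used == 1

    def test_sum_mode_scales_with_snp_count(self):
        dos = make_dosages([[1.0, 1.0]])
        effects = {"rs0": 0.2, "rs1": 0.2}
        pvs = {"rs0": 0.01, "rs1": 0.01}
        (mean_p,) = compute_scores(dos, effects, pvs, 0.05, mode="mean")
        (sum_p,) = compute_scores(dos, effects, pvs, 0.05, mode="sum")
        assert sum_p.score == pytest.approx(2 * mean_p.score)

    def test_zero_effects_give_zero_scores(self):
        dos = make_dosages(np.random.default_rng(0).integers(0, 3, (5, 4)))
        profiles = compute_scores(
            dos, {c: 0.0 for c in dos.columns}, {c: 0.5 for c in dos.columns}, 1.0
        )
        assert all(p.score == 0.0 for p in profiles)

    def test_missing_dosages_averaged_over_nonmissing(self):
        dos = make_dosages([[2.0, np.nan], [np.nan, np.nan]])
        profiles = compute_scores(
            dos, {"rs0": 0.1, "rs1": 0.3}, {"rs0": 0.01, "rs1": 0.01}, 0.05
        )
        assert profiles[0].score == pytest.approx(0.2)
        assert profiles[0].n_snps_used == 1
        assert np.isnan(profiles[1].score)

    def test_empty_subset_is_an_error_naming_threshold(self):
        dos = make_dosages([[1.0]])
        with pytest.raises(ValueError, match="1e-10"):
            compute_scores(dos, {"rs0": 0.1}, {"rs0": 0.5}, 1e-10)

    def test_threshold_subsets_are_nested(self):
        rng = np.random.default_rng(3)
        pvs = {f"rs{i}": float(p) for i, p in enumerate(rng.uniform(size=50))}
        effects = {s: 0.1 for s in pvs}
        dos = make_dosages(rng.integers(0, 3, (4, 50)), snps=list(pvs))
        previous: set = set()
        for thr in (0.01, 0.1, 0.5, 1.0):
            included = {s for s in pvs if pvs[s] <= thr}
            assert previous <= included
            previous = included
            profiles = compute_scores(dos, effects, pvs, thr)
            assert profiles[0].n_snps_used == len(included)


class TestScoreAssociation:
    def test_null_score_uninformative(self):
        rng = np.random.default_rng(4)
        dos = make_dosages(rng.integers(0, 3, (400, 100)))
        effects = {c: float(e) for c, e in zip(dos.columns, rng.normal(0, 0.1, 100))}
        pvs = {c: 1.0 for c in dos.columns}
        status = rng.integers(0, 2, 400)  # independent of genotype
        pv, r2 = score_association(compute_scores(dos, effects, pvs, 1.0), status)
        assert r2 < 0.03

    def test_pseudo_r2_affine_invariant_and_bounded(self):
        pair = generate_study_pair(n_snps=500, frac_causal=0.5, effect_scale=0.2, seed=15)
        dos, status = simulate_case_control_cohort(pair.truth, 300, 300, seed=16)
        effects = {s.snp_id: np.log(s.effect) for s in pair.discovery}
        pvs = {s.snp_id: s.pvalue for s in pair.discovery}
        profiles = compute_scores(dos, effects, pvs, 1.0)
        pv, r2 = score_association(profiles, status)
        assert 0.0 < r2 <= 1.0 and pv < 0.01
        rescaled = [
            type(p)(p.individual_id, 3.0 * p.score - 1.0, p.n_snps_used, p.threshold)
            for p in profiles
        ]
        pv2, r22 = score_association(rescaled, status)
        assert r22 == pytest.approx(r2, rel=1e-6)
        assert pv2 == pytest.approx(pv, rel=1e-6)

    def test_enriched_architecture_beats_null(self):
        pair = generate_study_pair(n_snps=800, frac_causal=0.5, effect_scale=0.2, seed=17)
        dos, status = simulate_case_control_cohort(pair.truth, 300, 300, seed=18)
        effects = {s.snp_id: np.log(s.effect) for s in pair.discovery}
        pvs = {s.snp_id: s.pvalue for s in pair.discovery}
        _, r2_enriched = score_association(compute_scores(dos, effects, pvs, 1.0), status)

        null_pair = generate_study_pair(n_snps=800, frac_causal=0.0, seed=19)
        dos0, status0 = simulate_case_control_cohort(null_pair.truth, 300, 300, seed=20)
        eff0 = {s.snp_id: np.log(s.effect) for s in null_pair.discovery}
        pv0 = {s.snp_id: s.pvalue for s in null_pair.discovery}
        _, r2_null = score_association(compute_scores(dos0, eff0, pv0, 1.0), status0)
        assert r2_enriched > r2_null + 0.05

    def test_larger_discovery_sharpens_the_score(self):
        """Better-estimated discovery effects should explain more variance."""
        r2s = {}
        for label, n_disc in (("small", (300, 300)), ("large", (20_000, 20_000))):
            vals = []
            for seed in range(6):
                pair = generate_study_pair(
                    n_snps=800, frac_causal=0.5, effect_scale=0.2,
                    n_disc=n_disc, seed=100 + seed,
                )
                dos, status = simulate_case_control_cohort(
                    pair.truth, 300, 300, seed=200 + seed
                )
                effects = {s.snp_id: np.log(s.effect) for s in pair.discovery}
                pvs = {s.snp_id: s.pvalue for s in pair.discovery}
                vals.append(
                    score_association(compute_scores(dos, effects, pvs, 1.0), status)[1]
                )
            r2s[label] = np.mean(vals)
        assert r2s["large"] > r2s["small"]

    def test_constant_score_rejected(self):
        profiles = compute_scores(
            make_dosages([[1.0], [1.0], [1.0], [1.0]]), {"rs0": 0.1}, {"rs0": 0.01}, 1.0
        )
        with pytest.raises(ValueError, match="constant"):
            score_association(profiles, [0, 0, 1, 1])

    def test_perfect_separation_flagged(self):
        dos = make_dosages([[0.0], [0.1], [0.2], [1.8], [1.9], [2.0]])
        profiles = compute_scores(dos, {"rs0": 1.0}, {"rs0": 0.01}, 1.0)
        with pytest.raises(SeparationError):
            score_association(profiles, [0, 0, 0, 1, 1, 1])

    def test_too_few_per_class_rejected(self):
        profiles = compute_scores(
            make_dosages([[0.0], [1.0], [2.0]]), {"rs0": 1.0}, {"rs0": 0.01}, 1.0
        )
        with pytest.raises(ValueError, match="phenotype class"):
            score_association(profiles, [0, 0, 1])


class TestProgressiveCurve:
    def test_curve_reproducible_and_well_formed(self):
        pair = generate_study_pair(n_snps=600, frac_causal=0.5, effect_scale=0.2, seed=21)
        dos, status = simulate_case_control_cohort(pair.truth, 250, 250, seed=22)
        effects = {s.snp_id: np.log(s.effect) for s in pair.discovery}
        pvs = {s.snp_id: s.pvalue for s in pair.discovery}
        a = progressive_thresholds(dos, effects, pvs, status)
        b = progressive_thresholds(dos, effects, pvs, status)
        pd.testing.assert_frame_equal(a, b)
        assert a["n_snps"].is_monotonic_increasing
        valid = a["pseudo_r2"].dropna()
        assert ((valid >= 0) & (valid <= 1)).all()


def test_nagelkerke_matches_reference_formula():
    # hand-computed: llnull=-60, llf=-50, n=100
    cs = 1 - np.exp(2 * (-60 + 50) / 100)
    mx = 1 - np.exp(2 * -60 / 100)
    assert nagelkerke_r2(-50.0, -60.0, 100) == pytest.approx(cs / mx)
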