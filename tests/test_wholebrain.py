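"""Repeated-CV ridge comparison: fits, permutation, bootstrap, grid run."""

import itertools

import numpy as np
import pandas as pd
import pytest

from edubrain import RegressionSpec, SyntheticConfig, simulate_cohort
from edubrain.regional import fdr_bh
from edubrain.wholebrain import (
    CVResult,
    RepeatedRidgeCV,
    compare_predictors,
    cv_ridge_r2,
    default_alpha_grid,
    run_group_modality_grid,
    _ridge_fit_predict,
)


def _participants(rng, n):
    return pd.DataFrame(
        {
            "eq": rng.normal(2.0, 0.5, n),
            "yoe": rng.uniform(0, 20, n),
            "age": rng.normal(60, 10, n),
            "sex": rng.integers(0, 2, n),
            "mmse": rng.normal(27, 2, n),
            "tiv": rng.normal(1.4e6, 1e5, n),
        }
    )


SPEC = RegressionSpec("eq", ("age", "sex", "mmse", "tiv"))


class TestAlphaGrid:
    def test_grid_endpoints_and_length(self):
        g = default_alpha_grid()
        assert len(g) == 1000
        assert g[0] == pytest.approx(1e-10)
        assert g[-1] == pytest.approx(1e10)


class TestRepeatedRidgeCV:
    def test_noiseless_linear_outcome_recovered(self, rng):
        df = _participants(rng, 300)
        y = 0.5 * df["eq"] + 0.01 * df["age"] + 0.2 * df["mmse"]
        cv = cv_ridge_r2(y.to_numpy(), df, SPEC, seed=0)
        assert len(cv.rep_scores) == 20
        assert (cv.rep_scores >= 0.99).all()

    def test_independent_outcome_near_zero_r2(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = _participants(rng, 300)
            y = rng.normal(size=300)
            means.append(cv_ridge_r2(y, df, SPEC, reps=5, seed=seed).mean_r2)
        assert np.mean(means) <= 0.02

    def test_infinite_shrinkage_limit(self, rng):
        df = _participants(rng, 120)
        y = 0.5 * df["eq"].to_numpy() + rng.normal(0, 0.1, 120)
        cv = cv_ridge_r2(y, df, SPEC, alphas=np.array([1e10]), seed=0)
        assert (cv.rep_scores <= 1e-3).all()

    def test_ridge_at_grid_minimum_matches_ols(self, rng):
        X = rng.normal(size=(200, 4))
        y = X @ np.array([0.5, -0.2, 0.1, 0.3]) + rng.normal(0, 0.5, 200)
        Xc = X - X.mean(axis=0)
        pred = _ridge_fit_predict(Xc, y, Xc, 1e-10)
        beta_ols, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(200), Xc]), y, rcond=None
        )
        pred_ols = np.column_stack([np.ones(200), Xc]) @ beta_ols
        np.testing.assert_allclose(pred, pred_ols, atol=1e-6)

    def test_ridge_path_matches_sklearn_ridge(self, rng):
        from sklearn.linear_model import Ridge

        X = rng.normal(size=(150, 5))
        y = rng.normal(size=150)
        Xc = X - X.mean(axis=0)
        for alpha in (1e-6, 1.0, 100.0):
            ours = _ridge_fit_predict(Xc, y, Xc, alpha)
            ref = Ridge(alpha=alpha).fit(Xc, y).predict(Xc)
            np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_zero_variance_outcome_rejected(self, rng):
        df = _participants(rng, 60)
        with pytest.raises(ValueError, match="zero-variance"):
            cv_ridge_r2(np.ones(60), df, SPEC)

    def test_too_few_subjects_rejected(self, rng):
        df = _participants(rng, 6)
        with pytest.raises(ValueError):
            cv_ridge_r2(rng.normal(size=6), df, SPEC)

    def test_deterministic_given_seed(self, rng):
        df = _participants(rng, 90)
        y = rng.normal(size=90)
        a = cv_ridge_r2(y, df, SPEC, reps=4, seed=5)
        b = cv_ridge_r2(y, df, SPEC, reps=4, seed=5)
        np.testing.assert_array_equal(a.rep_scores, b.rep_scores)
        np.testing.assert_array_equal(a.chosen_alphas, b.chosen_alphas)


def _cv(scores, name="eq", losses=None):
    scores = np.asarray(scores, dtype=float)
    return CVResult(name, scores, np.zeros((len(scores), 3)), 0, subject_losses=losses)


class TestComparePredictors:
    def test_identical_vectors_null_result(self, rng):
        v = rng.normal(0.2, 0.02, 20)
        res = compare_predictors(_cv(v), _cv(v, "yoe"), iterations=2000, seed=0)
        assert res.delta_mean == 0.0
        assert res.p == pytest.approx(1.0)

    def test_constant_offset_exact_enumeration(self):
        # reps=8 allows full enumeration; a constant offset is the most
        # extreme configuration, so p equals the enumeration minimum 2/2^8
        base = np.linspace(0.1, 0.2, 8)
        res = compare_predictors(
            _cv(base + 0.05), _cv(base, "yoe"), iterations=100_000, seed=0
        )
        assert res.delta_mean == pytest.approx(0.05)
        assert res.n_iterations == 256
        assert res.p == pytest.approx(2 / 256)

    def test_exhaustive_oracle_on_small_rep_count(self, rng):
        diff = rng.normal(0.01, 0.02, 6)
        a = 0.2 + diff
        b = np.full(6, 0.2)
        res = compare_predictors(_cv(a), _cv(b, "yoe"), iterations=100_000, seed=0)
        obs = abs(diff.mean())
        count = sum(
            abs(np.mean([d * s for d, s in zip(diff, signs)])) >= obs - 1e-15
            for signs in itertools.product([1, -1], repeat=6)
        )
        assert res.p == pytest.approx(count / 64)

    def test_antisymmetry_of_delta_and_ratio(self, rng):
        a, b = _cv(rng.normal(0.3, 0.02, 10)), _cv(rng.normal(0.2, 0.02, 10), "yoe")
        fwd = compare_predictors(a, b, iterations=500, seed=1)
        rev = compare_predictors(b, a, iterations=500, seed=1)
        assert fwd.delta_mean == pytest.approx(-rev.delta_mean)
        assert fwd.ratio == pytest.approx(1 / rev.ratio)

    def test_ratio_guard_for_near_zero_denominator(self, rng):
        res = compare_predictors(
            _cv(rng.normal(0.2, 0.01, 10)), _cv(np.zeros(10), "yoe"),
            iterations=200, seed=0,
        )
        assert np.isnan(res.ratio)

    def test_rep_scheme_super_uniform_under_exchangeable_null(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_sim = 500
        for i in range(n_sim):
            a = 0.2 + rng.normal(0, 0.03, 20)
            b = 0.2 + rng.normal(0, 0.03, 20)
            res = compare_predictors(_cv(a), _cv(b, "yoe"), iterations=400, seed=i)
            hits += res.p <= 0.05
        assert hits / n_sim <= 0.07

    def test_bootstrap_ci_contains_point_estimate(self, rng):
        for i in range(20):
            a = _cv(rng.normal(0.25, 0.03, 12))
            b = _cv(rng.normal(0.2, 0.03, 12), "yoe")
            res = compare_predictors(a, b, iterations=500, seed=i)
            assert res.ci95[0] <= res.delta_mean <= res.ci95[1]

    def test_mismatched_rep_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_predictors(_cv(rng.normal(size=5)), _cv(rng.normal(size=6)))

    def test_subject_scheme_used_when_losses_available(self, rng):
        losses_a = rng.random((5, 40))
        losses_b = losses_a + 0.2  # predictor a uniformly better
        res = compare_predictors(
            _cv(rng.random(5), losses=losses_a),
            _cv(rng.random(5), "yoe", losses=losses_b),
            iterations=2000,
            seed=0,
        )
        assert res.extras["scheme"] == "subject"
        assert res.p < 0.01


@pytest.fixture(scope="module")
def grid_cohort():
    return simulate_cohort(
        SyntheticConfig(
            n_subjects_per_group=(60, 40, 40),
            grid_shape=(7, 7, 7),
            n_rois=16,
            n_countries=10,
            seed=21,
        )
    )


class TestGroupModalityGrid:

    def test_grid_covers_all_cells_and_is_deterministic(self, grid_cohort):
        kwargs = dict(k=3, reps=4, iterations=300, seed=5)
        a = run_group_modality_grid(grid_cohort, **kwargs)
        b = run_group_modality_grid(grid_cohort, **kwargs)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 3 * 2 * 2
        assert set(a["contrast"]) == {"eq_vs_yoe", "eq_vs_eqxyoe"}

    def test_absent_group_rejected(self, grid_cohort):
        with pytest.raises(ValueError, match="absent"):
            run_group_modality_grid(grid_cohort, groups=("HC", "AD", "FTLD", "HC2"))

    def test_null_cohort_grid_calibrated_after_fdr(self):
        sig_free = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort = simulate_cohort(
                SyntheticConfig(
                    n_subjects_per_group=(70, 50, 50),
                    grid_shape=(6, 6, 6),
                    n_rois=20,
                    n_countries=10,
                    beta_eq=0.0,
                    beta_yoe=0.0,
                    seed=400 + seed,
                )
            )
            grid = run_group_modality_grid(
                cohort, k=3, reps=5, iterations=500, seed=seed
            )
            sig_free += not fdr_bh(grid["p"].to_numpy(), 0.05).any()
        assert sig_free >= int(0.9 * n_seeds)

    def test_planted_modality_ordering_reproduced(self):
        # FC edge effects planted much stronger than GM voxel effects
        cohort = simulate_cohort(
            SyntheticConfig(
                n_subjects_per_group=(150, 0, 0),
                grid_shape=(6, 6, 6),
                n_rois=24,
                beta_eq=0.08,
                beta_yoe=0.04,
                beta_eq_fc=1.2,
                beta_yoe_fc=0.2,
                fc_gain=0.9,
                seed=33,
            )
        )
        grid = run_group_modality_grid(
            cohort, groups=("HC",), contrasts=(("eq", "yoe"),),
            k=3, reps=8, iterations=1000, seed=3,
        )
        d = grid.set_index("modality")["delta_mean"]
        assert d["fc"] > d["gm"]
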