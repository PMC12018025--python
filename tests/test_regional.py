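"""Mass-univariate regression, FDR, assumption checks, paired map comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from edubrain.regional import (
    MassUnivariateOLS,
    RegressionSpec,
    adjusted_r2,
    build_design,
    check_assumptions,
    compare_effect_maps,
    fdr_bh,
    fit_mass_univariate,
)


def make_participants(rng, n, with_cov=True):
    df = pd.DataFrame(
        {
            "eq": rng.normal(2.0, 0.5, n),
            "yoe": rng.uniform(0, 20, n),
        }
    )
    if with_cov:
        df["age"] = rng.normal(60, 10, n)
        df["sex"] = rng.integers(0, 2, n)
        df["mmse"] = rng.normal(27, 2, n)
        df["tiv"] = rng.normal(1.4e6, 1e5, n)
    return df


def brute_force_bh(p, q):
    """Step-up oracle: reject smallest k where p_(k) <= k q / m."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, ix in enumerate(order, start=1):
        if p[ix] <= i * q / m:
            k = i
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2,n,p,expected",
        [
            (0.5, 100, 1, 0.49490),
            (1.0, 50, 3, 1.0),
            (0.0, 50, 3, -3 / 46),
        ],
    )
    def test_formula_arithmetic(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected, abs=1e-5)

    def test_monotone_in_r2_and_decreasing_in_p(self):
        assert adjusted_r2(0.6, 80, 2) > adjusted_r2(0.5, 80, 2)
        assert adjusted_r2(0.5, 80, 5) < adjusted_r2(0.5, 80, 2)

    def test_degenerate_sample_size_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 4, 3)


class TestFdrBH:
    def test_step_up_example(self):
        mask = fdr_bh([0.001, 0.02, 0.03, 0.04, 0.2], q=0.05)
        np.testing.assert_array_equal(mask, [True, True, True, True, False])

    def test_all_ones_rejects_none(self):
        assert not fdr_bh(np.ones(10)).any()

    def test_single_small_p_rejected(self):
        assert fdr_bh([0.01], q=0.05).all()

    def test_matches_brute_force_oracle_and_order_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            mask = fdr_bh(p, 0.05)
            np.testing.assert_array_equal(mask, brute_force_bh(p, 0.05))
            perm = rng.permutation(m)
            np.testing.assert_array_equal(fdr_bh(p[perm], 0.05), mask[perm])

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestMassUnivariate:
    def test_unit_equal_to_predictor_is_perfectly_fit(self, rng):
        df = make_participants(rng, 60, with_cov=False)
        em = fit_mass_univariate(
            df["eq"].to_numpy()[:, None], df, RegressionSpec("eq", covariates=())
        )
        assert em.r2[0] == pytest.approx(1.0)
        assert em.beta[0] == pytest.approx(1.0)

    def test_matches_per_unit_statsmodels_reference(self, rng):
        df = make_participants(rng, 80)
        Y = rng.normal(size=(80, 15)) + 0.3 * df["eq"].to_numpy()[:, None]
        spec = RegressionSpec("eq", ("age", "sex", "mmse", "tiv"))
        est = MassUnivariateOLS(spec).fit(Y, df)
        X, names = build_design(df, spec)
        j = names.index("eq")
        for u in range(15):
            ref = sm.OLS(Y[:, u], X).fit()
            assert est.beta_[u] == pytest.approx(ref.params[j], abs=1e-8)
            assert est.p_[u] == pytest.approx(ref.pvalues[j], abs=1e-8)
            assert est.r2_[u] == pytest.approx(ref.rsquared, abs=1e-8)
            assert est.r2_adj_[u] == pytest.approx(ref.rsquared_adj, abs=1e-8)

    def test_null_predictor_calibration(self):
        fracs, n_fdr = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = make_participants(rng, 100)
            Y = rng.normal(size=(100, 1000))
            em = fit_mass_univariate(Y, df, RegressionSpec("eq", ()))
            fracs.append((em.p < 0.05).mean())
            n_fdr.append(em.q_significant.sum())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)
        assert np.mean(n_fdr) < 1.0

    def test_planted_effect_recovered_at_fdr(self, hc500_cohort):
        cohort = hc500_cohort
        em = fit_mass_univariate(
            cohort.gm.data,
            cohort.participants,
            RegressionSpec("eq", ("age", "sex", "mmse", "tiv")),
        )
        tv = cohort.truth.eq_voxels
        assert (em.q_significant[tv] & (em.beta[tv] > 0)).mean() >= 0.90

    def test_eq_discovers_more_units_than_yoe(self, hc500_cohort):
        cohort = hc500_cohort
        spec = lambda p: RegressionSpec(p, ("age", "sex", "mmse", "tiv"))
        n_eq = fit_mass_univariate(
            cohort.gm.data, cohort.participants, spec("eq")
        ).q_significant.sum()
        n_yoe = fit_mass_univariate(
            cohort.gm.data, cohort.participants, spec("yoe")
        ).q_significant.sum()
        assert n_eq > n_yoe

    def test_collinear_design_names_columns(self, rng):
        df = make_participants(rng, 50)
        df["tiv"] = 2.0 * df["age"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            build_design(df, RegressionSpec("eq", ("age", "sex", "mmse", "tiv")))

    def test_missing_values_rejected(self, rng):
        df = make_participants(rng, 50)
        df.loc[3, "mmse"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design(df, RegressionSpec("eq", ("age", "sex", "mmse")))


class TestAssumptionChecks:
    def test_gaussian_homoscedastic_residuals_pass(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = make_participants(rng, 200, with_cov=False)
            X, _ = build_design(df, RegressionSpec("eq", ()))
            resid = rng.normal(size=(200, 1))
            rep = check_assumptions(resid, X)
            hits += (rep["shapiro_p"] > 0.05).all() and (
                rep["breusch_pagan_p"] > 0.05
            ).all()
        assert hits >= 17

    def test_heteroscedastic_residuals_flagged(self):
        rng = np.random.default_rng(2)
        df = make_participants(rng, 500, with_cov=False)
        X, _ = build_design(df, RegressionSpec("eq", ()))
        # residual SD proportional to the (positive) predictor level
        resid = (rng.normal(size=500) * df["eq"] ** 2).to_numpy()
        rep = check_assumptions(resid[:, None], X)
        assert (rep["breusch_pagan_p"] < 0.05).all()

    def test_deterministic_given_identical_residuals(self, rng):
        df = make_participants(rng, 100, with_cov=False)
        X, _ = build_design(df, RegressionSpec("eq", ()))
        resid = rng.normal(size=(100, 3))
        a = check_assumptions(resid, X)
        b = check_assumptions(resid, X)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            check_assumptions(np.ones((2, 1)), np.ones((2, 2)))


def _effect_map(r2_adj, floor=None):
    from edubrain.regional import EffectMap

    r2_adj = np.asarray(r2_adj, dtype=float)
    n = len(r2_adj)
    return EffectMap(
        predictor="eq",
        r2=r2_adj,
        r2_adj=r2_adj,
        beta=np.zeros(n),
        p=np.full(n, 0.5),
        q_significant=np.zeros(n, dtype=bool),
        floor_pass=np.ones(n, dtype=bool) if floor is None else floor,
        n_subjects=100,
        n_predictors=1,
        unit_ids=np.arange(n),
    )


class TestCompareEffectMaps:
    def test_identical_maps_report_no_discrimination(self, rng):
        m = _effect_map(rng.random(50))
        res = compare_effect_maps(m, m)
        assert res.note == "no discrimination"
        assert res.cohen_d == 0.0

    def test_constant_shift_triggers_degenerate_guard(self, rng):
        base = rng.random(1000)
        res = compare_effect_maps(_effect_map(base + 0.01), _effect_map(base))
        assert np.isinf(res.cohen_d) and res.cohen_d > 0
        assert res.p < 1e-6

    def test_noisy_shift_effect_size_and_rank_oracle(self):
        rng = np.random.default_rng(7)
        base = rng.random(1000)
        diff = rng.normal(0.01, 0.01, 1000)
        a, b = _effect_map(base + diff), _effect_map(base)
        res = compare_effect_maps(a, b)
        assert res.cohen_d == pytest.approx(1.0, abs=0.1)
        # independent rank-based oracle for the signed-rank statistic
        d = diff[diff != 0]
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        w_minus = ranks[d < 0].sum()
        assert res.W == pytest.approx(min(w_plus, w_minus))
        ref = stats.wilcoxon(a.r2_adj, b.r2_adj, method="approx", correction=True)
        assert res.p == pytest.approx(ref.pvalue)

    def test_unit_set_selection(self, rng):
        vals = rng.random(20)
        floor_a = np.zeros(20, dtype=bool)
        floor_a[:8] = True
        floor_b = np.zeros(20, dtype=bool)
        floor_b[4:12] = True
        a = _effect_map(vals + 0.05, floor=floor_a)
        b = _effect_map(vals, floor=floor_b)
        assert compare_effect_maps(a, b, unit_set="union").n_units == 12
        assert compare_effect_maps(a, b, unit_set="intersection").n_units == 4
        assert compare_effect_maps(a, b, unit_set="all").n_units == 20

    def test_mismatched_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_effect_maps(_effect_map(rng.random(5)), _effect_map(rng.random(6)))
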