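"""Design matrices, weighted fits, AIC and the selection/exploration grid."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_series
from molarage.errors import DegenerateDesignError, SingularDesignError
from molarage.model_search import (
    SEX_MODELS,
    WEIGHTINGS,
    ModelSpec,
    design_matrix,
    enumerate_toothsets,
    explore,
    fit_sex_model,
    fit_wls,
    ranking_pvalue,
    regression_weights,
    select_model,
)
from molarage.outcomes import enumerate_outcomes
from molarage.segmentation import FDI_TEETH

SPEC_4A = next(s for s in enumerate_outcomes() if s.label == "4a")


class TestToothsets:
    def test_eleven_sets(self):
        sets = enumerate_toothsets()
        assert len(sets) == 11
        assert sets[:4] == [(18,), (28,), (38,), (48,)]
        assert len([s for s in sets if len(s) > 1]) == 7
        assert (18, 28, 38, 48) in sets


class TestDesignMatrix:
    def test_model_i_base_case(self):
        series = make_series(n=3, seed=0)
        X, names = design_matrix(series, "i")
        assert X.shape == (3, 2)
        assert names == ["intercept", "age"]
        np.testing.assert_allclose(X[:, 0], 1.0)
        np.testing.assert_allclose(X[:, 1], series["age_years"])

    def test_model_iv_has_four_columns(self):
        series = make_series(n=30, seed=1)
        X, names = design_matrix(series, "iv")
        assert X.shape[1] == 4
        assert names == ["intercept", "male", "age_f", "age_m"]

    def test_model_ii_matches_hand_built_columns(self):
        series = make_series(n=12, seed=2)
        X, _ = design_matrix(series, "ii")
        is_m = (series["sex"] == "M").astype(float).to_numpy()
        hand = np.column_stack(
            [np.ones(12), is_m, series["age_years"].to_numpy()]
        )
        np.testing.assert_array_equal(X, hand)

    def test_model_iii_splits_age_by_sex(self):
        series = make_series(n=10, seed=3)
        X, _ = design_matrix(series, "iii")
        age = series["age_years"].to_numpy()
        assert np.allclose(X[:, 1] + X[:, 2], age)
        assert np.all((X[:, 1] == 0) | (X[:, 2] == 0))

    def test_single_sex_rejected_for_sex_models(self):
        series = make_series(n=20, seed=4, sex_ratio=1.0)
        for model in ("ii", "iii", "iv"):
            with pytest.raises(DegenerateDesignError):
                design_matrix(series, model)


class TestFitWLS:
    def test_exact_line(self):
        X = np.column_stack([np.ones(3), np.array([1.0, 2.0, 3.0])])
        fit = fit_wls(X, np.array([1.0, 2.0, 3.0]), np.ones(3), ["b0", "b1"])
        assert fit.coef["b1"] == pytest.approx(1.0)
        assert fit.coef["b0"] == pytest.approx(0.0, abs=1e-12)
        assert fit.degenerate  # zero residuals: AIC guarded
        assert fit.aic == -np.inf

    def test_weight_scale_invariance(self):
        series = make_series(n=60, seed=5)
        X, names = design_matrix(series, "ii")
        y = series["y"].to_numpy()
        w = regression_weights("inv_age", series["age_years"].to_numpy())
        f1 = fit_wls(X, y, w, names)
        f2 = fit_wls(X, y, 7.3 * w, names)
        np.testing.assert_allclose(f1.params, f2.params, rtol=1e-12)
        for n_ in names:
            assert f1.pvalues[n_] == pytest.approx(f2.pvalues[n_], rel=1e-10)
        # with the 1/2 sum log w likelihood term, AIC is scale-invariant too
        assert f1.aic == pytest.approx(f2.aic, rel=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n, p = 25, 3
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            w = rng.uniform(0.2, 3.0, size=n)
            fit = fit_wls(X, y, w)
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
            np.testing.assert_allclose(fit.params, beta, rtol=1e-10, atol=1e-12)

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(SingularDesignError):
            fit_wls(X, np.arange(10.0), np.ones(10))


class TestAIC:
    def test_useless_extra_coefficient_costs_exactly_two(self):
        """Adding a regressor orthogonal to the residuals leaves the fit
        unchanged, so AIC rises by the 2-unit penalty exactly."""
        rng = np.random.default_rng(7)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(size=n)
        f1 = fit_wls(X, y, np.ones(n))
        e = y - X @ f1.params
        z = rng.normal(size=n)
        # project out both the column space and the residual direction
        A = np.column_stack([X, e])
        z = z - A @ np.linalg.lstsq(A, z, rcond=None)[0]
        f2 = fit_wls(np.column_stack([X, z]), y, np.ones(n))
        assert f2.aic - f1.aic == pytest.approx(2.0, abs=1e-8)

    def test_formula_matches_independent_normal_loglik(self):
        series = make_series(n=50, seed=8)
        X, names = design_matrix(series, "ii")
        y = series["y"].to_numpy()
        w = regression_weights("inv_age", series["age_years"].to_numpy())
        fit = fit_wls(X, y, w, names)
        sigma_ml = np.sqrt(fit.sigma2_ml)
        llf = stats.norm.logpdf(y, X @ fit.params, sigma_ml / np.sqrt(w)).sum()
        assert fit.aic == pytest.approx(-2 * llf + 2 * fit.k, rel=1e-12)

    def test_sex_split_on_pooled_data_not_cheaper(self):
        """On data truly pooled across sexes, the split model's extra
        variance parameter cannot beat model iv's AIC."""
        series = make_series(n=400, seed=9, gap=0.0, variance="constant")
        f_iv = fit_sex_model(series, "iv", "constant")
        f_v = fit_sex_model(series, "v", "constant")
        assert f_v.k == f_iv.k + 1
        assert f_v.aic >= f_iv.aic - 1e-6


class TestSelectModel:
    def test_grid_is_five_by_three(self):
        assert len(SEX_MODELS) * len(WEIGHTINGS) == 15
        series = make_series(n=80, seed=10)
        for m in SEX_MODELS:
            for w in WEIGHTINGS:
                fit = fit_sex_model(series, m, w)
                assert np.isfinite(fit.aic)

    def test_recovers_generating_structure_modal(self):
        """Sex-offset intercepts with Var ~ age: (ii, 1/age) is the modal
        selection across replicates."""
        wins = {}
        for seed in range(15):
            fit = select_model(make_series(n=500, seed=100 + seed))
            key = (fit.spec.sex_model, fit.spec.weighting)
            wins[key] = wins.get(key, 0) + 1
        assert max(wins, key=wins.get) == ("ii", "inv_age")

    def test_null_data_selects_simplest_modal(self):
        """No sex effect, homoscedastic noise: (i, constant) is modal."""
        wins = {}
        for seed in range(15):
            fit = select_model(
                make_series(n=500, seed=200 + seed, gap=0.0, variance="constant")
            )
            key = (fit.spec.sex_model, fit.spec.weighting)
            wins[key] = wins.get(key, 0) + 1
        assert max(wins, key=wins.get) == ("i", "constant")

    def test_nesting_model_iv_rss_minimal(self):
        series = make_series(n=120, seed=11)
        w = regression_weights("inv_age", series["age_years"].to_numpy())
        y = series["y"].to_numpy()

        def wrss(model):
            X, names = design_matrix(series, model)
            fit = fit_wls(X, y, w, names)
            return np.sum(w * (y - X @ fit.params) ** 2)

        rss_iv = wrss("iv")
        for simpler in ("i", "ii", "iii"):
            assert rss_iv <= wrss(simpler) + 1e-10

    def test_age_pvalue_uniform_under_null(self):
        """With zero slope the age p-value is U(0,1): KS test across
        1000 simulated fits."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(1000):
            n = 40
            age = rng.uniform(14, 24, n)
            y = rng.normal(size=n)
            X = np.column_stack([np.ones(n), age])
            fit = fit_wls(X, y, np.ones(n), ["intercept", "age"])
            pvals.append(fit.pvalues["age"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestExplore:
    def test_report_covers_full_grid(self, default_cohort):
        retained = [s for s in enumerate_outcomes() if s.label in ("3a", "4a")]
        report = explore(default_cohort, retained)
        assert len(report) == 2 * 11
        assert report["ranking_p"].is_monotonic_increasing
        assert report.loc[0, "best"]

    def test_ranking_p_equals_wald_age_p_for_model_ii(self, default_cohort):
        from molarage.outcomes import outcome_series

        series = outcome_series(default_cohort, SPEC_4A, (18, 28))
        fit = select_model(series)
        if fit.spec.sex_model in ("i", "ii"):
            refit = fit_sex_model(series, fit.spec.sex_model, fit.spec.weighting)
            assert ranking_pvalue(fit) == pytest.approx(refit.pvalues["age"])
        else:
            assert ranking_pvalue(fit) == max(fit.age_pvalues().values())

    def test_signal_only_in_upper_molars_selects_them(self):
        """When only teeth 18/28 track age, the best candidate is the
        upper-molar pair on the soft-tissue ratio."""
        rng = np.random.default_rng(13)
        n = 160
        age = rng.uniform(14, 24, n)
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        cohort = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "sex": sex,
                "age_days": np.round(age * 365.25).astype(int),
                "age_years": age,
                "excluded_reason": "none",
            }
        )
        for t in FDI_TEETH:
            if t in (18, 28):
                lnr = -1.1 - 0.07 * age + rng.normal(0, 0.08, n)
            else:
                lnr = -2.4 + rng.normal(0, 0.08, n)  # ageless noise
            r = np.exp(lnr)
            hard = 0.75 * np.exp(rng.normal(0, 0.15, n))
            soft = hard * r / (1 - r)
            cohort[f"t{t}_pulp_ml"] = 0.76 * soft
            cohort[f"t{t}_predentine_ml"] = 0.24 * soft
            cohort[f"t{t}_hard_ml"] = hard
        report = explore(cohort, [SPEC_4A])
        assert report.loc[0, "outcome"] == "4a"
        assert report.loc[0, "teeth"] == "18+28"

    def test_insufficient_candidates_recorded_as_skipped(self, default_cohort):
        crippled = default_cohort.copy()
        for tissue in ("pulp", "predentine", "hard"):
            crippled[f"t48_{tissue}_ml"] = np.nan
        report = explore(crippled, [SPEC_4A])
        skipped = report[report["status"] == "skipped"]
        assert len(skipped) == 5  # every set containing tooth 48
        assert all("48" in teeth for teeth in skipped["teeth"])
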