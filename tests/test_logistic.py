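"""IRLS logistic regression: closed forms, independent oracles, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from iivd.errors import SeparationError
from iivd.logistic import (
    fit_logistic,
    hosmer_lemeshow,
    nagelkerke_r2,
    or_from_coef,
)


def _sim_design(rng, n=500, beta=(0.5, -0.8, 0.3)):
    X = rng.standard_normal((n, 2))
    eta = beta[0] + X @ np.array(beta[1:])
    y = (rng.random(n) < expit(eta)).astype(float)
    return y, X


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        fit = fit_logistic(y, np.empty((100, 0)))
        assert fit.coef[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-9)
        assert fit.lr_chi2 == pytest.approx(0.0, abs=1e-9)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        """Exposure x outcome counts 20/10/10/20: slope = log(20*20/(10*10))."""
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [20, 10, 10, 20])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [20, 10, 10, 20])
        fit = fit_logistic(y, x[:, None])
        assert fit.coef[1] == pytest.approx(np.log(4.0), abs=1e-8)
        assert fit.coef[0] == pytest.approx(np.log(10 / 20), abs=1e-8)

    def test_matches_statsmodels(self):
        y, X = _sim_design(np.random.default_rng(0))
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=False)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)
        assert fit.ll1 == pytest.approx(ref.llf, abs=1e-8)

    def test_matches_brute_force_newton_oracle(self):
        """Direct NLL minimisation (scipy BFGS) agrees with IRLS to 1e-6."""
        rng = np.random.default_rng(1)
        y, X = _sim_design(rng, n=300)
        fit = fit_logistic(y, X)
        Xd = np.column_stack([np.ones(len(y)), X])

        def nll(b):
            eta = Xd @ b
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        res = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-6)

    def test_score_equations_hold_at_optimum(self):
        y, X = _sim_design(np.random.default_rng(2))
        fit = fit_logistic(y, X)
        Xd = np.column_stack([np.ones(len(y)), X])
        assert np.abs(Xd.T @ (y - fit.fitted)).max() < 1e-6
        assert fit.converged and fit.ll1 >= fit.ll0

    def test_complete_separation_detected(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, x[:, None])

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(20), np.random.default_rng(3).standard_normal((20, 1)))


class TestOddsRatios:
    def test_zero_coefficient_gives_unit_or(self):
        ors, lo, hi = or_from_coef([0.0], [0.5])
        assert ors[0] == 1.0
        assert lo[0] == pytest.approx(np.exp(-1.959964 * 0.5))
        assert lo[0] < 1.0 < hi[0]

    def test_published_coefficient_values(self):
        ors, _, _ = or_from_coef([0.362, 0.09], [0.0, 0.0])
        assert ors[0] == pytest.approx(1.4362, abs=1e-4)
        assert ors[1] == pytest.approx(1.0942, abs=1e-4)


class TestNagelkerke:
    def test_null_fit_gives_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == 0.0

    def test_hand_arithmetic(self):
        # R2_CS = 1 - e^{-0.5}; max = 1 - e^{-1}
        expected = (1 - np.exp(-0.5)) / (1 - np.exp(-1.0))
        assert nagelkerke_r2(-10.0, -5.0, 20) == pytest.approx(expected, abs=1e-12)

    def test_perfect_prediction_of_balanced_outcome_reaches_one(self):
        n = 40
        ll0 = n * np.log(0.5)
        assert nagelkerke_r2(ll0, 0.0, n) == pytest.approx(1.0, abs=1e-12)


class TestHosmerLemeshow:
    def test_exact_calibration_gives_zero(self):
        p = np.repeat([0.2, 0.8], 10)
        y = np.array([0] * 8 + [1] * 2 + [1] * 8 + [0] * 2, dtype=float)
        stat, df, pval = hosmer_lemeshow(y, p, g=2)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_two_groups(self):
        """10 subjects at p=0.2 (3 events), 10 at p=0.7 (6 events)."""
        p = np.repeat([0.2, 0.7], 10)
        y = np.array([1] * 3 + [0] * 7 + [1] * 6 + [0] * 4, dtype=float)
        stat, df, _ = hosmer_lemeshow(y, p, g=2)
        # group 1: O1=3 E1=2, O0=7 E0=8; group 2: O1=6 E1=7, O0=4 E0=3
        oracle = (1 / 2 + 1 / 8) + (1 / 7 + 1 / 3)
        assert stat == pytest.approx(oracle, abs=1e-12)

    def test_decile_grouping_df(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.05, 0.95, 200)
        y = (rng.random(200) < p).astype(float)
        _, df, _ = hosmer_lemeshow(y, p, g=10)
        assert df == 8

    def test_ties_stay_together(self):
        p = np.repeat(0.3, 50)
        y = (np.arange(50) < 15).astype(float)
        stat, df, _ = hosmer_lemeshow(y, p, g=10)
        # single tied group survives; df clamped at 1
        assert df == 1
        assert stat == pytest.approx(0.0, abs=1e-12)


class TestConversionModels:
    def test_both_models_share_n_and_positive_lr(self, default_bundle):
        fits = default_bundle["fits"]
        assert fits["total"].n == fits["ae"].n
        for fit in fits.values():
            assert fit.lr_chi2 > 0
            assert 0 <= fit.nagelkerke_r2 <= 1
            assert (fit.ci_low <= fit.odds_ratio).all()
            assert (fit.odds_ratio <= fit.ci_high).all()

    def test_permuted_outcome_lr_near_df(self, default_bundle):
        """Null property: with shuffled outcomes E[LR chi2] = df = 2."""
        fits = default_bundle["fits"]
        n = fits["total"].n
        conv = default_bundle["outcomes"]
        followed = conv[conv["followed"]].merge(
            default_bundle["dispersion"], on="participant_id"
        )
        followed = followed[followed["visit_index"] == 0]
        base = default_bundle["cohort"]
        base = base[base["visit_index"] == 0][["participant_id", "updrs3"]]
        followed = followed.merge(base, on="participant_id").dropna(
            subset=["cov_total", "updrs3"]
        )
        y = followed["converted"].astype(float).to_numpy()
        X = followed[["cov_total", "updrs3"]].astype(float)
        rng = np.random.default_rng(9)
        stats = []
        for _ in range(40):
            fit = fit_logistic(rng.permutation(y), X)
            stats.append(fit.lr_chi2)
        assert 1.0 < np.mean(stats) < 3.2  # chi2_2 mean 2, 3-sigma band at 40 reps
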