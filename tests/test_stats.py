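"""Cohort statistics against independent closed-form and library oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from roiprog.screening import compute_auc
from roiprog.stats import (combined_model_eval, fit_logistic, group_pi_summary,
                           partial_pearson, roc_with_ci)


def pi_frame(pis, labels, groups=None):
    n = len(pis)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": groups or ["g"] * n,
        "label": pd.array(labels, dtype="Int64"),
        "pi": pis})


class TestGroupSummary:
    def test_identical_groups_zero_statistic(self):
        t = pi_frame([0.3, 0.4, 0.3, 0.4], [0, 0, 1, 1])
        gs = group_pi_summary(t)
        assert gs.statistic == pytest.approx(0.0, abs=1e-12)
        assert gs.pvalue == pytest.approx(1.0)

    def test_unadjusted_matches_pooled_t_oracle(self):
        t = pi_frame([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1])
        gs = group_pi_summary(t)
        tt = sps.ttest_ind([0.3, 0.4], [0.1, 0.2], equal_var=True)
        assert abs(gs.statistic) == pytest.approx(2.828427, abs=1e-5)
        assert gs.statistic == pytest.approx(tt.statistic, abs=1e-9)
        assert gs.pvalue == pytest.approx(tt.pvalue, abs=1e-9)

    def test_unadjusted_matches_t_test_on_random_data(self):
        rng = np.random.default_rng(3)
        pis = rng.uniform(size=40)
        labels = np.r_[np.zeros(22, int), np.ones(18, int)]
        gs = group_pi_summary(pi_frame(pis.tolist(), labels.tolist()))
        tt = sps.ttest_ind(pis[labels == 1], pis[labels == 0], equal_var=True)
        assert gs.statistic == pytest.approx(tt.statistic, abs=1e-9)
        assert gs.pvalue == pytest.approx(tt.pvalue, abs=1e-9)

    def test_orthogonal_covariate_leaves_group_coef(self):
        rng = np.random.default_rng(5)
        n = 40
        labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        pis = 0.3 + 0.2 * labels + rng.normal(0, 0.05, n)
        cov = rng.normal(size=n)
        cov -= cov.mean()
        # orthogonalize against the group indicator
        g = labels - labels.mean()
        cov = cov - (cov @ g) / (g @ g) * g
        t = pi_frame(pis.tolist(), labels.tolist())
        covdf = pd.DataFrame({"subject_id": t["subject_id"], "age": cov})
        unadj = group_pi_summary(t)
        adj = group_pi_summary(t, covariates=covdf, covariate_cols=["age"])
        assert adj.contrast_coef == pytest.approx(unadj.contrast_coef,
                                                  abs=1e-8)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            group_pi_summary(pi_frame([0.1, 0.5, 0.6], [0, 1, 1]))

    def test_per_group_means(self):
        t = pi_frame([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1],
                     groups=["sNC", "sNC", "pNC", "pNC"])
        gs = group_pi_summary(t)
        m = gs.per_group.set_index("group")["mean"]
        assert m["sNC"] == pytest.approx(0.3)
        assert m["pNC"] == pytest.approx(0.7)


def loglik_oracle(y, X):
    """Independent generic convex-optimizer fit of the logistic likelihood."""
    def nll(beta):
        eta = X @ beta
        return np.sum(np.logaddexp(0, eta) - y * eta)
    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return res.x


class TestLogistic:
    def test_2x2_closed_form_odds_ratio(self):
        # exposed: 30 events / 10 non-events; unexposed: 10 / 30
        x = np.r_[np.ones(40), np.zeros(40)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(10), np.zeros(30)]
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_logistic(df, "y", ["x"])
        i = fit.terms.index("x")
        assert fit.odds_ratio[i] == pytest.approx(9.0, abs=1e-6)
        assert fit.coef[i] == pytest.approx(np.log(9.0), abs=1e-7)
        assert np.exp(fit.coef[i]) == pytest.approx(fit.odds_ratio[i],
                                                    abs=1e-9)

    def test_intercept_only_logit_of_prevalence(self):
        df = pd.DataFrame({"y": np.r_[np.ones(10), np.zeros(30)]})
        fit = fit_logistic(df, "y", [])
        assert fit.coef[0] == pytest.approx(np.log(10 / 30), abs=1e-7)

    def test_constant_outcome_rejected(self):
        df = pd.DataFrame({"y": np.ones(10), "x": np.arange(10)})
        with pytest.raises(ValueError):
            fit_logistic(df, "y", ["x"])

    def test_missing_column_named_in_error(self):
        df = pd.DataFrame({"y": [0, 1], "x": [1.0, 2.0]})
        with pytest.raises(KeyError, match="zz"):
            fit_logistic(df, "y", ["zz"])

    def test_complete_case_rows_counted(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.integers(0, 2, 50).astype(float),
                           "x": rng.normal(size=50)})
        df.loc[:4, "x"] = np.nan
        fit = fit_logistic(df, "y", ["x"])
        assert fit.n_used == 45 and fit.n_dropped == 5

    def test_coefficient_recovery_at_n2000(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1 + 0.8 * x)))
        y = rng.binomial(1, p)
        fit = fit_logistic(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        assert fit.coef[fit.terms.index("x")] == pytest.approx(0.8, abs=0.15)

    def test_matches_generic_optimizer_on_random_datasets(self):
        rng = np.random.default_rng(21)
        for trial in range(20):
            n = int(rng.integers(40, 80))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            beta_true = rng.normal(scale=0.7, size=3)
            y = rng.binomial(1, 1 / (1 + np.exp(-X @ beta_true)))
            if y.sum() in (0, n):
                continue
            df = pd.DataFrame({"y": y, "a": X[:, 1], "b": X[:, 2]})
            fit = fit_logistic(df, "y", ["a", "b"])
            oracle = loglik_oracle(y.astype(float), X)
            np.testing.assert_allclose(fit.coef, oracle, atol=1e-5)

    def test_perfect_separation_flagged_not_raised(self):
        df = pd.DataFrame({"y": [0, 0, 0, 1, 1, 1],
                           "x": [1.0, 2, 3, 10, 11, 12]})
        fit = fit_logistic(df, "y", ["x"])
        assert fit.converged is False


class TestROC:
    def test_perfect_separation_auc_one(self):
        r = roc_with_ci([1, 2, 3, 10, 11], [0, 0, 0, 1, 1], n_boot=50, seed=0)
        assert r.auc == 1.0

    def test_point_auc_identical_to_rank_sum(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        r = roc_with_ci(s, y, n_boot=10, seed=1)
        assert r.auc == compute_auc(s, y)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        a = roc_with_ci(s, y, n_boot=20, seed=3)
        b = roc_with_ci(np.exp(2 * s) + 5, y, n_boot=20, seed=3)
        assert a.auc == b.auc
        assert a.ci95 == b.ci95

    def test_bootstrap_ci_covers_point_estimate(self):
        rng = np.random.default_rng(4)
        hits = 0
        for trial in range(100):
            s = rng.normal(size=50)
            y = np.r_[np.zeros(25, int), np.ones(25, int)]
            s[y == 1] += 0.5
            r = roc_with_ci(s, y, n_boot=200, seed=trial)
            hits += r.ci95[0] <= r.auc <= r.ci95[1]
        assert hits >= 99

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        r = roc_with_ci(s, y, n_boot=5, seed=0)
        assert np.all(np.diff(r.sensitivities) >= 0)
        assert np.all(np.diff(1 - r.specificities) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_ci([0.1, 0.2], [1, 1], n_boot=10, seed=0)


class TestCombinedModel:
    @staticmethod
    def _cohort(n=200, seed=0):
        rng = np.random.default_rng(seed)
        pi = rng.uniform(size=n)
        age = rng.normal(70, 5, n)
        p = 1 / (1 + np.exp(-(-2 + 3 * pi + 0.03 * (age - 70))))
        y = rng.binomial(1, p)
        t = pi_frame(pi.tolist(), y.tolist())
        cov = pd.DataFrame({"subject_id": t["subject_id"], "age": age,
                            "noise": rng.normal(size=n)})
        return t, cov

    def test_combined_auc_not_below_pi_alone_in_sample(self):
        t, cov = self._cohort()
        fit_pi, roc_pi = combined_model_eval(t, cov, [], n_boot=20, seed=0)
        fit_c, roc_c = combined_model_eval(t, cov, ["age"], n_boot=20, seed=0)
        assert roc_c.auc >= roc_pi.auc - 1e-9

    def test_outcome_independent_noise_barely_moves_auc(self):
        t, cov = self._cohort()
        _, roc_base = combined_model_eval(t, cov, ["age"], n_boot=20, seed=1)
        _, roc_noise = combined_model_eval(t, cov, ["age", "noise"],
                                           n_boot=20, seed=1)
        assert abs(roc_noise.auc - roc_base.auc) < 0.05

    def test_pi_scale_recorded_in_terms(self):
        t, cov = self._cohort(n=120, seed=3)
        fit, _ = combined_model_eval(t, cov, ["age"], n_boot=10, seed=0,
                                     pi_scale=100)
        assert "pi_x100" in fit.terms

    def test_cross_validated_auc_below_or_near_apparent(self):
        t, cov = self._cohort(n=150, seed=9)
        _, roc_app = combined_model_eval(t, cov, ["age"], n_boot=10, seed=2)
        _, roc_cv = combined_model_eval(t, cov, ["age"], n_boot=10, seed=2,
                                        cross_validated=True)
        # out-of-fold performance cannot systematically beat apparent
        assert roc_cv.auc <= roc_app.auc + 0.05
        assert 0.5 < roc_cv.auc <= 1.0

    def test_missing_covariate_column_named(self):
        t, cov = self._cohort(n=60, seed=4)
        with pytest.raises(KeyError, match="mmse"):
            combined_model_eval(t, cov, ["mmse"], n_boot=10, seed=0)


class TestPartialPearson:
    def test_identical_series_full_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        c = rng.normal(size=30)
        r, p = partial_pearson(x, x, c)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_covariate_explains_x_leaves_noise(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=50)
        x = 2 * c + 1  # exactly linear in the covariate -> zero residual
        y = rng.normal(size=50)
        with pytest.raises(ValueError):
            partial_pearson(x, y, c)
        # nearly linear: residual correlation ~ 0
        x2 = 2 * c + 1 + rng.normal(0, 0.1, 50)
        r, _ = partial_pearson(x2, y, c)
        assert abs(r) < 0.3

    def test_matches_two_stage_residual_oracle(self):
        x = np.array([1.0, 2.5, 3.0, 4.2, 5.1])
        y = np.array([2.0, 1.0, 4.0, 3.5, 6.0])
        c = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        r, p = partial_pearson(x, y, c)
        # independent oracle: explicit two-stage regression + pearsonr
        bx = np.polyfit(c, x, 1)
        by = np.polyfit(c, y, 1)
        rx = x - np.polyval(bx, c)
        ry = y - np.polyval(by, c)
        r_oracle, _ = sps.pearsonr(rx, ry)
        assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        c = rng.normal(size=40)
        y = 0.5 * x + 0.3 * c + rng.normal(size=40)
        r, p = partial_pearson(x, y, c)
        out = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "c": c}),
            x="x", y="y", covar="c")
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-9)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            partial_pearson([1, 2, 3], [1, 2, 3], [1, 2, 3])
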