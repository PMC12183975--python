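"""Evaluation statistics for the Progressive Index in a cohort.

Covers the analyses a longitudinal validation of the PI runs: per-group PI
summaries with a linear-model contrast between progressive and stable
subjects (optionally covariate-adjusted), nested covariate-adjusted logistic
regressions with odds ratios, ROC curves with a stratified-bootstrap AUC
confidence interval for PI-alone and PI-plus-clinical combined models, and
an age-adjusted partial Pearson correlation.

Model fits go through statsmodels (OLS / maximum-likelihood Logit with Wald
standard errors); missing data are handled complete-case per model with the
dropped-row count reported. Because odds ratios per unit of a 0-1 score are
unreadably large, PI enters logistic models on a 0-100 scale by default
(``pi_scale=100``); the scale is explicit in every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .screening import compute_auc

__all__ = [
    "LogisticFit",
    "ROCResult",
    "GroupSummary",
    "group_pi_summary",
    "fit_logistic",
    "roc_with_ci",
    "combined_model_eval",
    "partial_pearson",
]

DEFAULT_PI_SCALE = 100.0


@dataclass
class LogisticFit:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    n_used: int
    n_dropped: int
    converged: bool
    fitted: pd.Series = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "coef": self.coef, "se": self.se,
            "OR": self.odds_ratio, "OR_ci_low": self.ci_low,
            "OR_ci_high": self.ci_high, "p": self.pvalues})

    def to_dict(self) -> dict:
        d = self.to_frame().to_dict(orient="records")
        return {"terms": d, "n_used": self.n_used,
                "n_dropped": self.n_dropped, "converged": self.converged}


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    ci95: tuple[float, float]
    n_boot: int
    seed: int

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivities,
                             "specificity": self.specificities})

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ci95": list(self.ci95),
                "n_boot": self.n_boot, "seed": self.seed}


@dataclass
class GroupSummary:
    per_group: pd.DataFrame      # group, n, mean, sd
    contrast_coef: float         # progressive-minus-stable PI difference
    statistic: float             # t statistic of the group term
    pvalue: float
    adjusted: bool


def group_pi_summary(pi_table: pd.DataFrame,
                     covariates: pd.DataFrame | None = None,
                     covariate_cols: list[str] | None = None) -> GroupSummary:
    """Per-group PI mean/SD and the progressive-vs-stable linear contrast.

    Unadjusted, the contrast equals the classical pooled-variance two-sample
    t test on the known-label rows. With covariates, the reported statistic
    is the group coefficient's t in OLS of PI on group + covariates.
    """
    ok = pi_table[pi_table["pi"].notna()]
    per_group = (ok.groupby("group")["pi"]
                 .agg(n="count", mean="mean", sd="std")
                 .reset_index())
    known = ok[ok["label"].notna()].copy()
    y = known["pi"].to_numpy(dtype=float)
    g = known["label"].astype(int).to_numpy()
    for cls in (0, 1):
        if (g == cls).sum() < 2:
            raise ValueError(
                "group contrast needs >= 2 subjects in each label group")
    Xcols = {"group": g.astype(float)}
    adjusted = False
    if covariates is not None and covariate_cols:
        cov = covariates.set_index("subject_id").loc[
            known["subject_id"], list(covariate_cols)]
        for c in covariate_cols:
            Xcols[c] = cov[c].to_numpy(dtype=float)
        adjusted = True
    X = sm.add_constant(pd.DataFrame(Xcols))
    res = sm.OLS(y, X, missing="drop").fit()
    return GroupSummary(per_group=per_group,
                        contrast_coef=float(res.params["group"]),
                        statistic=float(res.tvalues["group"]),
                        pvalue=float(res.pvalues["group"]),
                        adjusted=adjusted)


def fit_logistic(data: pd.DataFrame, outcome: str,
                 include: list[str]) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald ORs and 95% CIs.

    Rows with a missing value in the outcome or any included predictor are
    dropped (complete case) and counted. Perfect separation is reported as a
    non-converged fit rather than an exception.
    """
    missing = [c for c in [outcome, *include] if c not in data.columns]
    if missing:
        raise KeyError(f"missing column(s): {missing}")
    sub = data[[outcome, *include]].apply(pd.to_numeric, errors="coerce")
    n_all = len(sub)
    sub = sub.dropna()
    n_used = len(sub)
    y = sub[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if n_used < len(include) + 1:
        raise ValueError("fewer complete-case rows than model parameters")
    X = sm.add_constant(sub[include].astype(float)) if include else \
        pd.DataFrame({"const": np.ones(n_used)}, index=sub.index)

    converged = True
    try:
        import warnings as _warnings
        with np.errstate(all="ignore"), _warnings.catch_warnings(record=True) as wlog:
            _warnings.simplefilter("always")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        if any(issubclass(w.category,
                          sm.tools.sm_exceptions.PerfectSeparationWarning)
               for w in wlog):
            converged = False
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        # refit with light ridge so diagnostics still come back
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit_regularized(alpha=1e-4, disp=0)
        converged = False
    coef = np.asarray(res.params, dtype=float)
    try:
        se = np.asarray(res.bse, dtype=float)
    except Exception:
        se = np.full_like(coef, np.nan)
    if not np.all(np.isfinite(se)):
        converged = False
    z = sps.norm.ppf(0.975)
    fitted = pd.Series(np.asarray(res.predict(X), dtype=float), index=sub.index)
    return LogisticFit(
        terms=list(X.columns), coef=coef, se=se,
        odds_ratio=np.exp(coef),
        ci_low=np.exp(coef - z * se), ci_high=np.exp(coef + z * se),
        pvalues=np.asarray(res.pvalues, dtype=float),
        n_used=n_used, n_dropped=n_all - n_used,
        converged=converged, fitted=fitted)


def _roc_curve(scores: np.ndarray, y: np.ndarray):
    """Sensitivity/specificity at every distinct score threshold (>= rule)."""
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    distinct = np.r_[True, np.diff(s) != 0]
    tps = np.cumsum(yy == 1)[distinct]
    fps = np.cumsum(yy == 0)[distinct]
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    thr = s[distinct]
    sens = np.r_[0.0, tps / n_pos]
    spec = np.r_[1.0, 1 - fps / n_neg]
    thr = np.r_[np.inf, thr]
    return thr, sens, spec


def roc_with_ci(scores, labels, n_boot: int = 2000, seed: int = 0) -> ROCResult:
    """ROC curve and rank-sum AUC with a stratified bootstrap percentile CI.

    Positives and negatives are resampled separately (class sizes preserved);
    the 95% CI is the 2.5/97.5 percentile of the bootstrap AUCs.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    auc = compute_auc(scores, y)  # raises on single-class input
    thr, sens, spec = _roc_curve(scores, y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        idx = np.r_[ip, ineg]
        boot[b] = compute_auc(scores[idx], y[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ROCResult(thresholds=thr, sensitivities=sens, specificities=spec,
                     auc=auc, ci95=(float(lo), float(hi)),
                     n_boot=int(n_boot), seed=int(seed))


def combined_model_eval(pi_table: pd.DataFrame, covariates: pd.DataFrame,
                        formula_terms: list[str], n_boot: int = 2000,
                        seed: int = 0, pi_scale: float = DEFAULT_PI_SCALE,
                        cross_validated: bool = False, n_folds: int = 5
                        ) -> tuple[LogisticFit, ROCResult]:
    """Fit outcome ~ PI + clinical terms; ROC of the model's probabilities.

    The PI enters on the 0-``pi_scale`` scale (term name records the scale).
    By default the ROC uses the in-sample fitted probabilities (apparent
    performance, what a single-cohort combined-model evaluation reports);
    with ``cross_validated`` the curve instead uses out-of-fold predictions
    from a seeded stratified ``n_folds``-fold split, while the returned
    coefficient fit is still the full-data fit.
    """
    known = pi_table[pi_table["label"].notna() & pi_table["pi"].notna()]
    df = known[["subject_id", "label", "pi"]].merge(covariates, on="subject_id",
                                                   how="left")
    pi_term = f"pi_x{pi_scale:g}"
    df[pi_term] = df["pi"].astype(float) * pi_scale
    df["outcome"] = df["label"].astype(int)
    terms = [pi_term, *formula_terms]
    fit = fit_logistic(df, "outcome", terms)
    used = df.loc[fit.fitted.index]
    y = used["outcome"].to_numpy()
    if not cross_validated:
        scores = fit.fitted.to_numpy()
    else:
        scores = np.empty(len(used))
        rng = np.random.default_rng(seed)
        folds = np.empty(len(used), dtype=int)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = idx[rng.permutation(idx.size)]
            folds[idx] = np.arange(idx.size) % n_folds
        used = used.reset_index(drop=True)
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            sub = fit_logistic(used[tr], "outcome", terms)
            Xte = sm.add_constant(used.loc[te, terms].astype(float),
                                  has_constant="add")
            eta = Xte.to_numpy() @ sub.coef
            scores[te] = 1 / (1 + np.exp(-eta))
    roc = roc_with_ci(scores, y, n_boot=n_boot, seed=seed)
    return fit, roc


def partial_pearson(x, y, covariate) -> tuple[float, float]:
    """Pearson correlation of x and y after removing a linear covariate.

    Both variables are residualized on [1, covariate]; the p-value uses the
    t transform of the residual correlation with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValueError("x, y and covariate must be equal-length 1D arrays")
    n = x.size
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    if not np.all(np.isfinite(np.r_[x, y, c])):
        raise ValueError("inputs must be finite")
    Z = np.column_stack([np.ones(n), c])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    # degenerate up to numerical noise from the residualization itself
    if sx <= 1e-12 * max(1.0, np.abs(x).max()) or \
            sy <= 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("zero residual variance: correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    dof = n - 3
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), dof)
    return r, float(p)
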