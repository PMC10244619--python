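"""Logistic outcome models, univariate screening and ROC comparison.

Per-predictor univariate logistic regression reports odds ratios with Wald
95% confidence intervals and p-values, mirroring standard "OR (95% CI)"
reporting; no multiplicity adjustment is applied across the predictor-by-
outcome grid (a documented caveat).  ROC AUCs are rank-based (Mann-Whitney,
ties count 0.5) and in-sample (apparent) unless cross-validation is
explicitly requested.  Complete or quasi-complete separation is flagged and
the odds ratio withheld rather than reporting astronomically large values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .errors import (
    CollinearityError,
    DegenerateOutcomeError,
    SchemaError,
    SmallSampleWarning,
    ValidationError,
)
from .io import CLINICAL_PREDICTORS, EIT_PREDICTORS

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: |coefficient| beyond this on the log-odds scale is treated as separation
_SEPARATION_COEF = 30.0


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


class WaldLogisticRegression(BaseEstimator):
    """Maximum-likelihood logistic regression with Wald inference.

    Fitting is Newton/IRLS (convergence: score tolerance 1e-8 or 50
    iterations); standard errors come from the inverse observed information.
    Complete separation is detected (runaway coefficients or degenerate
    fitted probabilities) and flagged via ``separation_`` with odds ratios
    withheld.

    Parameters
    ----------
    add_intercept : prepend an intercept column (default True).
    standardize : scale each predictor by its SD before fitting, so odds
        ratios are per-SD instead of per-unit (default False).
    tol, maxiter : Newton convergence controls.
    """

    def __init__(self, add_intercept=True, standardize=False, tol=1e-8, maxiter=50):
        self.add_intercept = add_intercept
        self.standardize = standardize
        self.tol = tol
        self.maxiter = maxiter

    def fit(self, X, y, feature_names=None):
        X, names = _as_matrix(X, feature_names)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValidationError("X and y lengths differ")
        classes = np.unique(y)
        if not np.isin(classes, [0.0, 1.0]).all():
            raise ValidationError("y must be binary 0/1")
        if len(classes) < 2:
            raise DegenerateOutcomeError("outcome is constant")

        self._scale_ = None
        if self.standardize:
            scale = X.std(axis=0, ddof=0)
            scale[scale == 0] = 1.0
            X = X / scale
            self._scale_ = scale
        design = X
        if self.add_intercept:
            design = np.column_stack([np.ones(len(y)), X])
            names = ["intercept"] + names
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CollinearityError("design matrix is rank deficient")
        if len(y) < 5 * design.shape[1]:
            warnings.warn(
                f"n={len(y)} below 5 per parameter (p={design.shape[1]})",
                SmallSampleWarning,
            )

        separation = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.Logit(y, design)
            try:
                res = model.fit(
                    method="newton", tol=self.tol, maxiter=self.maxiter, disp=0
                )
                params = np.asarray(res.params, dtype=float)
                bse = np.asarray(res.bse, dtype=float)
                converged = bool(res.mle_retvals.get("converged", False))
                llf = float(res.llf)
            except Exception:
                separation = True
                params = np.full(design.shape[1], np.nan)
                bse = np.full(design.shape[1], np.nan)
                converged = False
                llf = np.nan
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
        if not separation and np.nanmax(np.abs(params)) > _SEPARATION_COEF:
            separation = True
        if separation:
            converged = False

        self.feature_names_ = names
        self.n_used_ = len(y)
        self.n_events_ = int(y.sum())
        self.separation_ = separation
        self.converged_ = converged
        self.params_ = params
        self.se_ = bse
        self.llf_ = llf
        self.deviance_ = -2.0 * llf if np.isfinite(llf) else np.nan
        if separation:
            nan = np.full_like(params, np.nan)
            self.or_, self.or_ci_low_, self.or_ci_high_, self.pvalues_ = (
                nan, nan.copy(), nan.copy(), nan.copy()
            )
        else:
            self.or_ = np.exp(params)
            self.or_ci_low_ = np.exp(params - Z_95 * bse)
            self.or_ci_high_ = np.exp(params + Z_95 * bse)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = params / bse
            self.pvalues_ = 2.0 * norm.sf(np.abs(z))
        self._design_fit = None if separation else design
        return self

    def predict_proba(self, X):
        X, _ = _as_matrix(X)
        if self.standardize:
            # scaling was folded into params via the fit-time rescale of X;
            # apply the same convention: caller passes raw X
            scale = getattr(self, "_scale_", None)
            if scale is not None:
                X = X / scale
        if self.add_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        eta = X @ np.nan_to_num(self.params_)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class LogisticFit:
    """Result of one logistic fit, one row per model term."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    or_point: np.ndarray
    or_ci95: np.ndarray  # (p, 2)
    p_wald: np.ndarray
    converged: bool
    separation: bool
    n_used: int
    n_events: int
    deviance: float

    def term(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "or": float(self.or_point[i]),
            "ci_low": float(self.or_ci95[i, 0]),
            "ci_high": float(self.or_ci95[i, 1]),
            "p": float(self.p_wald[i]),
        }


def fit_logistic(design, y, feature_names=None, **kwargs) -> LogisticFit:
    """Fit a logistic model and return Wald summaries (thin wrapper over
    :class:`WaldLogisticRegression`)."""
    est = WaldLogisticRegression(**kwargs).fit(design, y, feature_names)
    return LogisticFit(
        names=est.feature_names_,
        coef=est.params_,
        se=est.se_,
        or_point=est.or_,
        or_ci95=np.column_stack([est.or_ci_low_, est.or_ci_high_]),
        p_wald=est.pvalues_,
        converged=est.converged_,
        separation=est.separation_,
        n_used=est.n_used_,
        n_events=est.n_events_,
        deviance=est.deviance_,
    )


@dataclass
class RocResult:
    """Rank-based (Mann-Whitney) area under the ROC curve."""

    auc: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> RocResult:
    """AUC = Mann-Whitney U / (n_pos * n_neg); tied pairs count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateOutcomeError("both classes required for ROC")
    return RocResult(
        auc=float(roc_auc_score(labels, scores)), n_pos=n_pos, n_neg=n_neg
    )


def sex_indicator(series: pd.Series) -> np.ndarray:
    """Encode sex as male=1, female=0."""
    return (series == "male").to_numpy(dtype=float)


def _predictor_matrix(cohort: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    cols = []
    for p in predictors:
        if p == "sex":
            cols.append(sex_indicator(cohort["sex"]))
        else:
            cols.append(cohort[p].to_numpy(dtype=float))
    return np.column_stack(cols)


def univariate_screen(
    cohort: pd.DataFrame,
    predictors: list[str] | None = None,
    outcomes: list[str] | str | None = None,
    alpha: float = 0.05,
    min_events: int = 5,
    standardize: bool = False,
) -> pd.DataFrame:
    """One single-predictor logistic fit per (predictor, outcome) pair.

    Returns one row per fit with OR, Wald 95% CI, p, a significance flag at
    *alpha* and a reliability flag (``n_pos``/``n_neg`` at least
    *min_events*).  P-values are unadjusted across the grid.
    """
    from .io import OUTCOME_COLUMNS

    predictors = predictors if predictors is not None else list(EIT_PREDICTORS)
    if outcomes is None:
        outcomes = list(OUTCOME_COLUMNS)
    elif isinstance(outcomes, str):
        outcomes = [outcomes]
    missing = [c for c in predictors + outcomes if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort missing columns: {', '.join(missing)}")

    rows = []
    for outcome in outcomes:
        y = cohort[outcome].to_numpy(dtype=float)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        for pred in predictors:
            x = _predictor_matrix(cohort, [pred])
            row = {
                "predictor": pred,
                "outcome": outcome,
                "n": len(y),
                "n_pos": n_pos,
                "reliable": n_pos >= min_events and n_neg >= min_events,
            }
            if not row["reliable"]:
                warnings.warn(
                    f"{outcome}: only {min(n_pos, n_neg)} events in the "
                    "smaller class; fit unreliable",
                    SmallSampleWarning,
                )
            try:
                fit = fit_logistic(x, y, [pred], standardize=standardize)
                t = fit.term(pred)
                row.update(
                    or_=t["or"], ci_low=t["ci_low"], ci_high=t["ci_high"],
                    p=t["p"], converged=fit.converged,
                    significant=bool(fit.converged and t["p"] < alpha),
                )
            except (DegenerateOutcomeError, CollinearityError) as exc:
                row.update(
                    or_=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                    converged=False, significant=False, error=str(exc),
                )
            rows.append(row)
    out = pd.DataFrame(rows).rename(columns={"or_": "or"})
    return out


#: the three Figure-2-style model specifications
MODEL_SPECS = {
    "clinical": list(CLINICAL_PREDICTORS),
    "eit": ["aer_pct", "ahr"],
    "combined": list(CLINICAL_PREDICTORS) + ["aer_pct", "ahr"],
}


def compare_models(
    cohort: pd.DataFrame,
    outcome: str,
    *,
    standardize: bool = False,
    cross_validate: bool = False,
    cv_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Clinical-only, EIT-only and combined multivariable models.

    AUCs are in-sample (apparent) — no shrinkage or cross-validation —
    unless ``cross_validate`` is set, in which case stratified K-fold
    out-of-sample AUCs are reported alongside.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    report: dict = {
        "outcome": outcome,
        "n": int(len(y)),
        "n_events": int(y.sum()),
        "note": "AUCs are apparent (in-sample); no cross-validation applied"
        if not cross_validate
        else f"apparent plus stratified {cv_folds}-fold out-of-sample AUCs",
        "models": {},
    }
    for name, preds in MODEL_SPECS.items():
        X = _predictor_matrix(cohort, preds)
        entry: dict = {"predictors": preds}
        try:
            est = WaldLogisticRegression(standardize=standardize).fit(
                X, y, preds
            )
            entry["converged"] = est.converged_
            entry["separation"] = est.separation_
            entry["deviance"] = (
                float(est.deviance_) if np.isfinite(est.deviance_) else None
            )
            scores = est.predict_proba(X)[:, 1]
            entry["auc"] = roc_auc(scores, y.astype(int)).auc
            if cross_validate:
                entry["auc_cv"] = _cv_auc(X, y, preds, cv_folds, seed, standardize)
        except (DegenerateOutcomeError, CollinearityError) as exc:
            entry["error"] = str(exc)
        report["models"][name] = entry
    return report


def _cv_auc(X, y, names, folds, seed, standardize) -> float | None:
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.full(len(y), np.nan)
    for train, test in skf.split(X, y):
        try:
            est = WaldLogisticRegression(standardize=standardize).fit(
                X[train], y[train], names
            )
        except (DegenerateOutcomeError, CollinearityError):
            return None
        scores[test] = est.predict_proba(X[test])[:, 1]
    return roc_auc(scores, y.astype(int)).auc
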