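"""Evaluation of single-layer and combined risk scores.

Validation-set evaluation collapses to one averaged score per participant,
so all evaluation models are ordinary (non-mixed) logistic regressions:

  - ROC AUC as the Mann-Whitney probability (ties count 1/2), with a DeLong
    95% confidence interval;
  - odds ratio per SD of score from  diagnosis ~ score (+ age + sex), with
    Wald CI and p-value;
  - Nagelkerke pseudo-R^2 against a nested null model;
  - the combined multi-omic model
        y = mu + b1*MGN + b2*MTS + b3*VRM + b4*MBL + b5*age + b6*sex
    with a leave-one-omic-out sensitivity variant;
  - pairwise Pearson co-occurrence of selected features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityWarning,
    CombinedModelError,
    EvaluationError,
    SeparationWarning,
)
from .omics_io import OmicLayerTable

Z95 = stats.norm.ppf(0.975)


# ------------------------------------------------------------------ ROC/AUC


def roc_auc(scores, labels) -> tuple[float, tuple[float, float]]:
    """AUC as the Mann-Whitney U probability with a DeLong 95% CI.

    Ties count one half.  Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    cases = s[y == 1]
    controls = s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise EvaluationError("both classes required to compute AUC")
    # pairwise win matrix (m x n); fine at validation-cohort scale
    diff = cases[:, None] - controls[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-case structural components
    v01 = psi.mean(axis=0)  # per-control
    var = 0.0
    if len(cases) > 1:
        var += float(np.var(v10, ddof=1)) / len(cases)
    if len(controls) > 1:
        var += float(np.var(v01, ddof=1)) / len(controls)
    half = Z95 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return auc, ci


# ------------------------------------------------------------------- OR/SD


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci: tuple[float, float]
    p_value: float
    beta: float
    se: float
    separation: bool = False


class _RidgeLogitResult:
    """Minimal stand-in for a statsmodels Logit result when the ML fit is
    (quasi-)separated: IRLS with a weakly-informative ridge on the
    non-intercept coefficients.  ``llf`` is the unpenalized log-likelihood
    at the stabilized estimate."""

    def __init__(self, y: np.ndarray, X: np.ndarray, ridge: float = 1.0):
        n, k = X.shape
        pen = np.full(k, ridge)
        pen[0] = 0.0  # intercept unpenalized
        beta = np.zeros(k)
        for _ in range(100):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            H = X.T @ (w[:, None] * X) + np.diag(pen)
            g = X.T @ (y - mu) - pen * beta
            step = np.linalg.solve(H, g)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = X @ beta
        self.params = beta
        cov = np.linalg.inv(X.T @ (np.clip(
            (1/(1+np.exp(-eta))) * (1 - 1/(1+np.exp(-eta))), 1e-10, None
        )[:, None] * X) + np.diag(pen))
        self.bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        z = np.divide(beta, self.bse, out=np.full(k, np.nan), where=self.bse > 0)
        self.pvalues = 2 * stats.norm.sf(np.abs(z))
        self.stabilized = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(X @ self.params)))


def _logit_fit(y: np.ndarray, X: np.ndarray):
    """Plain ML logistic fit; falls back to a ridge-stabilized IRLS fit when
    the ML problem is separated or singular."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton")
        if np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 1e3:
            return res
    except Exception:  # noqa: BLE001 - separation / singular Hessian
        pass
    warnings.warn(
        "logistic ML fit separated or singular; using ridge-stabilized fit",
        SeparationWarning,
    )
    return _RidgeLogitResult(y, X)


def or_per_sd(
    labels,
    score,
    covariates: Optional[pd.DataFrame] = None,
) -> OddsRatioResult:
    """Odds ratio for a one-SD increase in score from a plain logistic
    regression of diagnosis on the score (plus optional age/sex covariates).

    Wald 95% CI: exp(beta +/- 1.96 * SE).  Under separation the result is
    flagged and the CI reported as unbounded.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(score, dtype=float)
    cols = [np.ones_like(s), s]
    names = ["const", "score"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    stabilized = False
    try:
        res = _logit_fit(y, X)
        beta = float(res.params[1])
        se = float(res.bse[1])
        p = float(res.pvalues[1])
        stabilized = getattr(res, "stabilized", False)
    except Exception:  # noqa: BLE001 - statsmodels raises on separation
        beta, se, p = np.nan, np.inf, np.nan
    separation = (
        stabilized or not np.isfinite(se) or not np.isfinite(beta)
        or abs(beta) > 10 or se > 50
    )
    if separation:
        warnings.warn("separation in OR fit; CI unbounded", CollinearityWarning)
        return OddsRatioResult(
            odds_ratio=float(np.exp(beta)) if np.isfinite(beta) else np.inf,
            ci=(0.0, np.inf), p_value=p, beta=beta, se=se, separation=True,
        )
    return OddsRatioResult(
        odds_ratio=float(np.exp(beta)),
        ci=(float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))),
        p_value=p,
        beta=beta,
        se=se,
    )


# ------------------------------------------------------------- Nagelkerke


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from fitted and nested-null log-likelihoods.

    R2_CoxSnell = 1 - exp(2 (L0 - L1) / n), rescaled by its maximum
    1 - exp(2 L0 / n) so that the statistic ranges over [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("full-model log-likelihood below the nested null")
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom <= 0:
        return 0.0
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


# ----------------------------------------------------------- layer report


@dataclass
class EvaluationReport:
    label: str
    auc: float
    auc_ci: tuple[float, float]
    odds_ratio: OddsRatioResult
    r2: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "odds_ratio": self.odds_ratio.odds_ratio,
            "or_ci": list(self.odds_ratio.ci),
            "or_p": self.odds_ratio.p_value,
            "nagelkerke_r2": self.r2,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


def evaluate_layer(
    participant_scores: pd.Series,
    labels: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    adjusted: bool = True,
    label: str = "",
) -> EvaluationReport:
    """Evaluate one layer's participant-averaged scores against diagnosis.

    ``adjusted=True`` evaluates diagnosis ~ score + age + sex (AUC from the
    fitted probabilities); ``adjusted=False`` uses the score alone.
    """
    idx = participant_scores.index
    y = labels.reindex(idx).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise EvaluationError("scored participants missing labels")
    if len(set(y)) < 2:
        raise EvaluationError("both classes required for evaluation")
    cov = covariates.reindex(idx) if (covariates is not None and adjusted) else None
    orr = or_per_sd(y, participant_scores.to_numpy(), cov)

    cols = [np.ones(len(idx)), participant_scores.to_numpy(dtype=float)]
    if cov is not None:
        cols.extend(cov[c].to_numpy(dtype=float) for c in cov.columns)
    X = np.column_stack(cols)
    try:
        res = _logit_fit(y, X)
        pred = np.asarray(res.predict(X), dtype=float)
        l1 = float(res.llf)
    except Exception:  # separation: fall back to the raw score
        pred = participant_scores.to_numpy(dtype=float)
        l1 = _saturated_bound(y)
    null = _logit_fit(y, np.ones((len(y), 1)))
    r2 = nagelkerke_r2(max(l1, float(null.llf)), float(null.llf), len(y))
    auc_scores = pred if adjusted else participant_scores.to_numpy(dtype=float)
    auc, ci = roc_auc(auc_scores, y.astype(int))
    return EvaluationReport(
        label=label,
        auc=auc,
        auc_ci=ci,
        odds_ratio=orr,
        r2=r2,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
    )


def _saturated_bound(y: np.ndarray) -> float:
    return -1e-9 * len(y)


# --------------------------------------------------------- combined model


@dataclass
class CombinedModelResult:
    layers: list[str]
    coefficients: pd.Series
    se: pd.Series
    layer_or: dict[str, OddsRatioResult]
    r2_full: float
    r2_covariates_only: float
    r2_scores_only: float
    auc: float
    auc_ci: tuple[float, float]
    loglik_full: float
    loglik_null: float
    score_correlations: pd.DataFrame
    dropped_collinear: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "layers": self.layers,
            "coefficients": self.coefficients.to_dict(),
            "se": self.se.to_dict(),
            "layer_or": {
                k: {"or": v.odds_ratio, "ci": list(v.ci), "p": v.p_value}
                for k, v in self.layer_or.items()
            },
            "r2_full": self.r2_full,
            "r2_covariates_only": self.r2_covariates_only,
            "r2_scores_only": self.r2_scores_only,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "dropped_collinear": self.dropped_collinear,
        }


def _drop_collinear(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop later columns that are perfectly collinear with earlier ones."""
    keep: list[str] = []
    dropped: list[str] = []
    for col in df.columns:
        cand = df[keep + [col]].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(df)), cand])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            keep.append(col)
        else:
            dropped.append(col)
    if dropped:
        warnings.warn(
            f"perfectly collinear score columns dropped: {dropped}",
            CollinearityWarning,
        )
    return df[keep], dropped


def fit_combined(
    scores: pd.DataFrame,
    covariates: Optional[pd.DataFrame],
    labels: pd.Series,
    required_layers: int = 4,
) -> CombinedModelResult:
    """Fit the combined logistic model of diagnosis on all layer scores plus
    age and sex, over participants with every layer scored.

    Reports per-layer odds ratios with Wald CIs, Nagelkerke R^2 of the full
    model and its covariate-only and scores-only reductions, the AUC of the
    combined prediction, and the score correlation matrix.
    """
    layer_cols = list(scores.columns)
    if len(layer_cols) < required_layers:
        raise CombinedModelError(
            f"combined model needs {required_layers} layer scores, "
            f"got {len(layer_cols)}"
        )
    complete = scores.dropna()
    idx = complete.index
    y = labels.reindex(idx).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise EvaluationError("participants missing labels")
    if len(set(y)) < 2:
        raise EvaluationError("both classes required")
    corr = complete.corr()

    used, dropped = _drop_collinear(complete)
    cov = covariates.reindex(idx) if covariates is not None else None
    if cov is not None:
        cov = cov.astype(float)

    def design(frames) -> np.ndarray:
        cols = [np.ones(len(idx))]
        for fr in frames:
            if fr is not None and fr.shape[1]:
                cols.append(fr.to_numpy(dtype=float))
        return np.column_stack(cols)

    X_full = design([used, cov])
    names = ["const"] + list(used.columns) + (
        list(cov.columns) if cov is not None else []
    )
    res = _logit_fit(y, X_full)
    null = _logit_fit(y, np.ones((len(y), 1)))
    res_cov = _logit_fit(y, design([cov])) if cov is not None else null
    res_scores = _logit_fit(y, design([used]))

    n = len(y)
    coefs = pd.Series(res.params, index=names)
    ses = pd.Series(res.bse, index=names)
    for col in dropped:
        coefs[col] = np.nan
        ses[col] = np.nan
    layer_or = {}
    for col in layer_cols:
        if col in used.columns:
            b, se = coefs[col], ses[col]
            layer_or[col] = OddsRatioResult(
                odds_ratio=float(np.exp(b)),
                ci=(float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se))),
                p_value=float(
                    2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan
                ),
                beta=float(b),
                se=float(se),
            )
        else:
            layer_or[col] = OddsRatioResult(
                odds_ratio=np.nan, ci=(np.nan, np.nan), p_value=np.nan,
                beta=np.nan, se=np.nan, separation=True,
            )
    pred = np.asarray(res.predict(X_full), dtype=float)
    auc, auc_ci = roc_auc(pred, y.astype(int))
    return CombinedModelResult(
        layers=layer_cols,
        coefficients=coefs,
        se=ses,
        layer_or=layer_or,
        r2_full=nagelkerke_r2(max(float(res.llf), float(null.llf)), float(null.llf), n),
        r2_covariates_only=nagelkerke_r2(
            max(float(res_cov.llf), float(null.llf)), float(null.llf), n),
        r2_scores_only=nagelkerke_r2(
            max(float(res_scores.llf), float(null.llf)), float(null.llf), n),
        auc=auc,
        auc_ci=auc_ci,
        loglik_full=float(res.llf),
        loglik_null=float(null.llf),
        score_correlations=corr,
        dropped_collinear=dropped,
    )


def leave_one_omic_out(
    scores: pd.DataFrame,
    covariates: Optional[pd.DataFrame],
    labels: pd.Series,
) -> dict[str, CombinedModelResult]:
    """Refit the combined model once per layer with that layer omitted.

    Keyed by the omitted layer; compare each variant's R^2 and log-likelihood
    to the full model to gauge the layer's contribution.
    """
    out = {}
    for col in scores.columns:
        remaining = scores.drop(columns=[col])
        out[col] = fit_combined(
            remaining, covariates, labels, required_layers=remaining.shape[1]
        )
    return out


# ----------------------------------------------------------- co-occurrence


@dataclass
class CooccurrenceMatrix:
    feature_ids: list[str]
    correlations: pd.DataFrame
    undefined: list[str] = field(default_factory=list)

    def max_offdiagonal(self) -> float:
        m = self.correlations.to_numpy(dtype=float).copy()
        np.fill_diagonal(m, np.nan)
        return float(np.nanmax(m))


def cooccurrence(
    table: OmicLayerTable, feature_subset: Sequence[str]
) -> CooccurrenceMatrix:
    """Pairwise Pearson correlation of transformed abundances for a feature
    subset.  Zero-variance features are reported as undefined (NaN rows)."""
    if table.n_samples < 2:
        raise EvaluationError("co-occurrence needs >= 2 samples")
    subset = list(feature_subset)
    missing = [f for f in subset if f not in set(table.feature_ids)]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    x = table.data[subset].to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    undefined = [f for f, s in zip(subset, sd) if s == 0]
    bad = sd == 0
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, np.where(bad, np.nan, 1.0))
    return CooccurrenceMatrix(
        feature_ids=subset,
        correlations=pd.DataFrame(corr, index=subset, columns=subset),
        undefined=undefined,
    )
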