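"""L1-penalized logistic regression with random intercepts.

The selection model is a logistic regression of binary disease status on the
omic features (penalized), demographic covariates (age, sex, race,
antibiotic use; never penalized), and crossed random intercepts for study
site and participant:

    logit P(y=1) = mu + sum_j beta_j feature_j + covariates
                   + u_site + u_participant

Fitting alternates (a) coordinate-descent updates of the fixed effects on
the working (IRLS) quadratic approximation, with soft-thresholding of the
penalized block only, (b) Newton updates of the random-intercept modes, and
(c) variance-component updates.  At fixed variances the algorithm descends
the penalized joint (h-likelihood) objective with backtracking, so the
recorded objective trace is non-increasing by construction.  Variances are
estimated by an iterated quasi-likelihood fixed point, bounded above:
because the response is constant within participants, the marginal
likelihood in the participant variance is degenerate (intercepts that
interpolate the diagnosis are always preferred), so the variances are
treated as bounded shrinkage parameters rather than free ML parameters.

The lambda path is fit from the largest penalty down with warm starts; the
working penalty is chosen at the elbow of the selected-feature-count curve,
and the selected features are refit unpenalized (with the same covariates
and random intercepts) to obtain the weights used by the risk scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGridError, SeparationWarning
from .omics_io import CohortMetadata, OmicLayerTable

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "race", "antibiotic_use")
DEFAULT_RANDOM_FACTORS = ("site", "participant_id")


@dataclass
class MixedModelSpec:
    """Which columns are penalized, unpenalized, and grouping factors."""

    feature_ids: Sequence[str]
    covariates: Sequence[str] = DEFAULT_COVARIATES
    random_factors: Sequence[str] = DEFAULT_RANDOM_FACTORS
    standardize: bool = True
    include_intercept: bool = True


class CovariateEncoder:
    """Dummy-codes categorical covariates with categories frozen at fit time,
    so training and validation designs always share columns."""

    def __init__(self, covariates: Sequence[str]):
        self.covariates = list(covariates)
        self.categories_: dict[str, list] = {}
        self.columns_: list[str] = []

    def fit(self, meta: pd.DataFrame) -> "CovariateEncoder":
        cols = []
        for cov in self.covariates:
            s = meta[cov]
            if s.dtype.kind in "bifu" and cov != "antibiotic_use":
                cols.append(cov)
            else:
                levels = sorted(pd.unique(s.astype(str)))
                self.categories_[cov] = levels
                cols.extend(f"{cov}[{lv}]" for lv in levels[1:])  # drop first
        self.columns_ = cols
        return self

    def transform(self, meta: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for cov in self.covariates:
            s = meta[cov]
            if cov in self.categories_:
                s = s.astype(str)
                for lv in self.categories_[cov][1:]:
                    out[f"{cov}[{lv}]"] = (s == lv).astype(float).to_numpy()
            else:
                out[cov] = s.astype(float).to_numpy()
        return pd.DataFrame(out, index=meta.index)[self.columns_]


@dataclass
class ModelData:
    """Aligned numeric arrays for one fit."""

    y: np.ndarray  # (n,) binary
    X: np.ndarray  # (n, p) penalized features
    C: np.ndarray  # (n, k) unpenalized design (intercept first if present)
    feature_ids: list[str]
    covariate_names: list[str]  # matches C columns
    groups: dict[str, np.ndarray]  # factor -> integer codes (n,)
    group_levels: dict[str, list]  # factor -> level labels
    sample_ids: list[str]
    encoder: Optional[CovariateEncoder] = None


def build_model_data(
    table: OmicLayerTable,
    meta: CohortMetadata,
    spec: MixedModelSpec,
    encoder: Optional[CovariateEncoder] = None,
) -> ModelData:
    """Assemble the response, penalized block, covariate design and grouping
    codes for the samples shared by table and metadata (metadata order)."""
    mdf = meta.data.set_index("sample_id")
    shared = [s for s in meta.sample_ids if s in set(table.sample_ids)]
    mdf = mdf.loc[shared]
    y = (mdf["diagnosis"] != "nonIBD").astype(float).to_numpy()
    X = table.data.loc[shared, list(spec.feature_ids)].to_numpy(dtype=float)

    if encoder is None:
        encoder = CovariateEncoder(spec.covariates).fit(mdf)
    cov = encoder.transform(mdf)
    names = list(cov.columns)
    C = cov.to_numpy(dtype=float)
    if spec.include_intercept:
        C = np.column_stack([np.ones(len(mdf)), C])
        names = ["(intercept)"] + names

    groups: dict[str, np.ndarray] = {}
    levels: dict[str, list] = {}
    for factor in spec.random_factors:
        codes, lv = pd.factorize(mdf[factor], sort=True)
        if len(lv) < 2:
            logger.info("random factor %s has <2 levels; dropped", factor)
            continue
        if np.bincount(codes).max() < 2:
            # every group observed once: no repeated measures, the intercept
            # variance is not identifiable from a Bernoulli response
            logger.info("random factor %s has singleton groups only; dropped",
                        factor)
            continue
        groups[factor] = codes.astype(int)
        levels[factor] = list(lv)
    return ModelData(
        y=y, X=X, C=C, feature_ids=list(spec.feature_ids),
        covariate_names=names, groups=groups, group_levels=levels,
        sample_ids=shared, encoder=encoder,
    )


@dataclass
class PenalizedFit:
    lam: float
    beta: pd.Series  # penalized coefficients, original feature scale
    covariate_coefs: pd.Series
    u: dict[str, pd.Series]  # predicted random intercepts
    sigma2: dict[str, float]  # random-effect variances
    converged: bool
    n_iter: int
    objective: float
    objective_trace: list[float] = field(default_factory=list)
    separation_flag: bool = False

    @property
    def selected(self) -> list[str]:
        return [f for f, b in self.beta.items() if b != 0.0]


@dataclass
class LambdaPathEntry:
    lam: float
    n_selected: int
    selected: list[str]
    objective: float
    converged: bool
    error: Optional[str] = None


@dataclass
class LambdaPath:
    grid: np.ndarray  # strictly decreasing
    entries: list[LambdaPathEntry]

    @property
    def counts(self) -> np.ndarray:
        return np.array([e.n_selected for e in self.entries])


@dataclass
class GlmmFit:
    """Unpenalized mixed-logistic refit of the selected features."""

    coefficients: pd.Series  # intercept, covariates, then features
    se: pd.Series
    feature_ids: list[str]
    covariate_names: list[str]
    u: dict[str, pd.Series]
    sigma2: dict[str, float]
    loglik: float
    n_obs: int
    converged: bool
    ridge_used: bool = False

    @property
    def feature_coefs(self) -> pd.Series:
        return self.coefficients[self.feature_ids]


# ----------------------------------------------------------------- internals

_SIGMA_FLOOR = 1e-8
# Upper bound for the estimated random-intercept variances (logit scale).
# With a participant-level response, the participant variance is only weakly
# identified: unbounded likelihood estimates let the intercepts interpolate
# the diagnosis, leaving no signal for the penalized features.  Bounding the
# estimate keeps the intercepts in their intended role of absorbing repeated
# -measures correlation.
_SIGMA_CAP = 1.0


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class _State:
    """Mutable solver state for one fit."""

    def __init__(self, data: ModelData, lam: float, ridge: float = 0.0):
        self.data = data
        self.lam = lam
        self.ridge = ridge
        n, p = data.X.shape
        k = data.C.shape[1]
        self.beta = np.zeros(p)
        self.c = np.zeros(k)
        self.factors = list(data.groups)
        self.sizes = {f: len(data.group_levels[f]) for f in self.factors}
        self.u = {f: np.zeros(self.sizes[f]) for f in self.factors}
        self.sigma2 = {f: 0.1 for f in self.factors}
        # stacked random-effects design bookkeeping
        self.offsets = {}
        off = 0
        for f in self.factors:
            self.offsets[f] = off
            off += self.sizes[f]
        self.q = off
        self.iters = 0
        self.separation = False

    def copy_params(self):
        return (
            self.beta.copy(),
            self.c.copy(),
            {f: v.copy() for f, v in self.u.items()},
            dict(self.sigma2),
        )

    def set_params(self, params):
        beta, c, u, s2 = params
        self.beta = beta.copy()
        self.c = c.copy()
        self.u = {f: v.copy() for f, v in u.items()}
        self.sigma2 = dict(s2)

    def eta(self) -> np.ndarray:
        e = self.data.C @ self.c
        if self.data.X.shape[1]:
            e = e + self.data.X @ self.beta
        for f in self.factors:
            e = e + self.u[f][self.data.groups[f]]
        return e

    def u_stacked(self) -> np.ndarray:
        if not self.factors:
            return np.zeros(0)
        return np.concatenate([self.u[f] for f in self.factors])

    def d_inv_diag(self) -> np.ndarray:
        parts = [
            np.full(self.sizes[f], 1.0 / max(self.sigma2[f], _SIGMA_FLOOR))
            for f in self.factors
        ]
        return np.concatenate(parts) if parts else np.zeros(0)

    def ztwz(self, w: np.ndarray) -> np.ndarray:
        """Dense q x q cross-product of the stacked random-effects design."""
        q = self.q
        M = np.zeros((q, q))
        gidx = {
            f: self.offsets[f] + self.data.groups[f] for f in self.factors
        }
        for fa in self.factors:
            ia = gidx[fa]
            np.add.at(M, (ia, ia), w)
        # cross-factor blocks
        for a_i, fa in enumerate(self.factors):
            for fb in self.factors[a_i + 1:]:
                ia, ib = gidx[fa], gidx[fb]
                np.add.at(M, (ia, ib), w)
                np.add.at(M, (ib, ia), w)
        return M

    def zt_vec(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros(self.q)
        for f in self.factors:
            np.add.at(out, self.offsets[f] + self.data.groups[f], v)
        return out

    # ---------------------------------------------------------- objectives

    def conditional_penalty(self) -> float:
        """Quadratic random-effect prior term at current variances."""
        total = 0.0
        for f in self.factors:
            total += float(self.u[f] @ self.u[f]) / (
                2.0 * max(self.sigma2[f], _SIGMA_FLOOR)
            )
        return total

    def h_objective(self, eta: Optional[np.ndarray] = None) -> float:
        """Joint penalized objective at fixed variances (no log-det term)."""
        if eta is None:
            eta = self.eta()
        val = -_bernoulli_loglik(self.data.y, eta) + self.conditional_penalty()
        val += self.lam * float(np.abs(self.beta).sum())
        if self.ridge:
            c_pen = self.c
            if self.data.covariate_names and (
                self.data.covariate_names[0] == "(intercept)"
            ):
                c_pen = self.c[1:]
            val += 0.5 * self.ridge * (
                float(self.beta @ self.beta) + float(c_pen @ c_pen)
            )
        return val

    def laplace_objective(self) -> float:
        """Penalized negative Laplace marginal log-likelihood."""
        eta = self.eta()
        val = self.h_objective(eta)
        if self.q:
            w = np.clip(_sigmoid(eta) * (1.0 - _sigmoid(eta)), 1e-10, None)
            M = self.ztwz(w)
            A = M * self._sigma_diag()[None, :]
            A[np.diag_indices_from(A)] += 1.0
            sign, logdet = np.linalg.slogdet(A)
            if sign <= 0:
                logdet = 0.0
            val += 0.5 * logdet
        return val

    def _sigma_diag(self) -> np.ndarray:
        parts = [
            np.full(self.sizes[f], max(self.sigma2[f], _SIGMA_FLOOR))
            for f in self.factors
        ]
        return np.concatenate(parts) if parts else np.zeros(0)


def _cd_descent(
    state: _State,
    max_irls: int = 200,
    tol: float = 1e-6,
    trace: Optional[list] = None,
) -> bool:
    """Descend the penalized joint objective at fixed variances.

    Each IRLS iteration builds the working weighted-least-squares problem at
    the current linear predictor, then alternates an exact joint solve of the
    unpenalized block (covariates plus random intercepts, ridged by the
    prior precisions; solving jointly avoids the slow zigzag between the
    intercept and the near-collinear participant block) with soft-threshold
    coordinate descent over the penalized features.  The IRLS proposal is
    backtracked against the true objective, so every accepted step is
    downhill.  Diverging coefficients and numerically perfect fits trigger
    an early stop with the separation flag set.  Returns True when the
    objective change falls below ``tol``.
    """
    data, lam = state.data, state.lam
    X, C, y = data.X, data.C, data.y
    n, p = X.shape
    k = C.shape[1]
    ridge_c = np.ones(k) * state.ridge
    if k and data.covariate_names and data.covariate_names[0] == "(intercept)":
        ridge_c[0] = 0.0
    # fixed design of the unpenalized block: covariates then stacked
    # one-hot random-intercept indicators
    blocks = [C]
    for f in state.factors:
        Z = np.zeros((n, state.sizes[f]))
        Z[np.arange(n), data.groups[f]] = 1.0
        blocks.append(Z)
    A = np.column_stack(blocks) if blocks else np.zeros((n, 0))
    m = A.shape[1]
    swtol = 1e-7

    def unpack(sol):
        c = sol[:k]
        u = {
            f: sol[k + state.offsets[f]: k + state.offsets[f] + state.sizes[f]]
            for f in state.factors
        }
        return c, u

    prev = state.h_objective()
    if trace is not None:
        trace.append(prev)
    for _ in range(max_irls):
        state.iters += 1
        old = state.copy_params()
        eta = state.eta()
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-6, None)
        z = eta + (y - mu) / w

        beta = state.beta.copy()
        c, u = state.c.copy(), {f: state.u[f].copy() for f in state.factors}
        pen = np.concatenate([ridge_c] + [
            np.full(state.sizes[f], 1.0 / max(state.sigma2[f], _SIGMA_FLOOR))
            for f in state.factors
        ]) if m else np.zeros(0)
        wA = w[:, None] * A
        M = A.T @ wA
        M[np.diag_indices_from(M)] += pen
        wx2 = (w[:, None] * X * X).sum(axis=0) + state.ridge if p else np.zeros(0)

        for _round in range(3):
            # exact working solve of the unpenalized block
            if m:
                rhs = wA.T @ (z - (X @ beta if p else 0.0))
                sol = np.linalg.solve(M, rhs)
                c, u = unpack(sol)
            if p == 0:
                break
            # soft-threshold coordinate descent on the penalized block
            eta_un = A @ sol if m else np.zeros(n)
            r = z - eta_un - X @ beta
            changed = False
            budget = 100
            active = range(p)
            while budget > 0:
                budget -= 1
                delta_max = 0.0
                for j in active:
                    xj = X[:, j]
                    num = float((w * xj) @ r) + wx2[j] * beta[j]
                    anum = abs(num)
                    new = (
                        np.sign(num) * (anum - lam) / wx2[j]
                        if anum > lam else 0.0
                    )
                    d = new - beta[j]
                    if d != 0.0:
                        r -= d * xj
                        beta[j] = new
                        changed = True
                        delta_max = max(
                            delta_max, abs(d) * np.sqrt(wx2[j])
                        )
                if delta_max < swtol:
                    if isinstance(active, range):
                        break
                    active = range(p)  # re-check the full set once
                else:
                    active = [j for j in range(p) if beta[j] != 0.0]
            if not changed:
                break

        # backtrack the joint IRLS proposal against the true objective
        t = 1.0
        accepted = False
        for _bt in range(25):
            state.beta = old[0] + t * (beta - old[0])
            state.c = old[1] + t * (c - old[1])
            state.u = {
                f: old[2][f] + t * (u[f] - old[2][f]) for f in state.factors
            }
            if state.h_objective() <= prev + 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            state.set_params(old)
            if trace is not None:
                trace.append(trace[-1])
            return True
        obj = state.h_objective()
        if trace is not None:
            trace.append(min(obj, trace[-1]))
        if np.max(np.abs(state.beta), initial=0.0) > 12.0:
            state.separation = True
            return True
        if obj - lam * float(np.abs(state.beta).sum()) < 0.05:
            # essentially perfect in-sample fit: nothing left to descend
            state.separation = True
            return True
        if prev - obj < tol * (1.0 + abs(prev)):
            return True
        prev = obj
    return False


def _newton_random_effects(state: _State, max_iter: int = 50) -> None:
    """Posterior-mode update of the stacked random intercepts at fixed
    fixed-effects and variances (damped Newton)."""
    if not state.q:
        return
    data = state.data
    fix = data.C @ state.c + (data.X @ state.beta if data.X.shape[1] else 0.0)
    d_inv = state.d_inv_diag()
    u = state.u_stacked()

    def unstack(uvec):
        return {
            f: uvec[state.offsets[f]: state.offsets[f] + state.sizes[f]]
            for f in state.factors
        }

    def obj(uvec):
        parts = unstack(uvec)
        eta = fix.copy()
        for f in state.factors:
            eta += parts[f][data.groups[f]]
        return -_bernoulli_loglik(data.y, eta) + 0.5 * float(
            (uvec * uvec) @ d_inv
        ), eta

    val, eta = obj(u)
    for _ in range(max_iter):
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = -state.zt_vec(data.y - mu) + d_inv * u
        H = state.ztwz(w)
        H[np.diag_indices_from(H)] += d_inv
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.diag(H)
        t = 1.0
        for _bt in range(25):
            cand = u - t * step
            new_val, new_eta = obj(cand)
            if new_val <= val + 1e-12:
                break
            t *= 0.5
        else:
            break
        if val - new_val < 1e-10 * (1.0 + abs(val)):
            u, val, eta = cand, new_val, new_eta
            break
        u, val, eta = cand, new_val, new_eta
    state.u = {f: v.copy() for f, v in unstack(u).items()}


def _group_sum(codes: np.ndarray, q: int, v: np.ndarray) -> np.ndarray:
    out = np.zeros(q)
    np.add.at(out, codes, v)
    return out


def _update_variances(state: _State, max_em: int = 60, tol: float = 1e-3) -> None:
    """Quasi-likelihood variance update iterated to its fixed point:

        sigma_f^2  <-  ( ||u_f||^2 + tr[(Z'WZ + D^-1)^-1]_ff ) / q_f

    with the intercept modes refreshed after each step.  This deliberately
    follows the penalized quasi-likelihood estimate rather than the marginal
    maximum likelihood: the response is constant within participants, so the
    marginal likelihood in the participant variance is maximized by
    intercepts that interpolate the diagnosis, which would leave no signal
    for the penalized features to explain.  The quasi-likelihood fixed point
    stays finite and small in that regime.  A variance drifting monotonically
    below 1e-3 is snapped to the floor (the fixed-point iteration approaches
    zero only sublinearly).
    """
    if not state.q:
        return
    decreasing = {f: 0 for f in state.factors}
    for _ in range(max_em):
        eta = state.eta()
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = state.ztwz(w)
        H[np.diag_indices_from(H)] += state.d_inv_diag()
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return
        shift = 0.0
        for f in state.factors:
            a, b = state.offsets[f], state.offsets[f] + state.sizes[f]
            cand = (
                float(state.u[f] @ state.u[f]) + float(np.trace(Hinv[a:b, a:b]))
            ) / state.sizes[f]
            cand = float(np.clip(cand, _SIGMA_FLOOR, _SIGMA_CAP))
            if cand < state.sigma2[f]:
                decreasing[f] += 1
            else:
                decreasing[f] = 0
            if cand < 1e-3 and decreasing[f] >= 3:
                cand = _SIGMA_FLOOR
            shift = max(shift, abs(np.log(cand / state.sigma2[f])))
            state.sigma2[f] = cand
        _newton_random_effects(state)
        if shift < tol:
            break


def _solve(
    data: ModelData,
    lam: float,
    init=None,
    max_iter: int = 500,
    tol: float = 1e-6,
    ridge: float = 0.0,
    estimate_variance: bool = True,
    variance_rounds: int = 4,
) -> _State:
    """Alternating minimization of the penalized joint objective.

    At fixed variances, IRLS/coordinate-descent cycles monotonically
    decrease the penalized h-objective; the variances are then re-estimated
    by the quasi-likelihood fixed point and the descent repeated, until the
    variances stabilize.  The recorded trace is the final fixed-variance
    descent and is non-increasing by construction.
    """
    state = _State(data, lam, ridge=ridge)
    if init is not None:
        state.set_params(init)

    converged = _cd_descent(state, max_irls=max_iter, tol=tol)
    if state.q and estimate_variance:
        for _ in range(variance_rounds):
            old = dict(state.sigma2)
            _update_variances(state)
            converged = _cd_descent(state, max_irls=max_iter, tol=tol)
            shift = max(
                abs(np.log(max(state.sigma2[f], _SIGMA_FLOOR))
                    - np.log(max(old[f], _SIGMA_FLOOR)))
                for f in state.factors
            )
            if shift < 0.05:
                break
    trace: list[float] = []
    converged = _cd_descent(state, max_irls=max_iter, tol=tol, trace=trace) and converged
    state.trace = trace  # type: ignore[attr-defined]
    state.converged = converged  # type: ignore[attr-defined]
    state.n_iter = state.iters  # type: ignore[attr-defined]
    return state


def _standardize_X(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0) if X.size else np.zeros(X.shape[1])
    sd = X.std(axis=0) if X.size else np.ones(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


# ------------------------------------------------------------- public API


def _fit_null(data: ModelData, max_iter: int = 200, tol: float = 1e-8) -> _State:
    null_data = replace(data, X=np.zeros((len(data.y), 0)), feature_ids=[])
    return _solve(null_data, lam=0.0, max_iter=max_iter, tol=tol)


def _null_init(data: ModelData):
    """Warm start at the covariate-only fit (features at exactly zero), so a
    fit at lambda >= lambda_max is a stationary point by construction."""
    null = _fit_null(data)
    return (
        np.zeros(data.X.shape[1]),
        null.c.copy(),
        {f: v.copy() for f, v in null.u.items()},
        dict(null.sigma2),
    )


def lambda_grid(
    spec: MixedModelSpec,
    data: ModelData,
    n_points: int = 20,
    min_ratio: float = 0.01,
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to lambda_max*min_ratio.

    lambda_max is the largest absolute component of the score equation for
    the penalized block at the null (intercept + covariates + random
    intercepts) fit, i.e. the smallest penalty at which every penalized
    coefficient is exactly zero.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not (0 < min_ratio < 1):
        raise ValueError("min_ratio must be in (0, 1)")
    X = data.X
    Xs = _standardize_X(X)[0] if spec.standardize else X
    null = _fit_null(data)
    resid = data.y - _sigmoid(null.eta())
    lam_max = float(np.max(np.abs(Xs.T @ resid))) if X.shape[1] else 0.0
    if lam_max <= 0 or np.all(Xs.std(axis=0) == 0):
        raise DegenerateGridError("all penalized features are constant")
    return np.geomspace(lam_max, lam_max * min_ratio, n_points)


def _prepare(spec: MixedModelSpec, data: ModelData):
    if spec.standardize:
        Xs, mu, sd = _standardize_X(data.X)
        return replace(data, X=Xs), mu, sd
    p = data.X.shape[1]
    return data, np.zeros(p), np.ones(p)


def _state_to_fit(
    state: _State, data: ModelData, lam: float, mu: np.ndarray, sd: np.ndarray
) -> PenalizedFit:
    # numerical zero-clip: coefficients below working precision are not
    # meaningfully "selected"
    state.beta[np.abs(state.beta) < 1e-7] = 0.0
    beta_orig = state.beta / sd
    c = state.c.copy()
    if data.covariate_names and data.covariate_names[0] == "(intercept)":
        c[0] -= float((state.beta * mu / sd).sum())
    separation = bool(
        getattr(state, "separation", False)
        or np.max(np.abs(state.beta), initial=0.0) > 12.0
    )
    if separation:
        warnings.warn(
            "coefficients diverging: possible complete separation",
            SeparationWarning,
            stacklevel=3,
        )
    return PenalizedFit(
        lam=lam,
        beta=pd.Series(beta_orig, index=data.feature_ids),
        covariate_coefs=pd.Series(c, index=data.covariate_names),
        u={
            f: pd.Series(state.u[f], index=data.group_levels[f])
            for f in state.factors
        },
        sigma2={f: state.sigma2[f] for f in state.factors},
        converged=bool(state.converged),
        n_iter=int(state.n_iter),
        objective=float(state.trace[-1]),
        objective_trace=[float(v) for v in state.trace],
        separation_flag=separation,
    )


def fit_lasso_glmm(
    spec: MixedModelSpec,
    data: ModelData,
    lam: float,
    init=None,
    max_iter: int = 500,
    tol: float = 1e-6,
    estimate_variance: bool = True,
) -> PenalizedFit:
    """Fit the penalized mixed-effects logistic model at one penalty value.

    With ``estimate_variance=False`` the variance components stay at their
    null-model estimates (the convention used along the lambda path).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    classes = set(np.unique(data.y))
    if classes != {0.0, 1.0}:
        raise ValueError("response must contain both classes")
    work, mu, sd = _prepare(spec, data)
    if init is None:
        init = _null_init(work)
    state = _solve(
        work, lam, init=init, max_iter=max_iter, tol=tol,
        estimate_variance=estimate_variance,
    )
    return _state_to_fit(state, work, lam, mu, sd)


def lasso_path(
    spec: MixedModelSpec,
    data: ModelData,
    grid: np.ndarray,
    max_iter: int = 150,
    tol: float = 1e-6,
) -> LambdaPath:
    """Fit the grid from the largest penalty down with warm starts.

    The variance components are estimated once on the null (covariate-only)
    model and held fixed along the path, so the empty selection at
    lambda_max is a stationary point by construction and per-lambda
    selection differences reflect the penalty alone."""
    work, mu, sd = _prepare(spec, data)
    entries = []
    init = _null_init(work)
    for lam in grid:
        try:
            state = _solve(
                work, float(lam), init=init, max_iter=max_iter, tol=tol,
                estimate_variance=False,
            )
            init = state.copy_params()
            fit = _state_to_fit(state, work, float(lam), mu, sd)
            entries.append(
                LambdaPathEntry(
                    lam=float(lam),
                    n_selected=len(fit.selected),
                    selected=fit.selected,
                    objective=fit.objective,
                    converged=fit.converged,
                )
            )
        except Exception as exc:  # noqa: BLE001 - path continues past failures
            logger.warning("path fit failed at lambda=%.4g: %s", lam, exc)
            entries.append(
                LambdaPathEntry(
                    lam=float(lam), n_selected=0, selected=[],
                    objective=float("nan"), converged=False, error=str(exc),
                )
            )
    return LambdaPath(grid=np.asarray(grid, dtype=float), entries=entries)


def select_lambda_elbow(path: LambdaPath) -> float:
    """Penalty at the elbow of the selected-count curve.

    With counts c ordered by decreasing penalty, the elbow maximizes the
    discrete second difference c[i] - 2 c[i-1] + c[i-2]; ties break toward
    the larger penalty (sparser model).  If no second difference is
    positive (flat or linear curve) the grid point whose count is closest
    to half the maximum count is used instead, with a warning.
    """
    counts = path.counts
    if len(counts) < 3:
        raise ValueError("path needs >= 3 grid points")
    d2 = counts[2:] - 2 * counts[1:-1] + counts[:-2]
    if d2.max(initial=0) > 0:
        idx = int(np.argmax(d2)) + 2  # argmax returns first (largest-penalty) tie
        return float(path.grid[idx])
    warnings.warn(
        "selected-count curve has no positive curvature; "
        "falling back to the point nearest half the maximum count",
        stacklevel=2,
    )
    half = counts.max() / 2.0
    idx = int(np.argmin(np.abs(counts - half)))
    return float(path.grid[idx])


def refit_glmm(
    spec: MixedModelSpec,
    data: ModelData,
    selected: Sequence[str],
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GlmmFit:
    """Unpenalized mixed-logistic refit restricted to the selected features.

    Returns coefficients with Wald standard errors from the Laplace Fisher
    information (fixed-effects block, profiled over the random intercepts).
    On separation or a singular information matrix the fit is retried with a
    weakly-informative ridge stabilizer (unit Gaussian precision on the
    standardized coefficients), recorded on the result.
    """
    selected = list(selected)
    if not selected:
        warnings.warn("no selected features: covariate-only refit", stacklevel=2)
    idx = [data.feature_ids.index(f) for f in selected]
    sub = replace(data, X=data.X[:, idx], feature_ids=selected)
    work, mu, sd = _prepare(spec, sub)

    def attempt(ridge: float):
        state = _solve(work, lam=0.0, max_iter=max_iter, tol=tol, ridge=ridge)
        fit = _state_to_fit(state, work, 0.0, mu, sd)
        return state, fit

    ridge_used = False
    state, pfit = attempt(0.0)
    if pfit.separation_flag or not np.all(np.isfinite(state.beta)):
        ridge_used = True
        state, pfit = attempt(1.0)
        if not np.all(np.isfinite(state.beta)):
            raise np.linalg.LinAlgError("refit failed even with ridge stabilizer")

    # Fisher information of the fixed effects on the ORIGINAL feature scale
    A = np.column_stack([sub.C, sub.X]) if selected else sub.C
    eta = state.eta() if not spec.standardize else None
    if eta is None:
        # recompute eta on original scale (identical linear predictor)
        coefs = np.concatenate([pfit.covariate_coefs.to_numpy(),
                                pfit.beta.to_numpy()])
        eta = A @ coefs
        for f in state.factors:
            eta = eta + state.u[f][sub.groups[f]]
    m = _sigmoid(eta)
    w = np.clip(m * (1.0 - m), 1e-10, None)
    I_ff = A.T @ (w[:, None] * A)
    if state.q:
        ZtWA = np.zeros((state.q, A.shape[1]))
        for f in state.factors:
            np.add.at(ZtWA, state.offsets[f] + sub.groups[f], w[:, None] * A)
        H_uu = state.ztwz(w)
        H_uu[np.diag_indices_from(H_uu)] += state.d_inv_diag()
        I_ff = I_ff - ZtWA.T @ np.linalg.solve(H_uu, ZtWA)
    if ridge_used:
        I_ff = I_ff + 1.0 * np.eye(I_ff.shape[0])
    try:
        cov = np.linalg.inv(I_ff)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(I_ff)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    names = sub.covariate_names + selected
    coef_values = np.concatenate(
        [pfit.covariate_coefs.to_numpy(), pfit.beta.to_numpy()]
    )
    # Laplace marginal log-likelihood (unpenalized part of the objective)
    loglik = -(state.laplace_objective())
    return GlmmFit(
        coefficients=pd.Series(coef_values, index=names),
        se=pd.Series(se, index=names),
        feature_ids=selected,
        covariate_names=sub.covariate_names,
        u=pfit.u,
        sigma2=pfit.sigma2,
        loglik=float(loglik),
        n_obs=len(sub.y),
        converged=pfit.converged,
        ridge_used=ridge_used,
    )


def predict_linear(
    fit: GlmmFit,
    table: Optional[OmicLayerTable],
    meta: CohortMetadata,
    encoder: CovariateEncoder,
    use_site: bool = True,
) -> pd.Series:
    """Per-sample linear predictor for new samples.

    Covariate effects always apply; site intercepts apply when the site was
    seen in training; participant intercepts are 0 for unseen participants.
    """
    mdf = meta.data.set_index("sample_id")
    if table is not None:
        shared = [s for s in mdf.index if s in set(table.sample_ids)]
        mdf = mdf.loc[shared]
    cov = encoder.transform(mdf)
    eta = np.full(len(mdf), fit.coefficients.get("(intercept)", 0.0))
    for name in encoder.columns_:
        eta = eta + fit.coefficients.get(name, 0.0) * cov[name].to_numpy()
    if table is not None and fit.feature_ids:
        eta = eta + table.data.loc[mdf.index, fit.feature_ids].to_numpy() @ (
            fit.feature_coefs.to_numpy()
        )
    if use_site and "site" in fit.u:
        eta = eta + mdf["site"].map(fit.u["site"]).fillna(0.0).to_numpy()
    return pd.Series(eta, index=mdf.index)
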