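"""Maximum-likelihood Gaussian linear mixed models for two-level data.

The engine fits models of the form

    y_ij = x_ij' beta + z_ij' u_j + e_ij,
    u_j ~ N(0, G),   e_ij ~ N(0, sigma^2),

with a cluster random intercept and optionally a random slope on one
individual-level variable (with intercept-slope covariance).  Estimation is
by maximum likelihood (ML, not REML) so that Wald and likelihood-ratio
comparisons remain coherent across fixed-effect changes.

Implementation notes
--------------------
* The marginal likelihood is profiled over the fixed effects (GLS) and the
  residual variance, leaving an optimisation over the relative Cholesky
  factor ``theta`` of G/sigma^2 (diagonal entries bounded at 0, so every
  iterate maps to a valid covariance).  Because the profiled deviance
  depends on the data only through per-cluster cross-products
  (Z'Z, Z'X, Z'y, X'X, X'y, y'y), each evaluation costs O(J) regardless
  of cluster sizes.
* The parameter covariance is the inverse observed information at the
  optimum, computed jointly over the fixed effects AND the variance
  components (tau^2_0, tau_01, tau^2_1, sigma^2) in natural units: the
  beta block is analytic (X'V^-1 X), the variance block and the cross
  block use central finite differences of the exact log-likelihood.
  This joint covariance is what permits Wald tests that constrain
  variance components alongside fixed effects.
* Wald tests on a variance component at its boundary (tau^2_1 = 0) use the
  ordinary chi-square reference; this is anti-conservative at the boundary
  and the result carries an explicit caveat.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import TrialDataset, ConfigError

logger = logging.getLogger(__name__)

INTERCEPT = "Intercept"
VAR_INTERCEPT = "var_intercept"
COV_INT_SLOPE = "cov_intercept_slope"
VAR_SLOPE = "var_slope"
VAR_RESIDUAL = "var_residual"

BOUNDARY_CAVEAT = (
    "random-slope variance estimated at (or near) the boundary 0; the "
    "chi-square reference for Wald tests involving variance components is "
    "anti-conservative there"
)


class ConvergenceError(RuntimeError):
    """The optimiser failed to produce a usable fit."""


class RankDeficiencyError(ValueError):
    """The fixed-effect design matrix is not of full column rank."""


@dataclass(frozen=True)
class MixedModelSpec:
    """Structure of a two-level Gaussian mixed model.

    Parameters
    ----------
    response
        Column name of the response.
    fixed
        Fixed-effect terms: column names, or ``"a:b"`` for the elementwise
        product of two columns (cluster-level x individual-level
        interactions).  An intercept is always included first.
    random_slope
        Individual-level column receiving a cluster random slope, or None
        for a random-intercept-only model.
    slope_cov
        Whether the random slope covaries with the random intercept
        (only meaningful when ``random_slope`` is set).
    """

    response: str
    fixed: tuple[str, ...]
    random_slope: str | None = None
    slope_cov: bool = True

    def __init__(self, response, fixed, random_slope=None, slope_cov=True):
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "fixed", tuple(fixed))
        object.__setattr__(self, "random_slope", random_slope)
        object.__setattr__(self, "slope_cov", bool(slope_cov))

    @property
    def fixed_names(self) -> list[str]:
        return [INTERCEPT] + list(self.fixed)

    @property
    def varcomp_names(self) -> list[str]:
        names = [VAR_INTERCEPT]
        if self.random_slope is not None:
            if self.slope_cov:
                names.append(COV_INT_SLOPE)
            names.append(VAR_SLOPE)
        names.append(VAR_RESIDUAL)
        return names

    @property
    def n_random(self) -> int:
        return 2 if self.random_slope is not None else 1


@dataclass(frozen=True)
class WaldResult:
    """Chi-square Wald test on a subvector of model parameters."""

    statistic: float
    df: int
    p_value: float
    constrained_terms: tuple[str, ...]
    caveats: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "constrained_terms": list(self.constrained_terms),
            "caveats": list(self.caveats),
        }


@dataclass(frozen=True)
class FitResult:
    """ML fit of a :class:`MixedModelSpec`.

    ``parameter_covariance`` is indexed by ``param_names`` (fixed-effect
    terms followed by variance components in natural units).
    """

    spec: MixedModelSpec
    param_names: tuple[str, ...]
    estimates: np.ndarray  # aligned with param_names
    parameter_covariance: np.ndarray
    loglik: float
    n_obs: int
    n_clusters: int
    converged: bool
    n_iter: int
    grad_norm: float
    at_boundary: bool
    message: str = ""
    caveats: tuple[str, ...] = ()

    # -- accessors -------------------------------------------------------

    def _index(self, term: str) -> int:
        try:
            return self.param_names.index(term)
        except ValueError:
            raise KeyError(
                f"unknown term {term!r}; available: {list(self.param_names)}"
            ) from None

    def estimate(self, term: str) -> float:
        return float(self.estimates[self._index(term)])

    def se(self, term: str) -> float:
        i = self._index(term)
        return float(np.sqrt(max(self.parameter_covariance[i, i], 0.0)))

    def z_p_value(self, term: str) -> float:
        """Two-sided normal-reference p-value for a single coefficient."""
        se = self.se(term)
        if se == 0:
            return float(self.estimate(term) == 0.0)
        return float(2.0 * stats.norm.sf(abs(self.estimate(term) / se)))

    @property
    def fixed_estimates(self) -> dict[str, float]:
        return {t: self.estimate(t) for t in self.spec.fixed_names}

    @property
    def variance_components(self) -> dict[str, float]:
        return {t: self.estimate(t) for t in self.spec.varcomp_names}

    def cov_block(self, terms: list[str]) -> np.ndarray:
        idx = [self._index(t) for t in terms]
        return self.parameter_covariance[np.ix_(idx, idx)]

    def to_json(self, **dump_kwargs) -> str:
        payload = {
            "response": self.spec.response,
            "fixed_effects": {
                t: {"estimate": self.estimate(t), "se": self.se(t),
                    "p_value": self.z_p_value(t)}
                for t in self.spec.fixed_names
            },
            "variance_components": self.variance_components,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "parameter_names": list(self.param_names),
            "parameter_covariance": self.parameter_covariance.tolist(),
            "convergence": {
                "converged": self.converged,
                "n_iter": self.n_iter,
                "grad_norm": self.grad_norm,
                "at_boundary": self.at_boundary,
                "message": self.message,
            },
            "caveats": list(self.caveats),
        }
        return json.dumps(payload, **dump_kwargs)


# -- design construction ---------------------------------------------------


def _resolve_term(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == INTERCEPT or term == "1":
        return np.ones(len(df))
    if ":" in term:
        a, b = term.split(":", 1)
        return _resolve_term(df, a) * _resolve_term(df, b)
    if term not in df.columns:
        raise ConfigError(
            f"term {term!r} does not resolve to a column; "
            f"available: {list(df.columns)}"
        )
    return df[term].to_numpy(dtype=float)


def build_design(
    df: pd.DataFrame, spec: MixedModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (y, X, Z, cluster codes) for the spec on this frame."""
    y = _resolve_term(df, spec.response)
    X = np.column_stack([_resolve_term(df, t) for t in spec.fixed_names])
    if spec.random_slope is not None:
        Z = np.column_stack(
            [np.ones(len(df)), _resolve_term(df, spec.random_slope)]
        )
    else:
        Z = np.ones((len(df), 1))
    codes, _ = pd.factorize(df["cluster"], sort=False)
    _check_rank(X, spec.fixed_names)
    return y, X, Z, codes


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # QR with small diagonal of R identifies (near-)collinear columns
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    R = np.linalg.qr(X / scale, mode="r")
    diag = np.abs(np.diag(R))
    bad = [names[i] for i in range(len(names)) if diag[i] < 1e-8 * max(diag.max(), 1)]
    if bad:
        raise RankDeficiencyError(
            f"fixed-effect design is rank deficient; collinear term(s): {bad}"
        )


# -- sufficient statistics --------------------------------------------------


class _Suffstats:
    """Per-cluster cross-products; everything the likelihood needs."""

    def __init__(self, y, X, Z, codes):
        order = np.argsort(codes, kind="stable")
        y, X, Z, codes = y[order], X[order], Z[order], codes[order]
        self.N, self.p = X.shape
        self.q = Z.shape[1]
        uniq, starts = np.unique(codes, return_index=True)
        bounds = np.r_[starts, self.N]
        self.J = len(uniq)
        self.nj = np.diff(bounds)
        J, p, q = self.J, self.p, self.q
        self.ZtZ = np.empty((J, q, q))
        self.ZtX = np.empty((J, q, p))
        self.Zty = np.empty((J, q))
        self.XtX = np.empty((J, p, p))
        self.Xty = np.empty((J, p))
        self.yty = np.empty(J)
        for j in range(J):
            s = slice(bounds[j], bounds[j + 1])
            Xj, Zj, yj = X[s], Z[s], y[s]
            self.ZtZ[j] = Zj.T @ Zj
            self.ZtX[j] = Zj.T @ Xj
            self.Zty[j] = Zj.T @ yj
            self.XtX[j] = Xj.T @ Xj
            self.Xty[j] = Xj.T @ yj
            self.yty[j] = yj @ yj

    # ---- profiled pieces given relative covariance Gt = G / sigma^2 ----

    def _collapse(self, W):
        """GLS building blocks for V* = I + Z Gt Z' given W_j = Gt M_j^-1.

        Returns (A, b, yVy, logdet) with A = sum X'V*^-1 X, b = sum X'V*^-1 y,
        yVy = sum y'V*^-1 y, logdet = sum log|V*_j|;  W must satisfy
        W_j = Gt (I + Z'Z_j Gt)^-1 (symmetric).
        """
        # quadratic corrections via the q-dimensional projections
        WZtX = W @ self.ZtX                                     # (J,q,p)
        A = self.XtX.sum(0) - np.einsum("jqp,jqr->pr", self.ZtX, WZtX)
        WZty = np.einsum("jqr,jr->jq", W, self.Zty)             # (J,q)
        b = self.Xty.sum(0) - np.einsum("jqp,jq->p", self.ZtX, WZty)
        yVy = self.yty.sum() - np.einsum("jq,jq->", self.Zty, WZty)
        return A, b, yVy

    def profiled(self, Gt):
        """Profiled quantities for relative random-effect covariance Gt."""
        q = self.q
        M = np.eye(q)[None] + self.ZtZ @ Gt                     # (J,q,q)
        sign, logabs = np.linalg.slogdet(M)
        if np.any(sign <= 0):
            return None
        W = Gt[None] @ np.linalg.inv(M)
        W = 0.5 * (W + np.swapaxes(W, 1, 2))
        A, b, yVy = self._collapse(W)
        return A, b, yVy, float(logabs.sum())


def _theta_to_L(theta: np.ndarray, q: int, slope_cov: bool) -> np.ndarray:
    L = np.zeros((q, q))
    if q == 1:
        L[0, 0] = theta[0]
    elif slope_cov:
        L[0, 0], L[1, 0], L[1, 1] = theta
    else:
        L[0, 0], L[1, 1] = theta
    return L


def _profiled_deviance(theta, ss: _Suffstats, q, slope_cov):
    L = _theta_to_L(np.asarray(theta, float), q, slope_cov)
    out = ss.profiled(L @ L.T)
    if out is None:  # pragma: no cover - PD by construction here
        return np.inf, None, None
    A, b, yVy, logdet = out
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    rss = yVy - beta @ b
    if rss <= 0 or not np.isfinite(rss):
        return np.inf, None, None
    sigma2 = rss / ss.N
    dev = ss.N * np.log(2 * np.pi * sigma2) + logdet + ss.N
    return dev, beta, sigma2


def _loglik_natural(beta, phi, ss: _Suffstats, q, slope_cov):
    """Exact marginal log-likelihood at natural parameters.

    ``phi`` stacks the variance components in the order
    (tau^2_0[, tau_01, tau^2_1], sigma^2).  Valid as an analytic
    continuation for small negative excursions used by finite differences.
    """
    sigma2 = phi[-1]
    if sigma2 <= 0:
        return None
    G = np.zeros((q, q))
    G[0, 0] = phi[0]
    if q == 2:
        if slope_cov:
            G[0, 1] = G[1, 0] = phi[1]
            G[1, 1] = phi[2]
        else:
            G[1, 1] = phi[1]
    Gt = G / sigma2
    M = np.eye(q)[None] + ss.ZtZ @ Gt
    sign, logabs = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        return None
    W = Gt[None] @ np.linalg.inv(M)
    W = 0.5 * (W + np.swapaxes(W, 1, 2))
    A, b, yVy = ss._collapse(W)
    quad = yVy - 2 * beta @ b + beta @ A @ beta
    ll = -0.5 * (ss.N * np.log(2 * np.pi * sigma2) + logabs.sum() + quad / sigma2)
    return float(ll), A, b


def _beta_gradient(beta, phi, ss, q, slope_cov):
    out = _loglik_natural(beta, phi, ss, q, slope_cov)
    if out is None:
        return None
    _, A, b = out
    return (b - A @ beta) / phi[-1]


# -- observed information ---------------------------------------------------


def _observed_information(beta, phi, ss, q, slope_cov):
    """Negative Hessian of the log-likelihood over (beta, phi)."""
    p, k = len(beta), len(phi)
    ll0, A, _ = _loglik_natural(beta, phi, ss, q, slope_cov)
    sigma2 = phi[-1]
    H = np.zeros((p + k, p + k))
    H[:p, :p] = A / sigma2  # exact: X'V^-1X

    steps = np.array([1e-3 * max(abs(v), 1e-2 * sigma2) for v in phi])

    def ll_at(dphi):
        out = _loglik_natural(beta, phi + dphi, ss, q, slope_cov)
        return None if out is None else out[0]

    def grad_at(dphi):
        return _beta_gradient(beta, phi + dphi, ss, q, slope_cov)

    # cross block: FD of the analytic beta-gradient
    for a in range(k):
        h = steps[a]
        e = np.zeros(k)
        e[a] = h
        gp, gm = grad_at(e), grad_at(-e)
        if gp is None or gm is None:  # one-sided fallback near a boundary
            g0 = grad_at(np.zeros(k))
            if gp is not None:
                d = (gp - g0) / h
            elif gm is not None:
                d = (g0 - gm) / h
            else:  # pragma: no cover
                d = np.zeros(p)
        else:
            d = (gp - gm) / (2 * h)
        H[:p, p + a] = -d
        H[p + a, :p] = -d

    # variance block: central second differences of the log-likelihood
    lls = {}

    def cached(*dphi_key):
        if dphi_key not in lls:
            dphi = np.zeros(k)
            for idx, mult in dphi_key:
                dphi[idx] += mult * steps[idx]
            lls[dphi_key] = ll_at(dphi)
        return lls[dphi_key]

    for a in range(k):
        lp, lm = cached((a, 1)), cached((a, -1))
        if lp is None or lm is None:
            # forward differences away from the invalid region
            l2 = cached((a, 2)) if lm is None else cached((a, -2))
            base = lp if lm is None else lm
            if l2 is None or base is None:  # pragma: no cover
                H[p + a, p + a] = np.inf
                continue
            H[p + a, p + a] = -(l2 - 2 * base + ll0) / steps[a] ** 2
        else:
            H[p + a, p + a] = -(lp - 2 * ll0 + lm) / steps[a] ** 2
    for a in range(k):
        for c in range(a + 1, k):
            pp, pm = cached((a, 1), (c, 1)), cached((a, 1), (c, -1))
            mp, mm = cached((a, -1), (c, 1)), cached((a, -1), (c, -1))
            if None in (pp, pm, mp, mm):
                val = 0.0  # near-boundary cross term; conservative default
            else:
                val = -(pp - pm - mp + mm) / (4 * steps[a] * steps[c])
            H[p + a, p + c] = H[p + c, p + a] = val
    return H


# -- public API -------------------------------------------------------------


def fit_lmm(
    spec: MixedModelSpec,
    data: TrialDataset | pd.DataFrame,
    *,
    gtol: float = 1e-6,
    xtol: float = 1e-8,
    max_iter: int = 200,
) -> FitResult:
    """Fit a Gaussian linear mixed model by maximum likelihood.

    Deterministic: identical spec + data + settings give identical results
    (the optimiser is initialised from moment estimates, with no random
    restarts).
    """
    df = data.df if isinstance(data, TrialDataset) else data
    y, X, Z, codes = build_design(df, spec)
    ss = _Suffstats(y, X, Z, codes)
    q, slope_cov = spec.n_random, spec.slope_cov and spec.random_slope is not None

    if ss.J < 2:
        raise ConfigError("need at least 2 clusters to fit a mixed model")
    singleton_only = bool(np.all(ss.nj == 1))
    if singleton_only:
        warnings.warn(
            "all clusters have a single member: the intercept/residual "
            "variance split is unidentified (fixed effects reduce to OLS)",
            stacklevel=2,
        )

    theta0 = _start_values(y, X, codes, q, slope_cov)
    n_theta = len(theta0)
    if slope_cov and q == 2:
        bounds = [(0, None), (None, None), (0, None)]
    elif q == 2:
        bounds = [(0, None), (0, None)]
    else:
        bounds = [(0, None)]

    obj = lambda th: _profiled_deviance(th, ss, q, slope_cov)[0]
    res = optimize.minimize(
        obj,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": gtol * 1e-2},
    )
    if not res.success or not np.isfinite(res.fun):
        res2 = optimize.minimize(
            obj, res.x if np.isfinite(res.fun) else theta0,
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": 1e-10, "maxiter": 2000},
        )
        if np.isfinite(res2.fun) and res2.fun <= res.fun:
            res2.x = np.clip(res2.x, [b[0] if b[0] is not None else -np.inf
                                      for b in bounds], np.inf)
            res = res2
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"optimiser failed: {res.message}")

    # deterministic simplex polish: the quasi-Newton stop leaves theta at
    # ~1e-5 precision, which is visible in the variance components
    x0 = np.asarray(res.x, float)
    sim = np.vstack([x0] + [
        x0 + np.eye(n_theta)[i] * max(1e-4, 1e-3 * abs(x0[i]))
        for i in range(n_theta)
    ])
    polish = optimize.minimize(
        obj,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": xtol, "fatol": 1e-9, "maxiter": 300,
                 "initial_simplex": sim},
    )
    if np.isfinite(polish.fun) and polish.fun <= res.fun:
        polish.nit = int(res.nit) + int(polish.nit)
        if hasattr(res, "jac"):
            polish.jac = res.jac
        polish.success = res.success or polish.success
        res = polish

    theta = np.asarray(res.x, float)
    dev, beta, sigma2 = _profiled_deviance(theta, ss, q, slope_cov)
    L = _theta_to_L(theta, q, slope_cov)
    G = sigma2 * (L @ L.T)

    phi = [G[0, 0]]
    if q == 2:
        if slope_cov:
            phi.append(G[0, 1])
        phi.append(G[1, 1])
    phi.append(sigma2)
    phi = np.asarray(phi)

    ll = -0.5 * dev
    at_boundary = bool(np.any(theta[np.array([b[0] == 0 for b in bounds])] < 1e-5))
    caveats = []
    if q == 2 and G[1, 1] < 1e-8 * sigma2:
        caveats.append(BOUNDARY_CAVEAT)

    H = _observed_information(beta, phi, ss, q, slope_cov)
    cov = _safe_inverse(H)

    grad_norm = float(np.max(np.abs(res.jac))) if hasattr(res, "jac") else np.nan
    converged = bool(res.success and np.isfinite(ll))
    if not converged:
        logger.warning("mixed-model fit did not converge: %s", res.message)
    if singleton_only:
        at_boundary = True
        caveats.append("variance split unidentified (all clusters singleton)")

    names = tuple(spec.fixed_names + spec.varcomp_names)
    estimates = np.concatenate([beta, phi])
    return FitResult(
        spec=spec,
        param_names=names,
        estimates=estimates,
        parameter_covariance=cov,
        loglik=float(ll),
        n_obs=ss.N,
        n_clusters=ss.J,
        converged=converged,
        n_iter=int(res.nit) if hasattr(res, "nit") else -1,
        grad_norm=grad_norm,
        at_boundary=at_boundary,
        message=str(res.message),
        caveats=tuple(caveats),
    )


def _start_values(y, X, codes, q, slope_cov):
    """Moment-based starting values for the relative Cholesky factor."""
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    frame = pd.DataFrame({"r": resid, "g": codes})
    grp = frame.groupby("g")["r"]
    within = float(grp.transform(lambda v: v - v.mean()).pow(2).mean())
    between = float(grp.mean().var())
    within = max(within, 1e-8)
    ratio = np.sqrt(max(between, 1e-4 * within) / within)
    if q == 1:
        return np.array([ratio])
    if slope_cov:
        return np.array([ratio, 0.0, 0.1])
    return np.array([ratio, 0.1])


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        logger.warning("observed information singular; using pseudo-inverse")
    cov = 0.5 * (cov + cov.T)
    return cov


def wald_test(fit: FitResult, constrained_terms: list[str]) -> WaldResult:
    """Wald chi-square test that a subvector of parameters is zero.

    ``statistic = est' Cov[est]^-1 est`` over the constrained subvector;
    df equals the number of constrained parameters; the p-value is the
    upper chi-square tail.  Raises when the covariance block is singular.
    """
    if not constrained_terms:
        raise ValueError("constrained_terms must be non-empty")
    est = np.array([fit.estimate(t) for t in constrained_terms])
    block = fit.cov_block(list(constrained_terms))
    cond = np.linalg.cond(block)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "covariance block for the constrained terms is (near-)singular; "
            "consider re-parameterising the model or dropping a term"
        )
    statistic = float(est @ np.linalg.solve(block, est))
    statistic = max(statistic, 0.0)
    df = len(constrained_terms)
    p = float(stats.chi2.sf(statistic, df))
    caveats = tuple(
        c for c in fit.caveats if any(t in (VAR_SLOPE, COV_INT_SLOPE)
                                      for t in constrained_terms)
        and c == BOUNDARY_CAVEAT
    )
    return WaldResult(
        statistic=statistic,
        df=df,
        p_value=p,
        constrained_terms=tuple(constrained_terms),
        caveats=caveats,
    )
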