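"""Exact Gaussian-process inference for additive longitudinal models.

Implements the standard machinery for a zero-mean GP with additive
covariance ``K = sum_c K_c + sigma^2 I``: the log marginal likelihood
and its gradients with respect to log-hyperparameters, type-II maximum
likelihood fitting with multi-restart quasi-Newton optimization, exact
posterior prediction, and decomposition of the posterior mean into
per-component contributions with variance shares.

Responses are standardized (mean 0, sd 1 over the supplied
observations) before fitting; predictions are mapped back to the
original log2-intensity scale. Missing observations are handled by
omission — the GP operates on the irregular design directly and no
value is ever imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt

from .kernels import (
    AdditiveModelSpec,
    KernelSpec,
    LENGTHSCALE_BOUNDS,
    VARIANCE_BOUNDS,
    build_kernel,
    model_covariance,
)

__all__ = [
    "GPFit",
    "ComponentDecomposition",
    "GPNumericalError",
    "log_marginal_likelihood",
    "fit_hyperparameters",
    "predict",
    "decompose",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: jitter escalation ladder applied to the diagonal before declaring failure
_JITTERS = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


class GPNumericalError(RuntimeError):
    """Raised when the training covariance cannot be factorized."""


def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor of ``K`` with escalating diagonal jitter."""
    for jitter in _JITTERS:
        try:
            L = sla.cholesky(K + jitter * np.eye(len(K)), lower=True)
            return L, jitter
        except sla.LinAlgError:
            continue
    cond = np.linalg.cond(K)
    raise GPNumericalError(
        f"covariance not positive definite after jitter escalation "
        f"up to {_JITTERS[-1]:g} (condition number {cond:.3g})"
    )


class _Workspace:
    """Precomputed distance/match structures for fast repeated kernel builds.

    Hyperparameter optimization re-evaluates the covariance at every
    step; the squared age distances, seasonal ``sin^2`` terms and factor
    match matrices depend only on the design and are computed once.
    """

    def __init__(self, spec: AdditiveModelSpec, X: pd.DataFrame):
        self.spec = spec
        self.n = len(X)
        self.structs: list[tuple[str, tuple]] = []
        for comp in spec.components:
            if comp.kind == "se_age":
                d2 = _sqdist(X["age"].to_numpy(float))
                self.structs.append(("se", (d2,)))
            elif comp.kind == "periodic_season":
                t = X["season"].to_numpy(float)
                s2 = np.sin(np.pi * (t[:, None] - t[None, :]) / comp.period) ** 2
                self.structs.append(("per", (s2,)))
            elif comp.kind == "categorical":
                self.structs.append(("cat", (_match(X, comp.covariates),)))
            elif comp.kind == "product":
                cats = [c for c in comp.covariates if c not in ("age", "season")]
                d2 = _sqdist(X["age"].to_numpy(float))
                self.structs.append(("prod", (d2, _match(X, cats))))
            else:  # pragma: no cover - AdditiveModelSpec forbids this
                raise AssertionError(comp.kind)

    # --- hyperparameter vector <-> spec -------------------------------
    # layout: per component (log v [, log ell]) in order, then log sigma2

    def pack(self, spec: AdditiveModelSpec) -> np.ndarray:
        theta = []
        for comp in spec.components:
            theta.append(np.log(max(comp.variance, VARIANCE_BOUNDS[0])))
            if comp.n_params == 2:
                theta.append(np.log(comp.lengthscale))
        theta.append(np.log(spec.noise_variance))
        return np.asarray(theta)

    def unpack(self, theta: np.ndarray) -> AdditiveModelSpec:
        comps, i = [], 0
        for comp in self.spec.components:
            v = float(np.exp(theta[i])); i += 1
            if comp.n_params == 2:
                ell = float(np.exp(theta[i])); i += 1
                comps.append(replace(comp, variance=v, lengthscale=ell))
            else:
                comps.append(replace(comp, variance=v))
        return self.spec.with_params(comps, float(np.exp(theta[i])))

    def bounds(self) -> list[tuple[float, float]]:
        lv = tuple(np.log(VARIANCE_BOUNDS))
        ll = tuple(np.log(LENGTHSCALE_BOUNDS))
        b: list[tuple[float, float]] = []
        for comp in self.spec.components:
            b.append(lv)
            if comp.n_params == 2:
                b.append(ll)
        b.append(lv)
        return b

    def cov_and_grads(self, theta: np.ndarray
                      ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Training covariance (noise included) and per-log-parameter grads."""
        K = np.zeros((self.n, self.n))
        grads: list[np.ndarray] = []
        i = 0
        for kind, data in self.structs:
            v = np.exp(theta[i])
            if kind == "cat":
                Kc = v * data[0]
                K += Kc
                grads.append(Kc)
                i += 1
            elif kind == "se":
                ell = np.exp(theta[i + 1])
                r = data[0] / ell**2
                Kc = v * np.exp(-0.5 * r)
                K += Kc
                grads.append(Kc)
                grads.append(Kc * r)
                i += 2
            elif kind == "per":
                ell = np.exp(theta[i + 1])
                r = 2.0 * data[0] / ell**2
                Kc = v * np.exp(-r)
                K += Kc
                grads.append(Kc)
                grads.append(Kc * 2.0 * r)
                i += 2
            else:  # prod
                ell = np.exp(theta[i + 1])
                r = data[0] / ell**2
                Kc = v * np.exp(-0.5 * r) * data[1]
                K += Kc
                grads.append(Kc)
                grads.append(Kc * r)
                i += 2
        sigma2 = np.exp(theta[i])
        K[np.diag_indices(self.n)] += sigma2
        grads.append(sigma2 * np.eye(self.n))
        return K, grads

    def nll_and_grad(self, theta: np.ndarray, y: np.ndarray
                     ) -> tuple[float, np.ndarray]:
        K, grads = self.cov_and_grads(theta)
        try:
            L, _ = _chol_with_jitter(K)
        except GPNumericalError:
            return np.inf, np.zeros_like(theta)
        alpha = sla.cho_solve((L, True), y)
        lml = (-0.5 * y @ alpha
               - np.log(np.diag(L)).sum()
               - 0.5 * self.n * _LOG2PI)
        Kinv = sla.cho_solve((L, True), np.eye(self.n))
        M = np.outer(alpha, alpha) - Kinv
        g = np.array([0.5 * np.sum(M * dK) for dK in grads])
        return -lml, -g


def _sqdist(x: np.ndarray) -> np.ndarray:
    return (x[:, None] - x[None, :]) ** 2


def _match(X: pd.DataFrame, covariates) -> np.ndarray:
    m = np.ones((len(X), len(X)))
    for c in covariates:
        a = X[c].to_numpy()
        m *= (a[:, None] == a[None, :]).astype(float)
    return m


def log_marginal_likelihood(spec: AdditiveModelSpec, X: pd.DataFrame,
                            y: np.ndarray) -> float:
    """``log N(y | 0, K + sigma^2 I)`` at the spec's stored hyperparameters.

    ``y`` is taken as given (callers standardize beforehand); the result
    matches direct multivariate-normal density evaluation.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(X):
        raise ValueError("response must be a vector matching the design")
    K = model_covariance(spec, X)
    L, _ = _chol_with_jitter(K)
    alpha = sla.cho_solve((L, True), y)
    return float(-0.5 * y @ alpha - np.log(np.diag(L)).sum()
                 - 0.5 * len(y) * _LOG2PI)


@dataclass
class GPFit:
    """A fitted additive GP: optimized spec plus cached training solves.

    ``y`` is the standardized response actually modelled; ``y_mean`` and
    ``y_sd`` map back to the original scale. ``log_marginal_likelihood``
    is reproducible from the stored hyperparameters to high precision.
    """

    spec: AdditiveModelSpec
    X: pd.DataFrame
    y: np.ndarray
    y_mean: float
    y_sd: float
    log_marginal_likelihood: float
    seed: int | None = None
    n_restarts: int = 0
    converged: tuple[bool, ...] = ()
    jitter: float = 0.0
    _L: np.ndarray = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.y)

    def train_cov(self) -> np.ndarray:
        """Training covariance including the noise term (and fitted jitter)."""
        K = model_covariance(self.spec, self.X)
        if self.jitter:
            K = K + self.jitter * np.eye(len(K))
        return K

    def solve(self, B: np.ndarray) -> np.ndarray:
        return sla.cho_solve((self._L, True), B)


def _default_start(spec: AdditiveModelSpec, ws: _Workspace) -> np.ndarray:
    """Deterministic initialization: equal variance split, mid-range scales."""
    k = max(len(spec.components), 1)
    comps = []
    for comp in spec.components:
        ell = None
        if comp.kind in ("se_age", "product"):
            ell = 12.0  # months; roughly the spacing of later visits
        elif comp.kind == "periodic_season":
            ell = 1.0
        comps.append(replace(comp, variance=0.5 / k, lengthscale=ell))
    start = spec.with_params(comps, 0.5)
    return ws.pack(start)


def fit_hyperparameters(spec: AdditiveModelSpec, X: pd.DataFrame,
                        y: np.ndarray, n_restarts: int = 5,
                        seed: int | None = 0,
                        standardize: bool = True) -> GPFit:
    """Type-II maximum-likelihood fit of an additive GP.

    Maximizes the log marginal likelihood over log-hyperparameters with
    L-BFGS-B from one deterministic start plus ``n_restarts - 1`` random
    starts drawn uniformly in the log-bounds with the given seed; the
    best converged optimum is returned. Deterministic given
    ``(X, y, seed, n_restarts)``.

    Rows with missing response are dropped (no imputation). Requires at
    least 4 observations.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    X = X.iloc[np.flatnonzero(keep)].reset_index(drop=True)
    y = y[keep]
    if len(y) < 4:
        raise ValueError(f"need >=4 observations to fit, got {len(y)}")

    if standardize:
        y_mean = float(np.mean(y))
        y_sd = float(np.std(y))
        if y_sd == 0:
            raise ValueError("constant response: cannot standardize")
        ys = (y - y_mean) / y_sd
    else:
        y_mean, y_sd = 0.0, 1.0
        ys = y

    ws = _Workspace(spec, X)
    bounds = np.asarray(ws.bounds())
    rng = np.random.default_rng(seed)
    starts = [_default_start(spec, ws)]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.uniform(bounds[:, 0], bounds[:, 1]))

    best = None
    flags: list[bool] = []
    diagnostics: list[str] = []
    for theta0 in starts:
        res = sopt.minimize(
            ws.nll_and_grad, theta0, args=(ys,), jac=True,
            method="L-BFGS-B", bounds=[tuple(b) for b in bounds],
            options={"maxiter": 200},
        )
        ok = bool(res.success) and np.isfinite(res.fun)
        flags.append(ok)
        diagnostics.append(str(res.message))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise GPNumericalError(
            "all restarts failed to converge: " + "; ".join(diagnostics)
        )

    fitted = ws.unpack(best.x)
    K = model_covariance(fitted, X)
    L, jitter = _chol_with_jitter(K)
    alpha = sla.cho_solve((L, True), ys)
    lml = float(-0.5 * ys @ alpha - np.log(np.diag(L)).sum()
                - 0.5 * len(ys) * _LOG2PI)
    return GPFit(
        spec=fitted, X=X, y=ys, y_mean=y_mean, y_sd=y_sd,
        log_marginal_likelihood=lml, seed=seed, n_restarts=n_restarts,
        converged=tuple(flags), jitter=jitter, _L=L, _alpha=alpha,
    )


def predict(fit: GPFit, X_query: pd.DataFrame,
            include_noise: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at new inputs, on the original scale.

    With ``include_noise=True`` the predictive variance covers a new
    observation rather than the latent function value.
    """
    Ks = model_covariance(fit.spec, X_query, fit.X, include_noise=False)
    mean_s = Ks @ fit._alpha
    V = fit.solve(Ks.T)
    Kss_diag = np.array([
        sum(build_kernel(c, X_query.iloc[[i]]).item()
            for c in fit.spec.components)
        for i in range(len(X_query))
    ])
    var = Kss_diag - np.sum(Ks * V.T, axis=1)
    var = np.maximum(var, 0.0)
    if include_noise:
        var = var + fit.spec.noise_variance
    return fit.y_mean + fit.y_sd * mean_s, fit.y_sd**2 * var


@dataclass
class ComponentDecomposition:
    """Per-component posterior means and variance shares of a fitted model.

    ``means`` holds each component's posterior mean at the query inputs
    on the original scale but centred (the training mean is carried in
    ``intercept``); components sum to ``total - intercept`` exactly up
    to numerical precision. ``variance_shares`` are computed on the
    standardized scale at the training inputs: the empirical variance of
    each component's posterior mean, normalized together with the fitted
    noise variance so that shares and ``noise_share`` sum to 1.
    """

    means: dict[str, np.ndarray]
    total: np.ndarray
    intercept: float
    variance_shares: dict[str, float]
    noise_share: float


def decompose(fit: GPFit, X_query: pd.DataFrame | None = None
              ) -> ComponentDecomposition:
    """Split the posterior mean into additive per-component contributions.

    Component ``c`` contributes ``K_c(X*, X) (K + sigma^2 I)^{-1} y``;
    because the kernels add, these contributions sum to the full
    posterior mean. Variance shares follow the same decomposition at the
    training inputs, with the noise share set to the fitted noise
    variance on the standardized scale.
    """
    if X_query is None:
        X_query = fit.X
    means: dict[str, np.ndarray] = {}
    total = np.zeros(len(X_query))
    for comp in fit.spec.components:
        Kc = build_kernel(comp, X_query, fit.X)
        m = Kc @ fit._alpha
        means[comp.label] = fit.y_sd * m
        total += fit.y_sd * m

    shares_raw: dict[str, float] = {}
    for comp in fit.spec.components:
        Kc_train = build_kernel(comp, fit.X, fit.X)
        m_train = Kc_train @ fit._alpha
        shares_raw[comp.label] = float(np.var(m_train))
    denom = sum(shares_raw.values()) + fit.spec.noise_variance
    shares = {k: v / denom for k, v in shares_raw.items()}
    noise_share = fit.spec.noise_variance / denom
    return ComponentDecomposition(
        means=means, total=fit.y_mean + total, intercept=fit.y_mean,
        variance_shares=shares, noise_share=noise_share,
    )
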