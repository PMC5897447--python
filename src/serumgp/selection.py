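"""Covariate-effect detection by cross-validated model comparison.

For each protein, all 2^4 = 16 subsets of the optional covariates
{age, season, gender, location} are turned into candidate additive GP
models. Every candidate additionally carries a subject-identity (``id``)
component and a noise term, and whenever age is present an age-by-id
interaction component (per-subject smooth deviations from the shared
age trend). Candidates are scored by the mean log predictive density
(MLPD) of held-out data under two cross-validation schemes:

- LOOCV (leave one observation out) detects within-subject, time-varying
  effects (age, season); computed by the exact closed-form leave-one-out
  identities for Gaussian GPs at fixed hyperparameters.
- SCV (stratified cross-validation) holds out whole subjects, so that
  subject-constant covariates (gender, location) must generalize to
  unseen children; a held-out child's id component contributes prior
  variance only, never a learned offset.

A covariate is flagged significant when the best model containing it
beats the best model lacking it by at least ``delta`` nats of MLPD under
the scheme appropriate to that covariate, and the covariate's variance
share in that best containing model is at least ``rho``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .gp import GPFit, decompose, fit_hyperparameters
from .kernels import AdditiveModelSpec, KernelSpec, model_covariance

__all__ = [
    "OPTIONAL_COVARIATES",
    "CandidateModel",
    "SelectionThresholds",
    "SelectionResult",
    "InsufficientDataError",
    "enumerate_models",
    "loocv_mlpd",
    "stratified_cv_mlpd",
    "select_effects",
]

log = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

#: the four covariates whose inclusion is tested; id and noise are always in
OPTIONAL_COVARIATES = ("age", "season", "gender", "location")

#: covariates scored by LOOCV (time-varying within a subject)
LOOCV_COVARIATES = frozenset({"age", "season"})


class InsufficientDataError(ValueError):
    """Protein has too few observations or subjects for model selection."""


@dataclass(frozen=True)
class CandidateModel:
    """A covariate subset and the additive model spec it implies."""

    covariates: frozenset

    def __post_init__(self) -> None:
        extra = set(self.covariates) - set(OPTIONAL_COVARIATES)
        if extra:
            raise ValueError(f"not selectable covariates: {sorted(extra)}")

    @property
    def name(self) -> str:
        inc = [c for c in OPTIONAL_COVARIATES if c in self.covariates]
        return "+".join(inc) if inc else "null"

    def spec(self) -> AdditiveModelSpec:
        comps: list[KernelSpec] = []
        if "age" in self.covariates:
            comps.append(KernelSpec("se_age", ("age",), lengthscale=12.0))
        if "season" in self.covariates:
            comps.append(
                KernelSpec("periodic_season", ("season",), lengthscale=1.0))
        if "gender" in self.covariates:
            comps.append(KernelSpec("categorical", ("gender",)))
        if "location" in self.covariates:
            comps.append(KernelSpec("categorical", ("location",)))
        comps.append(KernelSpec("categorical", ("id",)))
        if "age" in self.covariates:
            comps.append(
                KernelSpec("product", ("age", "id"), lengthscale=12.0))
        return AdditiveModelSpec(components=tuple(comps), noise_variance=0.5)


def enumerate_models() -> list[CandidateModel]:
    """All 16 candidate covariate subsets in canonical binary order.

    Bit ``i`` of the subset index toggles ``OPTIONAL_COVARIATES[i]``, so
    the first candidate is the null (id + noise only) model and the last
    contains all four optional covariates.
    """
    out = []
    for bits in range(2 ** len(OPTIONAL_COVARIATES)):
        subset = frozenset(
            c for i, c in enumerate(OPTIONAL_COVARIATES) if bits >> i & 1)
        out.append(CandidateModel(subset))
    return out


def loocv_mlpd(fit: GPFit) -> float:
    """Mean log predictive density under exact leave-one-out CV.

    Uses the closed-form identities for Gaussian models at fixed
    hyperparameters: with ``K`` the training covariance (noise
    included), ``mu_i = y_i - [K^-1 y]_i / [K^-1]_ii`` and
    ``s2_i = 1 / [K^-1]_ii`` give the held-out predictive distribution
    of observation ``i`` given all others. Reported on the standardized
    response scale.
    """
    n = fit.n
    Kinv = fit.solve(np.eye(n))
    diag = np.diag(Kinv)
    alpha = Kinv @ fit.y
    s2 = 1.0 / diag
    resid = alpha / diag  # y_i - mu_i
    lpd = -0.5 * (np.log(s2) + resid**2 / s2 + _LOG2PI)
    return float(np.mean(lpd))


def _subject_folds(X: pd.DataFrame, stratify_by: str | None,
                   max_loso_subjects: int = 20, n_folds: int = 10,
                   seed: int = 0) -> list[np.ndarray]:
    """Folds of row indices holding out whole subjects.

    Leave-one-subject-out when the cohort is small (deterministic);
    for larger cohorts, stratified k-fold over subjects balancing the
    levels of ``stratify_by`` across folds (seeded).
    """
    subjects = pd.unique(X["id"])
    if len(subjects) <= max_loso_subjects:
        return [np.flatnonzero(X["id"].to_numpy() == s) for s in subjects]
    rng = np.random.default_rng(seed)
    level_of = {s: X.loc[X["id"] == s, stratify_by].iloc[0]
                for s in subjects} if stratify_by else {s: 0 for s in subjects}
    folds: list[list] = [[] for _ in range(n_folds)]
    for level in sorted(set(level_of.values()), key=str):
        members = [s for s in subjects if level_of[s] == level]
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            folds[j % n_folds].append(members[idx])
    return [
        np.flatnonzero(X["id"].isin(f).to_numpy()) for f in folds if f
    ]


def stratified_cv_mlpd(fit: GPFit, stratify_by: str | None = None,
                       seed: int = 0) -> float:
    """Mean log predictive density under subject-level cross-validation.

    Whole subjects are held out; their observations are predicted from
    the remaining subjects using the fitted hyperparameters. The id and
    age-by-id components have zero cross-covariance with unseen
    subjects, so they contribute prior variance to the prediction, and
    subject-constant effects (gender, location) are predicted through
    the shared categorical components. Pointwise predictive densities
    include the noise variance.
    """
    X, y = fit.X, fit.y
    K = fit.train_cov()  # noise included
    diag_full = np.diag(K)
    folds = _subject_folds(X, stratify_by, seed=seed)
    if any(len(f) == len(X) for f in folds):
        raise ValueError("a fold holds out every observation")
    lpds: list[np.ndarray] = []
    for test in folds:
        train = np.setdiff1d(np.arange(len(X)), test)
        Ktt = K[np.ix_(train, train)]
        # cross-covariance excludes noise (never shared across samples)
        Kst = K[np.ix_(test, train)]
        L = sla.cholesky(Ktt, lower=True)
        a = sla.cho_solve((L, True), y[train])
        mean = Kst @ a
        V = sla.cho_solve((L, True), Kst.T)
        var = diag_full[test] - np.sum(Kst * V.T, axis=1)
        var = np.maximum(var, 1e-12)
        r = y[test] - mean
        lpds.append(-0.5 * (np.log(var) + r**2 / var + _LOG2PI))
    return float(np.mean(np.concatenate(lpds)))


@dataclass(frozen=True)
class SelectionThresholds:
    """Empirical significance criteria for covariate effects.

    ``delta``: minimum MLPD gain (nats) of the best model containing a
    covariate over the best model lacking it. ``rho``: minimum variance
    share of the covariate's component in that best containing model.
    ``n_restarts``: optimizer restarts per candidate fit. ``min_obs``:
    minimum non-missing observations per protein.
    """

    delta: float = 0.05
    rho: float = 0.01
    n_restarts: int = 2
    min_obs: int = 8


@dataclass
class SelectionResult:
    """Per-protein outcome of the 16-model comparison."""

    scores: pd.DataFrame            # one row per candidate: name, loocv, scv
    best_model: frozenset           # covariate set of the best candidate
    best_fit: GPFit
    best_shares: dict[str, float]   # variance shares of the best model
    delta_mlpd: dict[str, float]    # per optional covariate
    covariate_shares: dict[str, float]
    significant: dict[str, bool]
    thresholds: SelectionThresholds
    seed: int

    @property
    def flagged(self) -> frozenset:
        return frozenset(c for c, f in self.significant.items() if f)


def _component_share(fit: GPFit, covariate: str) -> float:
    """Variance share of the covariate's main component in a fitted model."""
    dec = decompose(fit)
    return dec.variance_shares.get(covariate, 0.0)


def select_effects(X: pd.DataFrame, y: np.ndarray,
                   thresholds: SelectionThresholds = SelectionThresholds(),
                   seed: int = 0) -> SelectionResult:
    """Fit and compare all 16 candidate models for one protein.

    ``X`` carries the covariate columns (age, season, gender, location,
    id) and ``y`` the log2 response with NaN for missing values, which
    are dropped. Requires ``thresholds.min_obs`` observations spanning
    at least two subjects. Deterministic given ``(X, y, seed)``.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    Xo = X.iloc[np.flatnonzero(keep)].reset_index(drop=True)
    yo = y[keep]
    if len(yo) < thresholds.min_obs:
        raise InsufficientDataError(
            f"{len(yo)} observations < min_obs={thresholds.min_obs}")
    if Xo["id"].nunique() < 2:
        raise InsufficientDataError("observations span < 2 subjects")

    candidates = enumerate_models()
    seeds = np.random.SeedSequence(seed).generate_state(len(candidates))
    fits: list[GPFit] = []
    rows = []
    for cand, s in zip(candidates, seeds):
        fit = fit_hyperparameters(
            cand.spec(), Xo, yo, n_restarts=thresholds.n_restarts,
            seed=int(s % 2**31))
        loo = loocv_mlpd(fit)
        scv = stratified_cv_mlpd(fit, seed=int(s % 2**31))
        fits.append(fit)
        rows.append({
            "model": cand.name, "n_covariates": len(cand.covariates),
            "loocv_mlpd": loo, "scv_mlpd": scv,
            "log_marginal_likelihood": fit.log_marginal_likelihood,
        })
    scores = pd.DataFrame(rows)

    loo = scores["loocv_mlpd"].to_numpy()
    scv = scores["scv_mlpd"].to_numpy()

    # best overall model by LOOCV; ties broken toward parsimony, then
    # canonical order
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-round(loo[i], 9), len(candidates[i].covariates), i))
    best_i = order[0]
    best_fit = fits[best_i]
    best_dec = decompose(best_fit)
    best_shares = dict(best_dec.variance_shares)
    best_shares["noise"] = best_dec.noise_share

    delta_mlpd: dict[str, float] = {}
    covariate_shares: dict[str, float] = {}
    significant: dict[str, bool] = {}
    for cov in OPTIONAL_COVARIATES:
        score = loo if cov in LOOCV_COVARIATES else scv
        with_c = [i for i, c in enumerate(candidates)
                  if cov in c.covariates]
        without_c = [i for i, c in enumerate(candidates)
                     if cov not in c.covariates]
        best_with = max(with_c, key=lambda i: score[i])
        d = float(score[best_with] - max(score[i] for i in without_c))
        share = _component_share(fits[best_with], cov)
        delta_mlpd[cov] = d
        covariate_shares[cov] = share
        significant[cov] = (d >= thresholds.delta) and (share >= thresholds.rho)

    return SelectionResult(
        scores=scores, best_model=candidates[best_i].covariates,
        best_fit=best_fit, best_shares=best_shares, delta_mlpd=delta_mlpd,
        covariate_shares=covariate_shares, significant=significant,
        thresholds=thresholds, seed=seed,
    )
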