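"""Covariance functions for additive Gaussian-process models.

The longitudinal design is described by five covariates per sample:

``age``
    age of the child at sampling, in months (continuous);
``season``
    phase of the calendar year at sampling, in months within ``[0, 12)``
    (continuous, periodic);
``gender``, ``location``, ``id``
    subject-constant factors (girl/boy, birth city, subject identity).

Each kernel ties a covariance component to one covariate (or to an
interaction of covariates) so that a sum of kernels yields an additive
model whose posterior decomposes into per-covariate contribution
functions.

Kernel menu
-----------
- ``se_age``: squared-exponential on age,
  ``k(x, x') = v * exp(-(age - age')^2 / (2 * ell^2))``;
- ``categorical``: block-constant on a factor,
  ``k(x, x') = v * 1[level == level']`` (gender, location, id);
- ``periodic_season``: the exp-sine-squared kernel on month-of-year with
  the period fixed at 12 months,
  ``k(x, x') = v * exp(-2 * sin^2(pi * (t - t') / 12) / ell^2)``;
- ``product``: elementwise product of an ``se_age`` factor and a
  categorical factor with a single signal variance — used for the
  age-by-subject interaction (per-subject smooth deviations);
- ``noise``: ``v * I``, contributing only on identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATES",
    "KernelSpec",
    "AdditiveModelSpec",
    "build_kernel",
    "model_covariance",
]

#: canonical covariate order used throughout the package
COVARIATES = ("age", "season", "gender", "location", "id")

_KINDS = ("se_age", "categorical", "periodic_season", "product", "noise")

# bounds used by the fitter, on the standardized-response scale
VARIANCE_BOUNDS = (1e-6, 10.0)
LENGTHSCALE_BOUNDS = (0.5, 100.0)


@dataclass(frozen=True)
class KernelSpec:
    """One additive covariance component.

    Parameters
    ----------
    kind
        One of ``se_age``, ``categorical``, ``periodic_season``,
        ``product``, ``noise``.
    covariates
        Covariate names the component depends on. A ``product`` kernel
        must reference at least two distinct covariates; every other
        kind except ``noise`` references at least one.
    variance
        Signal variance ``v >= 0``.
    lengthscale
        Lengthscale ``ell > 0`` in months (``se_age``, ``product``) or
        on the unit-free periodic scale (``periodic_season``); ``None``
        for purely categorical and noise kernels.
    period
        Period of the seasonal kernel, fixed at 12 months.
    """

    kind: str
    covariates: tuple[str, ...] = ()
    variance: float = 1.0
    lengthscale: float | None = None
    period: float = 12.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        for c in self.covariates:
            if c not in COVARIATES:
                raise ValueError(f"unknown covariate {c!r}")
        if self.kind == "noise":
            if self.covariates:
                raise ValueError("noise kernel references no covariates")
        elif not self.covariates:
            raise ValueError(f"{self.kind} kernel must name >=1 covariate")
        if self.kind == "product" and len(set(self.covariates)) < 2:
            raise ValueError("product kernel needs >=2 distinct covariates")
        if not np.isfinite(self.variance) or self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")
        if self.kind in ("se_age", "periodic_season", "product"):
            if self.lengthscale is None or self.lengthscale <= 0:
                raise ValueError(
                    f"{self.kind} kernel requires lengthscale > 0, "
                    f"got {self.lengthscale}"
                )

    @property
    def label(self) -> str:
        """Human-readable component name, e.g. ``age`` or ``age_x_id``."""
        if self.kind == "noise":
            return "noise"
        return "_x_".join(self.covariates)

    @property
    def n_params(self) -> int:
        """Number of free hyperparameters (variance, optionally lengthscale)."""
        return 2 if self.kind in ("se_age", "periodic_season", "product") else 1

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "covariates": list(self.covariates),
             "variance": float(self.variance)}
        if self.lengthscale is not None:
            d["lengthscale"] = float(self.lengthscale)
        if self.kind == "periodic_season":
            d["period"] = float(self.period)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "KernelSpec":
        return cls(
            kind=d["kind"],
            covariates=tuple(d.get("covariates", ())),
            variance=float(d.get("variance", 1.0)),
            lengthscale=d.get("lengthscale"),
            period=float(d.get("period", 12.0)),
        )


@dataclass(frozen=True)
class AdditiveModelSpec:
    """An additive GP model: a sum of signal components plus white noise.

    ``components`` excludes the noise term, which is carried by
    ``noise_variance``. An empty component tuple is permitted and
    denotes a pure-noise model.
    """

    components: tuple[KernelSpec, ...] = ()
    noise_variance: float = 1.0

    def __post_init__(self) -> None:
        for comp in self.components:
            if comp.kind == "noise":
                raise ValueError(
                    "noise is carried by noise_variance, not a component"
                )
        if not np.isfinite(self.noise_variance) or self.noise_variance <= 0:
            raise ValueError(
                f"noise variance must be > 0, got {self.noise_variance}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.components)

    def with_params(self, components: Sequence[KernelSpec],
                    noise_variance: float) -> "AdditiveModelSpec":
        return replace(self, components=tuple(components),
                       noise_variance=float(noise_variance))

    def to_dict(self) -> dict:
        return {
            "components": [c.to_dict() for c in self.components],
            "noise_variance": float(self.noise_variance),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AdditiveModelSpec":
        return cls(
            components=tuple(KernelSpec.from_dict(c)
                             for c in d.get("components", [])),
            noise_variance=float(d.get("noise_variance", 1.0)),
        )


def _column(X: pd.DataFrame, name: str) -> np.ndarray:
    if name not in X.columns:
        raise KeyError(f"covariate column {name!r} missing from design")
    col = X[name]
    if name in ("age", "season"):
        return col.to_numpy(dtype=float)
    # factors are compared by code; strings and ints both work
    return col.to_numpy()


def _match_matrix(X1: pd.DataFrame, X2: pd.DataFrame,
                  covariates: Sequence[str]) -> np.ndarray:
    m = np.ones((len(X1), len(X2)), dtype=float)
    for c in covariates:
        a, b = _column(X1, c), _column(X2, c)
        m *= (a[:, None] == b[None, :]).astype(float)
    return m


def _se_matrix(X1: pd.DataFrame, X2: pd.DataFrame, lengthscale: float
               ) -> np.ndarray:
    a, b = _column(X1, "age"), _column(X2, "age")
    d2 = (a[:, None] - b[None, :]) ** 2
    return np.exp(-d2 / (2.0 * lengthscale**2))


def _periodic_matrix(X1: pd.DataFrame, X2: pd.DataFrame,
                     lengthscale: float, period: float) -> np.ndarray:
    a, b = _column(X1, "season"), _column(X2, "season")
    s2 = np.sin(np.pi * (a[:, None] - b[None, :]) / period) ** 2
    return np.exp(-2.0 * s2 / lengthscale**2)


def build_kernel(spec: KernelSpec, X1: pd.DataFrame,
                 X2: pd.DataFrame | None = None) -> np.ndarray:
    """Evaluate one covariance component between two design matrices.

    Passing ``X2=None`` evaluates the component on ``(X1, X1)``; this is
    the only case in which a ``noise`` kernel contributes (off the
    training inputs white noise has zero cross-covariance).
    """
    same = X2 is None
    if X2 is None:
        X2 = X1
    if spec.kind == "noise":
        if same:
            return spec.variance * np.eye(len(X1))
        return np.zeros((len(X1), len(X2)))
    if spec.kind == "se_age":
        return spec.variance * _se_matrix(X1, X2, spec.lengthscale)
    if spec.kind == "periodic_season":
        return spec.variance * _periodic_matrix(
            X1, X2, spec.lengthscale, spec.period)
    if spec.kind == "categorical":
        return spec.variance * _match_matrix(X1, X2, spec.covariates)
    if spec.kind == "product":
        cont = [c for c in spec.covariates if c in ("age", "season")]
        cats = [c for c in spec.covariates if c not in ("age", "season")]
        k = np.ones((len(X1), len(X2)))
        for c in cont:
            if c == "age":
                k *= _se_matrix(X1, X2, spec.lengthscale)
            else:
                k *= _periodic_matrix(X1, X2, spec.lengthscale, spec.period)
        if cats:
            k *= _match_matrix(X1, X2, cats)
        return spec.variance * k
    raise AssertionError(f"unreachable kind {spec.kind}")


def model_covariance(spec: AdditiveModelSpec, X1: pd.DataFrame,
                     X2: pd.DataFrame | None = None,
                     include_noise: bool = True) -> np.ndarray:
    """Sum of all component covariances, optionally plus the noise term.

    Noise enters only for ``X2=None`` (the training-covariance case).
    """
    n2 = len(X1) if X2 is None else len(X2)
    K = np.zeros((len(X1), n2))
    for comp in spec.components:
        K += build_kernel(comp, X1, X2)
    if include_noise and X2 is None:
        K += spec.noise_variance * np.eye(len(X1))
    return K
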