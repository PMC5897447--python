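"""Synthetic longitudinal serum-proteome data with known ground truth.

Emulates the cohort design behind the modelling pipeline: roughly 15
children from two birth cities (11/4 split), each sampled at nominal
ages of 3, 6, 12, 18, 24 and 36 months (slightly jittered), optionally
with a cord-blood sample at birth, processed in batches of one to two
subjects, and with a configurable fraction of missing values.

Protein observations are generated from the same additive structure
the fitter assumes: a smooth age trend drawn from a squared-exponential
GP, a periodic seasonal draw, subject-constant gender/location/identity
offsets, per-subject smooth age deviations (the age-by-id interaction)
and white noise. Every drawn component is stored, so the simulated
observation equals baseline + sum of components + noise exactly and
power / type-I studies can score detections against the truth.

Cord samples are simulated with an independent per-(protein, subject)
offset rather than by extrapolating the age trend to zero, reflecting
that cord serum is compositionally distinct from follow-up serum and is
processed as a separate batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .kernels import KernelSpec, build_kernel

__all__ = [
    "StudyDesign",
    "EffectConfig",
    "SyntheticTruth",
    "simulate_design",
    "simulate_protein",
    "simulate_dataset",
]

#: component names in generation order
COMPONENTS = ("age", "season", "gender", "location", "id", "age_x_id")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout for the synthetic generator.

    Defaults mirror the study design the pipeline targets: 15 subjects
    split 11/4 across two locations, six nominal follow-up ages with a
    0.3-month sampling jitter, a cord sample per subject, batches of up
    to two subjects and 10% missing values.
    """

    n_subjects: int = 15
    n_location_a: int = 11
    locations: tuple[str, str] = ("Espoo", "Tartu")
    nominal_ages: tuple[float, ...] = (3.0, 6.0, 12.0, 18.0, 24.0, 36.0)
    age_jitter_sd: float = 0.3
    missing_prob: float = 0.1
    include_cord: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_location_a <= self.n_subjects):
            raise ValueError("location split exceeds subject count")
        if not (0 <= self.missing_prob < 1):
            raise ValueError("missing_prob must lie in [0, 1)")
        if self.age_jitter_sd < 0:
            raise ValueError("age_jitter_sd must be >= 0")


@dataclass(frozen=True)
class EffectConfig:
    """Variances (on the log2 scale) of the additive generative components.

    A variance of 0 switches a component off. ``age_lengthscale`` and
    ``season_lengthscale`` control the smoothness of the corresponding
    GP draws; ``cord_offset_sd`` is the sd of the independent cord-blood
    offset used when the design includes cord samples.
    """

    age: float = 0.0
    season: float = 0.0
    gender: float = 0.0
    location: float = 0.0
    id: float = 0.0
    age_x_id: float = 0.0
    noise: float = 1.0
    age_lengthscale: float = 12.0
    season_lengthscale: float = 1.0
    cord_offset_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"variance {name} must be >= 0")
        if self.noise < 0:
            raise ValueError("noise variance must be >= 0")
        if self.age_lengthscale <= 0 or self.season_lengthscale <= 0:
            raise ValueError("lengthscales must be > 0")

    @property
    def active(self) -> frozenset:
        return frozenset(c for c in COMPONENTS if getattr(self, c) > 0)


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated protein.

    ``components`` maps each component name to its drawn values at the
    sampled inputs; ``noise`` is the drawn observation noise and
    ``baseline`` the protein's constant log2 abundance level. The
    observation equals ``baseline + sum(components) + noise`` exactly.
    ``active`` lists the covariates with non-zero generative variance.
    """

    components: dict[str, np.ndarray]
    noise: np.ndarray
    baseline: float
    active: frozenset
    cord_offsets: np.ndarray | None = None


def simulate_design(design: StudyDesign) -> pd.DataFrame:
    """Draw a sample annotation table for the given design.

    One row per (subject, nominal age), plus one cord row per subject
    when ``include_cord``. Ages are jittered with the configured sd
    (cord ages stay 0); each subject receives a gender, a location
    (first ``n_location_a`` subjects to the first location), a birth
    month uniform on the calendar year — so the seasonal phase of a
    sample is ``(birth month + age) mod 12`` — and a batch of at most
    two subjects. Deterministic given the design seed.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for i in range(design.n_subjects):
        subject = f"C{i + 1:02d}"
        gender = "girl" if rng.random() < 0.5 else "boy"
        location = (design.locations[0] if i < design.n_location_a
                    else design.locations[1])
        birth_month = float(rng.uniform(0.0, 12.0))
        batch = f"B{i // 2 + 1:02d}"
        if design.include_cord:
            rows.append({
                "sample_id": f"{subject}_cord", "subject_id": subject,
                "age_months": 0.0, "gender": gender, "location": location,
                "season": birth_month % 12.0, "batch": batch,
                "is_cord": True,
            })
        for age in design.nominal_ages:
            jitter = rng.normal(0.0, design.age_jitter_sd) \
                if design.age_jitter_sd > 0 else 0.0
            a = max(age + jitter, 0.25)
            rows.append({
                "sample_id": f"{subject}_{age:g}m", "subject_id": subject,
                "age_months": a, "gender": gender, "location": location,
                "season": (birth_month + a) % 12.0, "batch": batch,
                "is_cord": False,
            })
    ann = pd.DataFrame(rows).set_index("sample_id")
    return ann


def design_matrix(annotation: pd.DataFrame) -> pd.DataFrame:
    """Covariate frame with the kernel column naming (age, season, ... id)."""
    return pd.DataFrame({
        "age": annotation["age_months"].to_numpy(float),
        "season": annotation["season"].to_numpy(float),
        "gender": annotation["gender"].to_numpy(),
        "location": annotation["location"].to_numpy(),
        "id": annotation["subject_id"].to_numpy(),
    }, index=annotation.index)


def _draw_gp(rng: np.random.Generator, K: np.ndarray) -> np.ndarray:
    """Sample from N(0, K) via jittered Cholesky."""
    n = len(K)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    return L @ rng.standard_normal(n)


def _realize_scale(values: np.ndarray, variance: float) -> np.ndarray:
    """Centre a drawn component and set its realized design variance.

    Component variances parameterize the *realized* spread of the
    effect across the sampled design: a smooth GP draw carries a large
    constant part that is indistinguishable from a baseline shift and
    therefore contributes nothing detectable, so each systematic draw
    is centred and rescaled to an empirical standard deviation of
    ``sqrt(variance)``. Noise is never rescaled.
    """
    centred = values - values.mean()
    sd = centred.std()
    if sd < 1e-12:
        return np.zeros_like(values)
    return centred * (math.sqrt(variance) / sd)


def simulate_protein(annotation: pd.DataFrame, effects: EffectConfig,
                     seed: int = 0) -> tuple[pd.Series, SyntheticTruth]:
    """Simulate one protein's observations on the follow-up samples.

    Each active component is drawn from its prior on the follow-up
    rows — the age trend and per-subject age deviations from SE-kernel
    GPs, the seasonal term from the periodic kernel, and the factor
    components as level offsets with the configured variance. Cord rows
    (if present in the annotation) receive baseline + subject id offset
    + an independent cord offset + noise instead of the follow-up
    components. Returns the observation series (indexed like the
    annotation) and the stored truth for the follow-up rows.
    """
    rng = np.random.default_rng(seed)
    is_cord = annotation.get(
        "is_cord", pd.Series(False, index=annotation.index)).astype(bool)
    fu = annotation.loc[~is_cord]
    X = design_matrix(fu)
    n = len(X)

    components: dict[str, np.ndarray] = {}

    def _factor_offsets(column: str, variance: float) -> np.ndarray:
        levels = pd.unique(X[column])
        offs = {lv: rng.normal(0.0, math.sqrt(variance)) for lv in levels}
        return _realize_scale(np.array([offs[v] for v in X[column]]),
                              variance)

    if effects.age > 0:
        K = build_kernel(KernelSpec("se_age", ("age",), 1.0,
                                    effects.age_lengthscale), X)
        components["age"] = _realize_scale(_draw_gp(rng, K), effects.age)
    if effects.season > 0:
        K = build_kernel(KernelSpec("periodic_season", ("season",), 1.0,
                                    effects.season_lengthscale), X)
        components["season"] = _realize_scale(_draw_gp(rng, K),
                                              effects.season)
    if effects.gender > 0:
        components["gender"] = _factor_offsets("gender", effects.gender)
    if effects.location > 0:
        components["location"] = _factor_offsets("location", effects.location)
    if effects.id > 0:
        components["id"] = _factor_offsets("id", effects.id)
    if effects.age_x_id > 0:
        K = build_kernel(KernelSpec("product", ("age", "id"), 1.0,
                                    effects.age_lengthscale), X)
        components["age_x_id"] = _realize_scale(_draw_gp(rng, K),
                                                effects.age_x_id)

    noise = (rng.normal(0.0, math.sqrt(effects.noise), size=n)
             if effects.noise > 0 else np.zeros(n))
    baseline = 0.0
    signal = sum(components.values(), np.zeros(n))
    y_fu = baseline + signal + noise

    obs = pd.Series(np.nan, index=annotation.index, dtype=float)
    obs[fu.index] = y_fu

    cord_offsets = None
    if is_cord.any():
        cord = annotation.loc[is_cord]
        # share the subject offsets with the follow-up draw where present
        id_off = {s: 0.0 for s in cord["subject_id"]}
        if "id" in components:
            per_subject = pd.Series(components["id"],
                                    index=fu["subject_id"].to_numpy())
            for s in id_off:
                vals = per_subject.get(s)
                if vals is not None:
                    id_off[s] = float(np.atleast_1d(vals)[0])
        cord_offsets = rng.normal(0.0, effects.cord_offset_sd, len(cord)) \
            if effects.cord_offset_sd > 0 else np.zeros(len(cord))
        cord_noise = (rng.normal(0.0, math.sqrt(effects.noise), len(cord))
                      if effects.noise > 0 else np.zeros(len(cord)))
        obs[cord.index] = (baseline
                           + np.array([id_off[s]
                                       for s in cord["subject_id"]])
                           + cord_offsets + cord_noise)

    truth = SyntheticTruth(components=components, noise=noise,
                           baseline=baseline, active=effects.active,
                           cord_offsets=cord_offsets)
    return obs, truth


#: effect templates used by :func:`simulate_dataset` for each class label
def _class_effects(label: str, base: EffectConfig) -> EffectConfig:
    if label == "null":
        return replace(base, age=0, season=0, gender=0, location=0,
                       id=0, age_x_id=0)
    if label == "age":
        return replace(base, age=base.noise, season=0, gender=0, location=0,
                       id=0.25 * base.noise, age_x_id=0)
    if label == "location":
        return replace(base, age=0, season=0, gender=0,
                       location=base.noise, id=0.25 * base.noise, age_x_id=0)
    if label == "gender":
        return replace(base, age=0, season=0, gender=base.noise,
                       location=0, id=0.25 * base.noise, age_x_id=0)
    if label == "season":
        return replace(base, age=0, season=base.noise, gender=0,
                       location=0, id=0.25 * base.noise, age_x_id=0)
    if label == "id":
        return replace(base, age=0, season=0, gender=0, location=0,
                       id=2.0 * base.noise, age_x_id=0)
    raise ValueError(f"unknown effect class {label!r}")


def simulate_dataset(annotation: pd.DataFrame,
                     class_mix: dict[str, float],
                     n_proteins: int, seed: int = 0,
                     effects: EffectConfig = EffectConfig(),
                     missing_prob: float = 0.0,
                     baseline_range: tuple[float, float] = (15.0, 25.0)
                     ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a full proteins x samples expression matrix with truth labels.

    ``class_mix`` assigns fractions of proteins to effect classes
    (``null``, ``age``, ``season``, ``gender``, ``location``, ``id``)
    and must sum to 1; class effect sizes derive from the ``effects``
    template (active components get a variance equal to the noise
    variance, id-dominated proteins twice that). Each protein receives
    a constant baseline log2 abundance drawn uniformly from
    ``baseline_range``, and entries go missing independently with
    ``missing_prob``. Returns the expression matrix (annotation
    attached) and a truth table with each protein's class and active
    covariates.
    """
    fractions = np.array(list(class_mix.values()), float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {fractions.sum()}, not 1")
    labels = []
    for lab, frac in class_mix.items():
        labels += [lab] * int(round(frac * n_proteins))
    while len(labels) < n_proteins:
        labels.append(list(class_mix)[0])
    labels = labels[:n_proteins]

    root = np.random.SeedSequence(seed)
    mix_rng = np.random.default_rng(root.spawn(1)[0])
    protein_seeds = root.generate_state(n_proteins + 1)

    values = {}
    truth_rows = []
    for i, lab in enumerate(labels):
        pid = f"P{i + 1:04d}"
        eff = _class_effects(lab, effects)
        obs, truth = simulate_protein(annotation, eff,
                                      seed=int(protein_seeds[i] % 2**31))
        baseline = float(mix_rng.uniform(*baseline_range))
        values[pid] = obs + baseline
        truth_rows.append({
            "protein_id": pid, "effect_class": lab,
            "active_covariates": "+".join(sorted(truth.active)) or "none",
        })
    matrix = pd.DataFrame(values).T
    matrix.index.name = "protein_id"

    if missing_prob > 0:
        miss_rng = np.random.default_rng(
            int(protein_seeds[-1] % 2**31))
        mask = miss_rng.random(matrix.shape) < missing_prob
        matrix = matrix.mask(mask)

    truth = pd.DataFrame(truth_rows).set_index("protein_id")
    return ExpressionMatrix(values=matrix, annotation=annotation), truth
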