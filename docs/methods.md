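# Methods

## The modelling problem

Longitudinal serum proteomics of young children asks, per protein, which
covariates shape the expression trajectory: the child's age at sampling,
the season of the year, gender, living environment (birth city), and the
child's identity (which, in a design where each child's samples are
prepared in one batch, absorbs batch effects as well). Trajectories are
short (about six visits over three years), irregularly sampled, strongly
non-linear in age, and carry missing values that must never be imputed.

`serumgp` models each protein's log2 intensity vector `y` as a zero-mean
Gaussian process with additive covariance

```
K = K_age + K_season + K_gender + K_location + K_id + K_age×id + σ² I
```

so the posterior mean decomposes into per-covariate contribution
functions and the model's explained variation can be attributed to
individual components.

## Kernels and their parameters

| component | kernel | hyperparameters |
|---|---|---|
| age | squared-exponential on age (months) | signal variance `v`, lengthscale `ℓ` |
| season | exp-sine-squared on month-of-year, period fixed at 12 | `v`, `ℓ` |
| gender, location, id | block-constant (`v·1[same level]`) | `v` |
| age×id | SE(age) × 1[same subject] | `v`, `ℓ` |
| noise | `σ²·I` | `σ²` |

Responses are standardized per protein (mean 0, sd 1 over non-missing
values) before fitting; all variance bounds refer to that scale:
variances in `[1e-6, 10]`, lengthscales in `[0.5, 100]` months. The
period of the seasonal kernel is not optimized — a year is a year.
Hyperparameters are set by type-II maximum likelihood with L-BFGS-B on
log-parameters with analytic gradients, from one deterministic start
(equal variance split, `ℓ = 12` months for age, `ℓ = 1` for season)
plus random restarts drawn uniformly in the log-bounds (default 5 for a
standalone fit, 2 inside the 16-model selection loop where each protein
requires 16 fits). Cholesky factorizations fall back on an escalating
diagonal jitter (1e-8 up to 1e-4) before raising a numerical error.

Missing observations are dropped, never imputed — exact GP inference
handles the resulting irregular designs natively.

## Candidate models and cross-validated selection

The four optional covariates {age, season, gender, location} generate
2⁴ = 16 candidate models. Every candidate carries the id component and
noise; whenever age is included, the age×id interaction (per-subject
smooth deviations from the shared trend) is included with it rather
than toggled independently — this preserves the count of 16 while
keeping the interaction available exactly when it is interpretable.

Candidates are compared by mean log predictive density (MLPD) of
held-out data at fixed full-data hyperparameters:

- **LOOCV** for the time-varying covariates (age, season), computed by
  the exact closed-form leave-one-out identities for Gaussian models
  (`μᵢ = yᵢ − [K⁻¹y]ᵢ/[K⁻¹]ᵢᵢ`, `σᵢ² = 1/[K⁻¹]ᵢᵢ`) rather than n
  refits; per-fold re-optimization would multiply the cost by n for a
  second-order effect.
- **Subject-level CV (SCV)** for the subject-constant covariates
  (gender, location): whole subjects are held out
  (leave-one-subject-out for cohorts of ≤ 20 subjects, stratified
  k-fold over subjects above that), so a gender or location component
  only scores well if it generalizes to unseen children. A held-out
  subject's id and age×id components contribute prior variance, not a
  learned offset.

A covariate is called significant when (a) the best model containing it
beats the best model lacking it by `δ ≥ 0.05` nats of MLPD under the
scheme matched to that covariate, and (b) its variance share in that
best containing model is at least `ρ = 0.01`. Both thresholds are
package defaults exposed in the config; the type-I simulation below
shows they hold the false-flag rate of pure-noise proteins near 5%.
The best model overall is the LOOCV-highest candidate with ties (at
1e-9 resolution) broken toward the smaller covariate set.

Variance shares are defined as the empirical variance of each
component's posterior mean at the training inputs, normalized together
with the fitted noise variance `σ̂²` so that component shares plus the
noise share sum to 1. This is a descriptive attribution, not an exact
ANOVA: components are not mutually orthogonal on a finite design, but
the definition is simple, always non-negative and sums to one.

## Synthetic cohorts

The generator reproduces the cohort layout the pipeline targets: 15
children split 11/4 across two cities, nominal visits at 3, 6, 12, 18,
24 and 36 months with 0.3-month jitter, an optional cord sample per
child, batches of at most two children, seasonal phase derived from a
uniformly drawn birth month, and 10% independently missing entries.

Protein observations are drawn from the additive structure the fitter
assumes (well-specified regime): SE draws for age and age×id, a
periodic draw for season, Gaussian level offsets for the factors, iid
Gaussian noise. Component variances parameterize the **realized**
spread of each systematic effect across the sampled design: a smooth GP
draw carries a large constant part that is indistinguishable from a
baseline shift and contributes nothing detectable, so each systematic
draw is centred and rescaled to the configured empirical variance
(noise is never rescaled). "Age-effect sd = noise sd" therefore means
exactly that, independent of the lengthscale of the particular draw.
Every drawn component is stored, so observation = baseline + Σ
components + noise holds bitwise and detections can be scored against
truth.

Cord samples are generated with an independent per-(protein, subject)
offset rather than by extrapolating the age trend to birth: cord serum
is compositionally distinct from follow-up serum and is processed as a
separate batch, which is also why all cord/follow-up comparisons are
rank-based.

What the generator does **not** emulate: intensity-dependent missing
values (ours are missing completely at random), heteroscedastic or
heavy-tailed measurement noise, correlated missingness within runs,
peptide-level effects, or depletion-column artifacts. Passing power and
type-I checks on these cohorts therefore validate the inference
machinery under the model's own assumptions, not robustness to every
failure mode of real LFQ data (a sigmoidal misspecification mode for
the age trend can be emulated by drawing with a short lengthscale, and
the filtering/rank stages are distribution-free).

## Quantification-table processing

Filtering follows standard Perseus-style practice, with all removal
rules strict (`<`), so boundary cases — 25% run coverage, 50% sample
coverage — are retained: drop reverse and modification-site-only
identifications, require ≥ 2 unique peptides and ≥ 25% run coverage,
collapse technical replicates to the median of non-zero intensities
(all-zero → missing) followed by log2, then require ≥ 50% sample
coverage. Both filters are idempotent and no step writes a value where
the input was missing.

Z-score trajectories use the sample standard deviation (n−1); a
constant trajectory yields missing Z-scores, not zeros. Age-group
averages assign samples to the nominal bins {cord, 3, 6, 12, 18, 24,
36} by nearest bin within ±1.5 months. Paired fold changes between
batch-mates are computed as `2^|Δlog2|` (direction-agnostic) per shared
age bin, summarized by medians. SRM tables are normalized by the summed
transition intensity of a stable reference protein (default A1BG) per
sample before log2.

## Rank-based cord comparisons

The paired rank product ranks within-pair differences of within-sample
intensity ranks across proteins (both directions), normalizes ranks by
the number of proteins quantified in the pair, and geometrically
averages over the pairs where the protein is present (proteins in fewer
than half the pairs are dropped). For complete data this reduces to the
plain geometric-mean-rank statistic scaled by 1/m, which leaves the
significance computation unchanged. The percentage of false prediction
(pfp) is estimated from B = 10,000 within-pair permutations of the
observed ranks (missingness pattern preserved), with monotonicity in
rank-product order enforced; tiny complete instances switch to
exhaustive enumeration of the null automatically. Spearman correlations
between cord and follow-up values across subjects (≥ 5 complete pairs)
are pooled over all (protein, timepoint) tests into one
Benjamini–Hochberg family, flagged at q < 0.1.

## Numerical and design choices

- Tie-break in model selection: parsimony (smaller covariate set) at
  equal LOOCV score.
- SCV predictive densities are pointwise (per held-out observation,
  marginal), including the noise variance.
- The heatmap clustering of average Z-score profiles uses Ward linkage
  on Euclidean distances cut at k = 6 clusters — an interpretive
  default, not a canonical number.
- Pipeline reports are written with fixed float formatting (`%.10g`)
  and sorted-key JSON so identical configurations reproduce
  byte-identical outputs; manifests deliberately contain no timestamps.
- Season enters as a continuous periodic term rather than a 4-level
  factor: it preserves the circular topology of the calendar and needs
  one lengthscale instead of three free level offsets.

## Problem sizes used in the validation suite

The automated checks run at the cohort's own scale: power and type-I
simulations use 15 subjects × 6 visits with 10% missingness (50
replicates for power, 100 for the null), the location studies use 8+8
subjects without missingness (50 replicates each), rank-product null
calibration uses 40 proteins × 5 pairs × 100 replicates at B = 1000,
and the oracle comparisons use 100 random instances of n ≤ 8. The
`scripts/acceptance.py` report recomputes the same quantities at these
sizes from a single command-line seed.

## Known limitations

- LOOCV with hyperparameters optimized on the full data is mildly
  optimistic; the ΔMLPD comparison between candidate models largely
  cancels the bias, and the type-I simulation bounds its residual
  effect. Per-fold re-optimization is available via
  `fit_hyperparameters` but not the default.
- Variance shares depend on the training design (e.g. unbalanced
  location splits shrink the apparent location share).
- The empirical selection thresholds (δ, ρ) are calibrated for cohorts
  of this size; much larger cohorts would support smaller δ.
- The rank-product permutation null assumes exchangeability of proteins
  within a pair; strong global shifts between sample types are absorbed
  by ranking but protein-protein correlation is not modelled.
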