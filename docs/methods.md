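# Methods

## Model and likelihood

`dosabund` estimates the abundance of animal groups from a double-observer
sightability survey with a telemetry-collared subset. Each group has three
detection occasions: a *radio observer* with probability fixed at 1 for
collared groups and 0 for uncollared groups, and two visual observers whose
detection follows a logistic-linear model. The radio occasion is not a
sighting event: it contributes no design row, and it never triggers the
recapture (behavioural-response) term — that term applies only to observer
2 after an observer-1 detection within the same pass. This convention is a
documented choice; software packages in this family differ on it, and every
report the package renders states the convention in force.

Uncollared groups missed by both observers are unobservable, so their
records never exist; the likelihood for uncollared groups conditions on
detection by at least one observer (Huggins conditional likelihood),
dividing each history probability by `p* = 1 − (1−p1)(1−p2)`. Collared
groups enter unconditionally: a collared group with history (0,0)
contributes `(1−p1)(1−p2)`, which is the mechanism by which missed collared
groups inform residual heterogeneity.

Residual heterogeneity — group-to-group variation in sightability beyond
the covariates — is absorbed by surrogate parameterizations rather than a
random effect: (1) an additive logit shift for collared groups ("type"),
(2) an additive logit shift for observer 2 after an observer-1 detection
("recapture"), or (3) both. In simultaneous double-observer data, positive
detection dependence induced by heterogeneity loads onto the recapture
term.

The link is the logit (the convention of the MARK software family; the
analysis is not sensitive to this choice for probabilities away from the
boundary). Covariates (`ln` group size, forest cover, percent concealment,
percent snow, movement) enter additively on the logit scale, shared across
observers; observer 1 is the pilot+frontseat pool (or first TIR operator),
fixed by column order. Percent covariates are stored as fractions in
[0, 1].

## Fitting and numerical choices

The negative log-likelihood and its analytic gradient are evaluated in
numerically stable form (`log_expit`; the conditioning term via
`log(−expm1(·))`). Optimization is quasi-Newton (BFGS) from 5 starts —
zeros plus 4 draws from N(0, 0.5²) seeded by the user's seed — with
gradient tolerance 1e−8. The coefficient covariance is the inverse of a
Hessian obtained by central finite differences of the analytic gradient
(step `1e−5·max(1,|β|)`); a singular or ill-conditioned Hessian marks the
covariance unavailable. A fit is flagged `boundary` when any fitted
detection probability lies within 1e−6 of 0 or 1; boundary and
non-converged models are excluded from ranking and model averaging by
default (`include_boundary` in `FitConfig`), with the exclusion and its
reason recorded on the `ModelSet`.

Identifiability is checked before fitting: the type effect needs both
collared and uncollared groups, the recapture effect needs at least one
observer-1 detection, and covariates need variation across groups.

**Effective sample size for AICc.** The convention is not settled across
software in this family, so it is a config field: `n_eff_rule = "groups"`
(default) counts groups contributing likelihood terms (all records of the
observed dataset, including collared groups missed by both observers);
`"detections"` counts detection events (observer sightings plus radio
detections). AICc requires `n_eff > K + 1`; datasets too small for a given
model raise an error rather than silently reporting AIC. Reports print the
rule used. Ties in AICc ranking break by smaller K, then label.

## Abundance

Horvitz–Thompson: `N̂ = Σ s_i / p*_i` with `p*` the inclusion probability
(exactly 1 for collared groups, `1 − (1−p1)(1−p2_init)` otherwise).
Variance has two parts: binomial inclusion variance
`Σ s_i²(1−p*_i)/p*_i²` (zero for collared groups) plus the delta-method
term `Gᵀ V G`, `G` the central-difference gradient of `N̂` in the
coefficients. Inclusion probabilities below 1e−6 abort with the offending
group named, since the corresponding term would dominate the estimate.

The confidence interval is lognormal on the unobserved component
`f0 = N̂ − M`, where `M = Σ s_i` is the minimum known count:
`C = exp(z√(ln(1 + (SE/f0)²)))`, limits `M + f0/C` and `M + f0·C`. This
guarantees LCL ≥ M; `f0 ≤ 0` or `SE = 0` collapse to the point estimate.
Model averaging uses `N̄ = Σ w_k N̂_k` and the unconditional standard
error `Σ w_k √(var_k + (N̂_k − N̄)²)`, with the interval re-derived on
`f0 = N̄ − M`.

**Group sizes.** `size_best` is the photo-confirmed size when available,
else the larger observer count, else an imputation (mean detected size,
flagged `size_imputed`). Collared groups undetected by both observers must
carry an externally known size (`size_source`, e.g. the other survey
platform or telemetry); the same `size_best` feeds both `ln_size` in the
detection model and the abundance sum, so each group has exactly one size.

## Synthetic surveys

The generator emulates the structure the estimator assumes: a closed
population of `n_groups` bison-like groups; skewed group sizes
(zero-truncated negative binomial, default mean 8, dispersion k = 0.8 —
rare groups of 25+ individuals, matching the long right tail seen in field
tallies; a zero-truncated Poisson is available); Bernoulli forest cover
(default prevalence 0.5) and the other sighting covariates; collars
assigned uniformly at random (default 10% of groups); logit-linear
detection with any subset of the model terms as generating coefficients;
and the observation filter that deletes uncollared double-misses.

Residual heterogeneity is generated as a **shared group-level normal random
effect on the logit** (`sigma_het`), deliberately *not* one of the
surrogate parameterizations the fitted models use — so heterogeneity-aware
models are misspecified in the realistic way, and the experiments measure
how well the surrogates compensate rather than trivially recovering their
own generating term. One seed drives independent sub-streams for sizes,
covariates, collars, detections and counting noise, so results are
reproducible and adding a covariate does not perturb detection draws.
Observer counting noise (`count_error_sd`, default 0) perturbs only the
per-observer counts; `size_best` stays the true size, mirroring
photo-confirmed sizes.

What the generator does **not** emulate: spatial structure (transects,
group placement, double-counting across transects), observer fatigue or
time-varying conditions, collar assignment correlated with group size
(a `size_biased_collaring` sensitivity hook is a possible extension), and
misidentification of collar status. Passing recovery experiments therefore
validate the estimator under its own assumptions, not the field protocol.

## Study conditions used in tests and the acceptance script

- **Parameter recovery (no heterogeneity):** 200 replicates of 200 groups,
  10% collared, both observers at p = 0.5 (logit intercepts 0), default
  size distribution. Model-averaged abundance is essentially unbiased
  (|relative bias| well under 5%), 95% lognormal intervals cover the true
  total at close to nominal rate, and the mean estimated variance matches
  the Monte-Carlo variance of `N̂ − N_true` within ±30%.
- **Heterogeneity behaviour:** identical except `sigma_het = 1.5`. This SD
  was chosen as the "strong heterogeneity" condition: a power calculation
  on a 50,000-group fit shows that at SD 0.75 the induced recapture signal
  (expected 2Δℓ ≈ 0.6 at 200 groups) sits below the one-parameter AICc
  penalty (≈ 2.05), so single-survey data of this size cannot usually
  detect it — consistent with heterogeneity models losing on the small
  Powell-only datasets while winning on the pooled one. At SD 1.5 the
  observer+recapture model out-ranks observer-only in ~70% of replicates,
  and ignoring heterogeneity biases abundance low by ~18% while
  heterogeneity-aware averaging is within ~1%.
- The brute-force oracle suite uses randomized datasets of 4–6 groups
  (small enough for exhaustive history enumeration and an iteratively
  refined dense grid search over the two intercepts, final step 1.6e−4 per
  coordinate).

## Worked-example fixtures

The Powell Plateau fixtures reconstruct the two 11 February 2020 surveys
from published group/individual tallies. Unprinted record-level facts are
assumptions, each attached to the dataset and printed in every report
generated from it: which groups carried collars (assigned arbitrarily among
detected groups), the collar status of the singleton missed by one
observer, and individual group sizes (largest-remainder apportionment of
the printed totals, deterministic and summing exactly). Fixture fits
demonstrate the pipeline; they are not verified reproductions of the
published estimates, which would require the underlying data release.

## Known limitations

- No individual-level (within-group) detection modeling; the group is the
  sampling unit.
- No spatial or distance-sampling components; detection is marginal per
  group.
- No bootstrap or profile-likelihood intervals (the lognormal-on-`f0`
  convention is the only interval implemented).
- Collar-detection matching uses fixed time/space thresholds (defaults
  2 h — a typical collar fix interval — and 1 km); these are conventions,
  and dense fixes near multiple detections can make greedy per-collar
  assignment suboptimal.
- AICc values depend on the `n_eff` convention; published tables fitted
  with other software may not be numerically reproducible even with
  identical data.
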