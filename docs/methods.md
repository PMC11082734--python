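# Methods

## The model

SDNN measured by a wrist wearable follows a 24-h circadian rhythm and is
sampled sparsely and nonuniformly.  We model each subject's stream with a
cosinor regression of fixed period τ = 24 h,

    Y(t) = M + A·cos(2πt/τ + φ) + e(t),

and use the exact linearization x = cos(2πt/τ), z = sin(2πt/τ), so that
Y = M + βx + γz + e with β = A·cos φ, γ = −A·sin φ.  The inverse map is
A = √(β² + γ²), φ = atan2(−γ, β).  Because the linearization is exact,
ordinary least squares on (1, x, z) *is* nonlinear least squares of the
cosine model; the test suite verifies this against an independent
`scipy.optimize.curve_fit` oracle to 1e-6 and checks the algebraic
round-trip to 1e-12.

Acrophase is stored in the branch (−2π, 0], in which the clock time of
the daily peak is −φ·τ/(2π) ∈ [0, 24).  A fitted amplitude below 1e-8 ms
is flagged *degenerate*: the phase of a flat rhythm is meaningless and is
reported as 0 with the flag set rather than as noise.

### Longitudinal structure

The study timeline is anchored at each subject's intervention start.
Analysis windows are half-open 7-day blocks of *calendar-day* offsets:
baseline = [−7, 0), week k = [7(k−1), 7k), k = 1..7.  Calendar-day
differencing (rather than 24-h bins from a clock instant) is used because
wear days and biofeedback sessions are calendar-day phenomena.  A sample
at the intervention start instant belongs to week 1; nothing is ever in
two windows.

One joint linear mixed model is fitted across all windows:

* fixed effects — window factor (baseline reference) interacted with
  (1, x, z), so each window has its own (M, β, γ); week-k parameters are
  baseline coefficients plus the interaction contrasts;
* covariates — age and BMI (mean-centered at subject level) and sex
  (male indicator, centered) act on the intercept only, so the intercept
  is the adjusted MESOR for an average subject; covariate columns with no
  variation (single subject, single-sex stratum) are dropped;
* random effects — per-subject θ_i ~ MVN(0, Σ) on (intercept, x, z) with
  unstructured Σ, estimated by REML.

Fitting one joint model rather than eight separate ones shares the
variance components across windows, which is what makes each week
comparable to baseline on a common scale.

### Estimation engines

`FitOptions.re_structure` selects:

* `"intercept_xz"` (default) — full random (intercept, x, z) via
  statsmodels `MixedLM` (REML, max 200 iterations).  On non-convergence
  the fit falls back to a random intercept and records it in the fit
  metadata (`fallback_used`).
* `"intercept"` — random intercept only, via an in-package profiled-REML
  solver (`circhrv.lmm`).  For fixed variance ratio λ = τ²/σ² the GLS
  estimate and the restricted likelihood have closed forms in per-subject
  cross-products, reducing the fit to a one-dimensional optimization over
  log λ (coarse grid + Brent).  The solver is cross-validated against
  `MixedLM` in the test suite (coefficients to 1e-4).
* `"none"` — pooled least squares (used e.g. to reduce a single-subject
  fit to per-window OLS, which the tests verify exactly).

The fast engine exists because the bootstrap and the Monte-Carlo
calibration below need tens of thousands of refits: per-subject
sufficient statistics (n_i, X_i'X_i, X_i'y_i, column sums, y_i'y_i) fully
determine the random-intercept fit, and a subject-level resample is just
a re-summation of a multiset of precomputed statistics, so a
1000-replicate bootstrap costs about a second.  With subject-varying
amplitude and phase the random-intercept model is a *working* model; its
fixed effects remain unbiased (random effects are mean zero and
independent of sampling times), and the cluster bootstrap captures the
full between-subject variability nonparametrically.

## Bootstrap inference

Subjects are resampled with replacement (duplicates treated as
independent clusters — the resampling unit matches the correlation unit
the mixed model exists for), the model is refitted on the original
design with covariate centering frozen at the original cohort's means
(fixing the estimand), and per-window (M, A, φ) and window-minus-baseline
differences are collected.  Intervals are percentile; acrophase
differences are wrapped to (−π, π] so rhythms near the phase branch cut
cannot produce spurious 2π jumps.  The two-sided bootstrap p-value uses
the +1 continuity correction

    p = 2·min(#(d* ≤ 0) + 1, #(d* ≥ 0) + 1) / (B + 1),

floored at 2/(B+1), which agrees with whether the percentile interval
excludes zero up to the discrete bootstrap grid (tested).  Replicates
whose refit fails are dropped and counted; losing more than 10% raises a
warning flag on the result.  Default B = 1000 for reported CIs; the
repeated-simulation studies use B = 200.

No multiplicity adjustment is applied to the per-window p-values; the
two-sided 0.05 level is a reporting convention, never used to filter
rows.

## Compliance

The prescribed dose is one 5-minute biofeedback session per day for 5
weeks (35 sessions).  Compliance is the number of *distinct* session
dates inside the 35-day window divided by 35 — multiple sessions on one
day count once, and the denominator stays 35 regardless of dropout.
Strata: >0% means at least one session (strict), ≥20% and ≥50% are
inclusive thresholds, so the strata are nested by construction.  Stratum
percentages are taken of the full consented N (supplied explicitly,
since consented subjects without logs belong in the denominator) and
rounded half-up to one decimal.  Strata are analysed independently — the
model is refitted per stratum with no sharing of variance components —
matching how nested subgroup tables are usually presented.

## Survey instruments

Raw-sum scoring with reverse-scored items flipped as v → max + min − v
(an involution):

| instrument | items | item range | reversed | total | higher = |
|---|---|---|---|---|---|
| CD-RISC 10 | 10 | 0–4 | — | 0–40 | more resilient |
| PROMIS emotional support | 2 | 1–5 | — | 2–10 | more support |
| PSS-10 | 10 | 0–4 | 4, 5, 7, 8 | 0–40 | more stress |
| 2-item Global Health | 2 | 1–5 | — | 2–10 | better health |
| PHQ-4 | 4 | 0–3 | — | 0–12 | more impairment |
| PROMIS positive affect | 23 | 1–5 | — | 23–115 | more positive |

PSS-10 reversal indices follow the published instrument (the positively
worded items).  Global Health is scored so that higher totals mean
better health and quality of life.  Longitudinal change per instrument
and stratum is a linear mixed model (score ~ timepoint factor, random
subject intercept) at the four timepoints baseline / week 5 / week 7 /
week 17; missing questionnaires are handled by the likelihood, not
imputed.  Strata too small to support the model (fewer than two subjects
with follow-up) get a not-estimable marker (NaN) instead of a number; a
stratum with zero score variance gets contrast 0, p = 1 directly, since
the likelihood is degenerate there.

## The synthetic cohort generator

`generate_cohort` draws, per subject: demographics (age ~ N(37.3, 10.6²)
years clipped to [18, 80], 73.8% female, BMI ~ N(25.3, 5.5²) kg/m²
clipped to [15, 60]); circadian parameters as population means plus
independent Normal random effects (amplitude floored at 0, acrophase
wrapped); a compliance stratum from a mixture, then Bernoulli per-day
session completion at the stratum's rate.  Per day, the sample count is
negative binomial with mean 4.7 and size r = 2.926 (variance
μ + μ²/r, i.e. daily-count SD 3.5; a Poisson option exists); sample
clock times are a 50/50 mixture of Uniform(0 h, 6 h) — the device's
nighttime bias — and Uniform(0 h, 24 h).  Each value is the subject's
cosinor mean, plus the intervention shift on days in weeks 1–5 with a
completed session, plus N(0, 18²) ms residual noise, clipped to the
device range [10, 200] ms (truncation, mimicking device-side bounds,
rather than resampling).  Defaults: population M = 38 ms (so the value
median sits near 38 ms), A = 4.3 ms, φ = −2.93 rad; between-subject SDs
(15 ms, 2 ms, 0.5 rad); compliance mixture with per-day session
probabilities (0, 0.09, 0.33, 0.75) in fractions (55, 23, 28, 21)/127,
placing the realized strata at roughly 56.7% / 38.6% / 16.5% of a
consented cohort in expectation.

The generator records its truth: per subject and window, the true
(M, A, φ) with the MESOR shift prorated by the subject's adherent days in
that window.  Averaging the generating mean over a 24-h grid equals the
recorded MESOR (tested), so recovery tests compare estimates against an
internally consistent target.

Survey trajectories are rounded clamped Normals per item around a
baseline item mean, with per-timepoint shifts expressed on the *scored*
scale (reverse-scored raw items move the opposite way), so a configured
shift of s per item moves the scored total by s × n_items.

**What the generator does not emulate:** the right skew of real SDNN
(residuals are Gaussian, so the generated maximum rarely approaches the
200 ms device ceiling); wear-time gaps, travel/shift-work phase shifts,
or any weekday/weekend structure; measurement error correlated with
activity; item-level correlation structure within instruments beyond a
shared mean; dropout correlated with outcomes.  Passing recovery and
coverage tests therefore demonstrates correctness of the estimation and
resampling machinery under the assumed data-generating process, not
robustness to these real-data features.

## Monte-Carlo calibration (problem sizes)

Two repeated-simulation studies in `circhrv.experiments` back the
uncertainty statements, sized as a small wearable study arm:

* **Recovery** — 50 cohorts of 30 fully adherent subjects with a +5 ms
  MESOR shift in weeks 2–4 (truth M = 50, A = 5, φ = −2.9; between-subject
  SDs 8 ms / 1.5 ms / 0.3 rad; residual 10 ms, chosen so range clipping
  is negligible), 8 windows, B = 200.  Measured here: the true weekly
  MESOR falls inside its bootstrap 95% CI in ~95–96% of window checks,
  and the week-2 contrast excludes zero in 50/50 replicates.
* **Coverage** — 200 null cohorts of 25 subjects observed through week
  3, B = 200.  Measured empirical coverage of the nominal 95% baseline-
  MESOR CI: ~92–95% depending on seed, consistent with the mild
  undercoverage expected of percentile intervals at ~25 clusters.

Both use the random-intercept engine; all randomness flows from a single
seed through `numpy.random.SeedSequence`.

## Numerical choices

* REML variance-ratio search over λ ∈ [1e-10, 1e8] on a log grid with
  Brent refinement; a rank-deficient normal-equations matrix at some λ is
  penalized rather than fatal; a boundary solution at the lower end is
  OLS (τ² = 0).
* Degenerate noiseless data (residual SS ≤ 0 to machine precision) is
  floored at 1e-300 so the profiled criterion stays defined; fixed
  effects are unaffected.
* Single-rhythm fits require ≥ 4 samples at ≥ 3 distinct clock times;
  all-one-clock-time designs raise a rank-deficiency error naming the
  cause.
* CSV readers use exact (`round_trip`) float parsing so write∘read is the
  identity on records.
* Percent formatting is decimal round-half-up, making table percentages
  deterministic across platforms.
* Pipeline determinism: per-stage seeds are spawned from the run seed;
  identical config + seed gives byte-identical table files (tested).

## Design choices that were genuinely open

* The literature's linearized cosinor uses x = cos, z = sin; we use that
  standard transform (two distinct regressors are required for
  identifiability).
* Acrophase branch (−2π, 0] so that typical late-night SDNN peaks carry
  negative phase values and the peak-time map stays in [0, 24).
* Resampling unit, interval type and p-value construction for the
  bootstrap are conventions chosen here (subject-level, percentile,
  continuity-corrected two-sided); model-based Wald/delta-method
  inference is an extension point, not implemented.
* Joint window-interaction model by default; a per-window-pair
  sensitivity mode can be emulated by filtering the input to two windows.
* Covariates act on the MESOR only; amplitude/acrophase-by-covariate
  interactions are deliberately out of scope.
* Per-day sample counts: negative binomial was chosen for the count
  model because it nests Poisson and matches the target daily-count SD
  with one dispersion parameter.
* Night bias weight 0.5 is a stand-in for an unquantified device
  behaviour; it is a config knob, not a claim.

## Known limitations

* Single-harmonic cosinor with fixed τ = 24 h: no period estimation, no
  multi-component rhythms, no ultradian structure.
* The full random-(intercept, x, z) engine inherits statsmodels MixedLM
  convergence behaviour on small strata; the automatic fallback is
  recorded but changes the working covariance model.
* Percentile bootstrap CIs mildly undercover below ~25 subjects (see the
  coverage numbers above); BCa or studentized intervals would be the
  natural upgrade.
* Timestamps are treated as already-local; daylight-saving transitions
  and timezone travel are ignored.
* Native HealthKit/device export ingestion is an adapter point (the CSV
  schema in the README), not implemented.
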