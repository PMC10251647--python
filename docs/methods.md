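# Methods

`divebuzz` estimates deep-diver foraging effort from time-depth data alone.
The response of interest is the number of terminal echolocation buzzes —
used throughout as a proxy for prey-capture attempts (PCAs) — in a
fixed-duration segment of a dive.  This note records the model, the
processing conventions, the synthetic world the package tests itself
against, and the design choices made where the procedure was genuinely
open.

## Processing chain

**Downsampling.**  High-rate tag depth (20 or 25 Hz) is decimated to 1 Hz
by keeping the first sample of each second.  Decimation, not averaging: a
time-depth recorder (TDR) logs instantaneous pressure, so the faithful
emulation of a 1 Hz tag is a point sample.  The ratio of input to output
rate must be an integer; output length is `floor(n / ratio)`.

**Dive detection.**  A dive is a maximal run of samples deeper than 25 m.
The chronologically first dive of each individual is excluded (tagging
effects).  A dive is *foraging* when at least one buzz starts inside it;
only foraging dives feed the model, but non-foraging dives are retained
for reporting.  Crossing samples (the last/first samples at or above the
threshold) are kept on the dive record but excluded from the dive body:
durations, maximum depth and segmentation are all measured on the interior
samples.

**Phase labelling.**  Descent and ascent are periods of sustained positive
and negative depth rate `r(t) = depth(t) − depth(t−1)`; brief reversals are
ignored, and the bottom phase is whatever lies between.  A naive rule —
"absorb any opposite-sign episode shorter than the tolerance" — cannot
work: on a jittery bottom phase *every* reversal is brief, so such a rule
swallows the whole bottom into the descent.  The implemented rule instead
demands net progress: the descent is the longest prefix over which the
running depth **maximum** keeps advancing, with at most
`reversal_tolerance_s` (default 10 s, configurable; the tolerance is not a
published constant) between successive record-setting samples.  The ascent
is the mirror image on the time-reversed trace.  A brief upward blip
during descent is absorbed because depth sets a new record shortly after
it; a flat bottom stops setting records within the tolerance and therefore
terminates the descent there.  On a V-shaped dive the two phases meet at
the apex; the deepest sample is assigned to the descent and the bottom is
empty.

**Segmentation.**  Each dive is cut into contiguous, non-overlapping
windows of 30, 60, 180 or 300 s starting at the dive's first interior
sample; the trailing incomplete window is discarded, so segments per dive
= `floor(dive duration / segment duration)`.  A segment's phase is the
phase of its first second.  A buzz belongs to the segment in which it
*starts* (half-open windows, so a buzz on a boundary belongs to the later
segment); this start-time rule is a package choice — it is unambiguous and
conserves totals, which the tests verify per dive.

## Segment metrics

Sixteen segment-level metrics are computed per segment (the per-second
velocity and acceleration series are intermediates, not covariates):
average/maximum/variance of depth, absolute start-to-end depth difference;
fraction of time deeper than 60/70/80/90 % of the *dive's* maximum depth;
average and variance of vertical velocity and of vertical acceleration;
inflection count; wiggle count; steady-point count; vertical sinuosity.

Conventions that needed fixing:

- *Vertical velocity* is the signed first difference (m s⁻¹ at 1 Hz);
  the sign distinguishes descent from ascent and the variance is
  sign-sensitive, so the signed series feeds the average/variance.
  *Vertical acceleration* is the absolute difference of successive
  velocities.  `compute_metrics(..., absolute_velocity=True)` switches the
  velocity moments to |v| for sensitivity checks of the signed convention.
- Variances use the sample (n−1) denominator, in squared units (m²,
  (m s⁻¹)², (m s⁻²)²).
- An *inflection* is an interior sample that is a strict local depth
  extremum; a *wiggle* is an inflection whose depth differs by more than
  20 m from the immediately preceding inflection in the same segment (the
  first inflection can never be a wiggle).
- *Steady points* compare successive depths after quantizing to 0.1 m —
  typical TDR resolution; raw float equality would be vacuous.
- *Sinuosity* = |net depth change| / Σ|per-second depth change| ∈ [0, 1];
  1 means a straight vertical path.  An all-constant segment is defined to
  have sinuosity 1 (degenerate straight path), keeping the ratio total.

**Collinearity screening.**  Candidates are screened pairwise by Pearson
correlation at |r| ≥ 0.7; of a correlated pair the metric ranked lower in
an ecological priority list is dropped.  The default priority puts the
depth-use and manoeuvring metrics known to track buzz production first
(average depth, variance of depth, variance of vertical velocity, ...).
Walking the priority list and retaining a metric only if it is below
threshold against all already-retained metrics makes the outcome
deterministic.

## The buzz-count model

For segment *j* of individual *i*:

    y_ij ~ Poisson(λ_ij)
    log λ_ij = β₀ + x_ij' β + α_i,      α_i ~ N(0, σ²_α)

Predictors are z-scored with training-set statistics before fitting —
coefficients are only interpretable (and comparable across durations) on a
standardized scale, and test data always reuse the training
standardization.  The marginal likelihood integrates α_i out per
individual; because the group contribution depends on α_i only through the
group's total count and the sum of `exp(x'β)`, the integrand has closed
form and is evaluated with 15-node adaptive Gauss–Hermite quadrature
centred on the per-group mode (Newton steps with analytic derivatives).
The optimizer works on (β, log σ_α) with L-BFGS-B; σ_α below 1e-4 is
reported as 0 and the fit then equals an ordinary Poisson regression
(the degenerate path is delegated to a plain GLM when only one group is
present).  Standard errors are Wald, from a central-difference Hessian of
the negative marginal log-likelihood; the fit was cross-validated against
`lme4::glmer(..., nAGQ = 15)`, agreeing to ≈1e-4 on coefficients, σ²_α
and standard errors.

**Model comparison.**  AIC = −2 log L + 2 (n_fixed + 1), the +1 counting
the variance parameter.  Backward selection repeatedly drops the single
predictor whose removal lowers AIC most and stops when no removal helps,
recording a full trace.  Note the known behaviour of AIC: a pure-noise
predictor survives whenever its likelihood-ratio gain exceeds 2, which
happens with asymptotic probability P(χ²₁ > 2) ≈ 0.16 — selection is not
consistent, and the tests treat elimination rates accordingly.

**Variance explained.**  Marginal/conditional R² for log-link Poisson
mixed models: R²m = σ²_f / (σ²_f + σ²_α + σ²_d) and
R²c = (σ²_f + σ²_α) / (·), with σ²_f the population variance of the fixed
linear predictor on the training data and σ²_d the observation-level
variance, by default the log-normal approximation ln(1 + 1/λ̄) with
λ̄ = exp(β₀ + σ²_α/2); a trigamma variant (ψ₁(λ̄)) is available via
`r2_variant="trigamma"`.

**Prediction.**  For unseen individuals the random effect is set to its
population mean 0, so λ̂ = exp(β₀ + x'β).  "Exact count" comparisons use
λ̂ rounded to the nearest integer (ties to even); the rounding rule is a
package choice.

## Evaluation

Validation is leave-individuals-out: each run trains on a random 8 of the
12 individuals and tests on the other 4, so the reported accuracy is for
transfer to whales the model never saw.  Runs are drawn independently
(C(12,8) = 495, collisions allowed) from a single master seed, and the
same split sequence is shared across segment durations and across the
all-data/bottom-only comparison so reports pair by run id.

Segments are scored with p(y ≥ 1) = 1 − exp(−λ̂).  AUC uses the full
ranking; sensitivity, specificity and precision need a single operating
point, which no published rule fixes, so the default threshold maximizes
Youden's J on the *training* scores (a fixed 0.5 alternative is
available); the threshold used is stored per run.  Test segments are
pooled across the run's test individuals (one ROC per run).  Failed fits
are excluded from the across-run medians/SDs and counted, never imputed.
Per predictor, the number of runs with Wald p < 0.01 is tallied.

Dive-level accounting sums observed and rounded predicted counts over each
dive's complete segments; the percentage difference uses the observed
count as denominator (and is reported missing for dives with zero observed
buzzes, rather than inventing a scale).

## The synthetic world

The generator emulates the deployment scale the analysis is designed for:
12 individuals, Poisson(9) foraging dives each; descent speed
N(1.35, 0.21²) m s⁻¹ and ascent N(1.60, 0.19²) m s⁻¹ (published values
for the species, draws truncated at ±2 SD to keep implied dive durations
under the 3600 s cap); bottom depth uniform on 500–900 m; bottom duration
uniform on 600–1200 s (chosen so total dive durations land in the
realistic 25–45 min range); the bottom phase is a random walk with 3 m
steps reflected within ±80 m of the drawn bottom depth; surface intervals
≥ 60 s at 0 m with ±0.5 m jitter (clipped at 0) so the 25 m threshold is
exercised.

Buzz counts are generated *from the model the analysis fits*, at the 180 s
window scale: per window the three driving covariates (average depth,
variance of depth, variance of vertical velocity) are computed, z-scored
deployment-wide (so the truth coefficients live on the same scale the
fitter estimates), and the count is drawn Poisson with truth coefficients
(+0.955, −0.356, +0.187), random-intercept SD 0.3 and intercept −0.45.
The slopes carry the established field signs and magnitudes; the intercept
is set a priori so deployments average ≈ 12 buzzes per dive given the
covariate structure.  Each count is realized as that many non-overlapping
5–10 s buzz events placed uniformly within the window.  The realized
ground truth (random intercepts, per-window λ, counts) ships with the
deployment for recovery tests.

What the synthetic world does **not** reproduce — and hence what a green
test does not establish:

- Between-metric correlation structure.  In the generated profiles,
  variance of depth and variance of vertical velocity correlate at
  ≈ −0.87 (transit segments are smooth and steep, bottom segments jagged
  and flat), so the |r| < 0.7 screen keeps only one of them; in the real
  data both survived screening.  Parameter-recovery tests therefore fit
  the three-predictor truth model directly rather than relying on the
  screen to hand it back.
- Buzz timing within a dive follows depth-dependent covariates only;
  there is no explicit phase prior, prey-patch clustering, or
  inter-buzz-interval structure.
- No sensor noise or drift beyond surface jitter, no 3-D movement, no
  non-foraging dive types, no overdispersion relative to the Poisson.

Empirically (40 replicate deployments at the default scale, processed
through the full chain) each truth coefficient falls in its 95 % Wald
interval in 90–95 % of replicates and the recovered signs always match —
the acceptance suite recomputes this.

## Numerical and degenerate-input conventions

- Quadrature: 15 Gauss–Hermite nodes, adaptive (mode + curvature scaling);
  log-sum-exp throughout.  Newton mode search tolerance 1e-10.
- Optimizer: L-BFGS-B, two starts (σ_α = 0.5 and 0.05); log σ_α bounded in
  [log 1e-6, log 10].  Non-convergence raises with the optimizer
  diagnostics attached; a line-search breakdown at an essentially flat
  gradient is accepted.
- Zero-SD predictors are excluded from standardization (warning), and a
  single-class test set yields NaN AUC (warning) rather than a fabricated
  value.
- All report CSVs are written with fixed float formatting so a rerun with
  the same master seed is byte-identical.

## Known limitations

- The GLMM supports exactly one random intercept (the design needs no
  more); no random slopes, negative binomial, or zero inflation.
- The phase-labelling tolerance trades a small bias at phase boundaries
  (≤ tolerance seconds) for robustness to bottom jitter; boundary-exact
  recovery is only guaranteed on noiseless fixtures.
- Accuracy numbers obtained on the synthetic world should not be read as
  field performance: the generator's signal-to-noise is set by its truth
  coefficients, not by sperm-whale biology.
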