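# Methods

## The measurement model

Empathic accuracy for one perceiver × clip pair is a correlation between two
short, autocorrelated time series: the perceiver's continuous 1–9 dial
rating of how the target feels, and the target's own rating of the same
clip. The pipeline treats each stage explicitly.

### Binning and truncation

Streams are averaged over half-open windows `[k·b, (k+1)·b)` of width
`b = 5 s`, anchored at the stream's first timestamp (streams are assumed to
start at clip onset; anchoring is configuration, not an assertion about any
particular hardware). A trailing window covering less than `b` seconds of
recording is dropped so every bin averages an equal time span; recording
length is `t_last − t_first + dt` with `dt` the median sample spacing. The
first and last bin are then discarded — the dial's start-up and wind-down
seconds carry handling artifacts rather than judgment. For a 120-s clip at
1 Hz this yields 24 → 22 bins; in general `floor(D/b) − 2`.

Perceiver and target bins are aligned from bin 0 to the shorter common
length (dial logs may end a sample early); a mismatch over 2 bins is
flagged, and fewer than 3 common bins excludes the pair. Constant series are
excluded with a reason, never imputed — the correlation is undefined and
imputing 0 would bias the cell means.

### Serial dependence and the per-clip correlation

AR coefficients are estimated by the Yule-Walker method: the Toeplitz
system on biased (1/n) sample autocovariances, solved by the
Levinson–Durbin recursion, which guarantees a stationary fit. Order 1
reduces to the lag-1 sample autocorrelation. Tests verify the recursion
against a direct linear solve (1e-8, orders 1–5) and against an independent
reference implementation.

Three correlation methods are provided because "AR-corrected correlation"
underdetermines the computation; none is asserted as what any specific
historical analysis did:

- **naive** — Pearson on the binned series.
- **prewhiten** — each series filtered by its own AR(p) fit
  (`e_t = x_t − Σ φ_k x_{t−k}` on the centered series), Pearson on
  residuals.
- **ar_error_model** (default) — two-stage regression with AR(p) errors in
  the style of classic autoregressive-error estimation: OLS of perceiver on
  target, Yule-Walker on the OLS residuals, quasi-differencing of both
  series by the fitted coefficients, and the correlation of the transformed
  series signed by the structural slope. Default order 1, configurable 0–4;
  no automatic order selection, keeping the pipeline deterministic.

Correlations are clipped at |r| = 0.999 before z = atanh(r) so perfect
tracking (which occurs in real data) maps to z ≈ 3.8 instead of infinity.
All methods are invariant under positive affine rescaling of either series.

### The mixed model

Fisher-z scores are modeled with a perceiver random intercept only. The
fitter profiles the REML criterion over the variance ratio
λ = σ_u²/σ_e² (one-dimensional bounded optimization; each evaluation is a
closed-form GLS solve using per-group sums, so a fit takes milliseconds),
then reports GLS estimates and Wald F/t statistics. When the REML optimum
is at λ = 0 the fit coincides with OLS and the result notes the downgrade.
Test oracles: statsmodels MixedLM (estimates and standard errors agree to
~1e-5) and exact OLS equivalence on balanced data with zero subject
variance.

**Denominator df** use the containment (between-within) rule: a fixed
effect constant within subjects gets `n_subjects − p_between` df, where
`p_between` counts the intercept and all between-subject columns; a
within-subject effect gets `n_subjects − 1`. For a 54-subject design this
yields df 52 for a condition-only model, 53 for a single within-subject
factor (valence or target sex), and 50 for the
condition + centered moderator + interaction model — exactly the pattern a
subject-level analysis would give, and exact (not approximate) for balanced
between-subject contrasts under normality. Satterthwaite/Kenward-Roger
alternatives were considered and not implemented: the containment rule is
exact for the designs this pipeline targets and keeps the df integers.

**Moderation.** The continuous moderator (an AUDIT-style hazardous-drinking
score) is grand-mean centered using the mean over subjects; simple slopes
evaluate the condition contrast at the subject-level mean ∓ 1 SD with the
contrast's containment df (50 at n = 54). Valence-stratified models are
subset refits, not three-way interaction contrasts. No multiplicity
correction is applied to the two post-hoc contrasts by default.

**Effect sizes** are computed from the test statistics — d = 2·√(F/df_den)
for single-df F tests and d = 2·|t|/√df for contrasts — rather than from
raw means, so they are exactly reproducible from reported statistics.

### Descriptive statistics

Two-sample t-tests from summary statistics default to pooled Student
(Welch with Satterthwaite df as option). Re-computing a published t from
rounded summary rows can move the last printed digit (e.g. a pooled t of
0.3751 prints as 0.38 where the original, computed on unrounded data,
printed 0.37); tests therefore compare such values at ±0.01.
Cronbach's α uses the standard k/(k−1)·(1 − Σs_i²/s_T²) form with n−1
variances (cross-checked against pingouin). The revised AUDIT total sums
items 1–8 (range 0–32, hazard cutoff 8), the convention when items 9–10 are
unusable.

### Dose arithmetic

The vodka-volume calculator supports two conventions for a 0.56-per-kg
dose from 37.5 % ABV spirit: `ml_per_kg` (weight × 0.56/0.375) and
`g_per_kg` (additionally divided by ethanol density 0.789 g/ml). The
`ml_per_kg` arithmetic reproduces typical published served-volume ranges
for 57–99 kg participants, so it is the default; the served volume is split
over two equal glasses.

## The synthetic generator

The generator emulates the study conditions, not any particular dataset:

- **Targets**: mean-reverting AR(1) around a valence anchor (6.5 positive,
  3.5 negative on the 1–9 dial), AR coefficient 0.8, innovation SD 0.6,
  1 Hz, 120 s, clipped to the dial. 1 Hz is a deliberate desk-scale choice:
  coarse enough to keep a 54 × 16 cohort around 10⁵ samples, fine enough
  that each 5-s bin averages 5 samples.
- **Perceivers**: the standardized (optionally lagged) target mixed with an
  independent unit-variance AR(1) noise series with weights
  (r, √(1−r²)), mapped back to the target's dial location/scale and
  clipped. The noise persistence defaults to the target's AR coefficient so
  5-s binning attenuates signal and noise equally and the calibration
  survives binning; clipping shrinks realized correlations slightly, hence
  the ±0.05 calibration tolerance rather than exactness.
- **Cohort**: perceivers alternate placebo/alcohol (guaranteed near-equal
  arms at small n); every perceiver watches all 16 clips (8 positive, 8
  negative, 8 targets × 2 clips) in an order satisfying the presentation
  constraints (no target more than twice, no more than two same-valence
  clips in a row). The order sampler is uniform rejection sampling —
  exactly uniform among feasible orders — with a seeded backtracking
  fallback that is complete but not exactly uniform.
- **Truth**: per-pair true tracking correlation
  tanh(β₀ + β_val·pos + β_cond·alc + β_mod·m + β_int·alc·m + u_i + ε_ij)
  with m the generated AUDIT total standardized by the stated mean/SD
  (default 10.65 / 3.90). Default betas are calibrated analytically so the
  cohort means land near r ≈ 0.67 (positive) and 0.59 (negative): the
  intercept solves E[tanh(N(μ, σ²))] = target mean with
  σ² = sd_perceiver² + sd_residual² (0.15² + 0.35²), correcting for tanh
  concavity. With this coding, an alcohol deficit confined to low-moderator
  perceivers corresponds to β_cond < 0 with β_int > 0 of similar magnitude
  (the condition contrast at standardized moderator m is β_cond + β_int·m).
- **Questionnaires**: AUDIT items load on one latent factor (loading chosen
  so the items-1-8 total has the configured SD), giving α ≈ 0.75–0.8;
  daily-drink counts share the factor at ρ = 0.7; motive subscales,
  social-anxiety totals, urge ratings, weights and breath-alcohol peaks are
  drawn from baseline-table-shaped normals, rounded and clipped to their
  instrument ranges.

What the generator does **not** emulate: real dial hardware (irregular
sampling, missing samples), nonstationary affect trajectories, perceiver
response lag asymmetries, target-level random effects, or any
pharmacokinetics beyond storing a peak breath-alcohol value. Passing tests
therefore demonstrate that the pipeline recovers known effects from data
with the study's size, autocorrelation and noise structure — not that the
scoring method is optimal for real dial data.

## Simulation sizes and determinism

Every stochastic test is seeded. Monte-Carlo problem sizes are the
package's chosen trade-off between resolution and runtime: calibration uses
500 replicates per correlation level (±0.05 band); the interaction-test
type-I rate uses 1 000 replicates of the 54 × 16 design drawn at the
Fisher-z level of the generative model (the same linear model that sets the
per-pair true correlations — the stream → scoring link is calibrated
separately); simple-slopes sign recovery runs 60 full stream-level
replicates at |β_cond| = |β_int| = 0.3; z-level parameter recovery uses 60
replicates at n = 200 subjects. The full default pipeline (simulate →
preprocess → score → analyze, 54 × 16 at 1 Hz) completes in roughly two
seconds on one CPU.

## Known limitations

- Factors are restricted to two levels with fixed reference coding; the
  model builder is not a general formula interface.
- The mixed model supports a single random intercept (by design: the df
  pattern it must reproduce is subject-level), so crossed target random
  effects are out of scope.
- The containment df rule is implemented for the model shapes used here;
  unbalanced exclusions shift only the estimates, not the df convention.
- CSV round trips preserve 6 significant digits; byte-identical
  regeneration holds for identical config + seed, not across numpy
  versions.
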