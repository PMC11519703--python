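# Methods

This note records the models the package implements, the assumptions behind
the synthetic-data generator, and the numerical and design choices made
where more than one defensible option existed.

## Analysis pipeline

### AOI geometry

Webcam gaze estimators report raw screen coordinates, so the two picture
regions are reconstructed post hoc as fixed proportions of each
participant's viewport: left box x ∈ [0.15 W, 0.45 W), right box
x ∈ [0.55 W, 0.85 W), both y ∈ [0.225 H, 0.725 H) — on 1920×1080 that is
x 288–864 / 1056–1632 and y 243–783.  Coordinates are screen pixels, origin
top-left, y increasing downward.  Membership is half-open on both axes,
which gives a deterministic tie-break at box edges and makes the three
labels {target, foil, none} an exhaustive partition of the plane.  Samples
in neither box are kept in the raw store but flagged `discarded` and never
enter proportion denominators.  Lab exports are already labeled by the
acquisition software (whose AOIs also cover the response-key letters and
are not reconstructed here); they pass through verbatim.

### Trimming

Within each trial, gaze estimations whose timestamp lies more than two
sample standard deviations (n−1 denominator) from the trial's mean
timestamp are removed.  Trials with fewer than three samples, or zero
spread, pass through untouched — the SD is undefined or degenerate there.
The rule is deliberately applied exactly once (a provenance flag in
`DataFrame.attrs` guards re-application): 2-SD trimming is not idempotent,
so "trim once" is part of the definition.

For reaction times, inaccurate trials are dropped first; then, within each
participant × session (one session per tracking modality), trials with an
RT more than 2 SD from the session mean are removed.  Accuracy itself is
never trimmed.  RTs are square-root transformed before modeling.

### Binning

Surviving target/foil samples are counted into half-open 100-ms bins over
the 0–12,000 ms trial window (bin k = [100k, 100(k+1)); 120 bins), and each
(participant, modality, trial, bin) cell becomes one proportion
`n_target / (n_target + n_foil)` with weight `n = n_target + n_foil`.
Bins with no target/foil samples are removed rather than zero-filled.
Binning uses the absolute trial clock; `rel_bin` re-indexes each bin
relative to the bin containing the trial's disambiguation point for
display and alignment.  A `denominator="all"` switch counts none-labeled
samples in the denominator for sensitivity analyses; the default excludes
them, treating both modalities identically.

### Proportion models

Per-bin target proportions are over-dispersed relative to a binomial (the
generator's participant heterogeneity reproduces this, with typical
dispersions of 1.3–1.5 at the default settings), and random-effects
logistic fits on this kind of data are fragile.  The package therefore fits
**quasibinomial** models: binomial-likelihood point estimates via
iteratively reweighted least squares with prior weights `n`, a dispersion
estimated as Pearson χ² over residual degrees of freedom (the residual df
is the number of proportion rows minus parameters, the same convention R's
`glm(..., family = quasibinomial)` uses — the two agree to machine
precision on shared fixtures), and every covariance scaled by the
dispersion.  Inference uses t statistics on the residual df.  Random
effects are deliberately absent from this family.

The omnibus bin-interaction model (`BinwiseGazeModel`) is fit in its
saturated cell-means parameterization: one logit per observed
(bin × factor-combination) cell.  Because that design is an orthogonal
one-hot basis, the weighted MLE of each cell logit is the logit of the
cell's weighted mean proportion, with variance `φ / (W p (1−p))`; the
dispersion φ is pooled across all cells, which is exactly the single
omnibus model with bin interactions rather than 120 independent per-bin
fits.  Per-bin contrasts (e.g. PWA − control, or the difference of that
difference between web and lab) are linear combinations of cell logits;
marginal means average cell logits over the remaining factors with equal
weights.  Contiguous runs of significant bins with a common sign are
summarized as (onset, offset) windows, mirroring how divergence onsets are
narrated in this literature.  No multiplicity correction is applied across
bins by default, matching standard reporting practice in bin-wise
visual-world analyses; the per-bin p-values should be read accordingly.

A cell whose weighted proportion is exactly 0 or 1 receives a half-unit
continuity correction before the logit (`(Σwy + ½)/(W + 1)`).

The effect-size column `d` is derived from the test statistic as
`d = 2t/√df`.  It is an approximation, not a standardized mean difference
computed from raw scores.

### Behavioral models

Accuracy: binomial mixed-effects logistic regression with structure ×
modality fixed effects and participant and item random intercepts,
intended for the clinical group only when controls are at ceiling.  The
mixed fit uses a variational Bayes approximation (statsmodels
`BinomialBayesMixedGLM`), mapping posterior means/SDs to estimates/SEs;
when it fails the model falls back to a fixed-effects logistic GLM with a
logged warning.  RT: linear mixed model of √RT with group × structure ×
modality fixed effects and crossed participant/item intercepts encoded as
variance components, optimized with Powell then L-BFGS; marginal and
conditional variance-explained summaries follow the Nakagawa
decomposition var_fixed / (var_fixed + var_random + var_residual).
Reported confidence intervals are 95 % Wald/t intervals.

### Δgaze and lag estimation

For each (bin, structure, modality) cell, Δgaze is the control group's mean
target proportion minus the PWA group's, averaging trial-level proportions
with equal weight (a participant-means-first switch exists, since either
weighting is defensible).  Cells where either group mean would rest on
fewer than `min_cells = 5` trial-level proportions are dropped: late bins
are populated only by the slowest trials, and a "group mean" of one or two
trials is single-trial noise that can reach ±1 and dominate any downstream
comparison.  |Δgaze| ≤ 1 by construction, and swapping the group labels
negates the series exactly.

Δgaze is modeled by ordinary linear regression on bin × modality with bin
numeric — the points are already averages, so no random effects — and the
key term is the bin × web interaction: a positive coefficient means group
differences persist later on the web.  Serial correlation across bins is
not modeled; p-values from this regression inherit that caveat.

Three lag estimators compare the lab and web Δgaze series after aligning
them on a common integer bin grid (interior gaps linearly interpolated,
never extrapolated):

* **peak** / **dip** — difference of argmax/argmin locations, ties broken
  toward the earliest bin, with an optional centered 3-bin moving average
  (off by default).  These mirror how such comparisons are usually read
  off figures, and they work well when the difference curve is genuinely
  unimodal; on plateau-shaped or noisy series the arg-extremum is unstable,
  and the default simulated study has no true dip at all unless the late
  control decay (`late_decay_onset_ms`) is switched on.
* **xcorr** — the lag maximizing the normalized cross-correlation of the
  overlapping, demeaned segments over a ±20-bin window (≥5 valid pairs
  required; ties broken toward the smallest |lag|).  This uses the whole
  curve shape and is the recommended estimator; at default noise it
  recovers injected lags of 300–800 ms to within one bin on seed average.

## The synthetic-data generator

The generator is the package's ground-truth instrument.  It emulates:

* **Design** — 65 trials: 15 active, 15 passive, 15 locative, 10
  declarative + 10 wh fillers; target side left in half the trials per type
  (8/7 for the odd counts, the extra side seeded).  Disambiguation points —
  noun onset for active/passive, first preposition for locatives — are
  drawn uniformly inside per-structure windows (defaults: actives/passives
  1800–2600 ms, locatives 1600–2200 ms from trial onset, i.e. after the
  300 ms fixation cross and 700 ms picture apprehension phase).  Real
  item-level onset times are not public, so the windows are configurable
  stand-ins, not inferences about the actual stimuli.
* **Sampling clocks** — shifted-lognormal inter-sample intervals matched
  exactly to the configured mean and SD: lab 2.3 ms (SD 13.91, shift
  1.8 ms ≈ the hardware tick), web 49 ms (SD 162.2, shift 15 ms).  The
  SD > mean webcam distribution is strongly right-skewed — mostly regular
  frames with occasional long stalls — and the lognormal reproduces that
  while keeping the mean exact, which the interval-calibration tests
  verify at 10⁵ samples within 5 %.
* **Gaze time course** — the probability a sample lands in the target AOI
  is 0.5 until `disambiguation + group onset delay (+ web lag on the web)`,
  then rises logistically with a group time constant (`ramp_scale_ms`;
  0 = instantaneous step) to a group × structure asymptote (defaults:
  controls ≈ 0.84–0.88, PWA ≈ 0.70–0.80, with the passive structure
  weakest for PWA).  An optional control-group post-peak decay toward 0.5
  (`late_decay_onset_ms`, off by default) reproduces the late
  PWA > control crossover seen in this population.  The web lag enters as
  a pure translation of the time course, so Δgaze(web) is Δgaze(lab)
  shifted by the lag — the property the estimators are tested against.
* **Space and loss** — web samples are emitted as coordinates at the
  assigned box center plus isotropic Gaussian noise (40 px default);
  dropout samples (8 % web, 2 % lab) land in the inter-AOI gap.  Lab
  samples are emitted pre-labeled.  Recording lasts
  `min(RT + 300 ms, 12 s)`, so trial durations vary with response speed
  and late bins thin out, as in real sessions.
* **Behavior** — accuracy is Bernoulli from group × structure logits
  (controls near ceiling; PWA passive logit 1.0 below active); RT is
  lognormal around group × structure medians, scaled by a per-group web
  ratio (< 1: faster on the web, more so for PWA), floored just past the
  audio end.
* **Heterogeneity** — per-participant effects: a multiplier on
  (asymptote − 0.5) for gaze (so it vanishes exactly in null
  configurations where the asymptote is 0.5), a lognormal RT factor, and a
  normal accuracy-logit offset; plus a per-item RT factor.  These produce
  realistic overdispersion and non-degenerate random-effect estimates.

One integer seed determines everything through `numpy.random.SeedSequence`
spawning (design, effects, behavior, then one stream per
participant × modality, in fixed order); identical configurations are
byte-identical.

**What the generator does not emulate:** calibration drift, saccade
kinematics and fixation structure (samples are conditionally independent
given the ramp), blinks, screen-position estimation bias toward the screen
center, per-participant viewport diversity, and item-specific semantics.
Passing recovery tests therefore demonstrate that the *analysis* is correct
and calibrated under the stated data-generating assumptions — not that any
particular real dataset satisfies those assumptions.

## Monte-Carlo problem sizes

The stochastic checks use desk-scale configurations, chosen once:

* **Null calibration** — 200 replicates of a web-only, 6 + 6 participant,
  4-s-trial study with every group effect zeroed; per-bin group contrasts
  reject at the nominal 5 % within two Monte-Carlo standard errors
  (measured: ≈ 5.1 %).
* **Lag recovery** — injected web lags of 300/500/800 ms, full
  dual-modality 16 + 16 studies with 9-s trials, 9 seeds per lag; the
  cross-correlation estimate averages within one 100-ms bin of the truth.
* **Effect recovery** — 50 seeds each for the PWA passive-accuracy deficit
  (16 PWA × 65 trials × 2 sessions; mean recovered logit ≈ −1.0) and for a
  window-confined gaze deficit (web-only 16 + 16; detected-vs-injected
  window Jaccard ≈ 0.9).

## Known limitations

* The quasibinomial omnibus model treats proportion rows as exchangeable
  given their cell; clustering by participant is absorbed only through the
  pooled dispersion.  This matches the stated modeling choice but slightly
  understates uncertainty when participant effects are large.
* Peak/dip lag estimates are only meaningful for unimodal difference
  curves; prefer the cross-correlation estimator.
* The Δgaze regression ignores bin-to-bin autocorrelation.
* Variational inference for the mixed accuracy model mildly shrinks
  variance components; the fixed-effects fallback changes the estimand
  (marginal rather than conditional effects).
* Bayesian model comparison (Bayes-factor confirmation of null effects) is
  out of scope; it would attach at the same model surfaces.
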