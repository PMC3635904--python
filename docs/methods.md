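# Methods

This note documents the models implemented in `kinesig`, the assumptions
of the synthetic-data generator, and the numerical and design choices made
where the methodology left the design open.

## The movement model

A session consists of repeated trials of a brief goal-directed hand strike
followed by a spontaneous retraction, recorded as a 3D position series at
240 Hz.  Three layers of structure are analysed:

1. **Per-trial kinematics.**  Speed and acceleration magnitudes come from
   Savitzky–Golay smoothing/differentiation of position (window 11
   samples, polynomial order 3 at 240 Hz; both configurable).  Third
   derivatives (jerk) are never computed: differentiating smoothed capture
   data a third time amplifies instrumentation error, which is also why
   trajectory curvature is measured with the linearity index below rather
   than the differential-geometric curvature.  Scalar features per
   segment: peak speed `vmax`, peak acceleration `amax`, time to peak,
   duration, mean speed, and the normalized peak speed
   `vmax/(vmax + mean_speed)`.  The normalization is scale-invariant
   (hence free of allometric body-size effects) and lies in [0.5, 1),
   reaching 0.5 exactly when the speed is constant.  "Mean speed" is the
   time average over the *segment* (not the whole trial); a flag selects
   the whole-trial mean instead.

2. **Distributional signatures.**  For a subject × condition stream of a
   positive feature, the Gamma family f(x|a,b) = x^(a−1)e^(−x/b)/(b^aΓ(a))
   is fit by maximum likelihood; the (shape, scale) point is the subject's
   stochastic signature for that condition.  Mean = a·b, variance = a·b²,
   so the Fano factor (noise-to-signal ratio) equals the scale b; these
   identities hold exactly for every fitted signature by construction.
   95% confidence intervals are Wald intervals from the observed Fisher
   information n·[[ψ′(a), 1/b], [1/b, a/b²]]; they are approximate at
   block sizes of ~100 trials (the tests treat them accordingly).  The
   Gamma MLE refuses samples smaller than 10 rather than return unstable
   estimates.  The time window w (time to peak speed, ~200 ms) that the
   noise-to-signal ratio refers to is recorded as feature metadata
   (`t_peak`); the statistic itself is the Gamma-moment ratio.

3. **The trial-to-trial rule.**  Consecutive trials are linked by
   ln(vmax(t+1) + ν·vmax(t)) = m·ln(amax(t)) + b + ε with ν = υ − 1.
   υ = 10 by default: a cohort-scale normalization chosen from the range
   of speed/acceleration values a cohort spans, configurable because the
   constant differs for other cohorts.  The sign of ν follows the
   identity amax + υ·vmax = vmax(t+1) + ν·vmax(t) (ν = υ − 1 = 9); the
   alternative sign convention ν = 1 − υ would make the log argument
   negative and is rejected.  The slope decomposes as m = 1 − δ, and
   exponentiation plus a leading-order expansion yields
   vmax(t+1) = amax(t)·(1 − δ·ln amax(t))·e^(b+ε) − ν·vmax(t) + O(δ²);
   `power_form` reports δ, δ² and a numeric bound on the remainder over
   the scatter's amax range.  Fits are OLS (statsmodels) with SSE, R²,
   adjusted R² and RMSE = √(SSE/(n−2)).  Whether one pooled line or one
   line per instructed speed level describes a scatter is decided by a
   nested-model F-test at α = 0.05 (the methodology reports two-slope
   fits without naming a criterion; a nested F-test is the standard
   choice).  Trial pairs spanning a block/context boundary are excluded
   from the scatter by default, since the rule is stated within one task
   context.

## Unimodality, histograms, comparisons

* Histograms use Scott's bin width W = 3.49·s·N^(−1/3) with frequencies
  normalized to sum to 1 (density mode optional).  The bin *count* is
  invariant under affine rescaling of the data because W scales with s.
* Hartigan's dip statistic is implemented from the published iterative
  greatest-convex-minorant / least-concave-majorant algorithm (no suitable
  library is available in the environment).  Its correctness is verified
  in the tests against an independent brute-force solver of the dip's
  defining minimax problem (one linear program per candidate mode
  position), exact at small n.  P-values are bootstrapped from uniform
  samples of the same size (Hartigan's calibration), 2000 draws by
  default, seeded, with add-one smoothing ((k+1)/(B+1)).
* Condition comparisons are rank-based: Wilcoxon rank-sum (exact for
  small tie-free samples, asymptotic without continuity correction
  otherwise, so that identical samples give p = 1), Kruskal–Wallis, and
  Friedman for paired layouts.  Rank tests make the p-values invariant
  under monotone transformations of the data.
* Fatigue: the first k and last k trials of a same-speed block (k = 10)
  are compared on `vmax` and duration with rank-sum tests; fatigue in
  long sessions appears first in the durations of fast retractions.

## Trajectory linearity

Curves are resampled to M equally spaced points in normalized *time*
(`mode="arclength"` resamples along normalized arc length instead — for
uniform-speed curves the two coincide).  Each resampled point is
projected at a right angle onto the straight start–end chord; the
deviations (zero at both endpoints) are the linearity profile.  A
superposition check records the maximum distance between the original
points and the resampled polyline and flags resampling as faithful when
it stays below 0.5% of the chord length.  Deviations are invariant under
rigid motions and homogeneous of degree one under scaling.

## The synthetic-data generator

The generator's defaults *are* the emulated study conditions:

* 100 trials per subject–speed condition (study floor 100–120), 240 Hz,
  durations clipped to 0.8–2.1 s.  Within a condition, durations are
  drawn around speed-level means (slow 1.6 s, fast 0.95 s) with a 7%
  coefficient of variation — within-subject movement-time variability of
  practiced brief movements is small, and this keeps duration effects
  (e.g. injected fatigue) detectable at first-10/last-10 scale.
* Peak speeds per (subject, speed level, context) follow log-normal laws.
  The generic defaults put slow strikes at a median of 2 m/s and fast at
  5 m/s with log-sd 0.1, so that merged blocked levels are clearly
  bimodal while a single block is unimodal.
* Speed profiles are unimodal bells g(τ) = τ^(c·p)(1−τ)^(c·(1−p)) with
  peak fraction p and concentration c, scaled so the discrete maximum
  equals the programmed `vmax` exactly; p = 0.5 gives the symmetric
  minimum-jerk-like bell.  The profile shape is not otherwise
  constrained by the methodology beyond unimodality.
* Trajectories integrate the speed profile along a straight chord
  (strikes, bend 0) or a planar circular arc (retractions) whose
  dimensionless bend is the sagitta ratio: maximal perpendicular
  deviation = bend·chord/2, with bend 0.12 (slow) and 0.35 (fast) so
  retraction curvature splits by speed level.  The bend plane is a
  deterministic function of the chord direction.
* Trial-to-trial dependence: within each condition the (vmax, amax)
  sequence satisfies the stochastic rule.  The default direction draws
  the peak-speed sequence i.i.d. from its log-normal law and derives
  amax by exact inversion — this preserves the configured marginal law
  exactly and makes noise-free round trips exact to machine precision.
  The Gaussian form of ε is an assumption (the residual's distribution is
  otherwise unspecified); it is configurable.
* Nonpositive draws (possible only in the causal direction below) are
  redrawn up to 100 times and logged with the trial index, then raise.

**Recorded versus re-derived features.**  The per-trial (vmax, amax)
pairs that satisfy the rule are carried with the session as
instrument-grade *recorded* kinematics, playing the role of capture
software that outputs velocity and acceleration directly.  The raw traces
realize the recorded `vmax` exactly; the profile shape is solved per
trial (via the early-peaked subfamily g(τ) = τ(1−τ)^β) so the analytic
peak acceleration matches the recorded `amax` where the duration range
allows, and trace re-derivation recovers `vmax` to ~0.1% and `amax` to
~5–10% (smoothing tolerance).  Exact round-trip tests therefore run on
recorded features; the closed loop through Savitzky–Golay extraction is
tested at its smoothing tolerance.  The pipeline uses recorded features
by default (`use_recorded_features`).

**Why two generation directions exist.**  With the default inversion the
residual ε is placed inside the regressor ln amax, so for eps_sd > 0
ordinary least squares on such data is attenuated (an errors-in-variables
effect) — noise-free recovery is exact, noisy recovery is conservative.
The alternative `"amax_first"` direction fixes amax from the current
state and an intended next speed and realizes vmax(t+1) with ε in the
response, which is the correct construction for checking confidence-
interval coverage.  One genuine limitation follows from the speed
recursion itself: at υ = 10 the realized speed obeys
v(t+1) = C·e^ε − 9·v(t), so response noise feeds back into the next
trial's regressor with gain ≈ ν = 9, producing a small-sample slope bias
that depresses joint CI coverage to ~85% at T = 100 (no construction can
combine an exact rule identity, exogenous regressors and stable positive
speeds at ν = 9 — with exogenous combined speeds the recursion is
explosive).  Coverage checks therefore run the causal direction at a
weakly coupled normalization (υ = 2, ν = 1), where the recursion is
stationary, positivity truncation never binds and estimates are
unbiased; there the generating parameters fall inside both 95% CIs in
≈ 93% of replicates.

**Expert/novice presets.**  The expert preset spans condition medians
1.2 / 1.8 / 3.5 / 5.0 m/s (slow/fast × no-bag/bag) with log-sd 0.06 —
broad bandwidth, low noise; the novice preset spans 1.60 / 1.65 / 2.6 /
3.1 m/s with log-sd 0.25 — narrow bandwidth, high noise, with the slow
bag/no-bag laws nearly identical so those conditions are statistically
indistinguishable.  Rule parameters use representative values (expert
m = 0.69, b = 1.84; novice m = 1.03, b = 0.87).  Expertise thresholds
(bandwidth ≥ 2.5, max Fano ≤ 0.05) are calibrated once against these
presets; they are config parameters, since the criteria are qualitative.
Separability of two condition densities is defined as non-overlap of the
central 95% probability intervals of the fitted Gammas.

**What the generator does not emulate.**  Only the hand point is
simulated (no 15-sensor full-body kinematics, no force/load dynamics —
loads would enter as condition labels with altered curvature/speed laws);
profiles are exactly unimodal with clean segment boundaries, residuals
are Gaussian and stationarity is exact within a block.  Passing tests
therefore demonstrate the correctness and calibration of the estimators
under the stated statistical structure, not robustness to real capture
artifacts (sensor dropout, filtering transients, nonstationary fatigue
drift).

## Numerical choices and degenerate inputs

* Strike/retraction segmentation of a full-trial speed profile splits at
  the deepest interior minimum between the two largest peaks (peak
  prominence ≥ 5% of the maximum), earliest sample on ties for
  determinism; monotone or single-peak profiles return one segment plus
  a warning.
* Gamma MLE uses the scipy fit with location fixed at 0; a score check
  logs a warning if the gradient has not converged.
* `classify_shift` calls a transition neutral when |Δshape| < 5% of the
  smaller shape (the methodology defines direction only).
* The dip statistic returns its floor 1/(2n) for constant samples; the
  test requires n ≥ 30 and ≥ 500 bootstrap draws.
* Signature trajectories skip undersized groups with a warning rather
  than fail the whole session.
* All randomness flows through numpy Generators seeded from the run
  seed (`SeedSequence` spawning per subject); identical seeds reproduce
  sessions, reports and CLI outputs bit-identically.

## Problem sizes

The demonstration study (2 subjects × 2 speeds × 2 contexts × 100 trials,
segments both kept) runs end to end in well under a minute on one CPU,
dominated by trajectory synthesis and the 2000-draw dip bootstraps; the
acceptance script's recomputations (100-replicate coverage study, 2000
Gamma draws, two dip tests, the cohort study and fatigue checks) take a
few seconds.
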