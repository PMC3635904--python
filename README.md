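# kinesig

Stochastic signatures of trial-to-trial hand-speed variability.

`kinesig` analyses the micro-variability of repeated, brief hand movements
— the kind of forward strike + spontaneous retraction performed over and
over in a martial-arts or reaching session — treating the peak speed of
each trial as a stochastic process across the session.  It is written for
movement scientists who want to characterize individual performers
(athletes, trainees, patients) by the *statistics* of their kinematic
fluctuations rather than by group-averaged hypothesis tests.

Because the underlying motion-capture recordings of this kind of study are
rarely public, the package ships a first-class synthetic session generator
that emulates the study conditions (240 Hz sampling, 100–120 trials per
subject–speed condition, movement durations 0.8–2.1 s, blocked or randomly
interleaved speed instructions, log-normal peak-speed laws, speed-dependent
retraction curvature), so that every analysis stage is testable end to end
from a seed.

## The statistics at the core

**Gamma-plane signatures.**  For each subject and condition the empirical
distribution of the peak speed `vmax` (or of its allometry-free
normalization `vmax / (vmax + mean speed)` ∈ [0.5, 1)) is fit by maximum
likelihood with the two-parameter Gamma family

&nbsp;&nbsp;&nbsp;&nbsp;f(x | a, b) = x^(a−1) e^(−x/b) / (b^a Γ(a)),

giving one point (a, b) — shape and scale — per subject–condition.  Small
shapes sit near the memoryless Exponential; large shapes approach the
symmetric Gaussian range, interpreted as more predictive performance.
Since E = a·b and Var = a·b², the Fano factor (noise-to-signal ratio)
Var/E equals the scale b.  Signatures are tracked chronologically across
condition blocks; a right-shift in shape is a positive gain, a left-shift
a negative gain.

**A first-order stochastic rule.**  Consecutive trials are linked through

&nbsp;&nbsp;&nbsp;&nbsp;ln(vmax(t+1) + ν·vmax(t)) = m·ln(amax(t)) + b + ε,

with ν = υ − 1 and the cohort-scale normalization υ = 10.  The slope
decomposes as m = 1 − δ; exponentiating and expanding to leading order in
δ gives an anticipatory update of the next trial's peak speed from the
current trial's peak acceleration, with multiplicative error.  Fits are
ordinary least squares with the standard regression diagnostics (SSE, R²,
adjusted R², RMSE); a nested-model F-test decides whether one pooled line
or one line per instructed speed level describes the scatter.

**Expertise criteria.**  An expert-like profile combines (1) a broad
bandwidth of condition-wise distribution locations (ratio of largest to
smallest Gamma mean) with (2) low noise-to-signal ratios that keep the
per-condition densities pairwise separable.

Also included: Scott's histogram bin-width rule W = 3.49·s·N^(−1/3),
Hartigan's dip test of unimodality (own implementation, bootstrap
calibrated against the uniform null), a log-log power fit of the Gamma
plane, trajectory linearity (perpendicular deviations of time-normalized
resampled curves from the start–end chord), nonparametric condition
comparisons (rank-sum / Kruskal–Wallis / Friedman) and first-10 vs last-10
fatigue checks.

## Worked example

```python
import kinesig as ks

# a blocked study: expert + novice, bag/no-bag contexts, two speeds,
# 100 trials per condition
cfg = ks.cohort_config(seed=7, trials_per_condition=100)
session = ks.generate_session(cfg)
strikes = session.features[session.features.segment == "strike"]

for sid, grp in strikes.groupby("subject_id"):
    sigs = ks.condition_signatures(grp, "vmax")
    prof = ks.expertise_profile(sigs)
    print(f"{sid}: bandwidth={prof.bandwidth:.2f}  "
          f"max Fano={prof.max_fano:.3f}  expert-like={prof.expert_like}")

novice = strikes[strikes.subject_id == "novice_1"]
fit = ks.fit_rule(ks.build_rule_scatter(novice.sort_values("trial_index")))
print(f"rule fit: m={fit.m:.3f}  b={fit.b:.3f}  R^2={fit.r_squared:.3f}  "
      f"delta={fit.delta:+.3f}")

merged = strikes[strikes.subject_id == "expert_1"].vmax.to_numpy()
dip, p = ks.dip_unimodality(merged, n_boot=2000, seed=1)
print(f"dip test on merged blocked speeds: dip={dip:.3f}  p={p:.4f}")
```

Output:

```
expert_1: bandwidth=4.22  max Fano=0.015  expert-like=True
novice_1: bandwidth=1.89  max Fano=0.196  expert-like=False
rule fit: m=0.935  b=1.076  R^2=0.909  delta=+0.065
dip test on merged blocked speeds: dip=0.079  p=0.0005
```

The expert spans a 4.2-fold bandwidth of condition-wise peak-speed levels
with a worst-case noise-to-signal ratio of 0.015, and every pair of their
four condition densities is separable — the expert-like flag is set.  The
novice's bandwidth is below 2 with ten-fold higher noise, and the slow
bag/no-bag conditions are statistically indistinguishable.  The novice's
rule fit has a slope near unity (δ ≈ 0.07), i.e. the next peak speed is
nearly proportional to the current peak acceleration, with the session's
residual noise in the scatter.  Merging the expert's blocked slow and
fast trials produces a clearly bimodal speed distribution (dip p < 0.01),
which is why the distributional analyses are always run per instructed
speed.

## Command line

```bash
kinesig simulate --config study.yaml --seed 3 --out session/
kinesig features --in session/ --out features.csv
kinesig fit-gamma --in features.csv --group subject_id,speed_level,context
kinesig rule-fit --in features.csv --segment retraction
kinesig signatures --in features.csv --report out/
kinesig run --config study.yaml --seed 3 --out out/   # full pipeline
```

Sessions travel as a tidy CSV (one row per time sample: identifiers,
condition labels, `t_s`, `x_m`, `y_m`, `z_m`) with a JSON metadata sidecar
carrying the recorded per-segment kinematics.

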