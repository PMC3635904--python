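"""Seeded synthetic kinematic sessions with the statistical structure the
analysis pipeline assumes.

The generator emulates a motion-capture study of repeated forward strikes
(with spontaneous retractions) performed by experts and novices at two
instructed speed levels under several training contexts:

* 100-120 trials per subject-speed condition, sampled at 240 Hz, trial
  durations inside 0.8-2.1 s;
* unimodal bell-shaped speed profiles for the strikes and curved
  retraction trajectories whose curvature splits by speed level;
* log-normally fluctuating peak speeds per (subject, speed, context);
* blocked versus randomly interleaved speed designs;
* trial-to-trial dependence following the first-order stochastic rule
  ln(vmax(t+1) + nu*vmax(t)) = m * ln(amax(t)) + b + eps, with nu =
  upsilon - 1 (upsilon = 10 by default) and configurable slope/intercept/
  residual-sd.

Two generation directions are provided.  The default, ``"vmax_first"``,
draws the peak-speed sequence from its log-normal law and derives amax by
exact inversion of the rule, which guarantees exact parameter recovery when
``eps_sd = 0`` and preserves the configured marginal speed laws.  With
``eps_sd > 0`` that inversion places the residual inside the regressor
(ln amax), so ordinary least squares on such data is attenuated; the
``"amax_first"`` direction instead fixes amax from the current state and an
intended next speed and lets the residual enter the response, which is the
mode to use when checking confidence-interval coverage of noisy rule fits.

The per-trial (vmax, amax) pairs that satisfy the rule are carried with the
session as instrument-grade recorded features (playing the role of capture
software that outputs velocity and acceleration directly); the raw traces
realize vmax exactly and amax approximately through the profile shape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinematics import TrialRecord, FEATURE_COLUMNS

_log = logging.getLogger(__name__)

UPSILON_DEFAULT = 10.0
SPEED_LEVELS = ("slow", "fast")
CONTEXTS = ("simulation", "mirror", "dark", "loads", "body_lights",
            "mirror_lights", "bag", "no_bag")
MAX_REDRAWS = 100


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeedLaw:
    """Log-normal law of the per-trial peak speed: ln vmax ~ N(log_mean, log_sd^2)."""

    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")

    @property
    def median(self) -> float:
        return math.exp(self.log_mean)

    def scaled(self, factor: float) -> "SpeedLaw":
        return SpeedLaw(self.log_mean + math.log(factor), self.log_sd)


@dataclass(frozen=True)
class RuleParams:
    """Parameters of the trial-to-trial stochastic rule."""

    m: float                 # slope of the log-log rule
    b: float                 # intercept
    eps_sd: float = 0.0      # sd of the (Gaussian) residual
    direction: str = "vmax_first"   # "vmax_first" | "amax_first"

    def __post_init__(self) -> None:
        if self.m == 0:
            raise ValueError("rule slope m = 0: inversion is degenerate")
        if self.eps_sd < 0:
            raise ValueError("eps_sd must be >= 0")
        if self.direction not in ("vmax_first", "amax_first"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated participant: class, speed laws and rule parameters.

    ``speed_laws`` maps ``(speed_level, context)`` to the log-normal law of
    the strike peak speed.  ``rule`` is either one :class:`RuleParams` used
    everywhere or a mapping ``speed_level -> RuleParams``.
    """

    subject_id: str
    cls: str                                        # "expert" | "novice"
    speed_laws: Mapping[Tuple[str, str], SpeedLaw]
    rule: Union[RuleParams, Mapping[str, RuleParams]]
    retraction_speed_scale: float = 0.85

    def __post_init__(self) -> None:
        if self.cls not in ("expert", "novice"):
            raise ValueError("class must be 'expert' or 'novice'")
        if not (0 < self.retraction_speed_scale <= 1.5):
            raise ValueError("retraction_speed_scale out of range")

    def law(self, speed_level: str, context: str) -> SpeedLaw:
        return self.speed_laws[(speed_level, context)]

    def rule_for(self, speed_level: str) -> RuleParams:
        if isinstance(self.rule, RuleParams):
            return self.rule
        return self.rule[speed_level]


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition configuration of the synthetic session generator."""

    subjects: Tuple[SubjectProfile, ...]
    speed_levels: Tuple[str, ...] = SPEED_LEVELS
    contexts: Tuple[str, ...] = ("simulation",)
    design: str = "blocked"                      # "random" | "blocked"
    trials_per_condition: int = 100
    sampling_rate: float = 240.0
    duration_range: Tuple[float, float] = (0.8, 2.1)
    duration_means: Mapping[str, float] = field(
        default_factory=lambda: {"slow": 1.6, "fast": 0.95})
    duration_cv: float = 0.07
    retraction_curvature: Mapping[str, float] = field(
        default_factory=lambda: {"slow": 0.12, "fast": 0.35})
    strike_curvature: float = 0.0
    upsilon: float = UPSILON_DEFAULT
    strike_span: float = 0.6                      # reach distance, m
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("at least one subject profile is required")
        if not self.speed_levels or not self.contexts:
            raise ValueError("empty condition set")
        if self.design not in ("random", "blocked"):
            raise ValueError("design must be 'random' or 'blocked'")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.duration_range
        if not (0.3 < lo < hi < 3.0):
            raise ValueError("duration_range must lie within (0.3, 3.0) s")
        if self.trials_per_condition < 2:
            raise ValueError("trials_per_condition must be >= 2")
        if self.upsilon <= 1:
            raise ValueError("upsilon must exceed 1 (nu = upsilon - 1 > 0)")

    @property
    def nu(self) -> float:
        return self.upsilon - 1.0


@dataclass
class SessionRecord:
    """A generated session: ordered trial segments plus recorded features."""

    session_id: str
    design: str
    sampling_rate: float
    upsilon: float
    seed: int
    trials: List[TrialRecord]
    features: pd.DataFrame        # instrument-grade per-segment kinematics

    @property
    def n_trials(self) -> int:
        return int(self.features["trial_index"].max()) if len(self.features) else 0

    @property
    def n_segments(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# Presets: study-condition subject profiles
# ---------------------------------------------------------------------------

def default_speed_laws(contexts: Sequence[str],
                       slow_median: float = 2.0,
                       fast_median: float = 5.0,
                       log_sd: float = 0.1) -> Dict[Tuple[str, str], SpeedLaw]:
    """Generic laws: slow strikes around 2 m/s, fast around 5 m/s."""
    laws: Dict[Tuple[str, str], SpeedLaw] = {}
    for ctx in contexts:
        laws[("slow", ctx)] = SpeedLaw(math.log(slow_median), log_sd)
        laws[("fast", ctx)] = SpeedLaw(math.log(fast_median), log_sd)
    return laws


def expert_profile(subject_id: str = "expert_1") -> SubjectProfile:
    """An expert: broad bandwidth of condition-wise peak-speed levels with
    tight (low noise-to-signal) fluctuations in every condition."""
    laws = {
        ("slow", "no_bag"): SpeedLaw(math.log(1.2), 0.06),
        ("slow", "bag"):    SpeedLaw(math.log(1.8), 0.06),
        ("fast", "no_bag"): SpeedLaw(math.log(3.5), 0.06),
        ("fast", "bag"):    SpeedLaw(math.log(5.0), 0.06),
    }
    return SubjectProfile(subject_id, "expert", laws,
                          RuleParams(m=0.69, b=1.84, eps_sd=0.04))


def novice_profile(subject_id: str = "novice_1") -> SubjectProfile:
    """A novice: narrow bandwidth, noisy fluctuations; the slow bag and
    no-bag conditions are statistically indistinguishable."""
    laws = {
        ("slow", "bag"):    SpeedLaw(math.log(1.60), 0.25),
        ("slow", "no_bag"): SpeedLaw(math.log(1.65), 0.25),
        ("fast", "bag"):    SpeedLaw(math.log(2.60), 0.25),
        ("fast", "no_bag"): SpeedLaw(math.log(3.10), 0.25),
    }
    return SubjectProfile(subject_id, "novice", laws,
                          RuleParams(m=1.03, b=0.87, eps_sd=0.12))


def default_config(seed: int = 0,
                   design: str = "blocked",
                   trials_per_condition: int = 100,
                   contexts: Sequence[str] = ("simulation",),
                   subject: Optional[SubjectProfile] = None) -> SynthConfig:
    """A single generic subject under the default speed laws."""
    if subject is None:
        subject = SubjectProfile(
            "subject_1", "novice", default_speed_laws(contexts),
            RuleParams(m=1.0, b=0.0, eps_sd=0.05))
    return SynthConfig(subjects=(subject,), contexts=tuple(contexts),
                       design=design,
                       trials_per_condition=trials_per_condition, seed=seed)


def cohort_config(seed: int = 0,
                  design: str = "blocked",
                  trials_per_condition: int = 100) -> SynthConfig:
    """The expert/novice bag-vs-no-bag comparison preset."""
    return SynthConfig(subjects=(expert_profile(), novice_profile()),
                       contexts=("bag", "no_bag"), design=design,
                       trials_per_condition=trials_per_condition, seed=seed)


# ---------------------------------------------------------------------------
# Peak-speed / peak-acceleration sequences under the stochastic rule
# ---------------------------------------------------------------------------

def generate_vmax_sequence(law: SpeedLaw,
                           rule: RuleParams,
                           n: int,
                           rng: Union[int, np.random.Generator],
                           upsilon: float = UPSILON_DEFAULT,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Ordered (vmax, amax) pairs satisfying the stochastic rule.

    ``vmax_first`` draws ``n + 1`` peak speeds i.i.d. from the log-normal
    law and inverts the rule, ``amax(t) = exp[(ln(vmax(t+1) + nu*vmax(t)) -
    b - eps_t) / m]``; regressing ln(vmax(t+1) + nu*vmax(t)) on ln amax(t)
    then recovers (m, b) exactly when ``eps_sd = 0``.

    ``amax_first`` draws an intended next speed s(t+1) from the law, fixes
    ``ln amax(t) = (ln(s(t+1) + nu*vmax(t)) - b) / m`` from the current
    state, and realizes ``vmax(t+1) = amax(t)^m * e^(b + eps_t) -
    nu*vmax(t)``; the residual then lives in the response, so least-squares
    confidence intervals have their nominal coverage.  Residuals that would
    drive vmax(t+1) nonpositive are redrawn (up to 100 times, logged).
    """
    if n < 2:
        raise ValueError("need n >= 2 trials")
    if upsilon <= 1:
        raise ValueError("upsilon must exceed 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    nu = upsilon - 1.0

    if rule.direction == "vmax_first":
        v = rng.lognormal(law.log_mean, law.log_sd, size=n + 1)
        eps = rng.normal(0.0, rule.eps_sd, size=n) if rule.eps_sd > 0 \
            else np.zeros(n)
        combined = v[1:] + nu * v[:-1]
        amax = np.exp((np.log(combined) - rule.b - eps) / rule.m)
        return v[:n], amax

    # amax_first: causal realization with the residual in the response
    v = np.empty(n + 1)
    amax = np.empty(n)
    v[0] = rng.lognormal(law.log_mean, law.log_sd)
    for t in range(n):
        s_next = rng.lognormal(law.log_mean, law.log_sd)
        x = (math.log(s_next + nu * v[t]) - rule.b) / rule.m
        amax[t] = math.exp(x)
        for attempt in range(MAX_REDRAWS + 1):
            eps = rng.normal(0.0, rule.eps_sd) if rule.eps_sd > 0 else 0.0
            v_next = math.exp(rule.m * x + rule.b + eps) - nu * v[t]
            if v_next > 0:
                break
        else:
            raise RuntimeError(
                f"trial {t}: could not draw a positive next vmax "
                f"after {MAX_REDRAWS} redraws")
        if attempt:
            _log.debug("trial %d: redrew residual %d time(s) to keep "
                       "vmax positive", t, attempt)
        v[t + 1] = v_next
    return v[:n], amax


# ---------------------------------------------------------------------------
# Speed profiles
# ---------------------------------------------------------------------------

def generate_speed_profile(vmax: float,
                           duration: float,
                           sampling_rate: float,
                           peak_fraction: float = 0.5,
                           sharpness: float = 4.0) -> np.ndarray:
    """A unimodal bell-shaped speed profile scaled to the requested maximum.

    The template is ``g(tau) = tau^(c*p) * (1 - tau)^(c*(1-p))`` with peak
    at ``tau = p`` (``peak_fraction``) and concentration ``c``
    (``sharpness``); ``p = 0.5`` gives the symmetric minimum-jerk-like
    bell.  The series has exactly one local maximum, is nonnegative, starts
    and ends near zero, and its discrete maximum equals ``vmax`` exactly.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0.0 < peak_fraction < 1.0):
        raise ValueError("peak_fraction must lie in (0, 1)")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    n = max(int(round(duration * sampling_rate)), 5)
    tau = np.arange(1, n + 1) / (n + 1)
    alpha = sharpness * peak_fraction
    beta = sharpness * (1.0 - peak_fraction)
    g = tau ** alpha * (1.0 - tau) ** beta
    return vmax * g / np.max(g)


def _rise_k(beta: float) -> float:
    """Peak-acceleration factor k(beta) of the early-peaked profile family
    g(tau) = tau*(1-tau)^beta: analytic peak acceleration = vmax*k/duration."""
    return (1.0 + beta) * ((1.0 + beta) / beta) ** beta


_BETA_RANGE = (1.05, 40.0)


def _solve_profile_shape(vmax: float, amax: float, duration: float,
                         ) -> tuple[float, float]:
    """(peak_fraction, sharpness) of the profile whose analytic peak
    acceleration matches ``amax``; clamped to the representable family."""
    k_target = amax * duration / vmax
    k_lo, k_hi = _rise_k(_BETA_RANGE[0]), _rise_k(_BETA_RANGE[1])
    if k_target <= k_lo:
        beta = _BETA_RANGE[0]
    elif k_target >= k_hi:
        beta = _BETA_RANGE[1]
    else:
        beta = brentq(lambda b: _rise_k(b) - k_target, *_BETA_RANGE)
    return 1.0 / (1.0 + beta), 1.0 + beta


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def generate_trajectory(profile: np.ndarray,
                        sampling_rate: float,
                        start: Sequence[float],
                        end: Sequence[float],
                        bend: float = 0.0) -> np.ndarray:
    """3D positions integrating a speed profile along a straight or bent path.

    ``bend`` is the dimensionless sagitta ratio of a planar circular arc:
    the maximal perpendicular deviation from the chord equals ``bend *
    chord/2`` (``bend = 0`` gives an exactly straight path, ``bend = 1`` a
    semicircle).  The path starts at ``start`` and heads toward ``end``;
    its arc length equals the time integral of the speed profile, so the
    realized chord scales with the distance actually traveled.
    """
    profile = np.asarray(profile, dtype=float)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if np.allclose(start, end):
        raise ValueError("start and end must be distinct")
    if bend < 0:
        raise ValueError("bend must be >= 0")
    if bend > 1:
        raise ValueError("bend > 1 (beyond a semicircle) is not supported")
    dt = 1.0 / sampling_rate
    s = np.cumsum(profile) * dt          # arc length at each sample
    total = s[-1]
    if total <= 0:
        raise ValueError("speed profile integrates to zero length")
    t_hat = (end - start) / np.linalg.norm(end - start)
    if bend < 1e-12:
        return start + np.outer(s, t_hat)
    # unit-chord circular arc with sagitta h = bend/2, scaled so that the
    # arc length equals the traveled distance
    h1 = bend / 2.0
    R1 = (0.25 + h1 * h1) / (2.0 * h1)
    theta = math.asin(min(0.5 / R1, 1.0))
    if abs(2.0 * R1 * math.sin(theta) - 1.0) > 1e-9:   # h > c/2 branch
        theta = math.pi - theta
    arclen1 = 2.0 * R1 * theta
    c = total / arclen1                   # realized chord length
    R, h = R1 * c, h1 * c
    n_hat = _perpendicular_unit(t_hat)
    phi = -theta + (s / total) * 2.0 * theta
    xi = R * np.sin(phi) + c / 2.0        # along-chord offset from start
    eta = R * np.cos(phi) - (R - h)       # perpendicular offset
    return start + np.outer(xi, t_hat) + np.outer(eta, n_hat)


def _perpendicular_unit(t_hat: np.ndarray) -> np.ndarray:
    """A deterministic unit vector orthogonal to ``t_hat``."""
    e = np.zeros(3)
    e[int(np.argmin(np.abs(t_hat)))] = 1.0
    n = e - (e @ t_hat) * t_hat
    return n / np.linalg.norm(n)


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def _condition_order(config: SynthConfig, subject: SubjectProfile,
                     rng: np.random.Generator) -> List[tuple[str, str, str]]:
    """Chronological (context, speed_level, block) labels for every trial."""
    order: List[tuple[str, str, str]] = []
    for ctx in config.contexts:
        if config.design == "blocked":
            for level in config.speed_levels:
                block = f"{ctx}:{level}"
                order.extend((ctx, level, block)
                             for _ in range(config.trials_per_condition))
        else:
            levels = np.repeat(config.speed_levels,
                               config.trials_per_condition)
            rng.shuffle(levels)
            block = f"{ctx}:random"
            order.extend((ctx, str(level), block) for level in levels)
    return order


def generate_session(config: SynthConfig) -> SessionRecord:
    """Generate one full seeded session for every configured subject.

    Trials are emitted in acquisition order; each trial contributes a
    strike and a retraction segment.  Within each (subject, context,
    speed-level) condition the recorded (vmax, amax) sequence satisfies the
    subject's stochastic rule along that condition's own trial order.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(len(config.subjects))
    trials: List[TrialRecord] = []
    rows: List[dict] = []
    session_id = f"synth-{config.seed}"

    for subject, sseq in zip(config.subjects, subject_seeds):
        rng = np.random.default_rng(sseq)
        order = _condition_order(config, subject, rng)
        # draw rule-consistent (vmax, amax) per condition, then interleave
        counts: Dict[tuple[str, str], int] = {}
        for ctx, level, _ in order:
            counts[(level, ctx)] = counts.get((level, ctx), 0) + 1
        streams: Dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (level, ctx), cnt in counts.items():
            rule = subject.rule_for(level)
            law = subject.law(level, ctx)
            streams[("strike", level, ctx)] = generate_vmax_sequence(
                law, rule, cnt, rng, config.upsilon)
            streams[("retraction", level, ctx)] = generate_vmax_sequence(
                law.scaled(subject.retraction_speed_scale), rule, cnt, rng,
                config.upsilon)
        cursor: Dict[tuple[str, str], int] = {k: 0 for k in counts}

        for ti, (ctx, level, block) in enumerate(order, start=1):
            i = cursor[(level, ctx)]
            cursor[(level, ctx)] += 1
            for segment in ("strike", "retraction"):
                vmax_arr, amax_arr = streams[(segment, level, ctx)]
                vmax, amax = float(vmax_arr[i]), float(amax_arr[i])
                mean_d = config.duration_means[level]
                duration = float(np.clip(
                    rng.normal(mean_d, config.duration_cv * mean_d),
                    *config.duration_range))
                pf, sharp = _solve_profile_shape(vmax, amax, duration)
                profile = generate_speed_profile(
                    vmax, duration, config.sampling_rate, pf, sharp)
                if segment == "strike":
                    a, b = np.zeros(3), np.array([config.strike_span, 0., 0.])
                    bend = config.strike_curvature
                else:
                    a, b = np.array([config.strike_span, 0., 0.]), np.zeros(3)
                    bend = config.retraction_curvature[level]
                pos = generate_trajectory(profile, config.sampling_rate,
                                          a, b, bend)
                time = np.arange(len(profile)) / config.sampling_rate
                trials.append(TrialRecord(
                    session_id=session_id, subject_id=subject.subject_id,
                    trial_index=ti, segment=segment, speed_level=level,
                    context=ctx, design=config.design, block=block,
                    time=time, position=pos))
                ipk = int(np.argmax(profile))
                mean_speed = float(np.mean(profile))
                rows.append({
                    "session_id": session_id,
                    "subject_id": subject.subject_id,
                    "trial_index": ti, "segment": segment,
                    "speed_level": level, "context": ctx,
                    "design": config.design, "block": block,
                    "vmax": vmax, "amax": amax,
                    "t_peak": time[ipk],
                    "duration": float(time[-1]),
                    "mean_speed": mean_speed,
                    "norm_vmax": vmax / (vmax + mean_speed),
                })

    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return SessionRecord(session_id=session_id, design=config.design,
                         sampling_rate=config.sampling_rate,
                         upsilon=config.upsilon, seed=config.seed,
                         trials=trials, features=features)
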