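"""Per-trial kinematics: smooth differentiation, segmentation, scalar
features and trajectory-geometry (linearity) measures.

The raw material is a time-stamped 3D hand trajectory sampled uniformly
(240 Hz in the motion-capture sessions this package emulates).  Speed and
acceleration are obtained by Savitzky-Golay (polynomial-window) smoothing
and differentiation of the position series; jerk is deliberately never
computed, since third derivatives of smoothed capture data amplify
instrumentation error.  The scalar feature of primary interest is the peak
hand speed ``vmax`` and its allometry-free normalization
``vmax / (vmax + mean_speed)``, a scale-invariant quantity in [0.5, 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

_log = logging.getLogger(__name__)

#: Default Savitzky-Golay parameters (samples / polynomial order) used to
#: smooth and differentiate 240 Hz position data.
DEFAULT_SMOOTHING_WINDOW = 11
DEFAULT_POLYORDER = 3

_TIME_UNIFORMITY_TOL = 1e-9

SEGMENTS = ("strike", "retraction")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One movement segment of one trial: a uniformly sampled 3D trajectory.

    ``segment`` distinguishes the goal-directed forward strike from the
    spontaneous retraction.  ``speed`` and ``acceleration`` are derived
    magnitudes (m/s, m/s^2); they are ``None`` until :meth:`derive` or
    :func:`differentiate_smooth` fills them.
    """

    session_id: str
    subject_id: str
    trial_index: int            # 1-based acquisition order within the session
    segment: str                # "strike" | "retraction"
    speed_level: str            # "slow" | "fast"
    context: str                # training context label
    design: str                 # "random" | "blocked"
    block: str                  # condition-block label (chronological unit)
    time: np.ndarray            # seconds, uniform spacing
    position: np.ndarray        # (n, 3) meters
    speed: Optional[np.ndarray] = None
    acceleration: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 2 or self.position.shape[1] != 3:
            raise ValueError("position must be an (n, 3) array")
        if len(self.time) != len(self.position):
            raise ValueError("time and position lengths differ")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > _TIME_UNIFORMITY_TOL:
                raise ValueError("time spacing is not uniform")
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment label {self.segment!r}")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def derive(self,
               smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
               polyorder: int = DEFAULT_POLYORDER) -> "TrialRecord":
        """Return a copy with speed and acceleration series filled in."""
        speed, accel = differentiate_smooth(
            self.position, self.sampling_rate, smoothing_window, polyorder)
        return replace(self, speed=speed, acceleration=accel)


@dataclass(frozen=True)
class TrialFeatures:
    """Scalar per-segment kinematics."""

    vmax: float          # peak speed, m/s
    amax: float          # peak acceleration magnitude, m/s^2
    t_peak: float        # time of peak speed relative to segment start, s
    duration: float      # segment duration, s
    mean_speed: float    # time-averaged speed over the segment, m/s
    norm_vmax: float     # vmax / (vmax + mean_speed), dimensionless

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_speed <= self.vmax * (1 + 1e-12)):
            raise ValueError("require 0 < mean_speed <= vmax")
        if not (0.5 - 1e-12 <= self.norm_vmax < 1.0):
            raise ValueError("norm_vmax must lie in [0.5, 1)")


@dataclass(frozen=True)
class LinearityProfile:
    """Perpendicular deviations of a time-normalized, resampled trajectory
    from the straight start-end chord (the linearity index)."""

    n_frames: int
    deviations: np.ndarray       # meters, one per resampled frame
    chord_length: float
    superposition_error: float   # max distance original->resampled polyline

    @property
    def max_deviation(self) -> float:
        return float(np.max(self.deviations))

    @property
    def mean_deviation(self) -> float:
        return float(np.mean(self.deviations))

    @property
    def median_deviation(self) -> float:
        return float(np.median(self.deviations))

    @property
    def superposition_ok(self) -> bool:
        """True when resampling preserved the original curve (max distance
        below 0.5% of the chord length)."""
        return bool(self.superposition_error < 5e-3 * self.chord_length)


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------

def differentiate_smooth(position: np.ndarray,
                         sampling_rate: float,
                         smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                         polyorder: int = DEFAULT_POLYORDER,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Speed and acceleration magnitudes from a 3D position series.

    A Savitzky-Golay filter fits a local polynomial of order ``polyorder``
    over ``smoothing_window`` samples and evaluates its first and second
    derivatives, giving low-pass smoothed velocity and acceleration in one
    pass.  Polynomial trajectories of degree <= ``polyorder`` are
    differentiated exactly (including at the boundaries).

    Returns ``(speed, acceleration)`` with ``speed = |dx/dt|`` and
    ``acceleration = |d^2x/dt^2|`` (vector magnitudes).
    """
    from scipy.signal import savgol_filter

    position = np.atleast_2d(np.asarray(position, dtype=float))
    if position.shape[0] < 5:
        raise ValueError("need at least 5 samples to differentiate")
    if smoothing_window % 2 == 0 or smoothing_window < 5:
        raise ValueError("smoothing_window must be odd and >= 5")
    if smoothing_window > position.shape[0]:
        raise ValueError("smoothing_window exceeds series length")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    delta = 1.0 / sampling_rate
    vel = savgol_filter(position, smoothing_window, polyorder,
                        deriv=1, delta=delta, axis=0)
    acc = savgol_filter(position, smoothing_window, polyorder,
                        deriv=2, delta=delta, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    accel = np.linalg.norm(acc, axis=1)
    return speed, accel


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_strike_retraction(speed: np.ndarray,
                              min_prominence_frac: float = 0.05,
                              ) -> tuple[slice, Optional[slice]]:
    """Split a full-trial speed profile into strike and retraction.

    The full forward-and-back movement shows two speed bells separated by a
    dip; the split index is the deepest interior minimum between the two
    largest peaks (earliest sample on ties).  Both returned segments share
    the junction sample.  A monotone or single-peak profile cannot be split:
    the whole series is returned as a single segment together with ``None``
    and a warning.
    """
    from scipy.signal import find_peaks

    speed = np.asarray(speed, dtype=float)
    n = len(speed)
    prominence = min_prominence_frac * float(np.max(speed)) if n else 0.0
    peaks, props = find_peaks(speed, prominence=prominence)
    if len(peaks) < 2:
        warnings.warn("speed profile has fewer than two peaks; "
                      "returning a single segment", stacklevel=2)
        return slice(0, n), None
    # the two largest peaks, in temporal order
    order = np.argsort(speed[peaks])[::-1][:2]
    p1, p2 = sorted(peaks[order])
    split = p1 + int(np.argmin(speed[p1:p2 + 1]))
    return slice(0, split + 1), slice(split, n)


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------

def extract_features(trial: TrialRecord,
                     segment: Optional[slice] = None,
                     smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                     polyorder: int = DEFAULT_POLYORDER) -> TrialFeatures:
    """Scalar kinematic features of one movement segment.

    ``vmax``/``amax`` are the segment maxima of speed and acceleration,
    ``t_peak`` the time of ``vmax`` relative to segment start,
    ``mean_speed`` the time average of the instantaneous speed, and
    ``norm_vmax = vmax / (vmax + mean_speed)``.
    """
    if trial.speed is None or trial.acceleration is None:
        trial = trial.derive(smoothing_window, polyorder)
    if segment is None:
        segment = slice(0, trial.n_samples)
    speed = trial.speed[segment]
    accel = trial.acceleration[segment]
    time = trial.time[segment]
    if len(speed) < 5:
        raise ValueError("segment must contain at least 5 samples")
    if not np.any(speed > 0):
        raise ValueError("segment speed is identically zero")
    ipk = int(np.argmax(speed))
    vmax = float(speed[ipk])
    mean_speed = float(np.mean(speed))
    return TrialFeatures(
        vmax=vmax,
        amax=float(np.max(accel)),
        t_peak=float(time[ipk] - time[0]),
        duration=float(time[-1] - time[0]),
        mean_speed=mean_speed,
        norm_vmax=vmax / (vmax + mean_speed),
    )


def normalized_peak_speed(vmax: float, mean_speed: float) -> float:
    """``vmax / (vmax + mean_speed)``: scale-invariant, in [0.5, 1)."""
    if vmax <= 0 or mean_speed <= 0:
        raise ValueError("speeds must be positive")
    return vmax / (vmax + mean_speed)


# ---------------------------------------------------------------------------
# Trajectory linearity
# ---------------------------------------------------------------------------

def _resample_curve(position: np.ndarray, n_frames: int,
                    mode: str) -> np.ndarray:
    n = len(position)
    if mode == "time":
        u = np.linspace(0.0, 1.0, n)
    elif mode == "arclength":
        seg = np.linalg.norm(np.diff(position, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] <= 0:
            raise ValueError("degenerate curve: zero arc length")
        u = s / s[-1]
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    uu = np.linspace(0.0, 1.0, n_frames)
    return np.column_stack([np.interp(uu, u, position[:, k])
                            for k in range(3)])


def _max_dist_to_polyline(points: np.ndarray, poly: np.ndarray) -> float:
    """Max distance from each point to the nearest segment of a polyline."""
    a, b = poly[:-1], poly[1:]                     # (M-1, 3)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    worst = 0.0
    for p in points:
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        worst = max(worst, float(np.min(np.linalg.norm(p - proj, axis=1))))
    return worst


def linearity_profile(position: np.ndarray,
                      n_frames: int = 100,
                      mode: str = "time") -> LinearityProfile:
    """Linearity index of a 3D trajectory.

    The curve is resampled to ``n_frames`` equally spaced points in
    normalized time (``mode="arclength"`` resamples along normalized arc
    length instead), and each resampled point is projected at a right angle
    onto the straight start-end chord; the returned deviations are the
    perpendicular distances, zero at both endpoints by construction.  The
    superposition error checks that resampling preserved the original curve.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 2 or position.shape[1] != 3:
        raise ValueError("position must be an (n, 3) array")
    if len(position) < 3:
        raise ValueError("need at least 3 points")
    if n_frames < 3:
        raise ValueError("n_frames must be >= 3")
    chord = position[-1] - position[0]
    chord_length = float(np.linalg.norm(chord))
    if chord_length <= 0:
        raise ValueError("coincident endpoints: linearity undefined")
    resampled = _resample_curve(position, n_frames, mode)
    rel = resampled - position[0]
    u_hat = chord / chord_length
    along = rel @ u_hat
    perp = rel - np.outer(along, u_hat)
    deviations = np.linalg.norm(perp, axis=1)
    sup_err = _max_dist_to_polyline(position, resampled)
    return LinearityProfile(n_frames=n_frames,
                            deviations=deviations,
                            chord_length=chord_length,
                            superposition_error=sup_err)


# ---------------------------------------------------------------------------
# Session-level feature table
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "session_id", "subject_id", "trial_index", "segment", "speed_level",
    "context", "design", "block", "vmax", "amax", "t_peak", "duration",
    "mean_speed", "norm_vmax",
]


def features_table(session,
                   use_recorded: bool = True,
                   smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                   polyorder: int = DEFAULT_POLYORDER) -> pd.DataFrame:
    """One feature row per movement segment of a session.

    With ``use_recorded=True`` (default) the instrument-grade kinematics
    recorded with the session are returned, mirroring capture software that
    outputs velocity and acceleration directly.  With ``use_recorded=False``
    every feature is re-derived from the raw position traces through
    :func:`differentiate_smooth` and :func:`extract_features`.
    """
    recorded = getattr(session, "features", None)
    if use_recorded and recorded is not None:
        return recorded.copy()
    rows = []
    for trial in session.trials:
        feats = extract_features(trial, smoothing_window=smoothing_window,
                                 polyorder=polyorder)
        rows.append({
            "session_id": trial.session_id,
            "subject_id": trial.subject_id,
            "trial_index": trial.trial_index,
            "segment": trial.segment,
            "speed_level": trial.speed_level,
            "context": trial.context,
            "design": trial.design,
            "block": trial.block,
            "vmax": feats.vmax,
            "amax": feats.amax,
            "t_peak": feats.t_peak,
            "duration": feats.duration,
            "mean_speed": feats.mean_speed,
            "norm_vmax": feats.norm_vmax,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
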