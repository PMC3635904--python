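"""Gamma-plane signature trajectories, gain classification, nonparametric
condition comparisons, fatigue checks and expertise criteria.

A performer's stochastic signature — the MLE (shape, scale) point of the
Gamma fit to their peak-speed fluctuations — is tracked chronologically
across condition blocks.  A shift toward larger shape moves toward the
symmetric, predictive Gaussian range of the Gamma plane (positive gain); a
shift toward smaller shape moves toward the memoryless Exponential range
(negative gain).  Expertise combines two ingredients: a broad bandwidth of
condition-wise distribution locations and low noise-to-signal (Fano)
ratios that keep the per-condition distributions separable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import GammaSignature, fit_gamma_mle, MIN_GAMMA_N

_log = logging.getLogger(__name__)

#: Relative shape change below which a signature shift counts as neutral.
NEUTRAL_SHIFT_TOL = 0.05

#: Default expertise thresholds: minimal bandwidth (ratio of largest to
#: smallest condition-wise Gamma mean) and maximal tolerated Fano factor.
#: Calibrated once on the generator's expert/novice presets.
BANDWIDTH_THRESHOLD = 2.5
FANO_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureTrajectory:
    """Chronologically ordered Gamma-plane points with shift classes."""

    labels: Tuple[str, ...]
    signatures: Tuple[GammaSignature, ...]
    transitions: Tuple[str, ...]          # one per consecutive pair

    def __len__(self) -> int:
        return len(self.signatures)


@dataclass(frozen=True)
class ExpertiseProfile:
    """Bandwidth / noise-to-signal summary of per-condition signatures."""

    bandwidth: float                     # max condition mean / min mean
    max_fano: float
    separability: Mapping[Tuple[str, str], bool]
    expert_like: bool
    bandwidth_threshold: float
    fano_threshold: float

    @property
    def n_separable_pairs(self) -> int:
        return sum(self.separability.values())


@dataclass(frozen=True)
class ComparisonRow:
    """One Table-style row of a nonparametric condition comparison."""

    test: str
    groups: Tuple[str, ...]
    statistic: float
    p_value: float
    medians: Tuple[float, ...]
    ranges: Tuple[Tuple[float, float], ...]


@dataclass(frozen=True)
class FatigueReport:
    """First-k versus last-k trial comparison within one block."""

    k: int
    vmax_p: float
    duration_p: float
    vmax_statistic: float
    duration_statistic: float

    def fatigued(self, alpha: float = 0.05) -> bool:
        return self.vmax_p < alpha or self.duration_p < alpha


# ---------------------------------------------------------------------------
# Signature trajectories
# ---------------------------------------------------------------------------

def signature_trajectory(features: pd.DataFrame,
                         value_column: str = "vmax",
                         group_column: str = "block",
                         window: Optional[int] = None,
                         neutral_tol: float = NEUTRAL_SHIFT_TOL,
                         ) -> SignatureTrajectory:
    """One Gamma MLE point per chronological group of trials.

    Groups are either the condition blocks (``group_column``, in order of
    first appearance) or, when ``window`` is given, consecutive
    non-overlapping windows of that many trials.  Groups smaller than the
    Gamma-MLE minimum are skipped with a warning.
    """
    if window is not None:
        order = np.arange(len(features))
        group_ids = [f"window_{i // window}" for i in order]
        frame = features.assign(_group=group_ids)
        key = "_group"
    else:
        frame = features
        key = group_column
    labels: List[str] = []
    sigs: List[GammaSignature] = []
    for label, grp in frame.groupby(key, sort=False):
        values = grp[value_column].to_numpy(dtype=float)
        if len(values) < MIN_GAMMA_N:
            _log.warning("group %r has %d < %d trials; skipped",
                         label, len(values), MIN_GAMMA_N)
            continue
        labels.append(str(label))
        sigs.append(fit_gamma_mle(values))
    transitions = tuple(classify_shift(a, b, neutral_tol)
                        for a, b in zip(sigs[:-1], sigs[1:]))
    return SignatureTrajectory(tuple(labels), tuple(sigs), transitions)


def classify_shift(origin: GammaSignature,
                   target: GammaSignature,
                   neutral_tol: float = NEUTRAL_SHIFT_TOL) -> str:
    """Gain class of a Gamma-plane shift.

    A rightward shape shift (toward the symmetric Gaussian range) is
    ``positive_gain``; a leftward shift toward the memoryless Exponential
    range is ``negative_gain``; shape changes below ``neutral_tol`` of the
    smaller shape are ``neutral``.
    """
    d = target.shape - origin.shape
    if abs(d) < neutral_tol * min(origin.shape, target.shape):
        return "neutral"
    return "positive_gain" if d > 0 else "negative_gain"


# ---------------------------------------------------------------------------
# Nonparametric comparisons
# ---------------------------------------------------------------------------

def compare_conditions(groups: Mapping[str, Sequence[float]],
                       test: str = "ranksum") -> ComparisonRow:
    """Rank-based comparison of feature values across condition groups.

    ``ranksum`` (two groups, Wilcoxon rank-sum / Mann-Whitney; exact when
    samples are small and tie-free), ``kruskal_wallis`` (>= 2 independent
    groups) or ``friedman`` (>= 3 paired samples of equal length).
    """
    names = tuple(groups.keys())
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if test == "ranksum":
        if len(samples) != 2:
            raise ValueError("ranksum compares exactly two groups")
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided",
                                 use_continuity=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        if len(samples) < 2:
            raise ValueError("need at least two groups")
        res = stats.kruskal(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "friedman":
        if len(samples) < 3:
            raise ValueError("the Friedman test needs >= 3 paired samples")
        if len({len(s) for s in samples}) != 1:
            raise ValueError("friedman requires a paired (equal-length) "
                             "layout")
        res = stats.friedmanchisquare(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonRow(
        test=test, groups=names, statistic=stat, p_value=min(p, 1.0),
        medians=tuple(float(np.median(s)) for s in samples),
        ranges=tuple((float(np.min(s)), float(np.max(s))) for s in samples))


def comparison_table(features: pd.DataFrame,
                     value_column: str = "vmax",
                     by: Sequence[str] = ("speed_level",),
                     within: Sequence[str] = ("segment",),
                     test: str = "ranksum") -> pd.DataFrame:
    """Median/range/p rows comparing ``by`` groups within each ``within``
    stratum (the session-report table of condition effects)."""
    rows = []
    for keys, stratum in features.groupby(list(within), sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        grouped = {str(k): g[value_column].to_numpy(dtype=float)
                   for k, g in stratum.groupby(list(by), sort=False)}
        if len(grouped) < 2:
            continue
        if test == "ranksum" and len(grouped) != 2:
            use = "kruskal_wallis"
        else:
            use = test
        row = compare_conditions(grouped, use)
        for name, med, rng in zip(row.groups, row.medians, row.ranges):
            rows.append({
                **dict(zip(within, keys)),
                "group": name, "median": med,
                "min": rng[0], "max": rng[1],
                "test": row.test, "statistic": row.statistic,
                "p_value": row.p_value,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fatigue
# ---------------------------------------------------------------------------

def fatigue_check(block_features: pd.DataFrame, k: int = 10) -> FatigueReport:
    """Compare vmax and movement duration over the first k and last k
    trials of a same-speed block (rank-sum tests); long sessions show
    fatigue first in the durations."""
    n = len(block_features)
    if k < 1 or n < 2 * k:
        raise ValueError(f"block of {n} trials cannot support first/last "
                         f"{k} comparison")
    frame = block_features.sort_values("trial_index")
    first, last = frame.iloc[:k], frame.iloc[-k:]
    v = compare_conditions({"first": first["vmax"], "last": last["vmax"]},
                           "ranksum")
    d = compare_conditions({"first": first["duration"],
                            "last": last["duration"]}, "ranksum")
    return FatigueReport(k=k, vmax_p=v.p_value, duration_p=d.p_value,
                         vmax_statistic=v.statistic,
                         duration_statistic=d.statistic)


# ---------------------------------------------------------------------------
# Expertise
# ---------------------------------------------------------------------------

def expertise_profile(signatures: Mapping[str, GammaSignature],
                      bandwidth_threshold: float = BANDWIDTH_THRESHOLD,
                      fano_threshold: float = FANO_THRESHOLD,
                      level: float = 0.95) -> ExpertiseProfile:
    """Bandwidth, worst-case Fano and pairwise separability of a set of
    per-condition Gamma signatures.

    Two conditions are separable when the central ``level`` probability
    intervals of their fitted pdfs do not overlap.  ``expert_like``
    requires both broad bandwidth (>= threshold) and a low worst-case
    noise-to-signal ratio (<= threshold).
    """
    if len(signatures) < 2:
        raise ValueError("need at least two conditions")
    names = list(signatures.keys())
    means = {k: s.mean for k, s in signatures.items()}
    bandwidth = max(means.values()) / min(means.values())
    max_fano = max(s.fano for s in signatures.values())
    intervals = {k: s.central_interval(level) for k, s in signatures.items()}
    separability: Dict[Tuple[str, str], bool] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            lo_a, hi_a = intervals[a]
            lo_b, hi_b = intervals[b]
            separability[(a, b)] = bool(hi_a < lo_b or hi_b < lo_a)
    return ExpertiseProfile(
        bandwidth=float(bandwidth), max_fano=float(max_fano),
        separability=separability,
        expert_like=bool(bandwidth >= bandwidth_threshold
                         and max_fano <= fano_threshold),
        bandwidth_threshold=bandwidth_threshold,
        fano_threshold=fano_threshold)


def condition_signatures(features: pd.DataFrame,
                         value_column: str = "vmax",
                         by: Sequence[str] = ("speed_level", "context"),
                         ) -> Dict[str, GammaSignature]:
    """Fit one Gamma signature per condition (undersized groups skipped)."""
    out: Dict[str, GammaSignature] = {}
    for keys, grp in features.groupby(list(by), sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        label = "-".join(str(k) for k in keys)
        values = grp[value_column].to_numpy(dtype=float)
        if len(values) < MIN_GAMMA_N:
            _log.warning("condition %s has too few trials; skipped", label)
            continue
        out[label] = fit_gamma_mle(values)
    return out
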