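"""The first-order trial-to-trial stochastic rule linking peak speed and
peak acceleration.

Writing vmax(t) and amax(t) for the peak speed and peak acceleration of
trial t, consecutive trials are connected through the log-log linear rule

    ln(vmax(t+1) + nu * vmax(t)) = m * ln(amax(t)) + b + eps,

where nu = upsilon - 1 with upsilon = 10, a normalization chosen once for
the whole cohort from the range of speed/acceleration values it spans.
The slope decomposes as m = 1 - delta; exponentiating and expanding to
leading order in delta gives the anticipatory updating form

    vmax(t+1) = amax(t) * (1 - delta * ln amax(t)) * e^(b + eps)
                - nu * vmax(t) + O(delta^2),

so that |delta| measures how far the update departs from direct
proportionality to the previous trial's acceleration.  Fits are ordinary
least squares (single line, or one line per instructed speed level); the
pooled-versus-split choice is made by a nested-model F-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

_log = logging.getLogger(__name__)

UPSILON_DEFAULT = 10.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleScatter:
    """Per-pair points (x = ln amax(t), y = ln(vmax(t+1) + nu*vmax(t)))."""

    x: np.ndarray
    y: np.ndarray
    speed_level: np.ndarray      # label of trial t, per point
    context: np.ndarray
    upsilon: float

    def __post_init__(self) -> None:
        for arr in (self.x, self.y, self.speed_level, self.context):
            if len(arr) != len(self.x):
                raise ValueError("scatter arrays must share one length")

    @property
    def nu(self) -> float:
        return self.upsilon - 1.0

    def __len__(self) -> int:
        return len(self.x)

    def level_subset(self, level: str) -> "RuleScatter":
        mask = self.speed_level == level
        return RuleScatter(self.x[mask], self.y[mask],
                           self.speed_level[mask], self.context[mask],
                           self.upsilon)


@dataclass(frozen=True)
class RuleFit:
    """OLS fit of the log-log rule with regression diagnostics."""

    m: float                      # slope (p1)
    b: float                      # intercept (p2)
    ci_m: Tuple[float, float]     # 95% CIs
    ci_b: Tuple[float, float]
    sse: float
    r_squared: float
    adj_r_squared: float
    rmse: float                   # sqrt(SSE / (n - 2))
    n_points: int
    mode: str = "single"          # "single" | "per_level"
    per_level: Dict[str, "RuleFit"] = field(default_factory=dict)

    @property
    def delta(self) -> float:
        """delta = 1 - m, the departure from unit slope."""
        return 1.0 - self.m


@dataclass(frozen=True)
class SplitDecision:
    decision: str                 # "single" | "per_level"
    f_statistic: float
    p_value: float
    alpha: float


@dataclass(frozen=True)
class PowerForm:
    """Leading-order expansion report of the exponentiated rule."""

    delta: float
    delta_squared: float
    remainder_bound: float        # max |amax^m - amax*(1 - delta*ln amax)| * e^b
    amax_range: Tuple[float, float]
    summary: str


# ---------------------------------------------------------------------------
# Scatter construction
# ---------------------------------------------------------------------------

def build_rule_scatter(features: pd.DataFrame,
                       upsilon: float = UPSILON_DEFAULT,
                       exclude_block_boundaries: bool = True) -> RuleScatter:
    """One scatter point per consecutive trial pair, in acquisition order.

    ``features`` must carry one row per trial (a single segment type) with
    columns ``trial_index`` (strictly increasing), ``vmax``, ``amax`` and
    the condition labels ``speed_level``/``context``/``block``.  Labels are
    carried from trial t.  Pairs that span a block/context change are
    excluded by default, since the rule is stated within one task context.
    """
    if upsilon <= 1:
        raise ValueError("upsilon must exceed 1")
    if len(features) < 3:
        raise ValueError("need at least 3 trials")
    idx = features["trial_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("trials must be in acquisition order with unique "
                         "trial indices")
    vmax = features["vmax"].to_numpy(dtype=float)
    amax = features["amax"].to_numpy(dtype=float)
    if np.any(vmax <= 0) or np.any(amax <= 0):
        raise ValueError("vmax and amax must be positive")
    nu = upsilon - 1.0
    x = np.log(amax[:-1])
    y = np.log(vmax[1:] + nu * vmax[:-1])
    level = features["speed_level"].to_numpy()[:-1]
    context = features["context"].to_numpy()[:-1] \
        if "context" in features else np.full(len(x), "")
    keep = np.ones(len(x), dtype=bool)
    if exclude_block_boundaries and "block" in features:
        blocks = features["block"].to_numpy()
        keep = blocks[:-1] == blocks[1:]
    return RuleScatter(x[keep], y[keep], level[keep], context[keep], upsilon)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _ols_line(x: np.ndarray, y: np.ndarray, mode: str) -> RuleFit:
    if len(x) < 3:
        raise ValueError("need at least 3 points per fitted line")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ln(amax): cannot fit a line")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    n = len(x)
    sse = float(res.ssr)
    return RuleFit(
        m=float(res.params[1]), b=float(res.params[0]),
        ci_m=(float(ci[1, 0]), float(ci[1, 1])),
        ci_b=(float(ci[0, 0]), float(ci[0, 1])),
        sse=sse,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        rmse=math.sqrt(sse / (n - 2)),
        n_points=n, mode=mode)


def fit_rule(scatter: RuleScatter, mode: str = "single") -> RuleFit:
    """Least-squares fit of the rule, pooled or one line per speed level."""
    if mode == "single":
        return _ols_line(scatter.x, scatter.y, "single")
    if mode != "per_level":
        raise ValueError("mode must be 'single' or 'per_level'")
    levels = [str(l) for l in pd.unique(scatter.speed_level)]
    from dataclasses import replace
    sub = {level: _ols_line(*_level_xy(scatter, level), "single")
           for level in levels}
    pooled = _ols_line(scatter.x, scatter.y, "per_level")
    return replace(pooled, per_level=sub)


def _level_xy(scatter: RuleScatter, level: str):
    mask = scatter.speed_level == level
    return scatter.x[mask], scatter.y[mask]


def split_decision(scatter: RuleScatter,
                   alpha: float = 0.05) -> SplitDecision:
    """Pooled line versus level-specific lines, by a nested-model F-test.

    The full model fits one (slope, intercept) per speed level; the
    reduced model a single line.  F = ((SSE_r - SSE_f)/q) / (SSE_f/(n-p))
    with q extra parameters.  Decision ``per_level`` when p < alpha.
    """
    levels = [str(l) for l in pd.unique(scatter.speed_level)]
    if len(levels) < 2:
        raise ValueError("need at least two speed levels to compare")
    sse_full, n_total = 0.0, len(scatter)
    for level in levels:
        x, y = _level_xy(scatter, level)
        if len(x) < 3:
            raise ValueError(f"level {level!r} has fewer than 3 points")
        sse_full += _ols_line(x, y, "single").sse
    sse_red = _ols_line(scatter.x, scatter.y, "single").sse
    q = 2 * (len(levels) - 1)
    df_full = n_total - 2 * len(levels)
    f_stat = ((sse_red - sse_full) / q) / (sse_full / df_full)
    from scipy import stats
    p = float(stats.f.sf(f_stat, q, df_full))
    return SplitDecision(decision="per_level" if p < alpha else "single",
                         f_statistic=float(f_stat), p_value=p, alpha=alpha)


# ---------------------------------------------------------------------------
# Power form and prediction
# ---------------------------------------------------------------------------

def power_form(fit: RuleFit,
               amax_range: Optional[Tuple[float, float]] = None) -> PowerForm:
    """delta = 1 - m, its square, and the leading-order expansion report.

    The exponentiated rule vmax(t+1) + nu*vmax(t) = amax^m * e^(b+eps)
    expands around unit slope as amax^(1-delta) = amax * (1 - delta *
    ln amax) + O(delta^2); the numeric remainder bound is evaluated over
    the scatter's amax range (in the combined-velocity units, i.e. scaled
    by e^b).
    """
    delta = 1.0 - fit.m
    if amax_range is None:
        amax_range = (math.e ** -1, math.e)     # nominal unit range
    a = np.geomspace(max(amax_range[0], 1e-12), max(amax_range[1], 1e-12),
                     512)
    exact = a ** fit.m
    approx = a * (1.0 - delta * np.log(a))
    bound = float(np.max(np.abs(exact - approx)) * math.exp(fit.b))
    summary = (
        f"vmax(t+1) = amax(t)*(1 - {delta:.4g}*ln amax(t))*e^(b+eps) "
        f"- nu*vmax(t) + O(delta^2); delta^2 = {delta ** 2:.4g}, "
        f"remainder <= {bound:.4g} over amax in "
        f"[{amax_range[0]:.4g}, {amax_range[1]:.4g}]")
    return PowerForm(delta=float(delta), delta_squared=float(delta ** 2),
                     remainder_bound=bound,
                     amax_range=(float(amax_range[0]), float(amax_range[1])),
                     summary=summary)


def predict_next_vmax(fit: RuleFit, vmax_t: float, amax_t: float,
                      upsilon: float = UPSILON_DEFAULT) -> float:
    """One-step-ahead peak-speed prediction with eps set to zero:
    amax^m * e^b - nu * vmax(t).  Nonpositive predictions (out of the
    rule's regime) are returned as-is but logged."""
    if amax_t <= 0:
        raise ValueError("amax must be positive")
    pred = amax_t ** fit.m * math.exp(fit.b) - (upsilon - 1.0) * vmax_t
    if pred <= 0:
        _log.warning("nonpositive one-step prediction (%.3g): outside the "
                     "rule's regime", pred)
    return float(pred)
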