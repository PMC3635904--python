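"""Empirical frequency distributions and parametric signatures of
per-trial kinematic fluctuations.

Each subject-condition stream of a positive scalar feature (peak speed or
its normalization) is summarized by the maximum-likelihood (shape, scale)
point of the two-parameter Gamma family,

    f(x | a, b) = x^(a-1) exp(-x/b) / (b^a Gamma(a)),   x >= 0,

one point on the "Gamma plane".  Small shapes sit near the memoryless
Exponential (a = 1); large shapes approach the symmetric Gaussian range.
The moment identities E = a*b and Var = a*b^2 make the Fano factor
(noise-to-signal ratio, Var/E) equal the scale parameter b.

Also here: Scott's histogram bin-width rule W = 3.49*s*N^(-1/3), a
log-normal fit with log-scale normality check, Hartigan's dip test of
unimodality (own implementation of the published algorithm, bootstrap
calibrated against the uniform null), and the log-log power fit
b = n * a^m of a Gamma-plane scatter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats, special

_log = logging.getLogger(__name__)

MIN_GAMMA_N = 10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaSignature:
    """An MLE (shape, scale) point on the Gamma plane with Wald 95% CIs."""

    shape: float
    scale: float
    n: int
    ci_shape: Tuple[float, float]
    ci_scale: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale ** 2

    @property
    def fano(self) -> float:
        """Noise-to-signal ratio Var/E = a*b^2 / (a*b) = b."""
        return self.variance / self.mean

    def central_interval(self, level: float = 0.95) -> Tuple[float, float]:
        """Central probability interval of the fitted pdf."""
        tail = (1.0 - level) / 2.0
        dist = stats.gamma(self.shape, scale=self.scale)
        return float(dist.ppf(tail)), float(dist.ppf(1.0 - tail))


@dataclass(frozen=True)
class HistogramSpec:
    """A normalized frequency histogram with Scott's bin width."""

    bin_width: float
    edges: np.ndarray
    frequencies: np.ndarray     # sum to 1 in normalized mode

    @property
    def n_bins(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class LogNormalFit:
    log_mean: float
    log_sd: float
    normality_p: float          # normality of ln(x); NaN when degenerate
    n: int

    @property
    def degenerate(self) -> bool:
        return self.log_sd == 0.0


@dataclass(frozen=True)
class PowerFit:
    """Least-squares fit of b = prefactor * a^exponent on the Gamma plane."""

    prefactor: float
    exponent: float
    r_squared: float
    n_points: int


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def scott_bin_width(s: float, n: int) -> float:
    """Scott's optimal bin width W = 3.49 * s * n^(-1/3)."""
    if s <= 0:
        raise ValueError("standard deviation must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 3.49 * s * n ** (-1.0 / 3.0)


def normalized_histogram(values: Sequence[float],
                         density: bool = False) -> HistogramSpec:
    """Histogram with Scott's bin width; frequencies sum to 1 by default."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    w = scott_bin_width(float(np.std(x, ddof=1)), len(x))
    lo, hi = float(np.min(x)), float(np.max(x))
    n_bins = max(int(math.ceil((hi - lo) / w)), 1)
    edges = lo + w * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    if density:
        freqs = counts / (len(x) * w)
    else:
        freqs = counts / len(x)
    return HistogramSpec(bin_width=w, edges=edges, frequencies=freqs)


# ---------------------------------------------------------------------------
# Gamma family
# ---------------------------------------------------------------------------

def gamma_pdf(x: Union[float, np.ndarray], a: float, b: float):
    """The Gamma density with shape ``a`` and scale ``b``."""
    if a <= 0 or b <= 0:
        raise ValueError("shape and scale must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("the Gamma density is supported on x >= 0")
    out = stats.gamma.pdf(x, a, scale=b)
    return float(out) if out.ndim == 0 else out


def fit_gamma_mle(values: Sequence[float]) -> GammaSignature:
    """Maximum-likelihood (shape, scale) with observed-information CIs.

    The 95% intervals are Wald intervals from the inverse of the observed
    Fisher information at the MLE,

        I(a, b) = n * [[psi'(a), 1/b], [1/b, a/b^2]].
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < MIN_GAMMA_N:
        raise ValueError(f"need at least {MIN_GAMMA_N} values for a stable "
                         f"Gamma MLE (got {n})")
    if np.any(x <= 0):
        raise ValueError("Gamma MLE requires strictly positive values")
    a, _, b = stats.gamma.fit(x, floc=0)
    # score check: at the true MLE d/da loglik = n*(ln(mean-ish)...) ~ 0
    score_a = n * (-math.log(b) - special.digamma(a)) + np.sum(np.log(x))
    score_b = -n * a / b + np.sum(x) / b ** 2
    rel = max(abs(score_a), abs(score_b * b)) / n
    if rel > 1e-4:
        _log.warning("Gamma MLE gradient not fully converged "
                     "(relative score %.2e)", rel)
    info = n * np.array([[special.polygamma(1, a), 1.0 / b],
                         [1.0 / b, a / b ** 2]])
    cov = np.linalg.inv(info)
    se_a, se_b = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    z = stats.norm.ppf(0.975)
    return GammaSignature(shape=float(a), scale=float(b), n=n,
                          ci_shape=(float(a - z * se_a), float(a + z * se_a)),
                          ci_scale=(float(b - z * se_b), float(b + z * se_b)))


def fano_factor(sig: GammaSignature) -> float:
    """Variance-to-mean ratio of a Gamma signature (= its scale)."""
    return sig.fano


# ---------------------------------------------------------------------------
# Log-normal fit
# ---------------------------------------------------------------------------

def fit_lognormal(values: Sequence[float]) -> LogNormalFit:
    """MLE of a two-parameter log-normal law plus a log-scale normality p.

    The normality check is D'Agostino-Pearson on ln(x) (NaN for n < 20 or
    a degenerate constant sample, which is flagged via ``log_sd == 0``).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if np.any(x <= 0):
        raise ValueError("log-normal fit requires positive values")
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))      # MLE (ddof=0)
    if sigma == 0.0:
        _log.warning("constant sample: degenerate log-normal fit")
        return LogNormalFit(mu, 0.0, float("nan"), len(x))
    p = float(stats.normaltest(logs).pvalue) if len(x) >= 20 else float("nan")
    return LogNormalFit(mu, sigma, p, len(x))


# ---------------------------------------------------------------------------
# Hartigan's dip test
# ---------------------------------------------------------------------------

def dip_statistic(values: Sequence[float]) -> float:
    """Hartigan & Hartigan's dip statistic of unimodality.

    The dip is the maximum difference between the empirical CDF and the
    closest unimodal CDF (equivalently, twice it is the smallest achievable
    sup-distance).  Computed with the classical iterative greatest-convex-
    minorant / least-concave-majorant algorithm; the smallest possible
    value, attained by perfectly "spread" samples, is 1/(2n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    # previous-touch-point pointers of the greatest convex minorant of the
    # points (x_i, i), and next-touch-point pointers of the least concave
    # majorant, computed once over the full sample
    prev = np.empty(n, dtype=np.int64)
    prev[0] = 0
    for j in range(1, n):
        p = j - 1
        while p > 0 and ((x[j] - x[p]) * (p - prev[p])
                         >= (x[p] - x[prev[p]]) * (j - p)):
            p = prev[p]
        prev[j] = p
    nxt = np.empty(n, dtype=np.int64)
    nxt[n - 1] = n - 1
    for j in range(n - 2, -1, -1):
        p = j + 1
        while p < n - 1 and ((x[j] - x[p]) * (p - nxt[p])
                             >= (x[p] - x[nxt[p]]) * (j - p)):
            p = nxt[p]
        nxt[j] = p

    low, high = 0, n - 1
    dip = 1.0       # in count units; final statistic is dip / (2n)
    while True:
        if high - low < 1:      # modal interval collapsed to a point
            break
        # touch points of the GCM (descending from high) and LCM (ascending
        # from low) restricted to [low, high]
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(prev[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(nxt[lcm[-1]]))
        l_gcm, l_lcm = len(gcm), len(lcm)

        d = 0.0
        ig_i, ih_i = 0, l_lcm - 1
        if l_gcm != 2 or l_lcm != 2:
            ix, iv = l_gcm - 2, 1
            while True:
                gx, lv = gcm[ix], lcm[iv]
                if gx > lv:
                    # the next change point is on the LCM: gap between the
                    # LCM touch and the GCM chord below it
                    g1 = gcm[ix + 1]
                    dx = (lv - g1 + 1) - (x[lv] - x[g1]) \
                        * (gx - g1) / (x[gx] - x[g1])
                    iv += 1
                    if dx >= d:
                        d, ig_i, ih_i = dx, ix + 1, iv - 1
                else:
                    # the next change point is on the GCM: gap between the
                    # LCM chord and the GCM touch below it
                    l0 = lcm[iv - 1]
                    dx = (x[gx] - x[l0]) * (lv - l0) / (x[lv] - x[l0]) \
                        - (gx - l0 - 1)
                    ix -= 1
                    if dx >= d:
                        d, ig_i, ih_i = dx, ix + 1, iv
                ix = max(ix, 0)
                iv = min(iv, l_lcm - 1)
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # largest deviation between the empirical CDF and the GCM over the
        # left flank, and the LCM over the right flank
        dip_l = 0.0
        for j in range(ig_i, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                t = np.max((np.arange(jb, je + 1) - jb + 1)
                           - (x[jb:je + 1] - x[jb]) * c)
                dip_l = max(dip_l, float(t))
        dip_u = 0.0
        for j in range(ih_i, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                t = np.max((x[jb:je + 1] - x[jb]) * c
                           - (np.arange(jb, je + 1) - jb - 1))
                dip_u = max(dip_u, float(t))

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig_i], lcm[ih_i]
        if new_low == low and new_high == high:   # no further narrowing
            break
        low, high = new_low, new_high
    return dip / (2.0 * n)


def dip_unimodality(values: Sequence[float],
                    n_boot: int = 2000,
                    seed: Union[int, np.random.Generator] = 0,
                    ) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform null.

    The null distribution of the dip is simulated from ``n_boot`` uniform
    samples of the same size (Hartigan's calibration); the p-value is the
    (add-one smoothed) fraction of null dips at or above the observed one.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 30:
        raise ValueError("need at least 30 values for the dip test")
    if n_boot < 500:
        raise ValueError("need at least 500 bootstrap draws")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dip = dip_statistic(x)
    exceed = 0
    for _ in range(n_boot):
        if dip_statistic(rng.uniform(size=n)) >= dip:
            exceed += 1
    p = (exceed + 1) / (n_boot + 1)
    return dip, p


# ---------------------------------------------------------------------------
# Gamma-plane power fit
# ---------------------------------------------------------------------------

def gamma_plane_power_fit(signatures: Iterable[GammaSignature]) -> PowerFit:
    """Least-squares power law b = prefactor * a^exponent through a set of
    Gamma-plane points, fit as a line on (ln a, ln b)."""
    sigs = list(signatures)
    if len(sigs) < 3:
        raise ValueError("need at least 3 signatures")
    la = np.log([s.shape for s in sigs])
    lb = np.log([s.scale for s in sigs])
    if np.ptp(la) == 0:
        raise ValueError("degenerate scatter: all shapes equal")
    slope, intercept = np.polyfit(la, lb, 1)
    resid = lb - (slope * la + intercept)
    ss_tot = float(np.sum((lb - lb.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerFit(prefactor=float(np.exp(intercept)),
                    exponent=float(slope), r_squared=r2, n_points=len(sigs))
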