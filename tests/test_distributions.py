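"""Histograms, Gamma/log-normal signatures, the dip test and the
Gamma-plane power fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.optimize import linprog

import kinesig as ks


# ---------------------------------------------------------------------------
# Scott's rule and histograms
# ---------------------------------------------------------------------------

class TestHistograms:

    @pytest.mark.parametrize("s, n, expected",
                             [(1.0, 1000, 0.349),
                              (1.0, 1, 3.49),
                              (2.0, 8, 3.49)])
    def test_scott_bin_width(self, s, n, expected):
        assert ks.scott_bin_width(s, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("s, n", [(0.0, 10), (-1.0, 10), (1.0, 0)])
    def test_scott_rejects_degenerate_inputs(self, s, n):
        with pytest.raises(ValueError):
            ks.scott_bin_width(s, n)

    def test_normalized_frequencies_sum_to_one(self, rng):
        h = ks.normalized_histogram(rng.normal(size=500))
        assert h.frequencies.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.bin_width > 0

    def test_bin_count_is_invariant_under_affine_rescaling(self, rng):
        x = rng.normal(size=800)
        h1 = ks.normalized_histogram(x)
        h2 = ks.normalized_histogram(5.0 * x - 3.0)
        assert h1.n_bins == h2.n_bins


# ---------------------------------------------------------------------------
# Gamma family
# ---------------------------------------------------------------------------

class TestGamma:

    def test_exponential_density_at_zero(self):
        assert ks.gamma_pdf(0.0, 1.0, 4.0) == pytest.approx(0.25)

    def test_mode_location(self):
        # for shape 10, scale 4 the mode sits at (a-1)*b = 36
        x = np.linspace(0, 120, 24001)
        assert x[np.argmax(ks.gamma_pdf(x, 10.0, 4.0))] == \
            pytest.approx(36.0, abs=0.01)

    def test_density_normalization(self):
        val, _ = integrate.quad(lambda x: ks.gamma_pdf(x, 10.0, 4.0),
                                0, 60 * 4.0)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("x, a, b", [(-1, 1, 1), (1, 0, 1), (1, 1, 0)])
    def test_domain_violations(self, x, a, b):
        with pytest.raises(ValueError):
            ks.gamma_pdf(x, a, b)

    def test_mle_recovers_gamma_2_3(self, rng):
        sig = ks.fit_gamma_mle(rng.gamma(2.0, 3.0, 2000))
        assert 1.8 < sig.shape < 2.2
        assert 2.7 < sig.scale < 3.3
        assert sig.ci_shape[0] <= 2.0 <= sig.ci_shape[1]
        assert sig.ci_scale[0] <= 3.0 <= sig.ci_scale[1]

    def test_mle_identifies_the_exponential(self, rng):
        sig = ks.fit_gamma_mle(rng.exponential(4.0, 2000))
        assert sig.ci_shape[0] <= 1.0 <= sig.ci_shape[1]

    def test_mle_error_shrinks_with_sample_size(self):
        rng = np.random.default_rng(17)
        errs = [abs(ks.fit_gamma_mle(rng.gamma(2.0, 3.0, n)).shape - 2.0)
                for n in (100, 1000, 10000)]
        assert errs[0] > errs[2]
        assert errs[1] > errs[2]

    @pytest.mark.parametrize("bad", [[1.0] * 9,
                                     [0.0] + [1.0] * 20,
                                     [-1.0] + [1.0] * 20])
    def test_mle_rejects_invalid_samples(self, bad):
        with pytest.raises(ValueError):
            ks.fit_gamma_mle(bad)

    def test_moment_identities_hold_exactly(self, rng):
        sig = ks.fit_gamma_mle(rng.gamma(3.0, 0.5, 500))
        assert sig.mean == sig.shape * sig.scale
        assert sig.variance == sig.shape * sig.scale ** 2
        assert ks.fano_factor(sig) == pytest.approx(sig.scale, rel=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(a=st.floats(0.2, 50), b=st.floats(1e-3, 100))
    def test_fano_equals_scale_for_any_signature(self, a, b):
        sig = ks.GammaSignature(a, b, 100, (a, a), (b, b))
        assert sig.fano == pytest.approx(b, rel=1e-12)


# ---------------------------------------------------------------------------
# Log-normal fit
# ---------------------------------------------------------------------------

class TestLogNormal:

    def test_recovers_parameters(self, rng):
        fit = ks.fit_lognormal(rng.lognormal(1.0, 0.3, 2000))
        assert fit.log_mean == pytest.approx(1.0, rel=0.05)
        assert fit.log_sd == pytest.approx(0.3, rel=0.05)
        assert fit.normality_p > 0.05

    def test_exponential_data_fails_log_normality(self, rng):
        fit = ks.fit_lognormal(rng.gamma(1.0, 1.0, 2000))
        assert fit.normality_p < 0.05

    def test_constant_sample_is_flagged_degenerate(self):
        fit = ks.fit_lognormal([2.0] * 50)
        assert fit.degenerate
        assert fit.log_sd == 0.0


# ---------------------------------------------------------------------------
# Hartigan's dip
# ---------------------------------------------------------------------------

def _dip_bruteforce(x):
    """The dip as the exact solution of its defining minimax problem:
    min over unimodal CDFs G of sup |F_n - G|, solved as one LP per
    candidate mode position (independent of the fast implementation)."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    best = np.inf
    for j in range(n):
        c = np.zeros(n + 1)
        c[-1] = 1.0
        A, b = [], []
        for i in range(n):                  # sup-distance, jump-aware
            row = np.zeros(n + 1); row[i] = 1; row[-1] = -1
            A.append(row); b.append(i / n)
            row = np.zeros(n + 1); row[i] = -1; row[-1] = -1
            A.append(row); b.append(-(i + 1) / n)
        for i in range(n - 1):              # monotone
            row = np.zeros(n + 1); row[i] = 1; row[i + 1] = -1
            A.append(row); b.append(0.0)
        for i in range(1, n - 1):           # convex before j, concave after
            dx1, dx2 = x[i] - x[i - 1], x[i + 1] - x[i]
            if dx1 <= 0 or dx2 <= 0:
                continue
            row = np.zeros(n + 1)
            row[i - 1] = -1 / dx1
            row[i] = 1 / dx1 + 1 / dx2
            row[i + 1] = -1 / dx2
            if i + 1 <= j:
                A.append(row.copy()); b.append(0.0)
            if i - 1 >= j:
                A.append(-row); b.append(0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * n + [(0, 1)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


class TestDip:

    def test_matches_bruteforce_minimax_solution(self):
        rng = np.random.default_rng(42)
        for trial in range(18):
            n = int(rng.integers(4, 12))
            if trial % 3 == 0:
                x = rng.uniform(size=n)
            elif trial % 3 == 1:
                x = np.concatenate([rng.normal(0, .05, n // 2),
                                    rng.normal(1, .05, n - n // 2)])
            else:
                x = rng.exponential(size=n)
            assert ks.dip_statistic(x) == \
                pytest.approx(_dip_bruteforce(x), abs=1e-9)

    def test_minimal_dip_for_evenly_spread_samples(self):
        assert ks.dip_statistic(np.arange(1, 11)) == pytest.approx(1 / 20)

    def test_unimodal_sample_is_not_rejected(self, rng):
        _, p = ks.dip_unimodality(rng.normal(size=1000), n_boot=500, seed=1)
        assert p > 0.05

    def test_bimodal_mixture_is_rejected(self, rng):
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(6, 1, 500)])
        dip, p = ks.dip_unimodality(x, n_boot=500, seed=2)
        assert p < 0.01
        assert dip > 0.05

    def test_sample_size_and_bootstrap_preconditions(self, rng):
        with pytest.raises(ValueError):
            ks.dip_unimodality(rng.normal(size=20), seed=0)
        with pytest.raises(ValueError):
            ks.dip_unimodality(rng.normal(size=100), n_boot=100, seed=0)


# ---------------------------------------------------------------------------
# Gamma-plane power fit
# ---------------------------------------------------------------------------

class TestPowerFit:

    def _sigs(self, a, b):
        return [ks.GammaSignature(ai, bi, 100, (ai, ai), (bi, bi))
                for ai, bi in zip(a, b)]

    def test_exact_inverse_power_law(self):
        a = np.array([0.5, 1.0, 2.0, 4.0])
        fit = ks.gamma_plane_power_fit(self._sigs(a, 2.0 / a))
        assert fit.prefactor == pytest.approx(2.0, rel=1e-9)
        assert fit.exponent == pytest.approx(-1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_line_of_unity(self):
        a = np.array([0.5, 1.0, 2.0, 4.0])
        fit = ks.gamma_plane_power_fit(self._sigs(a, a))
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)

    def test_jittered_cohort_recovers_exponent(self, rng):
        a = np.geomspace(0.5, 20, 30)
        b = 3.0 * a ** -0.8 * np.exp(rng.normal(0, 0.05, 30))
        fit = ks.gamma_plane_power_fit(self._sigs(a, b))
        assert fit.exponent == pytest.approx(-0.8, abs=0.1)

    def test_degenerate_scatters_are_rejected(self):
        with pytest.raises(ValueError):
            ks.gamma_plane_power_fit(self._sigs([1, 2], [1, 2]))
        with pytest.raises(ValueError):
            ks.gamma_plane_power_fit(self._sigs([2, 2, 2], [1, 2, 3]))
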