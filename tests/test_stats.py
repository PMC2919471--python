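"""Gradient statistics: fits, boundaries, noise, bootstrap, tests, contours."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from bcdgeom import stats as st
from bcdgeom.profiles import BinnedProfile
from bcdgeom.synthetic import hill


class TestExponentialFit:
    def test_exact_samples_recovered(self):
        c = np.linspace(0, 500, 60)
        fit = st.fit_exponential(c, 10 * np.exp(-c / 104.8))
        assert fit.lam == pytest.approx(104.8, rel=1e-9)
        assert fit.B0 == pytest.approx(10.0, rel=1e-9)

    def test_two_point_analytic(self):
        with pytest.raises(ValueError):
            st.fit_exponential([0, 100], [10, 10 / np.e])
        # five points on the same line give the analytic answer
        x = np.array([0, 25, 50, 75, 100.0])
        fit = st.fit_exponential(x, 10 * np.exp(-x / 100.0))
        assert fit.lam == pytest.approx(100.0, rel=1e-9)

    def test_scale_equivariance(self):
        c = np.linspace(10, 400, 40)
        v = 7.3 * np.exp(-c / 88.0)
        a = st.fit_exponential(c, v)
        b = st.fit_exponential(c, 5.0 * v)
        assert b.lam == pytest.approx(a.lam, rel=1e-12)
        assert b.B0 == pytest.approx(5.0 * a.B0, rel=1e-9)

    def test_nonpositive_points_excluded_and_counted(self):
        c = np.linspace(0, 100, 20)
        v = 10 * np.exp(-c / 50.0)
        v[3] = -1.0
        fit = st.fit_exponential(c, v)
        assert fit.n_excluded == 1 and fit.n_points == 19

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match="fewer than 5"):
            st.fit_exponential([0, 1, 2, 3], [4, 3, 2, 1])


class TestHill:
    def test_half_maximal_at_kd_for_any_exponent(self):
        for n in (1.0, 2.5, 5.0, 11.0):
            assert hill(5.0, 5.0, n) == pytest.approx(0.5)

    def test_two_kd_with_n5(self):
        assert hill(10.0, 5.0, 5.0) == pytest.approx(32.0 / 33.0)

    def test_monotone_and_saturating(self):
        b = np.linspace(0.01, 500, 1000)
        h = hill(b, 5.0, 5.0)
        assert np.all(np.diff(h) > 0)
        assert hill(1e6, 5.0, 5.0) == pytest.approx(1.0, abs=1e-10)

    def test_noise_free_fit_recovers_parameters(self):
        b = np.linspace(0.5, 20, 60)
        h = hill(b, 5.0, 5.0)
        fit = st.fit_hill(b, h, "fitted")
        assert fit.Kd == pytest.approx(5.0, abs=1e-6)
        assert fit.n == pytest.approx(5.0, abs=1e-6)

    def test_fixed_kd_mode(self):
        b = np.linspace(0.5, 20, 60)
        h = hill(b, 5.0, 3.0)
        fit = st.fit_hill(b, h, "measured_at_boundary", fixed_Kd=5.0)
        assert fit.n == pytest.approx(3.0, abs=1e-6)
        assert fit.Kd == 5.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            st.fit_hill([1, 2, 3], [0.1, 0.5, 0.9])


class TestBoundary:
    def test_logistic_profile_center(self):
        x = np.linspace(0, 500, 251)
        v = 1.0 / (1.0 + np.exp((x - 250.0) / 20.0))
        b = st.find_half_max_boundary(x, x * 1.1, v)
        assert b.x_b == pytest.approx(250.0, abs=1e-9)
        assert b.c_b == pytest.approx(275.0, abs=1e-6)

    def test_linear_ramp(self):
        x = np.array([150.0, 200.0, 300.0, 350.0])
        v = np.array([1.0, 1.0, 0.0, 0.0])
        b = st.find_half_max_boundary(x, x, v)
        assert b.x_b == pytest.approx(250.0)

    def test_no_crossing_rejected(self):
        with pytest.raises(ValueError, match="cross"):
            st.find_half_max_boundary(np.arange(5.0), np.arange(5.0),
                                      np.full(5, 0.9))

    def test_multiple_crossings_uses_most_anterior(self, caplog):
        x = np.arange(8.0)
        v = np.array([1.0, 0.4, 0.8, 0.3, 0.9, 0.2, 0.1, 0.0])
        with caplog.at_level("WARNING"):
            b = st.find_half_max_boundary(x, x, v)
        assert b.x_b < 1.0
        assert any("multiple" in r.message for r in caplog.records)


class TestMeasureKd:
    def test_exponential_analytic(self):
        c = np.linspace(0, 300, 3001)
        B = 10 * np.exp(-c / 100.0)
        assert st.measure_kd(c, B, 100 * math.log(2)) == pytest.approx(5.0, abs=1e-4)

    def test_constant_trace(self):
        c = np.linspace(0, 100, 11)
        assert st.measure_kd(c, np.full(11, 4.8), 37.0) == pytest.approx(4.8)

    def test_outside_support_rejected(self):
        with pytest.raises(ValueError):
            st.measure_kd(np.arange(10.0), np.arange(10.0), 50.0)


class TestNoiseProfile:
    @staticmethod
    def _table(n_embryos, cv, seed=0, mean=10.0, n_bins=12):
        rng = np.random.default_rng(seed)
        vals = mean * (1 + rng.normal(0, cv, size=(n_embryos, n_bins)))
        return pd.DataFrame(vals, columns=(np.arange(n_bins) + 0.5) * 5.5)

    def test_identical_embryos_have_zero_noise(self):
        tab = self._table(10, 0.0)
        prof = st.intensity_noise_profile(tab)
        np.testing.assert_allclose(prof.noise, 0.0, atol=1e-15)

    def test_multiplicative_cv_recovered(self):
        prof = st.intensity_noise_profile(self._table(200, 0.10, seed=5))
        assert np.all(np.abs(prof.noise - 0.10) < 0.01)

    def test_sparse_bins_omitted(self):
        tab = self._table(4, 0.1)
        tab.iloc[2:, 0] = np.nan
        prof = st.intensity_noise_profile(tab, min_embryos=3)
        assert len(prof.abscissa) == tab.shape[1] - 1


class TestPositionalError:
    def test_exponential_closed_form(self):
        """sigma_c = lambda * (dB/B) for an exponential mean profile."""
        lam, dBB = 100.0, 0.1
        c = np.arange(0, 400, 5.0)
        mean = 50 * np.exp(-c / lam)
        prof = st.NoiseProfile(c, np.full_like(c, dBB), mean, dBB * mean,
                               np.full(len(c), 10))
        sigma = st.positional_error(prof, span=5)
        inner = slice(3, -3)
        np.testing.assert_allclose(sigma[inner], lam * dBB, rtol=0.02)

    def test_zero_noise_gives_zero_error(self):
        c = np.arange(0, 100, 5.0)
        mean = 50 * np.exp(-c / 80.0)
        prof = st.NoiseProfile(c, np.zeros_like(c), mean, np.zeros_like(c),
                               np.full(len(c), 5))
        sigma = st.positional_error(prof)
        np.testing.assert_allclose(sigma[np.isfinite(sigma)], 0.0, atol=1e-15)

    def test_flat_profile_reported_missing(self):
        c = np.arange(0, 50, 5.0)
        prof = st.NoiseProfile(c, np.full_like(c, 0.1), np.full_like(c, 3.0),
                               np.full_like(c, 0.3), np.full(len(c), 5))
        sigma = st.positional_error(prof)
        assert np.all(np.isnan(sigma))


class TestBootstrap:
    def test_identical_cohort_gives_zero_sd(self):
        sd = st.bootstrap_sd(lambda xs: float(np.mean(xs)), [3.0] * 10,
                             n_reps=200, rng=0)
        assert sd == 0.0

    def test_mean_of_normal_sample_matches_s_over_sqrt_n(self):
        rng = np.random.default_rng(17)
        sample = rng.normal(0, 1, size=100)
        sd = st.bootstrap_sd(lambda xs: float(np.mean(xs)), list(sample),
                             n_reps=1000, rng=3)
        expect = sample.std(ddof=1) / 10.0
        assert sd == pytest.approx(expect, rel=0.20)

    def test_seeded_reproducibility(self):
        sample = list(np.random.default_rng(2).normal(size=40))
        a = st.bootstrap_sd(lambda xs: float(np.median(xs)), sample, 200, rng=9)
        b = st.bootstrap_sd(lambda xs: float(np.median(xs)), sample, 200, rng=9)
        assert a == b

    def test_failing_statistic_raises(self):
        def bad(xs):
            raise RuntimeError("no")

        with pytest.raises(RuntimeError):
            st.bootstrap_sd(bad, [1.0, 2.0, 3.0], 100, rng=0)


def t_pvalue_oracle(t_obs: float, df: int) -> float:
    """Two-tailed Student p by direct integration of the explicit density."""
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda u: const * (1 + u * u / df) ** (-(df + 1) / 2)
    tail, _ = quad(pdf, abs(t_obs), np.inf)
    return 2.0 * tail


class TestSideTTest:
    def test_identical_samples_give_p_one(self):
        out = st.compare_sides_ttest([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        assert out[0][1] == pytest.approx(1.0)

    def test_matches_hand_computed_oracle(self):
        d = [1.0, 2.0, 3.0, 4.0, 5.0]
        v = [2.0, 3.0, 4.0, 5.0, 6.0]
        # hand computation: means 3 and 4, pooled variance 2.5,
        # t = (3-4)/sqrt(2.5*(1/5+1/5)) = -1, df = 8
        (t, p), = st.compare_sides_ttest([d], [v])
        assert t == pytest.approx(-1.0, abs=1e-12)
        assert p == pytest.approx(t_pvalue_oracle(-1.0, 8), abs=1e-10)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0, 1, 28)
        v = rng.normal(3.0, 1, 28)
        (t, p), = st.compare_sides_ttest([d], [v])
        assert p < 1e-6

    def test_degenerate_zero_variance(self):
        (t, p), = st.compare_sides_ttest([[2.0, 2.0]], [[2.0, 2.0]])
        assert p == 1.0


def _binned(centers, mean, axis="projected", side="D"):
    n = len(centers)
    return BinnedProfile(axis, centers[1] - centers[0], np.asarray(centers, float),
                         np.asarray(mean, float), np.zeros(n), np.full(n, 10),
                         "bcd", side)


class TestIsoContours:
    def test_identical_profiles_give_zero_offsets(self):
        x = np.arange(0, 400, 10.0)
        v = 20 * np.exp(-x / 100)
        iso = st.iso_concentration_contours(_binned(x, v), _binned(x, v, side="V"),
                                            _binned(x, v, "contour"),
                                            _binned(x, v, "contour", "V"),
                                            interval=1.0)
        np.testing.assert_allclose(iso.dx, 0.0, atol=1e-9)
        np.testing.assert_allclose(iso.dc, 0.0, atol=1e-9)

    def test_projected_offsets_exceed_contour_offsets(self, wt_analysis):
        """On an asymmetric cohort the iso-concentration offsets are larger
        in projected than in contour distance at mid-embryo thresholds."""
        iso = wt_analysis["iso"]
        sel = (iso.thresholds >= 2) & (iso.thresholds <= 10)
        assert np.all(iso.dx[sel] > iso.dc[sel])

    def test_out_of_range_thresholds_skipped(self):
        x = np.arange(0, 400, 10.0)
        v = 20 * np.exp(-x / 100)
        iso = st.iso_concentration_contours(
            _binned(x, v), _binned(x, v, side="V"), _binned(x, v, "contour"),
            _binned(x, v, "contour", "V"), thresholds=np.array([1.0, 500.0]))
        assert len(iso.thresholds) == 1


class TestTargetSlant:
    def test_symmetric_cohort_is_null(self):
        rng = np.random.default_rng(8)
        pairs = []
        for k in range(20):
            x = 250 + rng.normal(0, 5)
            jitter = rng.normal(0, 1.0)
            d = st.BoundaryEstimate(x + jitter, x + 30 + jitter, "D", embryo_id=k)
            v = st.BoundaryEstimate(x - jitter, x + 30 - jitter, "V", embryo_id=k)
            pairs.append((d, v))
        out = st.target_slant(pairs)
        assert abs(out["dx_mean"]) < 1.0
        assert out["dx_p"] > 0.05

    def test_boundary_spread_reported_per_side(self, wt_analysis):
        out = wt_analysis["slant"]
        assert out["sigma_c_Hb_D"] > 0 and out["sigma_c_Hb_V"] > 0
        assert out["n"] == 28
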