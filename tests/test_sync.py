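"""Synchrony battery: ratios, rolling r, IPS, TLCC, RWTLCC, period, pulses."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from hpadyn import TimeSeries
from hpadyn.sync import (
    UndefinedPeriodError, count_pulses, estimate_ultradian_period,
    hormone_ratio, instantaneous_phase_synchrony, rolling_correlation,
    rwtlcc, tlcc,
)

from conftest import make_ts


class TestHormoneRatio:
    def test_identical_series_unit_ratio(self, gauss_pulses):
        r = hormone_ratio(gauss_pulses, gauss_pulses)
        assert np.allclose(r.v[~np.isnan(r.v)], 1.0)

    def test_zero_denominator_flagged(self):
        a = make_ts([1.0, 2.0, 3.0])
        c = make_ts([1.0, 0.0, 3.0])
        r = hormone_ratio(a, c)
        assert np.isnan(r.v[1]) and r.v[0] == 1.0 and r.v[2] == 1.0

    def test_scales_with_numerator(self, gauss_pulses):
        c = make_ts(gauss_pulses.v + 1.0)
        base = hormone_ratio(gauss_pulses, c)
        scaled = hormone_ratio(make_ts(3.0 * gauss_pulses.v), c)
        assert np.allclose(scaled.v, 3.0 * base.v, equal_nan=True)


class TestRollingCorrelation:
    def test_affine_pair_perfect_r(self, gauss_pulses):
        c = make_ts(2.0 * gauss_pulses.v + 1.0)
        r = rolling_correlation(gauss_pulses, c, 60.0)
        interior = r.v[~np.isnan(r.v)]
        assert np.allclose(interior, 1.0)

    def test_negated_pair(self, gauss_pulses):
        c = make_ts(-gauss_pulses.v)
        r = rolling_correlation(gauss_pulses, c, 60.0)
        assert np.allclose(r.v[~np.isnan(r.v)], -1.0)

    def test_constant_window_missing(self):
        a = make_ts(np.r_[np.ones(10), np.arange(10.0)])
        c = make_ts(np.r_[np.ones(10), np.arange(10.0) ** 2])
        r = rolling_correlation(a, c, 40.0)
        assert np.isnan(r.v[4])  # fully constant window

    def test_window_longer_than_record(self):
        with pytest.raises(ValueError):
            rolling_correlation(make_ts(np.arange(5.0)), make_ts(np.arange(5.0)), 600.0)


class TestIPS:
    def _pair(self, dphi):
        t = np.arange(0.0, 1441.0, 10.0)
        a = TimeSeries("a", t, np.sin(2 * np.pi * t / 180.0), "dimensionless")
        c = TimeSeries("c", t, np.sin(2 * np.pi * t / 180.0 - dphi), "dimensionless")
        return a, c

    def test_identical_fully_synchronous(self, gauss_pulses):
        ips = instantaneous_phase_synchrony(gauss_pulses, gauss_pulses)
        assert np.all(ips.v[6:-6] >= 0.99)

    def test_antiphase_near_zero(self):
        a, c = self._pair(np.pi)
        ips = instantaneous_phase_synchrony(a, c)
        assert np.all(ips.v[36:-36] <= 0.05)

    @pytest.mark.parametrize("dphi", [0.5, 1.0, 2.0])
    def test_constant_offset_analytic(self, dphi):
        """Interior IPS (two periods from the edges) matches 1-|sin(dphi/2)|."""
        a, c = self._pair(dphi)
        ips = instantaneous_phase_synchrony(a, c)
        expected = 1.0 - abs(np.sin(dphi / 2.0))
        assert np.abs(ips.v[36:-36] - expected).max() <= 0.02

    def test_bounded_unit_interval(self, gauss_pulses):
        noisy = make_ts(gauss_pulses.v + 0.3 * np.random.default_rng(0).standard_normal(len(gauss_pulses)))
        ips = instantaneous_phase_synchrony(gauss_pulses, noisy)
        assert np.all((ips.v >= 0.0) & (ips.v <= 1.0))

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase_synchrony(make_ts(np.arange(5.0)), make_ts(np.arange(5.0)))


class TestTLCC:
    def test_exact_shifted_copy(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(120)
        a, c = make_ts(x), make_ts(np.roll(x, 3))
        lags, r, peak_lag, peak_r = tlcc(a, c, 180.0)
        assert peak_lag == 30.0 and peak_r == pytest.approx(1.0, abs=0.02)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(120)
        a, c = make_ts(x), make_ts(np.roll(x, 4))
        assert tlcc(a, c, 120.0)[2] == -tlcc(c, a, 120.0)[2]

    def test_matches_bruteforce_spearman_scan(self):
        """Full lag curve equals a per-lag scipy.stats.spearmanr scan."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        y = np.roll(x, 2) + 0.4 * rng.standard_normal(100)
        a, c = make_ts(x), make_ts(y)
        lags, r, _, _ = tlcc(a, c, 120.0)
        for lag, ri in zip(lags, r):
            k = int(round(lag / 10.0))
            if k >= 0:
                expected = spearmanr(x[: len(x) - k or None], y[k:]).statistic
            else:
                expected = spearmanr(x[-k:], y[:k]).statistic
            assert ri == pytest.approx(expected, abs=1e-12)

    def test_zero_max_lag_is_global_spearman(self, gauss_pulses):
        noisy = make_ts(gauss_pulses.v + 0.1 * np.random.default_rng(4).standard_normal(len(gauss_pulses)))
        _, r, _, _ = tlcc(gauss_pulses, noisy, 0.0)
        assert r[0] == pytest.approx(
            spearmanr(gauss_pulses.v, noisy.v).statistic, abs=1e-12)

    def test_correlations_bounded(self):
        rng = np.random.default_rng(5)
        a, c = make_ts(rng.standard_normal(90)), make_ts(rng.standard_normal(90))
        _, r, _, peak_r = tlcc(a, c, 180.0)
        finite = r[np.isfinite(r)]
        assert np.all((finite >= -1.0) & (finite <= 1.0))
        assert peak_r == np.nanmax(r)

    def test_max_lag_over_third_rejected(self):
        with pytest.raises(ValueError):
            tlcc(make_ts(np.arange(30.0)), make_ts(np.arange(30.0)), 180.0)


class TestRWTLCC:
    def test_stationary_pair_vertical_stripe(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(145)
        a, c = make_ts(x), make_ts(np.roll(x, 2))
        m, lags = rwtlcc(a, c, 360.0, 60.0, 100.0)
        argmax = [lags[np.argmax(row)] for row in m]
        assert len(set(argmax)) == 1 and argmax[0] == 20.0

    def test_lag_switch_detected_at_midpoint(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(145)
        y = np.concatenate([x[:72], np.roll(x, 3)[72:]])
        a, c = make_ts(x), make_ts(y)
        m, lags = rwtlcc(a, c, 360.0, 120.0, 100.0)
        argmax = np.array([lags[np.argmax(row)] for row in m])
        assert argmax[0] == 0.0 and argmax[-1] == 30.0
        switches = np.flatnonzero(np.diff(argmax) != 0)
        assert len(switches) == 1  # single transition, near the midpoint epoch

    def test_full_record_window_equals_tlcc(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(100)
        a, c = make_ts(x), make_ts(np.roll(x, 1))
        m, lags = rwtlcc(a, c, 2000.0, 2000.0, 120.0)
        assert m.shape[0] == 1
        ref_lags, ref_r, _, _ = tlcc(a, c, 120.0)
        assert np.allclose(m[0], ref_r, equal_nan=True)
        assert np.allclose(lags, ref_lags)

    def test_window_lag_consistency_enforced(self):
        a = make_ts(np.arange(100.0))
        with pytest.raises(ValueError, match="2\\*max_lag"):
            rwtlcc(a, a, 100.0, 30.0, 100.0)


class TestPeriodAndPulses:
    def test_sinusoid_period(self):
        t = np.arange(0.0, 1441.0, 10.0)
        ts = TimeSeries("x", t, np.sin(2 * np.pi * t / 180.0), "dimensionless")
        assert estimate_ultradian_period(ts) == pytest.approx(180.0, abs=10.0)

    def test_two_pulse_fallback(self):
        t = np.arange(0.0, 721.0, 10.0)
        v = (np.exp(-0.5 * ((t - 150.0) / 20.0) ** 2)
             + np.exp(-0.5 * ((t - 480.0) / 20.0) ** 2))
        ts = TimeSeries("x", t, v, "dimensionless")
        assert estimate_ultradian_period(ts) == pytest.approx(330.0, abs=10.0)

    def test_constant_has_no_period(self):
        with pytest.raises(UndefinedPeriodError):
            estimate_ultradian_period(make_ts(np.ones(73)))

    def test_three_equal_bumps(self, gauss_pulses):
        assert count_pulses(gauss_pulses) == 3

    def test_monotone_ramp_no_pulses(self):
        assert count_pulses(make_ts(np.arange(73.0))) == 0

    def test_constant_no_pulses(self):
        assert count_pulses(make_ts(np.ones(73))) == 0

    def test_invariant_under_affine_rescaling(self, gauss_pulses):
        scaled = make_ts(5.0 * gauss_pulses.v + 40.0)
        assert count_pulses(scaled) == count_pulses(gauss_pulses)
        assert estimate_ultradian_period(scaled) == pytest.approx(
            estimate_ultradian_period(gauss_pulses))
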