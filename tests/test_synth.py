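"""Synthetic-profile generator: regimes, determinism, noise, calibration."""

import numpy as np
import pytest

from hpadyn import CONTROL_PARAMS, area_under_curve, simulate_cortisol
from hpadyn.sync import count_pulses, estimate_ultradian_period
from hpadyn.synth import (
    RegimeSpec, default_spec, gen_cabg_profile, gen_cytokine_traces,
    gen_healthy_profile, gen_model_cortisol, gen_panel, gen_pulsatile_acth,
)


class TestSpecs:
    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            default_spec("bogus")

    def test_duration_must_cover_two_periods(self):
        with pytest.raises(ValueError, match="two pulse periods"):
            RegimeSpec("two_pulse", pulse_period=400.0, n_pulses=2,
                       acth_peak_scale=5.0, cortisol_lag=13.0,
                       synchrony_mode="stable", duration=700.0)

    def test_noise_bounds(self):
        with pytest.raises(ValueError):
            default_spec("control", noise_sd_frac=0.9)


class TestHealthyProfile:
    def test_seeded_determinism(self):
        a = gen_healthy_profile(seed=3)
        b = gen_healthy_profile(seed=3)
        assert np.array_equal(a.acth.v, b.acth.v)
        assert np.array_equal(a.cortisol.v, b.cortisol.v)

    def test_ultradian_period_in_band(self):
        """Cortisol T_u of healthy profiles falls in the 2.5-3 h band."""
        for seed in range(4):
            p = gen_healthy_profile(seed=seed)
            assert 150.0 <= estimate_ultradian_period(p.cortisol) <= 180.0

    def test_zero_noise_equals_model_output(self):
        spec = default_spec("control", noise_sd_frac=0.0)
        p = gen_healthy_profile(spec, seed=1)
        params = p.cortisol.meta["params"]
        c0 = p.cortisol.meta["c_obs0"]
        # regenerate the noiseless cortisol from the fine ACTH path
        fine = gen_healthy_profile(spec, seed=1)
        sim = simulate_cortisol(params, fine.acth, c_obs0=float(p.cortisol.v[0]))
        # identical seeds: observed cortisol is exactly the sampled model output
        assert np.array_equal(p.cortisol.v, fine.cortisol.v)
        assert params == CONTROL_PARAMS

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="12 h"):
            gen_healthy_profile(default_spec("control", duration=600.0,
                                             pulse_period=165.0))

    def test_nonnegative_concentrations(self):
        p = gen_healthy_profile(seed=9)
        assert np.all(p.acth.v >= 0) and np.all(p.cortisol.v >= 0)


class TestCabgProfiles:
    def test_control_regime_rejected(self):
        with pytest.raises(ValueError, match="gen_healthy_profile"):
            gen_cabg_profile(default_spec("control"))

    @pytest.mark.parametrize("regime,check", [
        ("two_pulse", lambda n: n == 2),
        ("multiple_pulse", lambda n: n >= 3),
        ("single_pulse", lambda n: n == 1),
    ])
    def test_cortisol_pulse_counts(self, regime, check):
        for seed in range(3):
            p = gen_cabg_profile(regime=regime, seed=seed)
            assert check(count_pulses(p.cortisol)), (regime, seed)

    def test_two_pulse_period_band(self):
        """Two-pulse profiles show the 5-6 h ultradian period."""
        for seed in range(3):
            p = gen_cabg_profile(regime="two_pulse", seed=seed)
            assert 300.0 <= estimate_ultradian_period(p.cortisol) <= 360.0

    def test_surgery_window_and_label_recorded(self):
        p = gen_cabg_profile(regime="single_pulse", seed=0)
        assert p.surgery_window is not None
        assert p.true_regime == "single_pulse"


class TestCytokines:
    def test_quiet_before_surgery_midpoint(self):
        """All four mediators stay below 5% of their peak pre-midpoint."""
        p = gen_cabg_profile(regime="single_pulse", seed=2)
        p = gen_cytokine_traces(p, seed=2)
        mid = 0.5 * (p.surgery_window[0] + p.surgery_window[1])
        for name, ts in p.cytokines.items():
            pre = ts.v[ts.t < mid]
            assert np.all(pre < 0.05 * ts.v.max()), name

    def test_zero_gain_flat_baseline(self):
        p = gen_cabg_profile(regime="two_pulse", seed=1)
        p = gen_cytokine_traces(p, seed=1, gains={k: 0.0 for k in ("IL6", "TNFa", "IL10", "IL8")})
        for ts in p.cytokines.values():
            assert np.ptp(ts.v) == 0.0

    def test_coupling_proportional_disturbance(self):
        p = gen_cabg_profile(regime="single_pulse", seed=4)
        p = gen_cytokine_traces(p, coupling={"IL6": 0.25}, seed=4)
        dist = p.cortisol.meta["disturbance"]
        assert np.allclose(dist, 0.25 * p.cytokines["IL6"].v)

    def test_requires_surgery_window(self):
        p = gen_healthy_profile(seed=0)
        with pytest.raises(RuntimeError, match="surgery_window"):
            gen_cytokine_traces(p)


class TestModelCortisol:
    def test_zero_noise_identity(self):
        acth = gen_pulsatile_acth(seed=5)
        a = gen_model_cortisol(CONTROL_PARAMS, acth, 0.0, seed=1)
        b = gen_model_cortisol(CONTROL_PARAMS, acth, 0.0, seed=99)
        assert np.array_equal(a.v, b.v)

    def test_seeded_determinism(self):
        acth = gen_pulsatile_acth(seed=5)
        a = gen_model_cortisol(CONTROL_PARAMS, acth, 0.05, seed=7)
        b = gen_model_cortisol(CONTROL_PARAMS, acth, 0.05, seed=7)
        assert np.array_equal(a.v, b.v)

    def test_noise_sd_matches_request(self):
        """Empirical relative deviation ~5% over >= 1e4 samples."""
        t = np.arange(0.0, 1e5 + 1, 10.0)
        from hpadyn import TimeSeries
        acth = TimeSeries("ACTH", t, np.full_like(t, 50.0), "ng/l")
        clean = gen_model_cortisol(CONTROL_PARAMS, acth, 0.0, seed=0)
        noisy = gen_model_cortisol(CONTROL_PARAMS, acth, 0.05, seed=0)
        rel = (noisy.v[100:] - clean.v[100:]) / clean.v[100:]
        assert np.std(rel) == pytest.approx(0.05, rel=0.05)


class TestPanelCalibration:
    def test_auc_ratios_near_study_levels(self):
        """Mixed CABG panel vs controls: ~6x ACTH and ~2x cortisol AUC."""
        ctrl_a = np.mean([area_under_curve(gen_healthy_profile(seed=s).acth, 0, 720)
                          for s in range(4)])
        ctrl_c = np.mean([area_under_curve(gen_healthy_profile(seed=s).cortisol, 0, 720)
                          for s in range(4)])
        panel = gen_panel(n_per_regime=3, seed=11)
        pa = np.mean([area_under_curve(p.acth, 0, 720) for p in panel])
        pc = np.mean([area_under_curve(p.cortisol, 0, 720) for p in panel])
        assert 4.5 <= pa / ctrl_a <= 7.5
        assert 1.5 <= pc / ctrl_c <= 2.8

    def test_panel_composition_and_determinism(self):
        a = gen_panel(n_per_regime=2, seed=3)
        b = gen_panel(n_per_regime=2, seed=3)
        assert [p.subject_id for p in a] == [p.subject_id for p in b]
        assert all(np.array_equal(x.cortisol.v, y.cortisol.v)
                   for x, y in zip(a, b))
        assert len(a) == 6
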