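"""Synthetic hormone and cytokine profiles with the study's statistical structure.

The generator emulates four dynamic regimes on the standard 10-min grid:

* ``control`` — healthy 24-h profiles: regular ultradian ACTH pulsatility
  (inter-pulse interval 150-180 min, i.e. T_u = 2.5-3 h) riding on a
  raised-cosine circadian envelope peaking at the record start (08:00);
  cortisol is produced from the ACTH trace by the two-compartment model with
  control parameters.
* ``two_pulse`` — two large ACTH/cortisol excursions 300-360 min apart
  (T_u = 5-6 h), near-physiological ACTH-cortisol lag, stable synchrony.
* ``multiple_pulse`` — pulses every ~2 h with a strongly dissociated
  cortisol lag emerging from surgery onward (partial synchrony).
* ``single_pulse`` — one large, broad excursion peaking ~2 h post-surgery
  with a dissociated lag and unstable, epoch-varying synchrony.

ACTH pulses are Gaussian bumps (FWHM ~30 min) on the envelope/baseline;
cortisol is always generated mechanistically from the ACTH trace via
:func:`hpadyn.model.simulate_cortisol` with regime-specific parameters, then
optionally time-warped (extra lag beyond the model's input delay) and
corrupted with multiplicative observation noise on both hormones.
Amplitudes are calibrated so a mixed surgical panel shows roughly a sixfold
ACTH and twofold cortisol increase in 12-h AUC over controls.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np

from .core import SubjectProfile, TimeSeries
from .model import CONTROL_PARAMS, ModelParams, simulate_cortisol, steady_state_cortisol

__all__ = [
    "RegimeSpec", "REGIMES", "default_spec", "regime_params",
    "gen_pulsatile_acth", "gen_healthy_profile", "gen_cabg_profile",
    "gen_cytokine_traces", "gen_model_cortisol", "gen_panel",
]

REGIMES = ("control", "two_pulse", "multiple_pulse", "single_pulse")

#: Gaussian ACTH pulse width: FWHM ~30 min
PULSE_SD = 12.7

#: circadian ACTH envelope (ng/l): trough and morning-peak baseline levels
ACTH_ENV_LO = 3.0
ACTH_ENV_HI = 14.0

#: control ACTH pulse amplitude at the envelope peak (ng/l)
ACTH_CONTROL_AMP = 60.0

#: default surgery window for surgical regimes, minutes from sampling start
SURGERY_WINDOW = (50.0, 230.0)


@dataclass
class RegimeSpec:
    """Generation recipe for one dynamic regime."""

    regime: str
    pulse_period: float            # nominal inter-pulse interval, min
    n_pulses: int                  # nominal pulse count over the record
    acth_peak_scale: float         # pulse amplitude vs the control amplitude
    cortisol_lag: float            # total ACTH->cortisol lag target, min
    synchrony_mode: str            # stable | partial | unstable
    noise_sd_frac: float = 0.05    # multiplicative observation noise
    duration: float = 720.0        # record length, min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.pulse_period <= 0:
            raise ValueError("pulse_period must be positive")
        if self.synchrony_mode not in ("stable", "partial", "unstable"):
            raise ValueError(f"unknown synchrony_mode {self.synchrony_mode!r}")
        if not 0 <= self.noise_sd_frac <= 0.5:
            raise ValueError("noise_sd_frac must lie in [0, 0.5]")
        if self.regime != "single_pulse" and self.duration < 2 * self.pulse_period:
            raise ValueError("duration must cover at least two pulse periods")


_DEFAULT_SPECS = {
    "control": RegimeSpec("control", pulse_period=165.0, n_pulses=9,
                          acth_peak_scale=1.0, cortisol_lag=10.0,
                          synchrony_mode="stable", duration=1440.0),
    "two_pulse": RegimeSpec("two_pulse", pulse_period=330.0, n_pulses=2,
                            acth_peak_scale=6.8, cortisol_lag=13.0,
                            synchrony_mode="stable"),
    "multiple_pulse": RegimeSpec("multiple_pulse", pulse_period=120.0,
                                 n_pulses=6, acth_peak_scale=3.7,
                                 cortisol_lag=106.0, synchrony_mode="partial"),
    "single_pulse": RegimeSpec("single_pulse", pulse_period=720.0, n_pulses=1,
                               acth_peak_scale=13.5, cortisol_lag=77.0,
                               synchrony_mode="unstable"),
}


def default_spec(regime: str, **overrides) -> RegimeSpec:
    """The default generation recipe for a regime, optionally overridden."""
    if regime not in _DEFAULT_SPECS:
        raise ValueError(f"unknown regime {regime!r}")
    return replace(_DEFAULT_SPECS[regime], **overrides)


def regime_params(regime: str) -> ModelParams:
    """Cortisol-model parameters used to generate each regime.

    Relative differences follow the fitted-parameter story: the two-pulse
    regime keeps control-like structure with a longer slow time constant;
    the multiple-pulse regime has heightened adrenal sensitivity (lower K_A);
    the single-pulse regime has a raised slow production share with faster
    slow turnover.  Surgical gains are scaled down against the saturating
    Hill drive so that a ~6x ACTH excursion maps onto a ~2x cortisol
    response, as observed.
    """
    if regime == "control":
        return CONTROL_PARAMS
    if regime == "two_pulse":
        return CONTROL_PARAMS.with_(p_f=270.0, p_s=1.5, lambda_s=380.0)
    if regime == "multiple_pulse":
        return CONTROL_PARAMS.with_(p_f=270.0, p_s=1.5, K_A=30.0, lambda_s=340.0)
    if regime == "single_pulse":
        return CONTROL_PARAMS.with_(p_f=245.0, p_s=3.7, lambda_s=150.0)
    raise ValueError(f"unknown regime {regime!r}")


def _envelope(t: np.ndarray) -> np.ndarray:
    """Circadian ACTH baseline: raised cosine over 24 h peaking at t = 0."""
    return ACTH_ENV_LO + (ACTH_ENV_HI - ACTH_ENV_LO) * 0.5 * (
        1.0 + np.cos(2.0 * np.pi * t / 1440.0))


def _gauss_train(t: np.ndarray, centers, amps, sd) -> np.ndarray:
    v = np.zeros_like(t)
    for c, a in zip(np.atleast_1d(centers), np.atleast_1d(amps)):
        v += a * np.exp(-0.5 * ((t - c) / sd) ** 2)
    return v


def _fine_grid(duration: float, dt_fine: float = 1.0) -> np.ndarray:
    return np.arange(0.0, duration + dt_fine / 2, dt_fine)


def gen_pulsatile_acth(n_pulses: int = 3, duration: float = 720.0,
                       seed: int = 0, amp: float = ACTH_CONTROL_AMP,
                       min_gap: float = 120.0, dt: float = 10.0,
                       pulse_sd: float = PULSE_SD) -> TimeSeries:
    """A pulsatile ACTH trace: ``n_pulses`` Gaussian pulses at random times
    (minimum spacing ``min_gap``) on the circadian envelope, sampled at ``dt``.

    Pulse amplitudes follow the envelope with lognormal jitter.  Used both as
    a generic model input and as the driving trace for delay-recovery checks.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 0.08 * duration, 0.92 * duration
    centers = np.sort(rng.uniform(lo, hi, n_pulses))
    while n_pulses > 1 and np.any(np.diff(centers) < min_gap):
        centers = np.sort(rng.uniform(lo, hi, n_pulses))
    amps = (amp * _envelope(centers) / ACTH_ENV_HI
            * np.exp(0.15 * rng.standard_normal(n_pulses)))
    t = np.arange(0.0, duration + dt / 2, dt)
    v = _envelope(t) + _gauss_train(t, centers, amps, pulse_sd)
    return TimeSeries("ACTH", t, v, "ng/l", dt,
                      {"pulse_centers": centers.tolist(), "seed": seed})


def _sample_to(t_out, t_fine, v_fine):
    return np.interp(t_out, t_fine, v_fine)


def _apply_noise(v: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    if frac == 0:
        return v
    return np.maximum(v * (1.0 + frac * rng.standard_normal(v.shape)), 0.0)


def _warp_lag(t_fine: np.ndarray, v_fine: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Evaluate v(t - delta(t)) on the fine grid (clamped at the record start)."""
    return np.interp(np.maximum(t_fine - delta, t_fine[0]), t_fine, v_fine)


def _extra_lag_profile(t_fine: np.ndarray, spec: RegimeSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Time-varying extra cortisol lag (beyond the model's input delay)."""
    base = max(spec.cortisol_lag - CONTROL_PARAMS.delay, 0.0)
    if spec.synchrony_mode == "stable":
        return np.full_like(t_fine, base)
    if spec.synchrony_mode == "partial":
        # lag absent before surgery, ramping in across the surgery window
        s0, s1 = SURGERY_WINDOW
        return base * np.clip((t_fine - s0) / (s1 - s0), 0.0, 1.0)
    # unstable: independent lag per 2-h epoch, smoothed
    n_ep = int(np.ceil(t_fine[-1] / 120.0))
    ep_lags = np.clip(base + rng.uniform(-35.0, 35.0, size=n_ep), 0.0, None)
    delta = ep_lags[np.minimum((t_fine // 120.0).astype(int), n_ep - 1)]
    kernel = np.ones(41) / 41.0
    return np.convolve(delta, kernel, mode="same")


def _build_profile(subject_id: str, spec: RegimeSpec, seed: int,
                   a_fine: np.ndarray, t_fine: np.ndarray,
                   params: ModelParams,
                   surgery_window: Optional[tuple]) -> SubjectProfile:
    rng = np.random.default_rng(seed)
    dt = 10.0
    t_out = np.arange(0.0, spec.duration + dt / 2, dt)

    acth_fine = TimeSeries("ACTH", t_fine, a_fine, "ng/l", 1.0)
    c0 = steady_state_cortisol(params, float(np.mean(a_fine[:60])))
    sim = simulate_cortisol(params, acth_fine, t_out=t_fine, c_obs0=c0)
    c_fine = sim.C

    delta = _extra_lag_profile(t_fine, spec, rng)
    if np.any(delta > 0):
        c_fine = _warp_lag(t_fine, c_fine, delta)

    acth_obs = _apply_noise(_sample_to(t_out, t_fine, a_fine),
                            spec.noise_sd_frac, rng)
    cort_obs = _apply_noise(_sample_to(t_out, t_fine, c_fine),
                            spec.noise_sd_frac, rng)

    meta = {"params": params, "seed": seed, "regime": spec.regime,
            "noise_sd_frac": spec.noise_sd_frac}
    return SubjectProfile(
        subject_id=subject_id,
        acth=TimeSeries("ACTH", t_out, acth_obs, "ng/l", dt, dict(meta)),
        cortisol=TimeSeries("cortisol", t_out, cort_obs, "nmol/l", dt,
                            {**meta, "c_obs0": c0}),
        surgery_window=surgery_window,
        true_regime=spec.regime,
    )


def gen_healthy_profile(spec: Optional[RegimeSpec] = None, seed: int = 0,
                        subject_id: str = "control") -> SubjectProfile:
    """Healthy profile: regular ultradian pulses with circadian amplitude."""
    spec = spec or default_spec("control")
    if spec.regime != "control":
        raise ValueError("gen_healthy_profile expects regime='control'")
    if spec.duration < 720:
        raise ValueError("healthy profiles need at least 12 h of record")
    rng = np.random.default_rng(seed)
    centers = []
    t = float(rng.uniform(20.0, 60.0))
    while t < spec.duration - 30.0:
        centers.append(t)
        t += float(rng.uniform(150.0, 180.0))
    centers = np.asarray(centers)
    amps = (ACTH_CONTROL_AMP * spec.acth_peak_scale
            * _envelope(centers) / ACTH_ENV_HI
            * np.exp(0.4 * rng.standard_normal(len(centers))))
    t_fine = _fine_grid(spec.duration)
    a_fine = _envelope(t_fine) + _gauss_train(t_fine, centers, amps, PULSE_SD)
    return _build_profile(subject_id, spec, seed, a_fine, t_fine,
                          regime_params("control"), None)


def gen_cabg_profile(spec: Optional[RegimeSpec] = None, seed: int = 0,
                     subject_id: Optional[str] = None,
                     regime: Optional[str] = None) -> SubjectProfile:
    """Post-surgical 12-h profile in one of the three disruption regimes.

    The circadian envelope is suppressed (hormone dynamics are dominated by
    the surgical response); pulse placement, spacing and amplitude follow the
    regime recipe, and the cortisol trace acquires the regime's extra lag and
    synchrony-stability structure.
    """
    if spec is None:
        if regime is None:
            raise ValueError("give either a RegimeSpec or a regime name")
        spec = default_spec(regime)
    if spec.regime == "control":
        raise ValueError("use gen_healthy_profile for the control regime")
    rng = np.random.default_rng(seed)
    s0, s1 = SURGERY_WINDOW

    pulse_sd = PULSE_SD
    if spec.regime == "two_pulse":
        first = float(rng.uniform(150.0, 210.0))
        spacing = float(rng.uniform(300.0, 360.0))
        centers = np.array([first, first + spacing])
        amps = (ACTH_CONTROL_AMP * spec.acth_peak_scale
                * np.exp(0.1 * rng.standard_normal(2)))
        pulse_sd = 20.0
    elif spec.regime == "multiple_pulse":
        centers = []
        t = float(rng.uniform(40.0, 90.0))
        while t < spec.duration - 30.0:
            centers.append(t)
            t += float(rng.uniform(spec.pulse_period - 15.0,
                                   spec.pulse_period + 15.0))
        centers = np.asarray(centers)
        amps = (ACTH_CONTROL_AMP * spec.acth_peak_scale
                * np.exp(0.25 * rng.standard_normal(len(centers))))
    else:  # single_pulse: one broad excursion peaking ~2 h post-surgery
        centers = np.array([s1 + 120.0 + float(rng.uniform(-20.0, 20.0))])
        amps = np.array([ACTH_CONTROL_AMP * spec.acth_peak_scale
                         * float(np.exp(0.1 * rng.standard_normal()))])
        pulse_sd = 55.0

    t_fine = _fine_grid(spec.duration)
    a_fine = ACTH_ENV_LO + _gauss_train(t_fine, centers, amps, pulse_sd)
    return _build_profile(
        subject_id or f"{spec.regime}_{seed}", spec, seed, a_fine, t_fine,
        regime_params(spec.regime), SURGERY_WINDOW,
    )


#: mediator response templates: (onset offset after surgery midpoint [min],
#: gamma-rise time constant tau [min], peak level [pg/ml])
CYTOKINE_TEMPLATES: Dict[str, tuple] = {
    "IL6": (20.0, 90.0, 250.0),
    "TNFa": (10.0, 60.0, 25.0),
    "IL10": (30.0, 50.0, 150.0),
    "IL8": (10.0, 70.0, 60.0),
}


def _gamma_pulse(t: np.ndarray, onset: float, tau: float) -> np.ndarray:
    """Rise-and-decay response, peak normalized to 1 at onset + 2*tau."""
    s = np.maximum(t - onset, 0.0) / tau
    return (s ** 2) * np.exp(2.0 - s) / 4.0


def gen_cytokine_traces(profile: SubjectProfile,
                        coupling: Optional[Dict[str, float]] = None,
                        seed: int = 0,
                        gains: Optional[Dict[str, float]] = None) -> SubjectProfile:
    """Add IL6/TNFa/IL10/IL8 responses starting in the second half of surgery.

    Each mediator is near-baseline (~1% of peak) before the surgery midpoint,
    then rises and decays with a mediator-specific time course.  ``gains``
    scales each mediator's peak (1.0 = template level; 0 = flat baseline).
    ``coupling`` maps mediator name -> gain g: a cortisol disturbance
    ``g * mediator_trace`` (nmol/l per pg/ml) is added to the cortisol trace,
    recorded under ``cortisol.meta["disturbance"]``.
    """
    if profile.surgery_window is None:
        raise RuntimeError("profile has no surgery_window; cannot place onset")
    rng = np.random.default_rng(seed)
    s0, s1 = profile.surgery_window
    midpoint = 0.5 * (s0 + s1)
    t = profile.acth.t
    gains = {**{k: 1.0 for k in CYTOKINE_TEMPLATES}, **(gains or {})}

    cytokines = {}
    for name, (onset_off, tau, peak) in CYTOKINE_TEMPLATES.items():
        g = gains.get(name, 1.0)
        if g == 0:
            v = np.full_like(t, 0.01 * peak)
        else:
            shape = _gamma_pulse(t, midpoint + onset_off, tau)
            v = 0.01 * g * peak + g * peak * shape
            v = np.maximum(v * (1.0 + 0.03 * rng.standard_normal(v.shape)), 0.0)
        cytokines[name] = TimeSeries(name, t.copy(), v, "pg/ml", profile.acth.dt)

    out = SubjectProfile(
        subject_id=profile.subject_id,
        acth=profile.acth.copy(),
        cortisol=profile.cortisol.copy(),
        cytokines=cytokines,
        surgery_window=profile.surgery_window,
        true_regime=profile.true_regime,
    )
    if coupling:
        disturbance = np.zeros_like(t)
        for name, g in coupling.items():
            if name not in cytokines:
                raise ValueError(f"cannot couple to absent mediator {name!r}")
            disturbance = disturbance + g * cytokines[name].v
        out.cortisol = out.cortisol.with_values(
            np.maximum(out.cortisol.v + disturbance, 0.0),
            disturbance=disturbance,
        )
    return out


def gen_model_cortisol(params: ModelParams, acth: TimeSeries,
                       noise_sd_frac: float = 0.0, seed: int = 0) -> TimeSeries:
    """Ground-truth cortisol from the model plus multiplicative noise.

    Used by parameter-recovery and delay-recovery tests; the generating
    parameters are recorded in the output metadata.
    """
    c0 = steady_state_cortisol(params, float(acth.v[0]))
    sim = simulate_cortisol(params, acth, c_obs0=c0)
    rng = np.random.default_rng(seed)
    v = _apply_noise(sim.C, noise_sd_frac, rng)
    return TimeSeries("cortisol", acth.t.copy(), v, "nmol/l", acth.dt,
                      {"params": params, "noise_sd_frac": noise_sd_frac,
                       "seed": seed, "c_obs0": c0})


def gen_panel(n_per_regime: int = 3, seed: int = 0,
              regimes=("two_pulse", "multiple_pulse", "single_pulse"),
              noise_sd_frac: float = 0.05,
              with_cytokines: bool = False) -> list:
    """A mixed panel: ``n_per_regime`` subjects per listed regime."""
    rng = np.random.default_rng(seed)
    panel = []
    for regime in regimes:
        for i in range(n_per_regime):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sid = f"{regime}_{i}"
            if regime == "control":
                spec = default_spec("control", noise_sd_frac=noise_sd_frac)
                p = gen_healthy_profile(spec, seed=sub_seed, subject_id=sid)
            else:
                spec = default_spec(regime, noise_sd_frac=noise_sd_frac)
                p = gen_cabg_profile(spec, seed=sub_seed, subject_id=sid)
            if with_cytokines and p.surgery_window is not None:
                p = gen_cytokine_traces(p, seed=sub_seed)
            panel.append(p)
    return panel
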