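"""Open-loop two-compartment cortisol model driven by delayed ACTH input.

Cortisol C(t) = C_f(t) + C_s(t) is split into a fast and a slow compartment,
each produced in proportion to a Hill-type adrenal response to the ACTH
concentration ``delay`` minutes earlier and cleared with its own first-order
turnover:

    dC_f/dt = -C_f / lambda_f + p_f * H(A(t - delay))
    dC_s/dt = -C_s / lambda_s + p_s * H(A(t - delay))
    H(A)    = A^m / (K_A^m + A^m)

ACTH is a measured (or synthetic) input, not a state variable: the loop
through hypothalamic/pituitary feedback is deliberately left open so that one
hormone's data can drive the other.  The model is linear in the states given
the drive, so the integrator below exploits nothing fancier than a fixed-step
classic Runge-Kutta scheme with the piecewise-linear input evaluated at stage
times.

Initial condition: the fast compartment starts at quasi-equilibrium with the
(delay-clamped) drive at t = 0, and the slow compartment absorbs whatever is
left of the observed initial cortisol,
``C_s(0) = max(C_obs(0) - C_f(0), 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .core import TimeSeries, RangeError

__all__ = [
    "ModelParams", "SimResult", "hill_drive", "initial_state",
    "simulate_cortisol", "steady_state_cortisol", "CONTROL_PARAMS",
]


@dataclass(frozen=True)
class ModelParams:
    """The six model parameters plus the input delay.

    p_f, p_s : nmol/l per min  — fast / slow cortisol production rates
    lambda_f, lambda_s : min   — fast / slow turnover time constants
                                 (1/lambda is the turnover rate)
    K_A : ng/l                 — adrenal sensitivity (Hill half-max)
    m : dimensionless >= 1     — Hill coefficient (sigmoid steepness)
    delay : min                — ACTH-to-adrenal input delay
    """

    p_f: float
    p_s: float
    lambda_f: float
    lambda_s: float
    K_A: float
    m: float
    delay: float = 10.0

    def __post_init__(self) -> None:
        if self.p_f < 0 or self.p_s < 0:
            raise ValueError("production rates must be non-negative")
        if self.lambda_f <= 0 or self.lambda_s <= 0 or self.K_A <= 0:
            raise ValueError("lambda_f, lambda_s and K_A must be positive")
        if self.lambda_f >= self.lambda_s:
            raise ValueError("need lambda_f < lambda_s (fast compartment is faster)")
        if self.m < 1:
            raise ValueError("Hill coefficient m must be >= 1")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


#: control-like parameter set used by the synthetic-data generator; adrenal
#: sensitivity sits at the control median K_A = 50.28 ng/l with a Hill
#: coefficient of 2.  The gain is strongly fast-dominated (rapid cortisol
#: turnover tracking the delayed ACTH drive) — the configuration consistent
#: with the near-physiological ~10-min ACTH-to-cortisol peak lag of healthy
#: profiles — and is calibrated so healthy synthetic ACTH yields cortisol in
#: the physiological few-hundred-nmol/l range.
CONTROL_PARAMS = ModelParams(
    p_f=325.0, p_s=0.8, lambda_f=2.5, lambda_s=300.0,
    K_A=50.28, m=2.0, delay=10.0,
)


@dataclass
class SimResult:
    """Simulated compartment traces on the requested output grid."""

    t: np.ndarray
    C_f: np.ndarray
    C_s: np.ndarray
    params: ModelParams
    C: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.C = self.C_f + self.C_s

    def total(self, name: str = "cortisol") -> TimeSeries:
        return TimeSeries(name, self.t, self.C, "nmol/l")


def hill_drive(A, K_A: float, m: float):
    """Sigmoidal adrenal response ``A^m / (K_A^m + A^m)`` in [0, 1).

    Accepts scalars or arrays for ``A``; ``K_A`` and ``m`` may be arrays
    broadcastable against ``A`` (used by the vectorized ensemble fitter).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("ACTH concentration must be non-negative")
    x = np.power(A, m)
    out = x / (np.power(K_A, m) + x)
    return float(out) if out.ndim == 0 else out


def _delayed_input(acth: TimeSeries, delay: float):
    """A(t - delay), linearly interpolated, clamped to A(t0) before the record."""
    t_data, v = acth.t, acth.v
    if np.isnan(v).any():
        raise ValueError("ACTH input contains missing samples; resample first")

    def A_eff(t):
        return np.interp(np.asarray(t, float) - delay, t_data, v,
                         left=v[0], right=v[-1])

    return A_eff


def initial_state(params: ModelParams, acth: TimeSeries,
                  c_obs0: float) -> Tuple[float, float]:
    """Quasi-equilibrium fast compartment; slow takes the remainder.

    ``C_f(0) = p_f * lambda_f * H(A_eff(0))`` with the delay-clamped input at
    the record start, then ``C_s(0) = max(c_obs0 - C_f(0), 0)``.
    """
    if c_obs0 < 0:
        raise ValueError("initial observed cortisol must be non-negative")
    drive0 = hill_drive(float(acth.v[0]), params.K_A, params.m)
    c_f0 = params.p_f * params.lambda_f * drive0
    return c_f0, max(c_obs0 - c_f0, 0.0)


def steady_state_cortisol(params: ModelParams, A_const: float) -> float:
    """Fixed point of the model under constant ACTH input:
    ``(p_f lambda_f + p_s lambda_s) * H(A_const)``."""
    h = hill_drive(A_const, params.K_A, params.m)
    return (params.p_f * params.lambda_f + params.p_s * params.lambda_s) * h


def _rk4_compartments(drive_half: np.ndarray, h: float, n_rec: int, n_sub: int,
                      p_f, p_s, inv_lf, inv_ls, C_f, C_s):
    """Advance both compartments with classic RK4, recording every n_sub steps.

    ``drive_half`` holds the drive at half-step resolution (length
    2 * n_rec * n_sub + 1); states/parameters may be scalars or 1-D arrays of
    parameter sets (shared drive index, per-set drive values allowed when
    ``drive_half`` is 2-D with shape (n_times, n_sets)).
    """
    shape = np.broadcast(np.asarray(C_f), np.asarray(C_s)).shape
    out_f = np.empty((n_rec + 1,) + shape)
    out_s = np.empty((n_rec + 1,) + shape)
    out_f[0], out_s[0] = C_f, C_s
    j = 0
    for rec in range(n_rec):
        for _ in range(n_sub):
            H1, H2, H3 = drive_half[2 * j], drive_half[2 * j + 1], drive_half[2 * j + 2]
            # fast compartment
            k1 = -C_f * inv_lf + p_f * H1
            k2 = -(C_f + 0.5 * h * k1) * inv_lf + p_f * H2
            k3 = -(C_f + 0.5 * h * k2) * inv_lf + p_f * H2
            k4 = -(C_f + h * k3) * inv_lf + p_f * H3
            C_f = C_f + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            # slow compartment
            k1 = -C_s * inv_ls + p_s * H1
            k2 = -(C_s + 0.5 * h * k1) * inv_ls + p_s * H2
            k3 = -(C_s + 0.5 * h * k2) * inv_ls + p_s * H2
            k4 = -(C_s + h * k3) * inv_ls + p_s * H3
            C_s = C_s + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            j += 1
        out_f[rec + 1], out_s[rec + 1] = C_f, C_s
    return out_f, out_s


def simulate_cortisol(params: ModelParams, acth: TimeSeries,
                      t_out: Optional[np.ndarray] = None,
                      c_obs0: Optional[float] = None,
                      step: float = 0.5) -> SimResult:
    """Integrate the two-compartment model over ``t_out``.

    Parameters
    ----------
    params
        Model parameters.
    acth
        ACTH input series (ng/l); must span ``t_out``.
    t_out
        Uniform output grid in minutes; defaults to the ACTH grid.
    c_obs0
        Observed cortisol at ``t_out[0]`` used by the initial condition.
        Defaults to the steady state at the initial (delay-clamped) input.
    step
        Internal integrator step in minutes (rounded down so that output
        intervals are integer multiples of it).
    """
    t_out = acth.t.copy() if t_out is None else np.asarray(t_out, dtype=float)
    if len(t_out) < 2:
        raise ValueError("t_out needs at least two points")
    dt_out = float(t_out[1] - t_out[0])
    if not np.allclose(np.diff(t_out), dt_out):
        raise ValueError("t_out must be uniform")
    if t_out[0] < acth.t[0] - 1e-9 or t_out[-1] > acth.t[-1] + 1e-9:
        raise RangeError("ACTH input does not span the requested output grid")
    if step <= 0:
        raise ValueError("step must be positive")

    A_eff = _delayed_input(acth, params.delay)
    if c_obs0 is None:
        c_obs0 = steady_state_cortisol(params, float(A_eff(t_out[0])))
    C_f0, C_s0 = initial_state(params, acth, c_obs0)

    n_rec = len(t_out) - 1
    n_sub = max(1, int(np.ceil(dt_out / step - 1e-12)))
    h = dt_out / n_sub
    t_half = t_out[0] + (h / 2.0) * np.arange(2 * n_rec * n_sub + 1)
    drive = hill_drive(A_eff(t_half), params.K_A, params.m)

    out_f, out_s = _rk4_compartments(
        drive, h, n_rec, n_sub,
        params.p_f, params.p_s, 1.0 / params.lambda_f, 1.0 / params.lambda_s,
        float(C_f0), float(C_s0),
    )
    # clip infinitesimal negative round-off; the dynamics are non-negative
    out_f = np.maximum(np.asarray(out_f, float), 0.0)
    out_s = np.maximum(np.asarray(out_s, float), 0.0)
    return SimResult(t=t_out, C_f=out_f, C_s=out_s, params=params)
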