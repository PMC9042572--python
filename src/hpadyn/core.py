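"""Shared time-series data model for hormone and cytokine profiles.

Every signal handled by the pipeline is a uniformly sampled scalar trace:
ACTH in ng/l, cortisol in nmol/l, inflammatory mediators in pg/ml.  Time is
always expressed in minutes since each subject's own sampling start (t = 0 at
the first sample); wall-clock times, where relevant, live in metadata only.
Missing samples are stored as NaN, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

CONCENTRATION_UNITS = frozenset({"ng/l", "nmol/l", "pg/ml"})
VALID_UNITS = CONCENTRATION_UNITS | {"dimensionless"}

CYTOKINE_NAMES = ("IL6", "TNFa", "IL10", "IL8", "IL2", "IL4", "IL1a")

#: relative spacing jitter accepted (and snapped) on the time grid
GRID_TOLERANCE = 0.01


class GridError(ValueError):
    """Raised when a time grid is non-uniform beyond tolerance or mismatched."""


class SchemaError(ValueError):
    """Raised when a CSV panel is missing required columns."""


class RangeError(ValueError):
    """Raised when a requested window falls outside a series' span."""


@dataclass
class TimeSeries:
    """A uniformly sampled, time-stamped scalar signal with units.

    Parameters
    ----------
    name
        Analyte label, e.g. ``"ACTH"`` or ``"cortisol"``.
    t
        Sample times in minutes, strictly increasing on a uniform grid.
    v
        Sample values; NaN marks an explicitly missing sample.
    units
        One of ``ng/l``, ``nmol/l``, ``pg/ml`` or ``dimensionless``.
    dt
        Sampling interval in minutes; inferred from ``t`` when omitted.
    meta
        Free-form metadata (interpolation gaps, generating parameters, ...).
    """

    name: str
    t: np.ndarray
    v: np.ndarray
    units: str = "dimensionless"
    dt: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.v.ndim != 1:
            raise ValueError("t and v must be one-dimensional")
        if len(self.t) != len(self.v):
            raise ValueError(
                f"t and v length mismatch: {len(self.t)} vs {len(self.v)}"
            )
        if len(self.t) < 2:
            raise ValueError("a TimeSeries needs at least two samples")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        diffs = np.diff(self.t)
        if np.any(diffs <= 0):
            raise GridError("time grid must be strictly increasing")
        dt = self.dt if self.dt is not None else float(np.median(diffs))
        if np.any(np.abs(diffs - dt) > GRID_TOLERANCE * dt):
            raise GridError(
                f"non-uniform grid: spacing deviates more than "
                f"{GRID_TOLERANCE:.0%} from dt={dt:g} min"
            )
        # snap small jitter onto the exact grid
        self.dt = float(dt)
        self.t = self.t[0] + self.dt * np.arange(len(self.t))
        finite = self.v[np.isfinite(self.v)]
        if np.any(~np.isfinite(self.v) & ~np.isnan(self.v)):
            raise ValueError("values must be finite or NaN (missing)")
        # difference series (e.g. model residuals) are signed by nature and
        # declare it via meta; actual concentrations must be non-negative
        if (self.units in CONCENTRATION_UNITS and not self.meta.get("signed")
                and np.any(finite < 0)):
            raise ValueError(
                f"negative concentration in {self.name!r} ({self.units})"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Record span in minutes."""
        return float(self.t[-1] - self.t[0])

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing samples."""
        return np.isnan(self.v)

    def with_values(self, v: np.ndarray, **meta) -> "TimeSeries":
        """Copy of this series with new values (same grid and units)."""
        return TimeSeries(
            self.name, self.t.copy(), np.asarray(v, dtype=float),
            self.units, self.dt, {**self.meta, **meta},
        )

    def copy(self) -> "TimeSeries":
        return TimeSeries(
            self.name, self.t.copy(), self.v.copy(),
            self.units, self.dt, dict(self.meta),
        )

    def same_grid(self, other: "TimeSeries") -> bool:
        return len(self) == len(other) and np.allclose(
            self.t, other.t, atol=1e-9 * max(self.dt, other.dt)
        )

    def require_same_grid(self, other: "TimeSeries") -> None:
        if not self.same_grid(other):
            raise GridError(
                f"series {self.name!r} and {other.name!r} are not on a "
                f"shared time grid"
            )


@dataclass
class SubjectProfile:
    """Paired ACTH + cortisol record with optional cytokine panel.

    ``surgery_window`` is ``(start_min, end_min)`` relative to sampling start;
    ``true_regime`` is only set on synthetic profiles and records the regime
    the generator was asked for.
    """

    subject_id: str
    acth: TimeSeries
    cortisol: TimeSeries
    cytokines: dict = field(default_factory=dict)
    surgery_window: Optional[tuple] = None
    true_regime: Optional[str] = None

    def __post_init__(self) -> None:
        for key in self.cytokines:
            if key not in CYTOKINE_NAMES:
                raise ValueError(f"unknown cytokine {key!r}")
        if self.surgery_window is not None:
            s, e = self.surgery_window
            if not s < e:
                raise ValueError("surgery_window start must precede end")
            self.surgery_window = (float(s), float(e))

    @property
    def series(self) -> Mapping[str, TimeSeries]:
        out = {"ACTH": self.acth, "cortisol": self.cortisol}
        out.update(self.cytokines)
        return out

    def validate_shared_grid(self) -> None:
        """Raise GridError unless all member series share one time grid."""
        for ts in self.series.values():
            self.acth.require_same_grid(ts)


def resample_uniform(ts: TimeSeries, dt_out: float) -> TimeSeries:
    """Linearly interpolate a series onto a uniform grid with spacing ``dt_out``.

    The output grid spans ``[t_first, t_last]``; both endpoints are preserved
    when the span is an integer multiple of ``dt_out``.  Missing samples are
    interpolated across and the bridged gaps recorded under
    ``meta["interpolated_gaps"]`` as ``(t_start, t_end)`` pairs.
    """
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    t0, t1 = ts.t[0], ts.t[-1]
    n = int(math.floor((t1 - t0) / dt_out + 1e-9)) + 1
    t_new = t0 + dt_out * np.arange(n)
    good = ~ts.missing
    if good.sum() < 2:
        raise ValueError("need at least two non-missing samples to resample")
    v_new = np.interp(t_new, ts.t[good], ts.v[good])
    gaps = []
    if ts.missing.any():
        idx = np.flatnonzero(ts.missing)
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                gaps.append((float(ts.t[start]), float(ts.t[prev])))
                start = i
            prev = i
        gaps.append((float(ts.t[start]), float(ts.t[prev])))
    meta = dict(ts.meta)
    if gaps:
        meta["interpolated_gaps"] = gaps
    return TimeSeries(ts.name, t_new, v_new, ts.units, dt_out, meta)


def area_under_curve(ts: TimeSeries, t0: float, t1: float) -> float:
    """Trapezoidal integral of ``ts`` over ``[t0, t1]`` in units x hours.

    Missing samples are interpolated across.  The window must lie within the
    record span.
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    if t0 < ts.t[0] - 1e-9 or t1 > ts.t[-1] + 1e-9:
        raise RangeError(
            f"window [{t0}, {t1}] outside record span "
            f"[{ts.t[0]}, {ts.t[-1]}]"
        )
    good = ~ts.missing
    inside = (ts.t > t0) & (ts.t < t1) & good
    tt = np.concatenate(([t0], ts.t[inside], [t1]))
    vv = np.interp(tt, ts.t[good], ts.v[good])
    return float(np.trapezoid(vv, tt) / 60.0)
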