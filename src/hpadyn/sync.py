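"""Non-stationary synchrony battery for paired ACTH/cortisol records.

Implements the statistics used to characterize hormone co-dynamics on a
uniform 10-min grid: time-dependent hormone ratio, rolling Pearson
correlation, instantaneous phase synchrony (IPS) of the band-passed analytic
signals, time-lagged cross-correlation (TLCC, Spearman), its rolling-window
variant (RWTLCC), ultradian period estimation and pulse counting.

Sign convention: a positive TLCC peak lag means the *first* argument (ACTH)
leads the second (cortisol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import rankdata

from .core import GridError, TimeSeries

__all__ = [
    "SyncMetrics", "UndefinedPeriodError",
    "hormone_ratio", "rolling_correlation", "instantaneous_phase_synchrony",
    "tlcc", "rwtlcc", "estimate_ultradian_period", "count_pulses",
    "compute_sync_metrics",
]


class UndefinedPeriodError(ValueError):
    """The record has no estimable ultradian period (constant / single pulse)."""


@dataclass
class SyncMetrics:
    """Bundle of synchrony statistics feeding the phenotype classifier."""

    tlcc_lags: np.ndarray          # minutes
    tlcc_r: np.ndarray             # Spearman r per lag
    peak_lag: float                # minutes; >0 means ACTH leads
    peak_r: float
    rwtlcc: np.ndarray             # epochs x lags
    rwtlcc_lags: np.ndarray        # minutes (per-epoch lag grid)
    ips: TimeSeries                # in [0, 1]
    rolling_r: TimeSeries          # in [-1, 1]
    ratio: TimeSeries
    period: Optional[float]        # minutes; None when undefined
    n_pulses: int


def hormone_ratio(a: TimeSeries, c: TimeSeries) -> TimeSeries:
    """Elementwise a/c; samples where c == 0 are flagged missing."""
    a.require_same_grid(c)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a.v / c.v
    r[c.v == 0] = np.nan
    return TimeSeries(f"{a.name}/{c.name}", a.t.copy(), r, "dimensionless", a.dt)


def rolling_correlation(a: TimeSeries, c: TimeSeries, window: float) -> TimeSeries:
    """Centered rolling Pearson correlation over ``window`` minutes.

    Samples whose window is incomplete (record ends) or degenerate (zero
    variance) are flagged missing.
    """
    a.require_same_grid(c)
    w = int(round(window / a.dt)) + 1
    if w < 3:
        raise ValueError("window must cover at least 3 samples")
    if w > len(a):
        raise ValueError("window longer than the record")
    sa, sc = pd.Series(a.v), pd.Series(c.v)
    r = sa.rolling(w, center=True, min_periods=w).corr(sc).to_numpy()
    r[~np.isfinite(r)] = np.nan
    # windows with (numerically) no variance have an undefined correlation
    tol_a = 1e-4 * (np.nanmax(a.v) - np.nanmin(a.v))
    tol_c = 1e-4 * (np.nanmax(c.v) - np.nanmin(c.v))
    sd_a = sa.rolling(w, center=True, min_periods=w).std().to_numpy()
    sd_c = sc.rolling(w, center=True, min_periods=w).std().to_numpy()
    r[(sd_a < tol_a) | (sd_c < tol_c)] = np.nan
    return TimeSeries("rolling_r", a.t.copy(), r, "dimensionless", a.dt)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant trace")
    return (v - np.mean(v)) / sd


def _bandpass(v: np.ndarray, dt: float, period_min: float,
              period_max: float) -> np.ndarray:
    fs = 1.0 / dt  # samples per minute
    lo, hi = 1.0 / period_max, 1.0 / period_min
    hi = min(hi, 0.99 * fs / 2.0)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, v)


def instantaneous_phase_synchrony(a: TimeSeries, c: TimeSeries,
                                  period_min: float = 60.0,
                                  period_max: float = 480.0) -> TimeSeries:
    """Per-sample phase agreement ``1 - |sin((phi_a - phi_c)/2)|`` in [0, 1].

    Both series are z-scored, band-passed to the ultradian band (periods
    ``period_min``..``period_max`` minutes) and Hilbert-transformed; the IPS
    maps zero phase difference to 1 and antiphase to 0.
    """
    a.require_same_grid(c)
    if a.duration < 2 * period_min:
        raise ValueError("record too short for phase extraction")
    pa = np.angle(signal.hilbert(_bandpass(_zscore(a.v), a.dt, period_min, period_max)))
    pc = np.angle(signal.hilbert(_bandpass(_zscore(c.v), c.dt, period_min, period_max)))
    ips = 1.0 - np.abs(np.sin((pa - pc) / 2.0))
    return TimeSeries("IPS", a.t.copy(), ips, "dimensionless", a.dt)


def _spearman_lagged(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Spearman r between x[t] and y[t + k] (k in samples)."""
    if k >= 0:
        xs, ys = x[: len(x) - k or None], y[k:]
    else:
        xs, ys = x[-k:], y[: len(y) + k]
    good = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[good], ys[good]
    if len(xs) < 3:
        return np.nan
    rx, ry = rankdata(xs), rankdata(ys)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _pick_peak(lags: np.ndarray, r: np.ndarray) -> Tuple[float, float]:
    """Argmax of r, ties broken toward the smallest |lag|."""
    finite = np.isfinite(r)
    if not finite.any():
        return 0.0, np.nan
    rmax = np.nanmax(r)
    cand = np.flatnonzero(finite & (r >= rmax - 1e-12))
    best = cand[np.argmin(np.abs(lags[cand]))]
    return float(lags[best]), float(r[best])


def _tlcc_curve(av: np.ndarray, cv: np.ndarray, dt: float, L: int):
    ks = np.arange(-L, L + 1)
    r = np.array([_spearman_lagged(av, cv, k) for k in ks])
    return ks * dt, r


def tlcc(a: TimeSeries, c: TimeSeries, max_lag: float):
    """Time-lagged Spearman cross-correlation.

    Returns ``(lags, r, peak_lag, peak_r)`` where lags run over integer
    multiples of the sampling step in ``[-max_lag, +max_lag]``.  A positive
    ``peak_lag`` means ``a`` leads ``c``.
    """
    a.require_same_grid(c)
    L = int(round(max_lag / a.dt))
    if 3 * L > len(a) and L > 0:
        raise ValueError("max_lag exceeds a third of the record length")
    lags, r = _tlcc_curve(a.v, c.v, a.dt, L)
    peak_lag, peak_r = _pick_peak(lags, r)
    return lags, r, peak_lag, peak_r


def rwtlcc(a: TimeSeries, c: TimeSeries, window: float, step: float,
           max_lag: float):
    """TLCC recomputed in rolling epochs: one matrix row per epoch.

    Epoch ``e`` covers the window starting at ``e * step``; elapsed time
    increases down the rows, suiting heat-map rendering.  Returns
    ``(matrix, lags_minutes)``.
    """
    a.require_same_grid(c)
    L = int(round(max_lag / a.dt))
    w = int(round(window / a.dt)) + 1
    s = max(1, int(round(step / a.dt)))
    if w < 2 * L + 3:
        raise ValueError(
            "window must cover at least 2*max_lag + 3 samples"
        )
    n = len(a)
    w_eff = min(w, n)
    starts = list(range(0, n - w_eff + 1, s)) or [0]
    rows = []
    for st in starts:
        _, r = _tlcc_curve(a.v[st:st + w_eff], c.v[st:st + w_eff], a.dt, L)
        rows.append(r)
    return np.vstack(rows), np.arange(-L, L + 1) * a.dt


def _detrend(ts: TimeSeries, window: float) -> np.ndarray:
    w = max(3, int(round(window / ts.dt)) + 1)
    trend = pd.Series(ts.v).rolling(w, center=True, min_periods=1).mean().to_numpy()
    return ts.v - trend


def count_pulses(ts: TimeSeries, prominence_frac: float = 0.2,
                 min_separation: float = 60.0) -> int:
    """Number of interior local maxima with prominence >= ``prominence_frac``
    of the trace range and separation >= ``min_separation`` minutes.

    Extrema at the record boundaries are never counted (their prominence is
    undefined), so a monotone ramp has zero pulses.
    """
    if ts.duration < 120:
        raise ValueError("record must span at least 2 h")
    v = np.where(np.isnan(ts.v), np.nanmean(ts.v), ts.v)
    rng = float(np.ptp(v))
    if rng == 0:
        return 0
    peaks, _ = signal.find_peaks(
        v, prominence=prominence_frac * rng,
        distance=max(1, int(round(min_separation / ts.dt))),
    )
    return int(len(peaks))


def _pulse_times(ts: TimeSeries, prominence_frac: float = 0.2,
                 min_separation: float = 60.0) -> np.ndarray:
    v = np.where(np.isnan(ts.v), np.nanmean(ts.v), ts.v)
    rng = float(np.ptp(v))
    if rng == 0:
        return np.array([])
    peaks, _ = signal.find_peaks(
        v, prominence=prominence_frac * rng,
        distance=max(1, int(round(min_separation / ts.dt))),
    )
    return ts.t[peaks]


def estimate_ultradian_period(ts: TimeSeries, detrend_window: float = 360.0,
                              prominence_frac: float = 0.2,
                              min_separation: float = 60.0) -> float:
    """Ultradian period T_u in minutes.

    Primary estimator: lag of the first prominent positive peak of the
    autocorrelation of the moving-average-detrended trace.  When the
    autocorrelation shows no prominent peak the estimate falls back to the
    mean peak-to-peak interval of the detected pulses.  Constant or
    single-pulse records raise :class:`UndefinedPeriodError`.
    """
    if np.ptp(ts.v[~np.isnan(ts.v)]) == 0:
        raise UndefinedPeriodError("constant record has no period")
    x = _detrend(ts, detrend_window)
    x = np.where(np.isnan(x), 0.0, x - np.nanmean(x))
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    if ac[0] > 0:
        ac = ac / ac[0]
        peaks, props = signal.find_peaks(ac, prominence=0.1)
        peaks = peaks[ac[peaks] > 0]
        if len(peaks):
            return float(peaks[0] * ts.dt)
    # fallback: mean inter-pulse interval
    pt = _pulse_times(ts, prominence_frac, min_separation)
    if len(pt) >= 2:
        return float(np.mean(np.diff(pt)))
    raise UndefinedPeriodError(
        f"no repeating structure found in {ts.name!r}"
    )


def compute_sync_metrics(acth: TimeSeries, cortisol: TimeSeries,
                         config=None) -> SyncMetrics:
    """Run the full battery on one ACTH/cortisol pair."""
    from .config import AnalysisConfig

    cfg = config or AnalysisConfig()
    lags, r, peak_lag, peak_r = tlcc(acth, cortisol, cfg.max_lag)
    matrix, rw_lags = rwtlcc(acth, cortisol, cfg.rwtlcc_window,
                             cfg.rwtlcc_step, cfg.rwtlcc_max_lag)
    ips = instantaneous_phase_synchrony(acth, cortisol,
                                        cfg.band_period_min, cfg.band_period_max)
    roll = rolling_correlation(acth, cortisol, cfg.rolling_window)
    ratio = hormone_ratio(acth, cortisol)
    try:
        period = estimate_ultradian_period(
            cortisol, cfg.detrend_window,
            cfg.pulse_prominence_frac, cfg.pulse_min_separation)
    except UndefinedPeriodError:
        period = None
    n_pulses = count_pulses(cortisol, cfg.pulse_prominence_frac,
                            cfg.pulse_min_separation)
    return SyncMetrics(
        tlcc_lags=lags, tlcc_r=r, peak_lag=peak_lag, peak_r=peak_r,
        rwtlcc=matrix, rwtlcc_lags=rw_lags, ips=ips, rolling_r=roll,
        ratio=ratio, period=period, n_pulses=n_pulses,
    )
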