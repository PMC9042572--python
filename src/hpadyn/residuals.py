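"""Residual-error versus inflammation analysis.

The cortisol model deliberately excludes cytokines, so any systematic
discrepancy between its best-fit prediction and the observed cortisol may
carry the signature of inflammatory regulation.  This module computes the
time-varying residual (observed minus predicted cortisol), z-scores it, and
correlates it with each subject's inflammatory-mediator trajectories and
additive combinations of them.  A PCA over the pooled post-surgery mediator
trajectories identifies which cytokines dominate the inflammatory response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import SubjectProfile, TimeSeries
from .config import DEFAULT_COMBOS

__all__ = [
    "ResidualReport", "residual_series", "zscore_normalize",
    "cytokine_pca", "residual_cytokine_correlations",
]


@dataclass
class ResidualReport:
    residuals: Dict[str, TimeSeries]      # subject -> residual trace (nmol/l)
    correlations: pd.DataFrame            # subjects x mediator-combinations
    pca: Optional[dict]                   # loadings + variance explained
    combos: List[str]                     # combo labels, column order


def residual_series(pred: TimeSeries, obs: TimeSeries) -> TimeSeries:
    """Observed minus predicted cortisol, elementwise on a shared grid."""
    pred.require_same_grid(obs)
    return TimeSeries("residual", obs.t.copy(), obs.v - pred.v,
                      obs.units, obs.dt, {"signed": True})


def zscore_normalize(ts: TimeSeries) -> TimeSeries:
    """(v - mean) / sd with the sample (n-1) standard deviation."""
    good = ~np.isnan(ts.v)
    if good.sum() < 2 or np.ptp(ts.v[good]) == 0:
        raise ValueError(f"cannot z-score constant series {ts.name!r}")
    mean = float(np.mean(ts.v[good]))
    sd = float(np.std(ts.v[good], ddof=1))
    return TimeSeries(ts.name, ts.t.copy(), (ts.v - mean) / sd,
                      "dimensionless", ts.dt, dict(ts.meta))


def _combo_label(combo: Sequence[str]) -> str:
    return "+".join(combo)


def _combo_trace(profile: SubjectProfile, combo: Sequence[str]) -> Optional[TimeSeries]:
    """Sum of individually z-scored members, re-z-scored; None if any absent."""
    traces = []
    for name in combo:
        ts = profile.cytokines.get(name)
        if ts is None or np.isnan(ts.v).all():
            return None
        traces.append(zscore_normalize(ts).v)
    total = np.sum(traces, axis=0)
    ref = profile.cytokines[combo[0]]
    summed = TimeSeries(_combo_label(combo), ref.t.copy(), total,
                        "dimensionless", ref.dt)
    return zscore_normalize(summed) if np.ptp(total) > 0 else summed


def cytokine_pca(panel: Sequence[SubjectProfile],
                 mediators: Sequence[str] = ("IL6", "TNFa", "IL10", "IL8"),
                 post_surgery_only: bool = True) -> dict:
    """PCA over pooled mediator trajectories.

    Observations are time points pooled across subjects (post-surgery-onset
    by default); variables are the per-subject z-scored mediators.  Returns
    component loadings, variance-explained ratios and the mediators that
    dominate the first component (|loading| >= half the largest).
    """
    rows = []
    for p in panel:
        cols = []
        for name in mediators:
            ts = p.cytokines.get(name)
            if ts is None or np.isnan(ts.v).mean() > 0.5:
                raise ValueError(
                    f"mediator {name!r} absent or mostly missing for "
                    f"subject {p.subject_id!r}"
                )
            cols.append(zscore_normalize(ts).v)
        block = np.column_stack(cols)
        if post_surgery_only and p.surgery_window is not None:
            block = block[p.acth.t >= p.surgery_window[0]]
        rows.append(block)
    X = np.vstack(rows)
    X = X[~np.isnan(X).any(axis=1)]
    pca = PCA()
    pca.fit(X)
    loadings = pd.DataFrame(pca.components_,
                            columns=list(mediators),
                            index=[f"PC{i+1}" for i in range(pca.n_components_)])
    pc1 = loadings.iloc[0].abs()
    dominant = list(pc1[pc1 >= 0.5 * pc1.max()].index)
    return {
        "loadings": loadings,
        "variance_explained": pca.explained_variance_ratio_,
        "dominant_mediators": dominant,
    }


def residual_cytokine_correlations(
        residuals: Dict[str, TimeSeries],
        panel: Sequence[SubjectProfile],
        combos: Optional[Sequence[Sequence[str]]] = None,
        run_pca: bool = True) -> ResidualReport:
    """Pearson correlations between z-scored residuals and mediator combos.

    One matrix row per subject, one column per additive mediator combination;
    combos referencing a mediator the subject lacks yield a missing cell.
    """
    combos = [list(c) for c in (combos or DEFAULT_COMBOS)]
    labels = [_combo_label(c) for c in combos]
    by_id = {p.subject_id: p for p in panel}
    rows = {}
    for sid, res in residuals.items():
        p = by_id[sid]
        zres = zscore_normalize(res)
        row = {}
        for combo, label in zip(combos, labels):
            trace = _combo_trace(p, combo)
            if trace is None:
                row[label] = np.nan
                continue
            good = ~(np.isnan(zres.v) | np.isnan(trace.v))
            if good.sum() < 3 or np.ptp(trace.v[good]) == 0:
                row[label] = np.nan
            else:
                row[label] = float(np.corrcoef(zres.v[good], trace.v[good])[0, 1])
        rows[sid] = row
    corr = pd.DataFrame.from_dict(rows, orient="index")[labels]

    pca_out = None
    if run_pca:
        with_cyt = [p for p in panel if p.subject_id in residuals
                    and all(m in p.cytokines for m in ("IL6", "TNFa", "IL10", "IL8"))]
        if with_cyt:
            pca_out = cytokine_pca(with_cyt)
    return ResidualReport(residuals=dict(residuals), correlations=corr,
                          pca=pca_out, combos=labels)
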