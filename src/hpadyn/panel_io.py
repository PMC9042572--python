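"""CSV persistence for subject panels.

The canonical on-disk form is a long table with columns
``subject_id, analyte, t_min, value, units`` (one row per sample; blank
``value`` cells mean missing).  Per-subject metadata that does not fit the
long table — the surgery window and, for synthetic profiles, the true regime
label — travels in an optional JSON sidecar written next to the CSV as
``<stem>.meta.json``.  A wide-format reader (one time column plus one column
per analyte, single subject) is provided for convenience.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CYTOKINE_NAMES,
    SchemaError,
    SubjectProfile,
    TimeSeries,
)

LONG_COLUMNS = ("subject_id", "analyte", "t_min", "value", "units")

_DEFAULT_UNITS = {"ACTH": "ng/l", "cortisol": "nmol/l"}
_DEFAULT_UNITS.update({c: "pg/ml" for c in CYTOKINE_NAMES})


def _meta_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def write_panel_csv(profiles: Sequence[SubjectProfile], path) -> None:
    """Write a panel in canonical long format plus its metadata sidecar."""
    rows = []
    meta = {}
    for p in profiles:
        for analyte, ts in p.series.items():
            for t, v in zip(ts.t, ts.v):
                rows.append((p.subject_id, analyte, float(t),
                             None if np.isnan(v) else float(v), ts.units))
        entry = {}
        if p.surgery_window is not None:
            entry["surgery_window"] = list(p.surgery_window)
        if p.true_regime is not None:
            entry["true_regime"] = p.true_regime
        if entry:
            meta[p.subject_id] = entry
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")
    if meta:
        _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_panel_csv(path, schema: Optional[dict] = None) -> list:
    """Read a canonical long-format panel into ``SubjectProfile`` objects.

    ``schema`` maps the canonical column names to the ones used in the file,
    e.g. ``{"t_min": "time"}``; unmapped names are taken verbatim.
    """
    schema = {**{c: c for c in LONG_COLUMNS}, **(schema or {})}
    df = pd.read_csv(path)
    missing = [schema[c] for c in LONG_COLUMNS if schema[c] not in df.columns]
    if missing:
        raise SchemaError(f"panel CSV is missing required columns: {missing}")
    df = df.rename(columns={v: k for k, v in schema.items()})

    sidecar = _meta_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    profiles = []
    for sid, g in df.groupby("subject_id", sort=False):
        series = {}
        for analyte, ga in g.groupby("analyte", sort=False):
            ga = ga.sort_values("t_min")
            units = ga["units"].iloc[0]
            series[analyte] = TimeSeries(
                analyte, ga["t_min"].to_numpy(dtype=float),
                ga["value"].to_numpy(dtype=float), units,
            )
        if "ACTH" not in series or "cortisol" not in series:
            raise SchemaError(
                f"subject {sid!r} lacks an ACTH or cortisol trace"
            )
        m = meta.get(str(sid), {})
        profiles.append(SubjectProfile(
            subject_id=str(sid),
            acth=series.pop("ACTH"),
            cortisol=series.pop("cortisol"),
            cytokines=series,
            surgery_window=tuple(m["surgery_window"])
            if "surgery_window" in m else None,
            true_regime=m.get("true_regime"),
        ))
    if not profiles:
        raise SchemaError("panel CSV contains no subjects")
    return profiles


def read_wide_csv(path, subject_id: str = "subject",
                  time_col: str = "t_min",
                  units: Optional[dict] = None) -> SubjectProfile:
    """Read a single-subject wide table (time column + one column per analyte)."""
    df = pd.read_csv(path)
    if time_col not in df.columns:
        raise SchemaError(f"wide CSV lacks time column {time_col!r}")
    analytes = [c for c in df.columns if c != time_col]
    if not analytes:
        raise SchemaError("wide CSV has a time column only")
    units = {**_DEFAULT_UNITS, **(units or {})}
    t = df[time_col].to_numpy(dtype=float)
    series = {
        c: TimeSeries(c, t, df[c].to_numpy(dtype=float),
                      units.get(c, "dimensionless"))
        for c in analytes
    }
    if "ACTH" not in series or "cortisol" not in series:
        raise SchemaError("wide CSV needs ACTH and cortisol columns")
    return SubjectProfile(
        subject_id=subject_id,
        acth=series.pop("ACTH"),
        cortisol=series.pop("cortisol"),
        cytokines=series,
    )
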