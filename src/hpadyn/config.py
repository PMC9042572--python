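"""Analysis configuration: every tunable window, lag range, threshold and
scenario switch used across the pipeline, serializable to YAML losslessly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import List

import yaml

#: mediator combinations used by the residual-correlation analysis
DEFAULT_COMBOS: List[List[str]] = [
    ["IL6"], ["TNFa"], ["IL8"], ["IL10"],
    ["IL6", "TNFa"],
    ["IL6", "TNFa", "IL8"],
    ["IL6", "TNFa", "IL10"],
    ["IL6", "TNFa", "IL8", "IL10"],
]


@dataclass
class AnalysisConfig:
    """Pipeline-wide parameters (times in minutes unless noted)."""

    # sampling
    dt: float = 10.0

    # synchrony battery
    rolling_window: float = 60.0          # rolling Pearson window
    max_lag: float = 180.0                # full-record TLCC lag range
    rwtlcc_window: float = 360.0          # rolling-window TLCC epoch length
    rwtlcc_step: float = 60.0
    rwtlcc_max_lag: float = 120.0         # per-epoch lag range
    band_period_min: float = 60.0         # ultradian band for IPS (period, min)
    band_period_max: float = 480.0
    detrend_window: float = 360.0         # moving-average detrend for period
    pulse_prominence_frac: float = 0.2    # of trace range
    pulse_min_separation: float = 60.0

    # phenotype decision thresholds
    period_two_pulse_min: float = 240.0   # T_u >= 4 h counts as "long period"
    period_multiple_max: float = 210.0    # T_u <= 3.5 h counts as "near normal"
    lag_control_max: float = 20.0         # |mu_lag| <= this = near-physiological
    lag_dissociated_min: float = 40.0     # |mu_lag| >= this = dissociated
    stability_min: float = 0.7
    stability_tol_lags: int = 2           # sampling steps around the modal lag

    # fitting
    scenario: str = "free_KA"             # free_KA | fixed_KA | fixed_m | fixed_both
    fixed_KA: float = 50.28               # control median adrenal sensitivity
    fixed_m: float = 2.0
    n_draws: int = 1_000_000
    keep_frac: float = 1e-3               # keep the lowest-error 0.1% of draws

    # residual-inflammation analysis
    combos: List[List[str]] = field(default_factory=lambda: [list(c) for c in DEFAULT_COMBOS])

    # reproducibility
    seed: int = 0

    @property
    def keep(self) -> int:
        return max(1, int(round(self.n_draws * self.keep_frac)))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        """Load from a YAML string or file path."""
        try:
            is_path = "\n" not in str(source) and str(source).endswith((".yml", ".yaml"))
        except Exception:
            is_path = False
        if is_path:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(str(source))
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
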