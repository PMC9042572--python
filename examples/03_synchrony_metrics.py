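"""Run the synchrony battery on a healthy and a disrupted profile.

Computes the time-lagged cross-correlation (TLCC), its rolling-window
variant, the instantaneous phase synchrony and the ultradian period, and
prints the evidence that separates preserved from dissociated ACTH-cortisol
coupling.
"""

import numpy as np

from hpadyn.phenotype import mean_epoch_lag, synchrony_stability
from hpadyn.sync import compute_sync_metrics
from hpadyn.synth import gen_cabg_profile, gen_healthy_profile

for profile in (gen_healthy_profile(seed=2, subject_id="control"),
                gen_cabg_profile(regime="multiple_pulse", seed=2)):
    m = compute_sync_metrics(profile.acth, profile.cortisol)
    stability = synchrony_stability(m.rwtlcc)
    mu_lag = mean_epoch_lag(m.rwtlcc, m.rwtlcc_lags)
    print(f"{profile.subject_id}:")
    print(f"  pulses {m.n_pulses}, T_u {m.period:.0f} min, "
          f"mu_lag {mu_lag:.0f} min (epoch mean), peak r {m.peak_r:.2f}")
    print(f"  synchrony stability {stability:.2f}, "
          f"mean IPS {np.nanmean(m.ips.v):.2f}")
print()
print("The control keeps a near-physiological ~10-min lag with a stable")
print("vertical stripe in the rolling-window TLCC; the multiple-pulse")
print("subject shows a dissociated lag of well over an hour.")
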