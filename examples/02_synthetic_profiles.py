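"""Generate one synthetic subject per dynamic regime and summarize each.

Shows the four generator regimes: healthy controls with regular ultradian
pulsatility, and the three post-surgical disruption patterns (two-pulse,
multiple-pulse, single-pulse), with 12-h areas under the curve and cortisol
pulse counts.
"""

from hpadyn import area_under_curve
from hpadyn.sync import UndefinedPeriodError, count_pulses, estimate_ultradian_period
from hpadyn.synth import gen_cabg_profile, gen_healthy_profile

profiles = [gen_healthy_profile(seed=1, subject_id="control")]
for regime in ("two_pulse", "multiple_pulse", "single_pulse"):
    profiles.append(gen_cabg_profile(regime=regime, seed=1))

print(f"{'subject':17s} {'AUC_ACTH':>9s} {'AUC_CORT':>9s} {'pulses':>6s} {'T_u':>8s}")
for p in profiles:
    auc_a = area_under_curve(p.acth, 0.0, 720.0)
    auc_c = area_under_curve(p.cortisol, 0.0, 720.0)
    n = count_pulses(p.cortisol)
    try:
        period = f"{estimate_ultradian_period(p.cortisol) / 60:.1f} h"
    except UndefinedPeriodError:
        period = "undef"
    print(f"{p.subject_id:17s} {auc_a:9.0f} {auc_c:9.0f} {n:6d} {period:>8s}")

print()
print("AUC units: ng h/l (ACTH) and nmol h/l (cortisol) over the first 12 h.")
print("Surgical subjects secrete roughly sixfold more ACTH but only about")
print("twice the cortisol of controls - the saturating adrenal response")
print("compresses the excursion.")
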