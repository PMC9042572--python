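"""Ensemble random-search calibration with known ground truth.

Generates noiseless cortisol from known parameters, runs the random search
with the adrenal sensitivity fixed at the control median (K_A = 50.28) and
the Hill coefficient at m = 2, and prints what the retained ensemble
recovers - including the identifiability contrast between the composite
drive gain (tight) and individual production parameters (sloppy).
"""

import numpy as np

from hpadyn import ModelParams, SubjectProfile
from hpadyn.fitting import fit_ensemble, summarize_ensemble
from hpadyn.model import hill_drive
from hpadyn.synth import gen_model_cortisol, gen_pulsatile_acth

true = ModelParams(p_f=30.0, p_s=4.0, lambda_f=12.0, lambda_s=200.0,
                   K_A=50.28, m=2.0)
acth = gen_pulsatile_acth(n_pulses=5, duration=720.0, seed=11)
cortisol = gen_model_cortisol(true, acth, noise_sd_frac=0.0, seed=0)
profile = SubjectProfile("demo", acth, cortisol)

ens = fit_ensemble(profile, n=200_000, seed=1, scenario="fixed_both")
q = summarize_ensemble(ens)["quantiles"]

gain = lambda p: (p.p_f * p.lambda_f + p.p_s * p.lambda_s) \
    * float(np.mean(hill_drive(acth.v, p.K_A, p.m)))
gains = [gain(r.params) for r in ens.results]

print(f"draws: {ens.n_sampled}, kept: {len(ens.results)}, "
      f"best epsilon: {ens.best.epsilon:.4f}")
print(f"true drive gain {gain(true):.1f} nmol/l; "
      f"kept median {np.median(gains):.1f} "
      f"(IQR {np.percentile(gains, 25):.1f}-{np.percentile(gains, 75):.1f})")
print(f"individual p_f: true {true.p_f:.0f}, kept median "
      f"{q.loc['50%', 'p_f']:.1f} (IQR {q.loc['25%', 'p_f']:.1f}-"
      f"{q.loc['75%', 'p_f']:.1f})")
print()
print("The composite gain is pinned within a few percent while p_f alone")
print("spreads over an order of magnitude: only the product of production")
print("and turnover is identifiable from the cortisol trajectory.")
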