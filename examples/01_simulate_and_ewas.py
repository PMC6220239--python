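"""Simulate a multi-cohort dataset and run the site-wise EWAS + meta-analysis.

Generates four cohorts with realistic demographics and a known per-CpG
ground truth, fits the basic covariate model (education ridit + sex, age,
cell percentages, plate/row) in each cohort, applies the bias/inflation
correction and combines the cohorts with an inverse-variance fixed-effects
meta-analysis.
"""

import numpy as np

from eduwas import DesignSpec, SimConfig, generate_cohort, meta_with_bacon, run_ewas
from eduwas.bacon import BaconSettings

cfg = SimConfig(n_cpgs=2000, n_causal=100, seed=7)
per_cohort, truth = [], None
for i, prof in enumerate(cfg.profiles):
    samples, meth, truth = generate_cohort(cfg, i)
    res = run_ewas(meth, samples, DesignSpec(model="model1"), cohort=prof.name)
    per_cohort.append(res)
    print(f"{prof.name}: n={len(samples)}, {len(res)} CpGs fitted")

meta, fits = meta_with_bacon(per_cohort,
                             settings=BaconSettings(n_iter=800, burn_in=300))
n_sig = int(meta["significant"].sum())
print(f"\nmeta-analysis: {len(meta)} CpGs, {n_sig} significant at "
      f"alpha={meta.attrs['bonferroni_alpha']:.2e}")
for tag, fit in fits.items():
    print(f"  bias/inflation [{tag}]: {fit.bias:+.3f} / {fit.inflation:.3f}")

causal = truth.cpgs.set_index("cpg_id").query("causal")
found = meta.set_index("cpg_id").loc[causal.index]
r = np.corrcoef(found["effect"], causal["beta_total"])[0, 1]
print(f"\ncorrelation of estimated vs true causal effects: r = {r:.3f}")
print("(bias/inflation near 0/1 say the statistics behave like a clean null "
      "outside the causal sites; significant CpGs are the recovered signal)")
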