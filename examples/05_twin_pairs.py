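"""Within-twin-pair discordance analysis.

Co-twins share prenatal and childhood environment (and, for MZ pairs, all
genetic variation), so regressing the within-pair methylation difference on
the within-pair education difference removes familial confounding.  The
example contrasts a shared-confounding scenario (population association,
null within pairs) with a direct-effect scenario (association survives
within pairs).
"""

import numpy as np

from eduwas import DesignSpec, SimConfig, TwinConfig, build_pairs, \
    generate_twin_cohort, run_ewas, within_pair_regression, \
    within_vs_population_ratio

for label, twin in (
    ("shared confounding only",
     TwinConfig(n_mz_pairs=492, n_dz_pairs=247, familial_variance_share=0.5,
                education_familial_loading=0.6)),
    ("direct effects only",
     TwinConfig(n_mz_pairs=492, n_dz_pairs=247)),
):
    effects = (0.0, 0.0) if label.startswith("shared") else (0.006, 0.060)
    cfg = SimConfig(n_cpgs=200, n_causal=0 if effects == (0.0, 0.0) else 200,
                    n_smoking_only=0, effect_range_education=effects,
                    mediation_fraction=0.0, seed=9, twin=twin)
    samples, meth, _ = generate_twin_cohort(cfg)
    pairs = build_pairs(samples)
    within = within_pair_regression(pairs, samples, meth, zygosity="MZ")
    pop = run_ewas(meth, samples, DesignSpec(model="model1"))
    _, summary = within_vs_population_ratio(within, pop, floor=0.004)
    print(f"{label}:")
    print(f"  pairs: {len(pairs)} ({(pairs['zygosity'] == 'MZ').sum()} MZ); "
          f"strata: {pairs['stratum'].value_counts().to_dict()}")
    print(f"  mean |z| within MZ pairs: "
          f"{np.mean(np.abs(within['effect'] / within['se'])):.2f} "
          "(~0.8 means null)")
    print(f"  mean within/population effect ratio: {summary.mean:.2f} "
          f"(n={summary.n})\n")
print("under pure confounding the within-pair slope vanishes; under direct "
      "effects it matches the population slope")
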