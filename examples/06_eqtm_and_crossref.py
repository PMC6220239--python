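"""Cis eQTM association and cross-study effect-size comparison.

Pairs transcripts within 100 kb of trait CpGs, regresses log-CPM on
methylation, and correlates meta-analysis effect sizes against an external
summary-statistics table with known noise.
"""

from dataclasses import replace

from eduwas import (DesignSpec, SimConfig, correlate_effects,
                    generate_cohort, generate_expression,
                    generate_external_sumstats, filter_transcripts, pair_cis,
                    run_ewas)
from eduwas.eqtm import eqtm_meta, eqtm_regression
from eduwas.synth import cpg_annotation

cfg = SimConfig(n_cpgs=400, n_causal=80, n_smoking_only=0, seed=3,
                expression=replace(SimConfig().expression, n_transcripts=200,
                                   cis_coef=-4.5))
cfg = cfg.with_sizes(800)
samples, meth, truth = generate_cohort(cfg, 0)
expr = generate_expression(cfg, meth)
kept = filter_transcripts(expr.counts)
print(f"transcript filters: {len(expr.counts)} -> {len(kept)} "
      "(detection >= 1% of samples, then bottom 1% variability dropped)")

annot = cpg_annotation(cfg)
pairs = pair_cis(annot, expr.annotation[expr.annotation["transcript_id"]
                                        .isin(kept.index)])
print(f"cis pairs within 100 kb: {len(pairs)} "
      f"({pairs.attrs['n_dropped_cpgs']} CpGs had no eligible transcript)")

res = eqtm_regression(pairs, kept, meth, samples,
                      covariates=("age", "neutrophil_pct", "monocyte_pct"),
                      cohort="sim")
meta = eqtm_meta([res])
sig = meta[meta["significant"]]
print(f"significant pairs at alpha=0.05/{len(meta)}: {len(sig)}")
cis = expr.truth.dropna(subset=["cis_cpg"]).query("coef != 0")
est = res.merge(cis, left_on=["cpg_id", "transcript_id"],
                right_on=["cis_cpg", "transcript_id"])
print(f"mean estimated cis coefficient: {est['effect'].mean():.2f} "
      "log2-CPM per methylation unit (configured -4.5)")

ewas = run_ewas(meth, samples, DesignSpec(model="model1"))
external = generate_external_sumstats(truth, noise_sd=0.01, seed=3)
causal_ids = truth.cpgs.loc[truth.cpgs["causal"], "cpg_id"]
c = correlate_effects(ewas, external, site_filter=causal_ids)
print(f"\neffect-size correlation with the external study: r = {c.r:.2f} "
      f"(p = {c.p:.1e}, {c.n_matched} matched CpGs)")
print("(the correlation quantifies how much the methylation signature of "
      "the exposure resembles the external study's signature)")
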