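"""End-to-end orchestration from a YAML config, with manifests.

The default run simulates a multi-cohort dataset, recomputes ridit scores
if absent, fits the per-cohort EWAS under the requested covariate models,
applies the bias/inflation correction per cohort and at the meta level,
and then runs the follow-up stages (mediation, twin-pair analysis,
cross-study comparison, cis eQTM, power).  Every stage writes TSV tables
into the output directory and the manifest records seeds, thresholds and
row counts so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bacon import BaconSettings
from .ewas import DesignSpec, run_ewas
from .mediation import attenuation_summary, mediate
from .meta import PowerSpec, meta_with_bacon, required_n
from .phenotypes import ridit_transform
from .synth import (SimConfig, SimTruth, cpg_annotation, generate_cohort,
                    generate_expression, generate_external_sumstats,
                    generate_twin_cohort, write_cohort)
from .twins import build_pairs, within_pair_regression, within_vs_population_ratio
from .eqtm import eqtm_meta, eqtm_regression, filter_transcripts, pair_cis
from .crossref import correlate_effects

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "validate_inputs"]


@dataclass
class RunConfig:
    outdir: str = "eduwas_run"
    seed: int = 0
    models: tuple[str, ...] = ("model1", "model2")
    fwer: float = 0.05
    bacon_per_cohort: bool = True
    bacon_at_meta: bool = True
    bacon_iterations: int = 2000
    bacon_burn_in: int = 800
    run_twins: bool = False
    run_eqtm: bool = False
    run_crossref: bool = False
    recompute_ridit: bool = False
    n_min: int = 30
    power_r2: float = 0.01
    power_alpha: float = 1e-7
    power_target: float = 0.80
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def validate_inputs(samples: pd.DataFrame, methylation: pd.DataFrame
                    ) -> dict:
    """Schema / value-range report (report-only; never raises)."""
    issues: list[str] = []
    required = ["sample_id", "sex", "age", "education_category",
                "smoking_status"]
    for c in required:
        if c not in samples.columns:
            issues.append(f"missing column: {c}")
    if "sample_id" in samples.columns and samples["sample_id"].duplicated().any():
        issues.append("duplicate sample ids")
    if methylation.index.duplicated().any():
        issues.append("duplicate CpG ids")
    if "education_category" in samples.columns:
        bad = ~samples["education_category"].isin(range(1, 8))
        if bad.any():
            issues.append(f"{int(bad.sum())} education categories outside 1-7")
    vals = methylation.to_numpy()
    out_of_range = int(((vals < 0) | (vals > 1)).sum())
    if out_of_range:
        issues.append(f"{out_of_range} beta values outside [0, 1]")
    if "sample_id" in samples.columns:
        overlap = len(set(methylation.columns) & set(samples["sample_id"]))
        if overlap < methylation.shape[1]:
            issues.append(
                f"{methylation.shape[1] - overlap} matrix samples missing "
                "from the sample table")
    return {"n_samples": len(samples), "n_cpgs": len(methylation),
            "violations": issues, "valid": not issues}


def _sim_config(cfg: RunConfig) -> SimConfig:
    return SimConfig(**{**cfg.sim, "seed": cfg.seed})


def run_all(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": {k: v for k, v in asdict(cfg).items()},
                      "stages": {}}
    sim = _sim_config(cfg)
    bacon_settings = BaconSettings(n_iter=cfg.bacon_iterations,
                                   burn_in=cfg.bacon_burn_in, seed=cfg.seed)

    # --- simulate cohorts
    cohorts = []
    annot = cpg_annotation(sim)
    for i, prof in enumerate(sim.profiles):
        samples, meth, truth = generate_cohort(sim, i)
        if cfg.recompute_ridit or "education_ridit" not in samples.columns:
            samples, _ = ridit_transform(samples)
        report = validate_inputs(samples, meth)
        if not report["valid"]:
            raise RuntimeError(
                f"stage simulate[{prof.name}]: invalid cohort: "
                f"{report['violations']}")
        cohorts.append((prof.name, samples, meth, truth))
        write_cohort(out / "cohorts" / prof.name, samples, meth, truth,
                     annotation=annot)
    manifest["stages"]["simulate"] = {
        "n_cohorts": len(cohorts),
        "n_cpgs": sim.n_cpgs,
        "n_samples": [len(s) for _, s, _, _ in cohorts],
    }

    # --- per-cohort EWAS + meta per model
    metas: dict[str, pd.DataFrame] = {}
    for model in cfg.models:
        per_cohort = []
        for name, samples, meth, _ in cohorts:
            design = DesignSpec(model=model, n_min=cfg.n_min)
            r = run_ewas(meth, samples, design, cohort=name)
            r.to_csv(out / f"ewas_{name}_{model}.tsv", sep="\t", index=False)
            per_cohort.append(r)
        meta, fits = meta_with_bacon(
            per_cohort, per_cohort=cfg.bacon_per_cohort,
            at_meta=cfg.bacon_at_meta, fwer=cfg.fwer,
            settings=bacon_settings)
        meta.to_csv(out / f"meta_{model}.tsv", sep="\t", index=False)
        for tag, fit in fits.items():
            fit.to_json(out / f"bacon_{model}_{tag}.json")
        metas[model] = meta
        manifest["stages"][f"meta_{model}"] = {
            "n_cpgs": len(meta),
            "bonferroni_alpha": meta.attrs["bonferroni_alpha"],
            "n_significant": int(meta["significant"].sum()),
            "bias_inflation": {t: [f.bias, f.inflation]
                               for t, f in fits.items()},
        }

    # --- mediation (model1 total vs model2 direct)
    if "model1" in metas and "model2" in metas:
        rec = mediate(metas["model1"], metas["model2"])
        rec.to_csv(out / "mediation.tsv", sep="\t", index=False)
        causal = cohorts[0][3].cpgs
        top = rec[rec["cpg_id"].isin(causal.loc[causal["causal"], "cpg_id"])]
        if len(top):
            s = attenuation_summary(top)
            manifest["stages"]["mediation"] = {
                "n_records": len(rec), "causal_mean_proportion": s.mean,
                "causal_min": s.min, "causal_max": s.max}
    elif "model2" in cfg.models or "model1" in cfg.models:
        missing = {"model1", "model2"} - set(metas)
        logger.info("mediation skipped: %s not run", sorted(missing))

    # --- twins
    if cfg.run_twins:
        if "model2" not in metas:
            raise RuntimeError("stage twins requires model2 meta results "
                               "(enable model2 or disable run_twins)")
        tsamples, tmeth, _ = generate_twin_cohort(sim)
        pairs = build_pairs(tsamples)
        pairs.to_csv(out / "twin_pairs.tsv", sep="\t", index=False)
        within = within_pair_regression(pairs, tsamples, tmeth,
                                        adjust_smoking=True)
        within.to_csv(out / "twin_within_pair.tsv", sep="\t", index=False)
        sig = metas["model2"].loc[metas["model2"]["significant"], "cpg_id"]
        use = metas["model2"][metas["model2"]["cpg_id"].isin(sig)] \
            if len(sig) >= 3 else metas["model2"]
        _, summary = within_vs_population_ratio(within, use)
        manifest["stages"]["twins"] = {
            "n_pairs": len(pairs), "ratio_mean": summary.mean,
            "effect_correlation": summary.correlation}

    # --- cross-study comparison on generator-produced external tables
    if cfg.run_crossref:
        model = cfg.models[0]
        truth = cohorts[0][3]
        ext = generate_external_sumstats(truth, noise_sd=0.01, seed=cfg.seed)
        causal_ids = truth.cpgs.loc[truth.cpgs["causal"], "cpg_id"]
        res = correlate_effects(metas[model], ext, site_filter=causal_ids)
        manifest["stages"]["crossref"] = {
            "r": res.r, "p": res.p, "n_matched": res.n_matched}

    # --- eQTM
    if cfg.run_eqtm:
        name, samples, meth, truth = cohorts[0]
        expr = generate_expression(sim, meth)
        kept = filter_transcripts(expr.counts)
        causal_ids = truth.cpgs.loc[truth.cpgs["causal"], "cpg_id"]
        cpg_tab = annot[annot["cpg_id"].isin(causal_ids)]
        tx_tab = expr.annotation[expr.annotation["transcript_id"].isin(kept.index)]
        pairs_tab = pair_cis(cpg_tab, tx_tab)
        res = eqtm_regression(pairs_tab, kept, meth, samples, cohort=name)
        combined = eqtm_meta([res], fwer=cfg.fwer)
        combined.to_csv(out / "eqtm.tsv", sep="\t", index=False)
        manifest["stages"]["eqtm"] = {
            "n_pairs": len(pairs_tab),
            "n_dropped_cpgs": pairs_tab.attrs["n_dropped_cpgs"],
            "n_significant": int(combined["significant"].sum())}

    # --- power
    spec = PowerSpec(r2=cfg.power_r2, alpha=cfg.power_alpha,
                     power=cfg.power_target)
    manifest["stages"]["power"] = {"required_n": required_n(spec),
                                   "r2": cfg.power_r2,
                                   "alpha": cfg.power_alpha,
                                   "target_power": cfg.power_target}

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_jsonable))
    return manifest


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)
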