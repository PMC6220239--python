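"""Inverse-variance fixed-effects meta-analysis, multiple testing and power.

Per-cohort EWAS results are combined with weights w_i = 1/SE_i^2:

    b_meta = sum(w_i b_i) / sum(w_i),   SE_meta = (sum w_i)^(-1/2)

followed by Bonferroni control of the family-wise error rate at the
realized number of tests.  Cochran's Q is reported per CpG as a
heterogeneity diagnostic only; no random-effects model is fitted.

Bias/inflation correction (see :mod:`eduwas.bacon`) is applied per cohort
before combining and then re-estimated and applied once more to the meta
statistics; either step can be disabled.

Power calculations treat the exposure as a single linear-model predictor
explaining R^2 of the outcome variance (Cohen's f^2 = R^2 / (1 - R^2)) and
use the noncentral-F distribution with noncentrality lambda = f^2 * N by
default; a Fisher-z approximation is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist, ncf, norm

from .bacon import BaconFit, BaconSettings, correct, fit_mixture

__all__ = ["fixed_effects_meta", "bonferroni_threshold", "meta_with_bacon",
           "PowerSpec", "power_at_n", "required_n"]


def bonferroni_threshold(n_tests: int, fwer: float = 0.05) -> float:
    """Per-test alpha controlling the family-wise error rate at ``fwer``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return fwer / n_tests


def fixed_effects_meta(results: Sequence[pd.DataFrame], *, fwer: float = 0.05
                       ) -> pd.DataFrame:
    """Combine per-cohort EWAS tables (columns cpg_id, effect, se, n).

    CpGs are matched by id; a CpG present in a single cohort passes through
    with ``single_cohort=True``.  Returns per CpG: effect, se, z, p,
    n_cohorts, n_total, q (Cochran), significant (Bonferroni at the realized
    number of tests).
    """
    if not results:
        raise ValueError("need at least one cohort result table")
    frames = []
    for i, r in enumerate(results):
        if (r["se"] <= 0).any():
            raise ValueError(f"cohort table {i} contains SE <= 0")
        frames.append(r[["cpg_id", "effect", "se", "n"]].assign(_k=i))
    stacked = pd.concat(frames, ignore_index=True)
    w = 1.0 / stacked["se"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["effect"])

    g = stacked.groupby("cpg_id", sort=True)
    sw = g["_w"].sum()
    eff = g["_wb"].sum() / sw
    se = 1.0 / np.sqrt(sw)
    n_cohorts = g["_k"].nunique()
    n_total = g["n"].sum()

    # Cochran's Q (diagnostic only)
    stacked = stacked.merge(eff.rename("_meta"), on="cpg_id")
    q = (stacked["_w"] * (stacked["effect"] - stacked["_meta"]) ** 2
         ).groupby(stacked["cpg_id"]).sum()

    z = (eff / se).to_numpy()
    p = np.maximum(2 * norm.sf(np.abs(z)), np.finfo(float).tiny)
    out = pd.DataFrame({
        "cpg_id": eff.index,
        "effect": eff.to_numpy(),
        "se": se.to_numpy(),
        "z": z,
        "p": p,
        "n_cohorts": n_cohorts.reindex(eff.index).to_numpy(),
        "n": n_total.reindex(eff.index).to_numpy(),
        "q": q.reindex(eff.index).to_numpy(),
    }).reset_index(drop=True)
    out["q_p"] = np.where(
        out["n_cohorts"] > 1,
        chi2.sf(out["q"], np.maximum(out["n_cohorts"] - 1, 1)), np.nan)
    out["single_cohort"] = out["n_cohorts"] == 1
    alpha = bonferroni_threshold(len(out), fwer)
    out["significant"] = out["p"] < alpha
    out.attrs["bonferroni_alpha"] = alpha
    out.attrs["n_tests"] = len(out)
    return out


def meta_with_bacon(results: Sequence[pd.DataFrame], *,
                    per_cohort: bool = True, at_meta: bool = True,
                    fwer: float = 0.05,
                    settings: BaconSettings | None = None
                    ) -> tuple[pd.DataFrame, dict[str, BaconFit]]:
    """Meta-analysis with bias/inflation adjustment.

    Each cohort's z statistics are corrected before combining
    (``per_cohort``), and the meta-analysis z statistics are corrected once
    more (``at_meta``).  All mixture fits are returned for reporting.
    """
    fits: dict[str, BaconFit] = {}
    adjusted = []
    base = settings or BaconSettings()
    for i, r in enumerate(results):
        if per_cohort:
            s = BaconSettings(**{**base.__dict__, "seed": base.seed + i + 1})
            fit = fit_mixture(r["z"].to_numpy(), s)
            tag = str(r["cohort"].iloc[0]) if "cohort" in r else f"cohort{i}"
            fits[tag] = fit
            adjusted.append(correct(r, fit))
        else:
            adjusted.append(r)
    meta = fixed_effects_meta(adjusted, fwer=fwer)
    if at_meta:
        fit = fit_mixture(meta["z"].to_numpy(), base)
        fits["meta"] = fit
        alpha = meta.attrs["bonferroni_alpha"]
        meta = correct(meta, fit)
        meta["significant"] = meta["p"] < alpha
        meta.attrs["bonferroni_alpha"] = alpha
    return meta, fits


# ---------------------------------------------------------------------------
# power / sample size

@dataclass(frozen=True)
class PowerSpec:
    """Power specification for a single linear-model predictor.

    ``r2`` is the proportion of outcome variance explained (|r| = sqrt(r2));
    ``alpha`` the two-sided significance level; ``power`` the target power.
    ``method``: "ncf" (noncentral F, default) or "fisher_z".
    """

    r2: float
    alpha: float = 1e-7
    power: float = 0.80
    method: str = "ncf"

    def __post_init__(self):
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ValueError("alpha and power must be in (0, 1)")


def power_at_n(spec: PowerSpec, n: int) -> float:
    """Power to detect the predictor at sample size ``n``."""
    if n < 4:
        raise ValueError("n must be >= 4")
    if spec.method == "ncf":
        f2 = spec.r2 / (1.0 - spec.r2)
        df2 = n - 2
        lam = f2 * n
        crit = f_dist.isf(spec.alpha, 1, df2)
        return float(ncf.sf(crit, 1, df2, lam))
    if spec.method == "fisher_z":
        zr = np.arctanh(np.sqrt(spec.r2))
        za = norm.isf(spec.alpha / 2)
        return float(norm.cdf(zr * np.sqrt(n - 3) - za))
    raise ValueError(f"unknown power method {spec.method!r}")


def required_n(spec: PowerSpec) -> int:
    """Smallest integer N achieving the target power."""
    lo, hi = 4, 8
    while power_at_n(spec, hi) < spec.power:
        lo, hi = hi, hi * 2
        if hi > 10 ** 9:
            raise ValueError("required sample size exceeds 1e9; check the spec")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at_n(spec, mid) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
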