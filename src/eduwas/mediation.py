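"""Difference-in-coefficients mediation of education effects through smoking.

The total association between education and methylation (model 1, no
smoking adjustment) is decomposed per CpG against the direct association
(model 2, smoking-adjusted):

    indirect = total - direct,  proportion mediated = indirect / total

Under linear no-interaction models the difference method coincides with
the product-of-coefficients decomposition.  The proportion is only defined
when |total| exceeds a floor (default 0.001 on the beta scale) and the
record is flagged when the floor is not met or when direct and total have
opposite signs (sign reversal makes the "proportion" uninterpretable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["mediate", "attenuation_summary", "bootstrap_proportions",
           "AttenuationSummary"]


def mediate(model1: pd.DataFrame, model2: pd.DataFrame, *,
            floor: float = 0.001) -> pd.DataFrame:
    """Per-CpG decomposition from matched model-1 / model-2 result tables.

    Both tables need columns cpg_id and effect and must cover the same CpG
    set.  Returns cpg_id, total, direct, indirect, proportion, flag where
    flag is '' | 'below_floor' | 'sign_reversal'.
    """
    m1 = model1.set_index("cpg_id")["effect"]
    m2 = model2.set_index("cpg_id")["effect"]
    if set(m1.index) != set(m2.index):
        raise ValueError("model 1 and model 2 tables cover different CpG sets")
    m2 = m2.reindex(m1.index)
    total = m1.to_numpy(dtype=float)
    direct = m2.to_numpy(dtype=float)
    indirect = total - direct
    with np.errstate(divide="ignore", invalid="ignore"):
        proportion = np.where(np.abs(total) >= floor, indirect / total, np.nan)
    flag = np.full(len(total), "", dtype=object)
    flag[np.abs(total) < floor] = "below_floor"
    reversal = (np.sign(direct) != np.sign(total)) & (np.abs(total) >= floor) \
        & (direct != 0)
    flag[reversal] = "sign_reversal"
    return pd.DataFrame({
        "cpg_id": m1.index,
        "total": total,
        "direct": direct,
        "indirect": indirect,
        "proportion": proportion,
        "flag": flag,
    }).reset_index(drop=True)


@dataclass(frozen=True)
class AttenuationSummary:
    min: float
    max: float
    mean: float
    n_valid: int
    n_invalid: int


def attenuation_summary(records: pd.DataFrame) -> AttenuationSummary:
    """Min / max / mean proportion mediated over the valid records."""
    if len(records) == 0:
        raise ValueError("need at least one mediation record")
    valid = records[(records["flag"] == "") & records["proportion"].notna()]
    n_invalid = len(records) - len(valid)
    if len(valid) == 0:
        return AttenuationSummary(np.nan, np.nan, np.nan, 0, n_invalid)
    p = valid["proportion"]
    return AttenuationSummary(float(p.min()), float(p.max()), float(p.mean()),
                              len(valid), n_invalid)


def bootstrap_proportions(methylation: pd.DataFrame, samples: pd.DataFrame,
                          design1, design2, cpg_ids, *, n_boot: int = 500,
                          seed: int = 0, floor: float = 0.001) -> pd.DataFrame:
    """Bootstrap (percentile) CIs for the proportion mediated.

    Resamples individuals with replacement and refits both covariate models
    on the selected CpGs.  Point estimates remain those of :func:`mediate`
    on the full data; this adds per-CpG 2.5/97.5% bounds.
    """
    from .ewas import run_ewas

    rng = np.random.default_rng(seed)
    M = methylation.loc[list(cpg_ids)]
    tab = samples.reset_index(drop=True)
    props = np.full((n_boot, len(cpg_ids)), np.nan)
    for b in range(n_boot):
        take = rng.integers(0, len(tab), size=len(tab))
        sub = tab.iloc[take].copy()
        sub["sample_id"] = [f"bs{i}" for i in range(len(sub))]
        Mb = M.iloc[:, take].copy()
        Mb.columns = sub["sample_id"].to_numpy()
        r1 = run_ewas(Mb, sub, design1)
        r2 = run_ewas(Mb, sub, design2)
        rec = mediate(r1, r2, floor=floor).set_index("cpg_id")
        props[b] = rec["proportion"].reindex(list(cpg_ids)).to_numpy()
    lo = np.nanpercentile(props, 2.5, axis=0)
    hi = np.nanpercentile(props, 97.5, axis=0)
    return pd.DataFrame({"cpg_id": list(cpg_ids), "ci_lo": lo, "ci_hi": hi})
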