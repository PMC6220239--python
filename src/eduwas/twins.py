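"""Within-twin-pair discordance regression and concordance strata.

Co-twins share the womb, childhood household and (for monozygotic pairs)
all segregating genetic variation, so regressing the within-pair
methylation difference on the within-pair exposure difference removes
familial confounding by design.  The within-pair estimator equals a
pair-fixed-effects regression on the stacked data.

Smoking-concordance strata follow the convention: discordant = one current
and one never smoker; concordant-current; concordant-never; every other
combination is excluded from stratified runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .ewas import _ols_multi

logger = logging.getLogger(__name__)

__all__ = ["build_pairs", "pair_deltas", "within_pair_regression",
           "within_vs_population_ratio", "RatioSummary", "SMOKING_CODE"]

#: numeric smoking coding used for within-pair smoking adjustment
SMOKING_CODE = {"never": 0.0, "former": 1.0, "current": 2.0}


def _stratum(s1: str, s2: str) -> str:
    pair = {s1, s2}
    if pair == {"current", "never"}:
        return "discordant"
    if pair == {"current"}:
        return "concordant-current"
    if pair == {"never"}:
        return "concordant-never"
    return "other"


def build_pairs(samples: pd.DataFrame, *, family_col: str = "family_id"
                ) -> pd.DataFrame:
    """Complete twin pairs from a sample table with family ids and zygosity.

    Within-pair ordering is by sample id, so delta signs are reproducible.
    Families with a single member are logged and skipped; families with more
    than two members are an error.
    """
    rows = []
    n_incomplete = 0
    for fam, grp in samples.groupby(family_col, sort=True):
        if len(grp) == 1:
            n_incomplete += 1
            continue
        if len(grp) > 2:
            raise ValueError(f"family {fam!r} has {len(grp)} members (max 2)")
        grp = grp.sort_values("sample_id")
        s1, s2 = grp.iloc[0], grp.iloc[1]
        rows.append({
            "pair_id": fam,
            "zygosity": s1.get("zygosity", "none"),
            "sample_id_1": s1["sample_id"],
            "sample_id_2": s2["sample_id"],
            "stratum": _stratum(s1["smoking_status"], s2["smoking_status"]),
        })
    if n_incomplete:
        logger.info("build_pairs: %d incomplete families excluded", n_incomplete)
    out = pd.DataFrame(rows, columns=["pair_id", "zygosity", "sample_id_1",
                                      "sample_id_2", "stratum"])
    out.attrs["n_incomplete"] = n_incomplete
    return out


def pair_deltas(pairs: pd.DataFrame, samples: pd.DataFrame,
                columns: tuple[str, ...] = ("education_ridit",)
                ) -> pd.DataFrame:
    """Within-pair differences (twin1 - twin2) of sample-table columns."""
    tab = samples.set_index("sample_id")
    out = pairs[["pair_id", "zygosity", "stratum"]].copy()
    for c in columns:
        if c == "smoking_status":
            v1 = tab.loc[pairs["sample_id_1"], c].map(SMOKING_CODE).to_numpy()
            v2 = tab.loc[pairs["sample_id_2"], c].map(SMOKING_CODE).to_numpy()
        else:
            v1 = tab.loc[pairs["sample_id_1"], c].to_numpy(dtype=float)
            v2 = tab.loc[pairs["sample_id_2"], c].to_numpy(dtype=float)
        out[f"d_{c}"] = v1 - v2
    return out


def within_pair_regression(pairs: pd.DataFrame, samples: pd.DataFrame,
                           methylation: pd.DataFrame, *,
                           cpg_ids=None, adjust_smoking: bool = False,
                           zygosity: str | None = None,
                           stratum: str | None = None,
                           intercept: bool = True,
                           min_pairs: int = 10) -> pd.DataFrame:
    """Per-CpG slope of the within-pair methylation difference on the
    within-pair exposure (ridit) difference.

    ``zygosity``/``stratum`` restrict the pair set; ``adjust_smoking`` adds
    the within-pair difference of a numeric smoking coding (never=0,
    former=1, current=2).  The estimate is invariant to flipping any pair's
    ordering.
    """
    sel = pairs
    if zygosity is not None:
        sel = sel[sel["zygosity"] == zygosity]
    if stratum is not None:
        sel = sel[sel["stratum"] == stratum]
    d = pair_deltas(sel, samples,
                    ("education_ridit", "smoking_status"))
    dx = d["d_education_ridit"].to_numpy()
    nonzero = int((dx != 0).sum())
    if len(d) < min_pairs:
        raise ValueError(f"only {len(d)} pairs (min {min_pairs})")
    if nonzero == 0:
        where = stratum or zygosity or "all pairs"
        raise ValueError(
            f"all within-pair exposure differences are zero in {where!r}")

    M = methylation if cpg_ids is None else methylation.loc[list(cpg_ids)]
    M1 = M[sel["sample_id_1"].to_numpy()].to_numpy(dtype=float)
    M2 = M[sel["sample_id_2"].to_numpy()].to_numpy(dtype=float)
    Y = (M1 - M2).T  # (pairs, cpgs)

    parts = [dx[:, None]]
    if intercept:
        parts.insert(0, np.ones((len(d), 1)))
    if adjust_smoking:
        parts.append(d["d_smoking_status"].to_numpy()[:, None])
    X = np.hstack(parts)
    exposure_idx = 1 if intercept else 0
    if np.allclose(Y, 0.0):
        eff = np.zeros(Y.shape[1])
        se = np.zeros(Y.shape[1])
    else:
        eff, se = _ols_multi(X, Y, exposure_idx=exposure_idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, eff / se, 0.0)
    return pd.DataFrame({
        "cpg_id": M.index,
        "effect": eff,
        "se": se,
        "p": np.maximum(2 * norm.sf(np.abs(z)), np.finfo(float).tiny),
        "n_pairs": len(d),
    }).reset_index(drop=True)


@dataclass(frozen=True)
class RatioSummary:
    mean: float
    median: float
    correlation: float
    n: int
    n_flagged: int


def within_vs_population_ratio(within: pd.DataFrame, population: pd.DataFrame,
                               *, floor: float = 1e-4
                               ) -> tuple[pd.DataFrame, RatioSummary]:
    """Per-CpG ratio of within-pair to population effect sizes.

    Ratios are flagged (and excluded from the summary) when the population
    effect is below the floor.  The summary also reports the Pearson
    correlation between the two effect vectors.
    """
    w = within.set_index("cpg_id")["effect"]
    p = population.set_index("cpg_id")["effect"]
    common = w.index.intersection(p.index)
    if len(common) == 0:
        raise ValueError("no matched CpGs")
    w, p = w.loc[common], p.loc[common]
    flagged = np.abs(p.to_numpy()) < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(flagged, np.nan, w.to_numpy() / p.to_numpy())
    tab = pd.DataFrame({"cpg_id": common, "within": w.to_numpy(),
                        "population": p.to_numpy(), "ratio": ratio,
                        "flagged": flagged}).reset_index(drop=True)
    ok = ~flagged
    if len(common) >= 2:
        r = float(pearsonr(w.to_numpy(), p.to_numpy())[0])
    else:
        r = np.nan
    summary = RatioSummary(
        mean=float(np.nanmean(ratio)) if ok.any() else np.nan,
        median=float(np.nanmedian(ratio)) if ok.any() else np.nan,
        correlation=r,
        n=int(ok.sum()),
        n_flagged=int(flagged.sum()),
    )
    return tab, summary
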