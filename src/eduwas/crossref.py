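"""Comparison of meta-analysis effect sizes with external resources.

Three operations: Pearson correlation of effect sizes against an external
EWAS summary-statistics table (matched on CpG id, optionally restricted to
the external study's significant set), Venn-style overlap counts between
significant-CpG sets, and proximity of CpGs to trait-associated SNPs
(closed-interval distance rule, default 500 kb, SNPs filtered at a nominal
p-value threshold).  External effect sizes are used as supplied (betas or
group differences); no rescaling is applied before correlating.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = ["correlate_effects", "venn_overlap", "gwas_proximity",
           "CorrelationResult", "ProximityResult"]


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n_matched: int


def correlate_effects(internal: pd.DataFrame, external: pd.DataFrame,
                      *, site_filter: Sequence[str] | None = None
                      ) -> CorrelationResult:
    """Pearson correlation between internal and external effect sizes.

    Both tables need cpg_id and effect columns.  ``site_filter`` (typically
    the external study's significant CpGs) restricts the matched set.
    Symmetric in the order of the two tables and invariant to row order.
    """
    a = internal.set_index("cpg_id")["effect"]
    b = external.set_index("cpg_id")["effect"]
    common = a.index.intersection(b.index)
    if site_filter is not None:
        common = common.intersection(pd.Index(site_filter))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} matched CpGs after filtering "
            f"(internal {len(a)}, external {len(b)}); need >= 3")
    x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    r, p = pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(common))


def venn_overlap(sets: Mapping[str, set]) -> dict[str, int]:
    """Counts for every intersection region of >= 2 named sets.

    Region keys are '&'-joined sorted member names; the count for a region
    is the number of elements in exactly those sets.  Region counts sum to
    the size of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    regions: dict[str, int] = {}
    universe = set().union(*sets.values())
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo),
                                  set())
            regions["&".join(combo)] = len(inside - outside)
    assert sum(regions.values()) == len(universe)
    return regions


class ProximityResult(NamedTuple):
    flags: pd.Series
    n_flagged: int


def gwas_proximity(cpgs: pd.DataFrame, snps: pd.DataFrame, *,
                   window: int = 500_000, p_thresh: float = 1e-4
                   ) -> ProximityResult:
    """Flag CpGs within ``window`` bases of a SNP passing the p filter.

    ``cpgs`` has cpg_id/chrom/pos (1-based); ``snps`` has chrom/pos/p.  The
    distance rule is the closed interval |pos_cpg - pos_snp| <= window on
    the same chromosome, symmetric in direction.
    """
    passing = snps[snps["p"] < p_thresh]
    flags = pd.Series(False, index=cpgs["cpg_id"].to_numpy(), name="near_snp")
    if passing.empty:
        warnings.warn("no SNPs pass the p-value filter; all flags are False",
                      stacklevel=2)
        return ProximityResult(flags, 0)
    by_chrom = {c: np.sort(g["pos"].to_numpy())
                for c, g in passing.groupby("chrom")}
    for _, row in cpgs.iterrows():
        pos = by_chrom.get(row["chrom"])
        if pos is None:
            continue
        i = np.searchsorted(pos, row["pos"])
        near = False
        if i < len(pos) and pos[i] - row["pos"] <= window:
            near = True
        if i > 0 and row["pos"] - pos[i - 1] <= window:
            near = True
        flags.loc[row["cpg_id"]] = near
    return ProximityResult(flags, int(flags.sum()))
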