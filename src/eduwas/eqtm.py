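"""Cis expression quantitative trait methylation (eQTM) analysis.

Transcripts within a window (default 100 kb, closed interval) of
trait-associated CpGs are paired with them and, per pair, the transcript's
log counts-per-million is regressed on the CpG's methylation level plus
covariates (age, sex, cell percentages).  Per-cohort pair estimates are
combined with the fixed-effects meta-analysis and Bonferroni-corrected at
the realized number of pairs.

Transcript filtering is applied in a fixed order: first the detection
filter (a read in >= 1% of samples), then removal of the 1% least variable
transcripts by log-CPM variance (ties broken by transcript id).  The
filter order matters and is part of the contract.

log-CPM uses log2((count + 0.5) / (library size + 1) * 1e6).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ewas import _ols_multi

logger = logging.getLogger(__name__)

__all__ = ["log_cpm", "filter_transcripts", "pair_cis", "eqtm_regression",
           "eqtm_meta"]


def log_cpm(counts: pd.DataFrame, *, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount (transcript x sample)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    return np.log2((counts + pseudocount).div(lib + 1.0, axis=1) * 1e6)


def filter_transcripts(counts: pd.DataFrame, *, min_detect: float = 0.01,
                       drop_bottom_variability: float = 0.01) -> pd.DataFrame:
    """Detection filter, then low-variability filter, in that order.

    Keeps transcripts detected (count > 0) in at least ``min_detect`` of
    samples, then removes the ``drop_bottom_variability`` fraction with the
    lowest log-CPM variance (ceil of the fraction; ties broken by
    transcript id, lowest ids removed first).
    """
    if counts.empty:
        raise ValueError("empty expression matrix")
    detect = (counts > 0).mean(axis=1) >= min_detect
    kept = counts.loc[detect]
    if kept.empty:
        raise ValueError("all transcripts removed by the detection filter")
    var = log_cpm(kept).var(axis=1)
    k = math.ceil(drop_bottom_variability * len(kept)) \
        if drop_bottom_variability > 0 else 0
    if k >= len(kept):
        raise ValueError("variability filter would remove all transcripts")
    order = var.sort_index().sort_values(kind="mergesort").index  # ties: by id
    drop = set(order[:k])
    out = kept.loc[[t for t in kept.index if t not in drop]]
    logger.info("filter_transcripts: %d -> %d (detection) -> %d (variability)",
                len(counts), len(kept), len(out))
    return out


def pair_cis(cpgs: pd.DataFrame, transcripts: pd.DataFrame, *,
             window: int = 100_000, anchor: str = "start") -> pd.DataFrame:
    """All (CpG, transcript) pairs within ``window`` bases (closed interval).

    ``cpgs``: cpg_id/chrom/pos (1-based).  ``transcripts``:
    transcript_id/chrom/start/end.  Distance is measured from the CpG
    position to the transcript start by default (``anchor='edge'`` uses the
    nearest transcript-body edge).  CpGs with no eligible transcript are
    dropped; their count is stored in ``attrs['n_dropped_cpgs']``.
    """
    rows = []
    n_dropped = 0
    tx_by_chrom = dict(tuple(transcripts.groupby("chrom")))
    for _, c in cpgs.iterrows():
        tx = tx_by_chrom.get(c["chrom"])
        found = False
        if tx is not None:
            if anchor == "start":
                dist = (tx["start"] - c["pos"]).abs()
            elif anchor == "edge":
                below = c["pos"] < tx["start"]
                above = c["pos"] > tx["end"]
                dist = pd.Series(0, index=tx.index)
                dist[below] = tx.loc[below, "start"] - c["pos"]
                dist[above] = c["pos"] - tx.loc[above, "end"]
            else:
                raise ValueError(f"unknown anchor {anchor!r}")
            hits = tx[dist <= window]
            for _, t in hits.iterrows():
                rows.append((c["cpg_id"], t["transcript_id"],
                             int(dist.loc[t.name])))
                found = True
        if not found:
            n_dropped += 1
    out = pd.DataFrame(rows, columns=["cpg_id", "transcript_id", "distance"])
    out = out.drop_duplicates(["cpg_id", "transcript_id"]).reset_index(drop=True)
    out.attrs["n_dropped_cpgs"] = n_dropped
    return out


def eqtm_regression(pairs: pd.DataFrame, expression: pd.DataFrame,
                    methylation: pd.DataFrame, samples: pd.DataFrame,
                    covariates: Sequence[str] = ("age",),
                    *, sex_col: str | None = "sex",
                    cohort: str | None = None) -> pd.DataFrame:
    """Per-pair OLS of log-CPM on methylation plus covariates.

    ``expression`` is a raw-count transcript x sample matrix (log-CPM is
    computed internally); samples are aligned across the three inputs.
    Pairs with a degenerate design (constant methylation) are flagged and
    given missing estimates; the run continues.
    """
    tab = samples.set_index("sample_id") if "sample_id" in samples.columns \
        else samples
    common = [s for s in expression.columns
              if s in methylation.columns and s in tab.index]
    if len(common) < 4:
        raise ValueError("fewer than 4 samples shared across inputs")
    lc = log_cpm(expression[common])
    tab = tab.loc[common]

    cov_parts = [np.ones((len(common), 1))]
    for c in covariates:
        cov_parts.append(tab[[c]].to_numpy(dtype=float))
    if sex_col is not None and sex_col in tab.columns:
        d = pd.get_dummies(tab[sex_col].astype("category"), drop_first=True)
        if d.shape[1]:
            cov_parts.append(d.to_numpy(dtype=float))
    Z = np.hstack(cov_parts)

    out = []
    for _, pr in pairs.iterrows():
        cpg, tx = pr["cpg_id"], pr["transcript_id"]
        if cpg not in methylation.index or tx not in lc.index:
            continue
        m = methylation.loc[cpg, common].to_numpy(dtype=float)
        y = lc.loc[tx].to_numpy(dtype=float)
        X = np.hstack([Z[:, :1], m[:, None], Z[:, 1:]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            out.append((cpg, tx, pr.get("distance", np.nan),
                        np.nan, np.nan, np.nan, len(common), True))
            continue
        eff, se = _ols_multi(X, y[:, None])
        e, s = float(eff[0]), float(se[0])
        p = float(2 * norm.sf(abs(e / s))) if s > 0 else 1.0
        out.append((cpg, tx, pr.get("distance", np.nan), e, s,
                    max(p, np.finfo(float).tiny), len(common), False))
    res = pd.DataFrame(out, columns=["cpg_id", "transcript_id", "distance",
                                     "effect", "se", "p", "n", "degenerate"])
    if cohort is not None:
        res.insert(2, "cohort", cohort)
    n_deg = int(res["degenerate"].sum())
    if n_deg:
        logger.info("eqtm_regression: %d degenerate pairs flagged", n_deg)
    return res


def eqtm_meta(per_cohort: Sequence[pd.DataFrame], *, fwer: float = 0.05
              ) -> pd.DataFrame:
    """Fixed-effects combination of per-cohort eQTM pair estimates with
    Bonferroni correction at the realized number of pairs."""
    from .meta import fixed_effects_meta

    keyed = []
    for r in per_cohort:
        ok = r[~r["degenerate"] & r["se"].notna() & (r["se"] > 0)].copy()
        ok["cpg_id"] = ok["cpg_id"] + ":" + ok["transcript_id"]
        keyed.append(ok[["cpg_id", "effect", "se", "n"]])
    meta = fixed_effects_meta(keyed, fwer=fwer)
    parts = meta["cpg_id"].str.split(":", n=1, expand=True)
    meta.insert(0, "transcript_id", parts[1])
    meta["cpg_id"] = parts[0]
    return meta
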