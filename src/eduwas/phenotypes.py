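"""Exposure and smoking phenotype transforms.

The exposure of interest is an ordinal education level on a 7-point scale
(1 = primary school only ... 7 = university).  Because educational
opportunities changed strongly across birth cohorts and between the sexes,
the ordinal level is converted into a *ridit* score ("relative to an
identified distribution") within sex x birth-cohort strata: the score of
category ``k`` is the proportion of the stratum below ``k`` plus half the
proportion within ``k``.  Ridit scores lie in (0, 1), have stratum mean 0.5
by construction, and express a person's relative educational position
within their own birth cohort and sex.

Smoking phenotypes handled here:

* pack-years = (cigarettes per day / 20) x years smoked,
* plasma cotinine classification (>=15 ng/mL active smoking, [1, 15)
  second-hand exposure, <1 unexposed),
* reconciliation of maternal-smoking questionnaire answers between
  co-twins,
* a weighted methylation-based smoking score built from externally
  supplied per-CpG weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "RiditSpec",
    "ridit_scores",
    "ridit_transform",
    "pack_years",
    "classify_cotinine",
    "reconcile_maternal_smoking",
    "reconcile_twin_answers",
    "methylation_smoking_score",
    "SmokingScore",
]

EDUCATION_LEVELS = tuple(range(1, 8))

#: questionnaire answer vocabulary for maternal smoking during pregnancy
MATERNAL_ANSWERS = ("yes", "no", "unknown", "missing")


@dataclass
class RiditSpec:
    """Audit record of a ridit transformation.

    ``table`` has one row per (stratum, category) with the observed category
    proportion and the assigned ridit value.  ``strata`` records which
    (sex, birth-bin) combinations were merged into each stratum.
    """

    table: pd.DataFrame
    strata: dict = field(default_factory=dict)

    def ridit_for(self, stratum: str, category: int) -> float:
        t = self.table
        row = t[(t["stratum"] == stratum) & (t["category"] == category)]
        if row.empty:
            raise KeyError(f"no ridit for stratum={stratum!r} category={category}")
        return float(row["ridit"].iloc[0])


def ridit_scores(categories: np.ndarray, levels: Iterable[int] = EDUCATION_LEVELS) -> tuple[np.ndarray, pd.DataFrame]:
    """Ridit scores for one stratum.

    R_k = sum_{j<k} p_j + p_k / 2 over the observed category distribution.
    Returns the per-sample scores and a (category, proportion, ridit) table.
    """
    categories = np.asarray(categories)
    levels = list(levels)
    counts = np.array([(categories == k).sum() for k in levels], dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty stratum: no samples with a valid category")
    p = counts / n
    ridit = np.cumsum(p) - p / 2.0
    lookup = dict(zip(levels, ridit))
    spec = pd.DataFrame({"category": levels, "proportion": p, "ridit": ridit})
    return np.array([lookup[c] for c in categories]), spec


def _birth_bins(birth_year: pd.Series, width: int) -> pd.Series:
    return (birth_year // width * width).astype(int)


def _merge_small_bins(counts: pd.Series, min_size: int) -> dict:
    """Map each birth bin to a merged bin label so every group >= min_size.

    Bins are scanned in ascending order; an undersized bin is merged with its
    right neighbour (left neighbour for the last bin).  Deterministic.
    """
    bins = list(counts.sort_index().index)
    sizes = [int(counts[b]) for b in bins]
    groups = [[b] for b in bins]
    i = 0
    while len(groups) > 1 and i < len(groups):
        if sizes[i] < min_size:
            j = i + 1 if i + 1 < len(groups) else i - 1
            groups[j] = (groups[i] + groups[j]) if j > i else (groups[j] + groups[i])
            sizes[j] += sizes[i]
            del groups[i], sizes[i]
            i = 0  # restart: merging can leave earlier groups adjacent to new ones
        else:
            i += 1
    mapping = {}
    for g in groups:
        label = f"{min(g)}-{max(g)}" if len(g) > 1 else str(g[0])
        for b in g:
            mapping[b] = label
    return mapping


def ridit_transform(
    samples: pd.DataFrame,
    *,
    stratify: bool = True,
    bin_width: int = 10,
    min_stratum: int = 10,
    category_col: str = "education_category",
    out_col: str = "education_ridit",
) -> tuple[pd.DataFrame, RiditSpec]:
    """Assign sex- and birth-cohort-specific ridit scores.

    Strata are sex x birth-year bins of ``bin_width`` years (decades by
    default).  Bins with fewer than ``min_stratum`` samples are merged with
    the adjacent bin (with a warning).  With ``stratify=False`` all samples
    form a single stratum.

    Returns a copy of ``samples`` with ``out_col`` added, plus a
    :class:`RiditSpec` for audit.
    """
    if category_col not in samples.columns:
        raise ValueError(f"missing column {category_col!r}")
    cats = samples[category_col]
    bad = ~cats.isin(EDUCATION_LEVELS)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} samples with education outside 1-7")

    out = samples.copy()
    out[out_col] = np.nan
    spec_rows = []
    strata_map: dict = {}

    if not stratify:
        scores, tab = ridit_scores(cats.to_numpy())
        out[out_col] = scores
        tab.insert(0, "stratum", "all")
        return out, RiditSpec(tab, {"all": ["all"]})

    for sex, sub in out.groupby("sex", sort=True):
        bins = _birth_bins(sub["birth_year"], bin_width)
        counts = bins.value_counts()
        if (counts < min_stratum).any() and len(counts) > 1:
            warnings.warn(
                f"sex={sex}: birth-cohort bins below {min_stratum} samples merged "
                "with adjacent bins",
                stacklevel=2,
            )
        mapping = _merge_small_bins(counts, min_stratum)
        merged = bins.map(mapping)
        for label, idx in merged.groupby(merged).groups.items():
            stratum = f"{sex}/{label}"
            strata_map[stratum] = sorted({int(b) for b, lab in mapping.items() if lab == label})
            scores, tab = ridit_scores(out.loc[idx, category_col].to_numpy())
            out.loc[idx, out_col] = scores
            tab.insert(0, "stratum", stratum)
            spec_rows.append(tab)

    spec = RiditSpec(pd.concat(spec_rows, ignore_index=True), strata_map)
    return out, spec


def pack_years(cigarettes_per_day, years_smoked):
    """Cumulative smoking dose: (cigarettes per day / 20) x years smoked.

    Missing input gives missing output; negative input is an error.
    Accepts scalars or array-likes.
    """
    cpd = np.asarray(cigarettes_per_day, dtype=float)
    yrs = np.asarray(years_smoked, dtype=float)
    if np.nanmin(cpd, initial=0.0) < 0 or np.nanmin(yrs, initial=0.0) < 0:
        raise ValueError("cigarettes_per_day and years_smoked must be >= 0")
    res = cpd / 20.0 * yrs
    if res.ndim == 0:
        return float(res)
    return res


def classify_cotinine(cotinine):
    """Classify plasma cotinine (ng/mL) into smoke-exposure groups.

    >= 15 -> "smoker"; >= 1 and < 15 -> "second_hand"; < 1 -> "unexposed".
    Missing stays missing; negative values are an error.  Accepts scalars or
    array-likes (returns an object array for array input).
    """
    x = np.asarray(cotinine, dtype=float)
    if np.nanmin(x, initial=0.0) < 0:
        raise ValueError("cotinine must be >= 0 ng/mL")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.full(x.shape, None, dtype=object)
    out[x >= 15] = "smoker"
    out[(x >= 1) & (x < 15)] = "second_hand"
    out[x < 1] = "unexposed"
    if scalar:
        return out[0]
    return out


def reconcile_maternal_smoking(answer_twin1: str, answer_twin2: str) -> tuple[str, str]:
    """Reconcile the maternal-smoking answer between two co-twins.

    A definite answer (yes/no) fills in the co-twin's missing/unknown answer;
    conflicting definite answers set both to missing; two indefinite answers
    stay missing.  Symmetric in twin order.
    """
    a, b = answer_twin1, answer_twin2
    for x in (a, b):
        if x not in MATERNAL_ANSWERS:
            raise ValueError(f"answer {x!r} not in {MATERNAL_ANSWERS}")
    definite = {"yes", "no"}
    if a in definite and b in definite:
        return (a, b) if a == b else ("missing", "missing")
    if a in definite:
        return a, a
    if b in definite:
        return b, b
    return "missing", "missing"


def reconcile_twin_answers(
    samples: pd.DataFrame,
    *,
    col: str = "maternal_smoking",
    family_col: str = "family_id",
) -> pd.DataFrame:
    """Apply :func:`reconcile_maternal_smoking` to every complete twin pair."""
    out = samples.copy()
    for _, idx in out.groupby(family_col).groups.items():
        if len(idx) != 2:
            continue
        i, j = idx
        r1, r2 = reconcile_maternal_smoking(out.at[i, col], out.at[j, col])
        out.at[i, col], out.at[j, col] = r1, r2
    return out


class SmokingScore(NamedTuple):
    scores: pd.Series
    n_cpgs_used: int


def methylation_smoking_score(
    methylation: pd.DataFrame,
    weights: pd.DataFrame,
    *,
    standardize: bool = False,
) -> SmokingScore:
    """Weighted per-sample smoking score from methylation levels.

    ``methylation`` is CpG x sample; ``weights`` has columns
    ``cpg_id``/``weight``.  score_i = sum_k w_k * m_ik over CpGs present in
    both; the raw beta values are used unless ``standardize`` z-scores each
    CpG across samples first.
    """
    w = weights.set_index("cpg_id")["weight"]
    common = methylation.index.intersection(w.index)
    if len(common) == 0:
        raise ValueError("no overlap between weight CpGs and the methylation matrix")
    m = methylation.loc[common]
    if standardize:
        sd = m.std(axis=1).replace(0, np.nan)
        m = m.sub(m.mean(axis=1), axis=0).div(sd, axis=0).fillna(0.0)
    scores = m.mul(w.loc[common], axis=0).sum(axis=0)
    scores.name = "smoking_score"
    return SmokingScore(scores, len(common))
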