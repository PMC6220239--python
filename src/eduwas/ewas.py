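"""Site-wise association of methylation beta values with the ridit exposure.

Each CpG is tested under an ordinary-least-squares linear model with the
beta value as outcome and the exposure plus covariates as predictors.
Three nested covariate sets are supported:

* model1: exposure, sex, age, array row, bisulphite plate (dummy-coded)
  and white-blood-cell percentages,
* model2: model1 + smoking status (current / former / never),
* model3: model2 + BMI,

optionally restricted to subsets (never smokers; cotinine-clean never
smokers) and extended with extra adjusters (pack-years, a methylation
smoking score, a reference-CpG methylation level, ...).

Standard errors come either from the independence (classical OLS) model or
from a family-clustered estimator: a CR1 cluster-robust sandwich (default;
point estimates are the OLS ones) or an exchangeable working-correlation
estimating-equation variance.  With no family of size >= 2 there is no
estimable within-family correlation and both clustered estimators reduce
to the classical OLS standard error.

The genome-wide path shares one design matrix across all CpGs and solves
the normal equations for every site at once, which is what makes null
simulations with tens of thousands of sites cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = ["DesignSpec", "SiteFit", "build_design", "fit_site", "run_ewas",
           "clustered_se"]

DEFAULT_CELL_COLS = ("neutrophil_pct", "monocyte_pct", "eosinophil_pct")

_SUBSETS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "never_smokers": lambda s: s["smoking_status"] == "never",
    "never_smokers_cotinine_clean":
        lambda s: (s["smoking_status"] == "never") & (s["cotinine"] < 15),
}


@dataclass(frozen=True)
class DesignSpec:
    """Covariate model, subset rule and variance estimator for one EWAS."""

    model: str = "model1"  # model1 | model2 | model3
    exposure: str = "education_ridit"
    cell_cols: tuple[str, ...] = DEFAULT_CELL_COLS
    categorical: tuple[str, ...] = ("sex", "array_row", "plate")
    continuous: tuple[str, ...] = ("age",)
    extra_adjusters: tuple[str, ...] = ()
    subset: str | None = None  # key of _SUBSETS, or None
    cluster_col: str | None = None  # e.g. "family_id"
    se_method: str = "sandwich"  # sandwich | exchangeable (used when clustered)
    n_min: int = 30

    def covariate_columns(self) -> tuple[list[str], list[str]]:
        """(categorical, continuous) covariate column names for this model."""
        if self.model not in ("model1", "model2", "model3"):
            raise ValueError(f"unknown model tag {self.model!r}")
        cat = list(self.categorical)
        cont = list(self.continuous) + list(self.cell_cols)
        if self.model in ("model2", "model3"):
            cat.append("smoking_status")
        if self.model == "model3":
            cont.append("bmi")
        cont.extend(self.extra_adjusters)
        return cat, cont

    def apply_subset(self, samples: pd.DataFrame) -> pd.DataFrame:
        if self.subset is None:
            return samples
        try:
            mask = _SUBSETS[self.subset](samples)
        except KeyError:
            raise ValueError(f"unknown subset rule {self.subset!r}") from None
        return samples.loc[mask]


class SiteFit(NamedTuple):
    effect: float
    se: float
    p: float
    n: int


def build_design(samples: pd.DataFrame, design: DesignSpec
                 ) -> tuple[np.ndarray, list[str], pd.Index]:
    """Design matrix (intercept, exposure, covariates) after listwise deletion.

    Returns (X, column names, row index used).  The exposure is always
    column 1.  Categorical covariates are dummy-coded dropping the first
    level; single-level categoricals contribute nothing.
    """
    cat, cont = design.covariate_columns()
    cols = [design.exposure] + cont + cat
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks columns {missing}")
    sub = samples[cols].dropna()
    idx = sub.index

    parts = [np.ones((len(sub), 1)), sub[[design.exposure]].to_numpy(dtype=float)]
    names = ["intercept", design.exposure]
    for c in cont:
        parts.append(sub[[c]].to_numpy(dtype=float))
        names.append(c)
    for c in cat:
        d = pd.get_dummies(sub[c].astype("category"), prefix=c, drop_first=True)
        if d.shape[1]:
            parts.append(d.to_numpy(dtype=float))
            names.extend(d.columns)
    X = np.hstack(parts)
    return X, names, idx


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient (constant exposure or collinear "
            "covariates)")


def _cluster_codes(ids: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(ids, return_inverse=True)
    return codes, int(codes.max()) + 1


def _ols_multi(X: np.ndarray, Y: np.ndarray, *, exposure_idx: int = 1,
               cluster: np.ndarray | None = None,
               se_method: str = "sandwich"
               ) -> tuple[np.ndarray, np.ndarray]:
    """Exposure coefficient and SE for every column of Y under a shared X.

    Y is (n, m).  Returns (effects, SEs), each length m.
    """
    n, k = X.shape
    XtX = X.T @ X
    XtXinv = np.linalg.inv(XtX)
    B = XtXinv @ (X.T @ Y)
    E = Y - X @ B
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", E, E) / dof
    a = XtXinv[:, exposure_idx]
    se_ols = np.sqrt(sigma2 * XtXinv[exposure_idx, exposure_idx])

    effects = B[exposure_idx]
    if cluster is None:
        return effects, se_ols
    codes, g = _cluster_codes(cluster)
    counts = np.bincount(codes, minlength=g)
    if counts.max() < 2:
        # singleton families: no within-family correlation is estimable
        return effects, se_ols

    h = X @ a  # n-vector; a' X_g' e_g = sum_{i in g} h_i e_i
    if se_method == "sandwich":
        HE = E * h[:, None]
        U = np.zeros((g, E.shape[1]))
        np.add.at(U, codes, HE)
        meat = np.einsum("ij,ij->j", U, U)
        c = g / (g - 1) * (n - 1) / (n - k)
        var = c * meat
    elif se_method == "exchangeable":
        # moment estimate of the common within-family residual correlation
        S = np.zeros((g, E.shape[1]))
        np.add.at(S, codes, E)
        SSQ = np.zeros((g, E.shape[1]))
        np.add.at(SSQ, codes, E ** 2)
        cross = (S ** 2 - SSQ).sum(axis=0)  # sum over i != j of e_i e_j
        n_pairs = float((counts * (counts - 1)).sum())
        rho = np.clip(cross / (n_pairs * sigma2), -0.99, 0.99)
        hs = np.zeros(g)
        np.add.at(hs, codes, h)
        aXa = float(a @ XtX @ a)
        var = sigma2 * ((1 - rho) * aXa + rho * float(hs @ hs))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return effects, np.sqrt(np.maximum(var, 0.0))


def clustered_se(X: np.ndarray, residuals: np.ndarray, family_ids: np.ndarray,
                 *, exposure_idx: int = 1, se_method: str = "sandwich"
                 ) -> float:
    """Family-clustered SE of the exposure coefficient from a fitted OLS.

    ``residuals`` is the n-vector of OLS residuals.  With all families of
    size 1 this equals the classical independence SE.
    """
    e = np.asarray(residuals, dtype=float).reshape(-1, 1)
    _, se = _ols_multi_from_residuals(X, e, family_ids, exposure_idx, se_method)
    return float(se[0])


def _ols_multi_from_residuals(X, E, cluster, exposure_idx, se_method):
    # shares the variance formulas of _ols_multi for externally supplied residuals
    n, k = X.shape
    XtX = X.T @ X
    XtXinv = np.linalg.inv(XtX)
    a = XtXinv[:, exposure_idx]
    sigma2 = np.einsum("ij,ij->j", E, E) / (n - k)
    codes, g = _cluster_codes(np.asarray(cluster))
    counts = np.bincount(codes, minlength=g)
    if counts.max() < 2:
        return None, np.sqrt(sigma2 * XtXinv[exposure_idx, exposure_idx])
    h = X @ a
    if se_method == "sandwich":
        U = np.zeros((g, E.shape[1]))
        np.add.at(U, codes, E * h[:, None])
        c = g / (g - 1) * (n - 1) / (n - k)
        return None, np.sqrt(c * np.einsum("ij,ij->j", U, U))
    if se_method == "exchangeable":
        S = np.zeros((g, E.shape[1]))
        np.add.at(S, codes, E)
        SSQ = np.zeros((g, E.shape[1]))
        np.add.at(SSQ, codes, E ** 2)
        cross = (S ** 2 - SSQ).sum(axis=0)
        n_pairs = float((counts * (counts - 1)).sum())
        rho = np.clip(cross / (n_pairs * sigma2), -0.99, 0.99)
        hs = np.zeros(g)
        np.add.at(hs, codes, h)
        aXa = float(a @ XtX @ a)
        return None, np.sqrt(np.maximum(
            sigma2 * ((1 - rho) * aXa + rho * float(hs @ hs)), 0.0))
    raise ValueError(f"unknown se_method {se_method!r}")


def fit_site(y, samples: pd.DataFrame, design: DesignSpec) -> SiteFit:
    """Fit one CpG: exposure effect, SE, two-sided normal p, and n used.

    ``y`` is a per-sample methylation vector aligned with ``samples`` (a
    Series indexed like ``samples`` or an array of equal length).
    """
    sub = design.apply_subset(samples)
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, dtype=float), index=samples.index)
    y = y.loc[sub.index]
    keep = y.notna()
    sub, y = sub.loc[keep], y.loc[keep]
    X, _, idx = build_design(sub, design)
    yv = y.loc[idx].to_numpy(dtype=float)
    n = len(idx)
    if n < design.n_min:
        raise ValueError(f"only {n} complete cases (< n_min={design.n_min})")
    _check_rank(X)
    cluster = sub.loc[idx, design.cluster_col].to_numpy() if design.cluster_col else None
    eff, se = _ols_multi(X, yv[:, None], cluster=cluster,
                         se_method=design.se_method)
    effect, s = float(eff[0]), float(se[0])
    if s == 0:
        p = 1.0 if effect == 0 else 0.0
    else:
        p = float(2 * norm.sf(abs(effect / s)))
    return SiteFit(effect, s, max(p, np.finfo(float).tiny), n)


def run_ewas(methylation: pd.DataFrame, samples: pd.DataFrame,
             design: DesignSpec, *, cohort: str | None = None) -> pd.DataFrame:
    """Genome-wide EWAS for one cohort.

    ``methylation`` is CpG x sample; ``samples`` has one row per sample with
    a ``sample_id`` column.  Returns one row per retained CpG with columns
    cpg_id, cohort, model, effect, se, z, p, n.  Sites that cannot be fitted
    (rank-deficient design after subsetting, too few complete cases) are
    skipped with a log entry.
    """
    tab = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    tab = design.apply_subset(tab)
    common = [s for s in methylation.columns if s in tab.index]
    if not common:
        raise ValueError("no overlapping samples between matrix and sample table")
    tab = tab.loc[common]
    M = methylation[common]

    X, _, idx = build_design(tab, design)
    if len(idx) < design.n_min:
        raise ValueError(
            f"only {len(idx)} complete cases (< n_min={design.n_min})")
    _check_rank(X)
    cluster = tab.loc[idx, design.cluster_col].to_numpy() if design.cluster_col else None
    Y = M[idx].to_numpy(dtype=float).T  # (n, n_cpgs)

    full = ~np.isnan(Y).any(axis=0)
    out_eff = np.full(M.shape[0], np.nan)
    out_se = np.full(M.shape[0], np.nan)
    out_n = np.full(M.shape[0], 0, dtype=int)
    if full.any():
        eff, se = _ols_multi(X, Y[:, full], cluster=cluster,
                             se_method=design.se_method)
        out_eff[full], out_se[full] = eff, se
        out_n[full] = len(idx)

    n_skipped = 0
    for j in np.flatnonzero(~full):
        y = pd.Series(Y[:, j], index=idx)
        try:
            f = fit_site(y, tab.loc[idx], replace(design, subset=None))
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_skipped += 1
            logger.debug("site %s skipped: %s", M.index[j], exc)
            continue
        out_eff[j], out_se[j], out_n[j] = f.effect, f.se, f.n
    if n_skipped:
        logger.info("run_ewas: %d sites skipped (missing data / degenerate)",
                    n_skipped)

    keep = ~np.isnan(out_eff)
    se_arr = out_se[keep]
    z = np.divide(out_eff[keep], se_arr, out=np.zeros(keep.sum()),
                  where=se_arr > 0)
    res = pd.DataFrame({
        "cpg_id": M.index[keep],
        "cohort": cohort if cohort is not None else tab.get("cohort", pd.Series(
            ["?"], dtype=object)).iloc[0],
        "model": design.model,
        "effect": out_eff[keep],
        "se": se_arr,
        "z": z,
        "p": np.maximum(2 * norm.sf(np.abs(z)), np.finfo(float).tiny),
        "n": out_n[keep],
    })
    return res.reset_index(drop=True)
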