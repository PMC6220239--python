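"""Multi-cohort synthetic phenotype, methylation and expression data.

The generator emulates the statistical structure of a multi-cohort,
population-based EWAS of educational attainment in whole blood:

* four cohorts with realistic demographics (sex ratio, age, BMI, birth-year
  range, smoking-status and 7-level education distributions),
* an education -> smoking dependence induced by a logistic model on the
  ridit score, with the slope calibrated numerically so that the
  education / current-smoking correlation hits a configurable target
  (default -0.11),
* per-CpG education effects on the beta (proportion) scale, 0.006-0.060
  per ridit unit with 76% positive by default, partially mediated through
  current smoking (default mediated fraction 0.28),
* smoking-only CpGs with current-vs-never effects in [-0.18, 0.07],
* covariate structure (age, sex, white-blood-cell percentages, bisulphite
  plate and array row batch effects) and i.i.d. noise, clipped to [0, 1],
* monozygotic / dizygotic twin families with shared familial and genetic
  variance components,
* RNA-seq-like counts whose log mean is linear in methylation for
  designated cis CpG-transcript pairs, and
* external summary-statistics tables correlated with the truth by
  construction.

Every per-CpG ground-truth quantity (total and direct education effect,
causal flag) is identical across cohorts; the cohort-specific
education->smoking path coefficient is absorbed into the cohort's smoking
coefficient so that the mediated fraction is also cohort-invariant.  One
seeded generator stream is used per cohort, so adding cohorts never
perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .phenotypes import pack_years, ridit_scores

__all__ = [
    "CohortProfile",
    "TwinConfig",
    "ExpressionConfig",
    "CovariateEffects",
    "SimConfig",
    "SimTruth",
    "default_profiles",
    "calibrate_smoking_model",
    "generate_cohort",
    "generate_twin_cohort",
    "generate_expression",
    "generate_external_sumstats",
    "cpg_annotation",
    "write_cohort",
    "write_expression",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class CohortProfile:
    """Demographic profile of one cohort (defaults mirror four Dutch
    population biobanks: a young twin register, two older population cohorts
    and a middle-aged deep-phenotyping cohort)."""

    name: str
    n_samples: int
    frac_female: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    birth_year_mean: int
    birth_year_range: tuple[int, int]
    smoking_fracs: tuple[float, float, float]  # current, former, never
    education_probs: tuple[float, ...]  # 7 categories


def default_profiles() -> tuple[CohortProfile, ...]:
    def _norm(v):
        v = np.asarray(v, dtype=float)
        return tuple(v / v.sum())

    return (
        CohortProfile("NTR", 2199, 0.686, 38.2, 12.6, 24.4, 4.0, 1968, (1926, 1989),
                      _norm([19.2, 24.3, 56.5]),
                      _norm([2.7, 7.6, 7.1, 28.2, 5.6, 27.9, 20.8])),
        CohortProfile("LLS", 668, 0.525, 59.1, 6.6, 25.5, 3.5, 1945, (1925, 1974),
                      _norm([12.7, 55.5, 31.7]),
                      _norm([3.9, 22.3, 18.3, 19.2, 3.1, 23.7, 9.6])),
        CohortProfile("RS", 608, 0.577, 68.6, 5.6, 27.7, 4.2, 1943, (1930, 1960),
                      _norm([9.4, 55.3, 35.4]),
                      _norm([15.8, 20.7, 15.8, 23.7, 4.1, 17.6, 2.3])),
        CohortProfile("LLD", 704, 0.577, 47.3, 12.5, 25.5, 4.2, 1965, (1931, 1987),
                      _norm([18.3, 35.8, 45.3]),
                      _norm([1.1, 8.4, 11.1, 24.3, 9.2, 32.4, 13.5])),
    )


@dataclass(frozen=True)
class TwinConfig:
    n_mz_pairs: int = 492
    n_dz_pairs: int = 247
    #: share of residual methylation variance from the pair-shared familial factor
    familial_variance_share: float = 0.2
    #: share from the additive genetic factor (shared fully in MZ, half in DZ)
    genetic_variance_share: float = 0.2
    #: loadings of the latent education score on the familial / genetic factors
    education_familial_loading: float = 0.0
    education_genetic_loading: float = 0.0
    #: if set, force this fraction of pairs to be current/never smoking-discordant
    smoking_discordant_frac: float | None = None


@dataclass(frozen=True)
class ExpressionConfig:
    n_transcripts: int = 500
    #: fraction of transcripts placed in cis of a CpG with a real effect
    frac_cis: float = 0.3
    #: fraction placed in cis with a zero coefficient (negative controls)
    frac_cis_null: float = 0.3
    #: log2-CPM change per unit methylation for cis pairs; None = draw N(0, 2)
    cis_coef: float | None = None
    #: maximum CpG-transcript distance used when placing cis transcripts (bases)
    placement_window: int = 50_000
    overdispersion: float = 0.05
    library_size_mean: float = 5e6
    library_size_log_sd: float = 0.3


@dataclass(frozen=True)
class CovariateEffects:
    """Per-CpG covariate-loading scales (sd of the random loadings)."""

    age_sd: float = 1.5e-4       # per year of age
    sex_sd: float = 0.004        # female vs male
    cell_sd: float = 3e-4        # per percentage point of cell fraction
    plate_sd: float = 0.002      # bisulphite-plate batch effect
    row_sd: float = 0.001        # array-row batch effect


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic multi-cohort dataset."""

    n_cpgs: int = 10_000
    n_causal: int = 200
    n_smoking_only: int = 300
    effect_range_education: tuple[float, float] = (0.006, 0.060)
    frac_positive: float = 0.76
    effect_range_smoking: tuple[float, float] = (-0.18, 0.07)
    mediation_fraction: float = 0.28
    education_smoking_corr: float = -0.11
    noise_sd: float = 0.04
    #: between-cohort sd of the education effect (the study conditions assume
    #: homogeneous effects; kept as an explicit dial, default 0)
    between_cohort_effect_sd: float = 0.0
    cotinine_misclassified_frac: float = 0.008
    cotinine_second_hand_frac: float = 0.26
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    twin: TwinConfig = field(default_factory=TwinConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    profiles: tuple[CohortProfile, ...] = field(default_factory=default_profiles)
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_positive", "mediation_fraction",
                     "cotinine_misclassified_frac", "cotinine_second_hand_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_causal > self.n_cpgs:
            raise ValueError("n_causal must be <= n_cpgs")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def n_cohorts(self) -> int:
        return len(self.profiles)

    def with_sizes(self, n_samples: int | Sequence[int]) -> "SimConfig":
        """Copy of the config with per-cohort sample sizes replaced."""
        if np.isscalar(n_samples):
            sizes = [int(n_samples)] * len(self.profiles)
        else:
            sizes = [int(n) for n in n_samples]
        profs = tuple(replace(p, n_samples=n) for p, n in zip(self.profiles, sizes))
        return replace(self, profiles=profs)


class SimTruth(NamedTuple):
    """Ground truth: per-CpG effects plus the per-sample familial component.

    ``gamma`` is the calibrated (population) education->current-smoking path
    coefficient per ridit unit; ``gamma_realized`` is the empirical linear
    projection of the drawn smoking indicator on the drawn ridit scores.
    The ``beta_total_realized`` truth column
    (= beta_direct + gamma_realized * beta_smoking) is the estimand of an
    unadjusted education model *conditional* on the realized smoking draw;
    comparing estimates against it separates regression bias from the
    binomial noise of the mediator.
    """

    cpgs: pd.DataFrame         # cpg_id, chrom, pos, causal, beta_total, beta_direct,
    #                            beta_indirect, beta_smoking, smoking_only, ...
    familial: pd.Series        # per-sample latent familial component
    gamma: float               # calibrated education->current-smoking path
    clip_fraction: float
    gamma_realized: float = np.nan


# ---------------------------------------------------------------------------
# seeding: one independent stream per cohort / purpose

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


_EFFECTS_KEY = 1_000  # stream for cohort-invariant per-CpG quantities
_EXPR_KEY = 2_000
_TWIN_KEY = 3_000
_EXT_KEY = 4_000


# ---------------------------------------------------------------------------
# education -> smoking calibration

def calibrate_smoking_model(
    education_probs: Sequence[float],
    target_current: float,
    target_corr: float,
) -> tuple[float, float, float]:
    """Calibrate the logistic model P(current | ridit) = expit(a + b*ridit).

    Solves for (a, b) such that the marginal current-smoking probability and
    the correlation between the ridit score and the current-smoking indicator
    match their targets exactly over the discrete category distribution.

    Returns (a, b, gamma) where gamma = cov(ridit, smoking) / var(ridit) is
    the linear-projection (path) coefficient of smoking on the ridit score.
    """
    p = np.asarray(education_probs, dtype=float)
    p = p / p.sum()
    r = np.cumsum(p) - p / 2.0
    r_mean = float(p @ r)
    r_var = float(p @ (r - r_mean) ** 2)
    if r_var == 0:
        raise ValueError("degenerate education distribution: single category")
    sd_r = np.sqrt(r_var)
    sd_s = np.sqrt(target_current * (1 - target_current))

    def intercept_for(b: float) -> float:
        span = abs(b) + 40.0
        return brentq(lambda a: float(p @ expit(a + b * r)) - target_current,
                      -span, span)

    def corr_for(b: float) -> float:
        a = intercept_for(b)
        pi = expit(a + b * r)
        cov = float(p @ (r * pi)) - r_mean * target_current
        return cov / (sd_r * sd_s)

    lo, hi = -80.0, 80.0
    c_lo, c_hi = corr_for(lo), corr_for(hi)
    if not c_lo <= target_corr <= c_hi:
        raise ValueError(
            f"education-smoking correlation target {target_corr} is unattainable "
            f"for these marginals (achievable range [{c_lo:.3f}, {c_hi:.3f}])"
        )
    b = brentq(lambda x: corr_for(x) - target_corr, lo, hi, xtol=1e-10)
    a = intercept_for(b)
    pi = expit(a + b * r)
    gamma = (float(p @ (r * pi)) - r_mean * target_current) / r_var
    return a, b, gamma


# ---------------------------------------------------------------------------
# per-CpG truth (cohort-invariant)

def cpg_annotation(config: SimConfig) -> pd.DataFrame:
    """Deterministic genomic annotation: CpGs spread over 22 autosomes."""
    idx = np.arange(config.n_cpgs)
    chrom = (idx % 22) + 1
    pos = 1_000_000 + (idx // 22) * 2_000 + 1  # 1-based
    return pd.DataFrame({
        "cpg_id": [f"cg{i:08d}" for i in idx],
        "chrom": [f"chr{c}" for c in chrom],
        "pos": pos,
    })


def _cpg_truth(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config.seed, _EFFECTS_KEY)
    n = config.n_cpgs
    annot = cpg_annotation(config)

    base = rng.uniform(0.10, 0.90, size=n)
    causal = np.zeros(n, dtype=bool)
    smoking_only = np.zeros(n, dtype=bool)
    order = rng.permutation(n)
    causal[order[: config.n_causal]] = True
    smoking_only[order[config.n_causal: config.n_causal + config.n_smoking_only]] = True

    lo, hi = config.effect_range_education
    mag = rng.uniform(lo, hi, size=n)
    sign = np.where(rng.random(n) < config.frac_positive, 1.0, -1.0)
    beta_total = np.where(causal, mag * sign, 0.0)
    beta_indirect = config.mediation_fraction * beta_total
    beta_direct = beta_total - beta_indirect

    slo, shi = config.effect_range_smoking
    beta_smoking_only = np.where(smoking_only, rng.uniform(slo, shi, size=n), 0.0)

    ce = config.covariate_effects
    truth = annot.copy()
    truth["base"] = base
    truth["causal"] = causal
    truth["smoking_only"] = smoking_only
    truth["beta_total"] = beta_total
    truth["beta_direct"] = beta_direct
    truth["beta_indirect"] = beta_indirect
    truth["beta_smoking_only"] = beta_smoking_only
    truth["age_coef"] = rng.normal(0, ce.age_sd, size=n)
    truth["sex_coef"] = rng.normal(0, ce.sex_sd, size=n)
    truth["neut_coef"] = rng.normal(0, ce.cell_sd, size=n)
    truth["mono_coef"] = rng.normal(0, ce.cell_sd, size=n)
    truth["eos_coef"] = rng.normal(0, ce.cell_sd, size=n)
    return truth


# ---------------------------------------------------------------------------
# cohort generation

def _realized_gamma(samples: pd.DataFrame) -> float:
    """Empirical linear projection of the current-smoking indicator on ridit."""
    r = samples["education_ridit"].to_numpy(dtype=float)
    s = (samples["smoking_status"] == "current").to_numpy(dtype=float)
    if len(r) < 2 or r.var() == 0:
        return np.nan
    return float(np.cov(s, r)[0, 1] / np.var(r, ddof=1))


def _sample_phenotypes(config: SimConfig, profile: CohortProfile,
                       rng: np.random.Generator, prefix: str) -> pd.DataFrame:
    n = profile.n_samples
    sex = np.where(rng.random(n) < profile.frac_female, "F", "M")
    by_lo, by_hi = profile.birth_year_range
    birth_year = np.clip(
        np.round(rng.normal(profile.birth_year_mean, profile.age_sd, size=n)),
        by_lo, by_hi,
    ).astype(int)
    sampling_year = profile.birth_year_mean + profile.age_mean
    age = sampling_year - birth_year
    bmi = np.round(rng.normal(profile.bmi_mean, profile.bmi_sd, size=n), 1)

    edu = rng.choice(np.arange(1, 8), size=n, p=profile.education_probs)
    ridit, _ = ridit_scores(edu)

    cur_frac, for_frac, nev_frac = profile.smoking_fracs
    a, b, _ = calibrate_smoking_model(
        profile.education_probs, cur_frac, config.education_smoking_corr)
    p_cur = expit(a + b * ridit)
    current = rng.random(n) < p_cur
    former = ~current & (rng.random(n) < for_frac / (for_frac + nev_frac))
    status = np.where(current, "current", np.where(former, "former", "never"))

    cpd = np.where(status == "never", 0.0, rng.poisson(14, size=n) + 1.0)
    dur_frac = rng.uniform(0.5, 1.0, size=n)
    years = np.where(
        status == "current", np.maximum(age - 18, 1) * dur_frac,
        np.where(status == "former", np.maximum(age - 18, 1) * dur_frac * 0.5, 0.0),
    )
    years = np.round(years, 1)
    py = pack_years(cpd, years)

    cot = np.empty(n)
    cur_m = status == "current"
    cot[cur_m] = np.exp(rng.normal(5.3, 0.6, size=int(cur_m.sum())))
    non = ~cur_m
    u = rng.random(n)
    mis = config.cotinine_misclassified_frac
    shs = config.cotinine_second_hand_frac
    cot[non & (u < mis)] = rng.uniform(15, 100, size=int((non & (u < mis)).sum()))
    sh_m = non & (u >= mis) & (u < mis + shs)
    cot[sh_m] = rng.uniform(1, 15, size=int(sh_m.sum()))
    rest = non & (u >= mis + shs)
    cot[rest] = rng.uniform(0, 1, size=int(rest.sum()))

    maternal = rng.choice(np.array(["yes", "no", "unknown", "missing"], dtype=object),
                          size=n, p=[0.10, 0.75, 0.10, 0.05])

    neut = np.clip(rng.normal(55, 7, size=n), 20, 85)
    mono = np.clip(rng.normal(8, 2, size=n), 1, 20)
    eos = np.clip(rng.normal(3, 1.5, size=n), 0, 12)
    lymph = np.clip(100 - neut - mono - eos + rng.normal(0, 1, size=n), 5, 70)

    sample_id = [f"{prefix}{i:05d}" for i in range(n)]
    return pd.DataFrame({
        "sample_id": sample_id,
        "family_id": sample_id,  # singleton families unless twins are generated
        "zygosity": "none",
        "cohort": profile.name,
        "sex": sex,
        "birth_year": birth_year,
        "age": np.round(age, 1),
        "bmi": bmi,
        "education_category": edu,
        "education_ridit": ridit,
        "smoking_status": status,
        "cigarettes_per_day": cpd,
        "years_smoked": years,
        "pack_years": py,
        "cotinine": np.round(cot, 2),
        "maternal_smoking": maternal,
        "neutrophil_pct": np.round(neut, 1),
        "monocyte_pct": np.round(mono, 1),
        "eosinophil_pct": np.round(eos, 1),
        "lymphocyte_pct": np.round(lymph, 1),
        "plate": [f"P{i // 96:02d}" for i in range(n)],
        "array_row": [f"R{i % 6 + 1:02d}" for i in range(n)],
    })


def _methylation(config: SimConfig, truth: pd.DataFrame, samples: pd.DataFrame,
                 gamma: float, rng: np.random.Generator,
                 familial: np.ndarray | None = None,
                 fam_sd: float = 0.0, gen: np.ndarray | None = None,
                 gen_sd: float = 0.0) -> tuple[pd.DataFrame, float]:
    """Beta-value matrix (CpG x sample) from the generating equations."""
    n = len(samples)
    m = truth["base"].to_numpy()[:, None] + np.zeros((1, n))

    ridit = samples["education_ridit"].to_numpy()
    current = (samples["smoking_status"] == "current").to_numpy().astype(float)

    jitter = config.between_cohort_effect_sd
    beta_direct = truth["beta_direct"].to_numpy()
    if jitter > 0:
        beta_direct = beta_direct + np.where(
            truth["causal"], rng.normal(0, jitter, size=len(truth)), 0.0)

    if abs(gamma) < 1e-12:
        if np.any(truth["beta_indirect"].to_numpy() != 0):
            raise ValueError(
                "mediation_fraction > 0 requires a nonzero education-smoking "
                "correlation (the education->smoking path coefficient is 0)")
        beta_smk = truth["beta_smoking_only"].to_numpy()
    else:
        beta_smk = (truth["beta_indirect"].to_numpy() / gamma
                    + truth["beta_smoking_only"].to_numpy())

    m += beta_direct[:, None] * ridit[None, :]
    m += beta_smk[:, None] * current[None, :]

    age_c = (samples["age"].to_numpy() - samples["age"].mean())
    female = (samples["sex"] == "F").to_numpy().astype(float)
    m += truth["age_coef"].to_numpy()[:, None] * age_c[None, :]
    m += truth["sex_coef"].to_numpy()[:, None] * female[None, :]
    for col, coef in (("neutrophil_pct", "neut_coef"), ("monocyte_pct", "mono_coef"),
                      ("eosinophil_pct", "eos_coef")):
        x = samples[col].to_numpy() - samples[col].mean()
        m += truth[coef].to_numpy()[:, None] * x[None, :]

    ce = config.covariate_effects
    for col, sd in (("plate", ce.plate_sd), ("array_row", ce.row_sd)):
        levels, codes = np.unique(samples[col], return_inverse=True)
        eff = rng.normal(0, sd, size=(len(truth), len(levels)))
        m += eff[:, codes]

    unique_sd = config.noise_sd
    if familial is not None and fam_sd > 0:
        sign = np.where(rng.random(len(truth)) < 0.5, 1.0, -1.0)
        m += fam_sd * sign[:, None] * familial[None, :]
    if gen is not None and gen_sd > 0:
        sign = np.where(rng.random(len(truth)) < 0.5, 1.0, -1.0)
        m += gen_sd * sign[:, None] * gen[None, :]
        unique_sd = config.noise_sd * np.sqrt(
            max(1.0 - (fam_sd ** 2 + gen_sd ** 2) / config.noise_sd ** 2, 0.0))
    elif familial is not None and fam_sd > 0:
        unique_sd = config.noise_sd * np.sqrt(
            max(1.0 - fam_sd ** 2 / config.noise_sd ** 2, 0.0))

    m += rng.normal(0, unique_sd, size=m.shape)

    clipped = float(((m < 0) | (m > 1)).mean())
    np.clip(m, 0.0, 1.0, out=m)
    return (
        pd.DataFrame(m, index=truth["cpg_id"].to_numpy(),
                     columns=samples["sample_id"].to_numpy()),
        clipped,
    )


def generate_cohort(config: SimConfig, cohort_index: int
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate one cohort: (sample table, CpG x sample beta matrix, truth)."""
    if not 0 <= cohort_index < len(config.profiles):
        raise IndexError(f"cohort_index {cohort_index} out of range")
    profile = config.profiles[cohort_index]
    rng = _rng(config.seed, cohort_index)
    truth = _cpg_truth(config)
    samples = _sample_phenotypes(config, profile, rng, prefix=f"{profile.name}_")
    _, _, gamma = calibrate_smoking_model(
        profile.education_probs, profile.smoking_fracs[0],
        config.education_smoking_corr)
    meth, clip_frac = _methylation(config, truth, samples, gamma, rng)

    cpg_truth = truth.drop(columns=["base", "age_coef", "sex_coef", "neut_coef",
                                    "mono_coef", "eos_coef"]).copy()
    if abs(gamma) >= 1e-12:
        cpg_truth["beta_smoking"] = (cpg_truth["beta_indirect"] / gamma
                                     + cpg_truth["beta_smoking_only"])
    else:
        cpg_truth["beta_smoking"] = cpg_truth["beta_smoking_only"]
    g_real = _realized_gamma(samples)
    cpg_truth["beta_total_realized"] = (cpg_truth["beta_direct"]
                                        + g_real * cpg_truth["beta_smoking"])
    fam = pd.Series(np.zeros(len(samples)), index=samples["sample_id"].to_numpy(),
                    name="familial")
    return samples, meth, SimTruth(cpg_truth, fam, gamma, clip_frac, g_real)


def generate_twin_cohort(config: SimConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a twin cohort of complete MZ and DZ pairs.

    MZ pairs share the familial and genetic components fully; DZ pairs share
    the familial component fully and the genetic component at half
    correlation.  Education may load on both components (shared confounding)
    via :class:`TwinConfig`.
    """
    tc = config.twin
    if tc.n_mz_pairs < 0 or tc.n_dz_pairs < 0:
        raise ValueError("pair counts must be >= 0")
    rng = _rng(config.seed, _TWIN_KEY)
    profile = config.profiles[0]
    n_pairs = tc.n_mz_pairs + tc.n_dz_pairs
    n = 2 * n_pairs
    truth = _cpg_truth(config)

    if n_pairs == 0:
        samples = _sample_phenotypes(config, replace(profile, n_samples=2), rng,
                                     "TWIN_").iloc[0:0].copy()
        samples["pair_id"] = pd.Series(dtype=object)
        meth = pd.DataFrame(np.empty((config.n_cpgs, 0)),
                            index=truth["cpg_id"].to_numpy())
        fam = pd.Series(dtype=float, name="familial")
        cols = ["base", "age_coef", "sex_coef", "neut_coef", "mono_coef",
                "eos_coef"]
        return samples, meth, SimTruth(truth.drop(columns=cols), fam, 0.0, 0.0)

    zyg = np.repeat(np.array(["MZ"] * tc.n_mz_pairs + ["DZ"] * tc.n_dz_pairs), 2)
    pair = np.repeat(np.arange(n_pairs), 2)

    f_pair = np.repeat(rng.normal(0, 1, size=n_pairs), 2)
    g_shared = np.repeat(rng.normal(0, 1, size=n_pairs), 2)
    g_unique = rng.normal(0, 1, size=n)
    is_mz = zyg == "MZ"
    g = np.where(is_mz, g_shared,
                 np.sqrt(0.5) * g_shared + np.sqrt(0.5) * g_unique)

    lf, lg = tc.education_familial_loading, tc.education_genetic_loading
    if lf ** 2 + lg ** 2 > 1:
        raise ValueError("education loadings imply variance > 1")
    lat = (lf * f_pair + lg * g
           + np.sqrt(1 - lf ** 2 - lg ** 2) * rng.normal(0, 1, size=n))
    cum = np.cumsum(profile.education_probs)
    thresholds = norm.ppf(np.clip(cum[:-1], 1e-12, 1 - 1e-12))
    edu = np.searchsorted(thresholds, lat) + 1
    ridit, _ = ridit_scores(edu)

    base = _sample_phenotypes(config, replace(profile, n_samples=n), rng, "TWIN_")
    samples = base.copy()
    samples["zygosity"] = zyg
    samples["pair_id"] = [f"pair{p:04d}" for p in pair]
    samples["family_id"] = samples["pair_id"]
    samples["education_category"] = edu
    samples["education_ridit"] = ridit
    # co-twins share sex and birth year
    samples["sex"] = np.repeat(samples["sex"].to_numpy()[::2], 2)
    samples["birth_year"] = np.repeat(samples["birth_year"].to_numpy()[::2], 2)
    samples["age"] = np.repeat(samples["age"].to_numpy()[::2], 2)

    cur_frac = profile.smoking_fracs[0]
    a, b, gamma = calibrate_smoking_model(
        profile.education_probs, cur_frac, config.education_smoking_corr)
    current = rng.random(n) < expit(a + b * ridit)
    for_frac, nev_frac = profile.smoking_fracs[1], profile.smoking_fracs[2]
    former = ~current & (rng.random(n) < for_frac / (for_frac + nev_frac))
    status = np.where(current, "current", np.where(former, "former", "never"))
    if tc.smoking_discordant_frac is not None:
        k = int(round(tc.smoking_discordant_frac * n_pairs))
        forced = rng.choice(n_pairs, size=k, replace=False)
        for p in forced:
            status[2 * p], status[2 * p + 1] = "current", "never"
    samples["smoking_status"] = status
    # regenerate dose variables consistently with the twin smoking status
    age = samples["age"].to_numpy()
    cpd = np.where(status == "never", 0.0, rng.poisson(14, size=n) + 1.0)
    dur = rng.uniform(0.5, 1.0, size=n)
    years = np.where(status == "current", np.maximum(age - 18, 1) * dur,
                     np.where(status == "former",
                              np.maximum(age - 18, 1) * dur * 0.5, 0.0))
    samples["cigarettes_per_day"] = cpd
    samples["years_smoked"] = np.round(years, 1)
    samples["pack_years"] = pack_years(cpd, np.round(years, 1))

    fam_sd = config.noise_sd * np.sqrt(tc.familial_variance_share)
    gen_sd = config.noise_sd * np.sqrt(tc.genetic_variance_share)
    meth, clip_frac = _methylation(config, truth, samples, gamma, rng,
                                   familial=f_pair, fam_sd=fam_sd,
                                   gen=g, gen_sd=gen_sd)

    cpg_truth = truth.drop(columns=["base", "age_coef", "sex_coef", "neut_coef",
                                    "mono_coef", "eos_coef"]).copy()
    if abs(gamma) >= 1e-12:
        cpg_truth["beta_smoking"] = (cpg_truth["beta_indirect"] / gamma
                                     + cpg_truth["beta_smoking_only"])
    else:
        cpg_truth["beta_smoking"] = cpg_truth["beta_smoking_only"]
    g_real = _realized_gamma(samples)
    cpg_truth["beta_total_realized"] = (cpg_truth["beta_direct"]
                                        + g_real * cpg_truth["beta_smoking"])
    fam = pd.Series(f_pair, index=samples["sample_id"].to_numpy(), name="familial")
    return samples, meth, SimTruth(cpg_truth, fam, gamma, clip_frac, g_real)


# ---------------------------------------------------------------------------
# expression

class ExpressionData(NamedTuple):
    counts: pd.DataFrame      # transcript x sample raw counts
    annotation: pd.DataFrame  # transcript_id, chrom, start, end
    truth: pd.DataFrame       # transcript_id, cis_cpg, coef


def generate_expression(config: SimConfig, methylation: pd.DataFrame
                        ) -> ExpressionData:
    """RNA-seq-like counts with log-mean linear in methylation for cis pairs."""
    ec = config.expression
    rng = _rng(config.seed, _EXPR_KEY)
    annot = cpg_annotation(config).set_index("cpg_id")
    cpg_ids = [c for c in methylation.index if c in annot.index]
    if not cpg_ids:
        raise ValueError("methylation matrix shares no CpGs with the annotation")

    n_t = ec.n_transcripts
    n_cis = int(round(ec.frac_cis * n_t))
    n_cis_null = int(round(ec.frac_cis_null * n_t))
    chosen = rng.choice(len(cpg_ids), size=min(n_cis + n_cis_null, len(cpg_ids)),
                        replace=False)
    rows = []
    for j in range(n_t):
        tid = f"ENST{j:08d}"
        if j < len(chosen):
            cid = cpg_ids[chosen[j]]
            chrom = annot.at[cid, "chrom"]
            start = int(annot.at[cid, "pos"]
                        + rng.integers(-ec.placement_window, ec.placement_window + 1))
            start = max(start, 1)
            if j < n_cis:
                coef = (ec.cis_coef if ec.cis_coef is not None
                        else float(rng.normal(0, 2.0)))
            else:
                coef = 0.0
            rows.append((tid, chrom, start, start + 1000, cid, coef))
        else:
            # far from every CpG: separate coordinate block
            rows.append((tid, "chr23", 1_000_000 + j * 10_000,
                         1_000_000 + j * 10_000 + 1000, None, 0.0))
    tab = pd.DataFrame(rows, columns=["transcript_id", "chrom", "start", "end",
                                      "cis_cpg", "coef"])

    n_s = methylation.shape[1]
    lib = rng.lognormal(np.log(ec.library_size_mean), ec.library_size_log_sd, size=n_s)
    # transcripts near a CpG get a detectable baseline; distant ones keep a
    # low-expression tail so the detection filter has something to remove
    near = tab["cis_cpg"].notna().to_numpy()
    base = np.where(near, rng.uniform(3.0, 8.0, size=n_t),
                    rng.uniform(0.0, 8.0, size=n_t))
    log2cpm = np.tile(base[:, None], (1, n_s))
    for i, row in tab.iterrows():
        if row["cis_cpg"] is not None:
            m = methylation.loc[row["cis_cpg"]].to_numpy()
            # centred so the cis slope does not push counts into the
            # low-count regime where log-CPM saturates
            log2cpm[i] = base[i] + row["coef"] * (m - m.mean())
    lam = (2.0 ** log2cpm) / 1e6 * lib[None, :]
    if ec.overdispersion > 0:
        shape = 1.0 / ec.overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=tab["transcript_id"].to_numpy(),
                             columns=methylation.columns)
    return ExpressionData(
        counts_df,
        tab[["transcript_id", "chrom", "start", "end"]].copy(),
        tab[["transcript_id", "cis_cpg", "coef"]].copy(),
    )


# ---------------------------------------------------------------------------
# external summary statistics

def generate_external_sumstats(truth: SimTruth | pd.DataFrame, noise_sd: float,
                               sign_flip: bool = False, *, seed: int = 0,
                               source: str = "external") -> pd.DataFrame:
    """Per-CpG external effect sizes correlated with the truth by construction.

    effect = s * (beta_total + N(0, noise_sd^2)), s = -1 if ``sign_flip``.
    With calibrated noise the correlation with the true effects over causal
    CpGs is r = 1 / sqrt(1 + noise_sd^2 / var(beta_total)).
    """
    cpgs = truth.cpgs if isinstance(truth, SimTruth) else truth
    rng = _rng(seed, _EXT_KEY)
    eff = cpgs["beta_total"].to_numpy(dtype=float).copy()
    if noise_sd > 0:
        eff = eff + rng.normal(0, noise_sd, size=len(eff))
    if sign_flip:
        eff = -eff
    return pd.DataFrame({"cpg_id": cpgs["cpg_id"].to_numpy(), "effect": eff,
                         "source": source})


# ---------------------------------------------------------------------------
# writers (TSV throughout; BED-like annotation is 0-based half-open)

def write_cohort(outdir: str | Path, samples: pd.DataFrame,
                 methylation: pd.DataFrame, truth: SimTruth | None = None,
                 annotation: pd.DataFrame | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    methylation.to_csv(outdir / "methylation.tsv", sep="\t",
                       index_label="cpg_id")
    if truth is not None:
        truth.cpgs.to_csv(outdir / "truth_cpgs.tsv", sep="\t", index=False)
        truth.familial.rename_axis("sample_id").to_frame().to_csv(
            outdir / "truth_familial.tsv", sep="\t")
    if annotation is not None:
        _write_bed(outdir / "cpgs.bed", annotation)


def write_expression(outdir: str | Path, expr: "ExpressionData") -> None:
    """Write expression counts TSV plus a minimal GFF-like annotation sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr.counts.to_csv(outdir / "expression_counts.tsv", sep="\t",
                       index_label="transcript_id")
    expr.annotation.to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
    expr.truth.to_csv(outdir / "expression_truth.tsv", sep="\t", index=False)


def _write_bed(path: Path, annotation: pd.DataFrame) -> None:
    bed = pd.DataFrame({
        "chrom": annotation["chrom"],
        "start": annotation["pos"] - 1,  # 1-based -> BED 0-based
        "end": annotation["pos"],
        "cpg_id": annotation["cpg_id"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
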