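import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from eduwas.ewas import (DesignSpec, build_design, clustered_se, fit_site,
                         run_ewas)
from eduwas.synth import SimConfig, TwinConfig, generate_cohort, \
    generate_twin_cohort


def minimal_design(**kw):
    """Exposure-only design (no covariates)."""
    return DesignSpec(cell_cols=(), categorical=(), continuous=(), **kw)


class TestFitSite:
    def test_noiseless_fit_recovers_exact_coefficient(self, tiny_samples):
        y = 0.2 + 0.1 * tiny_samples["education_ridit"]
        fit = fit_site(y, tiny_samples, minimal_design())
        assert fit.effect == pytest.approx(0.1, abs=1e-12)
        assert fit.se == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, tiny_samples, rng):
        y = pd.Series(rng.normal(0.5, 0.05, len(tiny_samples)),
                      index=tiny_samples.index)
        design = DesignSpec(model="model2")
        fit = fit_site(y, tiny_samples, design)
        X, names, idx = build_design(tiny_samples, design)
        res = sm.OLS(y.loc[idx].to_numpy(), X).fit()
        assert fit.effect == pytest.approx(res.params[1], abs=1e-10)
        assert fit.se == pytest.approx(res.bse[1], abs=1e-10)
        assert fit.n == len(idx)

    def test_constant_exposure_is_reported_not_crashed(self, tiny_samples):
        df = tiny_samples.copy()
        df["education_ridit"] = 0.5
        y = df["age"] / 100
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fit_site(y, df, minimal_design())

    def test_too_few_complete_cases(self, tiny_samples):
        y = pd.Series(np.nan, index=tiny_samples.index)
        y.iloc[:10] = 0.5
        with pytest.raises(ValueError, match="complete cases"):
            fit_site(y, tiny_samples, minimal_design(n_min=30))

    def test_orthogonal_covariate_leaves_exposure_unchanged(self, tiny_samples,
                                                            rng):
        y = pd.Series(rng.normal(0.5, 0.05, len(tiny_samples)),
                      index=tiny_samples.index)
        base = minimal_design()
        fit0 = fit_site(y, tiny_samples, base)
        x = tiny_samples["education_ridit"].to_numpy()
        raw = rng.normal(size=len(x))
        X0 = np.column_stack([np.ones_like(x), x])
        resid = raw - X0 @ np.linalg.lstsq(X0, raw, rcond=None)[0]
        df = tiny_samples.copy()
        df["orthogonal"] = resid
        fit1 = fit_site(y.loc[df.index], df,
                        minimal_design(extra_adjusters=("orthogonal",)))
        assert fit1.effect == pytest.approx(fit0.effect, abs=1e-8)


class TestClusteredSE:
    def test_singleton_families_equal_ols_se(self, tiny_samples, rng):
        y = pd.Series(rng.normal(0.5, 0.05, len(tiny_samples)),
                      index=tiny_samples.index)
        for method in ("sandwich", "exchangeable"):
            fit = fit_site(y, tiny_samples,
                           minimal_design(cluster_col="family_id",
                                          se_method=method))
            ols = fit_site(y, tiny_samples, minimal_design())
            assert fit.se == pytest.approx(ols.se, abs=1e-10)

    def test_sandwich_matches_statsmodels_cluster(self, rng):
        n = 120
        fam = np.repeat(np.arange(n // 2), 2)
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "family_id": [f"f{f}" for f in fam],
            "education_ridit": rng.uniform(0, 1, n),
            "age": rng.uniform(20, 70, n),
        })
        shared = rng.normal(0, 0.03, n // 2)[fam]
        y = pd.Series(0.4 + 0.05 * df["education_ridit"] + shared
                      + rng.normal(0, 0.02, n), index=df.index)
        design = DesignSpec(cell_cols=(), categorical=(), continuous=("age",),
                            cluster_col="family_id")
        fit = fit_site(y, df, design)
        X, _, idx = build_design(df, design)
        res = sm.OLS(y.to_numpy(), X).fit(cov_type="cluster",
                                          cov_kwds={"groups": fam})
        assert fit.effect == pytest.approx(res.params[1], abs=1e-10)
        assert fit.se == pytest.approx(res.bse[1], rel=1e-8)

    @pytest.mark.parametrize("method", ["sandwich", "exchangeable"])
    def test_duplicated_samples_inflate_se_by_sqrt2(self, method, rng):
        n = 200
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "education_ridit": rng.uniform(0, 1, n),
        })
        y = 0.4 + 0.03 * df["education_ridit"] + rng.normal(0, 0.02, n)
        dup = pd.concat([df, df.assign(sample_id=lambda d: d["sample_id"] + "b")],
                        ignore_index=True)
        dup["family_id"] = np.tile([f"f{i}" for i in range(n)], 2)
        y2 = pd.Series(np.concatenate([y, y]), index=dup.index)
        naive = fit_site(y2, dup, minimal_design())
        clust = fit_site(y2, dup, minimal_design(cluster_col="family_id",
                                                 se_method=method))
        assert clust.se / naive.se == pytest.approx(np.sqrt(2), rel=0.10)

    def test_clustered_se_function_api(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.uniform(size=n)])
        beta = np.linalg.lstsq(X, rng.normal(size=n), rcond=None)[0]
        y = rng.normal(size=n)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        fams = np.arange(n)  # all singletons
        se = clustered_se(X, resid, fams)
        sigma2 = resid @ resid / (n - 2)
        ols = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert se == pytest.approx(ols, abs=1e-12)

    def test_familial_correlation_widens_se_on_average(self):
        cfg = SimConfig(n_cpgs=120, n_causal=0, n_smoking_only=0, seed=21,
                        effect_range_education=(0.0, 0.0),
                        mediation_fraction=0.0,
                        twin=TwinConfig(n_mz_pairs=250, n_dz_pairs=0,
                                        familial_variance_share=0.5,
                                        genetic_variance_share=0.0,
                                        education_familial_loading=0.8))
        samples, meth, _ = generate_twin_cohort(cfg)
        ind = run_ewas(meth, samples, DesignSpec(model="model1"))
        clu = run_ewas(meth, samples, DesignSpec(model="model1",
                                                 cluster_col="family_id"))
        assert clu["se"].mean() > ind["se"].mean()


class TestRunEwas:
    def test_deterministic_and_matches_fit_site(self, cohort):
        samples, meth, _ = cohort
        design = DesignSpec(model="model1")
        res1 = run_ewas(meth, samples, design, cohort="NTR")
        res2 = run_ewas(meth, samples, design, cohort="NTR")
        pd.testing.assert_frame_equal(res1, res2)
        row = res1.iloc[7]
        tab = samples.set_index("sample_id")
        f = fit_site(meth.loc[row["cpg_id"], tab.index], tab.reset_index()
                     .set_index("sample_id"), design)
        assert row["effect"] == pytest.approx(f.effect, abs=1e-12)
        assert row["se"] == pytest.approx(f.se, abs=1e-12)

    def test_no_overlapping_samples_fails(self, cohort):
        samples, meth, _ = cohort
        renamed = meth.copy()
        renamed.columns = [c + "_x" for c in renamed.columns]
        with pytest.raises(ValueError, match="overlap"):
            run_ewas(renamed, samples, DesignSpec())

    def test_missing_values_fall_back_to_per_site_fit(self, cohort):
        samples, meth, _ = cohort
        m = meth.copy()
        m.iloc[0, :40] = np.nan
        res = run_ewas(m, samples, DesignSpec(model="model1"))
        assert res.loc[res["cpg_id"] == m.index[0], "n"].iloc[0] \
            == m.shape[1] - 40

    def test_type_one_error_near_nominal(self):
        cfg = SimConfig(n_cpgs=4000, n_causal=0, n_smoking_only=0,
                        effect_range_education=(0.0, 0.0),
                        mediation_fraction=0.0, seed=31)
        samples, meth, _ = generate_cohort(cfg, 0)
        res = run_ewas(meth, samples, DesignSpec(model="model1"))
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)

    def test_model2_attenuates_mediated_effects_toward_direct(self, cohort):
        samples, meth, truth = cohort
        causal = truth.cpgs[truth.cpgs["causal"]].set_index("cpg_id")
        r1 = run_ewas(meth, samples, DesignSpec(model="model1")) \
            .set_index("cpg_id").loc[causal.index]
        r2 = run_ewas(meth, samples, DesignSpec(model="model2")) \
            .set_index("cpg_id").loc[causal.index]
        # per-site attenuation: model2 closer to the direct effect
        d2 = (r2["effect"] - causal["beta_direct"]).abs().mean()
        d1 = (r1["effect"] - causal["beta_direct"]).abs().mean()
        assert d2 < d1

    def test_never_smoker_subset_nulls_smoking_driven_sites(self):
        # smoking is the only source of signal; in never smokers the
        # exposure effect should be null at ~ nominal coverage
        cfg = SimConfig(n_cpgs=500, n_causal=0, n_smoking_only=500,
                        effect_range_education=(0.0, 0.0),
                        mediation_fraction=0.0, seed=41)
        samples, meth, _ = generate_cohort(cfg, 0)
        res = run_ewas(meth, samples,
                       DesignSpec(model="model1", subset="never_smokers"))
        covered = ((res["effect"] - 1.96 * res["se"] <= 0)
                   & (0 <= res["effect"] + 1.96 * res["se"])).mean()
        assert covered >= 0.93
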