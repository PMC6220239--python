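import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from eduwas.synth import (SimConfig, TwinConfig, calibrate_smoking_model,
                          default_profiles, generate_cohort,
                          generate_external_sumstats, generate_twin_cohort)


def null_config(seed=0, **kw):
    """All effects zero: a global-null dataset."""
    base = dict(n_cpgs=200, n_causal=0, n_smoking_only=0,
                effect_range_education=(0.0, 0.0), mediation_fraction=0.0,
                seed=seed)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_reproduces_identically(self, small_cfg):
        s1, m1, t1 = generate_cohort(small_cfg, 1)
        s2, m2, t2 = generate_cohort(small_cfg, 1)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1.cpgs, t2.cpgs)

    def test_different_seed_differs(self, small_cfg):
        _, m1, _ = generate_cohort(small_cfg, 1)
        _, m2, _ = generate_cohort(replace(small_cfg, seed=small_cfg.seed + 1), 1)
        assert not np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_per_cohort_streams_are_independent(self, small_cfg):
        # generating cohort 2 directly gives the same data as after cohort 0
        s_a, m_a, _ = generate_cohort(small_cfg, 2)
        generate_cohort(small_cfg, 0)
        s_b, m_b, _ = generate_cohort(small_cfg, 2)
        pd.testing.assert_frame_equal(s_a, s_b)
        pd.testing.assert_frame_equal(m_a, m_b)


class TestConfigValidation:
    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frac_positive=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_cpgs=10, n_causal=20)
        with pytest.raises(ValueError):
            SimConfig(noise_sd=0.0)

    def test_impossible_correlation_target_named(self):
        prof = default_profiles()[0]
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_smoking_model(prof.education_probs,
                                    prof.smoking_fracs[0], -0.95)


class TestCohortStructure:
    def test_zero_effect_config_has_null_truth(self):
        _, _, truth = generate_cohort(null_config(seed=3), 0)
        assert (truth.cpgs["beta_total"] == 0).all()
        assert (truth.cpgs["beta_direct"] == 0).all()
        assert (truth.cpgs["beta_smoking"] == 0).all()

    def test_beta_values_in_unit_interval_with_rare_clipping(self, cohort):
        _, meth, truth = cohort
        v = meth.to_numpy()
        assert v.min() >= 0 and v.max() <= 1
        assert truth.clip_fraction < 0.01

    def test_education_smoking_correlation_near_target(self):
        # seed-averaged empirical correlation within +-0.03 of -0.11
        corrs = []
        for seed in range(4):
            cfg = SimConfig(n_cpgs=10, n_causal=0, n_smoking_only=0, seed=seed)
            s, _, _ = generate_cohort(cfg, 0)
            cur = (s["smoking_status"] == "current").astype(float)
            corrs.append(np.corrcoef(s["education_ridit"], cur)[0, 1])
        assert np.mean(corrs) == pytest.approx(-0.11, abs=0.03)

    def test_never_smoker_fraction_matches_profile(self):
        cfg = SimConfig(n_cpgs=10, n_causal=0, n_smoking_only=0, seed=2)
        s, _, _ = generate_cohort(cfg, 0)
        frac = (s["smoking_status"] == "never").mean()
        n = len(s)
        se = np.sqrt(0.565 * (1 - 0.565) / n)
        assert abs(frac - 0.565) < 3 * se

    def test_cotinine_consistent_with_status(self, cohort):
        samples, _, _ = cohort
        cur = samples[samples["smoking_status"] == "current"]["cotinine"]
        nev = samples[samples["smoking_status"] == "never"]["cotinine"]
        assert (cur >= 15).mean() > 0.9
        assert (nev < 15).mean() > 0.95

    def test_pack_years_zero_for_never_smokers(self, cohort):
        samples, _, _ = cohort
        nev = samples[samples["smoking_status"] == "never"]
        assert (nev["pack_years"] == 0).all()


class TestTwins:
    def test_no_pairs_gives_empty_tables_without_error(self):
        cfg = SimConfig(n_cpgs=50, n_causal=5, seed=1,
                        twin=TwinConfig(n_mz_pairs=0, n_dz_pairs=0))
        samples, meth, _ = generate_twin_cohort(cfg)
        assert len(samples) == 0 and meth.shape[1] == 0

    def test_pair_bookkeeping_and_shared_components(self):
        cfg = SimConfig(n_cpgs=50, n_causal=5, seed=1,
                        twin=TwinConfig(n_mz_pairs=30, n_dz_pairs=20))
        samples, meth, truth = generate_twin_cohort(cfg)
        assert len(samples) == 100
        assert (samples["zygosity"] == "MZ").sum() == 60
        # co-twins share the familial component, sex and birth year exactly
        fam = truth.familial.to_numpy()
        assert np.allclose(fam[::2], fam[1::2])
        assert (samples["sex"].to_numpy()[::2]
                == samples["sex"].to_numpy()[1::2]).all()

    def test_forced_smoking_discordance(self):
        cfg = SimConfig(n_cpgs=20, n_causal=0, n_smoking_only=0, seed=4,
                        twin=TwinConfig(n_mz_pairs=50, n_dz_pairs=0,
                                        smoking_discordant_frac=0.4))
        samples, _, _ = generate_twin_cohort(cfg)
        st = samples["smoking_status"].to_numpy()
        disc = sum({a, b} == {"current", "never"}
                   for a, b in zip(st[::2], st[1::2]))
        assert disc >= 20

    def test_overloaded_education_loadings_rejected(self):
        cfg = SimConfig(n_cpgs=10, n_causal=0, n_smoking_only=0, seed=0,
                        twin=TwinConfig(education_familial_loading=0.9,
                                        education_genetic_loading=0.9))
        with pytest.raises(ValueError, match="loadings"):
            generate_twin_cohort(cfg)


class TestWriters:
    def test_cohort_and_expression_round_trip(self, small_cfg, cohort, tmp_path):
        from eduwas.synth import (cpg_annotation, generate_expression,
                                  write_cohort, write_expression)
        samples, meth, truth = cohort
        write_cohort(tmp_path, samples, meth, truth,
                     annotation=cpg_annotation(small_cfg))
        back = pd.read_csv(tmp_path / "methylation.tsv", sep="\t",
                           index_col="cpg_id")
        assert np.allclose(back.to_numpy(), meth.to_numpy())
        bed = pd.read_csv(tmp_path / "cpgs.bed", sep="\t", header=None)
        assert (bed[2] - bed[1] == 1).all()  # 0-based half-open single base
        expr = generate_expression(small_cfg, meth)
        write_expression(tmp_path, expr)
        counts = pd.read_csv(tmp_path / "expression_counts.tsv", sep="\t",
                             index_col="transcript_id")
        assert counts.shape == expr.counts.shape


class TestExternalSumstats:
    def test_noiseless_correlation_is_one(self, cohort):
        _, _, truth = cohort
        causal = truth.cpgs[truth.cpgs["causal"]]
        ext = generate_external_sumstats(truth, noise_sd=0.0)
        merged = causal.merge(ext, on="cpg_id")
        assert np.corrcoef(merged["beta_total"], merged["effect"])[0, 1] \
            == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, cohort):
        _, _, truth = cohort
        causal = truth.cpgs[truth.cpgs["causal"]]
        ext = generate_external_sumstats(truth, noise_sd=0.0, sign_flip=True)
        merged = causal.merge(ext, on="cpg_id")
        assert np.corrcoef(merged["beta_total"], merged["effect"])[0, 1] \
            == pytest.approx(-1.0)

    def test_calibrated_noise_matches_closed_form(self):
        cfg = SimConfig(n_cpgs=4000, n_causal=4000, n_smoking_only=0, seed=9,
                        mediation_fraction=0.0)
        _, _, truth = generate_cohort(cfg, 0)
        noise = 0.02
        ext = generate_external_sumstats(truth, noise_sd=noise, seed=9)
        merged = truth.cpgs.merge(ext, on="cpg_id")
        var = merged["beta_total"].var()
        expected = 1.0 / np.sqrt(1.0 + noise ** 2 / var)
        r = np.corrcoef(merged["beta_total"], merged["effect"])[0, 1]
        # Fisher-z 99% interval at n = 4000
        z_err = 2.58 / np.sqrt(len(merged) - 3)
        assert abs(np.arctanh(r) - np.arctanh(expected)) < z_err
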