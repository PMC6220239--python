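import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eduwas.phenotypes import (classify_cotinine, methylation_smoking_score,
                               pack_years, reconcile_maternal_smoking,
                               reconcile_twin_answers, ridit_scores,
                               ridit_transform)


class TestRidit:
    @pytest.mark.parametrize("cats,expected", [
        # degenerate single category: everyone sits at the distribution centre
        (np.repeat(3, 20), {3: 0.5}),
        # two categories 50/50: quartile positions
        (np.array([1] * 10 + [2] * 10), {1: 0.25, 2: 0.75}),
        # proportions (.1,.2,.3,.4) -> cumulative-midpoint values
        (np.repeat([1, 2, 3, 4], [1, 2, 3, 4]),
         {1: 0.05, 2: 0.20, 3: 0.45, 4: 0.80}),
    ])
    def test_cumulative_midpoint_values(self, cats, expected):
        scores, spec = ridit_scores(cats, levels=sorted(set(cats.tolist())))
        got = dict(zip(cats.tolist(), scores.tolist()))
        for k, v in expected.items():
            assert got[k] == pytest.approx(v, abs=1e-12)

    def test_stratum_mean_is_half_and_monotone(self, cohort):
        samples, _, _ = cohort
        out, spec = ridit_transform(samples)
        key = out["sex"].astype(str)  # strata nest within sex
        for stratum, grp in spec.table.groupby("stratum"):
            mean = (grp["proportion"] * grp["ridit"]).sum()
            assert mean == pytest.approx(0.5, abs=1e-12)
            present = grp[grp["proportion"] > 0]
            assert present["ridit"].is_monotonic_increasing
        assert out["education_ridit"].between(0, 1, inclusive="neither").all()

    def test_invariant_to_sample_order(self, cohort):
        samples, _, _ = cohort
        a, _ = ridit_transform(samples)
        shuffled = samples.sample(frac=1.0, random_state=3)
        b, _ = ridit_transform(shuffled)
        merged = a.set_index("sample_id")["education_ridit"]
        assert np.allclose(
            merged.loc[b["sample_id"]].to_numpy(),
            b["education_ridit"].to_numpy())

    def test_small_strata_merge_with_warning(self):
        g = np.random.default_rng(0)
        tab = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(40)],
            "sex": ["F"] * 40,
            "birth_year": [1950] * 37 + [1988, 1989, 1989],  # tiny 1980s bin
            "education_category": g.integers(1, 8, size=40),
        })
        with pytest.warns(UserWarning, match="merged"):
            out, spec = ridit_transform(tab, min_stratum=10)
        assert out["education_ridit"].notna().all()
        assert len(spec.strata) == 1  # everything collapsed into one stratum

    def test_single_stratum_mode(self, cohort):
        samples, _, _ = cohort
        out, spec = ridit_transform(samples, stratify=False)
        assert set(spec.table["stratum"]) == {"all"}

    @given(st.lists(st.integers(1, 7), min_size=5, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_properties_hold_for_any_distribution(self, cats):
        scores, spec = ridit_scores(np.array(cats))
        weighted = (spec["proportion"] * spec["ridit"]).sum()
        assert weighted == pytest.approx(0.5, abs=1e-12)
        # monotone in category for samples present
        df = pd.DataFrame({"c": cats, "r": scores}).sort_values("c")
        assert df.groupby("c")["r"].first().is_monotonic_increasing


class TestPackYears:
    @pytest.mark.parametrize("cpd,yrs,expected", [(20, 10, 10), (10, 6, 3),
                                                  (0, 40, 0)])
    def test_formula(self, cpd, yrs, expected):
        assert pack_years(cpd, yrs) == expected

    def test_missing_propagates(self):
        assert np.isnan(pack_years(np.nan, 10))
        out = pack_years([10, np.nan], [6, 6])
        assert out[0] == 3 and np.isnan(out[1])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pack_years(-1, 10)


class TestCotinine:
    @pytest.mark.parametrize("value,expected", [
        (15.0, "smoker"),        # boundary: >= 15 is active smoking
        (1.0, "second_hand"),    # boundary: >= 1 is second-hand exposure
        (0.5, "unexposed"),
        (200.0, "smoker"),
        (14.999, "second_hand"),
    ])
    def test_cutoffs(self, value, expected):
        assert classify_cotinine(value) == expected

    def test_missing_and_negative(self):
        assert classify_cotinine(np.nan) is None
        with pytest.raises(ValueError):
            classify_cotinine(-0.1)

    @given(st.floats(min_value=0, max_value=1e4, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_partition_is_exhaustive_and_disjoint(self, x):
        assert classify_cotinine(x) in {"smoker", "second_hand", "unexposed"}


class TestMaternalSmoking:
    @pytest.mark.parametrize("a,b,expected", [
        ("yes", "missing", ("yes", "yes")),
        ("yes", "no", ("missing", "missing")),
        ("unknown", "unknown", ("missing", "missing")),
        ("no", "unknown", ("no", "no")),
        ("yes", "yes", ("yes", "yes")),
    ])
    def test_reconciliation(self, a, b, expected):
        assert reconcile_maternal_smoking(a, b) == expected

    @given(st.sampled_from(["yes", "no", "unknown", "missing"]),
           st.sampled_from(["yes", "no", "unknown", "missing"]))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_in_twin_order(self, a, b):
        r1, r2 = reconcile_maternal_smoking(a, b)
        s2, s1 = reconcile_maternal_smoking(b, a)
        assert (r1, r2) == (s1, s2)

    def test_table_helper_only_touches_complete_pairs(self):
        tab = pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "family_id": ["f1", "f1", "f2"],
            "maternal_smoking": ["yes", "missing", "unknown"],
        })
        out = reconcile_twin_answers(tab)
        assert list(out["maternal_smoking"]) == ["yes", "yes", "unknown"]


class TestSmokingScore:
    def test_hand_weighted_sum(self):
        meth = pd.DataFrame([[0.6], [0.2]], index=["cg1", "cg2"], columns=["s1"])
        w = pd.DataFrame({"cpg_id": ["cg1", "cg2"], "weight": [1.0, -1.0]})
        res = methylation_smoking_score(meth, w)
        assert res.scores["s1"] == pytest.approx(0.4)
        assert res.n_cpgs_used == 2

    def test_zero_weights_give_zero_scores(self):
        meth = pd.DataFrame(np.random.default_rng(0).random((3, 4)),
                            index=["cg1", "cg2", "cg3"])
        w = pd.DataFrame({"cpg_id": ["cg1", "cg3"], "weight": [0.0, 0.0]})
        assert (methylation_smoking_score(meth, w).scores == 0).all()

    def test_empty_intersection_fails(self):
        meth = pd.DataFrame([[0.5]], index=["cg1"], columns=["s1"])
        w = pd.DataFrame({"cpg_id": ["cgX"], "weight": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            methylation_smoking_score(meth, w)

    def test_separates_smokers_on_synthetic_data(self, cohort):
        samples, meth, truth = cohort
        smk = truth.cpgs[truth.cpgs["smoking_only"]]
        weights = pd.DataFrame({"cpg_id": smk["cpg_id"],
                                "weight": smk["beta_smoking"]})
        res = methylation_smoking_score(meth, weights)
        cur = res.scores[samples.set_index("sample_id")["smoking_status"] == "current"]
        nev = res.scores[samples.set_index("sample_id")["smoking_status"] == "never"]
        # rank-sum AUC
        ranks = pd.concat([cur, nev]).rank()
        auc = (ranks[cur.index].sum() - len(cur) * (len(cur) + 1) / 2) \
            / (len(cur) * len(nev))
        assert auc > 0.9
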