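import numpy as np
import pandas as pd
import pytest

from scnkit import stats as st
from scnkit.synthetic import CohortConfig, generate_cohort, records_to_frame


class TestClassifyCI:
    @pytest.mark.parametrize(
        "mmse, level, expected",
        [
            (18, "illiterate", "CI"),
            (19, "illiterate", "CI"),
            (20, "illiterate", "NCI"),
            (22, "elementary", "CI"),
            (23, "elementary", "NCI"),
            (26, "secondary", "CI"),
            (27, "secondary", "NCI"),
            (30, "illiterate", "NCI"),
            (30, "elementary", "NCI"),
            (30, "secondary", "NCI"),
        ],
    )
    def test_education_dependent_cutoffs(self, mmse, level, expected):
        assert st.classify_ci(mmse, level) == expected

    def test_unknown_education_level(self):
        with pytest.raises(ValueError, match="education"):
            st.classify_ci(25, "postgraduate")


class TestVolumeRatios:
    def test_identity_and_homogeneity(self):
        r = st.volume_ratios({"WM": 5e5}, etiv=5e5)
        assert r["WM"] == pytest.approx(100.0)
        r2 = st.volume_ratios({"WM": 5e5}, etiv=1e6)
        assert r2["WM"] == pytest.approx(r["WM"] / 2)

    def test_bilateral_structures_summed(self):
        r = st.volume_ratios(
            {"Left-Thalamus": 7000.0, "Right-Thalamus": 7000.0}, etiv=1.4e6
        )
        assert r["Thalamus"] == pytest.approx(100 * 14000 / 1.4e6)

    def test_hand_computed_table(self):
        vols = {"GM": 6.0e5, "Left-Hippocampus": 4000.0, "Right-Hippocampus": 3800.0}
        r = st.volume_ratios(vols, etiv=1.5e6)
        assert r["GM"] == pytest.approx(40.0)
        assert r["Hippocampus"] == pytest.approx(100 * 7800 / 1.5e6)

    def test_nonpositive_inputs_flagged(self):
        with pytest.raises(ValueError, match="etiv"):
            st.volume_ratios({"WM": 1.0}, etiv=0)
        with pytest.raises(ValueError, match="nonpositive"):
            st.volume_ratios({"WM": -1.0}, etiv=1e6)


class TestCompareVariable:
    def test_gaussian_data_routes_to_t(self, rng):
        vals = np.r_[rng.normal(0, 1, 18), rng.normal(0, 1, 33)]
        groups = ["CI"] * 18 + ["NCI"] * 33
        res = st.compare_variable(vals, groups)
        assert res.test == "t"
        assert "±" in res.group_summaries["CI"]

    def test_skewed_data_routes_to_mann_whitney(self, rng):
        vals = np.exp(np.r_[rng.normal(0, 1.5, 30), rng.normal(0, 1.5, 30)])
        groups = ["CI"] * 30 + ["NCI"] * 30
        res = st.compare_variable(vals, groups)
        assert res.test == "mann_whitney"
        assert "(" in res.group_summaries["CI"]  # median + IQR summary

    def test_identical_groups_tied_ranks_no_crash(self):
        vals = [1, 2, 3, 4, 5] * 2
        groups = ["CI"] * 5 + ["NCI"] * 5
        res = st.compare_variable(vals, groups, force_test="mann_whitney")
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_categorical_routes_to_chi_square(self):
        gender = ["F", "M"] * 10 + ["F"] * 10
        groups = ["CI"] * 15 + ["NCI"] * 15
        res = st.compare_variable(gender, groups)
        assert res.test == "chi_square"
        assert 0 <= res.p_value <= 1

    def test_constant_group_raises_routing_error(self):
        vals = [1.0] * 5 + [2.0, 3.0, 4.0, 5.0, 6.0]
        groups = ["CI"] * 5 + ["NCI"] * 5
        with pytest.raises(ValueError, match="constant"):
            st.compare_variable(vals, groups, variable="flatvar")

    def test_null_type_one_error_calibrated(self):
        """Same-distribution groups reject at ~5% (n=18/33, 400 replicates)."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            vals = rng.normal(0, 1, 51)
            groups = ["CI"] * 18 + ["NCI"] * 33
            res = st.compare_variable(vals, groups)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestLogistic:
    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(1)
        n = 2000
        df = pd.DataFrame(
            {
                "y": rng.integers(0, 2, n).astype(float),
                "x": rng.normal(0, 1, n),
                "age": rng.uniform(60, 80, n),
                "gender": rng.choice(["F", "M"], n),
                "duration": rng.uniform(1, 6, n),
            }
        )
        res = st.logistic_adjusted(df, df["y"], "x")
        assert 0.85 <= res.odds_ratio <= 1.18
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        assert res.odds_ratio == pytest.approx(np.exp(res.coef))

    def test_known_log_odds_recovered(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(0, 1, n)
        logit = -0.2 + np.log(2) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        df = pd.DataFrame(
            {
                "y": y,
                "x": x,
                "age": rng.uniform(60, 80, n),
                "gender": rng.choice(["F", "M"], n),
                "duration": rng.uniform(1, 6, n),
            }
        )
        res = st.logistic_adjusted(df, df["y"], "x")
        assert res.ci_low <= 2.0 <= res.ci_high

    def test_coefficient_scales_inversely_with_predictor(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        df = pd.DataFrame(
            {"y": y, "x": x, "age": rng.uniform(60, 80, n),
             "gender": rng.choice(["F", "M"], n), "duration": rng.uniform(1, 6, n)}
        )
        b1 = st.logistic_adjusted(df, df["y"], "x").coef
        df2 = df.assign(x=10.0 * df["x"])
        b2 = st.logistic_adjusted(df2, df2["y"], "x").coef
        assert b2 == pytest.approx(b1 / 10.0, rel=1e-6)

    def test_separation_reported_not_silent(self):
        df = pd.DataFrame(
            {
                "y": [0.0] * 10 + [1.0] * 10,
                "x": list(range(10)) + list(range(100, 110)),
                "age": np.linspace(60, 80, 20),
                "gender": ["F", "M"] * 10,
                "duration": np.linspace(1, 6, 20),
            }
        )
        with pytest.raises(ValueError):
            st.logistic_adjusted(df, df["y"], "x")

    def test_one_class_outcome_rejected(self):
        df = pd.DataFrame(
            {"y": [1.0] * 8, "x": range(8), "age": range(8),
             "gender": ["F"] * 8, "duration": range(8)}
        )
        with pytest.raises(ValueError, match="both classes"):
            st.logistic_adjusted(df, df["y"], "x", covariates=("age",))


class TestFDR:
    def test_hand_computed_step_up(self):
        adj = st.fdr_correct([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert st.fdr_correct([0.037]) == pytest.approx([0.037])

    def test_equal_ps_unchanged(self):
        assert np.allclose(st.fdr_correct([0.2, 0.2, 0.2]), 0.2)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        adj = st.fdr_correct(p)
        assert np.allclose(st.fdr_correct(p[perm]), adj[perm])

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(size=50)
        adj = st.fdr_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.fdr_correct([0.5, 1.2])


class TestCompareAUC:
    @pytest.fixture()
    def auc_and_subjects(self, rng):
        n = 40
        subs = pd.DataFrame(
            {
                "group": ["CI"] * 15 + ["NCI"] * 25,
                "age": rng.uniform(60, 80, n),
                "gender": rng.choice(["F", "M"], n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        auc = pd.DataFrame(
            rng.normal(0.2, 0.01, (n, 3)),
            index=subs.index,
            columns=["eloc", "eglob", "sigma"],
        )
        return auc, subs

    def test_constant_covariates_reduce_to_two_sample_t(self, auc_and_subjects):
        from scipy import stats as sps

        auc, subs = auc_and_subjects
        subs = subs.assign(age=70.0, gender="F")
        res = st.compare_auc_metrics(auc, subs, covariates=("age",))
        # constant age is dropped into the intercept; t equals plain t-test
        ci = subs["group"] == "CI"
        for r in res:
            t, _ = sps.ttest_ind(auc.loc[ci, r.variable], auc.loc[~ci, r.variable])
            assert r.statistic == pytest.approx(t, abs=1e-8)

    def test_fdr_applied_across_metrics(self, auc_and_subjects):
        auc, subs = auc_and_subjects
        res = st.compare_auc_metrics(auc, subs)
        adj = st.fdr_correct([r.p_value for r in res])
        assert [r.p_adjusted for r in res] == pytest.approx(list(adj))

    def test_missing_auc_listed(self, auc_and_subjects):
        auc, subs = auc_and_subjects
        auc = auc.copy()
        auc.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="s0"):
            st.compare_auc_metrics(auc, subs)

    def test_negative_t_when_ci_lower(self, auc_and_subjects):
        auc, subs = auc_and_subjects
        auc = auc.copy()
        auc.loc[subs["group"] == "CI", "eloc"] -= 0.05
        res = {r.variable: r for r in st.compare_auc_metrics(auc, subs)}
        assert res["eloc"].statistic < 0


class TestCohortTable:
    def test_default_cohort_layout(self):
        _, records = generate_cohort(CohortConfig(seed=6))
        subs = records_to_frame(records)
        table = st.cohort_table(subs)
        assert table.loc["n", "CI"].startswith("18 (35.3")
        assert table.loc["n", "NCI"].startswith("33 (64.7")
        assert table.loc["gender", "test"] == "chi_square"
        assert {"age", "mmse", "etiv"} <= set(table.index)

    def test_mmse_lower_in_ci_group(self):
        _, records = generate_cohort(CohortConfig(seed=6))
        subs = records_to_frame(records)
        assert subs.groupby("group")["mmse"].mean()["CI"] < (
            subs.groupby("group")["mmse"].mean()["NCI"]
        )
        res = st.compare_variable(subs["mmse"], subs["group"], variable="mmse")
        assert res.p_value < 0.01

    def test_single_group_rejected(self):
        _, records = generate_cohort(CohortConfig(seed=6))
        subs = records_to_frame(records)
        with pytest.raises(ValueError, match="empty"):
            st.cohort_table(subs[subs["group"] == "CI"])
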