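"""Tests of covariate adjustment, Z-scoring, panels, and rank tests."""

import numpy as np
import pandas as pd
import pytest

from dsimmune import scores
from dsimmune.errors import ConfigurationError

from oracles import bh_oracle, mannwhitney_oracle, wilcoxon_oracle


def _cohort(n=80, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    covs = pd.DataFrame({
        "age": rng.uniform(5, 60, n),
        "sex": rng.choice(["F", "M"], n),
        "batch": rng.choice(["b1", "b2", "b3"], n),
    }, index=ids)
    group = pd.Series(np.where(np.arange(n) < n // 2, "T21", "D21"),
                      index=ids, name="karyotype")
    return covs, group


class TestAdjustment:
    def test_constructed_age_effect_removed_exactly(self):
        # both groups share the same ages, so group is orthogonal to age and
        # the retained group effect cannot reintroduce an age correlation
        ages = np.linspace(5, 60, 40)
        ids = [f"s{i}" for i in range(80)]
        covs = pd.DataFrame({"age": np.concatenate([ages, ages])}, index=ids)
        group = pd.Series(["T21"] * 40 + ["D21"] * 40, index=ids,
                          name="karyotype")
        y = pd.DataFrame({"f1": 2.0 * covs["age"]
                          + 3.0 * (group == "T21")}, index=ids)
        model = scores.fit_covariate_adjustment(y, covs, keep=group)
        adj = scores.apply_adjustment(model, y, covs)
        r = np.corrcoef(adj["f1"], covs["age"])[0, 1]
        assert abs(r) < 1e-6

    def test_group_contrast_preserved_after_adjustment(self):
        covs, group = _cohort(seed=1)
        rng = np.random.default_rng(1)
        y = pd.DataFrame({
            "f1": 0.5 * covs["age"] + 3.0 * (group == "T21")
                  + rng.normal(size=len(covs)),
        })
        model = scores.fit_covariate_adjustment(y, covs[["age"]], keep=group)
        adj = scores.apply_adjustment(model, y, covs[["age"]])

        def contrast(values):
            x = np.column_stack([
                np.ones(len(values)), covs["age"],
                (group == "T21").astype(float)])
            beta, *_ = np.linalg.lstsq(x, values, rcond=None)
            return beta[2]

        assert contrast(adj["f1"].to_numpy()) == pytest.approx(
            contrast(y["f1"].to_numpy()), abs=1e-9)

    def test_batch_only_difference_is_equalized(self):
        ids = ["a", "b"]
        covs = pd.DataFrame({"batch": ["b1", "b2"]}, index=ids)
        # fit on a larger cohort with known batch offset 5
        covs_fit, group = _cohort(seed=2)
        y_fit = pd.DataFrame({
            "f1": 5.0 * (covs_fit["batch"] == "b2")
                  + 1.0 * (group == "T21")}, index=covs_fit.index)
        model = scores.fit_covariate_adjustment(
            y_fit, covs_fit[["batch"]], keep=group)
        y = pd.DataFrame({"f1": [0.0, 5.0]}, index=ids)
        adj = scores.apply_adjustment(model, y, covs)
        assert adj.loc["a", "f1"] == pytest.approx(adj.loc["b", "f1"], abs=1e-9)

    def test_adjustment_is_idempotent(self):
        covs, group = _cohort(seed=3)
        rng = np.random.default_rng(3)
        y = pd.DataFrame({"f1": rng.normal(size=len(covs))
                          + 0.1 * covs["age"]})
        model = scores.fit_covariate_adjustment(y, covs[["age"]], keep=group)
        once = scores.apply_adjustment(model, y, covs[["age"]])
        model2 = scores.fit_covariate_adjustment(once, covs[["age"]],
                                                 keep=group)
        twice = scores.apply_adjustment(model2, once, covs[["age"]])
        pd.testing.assert_frame_equal(once, twice, atol=1e-9, rtol=0)

    def test_collinear_design_rejected_with_names(self):
        covs, group = _cohort(seed=4)
        covs = covs.assign(age_copy=covs["age"])
        y = pd.DataFrame({"f1": np.arange(len(covs), dtype=float)},
                         index=covs.index)
        with pytest.raises(ConfigurationError, match="age_copy"):
            scores.fit_covariate_adjustment(
                y, covs[["age", "age_copy"]], keep=group)

    def test_missing_covariates_listed(self):
        covs, group = _cohort(seed=5)
        y = pd.DataFrame({"f1": np.zeros(len(covs))}, index=covs.index)
        covs.loc[covs.index[0], "age"] = np.nan
        with pytest.raises(ConfigurationError, match="s0"):
            scores.fit_covariate_adjustment(y, covs[["age"]], keep=group)


class TestReferenceZ:
    def test_reference_group_standardized(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(2, 3, size=(50, 4)),
                         index=[f"s{i}" for i in range(50)],
                         columns=list("abcd"))
        ref = [f"s{i}" for i in range(20)]
        z, stats_ = scores.reference_zscores(x, ref)
        assert np.allclose(z.loc[ref].mean(), 0, atol=1e-12)
        assert np.allclose(z.loc[ref].std(ddof=1), 1, atol=1e-12)

    def test_two_sigma_above_reference_scores_two(self):
        x = pd.DataFrame({"f": [0.0, 1.0, 2.0, np.nan]},
                         index=["r1", "r2", "r3", "t"])
        mu, sd = 1.0, 1.0
        x.loc["t", "f"] = mu + 2 * sd
        z, _ = scores.reference_zscores(x, ["r1", "r2", "r3"])
        assert z.loc["t", "f"] == pytest.approx(2.0)

    def test_zero_variance_feature_rejected_with_report(self):
        x = pd.DataFrame({"flat": [1.0, 1.0, 1.0, 5.0],
                          "ok": [0.0, 1.0, 2.0, 5.0]},
                         index=["r1", "r2", "r3", "t"])
        z, stats_ = scores.reference_zscores(x, ["r1", "r2", "r3"])
        assert stats_.rejected == ("flat",)
        assert list(z.columns) == ["ok"]


class TestPanelSelection:
    def test_rule_application_example(self):
        de = pd.DataFrame({
            "gene": ["G1", "G2", "G3", "MX1"],
            "fold_change": [1.6, 1.4, 2.0, 3.0],
            "q": [0.01, 0.01, 0.2, 0.001],
        })
        panel = scores.select_isg_panel(de, ["G1", "G2", "G3", "MX1"])
        assert panel.genes == ("G1",)

    def test_fold_change_exactly_at_threshold_included(self):
        de = pd.DataFrame({"gene": ["G"], "fold_change": [1.5], "q": [0.05]})
        assert scores.select_isg_panel(de, ["G"]).genes == ("G",)

    def test_log2fc_column_accepted(self):
        de = pd.DataFrame({"gene": ["G"], "log2fc": [1.0], "q": [0.01]})
        assert scores.select_isg_panel(de, ["G"]).genes == ("G",)

    def test_empty_candidates_give_empty_panel(self):
        de = pd.DataFrame({"gene": ["G"], "fold_change": [2.0], "q": [0.01]})
        assert scores.select_isg_panel(de, []).genes == ()

    def test_missing_candidate_rejected(self):
        de = pd.DataFrame({"gene": ["G"], "fold_change": [2.0], "q": [0.01]})
        with pytest.raises(ConfigurationError, match="H"):
            scores.select_isg_panel(de, ["G", "H"])


class TestCompositeScore:
    def test_sum_and_breakdown_consistency(self):
        z = pd.DataFrame([[1.0, 2.0, 0.0, -1.0]], index=["s"],
                         columns=list("abcd"))
        table = scores.composite_score(z, list("abcd"))
        assert table.values["s"] == pytest.approx(2.0)
        assert np.allclose(table.values, table.breakdown.sum(axis=1))

    def test_additive_over_disjoint_panels(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(rng.normal(size=(5, 6)),
                         columns=list("abcdef"))
        whole = scores.composite_score(z, list("abcdef")).values
        parts = (scores.composite_score(z, list("abc")).values
                 + scores.composite_score(z, list("def")).values)
        assert np.allclose(whole, parts)

    def test_duplicated_panel_doubles_score(self):
        z = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        once = scores.composite_score(z, ["a", "b"]).values
        twice = scores.composite_score(z, ["a", "b", "a", "b"]).values
        assert np.allclose(twice, 2 * once)

    def test_missing_feature_rejected(self):
        z = pd.DataFrame([[1.0]], columns=["a"])
        with pytest.raises(ConfigurationError):
            scores.composite_score(z, ["a", "zzz"])


class TestCompareGroups:
    def test_identical_groups_null(self):
        res = scores.compare_groups([1, 2, 3], [1, 2, 3])
        assert res["median_difference"] == 0
        assert res["p"] == pytest.approx(1.0)

    def test_separated_groups_match_enumeration(self):
        res = scores.compare_groups([1, 2, 3], [4, 5, 6])
        u, p = mannwhitney_oracle([1, 2, 3], [4, 5, 6])
        assert res["U"] == u == 0
        assert res["p"] == pytest.approx(p)
        assert res["median_difference"] == 3

    def test_shift_invariance(self):
        a, b = [1.0, 2.5, 3.0, 7.0], [2.0, 4.0, 9.0]
        r1 = scores.compare_groups(a, b)
        r2 = scores.compare_groups([x + 11 for x in a], [x + 11 for x in b])
        assert r1["U"] == r2["U"] and r1["p"] == pytest.approx(r2["p"])

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = list(rng.permutation(20)[:5].astype(float))
        y = list(rng.permutation(40)[20:25].astype(float) + 0.5)
        res = scores.compare_groups(x, y)
        _, p = mannwhitney_oracle(x, y)
        assert res["p"] == pytest.approx(p, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            scores.compare_groups([], [1.0])


class TestComparePaired:
    def test_five_negative_differences_exact_p(self):
        res = scores.paired_wilcoxon([5, 6, 7, 8, 9], [4, 4, 4, 4, 4])
        assert res["p"] == pytest.approx(2 * (1 / 2 ** 5))

    def test_antisymmetric_differences_give_p_one(self):
        before = [0.0, 0.0, 0.0, 0.0]
        after = [1.0, -1.0, 2.0, -2.0]
        res = scores.paired_wilcoxon(before, after)
        assert res["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_differences_match_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.permutation(30)[:8].astype(float) + 0.5
        d *= rng.choice([-1, 1], size=8)
        res = scores.paired_wilcoxon(np.zeros(8), d)
        _, p = wilcoxon_oracle(d)
        assert res["p"] == pytest.approx(p, rel=1e-9)

    def test_all_zero_differences_warn_and_p_one(self):
        with pytest.warns(UserWarning):
            res = scores.paired_wilcoxon([1.0, 2.0], [1.0, 2.0])
        assert res["p"] == 1.0

    def test_family_bh_matches_direct_stepup(self):
        rng = np.random.default_rng(0)
        pairs = {}
        for i in range(6):
            base = rng.normal(size=9)
            pairs[f"e{i}"] = (base, base + rng.normal(-0.5, 1.0, 9))
        out = scores.compare_paired(pairs)
        assert np.allclose(out["q"], bh_oracle(out["p"]))
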