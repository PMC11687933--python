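"""Tests of MAD normalization, positivity calling, and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsimmune import autoab
from dsimmune.errors import (AssayInvalidError, ConfigurationError,
                             DegenerateSampleError)

from oracles import fisher_oracle


def _mfi(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestMadTransform:
    def test_hand_computed_example(self):
        # median 3, raw MAD 1 -> (x - 3) / 1
        mfi = _mfi({"s1": [1, 2, 3, 4, 100]})
        out = autoab.mad_transform(mfi)
        assert np.allclose(out.values.loc["s1"], [-2, -1, 0, 1, 97])

    def test_constant_sample_rejected_by_name(self):
        mfi = _mfi({"good": [1, 2, 3, 9], "flat": [5, 5, 5, 5]})
        with pytest.raises(DegenerateSampleError, match="flat"):
            autoab.mad_transform(mfi)

    def test_too_few_finite_values_rejected(self):
        mfi = _mfi({"s1": [1.0, np.nan, np.nan, np.nan]})
        with pytest.raises(DegenerateSampleError):
            autoab.mad_transform(mfi)

    @settings(deadline=None, max_examples=50)
    @given(
        values=st.lists(st.floats(min_value=-100, max_value=100), min_size=5,
                        max_size=20),
        shift=st.floats(min_value=-1e3, max_value=1e3),
        scale=st.floats(min_value=1e-2, max_value=1e3),
    )
    def test_affine_invariance(self, values, shift, scale):
        """(x - med) / MAD is invariant to x -> a + b*x with b > 0."""
        base = _mfi({"s": values})
        med = np.median(values)
        if np.median(np.abs(np.array(values) - med)) < 1e-6:
            return  # degenerate spread is rejected, not transformed
        raw = autoab.mad_transform(base).values
        moved = autoab.mad_transform(base * scale + shift).values
        assert np.allclose(raw, moved, rtol=1e-6, atol=1e-6)


class TestCallPositivity:
    @pytest.fixture()
    def mad(self):
        # controls carry values 0..9 on antigen "A"; test sample 8.5
        data = {f"c{i}": [float(i), 0.0 + i, 1.0] for i in range(10)}
        data["t1"] = [8.5, 0.0, 1.0]
        df = pd.DataFrame.from_dict(
            data, orient="index", columns=["A", "B", "C"])
        return autoab.MadMatrix(values=df,
                                sample_median=pd.Series(0, index=df.index),
                                sample_mad=pd.Series(1, index=df.index))

    def test_linear_interpolation_percentile_convention(self, mad):
        """Type-7 90th percentile of 0..9 is 8.1; 8.5 exceeds it."""
        table = autoab.call_positivity(mad, [f"c{i}" for i in range(10)])
        assert table.thresholds["A"] == pytest.approx(8.1)
        assert bool(table.calls.loc["t1", "A"])

    def test_value_equal_to_threshold_is_negative(self, mad):
        table = autoab.call_positivity(mad, [f"c{i}" for i in range(10)])
        mad2 = autoab.MadMatrix(
            values=mad.values.assign(A=lambda d: d["A"].where(
                d.index != "t1", table.thresholds["A"])),
            sample_median=mad.sample_median, sample_mad=mad.sample_mad)
        table2 = autoab.call_positivity(mad2, [f"c{i}" for i in range(10)])
        assert not bool(table2.calls.loc["t1", "A"])

    def test_all_below_control_minimum_gives_zero_positives(self, mad):
        low = autoab.MadMatrix(values=mad.values - 100,
                               sample_median=mad.sample_median,
                               sample_mad=mad.sample_mad)
        low = autoab.MadMatrix(
            values=pd.concat([mad.values.iloc[:10], low.values.iloc[10:]]),
            sample_median=mad.sample_median, sample_mad=mad.sample_mad)
        table = autoab.call_positivity(low, [f"c{i}" for i in range(10)])
        assert not table.calls.loc["t1"].any()

    def test_control_positive_fraction_bounded(self, mad):
        """At most 1 - percentile (+1/n) of controls can exceed their own
        threshold."""
        table = autoab.call_positivity(mad, [f"c{i}" for i in range(10)])
        ctrl_frac = table.calls.loc[[f"c{i}" for i in range(10)]].mean()
        assert (ctrl_frac <= 0.1 + 1 / 10 + 1e-12).all()

    def test_too_few_controls_rejected(self, mad):
        with pytest.raises(ConfigurationError):
            autoab.call_positivity(mad, ["c1", "c2"])


class TestFilterDetected:
    def _table(self, counts):
        n = 40
        calls = pd.DataFrame(False, index=[f"s{i}" for i in range(n)],
                             columns=list(counts))
        for antigen, k in counts.items():
            calls.iloc[:k, calls.columns.get_loc(antigen)] = True
        thr = pd.Series(0.0, index=list(counts))
        return autoab.PositivityTable(calls=calls, thresholds=thr)

    def test_boundary_at_min_samples(self):
        table = self._table({"seventeen": 17, "eighteen": 18})
        out = autoab.filter_detected(table, min_samples=18)
        assert list(out.calls.columns) == ["eighteen"]
        assert out.removed_antigens == ("seventeen",)

    def test_zero_threshold_is_identity(self):
        table = self._table({"a": 0, "b": 5})
        out = autoab.filter_detected(table, min_samples=0)
        assert list(out.calls.columns) == ["a", "b"]


class TestFisherEnrichment:
    def test_example_table_against_enumeration_oracle(self):
        orr, p = autoab.fisher_test(30, 90, 3, 57)
        assert orr == pytest.approx((30 * 57) / (90 * 3))
        assert orr == pytest.approx(6.333, abs=1e-3)
        assert p == pytest.approx(fisher_oracle(30, 90, 3, 57), rel=1e-9)

    def test_null_table_gives_or_one_p_one(self):
        orr, p = autoab.fisher_test(10, 30, 10, 30)
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_q_values_dominate_p_and_bh_is_monotone(self):
        rng = np.random.default_rng(0)
        calls = pd.DataFrame(rng.random((60, 12)) < 0.3,
                             index=[f"s{i}" for i in range(60)],
                             columns=[f"a{j}" for j in range(12)])
        groups = pd.Series(["T21"] * 30 + ["D21"] * 30, index=calls.index)
        table = autoab.PositivityTable(
            calls=calls, thresholds=pd.Series(0.0, index=calls.columns))
        res = autoab.fisher_enrichment(table, groups)
        assert (res["q"] >= res["p"] - 1e-12).all()
        s = res.sort_values("p")
        assert s["q"].is_monotonic_increasing

    def test_empty_group_rejected(self):
        calls = pd.DataFrame([[True], [False]], index=["x", "y"],
                             columns=["a"])
        table = autoab.PositivityTable(
            calls=calls, thresholds=pd.Series([0.0], index=["a"]))
        groups = pd.Series(["T21", "T21"], index=calls.index)
        with pytest.raises(ConfigurationError):
            autoab.fisher_enrichment(table, groups)


class TestConditionAssociation:
    def _setup(self, n_cases):
        n = 40
        ids = [f"s{i}" for i in range(n)]
        participants = pd.DataFrame({
            "sample_id": ids, "karyotype": "T21",
            "cond": [i < n_cases for i in range(n)],
        })
        calls = pd.DataFrame({"a1": [i < n_cases for i in range(n)]},
                             index=ids)
        table = autoab.PositivityTable(
            calls=calls, thresholds=pd.Series(0.0, index=["a1"]))
        return table, participants

    def test_condition_below_min_cases_skipped(self):
        table, participants = self._setup(4)
        res, skipped = autoab.condition_association(table, participants,
                                                    ["cond"])
        assert res.empty
        assert skipped == [("cond", 4)]

    def test_condition_at_min_cases_tested(self):
        table, participants = self._setup(5)
        res, skipped = autoab.condition_association(table, participants,
                                                    ["cond"])
        assert len(res) == 1 and not skipped

    def test_case_only_positivity_matches_oracle(self):
        table, participants = self._setup(6)
        res, _ = autoab.condition_association(table, participants, ["cond"])
        row = res.iloc[0]
        assert row["odds_ratio"] > 1
        assert row["p"] == pytest.approx(
            fisher_oracle(int(row.a), int(row.b), int(row.c), int(row.d)),
            rel=1e-9)


class TestBurden:
    @pytest.fixture()
    def table(self):
        calls = pd.DataFrame(
            [[True, True, True, False], [False, False, False, False],
             [True, False, False, False]],
            index=["p1", "p2", "p3"], columns=list("abcd"))
        return autoab.PositivityTable(
            calls=calls, thresholds=pd.Series(0.0, index=list("abcd")))

    def test_counts_and_complement(self, table):
        burden, at_least = autoab.positivity_burden(table, ["a", "b", "c"])
        assert burden["p1"] == 3 and burden["p2"] == 0 and burden["p3"] == 1
        assert at_least[1] == pytest.approx(1 - (burden == 0).mean())

    def test_empty_subset_gives_zero_burden(self, table):
        burden, at_least = autoab.positivity_burden(table, [])
        assert (burden == 0).all() and len(at_least) == 0

    def test_unknown_antigen_rejected(self, table):
        with pytest.raises(ConfigurationError):
            autoab.positivity_burden(table, ["nope"])

    def test_burden_invariant_under_antigen_relabeling(self, table):
        b1, _ = autoab.positivity_burden(table, ["a", "b", "c", "d"])
        shuffled = autoab.PositivityTable(
            calls=table.calls[["d", "b", "a", "c"]],
            thresholds=table.thresholds)
        b2, _ = autoab.positivity_burden(shuffled, ["d", "b", "a", "c"])
        assert b1.equals(b2)


class TestScalarAssays:
    def test_tpo_index_arithmetic(self):
        res = autoab.tpo_index(50, 10, 90, control_values=[0.1, 0.2, 0.3])
        assert res.index == pytest.approx(0.5)

    def test_tpo_sample_equal_to_negative_gives_zero(self):
        res = autoab.tpo_index(10, 10, 90, control_values=[0.1, 0.2, 0.3])
        assert res.index == pytest.approx(0.0)

    def test_tpo_threshold_uses_type7_percentile(self):
        controls = [i / 10 for i in range(10)]  # 0.0 .. 0.9
        res = autoab.tpo_index(0.89 * 80 + 10, 10, 90, controls)
        assert res.threshold == pytest.approx(0.855)
        assert res.index == pytest.approx(0.88, abs=1e-9) or res.index > 0.855
        assert res.call

    def test_tpo_invalid_controls_rejected(self):
        with pytest.raises(AssayInvalidError):
            autoab.tpo_index(50, 90, 90, control_values=[0.1])

    @pytest.mark.parametrize("ratio,expected", [
        (2.1, True), (2.09, False), (1.0, False),
    ])
    def test_ana_ratio_boundary(self, ratio, expected):
        res = autoab.ana_call(ratio * 0.5, 0.5)
        assert res.index == pytest.approx(ratio)
        assert res.call is expected

    def test_ana_nonpositive_negative_control_rejected(self):
        with pytest.raises(AssayInvalidError):
            autoab.ana_call(1.0, 0.0)
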