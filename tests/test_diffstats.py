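import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evtrf import (
    FragmentTable,
    abundance_filter,
    benjamini_hochberg,
    cumulative_share,
    differential_expression,
    mann_whitney_u,
    rpm_normalize,
    wilcoxon_signed_rank,
)

from _oracles import bh_step_up, mw_exact_p_two_sided, wilcoxon_exact_p


def make_table(counts: dict) -> FragmentTable:
    return FragmentTable(pd.DataFrame(counts).astype(np.int64))


class TestRpmNormalize:
    def test_arithmetic(self):
        table = make_table({"s": {"f1": 10, "f2": 990}})
        classes = pd.Series({"f1": "tRNA", "f2": "tRNA"})
        rpm = rpm_normalize(table, classes)
        assert rpm.loc["f1", "s"] == pytest.approx(10_000)

    def test_sole_fragment_of_class_is_one_million(self):
        table = make_table({"s": {"f1": 7, "f2": 100}})
        classes = pd.Series({"f1": "miRNA", "f2": "tRNA"})
        rpm = rpm_normalize(table, classes)
        assert rpm.loc["f1", "s"] == pytest.approx(1e6)

    def test_absent_class_is_missing_not_zero(self):
        table = make_table({"s1": {"f1": 0, "f2": 100}, "s2": {"f1": 5, "f2": 100}})
        classes = pd.Series({"f1": "miRNA", "f2": "tRNA"})
        rpm = rpm_normalize(table, classes)
        assert np.isnan(rpm.loc["f1", "s1"])
        assert rpm.loc["f1", "s2"] == pytest.approx(1e6)

    def test_unmapped_carries_no_rpm(self):
        table = make_table({"s": {"f1": 10, "f2": 10}})
        classes = pd.Series({"f1": "tRNA", "f2": "unmapped"})
        rpm = rpm_normalize(table, classes)
        assert "f2" not in rpm.index

    def test_class_sums_conserved(self, rng):
        frags = [f"f{i}" for i in range(50)]
        classes = pd.Series(
            rng.choice(["tRNA", "miRNA", "rRNA"], size=50), index=frags
        )
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(50, 4)),
            index=frags,
            columns=list("abcd"),
        )
        rpm = rpm_normalize(FragmentTable(counts), classes)
        sums = rpm.groupby(classes).sum()
        present = counts.groupby(classes).sum() > 0
        assert np.allclose(sums.to_numpy()[present.to_numpy()], 1e6, rtol=1e-6)


class TestAbundanceFilter:
    def test_boundary_is_strict(self):
        rpm = pd.DataFrame({"m1": [100.0], "m2": [99.0]}, index=["f"])
        assert len(abundance_filter(rpm, ["m1", "m2"], 100.0)) == 0

    def test_single_sample_above_keeps(self):
        rpm = pd.DataFrame({"m1": [100.5], "m2": [0.0]}, index=["f"])
        assert list(abundance_filter(rpm, ["m1", "m2"], 100.0)) == ["f"]

    def test_all_zero_excluded(self):
        rpm = pd.DataFrame({"m1": [0.0], "m2": [0.0]}, index=["f"])
        assert len(abundance_filter(rpm, ["m1", "m2"])) == 0

    def test_empty_subset_is_error(self):
        rpm = pd.DataFrame({"m1": [5.0]}, index=["f"])
        with pytest.raises(ValueError):
            abundance_filter(rpm, [])


class TestMannWhitney:
    def test_identical_constant_groups(self):
        _, p = mann_whitney_u([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == pytest.approx(1.0)

    def test_complete_separation_6v8(self):
        a = [10.0 + i for i in range(8)]
        b = [float(i) for i in range(6)]
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(2 / 3003)

    def test_small_example_enumeration(self):
        _, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_matches_enumeration_on_random_data(self, rng):
        for _ in range(25):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(mw_exact_p_two_sided(a, b))


class TestWilcoxon:
    def test_all_positive_one_tailed(self):
        x = [2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 1.5, 2.0, 2.5, 3.0]
        _, p = wilcoxon_signed_rank(x, y, alternative="greater")
        assert p == pytest.approx(1 / 32)

    def test_identical_pairs_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_antisymmetric_two_sided(self):
        x = [1.0, -1.0, 2.0, -2.0]
        _, p = wilcoxon_signed_rank(x, [0.0] * 4, alternative="two-sided")
        assert p == pytest.approx(1.0)

    def test_matches_sign_pattern_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            d = rng.normal(size=n)
            _, p = wilcoxon_signed_rank(d, np.zeros(n), alternative="greater")
            assert p == pytest.approx(wilcoxon_exact_p(d, "greater"))


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_monotone_and_dominates_p(self, p):
        q = benjamini_hochberg(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_independent_step_up(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 60)))
            assert np.allclose(benjamini_hochberg(p), bh_step_up(p))


class TestDifferentialExpression:
    def _rpm(self, rng, n_frag=40, n_case=8, n_control=6, de=()):
        frags = [f"f{i}" for i in range(n_frag)]
        samples = [f"case_{i}" for i in range(n_case)] + [
            f"ctrl_{i}" for i in range(n_control)
        ]
        groups = pd.Series(
            ["case"] * n_case + ["control"] * n_control, index=samples
        )
        base = rng.uniform(100, 5000, size=n_frag)
        data = rng.lognormal(0, 0.2, size=(n_frag, len(samples))) * base[:, None]
        rpm = pd.DataFrame(data, index=frags, columns=samples)
        for f, fold in de:
            rpm.loc[f, groups == "case"] *= fold
        return rpm, groups

    def test_fold_change_pseudocount_arithmetic(self):
        rpm = pd.DataFrame(
            {
                "c1": [140.0], "c2": [141.0], "c3": [139.0],
                "n1": [100.0], "n2": [101.0], "n3": [99.0],
            },
            index=["f"],
        )
        groups = pd.Series(
            ["case"] * 3 + ["control"] * 3, index=rpm.columns
        )
        de = differential_expression(rpm, groups, threshold=50.0)
        assert de.loc["f", "fold_change"] == pytest.approx(141 / 101)

    def test_strong_effect_detected(self, rng):
        rpm, groups = self._rpm(rng, de=[("f0", 10.0), ("f1", 10.0)])
        de = differential_expression(rpm, groups)
        assert de.loc["f0", "significant"] and de.loc["f1", "significant"]
        assert de["significant"].sum() <= 4

    def test_no_fragment_passes_filter(self, rng):
        rpm, groups = self._rpm(rng)
        de = differential_expression(rpm, groups, threshold=1e9)
        assert len(de) == 0

    def test_q_dominates_p_and_significance_definition(self, rng):
        rpm, groups = self._rpm(rng, de=[("f0", 8.0)])
        de = differential_expression(rpm, groups, alpha=0.05)
        assert np.all(de["q"] >= de["p"] - 1e-12)
        assert (de["significant"] == (de["q"] < 0.05)).all()


class TestCumulativeShare:
    def _de(self, frags):
        return pd.DataFrame(
            {"significant": [True] * len(frags)},
            index=pd.Index(frags, name="fragment"),
        )

    def test_equal_counts(self):
        frags = [f"f{i}" for i in range(10)]
        rpm = pd.DataFrame({"c1": [10.0] * 10}, index=frags)
        assert cumulative_share(self._de(frags), rpm, ["c1"], 1) == pytest.approx(0.1)

    def test_k_equals_all(self):
        frags = ["a", "b", "c"]
        rpm = pd.DataFrame({"c1": [5.0, 1.0, 4.0]}, index=frags)
        assert cumulative_share(self._de(frags), rpm, ["c1"], 3) == pytest.approx(1.0)

    def test_top_two_of_three(self):
        frags = ["a", "b", "c"]
        rpm = pd.DataFrame({"c1": [50.0, 30.0, 20.0]}, index=frags)
        assert cumulative_share(self._de(frags), rpm, ["c1"], 2) == pytest.approx(0.8)

    def test_empty_table_error(self):
        de = pd.DataFrame({"significant": []}, index=pd.Index([], name="fragment"))
        rpm = pd.DataFrame({"c1": []})
        with pytest.raises(ValueError):
            cumulative_share(de, rpm, ["c1"], 1)
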