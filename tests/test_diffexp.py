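import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomirdiff.diffexp import (
    ComparisonPair,
    _bh_adjust,
    audic_claverie_p,
    conditional_pmf,
    enumerate_comparisons,
    log2_fold_change,
    nb_model_test,
    rollup,
    run_differential,
    size_factors,
)
from isomirdiff.synth import simulate_count_matrix


class TestAudicClaverie:
    def test_closed_case_zero_zero_equal_libraries(self):
        # p(k|0) = 2^-(k+1) when N1=N2: the lower tail at y=0 is exactly 1/2
        assert audic_claverie_p(0, 0, 10**6, 10**6) == 0.5

    def test_extreme_imbalance_is_tiny(self):
        assert audic_claverie_p(0, 100, 10**6, 10**6) < 1e-20

    def test_monotone_in_y_divergence(self):
        n = 10**6
        assert audic_claverie_p(10, 30, n, n) < audic_claverie_p(10, 15, n, n)

    def test_symmetric_counts_give_half(self):
        # equal counts in equal libraries: both tails exceed 1/2
        p = audic_claverie_p(25, 25, 5 * 10**5, 5 * 10**5)
        assert p == pytest.approx(0.5, abs=1e-9)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        x=st.integers(min_value=0, max_value=300),
        y=st.integers(min_value=0, max_value=300),
        ratio=st.sampled_from([0.2, 0.5, 1.0, 2.0, 5.0]),
        c=st.sampled_from([0.5, 1.0, 3.0, 17.0]),
    )
    def test_scale_invariance(self, x, y, ratio, c):
        """The statistic depends on the libraries only through N2/N1."""
        n1 = 1_000_000
        p1 = audic_claverie_p(x, y, n1, ratio * n1)
        p2 = audic_claverie_p(x, y, c * n1, c * ratio * n1)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_doubled_variant_caps_at_one(self):
        raw = audic_claverie_p(0, 0, 10**6, 10**6)
        doubled = audic_claverie_p(0, 0, 10**6, 10**6, double_tails=True)
        assert doubled == min(1.0, 2 * raw) == 1.0

    def test_upper_tail_nonincreasing_in_y(self):
        # for fixed x the upper tail P(K >= y) shrinks as y grows
        n = 10**6
        ps = [audic_claverie_p(5, y, n, n) for y in range(6, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            audic_claverie_p(1, 1, 0, 10)
        with pytest.raises(ValueError):
            audic_claverie_p(-1, 1, 10, 10)

    def test_result_in_unit_interval(self):
        for x, y in [(0, 0), (1000, 3), (3, 1000), (500, 500)]:
            p = audic_claverie_p(x, y, 2 * 10**5, 10**5)
            assert 0 < p <= 1


class TestConditionalPmf:
    @pytest.mark.parametrize("x", [0, 1, 5, 50, 500])
    @pytest.mark.parametrize("ratio", [0.1, 1.0, 10.0])
    def test_normalizes_to_one(self, x, ratio):
        pmf = conditional_pmf(x, 10**6, ratio * 10**6)
        assert abs(math.fsum(pmf) - 1.0) < 1e-12

    def test_matches_scipy_negative_binomial(self):
        """Cross-check: p(k|x) is the NB(x+1, N1/(N1+N2)) pmf in k."""
        from scipy import stats

        x, n1, n2 = 7, 10**6, 3 * 10**6
        pmf = conditional_pmf(x, n1, n2)
        expected = stats.nbinom.pmf(np.arange(len(pmf)), x + 1, n1 / (n1 + n2))
        np.testing.assert_allclose(pmf, expected, rtol=1e-9)


class TestLog2FoldChange:
    def test_identical_normalized_abundance_is_zero(self):
        assert log2_fold_change(10, 10, 10**6, 10**6, pseudocount=0.0) == 0.0

    def test_doubling_without_pseudocount(self):
        assert log2_fold_change(10, 20, 10**6, 10**6, pseudocount=0.0) == 1.0

    def test_zero_count_with_pseudocount(self):
        got = log2_fold_change(0, 8, 10**6, 10**6, pseudocount=0.5)
        assert got == pytest.approx(math.log2(8.5 / 0.5))

    def test_zero_count_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(0, 8, 10**6, 10**6, pseudocount=0.0)

    def test_library_normalization_direction(self):
        # same counts, bigger B library -> relatively lower in B
        assert log2_fold_change(10, 10, 10**6, 2 * 10**6) < 0


def _design(rows):
    return pd.DataFrame(rows, columns=["sample", "condition", "experiment", "is_control"])


class TestEnumerateComparisons:
    def test_single_stress_experiment(self):
        design = _design(
            [("s1", "control", "e1", 1), ("s2", "cold", "e1", 0)]
        )
        pairs = enumerate_comparisons(design)
        assert [(p.condition_a, p.condition_b) for p in pairs] == [("control", "cold")]

    def test_multi_stress_ladder(self):
        design = _design(
            [("s0", "control", "e1", 1)]
            + [(f"s{i}", f"S{i}", "e1", 0) for i in (1, 2, 3)]
        )
        pairs = enumerate_comparisons(design)
        assert [(p.condition_a, p.condition_b) for p in pairs] == [
            ("control", "S1"),
            ("control", "S2"),
            ("control", "S3"),
            ("S1", "S2"),
            ("S2", "S3"),
        ]

    def test_pairs_never_cross_experiments(self):
        design = _design(
            [
                ("a1", "control", "e1", 1),
                ("a2", "cold", "e1", 0),
                ("b1", "control", "e2", 1),
                ("b2", "heat", "e2", 0),
            ]
        )
        pairs = enumerate_comparisons(design)
        assert len(pairs) == 2
        assert all(
            {p.condition_a, p.condition_b} != {"cold", "heat"} for p in pairs
        )

    def test_experiment_without_control_is_error(self):
        design = _design([("s1", "cold", "e1", 0), ("s2", "heat", "e1", 0)])
        with pytest.raises(ValueError, match="control"):
            enumerate_comparisons(design)

    def test_single_condition_experiment_is_error(self):
        design = _design([("s1", "control", "e1", 1)])
        with pytest.raises(ValueError, match="stress"):
            enumerate_comparisons(design)

    def test_totals_pooled_per_condition(self):
        design = _design(
            [("s1", "control", "e1", 1), ("s2", "control", "e1", 1), ("s3", "cold", "e1", 0)]
        )
        (pair,) = enumerate_comparisons(design, {"s1": 100, "s2": 150, "s3": 300})
        assert (pair.N1, pair.N2) == (250, 300)


class TestNbModelTest:
    def test_identical_count_vectors_give_p_one(self):
        counts = np.array([[10, 12, 9]])
        res = nb_model_test(counts, counts, sf=np.ones(6))
        assert res["p_model"].iloc[0] == 1.0

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            nb_model_test(np.array([[5]]), np.array([[7, 8]]))

    def test_all_zero_isomir_untestable(self):
        a = np.array([[0, 0, 0], [5, 6, 7]])
        b = np.array([[0, 0, 0], [5, 6, 7]])
        res = nb_model_test(a, b, sf=np.ones(6))
        assert np.isnan(res["p_model"].iloc[0])
        assert res["p_model"].iloc[1] == 1.0

    def test_null_calibration_in_band(self):
        ca, cb, _, _ = simulate_count_matrix(
            n_null=2000, n_de=0, dispersion=0.1, mean=100.0, reps=(3, 3), seed=11
        )
        res = nb_model_test(ca, cb)
        rate = np.nanmean(res["p_model"].to_numpy() <= 0.05)
        assert 0.03 <= rate <= 0.07

    def test_power_on_planted_fourfold(self):
        ca, cb, is_de, _ = simulate_count_matrix(
            n_null=1800, n_de=200, fold_change=4.0, dispersion=0.1,
            mean=100.0, reps=(3, 3), seed=1,
        )
        res = nb_model_test(ca, cb)
        power = (res["p_model"].to_numpy()[is_de] <= 0.05).mean()
        assert power >= 0.85

    def test_size_factors_recover_depth_ratio(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(200, size=(500, 1))
        counts = np.hstack([base, base * 2, base])  # middle library 2x deeper
        sf = size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=0.05)


class TestBHAdjust:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200) ** 2
        ours = _bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_nan_passthrough(self):
        p = np.array([0.01, np.nan, 0.5])
        adj = _bh_adjust(p)
        assert np.isnan(adj[1]) and np.isfinite(adj[0])


class TestRunDifferential:
    def _inputs(self):
        counts = pd.DataFrame(
            {
                "c1": [10, 0, 100, 0],
                "c2": [12, 0, 110, 0],
                "t1": [30, 0, 20, 0],
                "t2": [28, 0, 25, 0],
            },
            index=["i1", "i2", "i3", "i4"],
        )
        design = pd.DataFrame(
            {
                "sample": ["c1", "c2", "t1", "t2"],
                "condition": ["control", "control", "salt", "salt"],
                "experiment": ["e1"] * 4,
                "is_control": [1, 1, 0, 0],
            }
        )
        totals = {"c1": 50_000, "c2": 52_000, "t1": 48_000, "t2": 51_000}
        return counts, design, totals

    def test_all_zero_isomirs_excluded(self):
        counts, design, totals = self._inputs()
        (table,) = run_differential(counts, design, totals).values()
        assert set(table["isomir_id"]) == {"i1", "i3"}

    def test_pooled_counts_and_totals(self):
        counts, design, totals = self._inputs()
        results = run_differential(counts, design, totals)
        (pair,) = results.keys()
        table = results[pair]
        assert (pair.N1, pair.N2) == (102_000, 99_000)
        row = table.set_index("isomir_id").loc["i1"]
        assert (row["x"], row["y"]) == (22, 58)

    def test_intersection_never_exceeds_either_method(self):
        counts, design, totals = self._inputs()
        results = run_differential(counts, design, totals)
        roll = rollup(results)
        assert (roll["n_intersection"] <= roll[["n_mapping", "n_model"]].min(axis=1)).all()
        for table in results.values():
            assert (
                table["in_intersection"] <= (table["significant_mapping"] & table["significant_model"])
            ).all()

    def test_unknown_sample_in_design_is_error(self):
        counts, design, totals = self._inputs()
        design.loc[0, "sample"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            run_differential(counts, design, totals)

    def test_single_replicate_leaves_model_p_absent(self):
        counts, design, totals = self._inputs()
        counts = counts[["c1", "t1"]]
        design = design[design["sample"].isin(["c1", "t1"])].reset_index(drop=True)
        (table,) = run_differential(counts, design, totals).values()
        assert table["p_model"].isna().all()
        assert not table["significant_model"].any()


def test_comparison_pair_rejects_self_comparison():
    with pytest.raises(ValueError):
        ComparisonPair("e1", "cold", "cold")
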