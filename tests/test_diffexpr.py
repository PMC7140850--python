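import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mediseq.diffexpr import (
    PairedDesign,
    call_degs,
    differential_table,
    fdr_adjust,
    heatmap_matrix,
    paired_test,
    quantile_normalize,
    regularized_log2fc,
    volcano_table,
)
from mediseq.quantify import ExpressionMatrix


def brute_force_bh(p):
    """Independent step-up BH: q_(i) = min_{j>=i} m p_(j)/j, straight
    from the definition with explicit loops."""
    order = sorted(range(len(p)), key=lambda i: p[i])
    m = len(p)
    q = [None] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def matrix_of(columns):
    data = {f"s{j + 1}": col for j, col in enumerate(columns)}
    n = len(columns[0])
    return ExpressionMatrix(
        pd.DataFrame(data, index=pd.Index([f"g{i}" for i in range(n)],
                                          name="gene_id"))
    )


class TestQuantileNormalize:
    def test_hand_oracle_two_columns(self):
        # sort each column, average across columns per rank ->
        # reference [1.5, 3.5, 5.5], map back by rank
        m = matrix_of([[5, 3, 1], [4, 2, 6]])
        out = quantile_normalize(m).values
        assert out["s1"].tolist() == [5.5, 3.5, 1.5]
        assert out["s2"].tolist() == [3.5, 1.5, 5.5]

    def test_identical_columns_fixed_point(self):
        m = matrix_of([[3, 1, 2], [3, 1, 2]])
        out = quantile_normalize(m).values
        assert out["s1"].tolist() == [3, 1, 2]
        assert out["s2"].tolist() == [3, 1, 2]

    def test_permuted_columns_share_multiset(self):
        m = matrix_of([[1, 5, 9, 7], [9, 7, 1, 5]])
        out = quantile_normalize(m).values
        assert sorted(out["s1"]) == sorted(out["s2"])
        # the permutation relation is preserved
        assert out["s1"].tolist() == [out["s2"].iloc[2], out["s2"].iloc[3],
                                      out["s2"].iloc[0], out["s2"].iloc[1]]

    def test_ties_get_mean_of_reference_values(self):
        m = matrix_of([[2, 2, 10], [1, 3, 9]])
        out = quantile_normalize(m).values
        # column 1 ties at ranks 1,2 -> both get mean(ref[0], ref[1])
        assert out["s1"].iloc[0] == out["s1"].iloc[1]

    def test_state_transition_and_errors(self):
        m = matrix_of([[1, 2], [3, 4]])
        norm = quantile_normalize(m)
        assert norm.normalization_state == "quantile"
        with pytest.raises(ValueError, match="already normalized"):
            quantile_normalize(norm)
        single = matrix_of([[1, 2]])
        with pytest.raises(ValueError, match=">= 2 samples"):
            quantile_normalize(single)

    @given(
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=2, max_value=12),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_columns_share_sorted_values_and_means(self, ncols, nrows, seed):
        rng = np.random.default_rng(seed)
        # continuous draws: the exact shared-multiset invariant holds in
        # the absence of ties (tie-averaging intentionally breaks it)
        m = matrix_of([rng.uniform(0, 50, nrows).tolist() for _ in range(ncols)])
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, ncols):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)
        np.testing.assert_allclose(
            out.mean(axis=0), np.full(ncols, out.mean()), atol=1e-9
        )


class TestRegularizedLog2fc:
    def test_fifteen_vs_five_with_r_five(self):
        assert regularized_log2fc(15, 5, 5) == pytest.approx(1.0)

    def test_zero_zero_is_zero(self):
        assert regularized_log2fc(0, 0, 7) == 0.0

    def test_damping_versus_unregularized(self):
        assert regularized_log2fc(5, 0, 5) == pytest.approx(1.0)
        with np.errstate(divide="ignore"):
            assert np.isinf(np.log2(5 / np.float64(0.0)))

    def test_antisymmetry(self):
        assert regularized_log2fc(12, 3, 5) == pytest.approx(
            -regularized_log2fc(3, 12, 5)
        )

    def test_invalid_regularizer(self):
        with pytest.raises(ValueError):
            regularized_log2fc(1, 2, 0)

    @given(
        st.floats(min_value=0, max_value=5),
        st.floats(min_value=0, max_value=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_low_expression_capped_at_one(self, a, b):
        """For a, b <= 5 and r = 5 the apparent |log2 FC| never exceeds 1."""
        assert abs(regularized_log2fc(a, b, 5)) <= 1.0 + 1e-12

    @given(
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0.5, max_value=50),
        st.floats(min_value=0.1, max_value=50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing_in_r(self, a, b, r, dr):
        if abs(a - b) < 1e-9:
            return
        assert abs(regularized_log2fc(a, b, r + dr)) <= abs(
            regularized_log2fc(a, b, r)
        ) + 1e-12


class TestPairedTest:
    def test_differences_one_two_three(self):
        # oracle: mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.4641, df 2
        p = paired_test(np.array([1.0, 2.0, 3.0]))
        assert p == pytest.approx(2 * stats.t.sf(3.4641016, 2), rel=1e-6)
        assert p == pytest.approx(0.074180, abs=1e-5)

    def test_near_null_differences(self):
        p = paired_test(np.array([0.0, 0.001, -0.001]))
        assert p > 0.95

    def test_degenerate_differences_are_nan(self):
        assert np.isnan(paired_test(np.array([5.0, 5.0, 5.0])))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_test(np.array([1.0]))

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50), min_size=3, max_size=8
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_ttest_rel(self, diffs):
        d = np.array(diffs)
        if d.std(ddof=1) == 0:
            assert np.isnan(paired_test(d))
            return
        expected = stats.ttest_rel(d, np.zeros_like(d)).pvalue
        assert paired_test(d) == pytest.approx(expected, rel=1e-9)


class TestFdrAdjust:
    def test_hand_oracle(self):
        # m=4: q4=0.5; q3=min(0.5, 4*0.03/3)=0.04; q2=q1=0.04
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_single_p_identity(self):
        np.testing.assert_allclose(fdr_adjust([0.5]), [0.5])

    def test_all_equal_p(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_empty(self):
        assert fdr_adjust([]).size == 0

    def test_nan_excluded_from_m(self):
        q = fdr_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_thousand_random_vectors_match_brute_force(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 12)).tolist()
            np.testing.assert_allclose(
                fdr_adjust(p), brute_force_bh(p), atol=1e-12
            )

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(30)
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)


class TestPairedDesign:
    def test_reused_sample_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            PairedDesign((("a", "b"), ("a", "c")))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match=">= 2 pairs"):
            PairedDesign((("a", "b"),))

    def test_missing_sample_detected(self):
        design = PairedDesign((("c1", "t1"), ("c2", "t2")))
        m = matrix_of([[1.0], [2.0]])
        with pytest.raises(ValueError, match="absent"):
            design.validate_against(m)

    def test_tsv_roundtrip(self, tmp_path):
        design = PairedDesign((("c1", "t1"), ("c2", "t2")))
        design.to_tsv(tmp_path / "d.tsv")
        back = PairedDesign.from_tsv(tmp_path / "d.tsv")
        assert back.pairs == design.pairs


def _results_frame():
    return pd.DataFrame(
        {
            "mean_ctrl": [10.0, 10, 10, 10],
            "mean_treat": [20.0, 12, 30, 9],
            "log2fc_reg": [np.log2(1.6), np.log2(1.4), 1.0, -1.0],
            "p_value": [0.01, 0.001, 0.2, 0.01],
            "q_value": [0.01, 0.001, 0.3, 0.01],
        },
        index=pd.Index(["a", "b", "c", "d"], name="gene_id"),
    )


class TestCallDegs:
    def test_all_gates_passed(self):
        out = call_degs(_results_frame())
        assert bool(out.loc["a", "is_deg"]) is True

    def test_fc_gate_fails(self):
        out = call_degs(_results_frame())
        assert bool(out.loc["b", "is_deg"]) is False

    def test_p_gate_fails(self):
        out = call_degs(_results_frame())
        assert bool(out.loc["c", "is_deg"]) is False

    def test_downregulated_gene_called(self):
        out = call_degs(_results_frame())
        assert bool(out.loc["d", "is_deg"]) is True

    def test_summary_counts(self):
        out = call_degs(_results_frame())
        assert out.attrs["summary"] == {"total": 2, "up": 1, "down": 1}


class TestVolcanoTable:
    def test_transforms(self):
        res = _results_frame()
        v = volcano_table(res)
        assert v.loc["a", "neg_log10_p"] == pytest.approx(2.0)
        assert bool(v.loc["a", "highlight"]) is True
        assert bool(v.loc["b", "highlight"]) is False

    def test_identity_point(self):
        res = _results_frame()
        res.loc["a", ["p_value", "log2fc_reg"]] = [1.0, 0.0]
        v = volcano_table(res)
        assert v.loc["a", "neg_log10_p"] == 0.0
        assert bool(v.loc["a", "highlight"]) is False

    def test_p_floor_keeps_values_finite(self):
        res = _results_frame()
        res.loc["a", "p_value"] = 0.0
        v = volcano_table(res)
        assert np.isfinite(v.loc["a", "neg_log10_p"])

    def test_monotone_in_p(self):
        res = _results_frame()
        v = volcano_table(res)
        assert v.loc["b", "neg_log10_p"] > v.loc["a", "neg_log10_p"]


class TestHeatmapMatrix:
    @pytest.mark.parametrize("value,expected", [(0, 0), (1, 1), (7, 3)])
    def test_log2_plus_one(self, value, expected):
        m = matrix_of([[float(value)], [float(value)]])
        out = heatmap_matrix(m)
        assert out.iloc[0, 0] == pytest.approx(expected)


class TestDifferentialTable:
    def test_end_to_end_small(self):
        m = matrix_of(
            [[10.0, 100.0], [11.0, 104.0], [10.5, 98.0],
             [40.0, 100.0], [41.0, 99.0], [42.0, 101.0]]
        )
        design = PairedDesign((("s1", "s4"), ("s2", "s5"), ("s3", "s6")))
        res = differential_table(m, design, regularizer=5)
        # gene 0: ctrl mean 10.5, treat mean 41 -> log2(46/15.5)
        assert res.loc["g0", "log2fc_reg"] == pytest.approx(
            np.log2(46 / 15.5)
        )
        d = np.array([40 - 10, 41 - 11, 42 - 10.5])
        expected_p = 2 * stats.t.sf(
            abs(d.mean() / (d.std(ddof=1) / np.sqrt(3))), 2
        )
        assert res.loc["g0", "p_value"] == pytest.approx(expected_p)

    def test_degenerate_gene_is_nan_and_excluded(self):
        m = matrix_of(
            [[10.0, 5.0], [10.0, 6.0], [10.0, 7.0],
             [10.0, 9.0], [10.0, 8.0], [10.0, 10.0]]
        )
        design = PairedDesign((("s1", "s4"), ("s2", "s5"), ("s3", "s6")))
        res = differential_table(m, design)
        assert np.isnan(res.loc["g0", "p_value"])
        assert np.isnan(res.loc["g0", "q_value"])
        assert not np.isnan(res.loc["g1", "p_value"])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(1)
        m = matrix_of([rng.uniform(1, 100, 50).tolist() for _ in range(6)])
        design = PairedDesign((("s1", "s4"), ("s2", "s5"), ("s3", "s6")))
        res = differential_table(m, design)
        ok = ~res["p_value"].isna()
        assert (res.loc[ok, "q_value"] >= res.loc[ok, "p_value"] - 1e-12).all()
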