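"""Differential-expression stage: filtering, TMM, log-CPM, testing, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyconet import (
    DEThresholds,
    ExpressionMatrix,
    SampleDesign,
    bh_fdr,
    filter_low_expression,
    log_cpm,
    permutation_pvalues,
    select_degs,
    tmm_factors,
    two_class_test,
)
from glyconet.diffexpr import read_design_tsv


def _counts(rows, genes=None, samples=None):
    arr = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestFilterLowExpression:
    def test_cpm_rule_hand_computed(self):
        # gene0: CPM [1,1,1,0] with libsize 1e6 -> 3 samples > 0.5 -> kept
        # gene1: all zero -> removed; gene2 keeps library sizes at 1e6
        m = _counts(
            [
                [1, 1, 1, 0],
                [0, 0, 0, 0],
                [999999, 999999, 999999, 1000000],
            ]
        )
        out = filter_low_expression(m, DEThresholds())
        assert out.gene_ids == ["g0", "g2"]
        assert out.sample_ids == m.sample_ids

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = _counts(rng.poisson(5, size=(50, 6)))
        once = filter_low_expression(m)
        twice = filter_low_expression(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_zero_library_size_names_sample(self):
        m = _counts([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            filter_low_expression(m)

    def test_empty_result_is_error(self):
        m = _counts([[1, 1, 1, 1]])
        t = DEThresholds(cpm_min=2e6)  # unreachable CPM
        with pytest.raises(ValueError, match="no genes pass"):
            filter_low_expression(m, t)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        m = _counts(np.tile([[10], [20], [5]], (1, 4)))
        f = tmm_factors(m)
        assert np.allclose(f, 1.0)

    def test_doubled_column_is_library_size_not_composition(self):
        rng = np.random.default_rng(3)
        col = rng.poisson(50, size=40).astype(float) + 1
        m = _counts(np.column_stack([col, 2 * col]))
        f = tmm_factors(m)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self, tmm_fixture_matrix):
        f = tmm_factors(tmm_fixture_matrix)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_on_frozen_fixture(self, tmm_fixture_matrix):
        # expected factors computed once with edgeR::calcNormFactors("TMM")
        expected = {"A": 1.165338, "B": 1.172183, "C": 1.169958, "D": 0.625723}
        f = tmm_factors(tmm_fixture_matrix)
        for s, v in expected.items():
            assert f[s] == pytest.approx(v, abs=1e-6)

    def test_invariant_to_gene_order(self, tmm_fixture_matrix):
        f = tmm_factors(tmm_fixture_matrix)
        shuffled = ExpressionMatrix(
            tmm_fixture_matrix.values.sample(frac=1, random_state=5)
        )
        f2 = tmm_factors(shuffled)
        assert np.allclose(f.to_numpy(), f2.to_numpy())

    def test_no_shared_genes_is_error(self):
        m = _counts([[5, 0], [0, 7]])
        with pytest.raises(ValueError, match="no co-expressed"):
            tmm_factors(m, ref="s0")


class TestLogCpm:
    def test_hand_computed_zero_count(self):
        # count 0, libsize 1e6, factor 1, pseudocount 0.5
        m = _counts([[0, 1], [1000000 - 0, 999999]])
        f = pd.Series([1.0, 1.0], index=["s0", "s1"])
        out = log_cpm(m, f, pseudocount=0.5)
        assert out.values.loc["g0", "s0"] == pytest.approx(
            np.log2(0.5 / 1000001 * 1e6), rel=1e-9
        )
        assert out.scale == "log2"

    def test_pseudocount_monotonicity(self):
        rng = np.random.default_rng(1)
        m = _counts(rng.poisson(20, size=(30, 4)))
        lo = log_cpm(m, None, pseudocount=0.5).values.to_numpy()
        hi = log_cpm(m, None, pseudocount=1.0).values.to_numpy()
        assert (hi > lo).all()

    def test_equal_samples_give_identical_columns(self):
        m = _counts(np.tile([[3], [9], [1]], (1, 2)))
        out = log_cpm(m, None)
        assert np.allclose(out.values["s0"], out.values["s1"])


class TestTwoClassTest:
    def test_identical_groups_are_null(self):
        df = pd.DataFrame(
            [[1, 2, 3, 1, 2, 3]], index=["g0"],
            columns=[f"s{i}" for i in range(6)], dtype=float,
        )
        m = ExpressionMatrix(df, scale="log2")
        d = SampleDesign(
            {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}, "control"
        )
        res = two_class_test(m, d)
        assert res.loc["g0", "log2_fold_change"] == 0.0
        assert res.loc["g0", "statistic"] == 0.0

    def test_hand_computed_welch(self):
        # case [3,4] vs control [1,2]: lfc 2, t = 2 / sqrt(0.5/2 + 0.5/2)
        df = pd.DataFrame([[3, 4, 1, 2]], index=["g0"],
                          columns=list("abcd"), dtype=float)
        m = ExpressionMatrix(df, scale="log2")
        d = SampleDesign({"a": "case", "b": "case", "c": "ctl", "d": "ctl"}, "ctl")
        res = two_class_test(m, d)
        assert res.loc["g0", "log2_fold_change"] == pytest.approx(2.0)
        assert res.loc["g0", "statistic"] == pytest.approx(2 / np.sqrt(0.5), rel=1e-9)

    def test_label_swap_antisymmetry(self, small_log_matrix):
        m, d = small_log_matrix
        flipped = SampleDesign(d.labels, reference=d.case)
        a = two_class_test(m, d)
        b = two_class_test(m, flipped)
        assert np.allclose(a["log2_fold_change"], -b["log2_fold_change"])
        assert np.allclose(a["statistic"], -b["statistic"])

    def test_single_sample_class_rejected(self):
        with pytest.raises(ValueError, match="< 2"):
            SampleDesign({"a": "case", "b": "ctl", "c": "ctl"}, "ctl")


class TestPermutationPvalues:
    def test_three_vs_three_is_exact_enumeration(self, small_log_matrix):
        # C(6,3) = 20 assignments -> p on the grid k/20 even for small B
        m, d = small_log_matrix
        p = permutation_pvalues(m, d, B=5, seed=0)
        assert np.allclose((p * 20) % 1, 0)
        assert (p >= 1 / 20).all()

    def test_null_gene_has_p_one(self):
        df = pd.DataFrame([[2, 2, 2, 2, 2, 2]], index=["g0"],
                          columns=[f"s{i}" for i in range(6)], dtype=float)
        m = ExpressionMatrix(df, scale="log2")
        d = SampleDesign(
            {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}, "control"
        )
        assert permutation_pvalues(m, d, B=999, seed=1).loc["g0"] == 1.0

    def test_seed_determinism_in_sampled_regime(self):
        # 7 vs 7 -> C(14,7) = 3432 > max(B, 1000) -> sampling path
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 14)),
                          index=[f"g{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(14)])
        m = ExpressionMatrix(df, scale="log2")
        d = SampleDesign(
            {f"s{i}": ("case" if i < 7 else "control") for i in range(14)}, "control"
        )
        p1 = permutation_pvalues(m, d, B=99, seed=7)
        p2 = permutation_pvalues(m, d, B=99, seed=7)
        p3 = permutation_pvalues(m, d, B=99, seed=8)
        pd.testing.assert_series_equal(p1, p2)
        assert not p1.equals(p3)
        # add-one estimator keeps p on the grid (1+k)/(B+1), within bounds
        assert ((p1 * 100) % 1 < 1e-9).all()
        assert (p1 >= 1 / 100).all() and (p1 <= 1.0).all()

    def test_invalid_b(self, small_log_matrix):
        m, d = small_log_matrix
        with pytest.raises(ValueError):
            permutation_pvalues(m, d, B=0)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
            min_size=1, max_size=10,
        )
    )
    def test_agrees_with_bruteforce_step_up(self, p):
        def brute(p):
            m = len(p)
            order = sorted(range(m), key=lambda i: p[i])
            adj = [None] * m
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = min(running, 1.0)
            return adj

        assert np.allclose(bh_fdr(p), brute(p), rtol=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=200)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])


class TestSelectDegs:
    def _stats(self, lfc):
        return pd.DataFrame(
            {"log2_fold_change": lfc, "statistic": np.sign(lfc)},
            index=[f"g{i}" for i in range(len(lfc))],
        )

    def test_threshold_arithmetic(self):
        stats = self._stats([1.2, 3.0, -1.5])
        p = pd.Series([0.01, 0.2, 0.04], index=stats.index)
        fdr = [0.05, 0.5, 0.09]
        out = select_degs(stats, p, fdr, DEThresholds())
        assert out.loc["g0", "selected"] and out.loc["g0", "direction"] == "up"
        assert not out.loc["g1", "selected"]  # p too large despite big fc
        assert out.loc["g2", "selected"] and out.loc["g2", "direction"] == "down"

    def test_selected_implies_directioned(self):
        stats = self._stats([2.0, 0.1])
        p = pd.Series([0.01, 0.01], index=stats.index)
        out = select_degs(stats, p, [0.01, 0.01], DEThresholds())
        assert set(out.loc[out["selected"], "direction"]) <= {"up", "down"}
        assert (out.loc[~out["selected"], "direction"] == "ns").all()

    def test_misaligned_lengths(self):
        stats = self._stats([1.0])
        with pytest.raises(ValueError, match="misaligned"):
            select_degs(stats, pd.Series([0.1, 0.2]), None, DEThresholds())

    def test_default_thresholds(self):
        t = DEThresholds()
        assert (t.p_max, t.fdr_max, t.min_abs_log2fc) == (0.05, 0.1, 1.0)
        assert (t.cpm_min, t.cpm_min_samples) == (0.5, 3)


class TestDesignIO:
    def test_control_label_convention(self, tmp_path):
        f = tmp_path / "design.tsv"
        f.write_text("a\tdisease\nb\tdisease\nc\tcontrol\nd\tcontrol\n")
        d = read_design_tsv(f)
        assert d.reference == "control" and d.case == "disease"

    def test_explicit_reference_wins(self, tmp_path):
        f = tmp_path / "design.tsv"
        f.write_text("a\tx\nb\tx\nc\ty\nd\ty\n")
        assert read_design_tsv(f, reference="y").reference == "y"
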