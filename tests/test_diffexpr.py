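"""Fold changes, Welch tests, BH adjustment and significance calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kmerquant as kq

from .conftest import oracle_bh, oracle_welch


class TestGeometricFoldChange:
    @pytest.mark.parametrize(
        "ref, trt, expected",
        [
            ((1, 1, 1), (4, 4, 4), 4.0),
            ((2, 2), (1, 16), 2.0),  # geometric means 2 and 4
            ((3, 5, 7), (3, 5, 7), 1.0),
        ],
    )
    def test_ratio_of_geometric_means(self, ref, trt, expected):
        fc, log2fc = kq.geometric_fold_change(ref, trt)
        assert fc == pytest.approx(expected)
        assert log2fc == pytest.approx(np.log2(expected))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(kq.ContractError):
            kq.geometric_fold_change((1, 2), (0, 3))


class TestWelch:
    def test_identical_groups(self):
        t, df, p = kq.welch_t_test((1, 2, 3), (1, 2, 3))
        assert t == 0 and p == pytest.approx(1.0)

    def test_worked_example(self):
        t, df, p = kq.welch_t_test((1, 2, 3), (2, 3, 4))
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2878, abs=1e-4)

    def test_affine_invariance(self):
        a, b = (1.0, 2.5, 3.1), (2.2, 3.3, 4.9)
        base = kq.welch_t_test(a, b)
        shifted = kq.welch_t_test(
            tuple(5 * x + 7 for x in a), tuple(5 * x + 7 for x in b)
        )
        assert shifted == pytest.approx(base)

    def test_constant_equal_groups_flagged_null(self):
        t, df, p = kq.welch_t_test((2, 2, 2), (2, 2, 2))
        assert t == 0 and p == 1.0

    def test_constant_unequal_groups_untestable(self):
        t, df, p = kq.welch_t_test((2, 2, 2), (3, 3, 3))
        assert np.isnan(t) and np.isnan(p)

    def test_single_value_group_rejected(self):
        with pytest.raises(kq.ContractError):
            kq.welch_t_test((1,), (1, 2))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    def test_matches_hand_formula_oracle(self, a, b):
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        if va == 0 and vb == 0:
            return
        got = kq.welch_t_test(a, b)
        assert got == pytest.approx(oracle_welch(a, b), rel=1e-10, abs=1e-12)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert kq.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_enforces_monotonicity_from_largest(self):
        assert kq.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_nan_entries_excluded_from_family_size(self):
        got = kq.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(got[1])
        assert got[[0, 2]] == pytest.approx(oracle_bh([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(kq.ContractError):
            kq.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_step_up(self, p):
        got = kq.bh_adjust(p)
        assert got == pytest.approx(oracle_bh(p), rel=1e-12)
        assert np.all(got >= np.asarray(p) - 1e-15)


class TestCallSignificant:
    def make_table(self, fc, fdr):
        return pd.DataFrame({"fold_change": [fc], "fdr": [fdr]}, index=["g"])

    @pytest.mark.parametrize(
        "fc, fdr, expected",
        [
            (1.61, 0.001, "not_significant"),  # strict > on fold change
            (2.0, 0.049, "up"),
            (3.0, 0.05, "not_significant"),  # strict < on FDR
            (0.3, 0.01, "down"),
            (1.0 / 1.61, 0.01, "not_significant"),  # strict < on 1/threshold
            (np.nan, np.nan, "untestable"),
        ],
    )
    def test_threshold_rules(self, fc, fdr, expected):
        out = kq.call_significant(self.make_table(fc, fdr), kq.DEConfig())
        assert out.loc["g", "call"] == expected


def normalized_matrix(values, samples):
    genes = [f"g{i + 1}" for i in range(values.shape[0])]
    return kq.ExpressionMatrix(
        data=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                          columns=samples),
        scale="normalized-log2",
    )


class TestDifferentialExpression:
    samples = ["c1", "c2", "c3", "t1", "t2", "t3"]
    design = kq.ExperimentDesign(
        groups={"c1": "ctrl", "c2": "ctrl", "c3": "ctrl",
                "t1": "trt", "t2": "trt", "t3": "trt"},
        contrast=("ctrl", "trt"),
    )

    @pytest.fixture()
    def matrix(self):
        rng = np.random.default_rng(7)
        values = rng.normal(5, 0.3, size=(100, 6))
        values[:10, 3:] += 3.0  # strong induction in the first ten genes
        values[50] = np.nan  # an absent gene
        return normalized_matrix(values, self.samples)

    def test_fit_calls_induced_genes_up(self, matrix):
        results = kq.DifferentialExpression(matrix, self.design).fit()
        assert set(results.up) >= {f"g{i}" for i in range(1, 9)}
        assert results.table.loc["g51", "call"] == "untestable"
        # fdr >= p wherever both are defined
        t = results.table.dropna(subset=["p"])
        assert (t["fdr"] >= t["p"] - 1e-15).all()

    def test_fold_change_matches_geometric_mean_of_linear_values(self, matrix):
        results = kq.DifferentialExpression(matrix, self.design).fit()
        gene = "g3"
        linear = 2 ** matrix.data.loc[gene]
        fc, _ = kq.geometric_fold_change(
            linear[["c1", "c2", "c3"]], linear[["t1", "t2", "t3"]]
        )
        assert results.table.loc[gene, "fold_change"] == pytest.approx(fc)

    def test_swapping_contrast_inverts_fold_change_and_negates_t(self, matrix):
        fwd = kq.DifferentialExpression(matrix, self.design).fit()
        swapped_design = kq.ExperimentDesign(
            groups=self.design.groups, contrast=("trt", "ctrl")
        )
        rev = kq.DifferentialExpression(matrix, swapped_design).fit()
        f, r = fwd.table.dropna(subset=["p"]), rev.table.dropna(subset=["p"])
        assert np.allclose(r["fold_change"], 1 / f["fold_change"])
        assert np.allclose(r["t"], -f["t"])
        assert np.allclose(r["p"], f["p"])
        assert np.allclose(r["fdr"], f["fdr"])

    def test_raw_matrix_rejected(self, matrix):
        raw = kq.ExpressionMatrix(data=matrix.data, scale="raw")
        with pytest.raises(kq.ValidationError):
            kq.DifferentialExpression(raw, self.design)

    def test_undersized_group_rejected(self):
        with pytest.raises(kq.ValidationError):
            kq.ExperimentDesign(groups={"a": "x", "b": "y", "c": "y"},
                                contrast=("x", "y"))

    def test_summary_reports_counts(self, matrix):
        results = kq.DifferentialExpression(matrix, self.design).fit()
        text = results.summary()
        assert "upregulated" in text and "untestable" in text
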