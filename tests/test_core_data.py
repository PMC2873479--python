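import numpy as np
import pytest

from generank import (
    ClassDesignError,
    DuplicateGeneError,
    ExpressionMatrix,
    FormatError,
    class_stats,
    normalize_genes,
    read_expression,
    read_labels,
    write_cls,
    write_expression,
)


def make_matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        labels,
    )


class TestExpressionMatrix:
    def test_shape_and_id_validation(self):
        with pytest.raises(ValueError, match="gene ids"):
            ExpressionMatrix(np.zeros((3, 2)), ["a", "b"], ["s1", "s2"])
        with pytest.raises(DuplicateGeneError, match="dup"):
            ExpressionMatrix(np.zeros((2, 2)), ["dup", "dup"], ["s1", "s2"])

    def test_label_length_and_coding_checked(self):
        with pytest.raises(ValueError, match="4-sample"):
            make_matrix(np.zeros((2, 4)), labels=[1, 1, -1])
        with pytest.raises(ValueError, match=r"\{\+1, -1\}"):
            make_matrix(np.zeros((2, 2)), labels=[0, 1])

    def test_single_class_rejected_by_scoring_precondition(self):
        X = make_matrix(np.zeros((2, 3)), labels=[1, 1, 1])
        with pytest.raises(ClassDesignError):
            X.require_labels()


class TestNormalizeGenes:
    def test_constant_row_maps_to_zeros(self):
        X = normalize_genes(make_matrix([[5.0, 5.0, 5.0]]))
        assert np.array_equal(X.values, np.zeros((1, 3)))

    def test_hand_computed_row(self):
        # (x - mean) / population SD with SD = sqrt(2/3)
        X = normalize_genes(make_matrix([[1.0, 2.0, 3.0]]))
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(X.values[0], expected, atol=1e-9)
        np.testing.assert_allclose(X.values[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = normalize_genes(make_matrix(rng.normal(2.0, 5.0, size=(30, 11))))
        np.testing.assert_allclose(X.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.values.std(axis=1), 1.0, atol=1e-12)

    def test_idempotent_and_affine_invariant(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(10, 8))
        once = normalize_genes(make_matrix(raw))
        twice = normalize_genes(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)
        rescaled = normalize_genes(make_matrix(3.7 * raw - 11.0))
        np.testing.assert_allclose(once.values, rescaled.values, atol=1e-9)


class TestClassStats:
    def test_hand_values_population_and_sample_sd(self, micro_matrix):
        st0 = class_stats(micro_matrix, ddof=0)
        assert (st0.mu_pos[0], st0.mu_neg[0]) == (3.0, 1.0)
        assert (st0.sigma_pos[0], st0.sigma_neg[0]) == (1.0, 1.0)
        assert (st0.m_pos, st0.m_neg) == (2, 2)
        st1 = class_stats(micro_matrix, ddof=1)
        np.testing.assert_allclose([st1.sigma_pos[0], st1.sigma_neg[0]],
                                   [np.sqrt(2.0), np.sqrt(2.0)], atol=1e-12)

    def test_degenerate_designs_rejected(self):
        X = make_matrix(np.zeros((1, 3)), labels=[1, 1, 1])
        with pytest.raises(ClassDesignError):
            class_stats(X)
        X2 = make_matrix(np.zeros((1, 3)), labels=[1, 1, -1])
        with pytest.raises(ClassDesignError, match="ddof=1"):
            class_stats(X2, ddof=1)


class TestExpressionIO:
    @pytest.mark.parametrize("fmt", ["gct", "delimited", "res"])
    def test_write_read_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(2)
        X = make_matrix(rng.normal(size=(5, 4)))
        path = tmp_path / f"m.{fmt}"
        write_expression(X, path, format=fmt)
        back = read_expression(path, format=fmt)
        np.testing.assert_array_equal(back.values, X.values)
        assert back.gene_ids == X.gene_ids
        assert back.sample_ids == X.sample_ids
        assert back.labels is None

    def test_delimited_reader_with_transpose(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\tg0\tg1\tg2\ns0\t1\t2\t3\ns1\t4\t5\t6\n")
        X = read_expression(path, format="delimited", transpose=True)
        assert X.values.shape == (3, 2)
        assert X.gene_ids == ["g0", "g1", "g2"]

    def test_gct_header_body_mismatch_is_format_error(self, tmp_path):
        path = tmp_path / "bad.gct"
        rows = "\n".join(f"g{i}\tna\t1.0\t2.0" for i in range(4))
        path.write_text(f"#1.2\n3\t2\nName\tDescription\ts1\ts2\n{rows}\n")
        with pytest.raises(FormatError, match="3x2"):
            read_expression(path, format="gct")

    def test_gct_requires_version_header(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("not-gct\n1\t1\nName\tDescription\ts1\ng\tna\t1.0\n")
        with pytest.raises(FormatError, match="#1.2"):
            read_expression(path, format="gct")

    def test_res_call_columns_discarded(self, tmp_path):
        path = tmp_path / "m.res"
        path.write_text(
            "Description\tAccession\ts1\t\ts2\n\n2\n"
            "na\tgA\t1.5\tP\t2.5\tA\nna\tgB\t3.0\tM\t4.0\tP\n"
        )
        X = read_expression(path, format="res")
        np.testing.assert_array_equal(X.values, [[1.5, 2.5], [3.0, 4.0]])
        assert X.gene_ids == ["gA", "gB"]

    def test_duplicate_ids_rejected_then_suffixed(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("gene_id\ts1\ts2\nG\t1\t2\nG\t3\t4\n")
        with pytest.raises(DuplicateGeneError, match="G"):
            read_expression(path, format="delimited")
        X = read_expression(path, format="delimited", dedup="suffix")
        assert X.gene_ids == ["G", "G.1"]


class TestLabelIO:
    def test_cls_first_name_maps_to_plus_one(self, tmp_path):
        path = tmp_path / "x.cls"
        path.write_text("4 2 1\n# A B\nA A B B\n")
        ls = read_labels(path, format="cls")
        np.testing.assert_array_equal(ls.labels, [1, 1, -1, -1])
        assert ls.mapping == {"A": 1, "B": -1}

    def test_cls_index_coded_labels(self, tmp_path):
        path = tmp_path / "x.cls"
        path.write_text("4 2 1\n# ALL AML\n0 1 1 0\n")
        ls = read_labels(path, format="cls")
        np.testing.assert_array_equal(ls.labels, [1, -1, -1, 1])

    def test_cls_round_trip(self, tmp_path):
        path = tmp_path / "y.cls"
        labels = np.array([1, -1, -1, 1, 1])
        write_cls(labels, path, names=("ALL", "AML"))
        back = read_labels(path, format="cls")
        np.testing.assert_array_equal(back.labels, labels)

    def test_two_column_with_explicit_positive_class(self, tmp_path):
        path = tmp_path / "lab.tsv"
        path.write_text("s1\ttumor\ns2\tnormal\ns3\tnormal\ns4\ttumor\n")
        ls = read_labels(path, format="two_column", positive_class="normal")
        np.testing.assert_array_equal(ls.labels, [-1, 1, 1, -1])
        assert int((ls.labels == 1).sum()) == 2

    def test_more_than_two_classes_unsupported(self, tmp_path):
        path = tmp_path / "bad.cls"
        path.write_text("3 3 1\n# A B C\nA B C\n")
        with pytest.raises(ClassDesignError, match="two-class"):
            read_labels(path, format="cls")
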