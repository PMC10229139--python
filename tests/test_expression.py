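"""Loading, transforms, gene attributes, filtering and cell sampling."""

import numpy as np
import pandas as pd
import pytest

from sccausal import expression
from sccausal.expression import ExpressionMatrix, FilterSpec, ValidationError


class TestLoading:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("gene,c1,c2\nA,0,1\nB,2.5,0\nC,4,4\n")
        m = expression.load_expression(path, "csv")
        assert m.values.shape == (3, 2)
        assert m.gene_ids == ("A", "B", "C")
        assert m.cell_ids == ("c1", "c2")
        assert m.transform == "raw"
        assert m.values[1, 0] == 2.5

    def test_mtx_triplet_zero_fill(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n2 2 1\n1 1 3.0\n"
        )
        (tmp_path / "genes.tsv").write_text("g1\ng2\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        m = expression.load_expression(tmp_path / "m.mtx", "mtx-triplet")
        assert m.values[0, 0] == 3.0
        assert m.values.sum() == 3.0  # every unlisted entry is zero

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("gene,c1\nA,0\nA,1\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            expression.load_expression(path, "csv")

    def test_negative_raw_values_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            ExpressionMatrix(np.array([[-1.0]]), ("g",), ("c",))


class TestTransform:
    def test_log2_values(self, tiny_matrix):
        out = expression.transform(tiny_matrix, "log2")
        assert out.transform == "log2"
        assert out.values[0, 0] == 0.0  # log2(0+1)
        assert out.values[1, 2] == 2.0  # log2(3+1)

    def test_log2_twice_is_a_state_error(self, tiny_matrix):
        once = expression.transform(tiny_matrix, "log2")
        with pytest.raises(ValidationError, match="raw"):
            expression.transform(once, "log2")

    def test_zscore_standardizes_rows(self):
        m = ExpressionMatrix(np.array([[1.0, 2.0, 3.0]]), ("g",), ("a", "b", "c"))
        out = expression.transform(m, "zscore")
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]])  # (x−2)/1

    def test_zscore_constant_row_maps_to_zero(self, tiny_matrix):
        out = expression.transform(tiny_matrix, "zscore")
        np.testing.assert_array_equal(out.values[2], 0.0)

    def test_log2_monotone_and_nonnegative(self):
        rng = np.random.default_rng(0)
        raw = np.sort(rng.uniform(0, 50, size=(1, 30)))
        out = expression.transform(ExpressionMatrix(raw, ("g",), tuple(f"c{i}" for i in range(30))), "log2")
        assert (out.values >= 0).all()
        assert (np.diff(out.values[0]) >= 0).all()


class TestAttributes:
    def test_hand_computed_row(self, tiny_matrix):
        attrs = expression.compute_gene_attributes(tiny_matrix)
        row = attrs.loc["GATA1"]
        assert row["mean_expr"] == 2.0
        assert row["pct_cells"] == 0.5
        assert row["variance"] == pytest.approx(16 / 3)

    def test_silent_gene(self, tiny_matrix):
        row = expression.compute_gene_attributes(tiny_matrix).loc["SPI1"]
        assert row["mean_expr"] == 0.0 and row["pct_cells"] == 0.0 and row["variance"] == 0.0

    def test_identical_case_control_gives_zero_log_fc(self, tiny_matrix):
        attrs = expression.compute_gene_attributes(tiny_matrix, control=tiny_matrix)
        np.testing.assert_allclose(attrs["log_fc"], 0.0)

    def test_gene_absent_from_control_gets_nan(self, tiny_matrix):
        ctrl = ExpressionMatrix(np.array([[1.0, 1.0]]), ("GATA1",), ("d1", "d2"))
        attrs = expression.compute_gene_attributes(tiny_matrix, control=ctrl)
        assert np.isfinite(attrs.loc["GATA1", "log_fc"])
        assert np.isnan(attrs.loc["TAL1", "log_fc"])

    def test_permutation_invariant_over_cells(self, tiny_matrix):
        rng = np.random.default_rng(1)
        perm = rng.permutation(tiny_matrix.n_cells)
        shuffled = ExpressionMatrix(
            tiny_matrix.values[:, perm],
            tiny_matrix.gene_ids,
            tuple(tiny_matrix.cell_ids[c] for c in perm),
        )
        a = expression.compute_gene_attributes(tiny_matrix)
        b = expression.compute_gene_attributes(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_tf_flag(self, tiny_matrix):
        attrs = expression.compute_gene_attributes(tiny_matrix, tf_list=["TAL1"])
        assert attrs["is_tf"].tolist() == [False, True, False]


class TestFiltering:
    def _attrs(self, **kw):
        base = dict(mean_expr=0.2, pct_cells=0.6, variance=1.0, log_fc=0.4)
        base.update(kw)
        return pd.DataFrame([base], index=["g1"])

    def test_packaged_defaults_retain_qualifying_gene(self):
        attrs = self._attrs()
        assert expression.filter_genes(attrs, FilterSpec.default()) == ["g1"]

    def test_strict_inequality_at_boundary(self):
        attrs = self._attrs(mean_expr=0.1)
        spec = FilterSpec(min_mean_expr=0.1)
        assert expression.filter_genes(attrs, spec) == []

    def test_empty_spec_rejected(self):
        with pytest.raises(ValidationError):
            FilterSpec()

    def test_subset_and_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        attrs = pd.DataFrame(
            {
                "mean_expr": rng.uniform(0, 1, 40),
                "pct_cells": rng.uniform(0, 1, 40),
                "variance": rng.uniform(0, 2, 40),
            },
            index=[f"g{i:02d}" for i in range(40)],
        )
        loose = expression.filter_genes(attrs, FilterSpec(min_mean_expr=0.2, min_pct_cells=0.3))
        tight = expression.filter_genes(attrs, FilterSpec(min_mean_expr=0.5, min_pct_cells=0.3))
        assert set(loose) <= set(attrs.index)
        assert set(tight) <= set(loose)

    def test_ordering_descending_with_lexicographic_ties(self):
        attrs = pd.DataFrame(
            {"mean_expr": [1.0, 2.0, 1.0], "pct_cells": [1, 1, 1]},
            index=["b", "a", "c"],
        )
        out = expression.filter_genes(attrs, FilterSpec(min_mean_expr=0.5))
        assert out == ["a", "b", "c"]

    def test_tf_only_without_column_fails(self):
        with pytest.raises(ValidationError, match="is_tf"):
            expression.filter_genes(self._attrs(), FilterSpec(tf_only=True))


class TestSampling:
    def test_full_sample_is_identity(self, tiny_matrix):
        out = expression.sample_cells(tiny_matrix, tiny_matrix.n_cells, "first")
        np.testing.assert_array_equal(out.values, tiny_matrix.values)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        m = ExpressionMatrix(
            rng.uniform(0, 5, (4, 100)),
            tuple("abcd"),
            tuple(f"c{i}" for i in range(100)),
        )
        a = expression.sample_cells(m, 30, "random", seed=11)
        b = expression.sample_cells(m, 30, "random", seed=11)
        assert a.cell_ids == b.cell_ids
        np.testing.assert_array_equal(a.values, b.values)
        assert a.gene_ids == m.gene_ids

    def test_oversampling_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError):
            expression.sample_cells(tiny_matrix, 5, "first")
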