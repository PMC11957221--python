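"""Containers, IO round-trips, one-hot encodings, and stratified folds."""

import numpy as np
import pandas as pd
import pytest

from mixedae.data_model import (BatchDesign, ExpressionDataset, FoldSplit,
                                LatentSpace, load_expression, make_batch_design,
                                save_expression, stratified_kfold)


def small_dataset(labels=("b1", "b2", "b1"), types=None):
    counts = np.array([[1.0, 2.0], [3.0, 0.0], [5.0, 6.0]])
    ann = pd.DataFrame({"batch_label": list(labels)})
    if types is not None:
        ann["cell_type_label"] = list(types)
    return ExpressionDataset(counts, ["g1", "g2"], ["c1", "c2", "c3"], ann)


class TestExpressionDataset:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ExpressionDataset(np.array([[1.0, -1.0]]), ["g1", "g2"], ["c1"],
                              pd.DataFrame({"batch_label": ["b"]}))

    def test_duplicate_gene_ids_named(self):
        with pytest.raises(ValueError, match="g1"):
            ExpressionDataset(np.ones((1, 2)), ["g1", "g1"], ["c1"],
                              pd.DataFrame({"batch_label": ["b"]}))

    def test_missing_batch_label_lists_cells(self):
        with pytest.raises(ValueError, match="c2"):
            ExpressionDataset(np.ones((2, 1)), ["g1"], ["c1", "c2"],
                              pd.DataFrame({"batch_label": ["b", None]}))

    def test_id_length_mismatch(self):
        with pytest.raises(ValueError):
            ExpressionDataset(np.ones((2, 2)), ["g1"], ["c1", "c2"],
                              pd.DataFrame({"batch_label": ["b", "b"]}))


class TestIO:
    @pytest.mark.parametrize("fmt,suffix", [("csv", ".csv"), ("mtx", ".mtx"),
                                            ("h5ad", ".h5ad")])
    def test_round_trip_preserves_everything(self, tmp_path, fmt, suffix):
        ds = small_dataset(types=("t1", "t2", "t1"))
        path = tmp_path / f"data{suffix}"
        save_expression(ds, path, format=fmt)
        back = load_expression(path, format=fmt)
        np.testing.assert_array_equal(back.counts, ds.counts)
        assert back.gene_ids == ds.gene_ids
        assert back.cell_ids == ds.cell_ids
        assert list(back.annotations["batch_label"]) == list(
            ds.annotations["batch_label"])

    def test_csv_reads_header_and_index(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",g1,g2\nc1,1,2\nc2,3,4\nc3,5,6\n")
        ann = pd.DataFrame({"batch_label": ["b"] * 3}, index=["c1", "c2", "c3"])
        ds = load_expression(path, annotations=ann)
        assert ds.n_cells == 3 and ds.n_genes == 2

    def test_mtx_missing_companions_is_format_error(self, tmp_path):
        from scipy import io as spio
        from scipy import sparse

        path = tmp_path / "m.mtx"
        spio.mmwrite(str(path), sparse.eye(2, format="csr"))
        with pytest.raises(ValueError, match="companion"):
            load_expression(path, format="mtx")

    def test_negative_value_in_file_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",g1\nc1,-1\n")
        ann = pd.DataFrame({"batch_label": ["b"]}, index=["c1"])
        with pytest.raises(ValueError, match="negative"):
            load_expression(path, annotations=ann)


class TestBatchDesign:
    def test_direct_encoding(self):
        design = make_batch_design(small_dataset(("b1", "b2", "b1")))
        np.testing.assert_array_equal(design.onehot,
                                      [[1, 0], [0, 1], [1, 0]])
        assert design.batch_vocab == ["b1", "b2"]

    def test_single_batch_degenerate(self):
        design = make_batch_design(small_dataset(("b", "b", "b")))
        assert design.n_batches == 1
        np.testing.assert_array_equal(design.onehot, [[1], [1], [1]])

    def test_vocab_is_sorted(self):
        design = make_batch_design(small_dataset(("z", "a", "z")))
        assert design.batch_vocab == ["a", "z"]

    def test_rows_sum_to_one_over_random_labels(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            labels = rng.choice(list("abcd"), size=30)
            ann = pd.DataFrame({"batch_label": labels})
            ds = ExpressionDataset(np.ones((30, 2)), ["g1", "g2"],
                                   [f"c{i}" for i in range(30)], ann)
            design = make_batch_design(ds)
            np.testing.assert_allclose(design.onehot.sum(axis=1), 1.0)

    def test_invalid_onehot_rejected(self):
        with pytest.raises(ValueError):
            BatchDesign(np.array([[1.0, 1.0]]), ["a", "b"])


class TestStratifiedKFold:
    @staticmethod
    def balanced_dataset(n_per=25):
        n = n_per * 4
        ann = pd.DataFrame({
            "batch_label": ["b1"] * (2 * n_per) + ["b2"] * (2 * n_per),
            "cell_type_label": (["t1"] * n_per + ["t2"] * n_per) * 2,
        })
        return ExpressionDataset(np.ones((n, 2)), ["g1", "g2"],
                                 [f"c{i}" for i in range(n)], ann)

    def test_even_per_stratum_allocation(self):
        # 4 strata x 25 cells, k=5 -> each test fold holds 5 per stratum
        ds = self.balanced_dataset(25)
        folds = stratified_kfold(ds, k=5, seed=0)
        strata = [f"{b}|{t}" for b, t in zip(ds.batch_labels,
                                             ds.cell_type_labels)]
        for fold in folds:
            counts = pd.Series([strata[i] for i in fold.test_cells]).value_counts()
            assert set(counts) == {5}

    def test_test_sets_partition_all_cells(self):
        ds = self.balanced_dataset(10)
        folds = stratified_kfold(ds, k=5, seed=1)
        all_test = np.concatenate([f.test_cells for f in folds])
        assert len(all_test) == len(set(all_test)) == ds.n_cells

    def test_train_val_test_disjoint(self):
        ds = self.balanced_dataset(10)
        for fold in stratified_kfold(ds, k=5, seed=2):
            assert not (set(fold.train_cells) & set(fold.val_cells))
            assert not (set(fold.train_cells) & set(fold.test_cells))
            assert not (set(fold.val_cells) & set(fold.test_cells))

    def test_small_stratum_round_robin_warns(self):
        ann = pd.DataFrame({"batch_label": ["b1"] * 20 + ["tiny"] * 3})
        ds = ExpressionDataset(np.ones((23, 1)), ["g"],
                               [f"c{i}" for i in range(23)], ann)
        with pytest.warns(UserWarning, match="tiny"):
            folds = stratified_kfold(ds, k=5, seed=0)
        tiny_cells = set(range(20, 23))
        holding = [f.fold_index for f in folds
                   if tiny_cells & set(f.test_cells.tolist())]
        assert len(holding) == 3  # three distinct folds

    def test_same_seed_identical_different_seed_same_shape(self):
        ds = self.balanced_dataset(10)
        a = stratified_kfold(ds, k=5, seed=7)
        b = stratified_kfold(ds, k=5, seed=7)
        c = stratified_kfold(ds, k=5, seed=8)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.test_cells, fb.test_cells)
            np.testing.assert_array_equal(fa.train_cells, fb.train_cells)
        assert any(not np.array_equal(fa.test_cells, fc.test_cells)
                   for fa, fc in zip(a, c))
        for fa, fc in zip(a, c):
            assert len(fa.test_cells) == len(fc.test_cells)

    def test_k_must_exceed_one(self):
        with pytest.raises(ValueError):
            stratified_kfold(self.balanced_dataset(5), k=1)


def test_fold_split_overlap_rejected():
    with pytest.raises(ValueError):
        FoldSplit(0, [0, 1], [1, 2], [3])


def test_fold_split_json_serialization():
    fold = FoldSplit(2, [0], [1], [2])
    doc = fold.to_json(["c0", "c1", "c2"])
    assert '"fold": 2' in doc and '"test": ["c2"]' in doc


def test_latent_space_validates_alignment_and_finiteness():
    with pytest.raises(ValueError):
        LatentSpace(np.ones((3, 2)), ["a", "b"], source="FE")
    with pytest.raises(ValueError):
        LatentSpace(np.array([[np.nan, 0.0]]), ["a"], source="FE")
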