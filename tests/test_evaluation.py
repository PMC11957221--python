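"""Separability metrics vs brute-force oracles, fusion, classification."""

import numpy as np
import pytest

from mixedae.data_model import FoldSplit, LatentSpace
from mixedae.evaluation import (classify_latent, fuse_latents,
                                report_across_folds, separability_metrics)


# ---------------------------------------------------------------------------
# O(n^2) brute-force oracles, independent of scikit-learn
# ---------------------------------------------------------------------------

def brute_silhouette(X, labels):
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        same[i] = False
        if same.sum() == 0:
            s[i] = 0.0
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == lab].mean()
                for lab in set(labels) if lab != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s.mean()


def brute_calinski_harabasz(X, labels):
    n, labs = len(X), sorted(set(labels))
    overall = X.mean(axis=0)
    bss = sum((labels == lab).sum() *
              ((X[labels == lab].mean(axis=0) - overall) ** 2).sum()
              for lab in labs)
    wss = sum(((X[labels == lab] - X[labels == lab].mean(axis=0)) ** 2).sum()
              for lab in labs)
    k = len(labs)
    return (bss / (k - 1)) / (wss / (n - k))


def brute_davies_bouldin(X, labels):
    labs = sorted(set(labels))
    cents = np.array([X[labels == lab].mean(axis=0) for lab in labs])
    scatter = np.array([
        np.mean(np.linalg.norm(X[labels == lab] - cents[i], axis=1))
        for i, lab in enumerate(labs)])
    k = len(labs)
    total = 0.0
    for i in range(k):
        worst = max((scatter[i] + scatter[j]) / np.linalg.norm(cents[i] - cents[j])
                    for j in range(k) if j != i)
        total += worst
    return total / k


@pytest.mark.parametrize("seed", range(20))
def test_metrics_match_brute_force_oracles(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 61))
    k = int(rng.integers(2, 5))
    X = rng.normal(size=(n, 2))
    labels = rng.integers(0, k, size=n)
    while len(set(labels.tolist())) < 2 or min(np.bincount(labels)) < 2:
        labels = rng.integers(0, k, size=n)
    m = separability_metrics(X, labels)
    assert m["asw"] == pytest.approx(brute_silhouette(X, labels), abs=1e-9)
    assert m["ch"] == pytest.approx(brute_calinski_harabasz(X, labels), abs=1e-9)
    assert 1.0 / m["inv_db"] == pytest.approx(brute_davies_bouldin(X, labels),
                                              abs=1e-9)


class TestSeparability:
    def test_two_separated_clusters_hand_value(self):
        # pairs at x=0 and x=10, unit vertical spread: a=1, b=(10+sqrt(101))/2
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array(["l", "l", "r", "r"])
        a = 1.0
        b = (10.0 + np.sqrt(101.0)) / 2.0
        expected = (b - a) / b
        m = separability_metrics(X, labels)
        assert m["asw"] == pytest.approx(expected, abs=1e-12)
        assert m["asw"] == pytest.approx(0.90, abs=5e-3)

    def test_random_labels_on_blob_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 2))
        labels = rng.integers(0, 2, 500)
        assert abs(separability_metrics(X, labels)["asw"]) < 0.1

    def test_degenerate_identical_points_defined_as_zero(self):
        X = np.zeros((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        m = separability_metrics(X, labels)
        assert m == {"asw": 0.0, "ch": 0.0, "inv_db": 0.0}

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            separability_metrics(np.ones((4, 2)), np.zeros(4))

    def test_singleton_labels_dropped_with_warning(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 5,
                       np.array([[99.0, 99.0]])])
        labels = np.array([0, 0, 0, 1, 1, 1, 2])
        with pytest.warns(UserWarning, match="singleton"):
            m = separability_metrics(X, labels)
        assert m["asw"] > 0.9


class TestFoldReport:
    def test_identical_values_zero_width(self):
        rep = report_across_folds([0.5] * 5)
        assert rep["mean"] == 0.5
        assert rep["ci_lower"] == rep["ci_upper"] == 0.5

    def test_t_interval_arithmetic(self):
        rep = report_across_folds([0.0, 0.0, 0.0, 0.0, 1.0])
        assert rep["mean"] == pytest.approx(0.2)
        half = 2.776 * (0.4472 / np.sqrt(5))
        assert rep["ci_upper"] - rep["mean"] == pytest.approx(half, abs=2e-3)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            report_across_folds([0.3])


class TestFusion:
    @staticmethod
    def latents(n=30, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"c{i}" for i in range(n)]
        fe = LatentSpace(rng.normal(2.0, 3.0, (n, 2)), ids, "FE")
        re = LatentSpace(rng.normal(-1.0, 0.5, (n, 2)), ids, "RE")
        return fe, re

    def test_concatenation_width(self):
        fe, re = self.latents()
        fused = fuse_latents(fe, re)
        assert fused.embedding.shape[1] == 4
        assert fused.source == "fused"

    def test_fit_columns_standardized(self):
        fe, re = self.latents()
        fit_idx = np.arange(20)
        fused = fuse_latents(fe, re, fit_idx=fit_idx)
        cols = fused.embedding[fit_idx]
        np.testing.assert_allclose(cols.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(cols.std(axis=0), 1.0, atol=1e-10)

    def test_cell_order_mismatch_rejected(self):
        fe, re = self.latents()
        re.cell_ids = list(reversed(re.cell_ids))
        with pytest.raises(ValueError):
            fuse_latents(fe, re)


class TestClassification:
    @staticmethod
    def fold_for(n, seed=0):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return FoldSplit(0, perm[: n // 2], perm[n // 2: 3 * n // 4],
                         perm[3 * n // 4:])

    def test_perfectly_separable_latent_scores_100(self):
        n = 80
        labels = np.array(["a"] * 40 + ["b"] * 40)
        X = np.where(labels == "a", -5.0, 5.0)[:, None] * np.ones((n, 2))
        ls = LatentSpace(X + np.random.default_rng(0).normal(0, 0.1, (n, 2)),
                         [f"c{i}" for i in range(n)], "FE")
        rep = classify_latent(ls, labels, [self.fold_for(n)], seed=0)
        assert rep["accuracy"].iloc[0] == 100.0
        assert rep["balanced_accuracy"].iloc[0] == 100.0

    def test_stratified_chance_accuracy_matches_prevalence_identity(self):
        # 90/10 prevalence: expected chance accuracy = 0.9^2 + 0.1^2 = 82%
        rng = np.random.default_rng(1)
        n = 4000
        labels = np.array(["maj"] * int(n * 0.9) + ["min"] * int(n * 0.1))
        ls = LatentSpace(rng.normal(size=(n, 2)), [f"c{i}" for i in range(n)],
                         "PCA")
        rep = classify_latent(ls, labels, [self.fold_for(n, seed=2)], seed=0)
        assert rep["chance_accuracy"].iloc[0] == pytest.approx(82.0, abs=4.0)

    def test_majority_vote_balanced_accuracy(self):
        # a latent with no signal and 90/10 classes: RF approximates the
        # majority vote, so accuracy ~90% while balanced accuracy ~50%
        rng = np.random.default_rng(3)
        n = 1000
        labels = np.array(["maj"] * 900 + ["min"] * 100)
        ls = LatentSpace(rng.normal(size=(n, 1)) * 1e-9,
                         [f"c{i}" for i in range(n)], "PCA")
        rep = classify_latent(ls, labels, [self.fold_for(n, seed=4)], seed=0)
        assert rep["accuracy"].iloc[0] > 80.0
        assert rep["balanced_accuracy"].iloc[0] < 60.0


def test_umap_figure_writes_files_and_returns_paths_only(tmp_path):
    rng = np.random.default_rng(5)
    ls = LatentSpace(rng.normal(size=(40, 2)), [f"c{i}" for i in range(40)],
                     "FE")
    from mixedae.evaluation import umap_figure

    paths = umap_figure(ls, {"batch": rng.integers(0, 2, 40),
                             "cell_type": rng.integers(0, 3, 40)},
                        tmp_path, seed=1)
    assert len(paths) == 2
    for p in paths:
        assert (tmp_path / p.split("/")[-1]).exists()
    assert all(isinstance(p, str) for p in paths)  # no metric values returned
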