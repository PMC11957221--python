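"""Counterfactual projection panels and the Mann-Whitney contrast."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mixedae.counterfactual import (ProjectionPanel, build_projection_panel,
                                    project_to_batch, projection_contrast)


class TestProjectToBatch:
    def test_own_batch_projection_is_ordinary_reconstruction(self, tiny, tiny_re):
        vocab = tiny_re.batch_vocab_
        own = vocab[0]
        members = np.flatnonzero(tiny["design"].onehot[:, 0] == 1)[:10]
        from mixedae.data_model import BatchDesign

        sub = BatchDesign(tiny["design"].onehot[members], vocab)
        ordinary = tiny_re.reconstruct(tiny["X"][members], sub)
        projected = project_to_batch(tiny_re, tiny["X"][members], own)
        np.testing.assert_array_equal(ordinary, projected)

    def test_unknown_target_batch_rejected(self, tiny, tiny_re):
        with pytest.raises(ValueError, match="unknown"):
            project_to_batch(tiny_re, tiny["X"][:3], "no_such_batch")


class TestPanel:
    def test_row_count_and_metadata(self, tiny, tiny_fe, tiny_re):
        K = len(tiny_re.batch_vocab_)
        panel = build_projection_panel(tiny_re, tiny_fe, tiny["dataset"],
                                       tiny["X"], n=20, seed=0)
        assert panel.matrix.shape[0] == 20 * (1 + 1 + K)
        assert set(panel.metadata["target"]) == {"original", "FE",
                                                *tiny_re.batch_vocab_}

    def test_without_fe_rows(self, tiny, tiny_re):
        K = len(tiny_re.batch_vocab_)
        panel = build_projection_panel(tiny_re, None, tiny["dataset"],
                                       tiny["X"], n=15, seed=0)
        assert panel.matrix.shape[0] == 15 * (1 + K)

    def test_seeded_sampling_is_deterministic(self, tiny, tiny_fe, tiny_re):
        p1 = build_projection_panel(tiny_re, tiny_fe, tiny["dataset"],
                                    tiny["X"], n=20, seed=5)
        p2 = build_projection_panel(tiny_re, tiny_fe, tiny["dataset"],
                                    tiny["X"], n=20, seed=5)
        np.testing.assert_array_equal(p1.matrix, p2.matrix)
        assert p1.metadata.equals(p2.metadata)

    def test_standardized_columns(self, tiny, tiny_fe, tiny_re):
        panel = build_projection_panel(tiny_re, tiny_fe, tiny["dataset"],
                                       tiny["X"], n=20, seed=1)
        assert np.all(np.abs(panel.matrix.mean(axis=0)) < 1e-10)

    def test_oversized_request_takes_all_with_warning(self, tiny, tiny_fe, tiny_re):
        with pytest.warns(UserWarning, match="available"):
            panel = build_projection_panel(
                tiny_re, tiny_fe, tiny["dataset"], tiny["X"],
                cell_type=sorted(set(tiny["dataset"].cell_type_labels))[0],
                n=10_000, seed=0)
        assert panel.matrix.shape[0] > 0

    def test_unknown_cell_type_rejected(self, tiny, tiny_fe, tiny_re):
        with pytest.raises(ValueError, match="no cells"):
            build_projection_panel(tiny_re, tiny_fe, tiny["dataset"],
                                   tiny["X"], cell_type="unicorn", n=5, seed=0)


def synthetic_panel(rng, n_per=12, g=40, shift=None):
    rows, targets = [], []
    for grp in ("A", "B"):
        block = rng.normal(size=(n_per, g))
        if grp == "B" and shift is not None:
            block = block + shift
        rows.append(block)
        targets += [grp] * n_per
    M = np.vstack(rows)
    meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(M))],
                         "source_batch": "A", "target": targets})
    return ProjectionPanel(M, meta, [f"g{j}" for j in range(g)])


class TestContrast:
    def test_overlapping_groups_rejected(self, ):
        panel = synthetic_panel(np.random.default_rng(0))
        with pytest.raises(ValueError, match="overlap"):
            projection_contrast(panel, {"A"}, {"A", "B"})

    def test_empty_group_rejected(self):
        panel = synthetic_panel(np.random.default_rng(0))
        with pytest.raises(ValueError):
            projection_contrast(panel, {"A"}, {"C"})

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        panel = synthetic_panel(rng, n_per=30, g=400)
        table = projection_contrast(panel, {"A"}, {"B"}, alpha=0.05)
        frac = table["significant"].mean()
        # binomial(400, 0.05): 3 sd band around 0.05
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_spiked_gene_detected(self):
        rng = np.random.default_rng(7)
        g = 60
        shift = np.zeros(g)
        shift[17] = 5.0
        panel = synthetic_panel(rng, n_per=25, g=g, shift=shift)
        table = projection_contrast(panel, {"A"}, {"B"})
        assert bool(table.loc[table["gene"] == "g17", "significant"].iloc[0])
        assert table["significant"].mean() < 0.2

    def test_bh_column_is_monotone_transform(self):
        rng = np.random.default_rng(3)
        panel = synthetic_panel(rng, n_per=10, g=30)
        table = projection_contrast(panel, {"A"}, {"B"})
        assert (table["p_bh"] >= table["p"] - 1e-12).all()


def exact_mannwhitney_p(a, b):
    """Exhaustive rank-enumeration oracle for tie-free samples."""
    from itertools import combinations as combs

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    idx = np.arange(len(pooled))
    for chosen in combs(range(len(pooled)), n1):
        r = ranks[list(chosen)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    m = len(us)
    lo, hi = min(u_obs, n1 * len(b) - u_obs), max(u_obs, n1 * len(b) - u_obs)
    p = (np.sum(us <= lo) + np.sum(us >= hi)) / m
    return min(1.0, p)


@pytest.mark.parametrize("seed", range(6))
def test_contrast_pvalues_match_exhaustive_enumeration(seed):
    """Small-group contrast p-values agree with the rank-enumeration oracle."""
    rng = np.random.default_rng(seed)
    n1, n2 = int(rng.integers(3, 9)), int(rng.integers(3, 9))
    g = 5
    M = rng.normal(size=(n1 + n2, g))
    meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n1 + n2)],
                         "source_batch": "A",
                         "target": ["A"] * n1 + ["B"] * n2})
    panel = ProjectionPanel(M, meta, [f"g{j}" for j in range(g)])
    table = projection_contrast(panel, {"A"}, {"B"})
    for j in range(g):
        expected = exact_mannwhitney_p(M[:n1, j], M[n1:, j])
        assert table["p"].iloc[j] == pytest.approx(expected, abs=1e-12)
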