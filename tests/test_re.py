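"""Random-effects subnetwork: REDEN blocks, variational terms, training."""

import numpy as np
import pytest

from mixedae._engine import Tensor
from mixedae.data_model import BatchDesign
from mixedae.losses import gaussian_kl
from mixedae.re import RandomEffectsAutoencoder, REConfig


def manual_block(model, X, Z):
    """First REDEN block forward with explicit parameters, for hand checks."""
    return model._block_forward(0, Tensor(X), Tensor(Z), "posterior_mean",
                                model.params_, last=True).value


class TestREDENForward:
    @staticmethod
    def crafted_model():
        """One-block identity-dense model with hand-set slopes/biases."""
        m = RandomEffectsAutoencoder(encoder_sizes=(), latent_dim=2)
        p = m._init_params(n_genes=2, K=2)
        p["blk0_W"].value = np.eye(2)
        p["blk0_c"].value = np.zeros(2)
        p["blk0_gamma_mu"].value = np.array([[-0.5, 1.0], [0.0, 0.0]])
        p["blk0_b_mu"].value = np.array([[1.0, -1.0], [0.0, 0.0]])
        m.params_ = p
        m.n_genes_ = 2
        m.batch_vocab_ = ["a", "b"]
        return m

    def test_hand_computed_scale_shift(self):
        # d=[2,3], gamma=[-0.5,1], b=[1,-1] -> [(1-0.5)*2+1, (1+1)*3-1] = [2,5]
        m = self.crafted_model()
        out = manual_block(m, np.array([[2.0, 3.0]]), np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(out, [[2.0, 5.0]])

    def test_prior_mean_is_batch_agnostic_pass_through(self):
        m = self.crafted_model()
        X = np.array([[2.0, 3.0]])
        out = m._block_forward(0, Tensor(X), Tensor(np.array([[1.0, 0.0]])),
                               "prior_mean", m.params_, last=True).value
        np.testing.assert_allclose(out, X)  # identity dense, zero effects

    def test_sampling_is_seeded_and_repeatable(self, tiny, tiny_re):
        r1 = tiny_re.reconstruct(tiny["X"][:5], _subdesign(tiny, 5),
                                 mode="sample", sample_seed=123)
        r2 = tiny_re.reconstruct(tiny["X"][:5], _subdesign(tiny, 5),
                                 mode="sample", sample_seed=123)
        r3 = tiny_re.reconstruct(tiny["X"][:5], _subdesign(tiny, 5),
                                 mode="sample", sample_seed=124)
        np.testing.assert_array_equal(r1, r2)
        assert not np.allclose(r1, r3)


def _subdesign(tiny, n):
    return BatchDesign(tiny["design"].onehot[:n], tiny["design"].batch_vocab)


class TestTraining:
    def test_same_seed_identical_history(self, tiny):
        kwargs = dict(encoder_sizes=(16, 8), latent_dim=2, lambda_l=5.0,
                      lambda_k=0.02, learning_rate=1e-3, max_epochs=5,
                      patience=4, batch_size=64, seed=6)
        hists = []
        for _ in range(2):
            m = RandomEffectsAutoencoder(**kwargs)
            m.fit(tiny["X"], design=tiny["design"],
                  train_idx=tiny["fold"].train_cells,
                  val_idx=tiny["fold"].val_cells)
            hists.append(m.history_)
        assert hists[0].equals(hists[1])

    def test_unseen_training_batch_rejected(self, tiny):
        Z = tiny["design"].onehot.copy()
        Z = np.hstack([Z, np.zeros((len(Z), 1))])
        design = BatchDesign(Z, tiny["design"].batch_vocab + ["ghost"])
        m = RandomEffectsAutoencoder(encoder_sizes=(8, 4), max_epochs=3,
                                     patience=2, seed=0)
        with pytest.raises(ValueError, match="ghost"):
            m.fit(tiny["X"], design=design,
                  train_idx=tiny["fold"].train_cells,
                  val_idx=tiny["fold"].val_cells)

    def test_objective_decreases_most_epochs(self, tiny):
        m = RandomEffectsAutoencoder(encoder_sizes=(16, 8), latent_dim=2,
                                     lambda_l=5.0, lambda_k=0.02,
                                     learning_rate=1e-3, max_epochs=25,
                                     patience=20, batch_size=64, seed=1)
        m.fit(tiny["X"], design=tiny["design"],
              train_idx=tiny["fold"].train_cells, val_idx=tiny["fold"].val_cells)
        totals = m.history_["train_total"].to_numpy()
        decreases = np.diff(totals) < 0
        assert decreases.mean() >= 0.95

    def test_kl_shrinkage_monotone_in_weight(self, tiny):
        """Stronger KL regularization shrinks posterior means toward zero."""
        norms = []
        for lk in (0.0, 0.1, 10.0):
            m = RandomEffectsAutoencoder(encoder_sizes=(12, 6), latent_dim=2,
                                         lambda_l=1.0, lambda_k=lk,
                                         learning_rate=1e-3, max_epochs=20,
                                         patience=19, batch_size=64, seed=2)
            m.fit(tiny["X"], design=tiny["design"],
                  train_idx=tiny["fold"].train_cells,
                  val_idx=tiny["fold"].val_cells)
            total = sum(np.abs(m.params_[k].value).sum()
                        for k in m.params_ if k.endswith(("gamma_mu", "b_mu")))
            norms.append(total)
        assert norms[0] > norms[1] > norms[2]


class TestInference:
    def test_posterior_mean_deterministic(self, tiny, tiny_re):
        e1 = tiny_re.transform(tiny["X"], tiny["design"])
        e2 = tiny_re.transform(tiny["X"], tiny["design"])
        np.testing.assert_array_equal(e1, e2)
        assert e1.shape[1] == 2

    def test_prior_mean_ignores_batch_assignment(self, tiny, tiny_re):
        r1 = tiny_re.reconstruct(tiny["X"][:6], None, mode="prior_mean")
        # swapping batch rows cannot matter because Z is unused
        shuffled = BatchDesign(tiny["design"].onehot[:6][::-1].copy(),
                               tiny["design"].batch_vocab)
        r2 = tiny_re.reconstruct(tiny["X"][:6], shuffled, mode="prior_mean")
        np.testing.assert_array_equal(r1, r2)

    def test_unknown_batch_vocabulary_rejected(self, tiny, tiny_re):
        bad = BatchDesign(np.eye(2)[[0, 1]], ["nope", "alsono"])
        with pytest.raises(ValueError, match="nope"):
            tiny_re.transform(tiny["X"][:2], bad)

    def test_latent_classifier_probabilities(self, tiny, tiny_re):
        probs = tiny_re.predict_batch_proba(tiny["X"][:7], _subdesign(tiny, 7))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_posterior_table_covers_all_blocks_and_batches(self, tiny, tiny_re):
        table = tiny_re.posterior_table()
        K = tiny["design"].n_batches
        widths = tiny_re._block_widths(tiny_re.n_genes_)
        expected = K * sum(w for _, w in widths)
        assert len(table) == expected
        assert (table["gamma_scale"] > 0).all()
        assert (table["b_scale"] > 0).all()


def test_kl_closed_form_matches_monte_carlo():
    """Closed-form KL within 3 standard errors of a sampling estimate."""
    rng = np.random.default_rng(17)
    n = 100_000
    for _ in range(20):
        mu = rng.normal(0, 1.5)
        sigma = rng.uniform(0.2, 2.0)
        s = rng.uniform(0.2, 2.0)
        x = rng.normal(mu, sigma, size=n)
        log_q = -0.5 * np.log(2 * np.pi * sigma**2) - (x - mu) ** 2 / (2 * sigma**2)
        log_p = -0.5 * np.log(2 * np.pi * s**2) - x**2 / (2 * s**2)
        draws = log_q - log_p
        mc, se = draws.mean(), draws.std(ddof=1) / np.sqrt(n)
        assert abs(gaussian_kl(mu, sigma, s) - mc) < 3 * se


def test_config_validation():
    with pytest.raises(ValueError):
        REConfig(mc_samples=0)
    with pytest.raises(ValueError):
        REConfig(lambda_k=-0.1)
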