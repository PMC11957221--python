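"""Fixed-effects adversarial autoencoder.

A dense, weight-tied autoencoder whose encoder is trained against an
adversarial batch classifier: the adversary minimizes a cross-entropy
on the batch label from the encoder's intermediate activations, while
the autoencoder minimizes

    lambda_recon_f * MSE  -  lambda_a * CCE(batch)  [+ lambda_y * CCE(cell type)]

so reconstruction fidelity is traded against batch predictability.
The optional cell-type head (``lambda_y > 0``) turns the model into
its supervised variant.  With ``lambda_a = lambda_y = 0`` the trainer
is exactly a plain autoencoder (the ablation baseline).

Training is alternating per mini-batch: one adversary update on
detached encoder activations, then one autoencoder update with the
adversary frozen.  Optimization is Adam; early stopping monitors
validation reconstruction MSE and restores the best weights.

Weight initialization is Glorot-uniform draws from
``np.random.default_rng([seed, 0])`` consumed in layer order (encoder
dense layers first, then adversary, then cell-type head; decoder
weights are tied transposes and decoder biases start at zero), and the
epoch shuffling stream is ``np.random.default_rng([seed, 1])``.  The
scheme is documented so an independently coded network can reproduce
the exact trajectory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._engine import Adam, Tensor, concat, softmax
from .data_model import BatchDesign, CellTypeLabels, ExpressionDataset, FoldSplit, LatentSpace
from .losses import categorical_ce_t, cce_t, mse_t

__all__ = ["FEConfig", "FixedEffectsAutoencoder", "PlainAutoencoder",
           "train_fe", "encode_fe"]


@dataclass
class FEConfig:
    """Hyperparameters of the fixed-effects subnetwork."""

    encoder_sizes: tuple[int, ...] = (512, 132)
    latent_dim: int = 2
    activation: str = "selu"
    lambda_recon_f: float = 1.0
    lambda_a: float = 1.0
    lambda_y: float = 0.0  # > 0 enables the cell-type head (supervised variant)
    adversary_hidden_sizes: tuple[int, ...] | None = None  # defaults to encoder_sizes
    classifier_hidden_size: int = 64
    learning_rate: float = 1e-4
    max_epochs: int = 500
    patience: int = 30
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda_recon_f, self.lambda_a, self.lambda_y) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.activation not in ("selu", "relu"):
            raise ValueError("activation must be 'selu' or 'relu'")


def _glorot(rng: np.random.Generator, fin: int, fout: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fin + fout))
    return rng.uniform(-lim, lim, size=(fin, fout))


def _act(x: Tensor, kind: str) -> Tensor:
    if kind == "selu":
        return x.selu()
    return x.clip(0.0, np.inf)  # relu


class FixedEffectsAutoencoder(BaseEstimator, TransformerMixin):
    """Adversarially batch-regularized autoencoder (scikit-learn style).

    Parameters mirror :class:`FEConfig`.  ``fit`` expects an already
    standardized cells x genes matrix plus a one-hot batch design;
    ``transform`` returns the latent embedding.

    Attributes
    ----------
    params_ : dict[str, Tensor]
        Learned weights.  Decoder weight matrices are the transposes of
        the encoder matrices by construction (shared storage).
    history_ : pandas.DataFrame
        Per-epoch loss-term records.
    """

    def __init__(self, encoder_sizes=(512, 132), latent_dim=2, activation="selu",
                 lambda_recon_f=1.0, lambda_a=1.0, lambda_y=0.0,
                 adversary_hidden_sizes=None, classifier_hidden_size=64,
                 learning_rate=1e-4, max_epochs=500, patience=30,
                 batch_size=256, seed=0):
        self.encoder_sizes = encoder_sizes
        self.latent_dim = latent_dim
        self.activation = activation
        self.lambda_recon_f = lambda_recon_f
        self.lambda_a = lambda_a
        self.lambda_y = lambda_y
        self.adversary_hidden_sizes = adversary_hidden_sizes
        self.classifier_hidden_size = classifier_hidden_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.seed = seed

    # -- construction ----------------------------------------------------
    @property
    def config(self) -> FEConfig:
        return FEConfig(
            encoder_sizes=tuple(self.encoder_sizes), latent_dim=self.latent_dim,
            activation=self.activation, lambda_recon_f=self.lambda_recon_f,
            lambda_a=self.lambda_a, lambda_y=self.lambda_y,
            adversary_hidden_sizes=self.adversary_hidden_sizes,
            classifier_hidden_size=self.classifier_hidden_size,
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            patience=self.patience, batch_size=self.batch_size, seed=self.seed)

    def _init_params(self, n_genes: int, n_batches: int, n_types: int) -> dict[str, Tensor]:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 0])
        widths = [n_genes, *cfg.encoder_sizes, cfg.latent_dim]
        p: dict[str, Tensor] = {}
        for i in range(len(widths) - 1):
            p[f"enc_W{i}"] = Tensor(_glorot(rng, widths[i], widths[i + 1]), requires_grad=True)
            p[f"enc_b{i}"] = Tensor(np.zeros(widths[i + 1]), requires_grad=True)
        # decoder weights are tied (enc_Wi transposed in the forward pass);
        # only decoder biases are free parameters
        dec_widths = widths[::-1]
        for i in range(len(dec_widths) - 1):
            p[f"dec_b{i}"] = Tensor(np.zeros(dec_widths[i + 1]), requires_grad=True)
        if cfg.lambda_a > 0:
            adv_in = sum(cfg.encoder_sizes) + cfg.latent_dim
            adv_sizes = tuple(cfg.adversary_hidden_sizes or cfg.encoder_sizes)
            a_widths = [adv_in, *adv_sizes, n_batches]
            for i in range(len(a_widths) - 1):
                p[f"adv_W{i}"] = Tensor(_glorot(rng, a_widths[i], a_widths[i + 1]),
                                        requires_grad=True)
                p[f"adv_b{i}"] = Tensor(np.zeros(a_widths[i + 1]), requires_grad=True)
        if cfg.lambda_y > 0:
            p["head_W0"] = Tensor(_glorot(rng, cfg.latent_dim, cfg.classifier_hidden_size),
                                  requires_grad=True)
            p["head_b0"] = Tensor(np.zeros(cfg.classifier_hidden_size), requires_grad=True)
            p["head_W1"] = Tensor(_glorot(rng, cfg.classifier_hidden_size, n_types),
                                  requires_grad=True)
            p["head_b1"] = Tensor(np.zeros(n_types), requires_grad=True)
        return p

    # -- forward passes --------------------------------------------------
    def _encode_graph(self, X: Tensor, p: dict[str, Tensor]) -> tuple[Tensor, list[Tensor]]:
        cfg = self.config
        n_enc = len(cfg.encoder_sizes) + 1
        h = X
        hidden: list[Tensor] = []
        for i in range(n_enc):
            h = _act(h @ p[f"enc_W{i}"] + p[f"enc_b{i}"], cfg.activation)
            hidden.append(h)
        return hidden[-1], hidden

    def _decode_graph(self, latent: Tensor, p: dict[str, Tensor]) -> Tensor:
        cfg = self.config
        n_enc = len(cfg.encoder_sizes) + 1
        h = latent
        for i in range(n_enc):
            W = p[f"enc_W{n_enc - 1 - i}"].T  # tied weights
            h = h @ W + p[f"dec_b{i}"]
            if i < n_enc - 1:
                h = _act(h, cfg.activation)  # final layer linear
        return h

    def _adversary_graph(self, feats: Tensor, p: dict[str, Tensor]) -> Tensor:
        cfg = self.config
        adv_sizes = tuple(cfg.adversary_hidden_sizes or cfg.encoder_sizes)
        h = feats
        for i in range(len(adv_sizes)):
            h = _act(h @ p[f"adv_W{i}"] + p[f"adv_b{i}"], cfg.activation)
        i = len(adv_sizes)
        return softmax(h @ p[f"adv_W{i}"] + p[f"adv_b{i}"])

    def _head_graph(self, latent: Tensor, p: dict[str, Tensor]) -> Tensor:
        h = _act(latent @ p["head_W0"] + p["head_b0"], self.activation)
        return softmax(h @ p["head_W1"] + p["head_b1"])

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray | None = None, *,
            design: BatchDesign, labels: CellTypeLabels | None = None,
            train_idx: np.ndarray | None = None,
            val_idx: np.ndarray | None = None) -> "FixedEffectsAutoencoder":
        """Train on standardized expression; ``y`` is unused (sklearn API)."""
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        n, g = X.shape
        Z = design.onehot
        if Z.shape[0] != n:
            raise ValueError("design rows do not match X")
        if cfg.lambda_y > 0 and labels is None:
            raise ValueError("lambda_y > 0 requires cell-type labels")
        Y = labels.onehot if labels is not None else None

        if train_idx is None:
            split_rng = np.random.default_rng([cfg.seed, 9])
            perm = split_rng.permutation(n)
            n_val = max(1, int(round(0.1 * n)))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        train_idx = np.asarray(train_idx, dtype=int)
        val_idx = np.asarray(val_idx, dtype=int) if val_idx is not None else train_idx

        n_types = Y.shape[1] if Y is not None else 0
        p = self._init_params(g, Z.shape[1], n_types)
        ae_names = [k for k in p if k.startswith(("enc_", "dec_", "head_"))]
        adv_names = [k for k in p if k.startswith("adv_")]
        opt_ae = Adam([p[k] for k in ae_names], lr=cfg.learning_rate)
        opt_adv = Adam([p[k] for k in adv_names], lr=cfg.learning_rate) if adv_names else None

        shuffle_rng = np.random.default_rng([cfg.seed, 1])
        Xtr, Ztr = X[train_idx], Z[train_idx]
        Ytr = Y[train_idx] if Y is not None else None
        Xval = X[val_idx]

        best_val = np.inf
        best_params: dict[str, np.ndarray] | None = None
        wait = 0
        history: list[dict] = []

        for epoch in range(cfg.max_epochs):
            perm = shuffle_rng.permutation(len(train_idx))
            terms = {"recon": [], "adversarial": [], "celltype": [], "total": []}
            for start in range(0, len(perm), cfg.batch_size):
                mb = perm[start:start + cfg.batch_size]
                xb = Tensor(Xtr[mb])
                zb = Tensor(Ztr[mb])

                if opt_adv is not None:
                    # adversary step on detached encoder activations
                    _, hidden = self._encode_graph(xb, p)
                    feats = Tensor(np.concatenate([h.value for h in hidden], axis=1))
                    probs = self._adversary_graph(feats, p)
                    adv_loss = cce_t(zb, probs)
                    opt_adv.zero_grad()
                    adv_loss.backward()
                    opt_adv.step()

                # autoencoder step (adversary frozen)
                latent, hidden = self._encode_graph(xb, p)
                recon = self._decode_graph(latent, p)
                recon_loss = mse_t(xb, recon)
                total = cfg.lambda_recon_f * recon_loss
                adv_val = 0.0
                if opt_adv is not None:
                    feats = concat(hidden, axis=1)
                    probs = self._adversary_graph(feats, p)
                    adv_loss = cce_t(zb, probs)
                    total = total - cfg.lambda_a * adv_loss
                    adv_val = float(adv_loss.value)
                ct_val = 0.0
                if cfg.lambda_y > 0:
                    yb = Tensor(Ytr[mb])
                    ct_loss = categorical_ce_t(yb, self._head_graph(latent, p))
                    total = total + cfg.lambda_y * ct_loss
                    ct_val = float(ct_loss.value)
                for name, v in (("recon", float(recon_loss.value)),
                                ("adversarial", adv_val), ("celltype", ct_val),
                                ("total", float(total.value))):
                    if not np.isfinite(v):
                        raise RuntimeError(f"non-finite {name} loss at epoch {epoch}")
                    terms[name].append(v)
                opt_ae.zero_grad()
                if opt_adv is not None:
                    opt_adv.zero_grad()
                total.backward()
                opt_ae.step()

            val_recon = self._reconstruction_mse(Xval, p)
            if not np.isfinite(val_recon):
                raise RuntimeError(f"non-finite validation recon loss at epoch {epoch}")
            history.append({"epoch": epoch,
                            **{f"train_{k}": float(np.mean(v)) for k, v in terms.items()},
                            "val_recon": val_recon})
            if val_recon < best_val:
                best_val = val_recon
                best_params = {k: t.value.copy() for k, t in p.items()}
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break

        if best_params is not None:
            for k, t in p.items():
                t.value = best_params[k]
        self.params_ = p
        self.history_ = pd.DataFrame(history)
        self.n_genes_ = g
        self.batch_vocab_ = list(design.batch_vocab)
        self.best_val_recon_ = float(best_val)
        self.source_ = "FEC" if cfg.lambda_y > 0 else ("FE" if cfg.lambda_a > 0 else "AE")
        return self

    def _reconstruction_mse(self, X: np.ndarray, p: dict[str, Tensor]) -> float:
        latent, _ = self._encode_graph(Tensor(X), p)
        recon = self._decode_graph(latent, p)
        return float(np.mean(np.sum((X - recon.value) ** 2, axis=1)))

    # -- inference -------------------------------------------------------
    def transform(self, X: np.ndarray) -> np.ndarray:
        """Deterministic latent embedding of standardized expression."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_genes_:
            raise ValueError(f"expected {self.n_genes_} genes, got {X.shape[1]}")
        latent, _ = self._encode_graph(Tensor(X), self.params_)
        return latent.value

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_genes_:
            raise ValueError(f"expected {self.n_genes_} genes, got {X.shape[1]}")
        latent, _ = self._encode_graph(Tensor(X), self.params_)
        return self._decode_graph(latent, self.params_).value

    def predict_batch_proba(self, X: np.ndarray) -> np.ndarray:
        """Adversary's batch posterior for each cell."""
        if self.lambda_a <= 0:
            raise ValueError("model has no adversary (lambda_a = 0)")
        _, hidden = self._encode_graph(Tensor(np.asarray(X, dtype=float)), self.params_)
        feats = Tensor(np.concatenate([h.value for h in hidden], axis=1))
        return self._adversary_graph(feats, self.params_).value

    def predict_celltype_proba(self, X: np.ndarray) -> np.ndarray:
        if self.lambda_y <= 0:
            raise ValueError("model has no cell-type head (lambda_y = 0)")
        latent, _ = self._encode_graph(Tensor(np.asarray(X, dtype=float)), self.params_)
        return self._head_graph(latent, self.params_).value


class PlainAutoencoder(FixedEffectsAutoencoder):
    """Ablation baseline: the same trainer with the adversary disabled."""

    def __init__(self, encoder_sizes=(512, 132), latent_dim=2, activation="selu",
                 lambda_recon_f=1.0, learning_rate=1e-4, max_epochs=500,
                 patience=30, batch_size=256, seed=0):
        super().__init__(encoder_sizes=encoder_sizes, latent_dim=latent_dim,
                         activation=activation, lambda_recon_f=lambda_recon_f,
                         lambda_a=0.0, lambda_y=0.0,
                         learning_rate=learning_rate, max_epochs=max_epochs,
                         patience=patience, batch_size=batch_size, seed=seed)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_fe(dataset: ExpressionDataset | np.ndarray, design: BatchDesign,
             labels: CellTypeLabels | None = None, fold: FoldSplit | None = None,
             config: FEConfig | None = None) -> FixedEffectsAutoencoder:
    """Train a fixed-effects autoencoder on standardized expression."""
    config = config or FEConfig()
    X = dataset.counts if isinstance(dataset, ExpressionDataset) else np.asarray(dataset)
    model = FixedEffectsAutoencoder(**{k: v for k, v in asdict(config).items()})
    kwargs = {}
    if fold is not None:
        kwargs = {"train_idx": fold.train_cells, "val_idx": fold.val_cells}
    return model.fit(X, design=design, labels=labels, **kwargs)


def encode_fe(model: FixedEffectsAutoencoder, X: np.ndarray,
              cell_ids: list[str] | None = None,
              fold_index: int | None = None) -> LatentSpace:
    emb = model.transform(X)
    ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(len(emb))]
    return LatentSpace(emb, ids, source=model.source_, fold_index=fold_index,
                       seed=model.seed)
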