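"""Random-effects Bayesian autoencoder.

Each layer is a random-effects dense (REDEN) block: a dense layer whose
output ``d`` is rescaled and shifted in a batch-dependent manner,

    out = activation( (1 + gamma(z)) * d + b(z) )

with per-batch slope ``gamma(z)`` and bias ``b(z)`` carrying
fully-factorized Gaussian variational posteriors (one mean/scale pair
per batch x unit) against zero-mean priors ``N(0, sigma_gamma^2)`` and
``N(0, sigma_b^2)`` whose scales are learnable scalars shared across
batches.  The slope is applied as ``1 + gamma`` so the zero-mean prior
is the identity rescale and ``prior_mean`` mode is a batch-agnostic
pass-through.

A small batch classifier on the bottleneck rewards batch-predictive
latents.  The minimized objective is the negative-ELBO form

    lambda_recon_r * MSE + lambda_l * CCE(z, zhat_L) + lambda_k * KL(q || p)

trained with reparameterized single-sample gradients (``mc_samples``
configurable), Adam, and early stopping on validation total loss.
No weight tying is used in this subnetwork.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._engine import Adam, Tensor, softmax
from .data_model import BatchDesign, ExpressionDataset, FoldSplit, LatentSpace
from .losses import cce_t, gaussian_kl_t, mse_t

__all__ = ["REConfig", "RandomEffectsAutoencoder", "train_re", "encode_re",
           "reconstruct_re"]

_MODES = ("sample", "posterior_mean", "prior_mean")
# softplus^-1(0.05): posteriors start narrow around zero
_RHO_INIT = float(np.log(np.expm1(0.05)))
# softplus^-1(1.0): prior scales start at 1
_PRIOR_RHO_INIT = float(np.log(np.expm1(1.0)))


@dataclass
class REConfig:
    """Hyperparameters of the random-effects subnetwork."""

    encoder_sizes: tuple[int, ...] = (512, 132)
    latent_dim: int = 2
    activation: str = "selu"
    lambda_recon_r: float = 1.0
    lambda_l: float = 1.0
    lambda_k: float = 1e-3
    mc_samples: int = 1
    classifier_hidden_size: int = 64
    learning_rate: float = 1e-4
    max_epochs: int = 500
    patience: int = 30
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda_recon_r, self.lambda_l, self.lambda_k) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class RandomEffectsAutoencoder(BaseEstimator, TransformerMixin):
    """Batch-aware Bayesian autoencoder (scikit-learn style).

    ``fit`` expects standardized expression plus a one-hot batch
    design; ``transform`` returns the (posterior-mean) latent and
    ``reconstruct`` the decoded expression, optionally under a
    counterfactual batch assignment.
    """

    def __init__(self, encoder_sizes=(512, 132), latent_dim=2, activation="selu",
                 lambda_recon_r=1.0, lambda_l=1.0, lambda_k=1e-3, mc_samples=1,
                 classifier_hidden_size=64, learning_rate=1e-4, max_epochs=500,
                 patience=30, batch_size=256, seed=0):
        self.encoder_sizes = encoder_sizes
        self.latent_dim = latent_dim
        self.activation = activation
        self.lambda_recon_r = lambda_recon_r
        self.lambda_l = lambda_l
        self.lambda_k = lambda_k
        self.mc_samples = mc_samples
        self.classifier_hidden_size = classifier_hidden_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.seed = seed

    @property
    def config(self) -> REConfig:
        return REConfig(
            encoder_sizes=tuple(self.encoder_sizes), latent_dim=self.latent_dim,
            activation=self.activation, lambda_recon_r=self.lambda_recon_r,
            lambda_l=self.lambda_l, lambda_k=self.lambda_k,
            mc_samples=self.mc_samples,
            classifier_hidden_size=self.classifier_hidden_size,
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            patience=self.patience, batch_size=self.batch_size, seed=self.seed)

    # -- construction ----------------------------------------------------
    def _block_widths(self, n_genes: int) -> list[tuple[int, int]]:
        enc = [n_genes, *self.config.encoder_sizes, self.config.latent_dim]
        dec = enc[::-1]
        pairs = [(enc[i], enc[i + 1]) for i in range(len(enc) - 1)]
        pairs += [(dec[i], dec[i + 1]) for i in range(len(dec) - 1)]
        return pairs

    def _init_params(self, n_genes: int, K: int) -> dict[str, Tensor]:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 0])
        p: dict[str, Tensor] = {}
        for l, (fin, fout) in enumerate(self._block_widths(n_genes)):
            lim = np.sqrt(6.0 / (fin + fout))
            p[f"blk{l}_W"] = Tensor(rng.uniform(-lim, lim, size=(fin, fout)),
                                    requires_grad=True)
            p[f"blk{l}_c"] = Tensor(np.zeros(fout), requires_grad=True)
            for kind in ("gamma", "b"):
                p[f"blk{l}_{kind}_mu"] = Tensor(np.zeros((K, fout)), requires_grad=True)
                p[f"blk{l}_{kind}_rho"] = Tensor(np.full((K, fout), _RHO_INIT),
                                                 requires_grad=True)
                p[f"blk{l}_{kind}_prior_rho"] = Tensor(np.array(_PRIOR_RHO_INIT),
                                                       requires_grad=True)
        lim = np.sqrt(6.0 / (cfg.latent_dim + cfg.classifier_hidden_size))
        p["cls_W0"] = Tensor(rng.uniform(-lim, lim,
                                         (cfg.latent_dim, cfg.classifier_hidden_size)),
                             requires_grad=True)
        p["cls_b0"] = Tensor(np.zeros(cfg.classifier_hidden_size), requires_grad=True)
        lim = np.sqrt(6.0 / (cfg.classifier_hidden_size + K))
        p["cls_W1"] = Tensor(rng.uniform(-lim, lim, (cfg.classifier_hidden_size, K)),
                             requires_grad=True)
        p["cls_b1"] = Tensor(np.zeros(K), requires_grad=True)
        return p

    # -- forward ---------------------------------------------------------
    def _block_forward(self, l: int, x: Tensor, Zb: Tensor, mode: str,
                       p: dict[str, Tensor], last: bool,
                       eps: dict[str, np.ndarray] | None = None) -> Tensor:
        d = x @ p[f"blk{l}_W"] + p[f"blk{l}_c"]
        if mode == "prior_mean":
            out = d  # gamma = 0, b = 0: batch-agnostic pass-through
        else:
            if mode == "sample":
                g_full = p[f"blk{l}_gamma_mu"] + \
                    p[f"blk{l}_gamma_rho"].softplus() * Tensor(eps[f"blk{l}_gamma"])
                b_full = p[f"blk{l}_b_mu"] + \
                    p[f"blk{l}_b_rho"].softplus() * Tensor(eps[f"blk{l}_b"])
            else:  # posterior_mean
                g_full = p[f"blk{l}_gamma_mu"]
                b_full = p[f"blk{l}_b_mu"]
            gamma = Zb @ g_full
            bias = Zb @ b_full
            out = (1.0 + gamma) * d + bias
        if last:
            return out  # final decoder layer is linear
        return out.selu() if self.activation == "selu" else out.clip(0.0, np.inf)

    def _forward(self, X: Tensor, Zb: Tensor, mode: str, p: dict[str, Tensor],
                 eps: dict[str, np.ndarray] | None = None
                 ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (latent, reconstruction, batch classifier probabilities)."""
        n_blocks = len(self._block_widths(X.shape[1]))
        n_enc = n_blocks // 2
        h = X
        for l in range(n_enc):
            h = self._block_forward(l, h, Zb, mode, p, last=False, eps=eps)
        latent = h
        for l in range(n_enc, n_blocks):
            h = self._block_forward(l, h, Zb, mode, p, last=(l == n_blocks - 1), eps=eps)
        cls_h = (latent @ p["cls_W0"] + p["cls_b0"]).selu()
        probs = softmax(cls_h @ p["cls_W1"] + p["cls_b1"])
        return latent, h, probs

    def _kl_total(self, p: dict[str, Tensor], n_genes: int) -> Tensor:
        total = None
        for l in range(len(self._block_widths(n_genes))):
            for kind in ("gamma", "b"):
                kl = gaussian_kl_t(p[f"blk{l}_{kind}_mu"],
                                   p[f"blk{l}_{kind}_rho"].softplus(),
                                   p[f"blk{l}_{kind}_prior_rho"].softplus())
                total = kl if total is None else total + kl
        return total

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray | None = None, *,
            design: BatchDesign, train_idx: np.ndarray | None = None,
            val_idx: np.ndarray | None = None) -> "RandomEffectsAutoencoder":
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        n, g = X.shape
        Z = design.onehot
        if Z.shape[0] != n:
            raise ValueError("design rows do not match X")

        if train_idx is None:
            split_rng = np.random.default_rng([cfg.seed, 9])
            perm = split_rng.permutation(n)
            n_val = max(1, int(round(0.1 * n)))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        train_idx = np.asarray(train_idx, dtype=int)
        val_idx = np.asarray(val_idx, dtype=int) if val_idx is not None else train_idx

        empty = np.flatnonzero(Z[train_idx].sum(axis=0) == 0)
        if len(empty):
            names = [design.batch_vocab[j] for j in empty]
            raise ValueError(f"batches never seen in training cells: {names}")

        p = self._init_params(g, Z.shape[1])
        opt = Adam(list(p.values()), lr=cfg.learning_rate)
        shuffle_rng = np.random.default_rng([cfg.seed, 1])
        sample_rng = np.random.default_rng([cfg.seed, 2])

        Xtr, Ztr = X[train_idx], Z[train_idx]
        Xval, Zval = X[val_idx], Z[val_idx]
        n_blocks = len(self._block_widths(g))

        best_val = np.inf
        best_params = None
        wait = 0
        history: list[dict] = []

        for epoch in range(cfg.max_epochs):
            perm = shuffle_rng.permutation(len(train_idx))
            terms = {"recon": [], "batch_ce": [], "kl": [], "total": []}
            for start in range(0, len(perm), cfg.batch_size):
                mb = perm[start:start + cfg.batch_size]
                xb, zb = Tensor(Xtr[mb]), Tensor(Ztr[mb])
                kl = self._kl_total(p, g)
                recon_acc = None
                ce_acc = None
                for _ in range(cfg.mc_samples):
                    eps = {}
                    for l in range(n_blocks):
                        for kind in ("gamma", "b"):
                            shape = p[f"blk{l}_{kind}_mu"].shape
                            eps[f"blk{l}_{kind}"] = sample_rng.standard_normal(shape)
                    _, recon, probs = self._forward(xb, zb, "sample", p, eps)
                    r = mse_t(xb, recon)
                    c = cce_t(zb, probs)
                    recon_acc = r if recon_acc is None else recon_acc + r
                    ce_acc = c if ce_acc is None else ce_acc + c
                recon_loss = recon_acc / float(cfg.mc_samples)
                ce_loss = ce_acc / float(cfg.mc_samples)
                total = cfg.lambda_recon_r * recon_loss + cfg.lambda_l * ce_loss \
                    + cfg.lambda_k * kl
                for name, v in (("recon", float(recon_loss.value)),
                                ("batch_ce", float(ce_loss.value)),
                                ("kl", float(kl.value)),
                                ("total", float(total.value))):
                    if not np.isfinite(v):
                        raise RuntimeError(f"non-finite {name} loss at epoch {epoch}")
                    terms[name].append(v)
                opt.zero_grad()
                total.backward()
                opt.step()

            val = self._eval_total(Xval, Zval, p)
            history.append({"epoch": epoch,
                            **{f"train_{k}": float(np.mean(v)) for k, v in terms.items()},
                            "val_total": val["total"], "val_recon": val["recon"]})
            if val["total"] < best_val:
                best_val = val["total"]
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
        self.best_val_total_ = float(best_val)
        self.source_ = "RE"
        return self

    def _eval_total(self, X: np.ndarray, Z: np.ndarray,
                    p: dict[str, Tensor]) -> dict[str, float]:
        cfg = self.config
        _, recon, probs = self._forward(Tensor(X), Tensor(Z), "posterior_mean", p)
        recon_v = float(np.mean(np.sum((X - recon.value) ** 2, axis=1)))
        P = np.clip(probs.value, 1e-7, 1 - 1e-7)
        ce = float(-np.mean((Z * np.log(P) + (1 - Z) * np.log(1 - P)).sum(axis=1)))
        kl = float(self._kl_total(p, X.shape[1]).value)
        return {"recon": recon_v, "batch_ce": ce, "kl": kl,
                "total": cfg.lambda_recon_r * recon_v + cfg.lambda_l * ce
                + cfg.lambda_k * kl}

    # -- inference -------------------------------------------------------
    def _check_design(self, design: BatchDesign, strict: bool = True) -> None:
        unknown = [b for b in design.batch_vocab if b not in self.batch_vocab_]
        if unknown and strict:
            raise ValueError(f"unknown batches: {unknown}")
        if design.batch_vocab != self.batch_vocab_ and not unknown:
            raise ValueError("batch vocabulary order does not match the trained model")

    def _prep_inputs(self, X, design, mode):
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_genes_:
            raise ValueError(f"expected {self.n_genes_} genes, got {X.shape[1]}")
        if mode != "prior_mean":
            self._check_design(design)
            Z = design.onehot
            if Z.shape[0] != X.shape[0]:
                raise ValueError("design rows do not match X rows")
        else:
            Z = np.zeros((X.shape[0], len(self.batch_vocab_)))
            Z[:, 0] = 1.0  # ignored by prior_mean forward; placeholder shape
        return X, Z

    def _sample_eps(self, seed: int | None) -> dict[str, np.ndarray]:
        rng = np.random.default_rng([self.seed, 3] if seed is None else seed)
        eps = {}
        for l in range(len(self._block_widths(self.n_genes_))):
            for kind in ("gamma", "b"):
                eps[f"blk{l}_{kind}"] = rng.standard_normal(
                    self.params_[f"blk{l}_{kind}_mu"].shape)
        return eps

    def transform(self, X: np.ndarray, design: BatchDesign | None = None,
                  mode: str = "posterior_mean", sample_seed: int | None = None
                  ) -> np.ndarray:
        X, Z = self._prep_inputs(X, design, mode)
        eps = self._sample_eps(sample_seed) if mode == "sample" else None
        latent, _, _ = self._forward(Tensor(X), Tensor(Z), mode, self.params_, eps)
        return latent.value

    def reconstruct(self, X: np.ndarray, design: BatchDesign | None = None,
                    mode: str = "posterior_mean", sample_seed: int | None = None
                    ) -> np.ndarray:
        X, Z = self._prep_inputs(X, design, mode)
        eps = self._sample_eps(sample_seed) if mode == "sample" else None
        _, recon, _ = self._forward(Tensor(X), Tensor(Z), mode, self.params_, eps)
        return recon.value

    def predict_batch_proba(self, X: np.ndarray, design: BatchDesign | None = None,
                            mode: str = "posterior_mean") -> np.ndarray:
        X, Z = self._prep_inputs(X, design, mode)
        _, _, probs = self._forward(Tensor(X), Tensor(Z), mode, self.params_, None)
        return probs.value

    def posterior_table(self) -> pd.DataFrame:
        """Per-batch posterior means/scales for every REDEN unit."""
        rows = []
        for l in range(len(self._block_widths(self.n_genes_))):
            g_mu = self.params_[f"blk{l}_gamma_mu"].value
            g_sc = _softplus(self.params_[f"blk{l}_gamma_rho"].value)
            b_mu = self.params_[f"blk{l}_b_mu"].value
            b_sc = _softplus(self.params_[f"blk{l}_b_rho"].value)
            K, units = g_mu.shape
            for j in range(K):
                for u in range(units):
                    rows.append({"batch": self.batch_vocab_[j], "layer": l, "unit": u,
                                 "gamma_mean": g_mu[j, u], "gamma_scale": g_sc[j, u],
                                 "b_mean": b_mu[j, u], "b_scale": b_sc[j, u]})
        return pd.DataFrame(rows)

    def output_bias_posterior_mean(self) -> np.ndarray:
        """Posterior-mean per-gene biases of the decoder output block (K x g)."""
        last = len(self._block_widths(self.n_genes_)) - 1
        return self.params_[f"blk{last}_b_mu"].value.copy()


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_re(dataset: ExpressionDataset | np.ndarray, design: BatchDesign,
             fold: FoldSplit | None = None,
             config: REConfig | None = None) -> RandomEffectsAutoencoder:
    config = config or REConfig()
    X = dataset.counts if isinstance(dataset, ExpressionDataset) else np.asarray(dataset)
    model = RandomEffectsAutoencoder(**asdict(config))
    kwargs = {}
    if fold is not None:
        kwargs = {"train_idx": fold.train_cells, "val_idx": fold.val_cells}
    return model.fit(X, design=design, **kwargs)


def encode_re(model: RandomEffectsAutoencoder, X: np.ndarray, design: BatchDesign,
              mode: str = "posterior_mean", cell_ids: list[str] | None = None,
              fold_index: int | None = None) -> LatentSpace:
    emb = model.transform(X, design, mode=mode)
    ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(len(emb))]
    return LatentSpace(emb, ids, source="RE", fold_index=fold_index, seed=model.seed)


def reconstruct_re(model: RandomEffectsAutoencoder, X: np.ndarray,
                   design: BatchDesign, mode: str = "posterior_mean") -> np.ndarray:
    return model.reconstruct(X, design, mode=mode)
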