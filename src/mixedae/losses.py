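"""Loss terms for the fixed- and random-effects subnetworks.

Conventions, chosen to match the model definitions exactly and kept
identical between the public numpy functions (used for reporting and
testing) and the in-graph Tensor versions (used for training):

* ``mse_loss`` is the mean over cells of the squared Euclidean norm of
  the residual — NOT additionally averaged over genes.
* ``cce_loss`` is the element-wise binary cross-entropy summed over
  classes and averaged over cells:
  ``-(1/n) sum_i sum_k [z log zhat + (1-z) log(1-zhat)]``.
  This is the printed form of the adversarial/batch-classifier loss;
  a standard categorical cross-entropy (``categorical_ce``) is also
  provided and is used for the cell-type head.
* Probabilities are clipped to ``[eps, 1-eps]`` with ``eps = 1e-7``
  before logarithms.
* ``gaussian_kl`` is the closed-form KL between a diagonal Gaussian
  posterior ``N(mu, sigma^2)`` and a zero-mean prior ``N(0, s^2)``.
"""

from __future__ import annotations

import numpy as np

from ._engine import Tensor

CLIP_EPS = 1e-7

__all__ = ["mse_loss", "cce_loss", "categorical_ce", "gaussian_kl",
           "fe_loss", "re_loss"]


# ---------------------------------------------------------------------------
# public numpy implementations
# ---------------------------------------------------------------------------

def mse_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean over cells of the squared residual norm."""
    X, X_hat = np.asarray(X, dtype=float), np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(np.mean(np.sum((X - X_hat) ** 2, axis=1)))


def _check_onehot(Z: np.ndarray) -> None:
    if not (np.isin(Z, (0.0, 1.0)).all() and np.allclose(Z.sum(axis=1), 1.0)):
        raise ValueError("rows of Z must be one-hot")


def cce_loss(Z: np.ndarray, Z_hat: np.ndarray) -> float:
    """Element-wise binary cross-entropy summed over classes, mean over cells."""
    Z, Z_hat = np.asarray(Z, dtype=float), np.asarray(Z_hat, dtype=float)
    if Z.shape != Z_hat.shape:
        raise ValueError(f"shape mismatch: {Z.shape} vs {Z_hat.shape}")
    _check_onehot(Z)
    P = np.clip(Z_hat, CLIP_EPS, 1.0 - CLIP_EPS)
    terms = Z * np.log(P) + (1.0 - Z) * np.log(1.0 - P)
    return float(-np.mean(terms.sum(axis=1)))


def categorical_ce(Y: np.ndarray, P: np.ndarray) -> float:
    """Standard categorical cross-entropy, mean over cells."""
    Y, P = np.asarray(Y, dtype=float), np.asarray(P, dtype=float)
    if Y.shape != P.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {P.shape}")
    _check_onehot(Y)
    P = np.clip(P, CLIP_EPS, 1.0 - CLIP_EPS)
    return float(-np.mean((Y * np.log(P)).sum(axis=1)))


def gaussian_kl(post_mean, post_scale, prior_scale):
    """KL( N(mu, sigma^2) || N(0, s^2) ), elementwise; scalar for scalars.

    ``log(s/sigma) + (sigma^2 + mu^2) / (2 s^2) - 1/2``
    """
    mu = np.asarray(post_mean, dtype=float)
    sigma = np.asarray(post_scale, dtype=float)
    s = np.asarray(prior_scale, dtype=float)
    if np.any(sigma <= 0) or np.any(s <= 0):
        raise ValueError("scales must be strictly positive")
    kl = np.log(s / sigma) + (sigma**2 + mu**2) / (2.0 * s**2) - 0.5
    return float(kl) if kl.ndim == 0 else kl


def fe_loss(X, X_hat, Z, Z_hat_adv, lambda_recon_f: float = 1.0,
            lambda_a: float = 0.0, lambda_y: float = 0.0,
            Y=None, Y_hat=None) -> dict[str, float]:
    """Fixed-effects objective: ``lr*MSE - la*CCE(Z) [+ ly*CCE(y)]``.

    The adversarial term enters with a minus sign: a successful
    adversary makes the total loss more negative, which is what the
    encoder is trained against.  With ``lambda_y > 0`` the cell-type
    classification term of the supervised variant is added.
    """
    recon = mse_loss(X, X_hat)
    adv = cce_loss(Z, Z_hat_adv)
    out = {"recon": recon, "adversarial": adv}
    total = lambda_recon_f * recon - lambda_a * adv
    if lambda_y > 0:
        if Y is None or Y_hat is None:
            raise ValueError("lambda_y > 0 requires cell-type labels and predictions")
        ct = categorical_ce(Y, Y_hat)
        out["celltype"] = ct
        total += lambda_y * ct
    else:
        out["celltype"] = 0.0
    out["total"] = total
    return out


def re_loss(X, X_hat, Z, Z_hat_latent, kl_total: float,
            lambda_recon_r: float = 1.0, lambda_l: float = 1.0,
            lambda_k: float = 1.0) -> dict[str, float]:
    """Random-effects objective: ``lr*MSE + ll*CCE(Z) + lk*KL`` (negative ELBO form)."""
    recon = mse_loss(X, X_hat)
    batch_ce = cce_loss(Z, Z_hat_latent)
    kl_total = float(kl_total)
    total = lambda_recon_r * recon + lambda_l * batch_ce + lambda_k * kl_total
    return {"total": total, "recon": recon, "batch_ce": batch_ce, "kl": kl_total}


# ---------------------------------------------------------------------------
# in-graph Tensor versions (identical formulas)
# ---------------------------------------------------------------------------

def mse_t(X: Tensor, X_hat: Tensor) -> Tensor:
    return (X - X_hat).square().sum(axis=1).mean()


def cce_t(Z: Tensor, P: Tensor) -> Tensor:
    P = P.clip(CLIP_EPS, 1.0 - CLIP_EPS)
    terms = Z * P.log() + (1.0 - Z) * (1.0 - P).log()
    return -(terms.sum(axis=1).mean())


def categorical_ce_t(Y: Tensor, P: Tensor) -> Tensor:
    P = P.clip(CLIP_EPS, 1.0 - CLIP_EPS)
    return -((Y * P.log()).sum(axis=1).mean())


def gaussian_kl_t(mu: Tensor, sigma: Tensor, s: Tensor) -> Tensor:
    """Closed-form KL as a graph node; summed over all entries."""
    kl = (s / sigma).log() + (sigma.square() + mu.square()) / (2.0 * s.square()) - 0.5
    return kl.sum()
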