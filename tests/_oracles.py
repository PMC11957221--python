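"""Independent reference implementations used as test oracles.

``train_reference_autoencoder`` is a from-scratch, manual-gradient
implementation of a weight-tied SELU autoencoder trained with Adam and
validation-MSE early stopping.  It shares no code with the package's
training loop; it only follows the same documented initialization and
shuffling scheme (Glorot-uniform draws from ``default_rng([seed, 0])``
in encoder-layer order, shuffling stream ``default_rng([seed, 1])``)
so trajectories are comparable.
"""

from __future__ import annotations

import numpy as np

_A = 1.6732632423543772848170429916717
_S = 1.0507009873554804934193349852946


def _selu(x):
    return _S * np.where(x > 0, x, _A * (np.exp(np.minimum(x, 0.0)) - 1.0))


def _dselu(x):
    return _S * np.where(x > 0, 1.0, _A * np.exp(np.minimum(x, 0.0)))


def train_reference_autoencoder(X, hidden_sizes, latent_dim, lr, max_epochs,
                                patience, batch_size, seed, train_idx, val_idx):
    """Returns the best validation reconstruction MSE (mean squared norm)."""
    rng = np.random.default_rng([seed, 0])
    widths = [X.shape[1], *hidden_sizes, latent_dim]
    n_layers = len(widths) - 1
    Ws, bs = [], []
    for i in range(n_layers):
        lim = np.sqrt(6.0 / (widths[i] + widths[i + 1]))
        Ws.append(rng.uniform(-lim, lim, (widths[i], widths[i + 1])))
        bs.append(np.zeros(widths[i + 1]))
    dec_b = [np.zeros(w) for w in widths[::-1][1:]]

    params = Ws + bs + dec_b
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    shuffle_rng = np.random.default_rng([seed, 1])
    Xtr, Xval = X[train_idx], X[val_idx]

    def forward(xb):
        acts, pre, dpre = [xb], [], []
        h = xb
        for i in range(n_layers):
            z = h @ Ws[i] + bs[i]
            pre.append(z)
            h = _selu(z)
            acts.append(h)
        for i in range(n_layers):
            z = h @ Ws[n_layers - 1 - i].T + dec_b[i]
            dpre.append(z)
            h = _selu(z) if i < n_layers - 1 else z
            acts.append(h)
        return acts, pre, dpre

    def val_mse():
        acts, _, _ = forward(Xval)
        return float(np.mean(np.sum((Xval - acts[-1]) ** 2, axis=1)))

    best, wait = np.inf, 0
    for _ in range(max_epochs):
        perm = shuffle_rng.permutation(len(train_idx))
        for s0 in range(0, len(perm), batch_size):
            mb = perm[s0:s0 + batch_size]
            xb = Xtr[mb]
            acts, pre, dpre = forward(xb)
            gW = [np.zeros_like(w) for w in Ws]
            gb = [np.zeros_like(b) for b in bs]
            gdb = [np.zeros_like(b) for b in dec_b]
            delta = 2.0 * (acts[-1] - xb) / len(mb)
            dec_inputs = [acts[n_layers + i] for i in range(n_layers)]
            for i in reversed(range(n_layers)):
                delta_z = delta * _dselu(dpre[i]) if i < n_layers - 1 else delta
                gdb[i] += delta_z.sum(axis=0)
                gW[n_layers - 1 - i] += (dec_inputs[i].T @ delta_z).T
                delta = delta_z @ Ws[n_layers - 1 - i]
            for i in reversed(range(n_layers)):
                delta_z = delta * _dselu(pre[i])
                gb[i] += delta_z.sum(axis=0)
                gW[i] += acts[i].T @ delta_z
                delta = delta_z @ Ws[i].T
            grads = gW + gb + gdb
            t += 1
            for j, (p, g) in enumerate(zip(params, grads)):
                m[j] = 0.9 * m[j] + 0.1 * g
                v[j] = 0.999 * v[j] + 0.001 * g * g
                p -= lr * (m[j] / (1 - 0.9 ** t)) / (
                    np.sqrt(v[j] / (1 - 0.999 ** t)) + 1e-8)
        vm = val_mse()
        if vm < best:
            best, wait = vm, 0
        else:
            wait += 1
            if wait >= patience:
                break
    return best
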