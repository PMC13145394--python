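"""Minimal dense network with an optional per-person embedding table.

A small feed-forward regressor (ReLU hidden layers, linear output, squared
error, Adam) written on numpy.  The embedding variant owns a table of
per-participant vectors that are concatenated with the feature vector before
the first layer; a freeze mask allows training only selected embedding rows,
which is exactly the partial fine-tuning contract needed for new-user
adaptation (all dense weights frozen, only new embedding rows move).
"""

from __future__ import annotations

import numpy as np


class _Adam:
    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class DenseNet:
    """Fully connected ReLU network with a linear output node."""

    def __init__(self, n_in, hidden=(64, 32), rng=None, weight_scale=None):
        rng = rng or np.random.default_rng(0)
        dims = [n_in, *hidden, 1]
        self.W, self.b = [], []
        for i in range(len(dims) - 1):
            scale = weight_scale or np.sqrt(2.0 / dims[i])
            self.W.append(rng.normal(0, scale, (dims[i], dims[i + 1])))
            self.b.append(np.zeros(dims[i + 1]))

    def params(self):
        return self.W + self.b

    def forward(self, X):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h[:, 0], acts

    def backward(self, acts, dloss):
        """Gradients of the loss; returns (dW list, db list, dX)."""
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        delta = dloss[:, None]  # (n, 1)
        for i in range(len(self.W) - 1, -1, -1):
            dW[i] = acts[i].T @ delta
            db[i] = delta.sum(axis=0)
            delta = delta @ self.W[i].T
            if i > 0:
                delta *= acts[i] > 0
        return dW, db, delta

    def predict(self, X):
        return self.forward(X)[0]


def train_dense(
    net: DenseNet,
    X: np.ndarray,
    y: np.ndarray,
    epochs=200,
    batch_size=64,
    lr=1e-3,
    l2=1e-4,
    rng=None,
    embedding=None,
    group_rows=None,
    trainable_rows=None,
    freeze_dense=False,
):
    """Mini-batch Adam training; optionally with an embedding table.

    ``embedding`` is an (n_ids, d) array; ``group_rows`` maps each sample to
    its embedding row.  When given, the network input is
    [embedding[row], X].  ``trainable_rows`` restricts which embedding rows
    receive updates; ``freeze_dense`` stops all dense-weight updates (used
    for new-user fine-tuning).  Returns the per-epoch training loss curve.
    """
    rng = rng or np.random.default_rng(0)
    n = len(X)
    use_emb = embedding is not None
    dense_params = net.params()
    opt_dense = _Adam([p.shape for p in dense_params], lr=lr)
    if use_emb:
        opt_emb = _Adam([embedding.shape], lr=lr)
    max_norm = 5.0  # global gradient clip keeps Adam stable at higher lr
    curve = []
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            xb = X[idx]
            if use_emb:
                rows = group_rows[idx]
                xb = np.concatenate([embedding[rows], xb], axis=1)
            pred, acts = net.forward(xb)
            err = pred - y[idx]
            total += float(np.sum(err ** 2))
            dloss = 2.0 * err / len(idx)
            dW, db, dX = net.backward(acts, dloss)
            if not freeze_dense:
                grads = [g + l2 * p for g, p in zip(dW, net.W)] + db
                gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if gnorm > max_norm:
                    grads = [g * (max_norm / gnorm) for g in grads]
                opt_dense.step(dense_params, grads)
            if use_emb:
                # the first d input columns are the embedding slice
                demb_rows = dX[:, : embedding.shape[1]]
                grad_table = np.zeros_like(embedding)
                np.add.at(grad_table, rows, demb_rows)
                if trainable_rows is not None:
                    keep = np.zeros(len(embedding), bool)
                    keep[trainable_rows] = True
                    grad_table[~keep] = 0.0
                opt_emb.step([embedding], [grad_table])
        curve.append(total / n)
    return curve
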