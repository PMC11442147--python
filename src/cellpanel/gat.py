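"""A compact NumPy graph attention network for cell-state classification.

Two GAT layers (multi-head attention over a k-nearest-neighbour cell
graph) with ELU in between, trained full-batch by Adam on a weighted
cross-entropy with manual backpropagation. Attention follows the standard
formulation: per head, node features are projected linearly, an edge score
``LeakyReLU(a_dst . h_i + a_src . h_j)`` is softmax-normalized over each
node's in-neighbourhood, and messages are the attention-weighted sum of
projected neighbour features. Dropout is applied to layer inputs and to
attention coefficients during training.

Prediction on a new cohort is inductive: the graph is rebuilt within the
new data and the trained weights are applied in a single forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["GATConfig", "GATClassifier"]

_LEAKY = 0.2


@dataclass(frozen=True)
class GATConfig:
    hidden: int = 8          # features per head, first layer
    heads: int = 8
    dropout: float = 0.4
    lr: float = 5e-3
    weight_decay: float = 5e-4
    max_epochs: int = 200
    patience: int = 20       # early-stopping patience (epochs)
    seed: int = 0


class _Graph:
    """Edge list sorted by destination, CSR-style, self-loops included."""

    def __init__(self, indptr: np.ndarray, src: np.ndarray, n: int):
        self.indptr = indptr
        self.src = src
        self.n = n
        self.dst = np.repeat(np.arange(n), np.diff(indptr))

    @classmethod
    def from_adjacency(cls, adj: sp.spmatrix) -> "_Graph":
        n = adj.shape[0]
        adj = sp.csr_matrix(adj, copy=True)
        adj.setdiag(1.0)  # self-loops: every node attends to itself
        adj.eliminate_zeros()
        adj.sort_indices()
        return cls(adj.indptr.copy(), adj.indices.copy(), n)


def _segment_softmax(e: np.ndarray, g: _Graph) -> np.ndarray:
    mx = np.maximum.reduceat(e, g.indptr[:-1])
    ex = np.exp(e - mx[g.dst])
    denom = np.add.reduceat(ex, g.indptr[:-1])
    return ex / denom[g.dst]


class _GATLayer:
    """One multi-head attention layer with cached forward state."""

    def __init__(self, d_in: int, d_out: int, heads: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(heads, d_in, d_out))
        la = np.sqrt(6.0 / (d_out + 1))
        self.a_dst = rng.uniform(-la, la, size=(heads, d_out))
        self.a_src = rng.uniform(-la, la, size=(heads, d_out))

    def params(self):
        return [self.W, self.a_dst, self.a_src]

    def forward(self, X, g: _Graph, drop_p: float, rng, training: bool):
        H = self.W.shape[0]
        self._cache = []
        outs = []
        if training and drop_p > 0:
            keep = (rng.random(X.shape) >= drop_p) / (1.0 - drop_p)
            Xd = X * keep
        else:
            keep = None
            Xd = X
        for h in range(H):
            Hh = Xd @ self.W[h]
            s = Hh @ self.a_dst[h]
            t = Hh @ self.a_src[h]
            z = s[g.dst] + t[g.src]
            e = np.where(z > 0, z, _LEAKY * z)
            alpha = _segment_softmax(e, g)
            if training and drop_p > 0:
                amask = (rng.random(alpha.shape) >= drop_p) / (1.0 - drop_p)
                alpha_t = alpha * amask
            else:
                amask = None
                alpha_t = alpha
            A = sp.csr_matrix((alpha_t, g.src, g.indptr), shape=(g.n, g.n))
            O = A @ Hh
            self._cache.append((Hh, z, alpha, amask, alpha_t, A))
            outs.append(O)
        self._Xd, self._keep = Xd, keep
        return np.concatenate(outs, axis=1)  # n x (heads * d_out)

    def backward(self, dOut, g: _Graph):
        H, d_in, d_out = self.W.shape
        dW = np.zeros_like(self.W)
        da_d = np.zeros_like(self.a_dst)
        da_s = np.zeros_like(self.a_src)
        dXd = np.zeros_like(self._Xd)
        for h in range(H):
            Hh, z, alpha, amask, alpha_t, A = self._cache[h]
            dO = dOut[:, h * d_out : (h + 1) * d_out]
            # O = A @ Hh  ->  dHh += A.T @ dO ; dalpha_t_e = dO[dst].Hh[src]
            dHh = A.T @ dO
            dalpha_t = np.einsum("ef,ef->e", dO[g.dst], Hh[g.src])
            dalpha = dalpha_t * amask if amask is not None else dalpha_t
            # softmax backward within each destination group
            inner = np.add.reduceat(alpha * dalpha, g.indptr[:-1])
            de = alpha * (dalpha - inner[g.dst])
            dz = de * np.where(z > 0, 1.0, _LEAKY)
            ds = np.add.reduceat(dz, g.indptr[:-1])  # per dst node
            dt = np.bincount(g.src, weights=dz, minlength=g.n)
            dHh += np.outer(ds, self.a_dst[h]) + np.outer(dt, self.a_src[h])
            da_d[h] = Hh.T @ ds
            da_s[h] = Hh.T @ dt
            dW[h] = self._Xd.T @ dHh
            dXd += dHh @ self.W[h].T
        dX = dXd * self._keep if self._keep is not None else dXd
        return dX, [dW, da_d, da_s]


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


class GATClassifier:
    """Binary node classifier on a cell kNN graph.

    ``fit`` expects standardized features, a symmetric adjacency matrix,
    binary labels, per-cell weights, and boolean train/validation node
    masks (validation nodes contribute no gradient and drive early
    stopping). Deterministic for a fixed config seed.
    """

    def __init__(self, cfg: GATConfig | None = None):
        self.cfg = cfg or GATConfig()

    # -- forward ---------------------------------------------------------
    def _forward(self, X, g, training, rng):
        h1 = self.l1.forward(X, g, self.cfg.dropout, rng, training)
        a1 = _elu(h1)
        logits = self.l2.forward(a1, g, self.cfg.dropout, rng, training)
        self._h1 = h1
        return logits

    def _loss_grad(self, logits, y, w, mask):
        """Weighted cross-entropy over masked nodes; returns loss, dlogits."""
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        wm = w * mask
        wsum = wm.sum()
        eps = 1e-12
        loss = -np.sum(wm * np.log(p[np.arange(len(y)), y] + eps)) / wsum
        dlog = p.copy()
        dlog[np.arange(len(y)), y] -= 1.0
        dlog *= (wm / wsum)[:, None]
        return float(loss), dlog

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        adjacency: sp.spmatrix,
        sample_weight: np.ndarray | None = None,
        train_mask: np.ndarray | None = None,
        val_mask: np.ndarray | None = None,
    ) -> "GATClassifier":
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        n, d = X.shape
        y = np.asarray(y, dtype=int)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if train_mask is None:
            train_mask = np.ones(n, dtype=bool)
        g = _Graph.from_adjacency(adjacency)
        self.l1 = _GATLayer(d, cfg.hidden, cfg.heads, rng)
        self.l2 = _GATLayer(cfg.hidden * cfg.heads, 2, 1, rng)
        params = self.l1.params() + self.l2.params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        best_loss, best_state, patience_left = np.inf, None, cfg.patience
        monitor = val_mask if val_mask is not None and val_mask.any() else train_mask
        for epoch in range(1, cfg.max_epochs + 1):
            logits = self._forward(X, g, True, rng)
            loss, dlog = self._loss_grad(logits, y, w, train_mask)
            da1, g2 = self.l2.backward(dlog, g)
            dh1 = da1 * _elu_grad(self._h1)
            _, g1 = self.l1.backward(dh1, g)
            grads = g1 + g2
            for i, (p, gr) in enumerate(zip(params, grads)):
                gr = gr + cfg.weight_decay * p
                m[i] = b1 * m[i] + (1 - b1) * gr
                v[i] = b2 * v[i] + (1 - b2) * gr * gr
                mhat = m[i] / (1 - b1**epoch)
                vhat = v[i] / (1 - b2**epoch)
                p -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
            # monitor without dropout
            logits_eval = self._forward(X, g, False, rng)
            mon_loss, _ = self._loss_grad(logits_eval, y, w, monitor)
            if mon_loss < best_loss - 1e-5:
                best_loss = mon_loss
                best_state = [p.copy() for p in params]
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_state is not None:
            for p, bp in zip(params, best_state):
                p[...] = bp
        return self

    def predict_proba(self, X: np.ndarray, adjacency: sp.spmatrix) -> np.ndarray:
        g = _Graph.from_adjacency(adjacency)
        rng = np.random.default_rng(0)  # unused: no dropout at inference
        logits = self._forward(X, g, False, rng)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)
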