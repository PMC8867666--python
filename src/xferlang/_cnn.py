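"""Small 1-D convolutional text classifier, numpy with manual backprop.

Embedding -> 1-D convolution -> ReLU -> global max pool -> dropout -> dense
-> sigmoid.  Written directly in numpy so that (a) the embedding table can be
initialised bitwise from a word-embedding model and inspected afterwards, and
(b) the exact gradient of the loss with respect to each token's embedded
input is available for sensitivity heatmaps.  float64 throughout: the nets
are tiny and exact gradients matter more than speed.

Index 0 is the padding index; its embedding row is frozen at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PAD = 0


@dataclass
class CNNParams:
    n_filters: int = 64
    kernel: int = 5
    dropout: float = 0.5
    epochs: int = 30
    batch_size: int = 32
    lr: float = 3e-3
    max_len: int = 100
    dim: int = 100


class TextCNN:
    def __init__(self, n_vocab: int, params: CNNParams, seed: int,
                 embedding_init: np.ndarray | None = None):
        self.params = params
        self.n_vocab = n_vocab
        rng = np.random.default_rng(seed)
        d, F, K = params.dim, params.n_filters, params.kernel
        # table row 0 = pad, rows 1..n_vocab = tokens
        self.E = np.zeros((n_vocab + 1, d))
        if embedding_init is not None:
            if embedding_init.shape != (n_vocab, d):
                raise ValueError(
                    f"embedding_init shape {embedding_init.shape} does not "
                    f"match (n_vocab={n_vocab}, dim={d})")
            self.E[1:] = embedding_init
        else:
            self.E[1:] = rng.normal(0.0, 0.1, size=(n_vocab, d))
        limit = np.sqrt(6.0 / (K * d + F))
        self.W = rng.uniform(-limit, limit, size=(F, K * d))
        self.b = np.zeros(F)
        self.w_out = rng.uniform(-limit, limit, size=F)
        self.b_out = 0.0
        self._rng = rng
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _embed(self, batch: np.ndarray) -> np.ndarray:
        return self.E[batch]                       # (B, L, d)

    def _windows(self, X: np.ndarray) -> np.ndarray:
        B, L, d = X.shape
        K = self.params.kernel
        P = L - K + 1
        s0, s1, s2 = X.strides
        win = np.lib.stride_tricks.as_strided(
            X, shape=(B, P, K, d), strides=(s0, s1, s1, s2))
        return win.reshape(B, P, K * d)

    def forward(self, batch: np.ndarray, X: np.ndarray | None = None):
        """Returns (prob, cache). ``X`` overrides the embedded input (used by
        the finite-difference gradient check)."""
        if X is None:
            X = self._embed(batch)
        win = self._windows(X)                       # (B, P, Kd)
        conv = win @ self.W.T + self.b               # (B, P, F)
        relu = np.maximum(conv, 0.0)
        amax = relu.argmax(axis=1)                   # (B, F)
        B = X.shape[0]
        bi = np.arange(B)[:, None]
        pooled = relu[bi, amax, np.arange(self.params.n_filters)]   # (B, F)
        logit = pooled @ self.w_out + self.b_out
        prob = 1.0 / (1.0 + np.exp(-logit))
        cache = (batch, X, win, conv, amax, pooled, logit)
        return prob, cache

    # -- backward ----------------------------------------------------------

    def backward(self, cache, y: np.ndarray, drop_mask: np.ndarray | None,
                 want_input_grad: bool = False):
        """Gradients of mean binary cross-entropy over the batch.

        Returns dict of parameter grads; with ``want_input_grad`` also the
        gradient w.r.t. the embedded input X (per position, before pooling
        sparsity is applied it flows only through argmax windows).
        """
        batch, X, win, conv, amax, pooled, logit = cache
        B, L, d = X.shape
        F = self.params.n_filters
        K = self.params.kernel
        prob = 1.0 / (1.0 + np.exp(-logit))
        dlogit = (prob - y) / B                       # (B,)
        pooled_eff = pooled if drop_mask is None else pooled * drop_mask
        dw_out = pooled_eff.T @ dlogit
        db_out = dlogit.sum()
        dpooled = np.outer(dlogit, self.w_out)        # (B, F)
        if drop_mask is not None:
            dpooled = dpooled * drop_mask
        # route through max pool and ReLU
        dconv = np.zeros_like(conv)                   # (B, P, F)
        bi = np.arange(B)[:, None]
        fi = np.arange(F)[None, :]
        relu_alive = conv[bi, amax, fi] > 0.0
        dconv[bi, amax, fi] = dpooled * relu_alive
        dwin = dconv @ self.W                         # (B, P, Kd)
        dW = np.einsum("bpf,bpk->fk", dconv, win)
        db = dconv.sum(axis=(0, 1))
        # scatter window grads back to positions
        dX = np.zeros_like(X)
        dwin4 = dwin.reshape(B, -1, K, d)
        P = L - K + 1
        for k in range(K):
            dX[:, k:k + P, :] += dwin4[:, :, k, :]
        grads = {"W": dW, "b": db, "w_out": dw_out, "b_out": np.array(db_out)}
        # embedding grads: scatter-add per token index; pad row stays frozen
        dE = np.zeros_like(self.E)
        np.add.at(dE, batch.ravel(), dX.reshape(-1, d))
        dE[PAD] = 0.0
        grads["E"] = dE
        if want_input_grad:
            return grads, dX
        return grads

    # -- training ----------------------------------------------------------

    def _adam_step(self, grads: dict):
        self._adam_t += 1
        t = self._adam_t
        lr, b1, b2, eps = self.params.lr, 0.9, 0.999, 1e-8
        for name in ("E", "W", "b", "w_out", "b_out"):
            p = getattr(self, name)
            g = grads[name]
            if name not in self._adam:
                self._adam[name] = (np.zeros_like(p, dtype=float),
                                    np.zeros_like(p, dtype=float))
            m, v = self._adam[name]
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._adam[name] = (m, v)
            mh = m / (1 - b1 ** t)
            vh = v / (1 - b2 ** t)
            upd = lr * mh / (np.sqrt(vh) + eps)
            if name in ("b_out",):
                setattr(self, name, float(p - upd))
            else:
                setattr(self, name, p - upd)
        self.E[PAD] = 0.0

    def fit(self, sequences: np.ndarray, y: np.ndarray) -> list[float]:
        """Mini-batch Adam training; returns per-epoch mean loss."""
        n = sequences.shape[0]
        losses = []
        for _ in range(self.params.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.params.batch_size):
                idx = order[start:start + self.params.batch_size]
                batch, yb = sequences[idx], y[idx]
                prob, cache = self.forward(batch)
                p = self.params.dropout
                if p > 0:
                    mask = (self._rng.random((len(idx), self.params.n_filters))
                            >= p) / (1.0 - p)
                    pooled = cache[5] * mask
                    logit = pooled @ self.w_out + self.b_out
                    prob = 1.0 / (1.0 + np.exp(-logit))
                    cache = cache[:5] + (cache[5],) + (logit,)
                else:
                    mask = None
                eps = 1e-12
                loss = -np.mean(yb * np.log(prob + eps)
                                + (1 - yb) * np.log(1 - prob + eps))
                epoch_loss += loss * len(idx)
                grads = self.backward(cache, yb, mask)
                self._adam_step(grads)
            losses.append(epoch_loss / n)
        return losses

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        prob, _ = self.forward(sequences)
        return prob

    # -- sensitivity -------------------------------------------------------

    def input_gradient(self, sequence: np.ndarray, target: int) -> np.ndarray:
        """Gradient of the cross-entropy loss at label ``target`` w.r.t. the
        embedded input of one sequence; returns (L, d)."""
        batch = sequence[None, :]
        prob, cache = self.forward(batch)
        _, dX = self.backward(cache, np.array([float(target)]), None,
                              want_input_grad=True)
        return dX[0]
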