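"""Minimal pre-LayerNorm transformer encoder for masked-token prediction.

Numpy forward/backward written by hand, float64, Adam updates.  Sized for
desk-scale corpora (two layers, hidden 128): the object of interest is the
transfer-initialisation mechanism and the small-corpus behaviour of a
context-dependent model, not large-scale pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TransformerConfig:
    vocab_size: int
    layers: int = 2
    hidden: int = 128
    heads: int = 2
    d_ff: int = 256
    max_seq_len: int = 128

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")


def init_params(cfg: TransformerConfig, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    H, F, V = cfg.hidden, cfg.d_ff, cfg.vocab_size
    s = 0.02
    p = {
        "E_tok": rng.normal(0, s, (V, H)),
        "E_pos": rng.normal(0, s, (cfg.max_seq_len, H)),
        "W_out": rng.normal(0, s, (H, V)),
        "b_out": np.zeros(V),
        "g_f": np.ones(H), "b_f": np.zeros(H),
    }
    for l in range(cfg.layers):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"{name}{l}"] = rng.normal(0, s, (H, H))
            p[f"{name.replace('W', 'b')}{l}"] = np.zeros(H)
        p[f"g1_{l}"] = np.ones(H); p[f"b1_{l}"] = np.zeros(H)
        p[f"g2_{l}"] = np.ones(H); p[f"b2_{l}"] = np.zeros(H)
        p[f"W1_{l}"] = rng.normal(0, s, (H, F)); p[f"c1_{l}"] = np.zeros(F)
        p[f"W2_{l}"] = rng.normal(0, s, (F, H)); p[f"c2_{l}"] = np.zeros(H)
    return p


_EPS = 1e-5


def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    H = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _split_heads(x, heads):
    B, T, H = x.shape
    return x.reshape(B, T, heads, H // heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, nh, T, hd = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, nh * hd)


def forward(p: dict, cfg: TransformerConfig, ids: np.ndarray,
            pad_mask: np.ndarray):
    """ids: (B, T) int; pad_mask: (B, T) bool, True at real tokens.

    Returns (logits, hidden, cache); ``hidden`` is the final LayerNormed
    token representation used for report embeddings.
    """
    B, T = ids.shape
    x = p["E_tok"][ids] + p["E_pos"][:T]
    neg = np.where(pad_mask, 0.0, -1e9)[:, None, None, :]   # (B,1,1,T) keys
    caches = []
    for l in range(cfg.layers):
        a, ln1 = _ln_fwd(x, p[f"g1_{l}"], p[f"b1_{l}"])
        Q = a @ p[f"Wq{l}"] + p[f"bq{l}"]
        K = a @ p[f"Wk{l}"] + p[f"bk{l}"]
        V = a @ p[f"Wv{l}"] + p[f"bv{l}"]
        qh, kh, vh = (_split_heads(z, cfg.heads) for z in (Q, K, V))
        scale = 1.0 / np.sqrt(cfg.hidden // cfg.heads)
        S = qh @ kh.transpose(0, 1, 3, 2) * scale + neg
        S = S - S.max(-1, keepdims=True)
        expS = np.exp(S)
        A = expS / expS.sum(-1, keepdims=True)
        C = _merge_heads(A @ vh)
        O = C @ p[f"Wo{l}"] + p[f"bo{l}"]
        x1 = x + O
        a2, ln2 = _ln_fwd(x1, p[f"g2_{l}"], p[f"b2_{l}"])
        z1 = a2 @ p[f"W1_{l}"] + p[f"c1_{l}"]
        r = np.maximum(z1, 0.0)
        f = r @ p[f"W2_{l}"] + p[f"c2_{l}"]
        x2 = x1 + f
        caches.append((a, ln1, qh, kh, vh, A, C, x, x1, a2, ln2, z1, r, scale))
        x = x2
    hidden, lnf = _ln_fwd(x, p["g_f"], p["b_f"])
    logits = hidden @ p["W_out"] + p["b_out"]
    return logits, hidden, (ids, pad_mask, caches, lnf, hidden)


def loss_and_grads(p: dict, cfg: TransformerConfig, ids: np.ndarray,
                   pad_mask: np.ndarray, target_pos: np.ndarray,
                   target_ids: np.ndarray):
    """Mean cross-entropy over the masked positions, with full gradients.

    target_pos: (M, 2) array of (batch, position) indices; target_ids: (M,).
    """
    logits, hidden, cache = forward(p, cfg, ids, pad_mask)
    ids_, pad_mask_, caches, lnf, _ = cache
    M = len(target_ids)
    sel = logits[target_pos[:, 0], target_pos[:, 1]]          # (M, V)
    sel = sel - sel.max(-1, keepdims=True)
    logZ = np.log(np.exp(sel).sum(-1, keepdims=True))
    logp = sel - logZ
    loss = -logp[np.arange(M), target_ids].mean()

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dsel = np.exp(logp)
    dsel[np.arange(M), target_ids] -= 1.0
    dsel /= M
    dlogits = np.zeros_like(logits)
    np.add.at(dlogits, (target_pos[:, 0], target_pos[:, 1]), dsel)

    grads["W_out"] = np.einsum("bth,btv->hv", hidden, dlogits)
    grads["b_out"] = dlogits.sum((0, 1))
    dhidden = dlogits @ p["W_out"].T
    dx, dg, db = _ln_bwd(dhidden, lnf)
    grads["g_f"], grads["b_f"] = dg, db

    for l in reversed(range(cfg.layers)):
        (a, ln1, qh, kh, vh, A, C, x_in, x1, a2, ln2, z1, r, scale) = caches[l]
        # FFN block: x2 = x1 + relu(a2 W1 + c1) W2 + c2
        df = dx
        grads[f"W2_{l}"] += np.einsum("btf,bth->fh", r, df)
        grads[f"c2_{l}"] += df.sum((0, 1))
        dr = df @ p[f"W2_{l}"].T
        dz1 = dr * (z1 > 0)
        grads[f"W1_{l}"] += np.einsum("bth,btf->hf", a2, dz1)
        grads[f"c1_{l}"] += dz1.sum((0, 1))
        da2 = dz1 @ p[f"W1_{l}"].T
        dx1_ln, dg2, db2 = _ln_bwd(da2, ln2)
        grads[f"g2_{l}"] += dg2
        grads[f"b2_{l}"] += db2
        dx1 = dx + dx1_ln
        # attention block: x1 = x_in + (merge(A @ vh)) Wo + bo
        dO = dx1
        grads[f"Wo{l}"] += np.einsum("bth,btk->hk", C, dO)
        grads[f"bo{l}"] += dO.sum((0, 1))
        dC = dO @ p[f"Wo{l}"].T
        dCh = _split_heads(dC, cfg.heads)
        dA = dCh @ vh.transpose(0, 1, 3, 2)
        dvh = A.transpose(0, 1, 3, 2) @ dCh
        dS = A * (dA - (dA * A).sum(-1, keepdims=True))
        dqh = dS @ kh * scale
        dkh = dS.transpose(0, 1, 3, 2) @ qh * scale
        dQ, dK, dV = (_merge_heads(z) for z in (dqh, dkh, dvh))
        da = np.zeros_like(a)
        for nm, dz in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            grads[f"{nm}{l}"] += np.einsum("bth,btk->hk", a, dz)
            grads[f"{nm.replace('W', 'b')}{l}"] += dz.sum((0, 1))
            da += dz @ p[f"{nm}{l}"].T
        dx_ln, dg1, db1 = _ln_bwd(da, ln1)
        grads[f"g1_{l}"] += dg1
        grads[f"b1_{l}"] += db1
        dx = dx1 + dx_ln
    # embeddings
    T = ids.shape[1]
    np.add.at(grads["E_tok"], ids, dx)
    grads["E_pos"][:T] += dx.sum(0)
    return loss, grads


class AdamState:
    def __init__(self, params: dict, lr: float = 1e-3):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.lr = lr

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t)
            vh = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + eps)
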