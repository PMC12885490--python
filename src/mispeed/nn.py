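"""Minimal numpy building blocks for the conv-transformer decoder.

Each primitive is a pair of pure functions, ``*_forward`` returning
``(output, cache)`` and ``*_backward`` taking the upstream gradient and the
cache.  Gradients are exact (verified against central finite differences in
the test suite).  Everything is float64 and fully deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# --------------------------------------------------------------------------
# convolution module pieces


def conv_module_forward(X, K, W):
    """Temporal filter bank + spatial projection.

    X: (B, C, T) input;  K: (F, L) temporal kernels;  W: (F, C) spatial
    filter matrix.  Output S: (B, F, T-L+1) with
    ``S[b,f,t] = sum_c W[f,c] * sum_l K[f,l] X[b,c,t+l]``
    (each channel correlated with the kernel — i.e. convolved with the
    time-reversed kernel — then projected across channels).  The two linear
    stages commute, so the spatial projection is applied first for speed.
    """
    Z = np.einsum("fc,bct->bft", W, X)  # (B, F, T)
    Zw = sliding_window_view(Z, K.shape[1], axis=-1)  # (B, F, T1, L)
    S = np.einsum("bftl,fl->bft", Zw, K)
    return S, (X, K, W, Z)


def conv_module_backward(dS, cache):
    X, K, W, Z = cache
    L = K.shape[1]
    Zw = sliding_window_view(Z, L, axis=-1)
    dK = np.einsum("bft,bftl->fl", dS, Zw)
    # dZ[t'] = sum_l K[l] dS[t'-l]  (full correlation with flipped kernel)
    pad = np.pad(dS, ((0, 0), (0, 0), (L - 1, L - 1)))
    dZ = np.einsum("bftl,fl->bft", sliding_window_view(pad, L, axis=-1), K[:, ::-1])
    dW = np.einsum("bft,bct->fc", dZ, X)
    return dK, dW


def elu_forward(x):
    neg = x < 0
    y = np.where(neg, np.expm1(x), x)
    return y, (y, neg)


def elu_backward(dy, cache):
    y, neg = cache
    return dy * np.where(neg, y + 1.0, 1.0)


def avgpool_forward(x, pool_len, stride):
    """Average pooling along the last axis. x: (B, F, T) -> (B, F, n_tokens)."""
    T = x.shape[-1]
    n_tokens = (T - pool_len) // stride + 1
    if n_tokens < 1:
        raise ValueError(f"pool length {pool_len} exceeds input length {T}")
    starts = np.arange(n_tokens) * stride
    cs = np.cumsum(x, axis=-1, dtype=float)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), cs], axis=-1)
    y = (cs[..., starts + pool_len] - cs[..., starts]) / pool_len
    return y, (x.shape, pool_len, stride, starts)


def avgpool_backward(dy, cache):
    shape, pool_len, stride, starts = cache
    dx = np.zeros(shape)
    contrib = dy / pool_len
    for j, s in enumerate(starts):  # overlapping windows accumulate
        dx[..., s : s + pool_len] += contrib[..., j : j + 1]
    return dx


def dropout_forward(x, p, rng, train):
    if not train or p <= 0:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def dropout_backward(dy, mask):
    return dy if mask is None else dy * mask


# --------------------------------------------------------------------------
# transformer pieces


def linear_forward(x, w, b):
    return x @ w + b, (x, w)


def linear_backward(dy, cache):
    x, w = cache
    dx = dy @ w.T
    dw = np.tensordot(x, dy, axes=(range(x.ndim - 1), range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dw, db


def layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = (dxhat - m1 - xhat * m2) * inv
    return dx, dg, db


def gelu_forward(x):
    c = np.sqrt(2.0 / np.pi)
    u = c * (x + 0.044715 * x**3)
    t = np.tanh(u)
    return 0.5 * x * (1.0 + t), (x, t, c)


def gelu_backward(dy, cache):
    x, t, c = cache
    du = c * (1.0 + 3 * 0.044715 * x**2)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du)


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_forward(x, p, n_heads):
    """Multi-head self-attention. x: (B, T, E); p: dict with wq..wo, bq..bo."""
    B, T, E = x.shape
    dh = E // n_heads

    def heads(m):
        return m.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)  # (B, H, T, dh)

    q, cq = linear_forward(x, p["wq"], p["bq"])
    k, ck = linear_forward(x, p["wk"], p["bk"])
    v, cv = linear_forward(x, p["wv"], p["bv"])
    qh, kh, vh = heads(q), heads(k), heads(v)
    scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
    attn = softmax(scores)
    oh = attn @ vh  # (B, H, T, dh)
    o = oh.transpose(0, 2, 1, 3).reshape(B, T, E)
    out, co = linear_forward(o, p["wo"], p["bo"])
    return out, (cq, ck, cv, co, qh, kh, vh, attn, n_heads)


def attention_backward(dy, cache):
    cq, ck, cv, co, qh, kh, vh, attn, n_heads = cache
    B, H, T, dh = qh.shape
    E = H * dh
    do, dwo, dbo = linear_backward(dy, co)
    doh = do.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
    dattn = doh @ vh.transpose(0, 1, 3, 2)
    dvh = attn.transpose(0, 1, 3, 2) @ doh
    dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    dscores /= np.sqrt(dh)
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 1, 3, 2) @ qh

    def merge(m):
        return m.transpose(0, 2, 1, 3).reshape(B, T, E)

    dxq, dwq, dbq = linear_backward(merge(dqh), cq)
    dxk, dwk, dbk = linear_backward(merge(dkh), ck)
    dxv, dwv, dbv = linear_backward(merge(dvh), cv)
    grads = {
        "wq": dwq, "bq": dbq, "wk": dwk, "bk": dbk,
        "wv": dwv, "bv": dbv, "wo": dwo, "bo": dbo,
    }
    return dxq + dxk + dxv, grads


def cross_entropy(logits, labels):
    """Mean cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adaptive-moment gradient descent on a flat dict of arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
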