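"""Minimal numpy neural-network core: a BERT-style encoder with explicit
backpropagation.

Implements exactly what the angle regressor needs — token + positional
embeddings, post-layer-norm transformer encoder blocks (multi-head
self-attention and a GELU feed-forward), layer normalization, linear layers,
the tanh-approximated GELU, and an Adam optimizer.  Forward passes cache the
intermediates required by ``backward``; gradients are validated against
finite differences in the test suite.

Shapes are single-sequence: (T, H) for T tokens.  Training loops over
examples, which is the regime this package targets (desk-scale models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """GELU activation (tanh approximation, as in BERT)."""
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    return 0.5 * x * (1.0 + np.tanh(inner))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    dinner = _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# parameter store

@dataclass
class ParamStore:
    """Named parameter tensors with matching gradient buffers."""

    params: dict[str, np.ndarray] = field(default_factory=dict)
    grads: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, value: np.ndarray) -> np.ndarray:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def accumulate(self, name: str, grad: np.ndarray) -> None:
        self.grads[name] += grad


class Adam:
    """Adam optimizer over a :class:`ParamStore`."""

    def __init__(self, store: ParamStore, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.store = store
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in store.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in store.params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.store.params.items():
            g = self.store.grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# layers (forward returns output + cache; backward consumes cache)

def linear_forward(x, W, b):
    return x @ W + b, (x, W)


def linear_backward(dy, cache):
    x, W = cache
    dW = x.T @ dy
    db = dy.sum(axis=0)
    dx = dy @ W.T
    return dx, dW, db


def layernorm_forward(x, g, b, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv_std
    return xhat * g + b, (xhat, inv_std, g)


def layernorm_backward(dy, cache):
    xhat, inv_std, g = cache
    dg = (dy * xhat).sum(axis=0)
    db = dy.sum(axis=0)
    dxhat = dy * g
    dx = inv_std * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


def attention_forward(x, Wq, bq, Wk, bk, Wv, bv, Wo, bo, n_heads: int):
    """Multi-head scaled dot-product self-attention on a (T, H) input."""
    T, H = x.shape
    dh = H // n_heads

    def split(z):  # (T, H) -> (nh, T, dh)
        return z.reshape(T, n_heads, dh).transpose(1, 0, 2)

    q, k, v = x @ Wq + bq, x @ Wk + bk, x @ Wv + bv
    qh, kh, vh = split(q), split(k), split(v)
    scores = qh @ kh.transpose(0, 2, 1) / math.sqrt(dh)
    attn = softmax(scores, axis=-1)
    ctx = attn @ vh                                  # (nh, T, dh)
    ctx_flat = ctx.transpose(1, 0, 2).reshape(T, H)
    out = ctx_flat @ Wo + bo
    cache = (x, Wq, Wk, Wv, Wo, qh, kh, vh, attn, ctx_flat, n_heads)
    return out, cache


def attention_backward(dy, cache):
    x, Wq, Wk, Wv, Wo, qh, kh, vh, attn, ctx_flat, n_heads = cache
    T, H = x.shape
    dh = H // n_heads

    dWo = ctx_flat.T @ dy
    dbo = dy.sum(axis=0)
    dctx_flat = dy @ Wo.T
    dctx = dctx_flat.reshape(T, n_heads, dh).transpose(1, 0, 2)

    dattn = dctx @ vh.transpose(0, 2, 1)
    dvh = attn.transpose(0, 2, 1) @ dctx
    dscores = (dattn - (dattn * attn).sum(axis=-1, keepdims=True)) * attn
    dscores /= math.sqrt(dh)
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 2, 1) @ qh

    def merge(z):  # (nh, T, dh) -> (T, H)
        return z.transpose(1, 0, 2).reshape(T, H)

    dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
    dWq, dbq = x.T @ dq, dq.sum(axis=0)
    dWk, dbk = x.T @ dk, dk.sum(axis=0)
    dWv, dbv = x.T @ dv, dv.sum(axis=0)
    dx = dq @ Wq.T + dk @ Wk.T + dv @ Wv.T
    return dx, (dWq, dbq, dWk, dbk, dWv, dbv, dWo, dbo)


# ---------------------------------------------------------------------------
# encoder

class TransformerEncoder:
    """Token + positional embeddings followed by post-LN encoder blocks."""

    def __init__(self, vocab_size: int, hidden: int, depth: int,
                 n_heads: int, max_tokens: int, rng: np.random.Generator,
                 ffn_mult: int = 4, init_scale: float = 0.02):
        if hidden % n_heads:
            raise ValueError("hidden size must be divisible by n_heads")
        self.hidden = hidden
        self.depth = depth
        self.n_heads = n_heads
        self.max_tokens = max_tokens
        self.store = ParamStore()
        add = self.store.add

        def randn(*shape):
            return rng.normal(0.0, init_scale, size=shape)

        add("tok_emb", randn(vocab_size, hidden))
        add("pos_emb", randn(max_tokens, hidden))
        ffn = ffn_mult * hidden
        for i in range(depth):
            p = f"layer{i}."
            for nm, shape in (
                ("Wq", (hidden, hidden)), ("Wk", (hidden, hidden)),
                ("Wv", (hidden, hidden)), ("Wo", (hidden, hidden)),
                ("W1", (hidden, ffn)), ("W2", (ffn, hidden)),
            ):
                add(p + nm, randn(*shape))
            for nm, size in (
                ("bq", hidden), ("bk", hidden), ("bv", hidden),
                ("bo", hidden), ("b1", ffn), ("b2", hidden),
            ):
                add(p + nm, np.zeros(size))
            add(p + "ln1_g", np.ones(hidden))
            add(p + "ln1_b", np.zeros(hidden))
            add(p + "ln2_g", np.ones(hidden))
            add(p + "ln2_b", np.zeros(hidden))

    def forward(self, token_ids: np.ndarray):
        P = self.store.params
        T = len(token_ids)
        if T > self.max_tokens:
            raise ValueError(f"{T} tokens exceeds max_tokens={self.max_tokens}")
        x = P["tok_emb"][token_ids] + P["pos_emb"][:T]
        caches = []
        for i in range(self.depth):
            p = f"layer{i}."
            att, c_att = attention_forward(
                x, P[p + "Wq"], P[p + "bq"], P[p + "Wk"], P[p + "bk"],
                P[p + "Wv"], P[p + "bv"], P[p + "Wo"], P[p + "bo"],
                self.n_heads,
            )
            h1, c_ln1 = layernorm_forward(
                x + att, P[p + "ln1_g"], P[p + "ln1_b"]
            )
            z1, c_l1 = linear_forward(h1, P[p + "W1"], P[p + "b1"])
            a1 = gelu(z1)
            z2, c_l2 = linear_forward(a1, P[p + "W2"], P[p + "b2"])
            x_new, c_ln2 = layernorm_forward(
                h1 + z2, P[p + "ln2_g"], P[p + "ln2_b"]
            )
            caches.append((c_att, c_ln1, c_l1, z1, c_l2, c_ln2))
            x = x_new
        return x, (token_ids, caches)

    def backward(self, dx: np.ndarray, cache) -> None:
        token_ids, caches = cache
        acc = self.store.accumulate
        for i in reversed(range(self.depth)):
            p = f"layer{i}."
            c_att, c_ln1, c_l1, z1, c_l2, c_ln2 = caches[i]
            dres2, dg2, db2 = layernorm_backward(dx, c_ln2)
            acc(p + "ln2_g", dg2)
            acc(p + "ln2_b", db2)
            da1, dW2, db_2 = linear_backward(dres2, c_l2)
            acc(p + "W2", dW2)
            acc(p + "b2", db_2)
            dz1 = da1 * gelu_grad(z1)
            dh1_ffn, dW1, db_1 = linear_backward(dz1, c_l1)
            acc(p + "W1", dW1)
            acc(p + "b1", db_1)
            dh1 = dres2 + dh1_ffn
            dres1, dg1, db1 = layernorm_backward(dh1, c_ln1)
            acc(p + "ln1_g", dg1)
            acc(p + "ln1_b", db1)
            dx_att, att_grads = attention_backward(dres1, c_att)
            for nm, g in zip(
                ("Wq", "bq", "Wk", "bk", "Wv", "bv", "Wo", "bo"), att_grads
            ):
                acc(p + nm, g)
            dx = dres1 + dx_att
        np.add.at(self.store.grads["tok_emb"], token_ids, dx)
        self.store.grads["pos_emb"][: len(token_ids)] += dx
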