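"""Multi-head self-attention and post-norm transformer encoder layers."""

from __future__ import annotations

import numpy as np

from .core import Module
from .layers import Dropout, LayerNorm, Linear, ReLU


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Module):
    """Standard scaled dot-product self-attention over (N, T, d) inputs."""

    def __init__(self, d_model, n_heads, rng):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(
                f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d = d_model
        self.h = n_heads
        self.dh = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng, init="xavier")
        self.wk = Linear(d_model, d_model, rng, init="xavier")
        self.wv = Linear(d_model, d_model, rng, init="xavier")
        self.wo = Linear(d_model, d_model, rng, init="xavier")

    def _split(self, x):
        n, t, _ = x.shape
        return x.reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):
        n, h, t, dh = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, t, h * dh)

    def forward(self, x):
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scale = 1.0 / np.sqrt(self.dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = softmax(scores, axis=-1)
        ctx = attn @ v
        if self.training:
            self._q, self._k, self._v, self._attn = q, k, v, attn
        return self.wo.forward(self._merge(ctx))

    def backward(self, grad):
        q, k, v, attn = self._q, self._k, self._v, self._attn
        gctx = self._split(self.wo.backward(grad))
        gattn = gctx @ v.transpose(0, 1, 3, 2)
        gv = attn.transpose(0, 1, 3, 2) @ gctx
        # softmax jacobian applied row-wise
        gscores = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        gscores *= 1.0 / np.sqrt(self.dh)
        gq = gscores @ k
        gk = gscores.transpose(0, 1, 3, 2) @ q
        gx = self.wq.backward(self._merge(gq))
        gx = gx + self.wk.backward(self._merge(gk))
        gx = gx + self.wv.backward(self._merge(gv))
        self._q = self._k = self._v = self._attn = None
        return gx


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: LN(x + MHA(x)), then LN(x + FFN(x))."""

    def __init__(self, d_model, n_heads, ff_dim, rng, dropout=0.0):
        super().__init__()
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)
        self.relu = ReLU()
        self.drop = Dropout(dropout, rng)

    def forward(self, x):
        x1 = self.ln1.forward(x + self.attn.forward(x))
        f = self.ff2.forward(self.drop.forward(self.relu.forward(self.ff1.forward(x1))))
        return self.ln2.forward(x1 + f)

    def backward(self, grad):
        g2 = self.ln2.backward(grad)
        gf = self.ff1.backward(self.relu.backward(self.drop.backward(self.ff2.backward(g2))))
        g1 = self.ln1.backward(g2 + gf)
        return g1 + self.attn.backward(g1)
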