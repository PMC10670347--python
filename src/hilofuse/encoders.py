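"""The three feature extractors.

* MHFE (meta-high-frequency encoder): a lightweight fully convolutional 3D
  network in the SFCN style - four blocks of 3x3x3 conv (pad 1) -> BatchNorm
  -> ReLU -> 2x max-pool, a fifth block of 1x1x1 conv -> BatchNorm -> ReLU,
  then global average pooling.  Channel widths default to [32, 64, 128, 64,
  32], so the output feature has length 32 and the spatial trace at a
  112-voxel edge is 112 -> 56 -> 28 -> 14 -> 7.
* MLFE (meta-low-frequency encoder): a 3D vision-transformer branch -
  non-overlapping patch embedding by a convolution with kernel = stride =
  patch size, a learnable cls token, learnable (randomly initialized)
  positional encodings for all tokens, and a stack of standard post-norm
  transformer encoder layers.  The final cls representation (length d_model,
  default 512) is the low-frequency feature.
* FCMLP: a three-layer perceptron on the strictly-upper-triangle
  vectorization of the functional-connectivity matrix, with ReLU and 20%
  dropout after the first two layers, ending in a single logit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters shared by the three extractors."""

    cnn_channels: tuple = (32, 64, 128, 64, 32)
    d_model: int = 512
    n_heads: int = 4
    n_layers: int = 6
    patch_size: int = 16
    mlp_hidden: int = 256
    dropout_rate: float = 0.20
    volume_shape: tuple = (112, 112, 112)
    n_rois: int = 116
    ff_dim: int = 0  # 0 -> 2 * d_model

    def __post_init__(self):
        object.__setattr__(self, "cnn_channels", tuple(self.cnn_channels))
        object.__setattr__(self, "volume_shape",
                           tuple(int(s) for s in self.volume_shape))
        if self.ff_dim == 0:
            object.__setattr__(self, "ff_dim", 2 * self.d_model)
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by "
                f"n_heads={self.n_heads}")
        d, h, w = self.volume_shape
        if not (d == h == w):
            raise ValueError(f"volume_shape must be cubic, got {self.volume_shape}")
        self.check_volume_shape(self.volume_shape)
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")

    @property
    def pool_factor(self):
        return 2 ** (len(self.cnn_channels) - 1)

    def check_volume_shape(self, shape):
        edge = shape[0]
        if any(s != edge for s in shape):
            raise ValueError(f"volume must be cubic, got {shape}")
        if edge % self.pool_factor:
            raise ValueError(
                f"volume edge {edge} must be divisible by {self.pool_factor} "
                f"(one halving per max-pool block)")
        if edge % self.patch_size:
            raise ValueError(
                f"volume edge {edge} must be divisible by patch_size "
                f"{self.patch_size}")

    @property
    def n_patch_tokens(self):
        return (self.volume_shape[0] // self.patch_size) ** 3

    @property
    def n_tri(self):
        return self.n_rois * (self.n_rois - 1) // 2

    @classmethod
    def tiny(cls, **overrides):
        """CPU-scale profile matching SimParams.tiny()."""
        base = dict(d_model=64, n_layers=2, patch_size=8, mlp_hidden=32,
                    volume_shape=(16, 16, 16), n_rois=16)
        base.update(overrides)
        return cls(**base)

    def to_dict(self):
        return dict(cnn_channels=list(self.cnn_channels), d_model=self.d_model,
                    n_heads=self.n_heads, n_layers=self.n_layers,
                    patch_size=self.patch_size, mlp_hidden=self.mlp_hidden,
                    dropout_rate=self.dropout_rate,
                    volume_shape=list(self.volume_shape), n_rois=self.n_rois,
                    ff_dim=self.ff_dim)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["cnn_channels"] = tuple(d["cnn_channels"])
        d["volume_shape"] = tuple(d["volume_shape"])
        return cls(**d)


def _as_batch(volume):
    """Accept (D,H,W), (N,D,H,W) or (N,1,D,H,W) and return (N,1,D,H,W)."""
    v = np.asarray(volume, dtype=nn.DTYPE)
    if v.ndim == 3:
        v = v[None, None]
    elif v.ndim == 4:
        v = v[:, None]
    elif v.ndim != 5:
        raise ValueError(f"expected a 3D volume batch, got ndim={v.ndim}")
    return v


class MHFE(nn.Module):
    """Meta-high-frequency encoder (SFCN-style 3D CNN)."""

    def __init__(self, cfg: EncoderConfig, rng):
        super().__init__()
        self.cfg = cfg
        mods = []
        c_prev = 1
        for c in cfg.cnn_channels[:-1]:
            mods += [nn.Conv3d(c_prev, c, 3, rng, pad=1), nn.BatchNorm3d(c),
                     nn.ReLU(), nn.MaxPool3d(2)]
            c_prev = c
        c_last = cfg.cnn_channels[-1]
        mods += [nn.Conv3d(c_prev, c_last, 1, rng), nn.BatchNorm3d(c_last),
                 nn.ReLU(), nn.GlobalAvgPool3d()]
        self.body = nn.Sequential(*mods)
        self.out_dim = c_last

    def forward(self, x):
        x = _as_batch(x)
        edge = x.shape[2]
        if any(s != edge for s in x.shape[2:]) or edge % self.cfg.pool_factor:
            raise ValueError(
                f"MHFE input must be cubic with edge divisible by "
                f"{self.cfg.pool_factor}, got {x.shape[2:]}")
        return self.body.forward(x)

    def backward(self, grad):
        return self.body.backward(grad)

    def spatial_trace(self, edge):
        """Edge lengths after each max-pool block (shape bookkeeping)."""
        trace = [edge]
        for _ in self.cfg.cnn_channels[:-1]:
            trace.append(trace[-1] // 2)
        return trace


class MLFE(nn.Module):
    """Meta-low-frequency encoder (3D ViT branch returning the cls token)."""

    def __init__(self, cfg: EncoderConfig, rng):
        super().__init__()
        self.cfg = cfg
        p = cfg.patch_size
        self.patch_embed = nn.Conv3d(1, cfg.d_model, p, rng, stride=p)
        n_tok = cfg.n_patch_tokens + 1
        self.cls_token = nn.Parameter(rng.normal(0.0, 0.02, (1, 1, cfg.d_model)))
        self.pos_embed = nn.Parameter(rng.normal(0.0, 0.02, (1, n_tok, cfg.d_model)))
        self.layers = [
            nn.TransformerEncoderLayer(cfg.d_model, cfg.n_heads, cfg.ff_dim, rng)
            for _ in range(cfg.n_layers)
        ]
        self.out_dim = cfg.d_model

    def tokenize(self, x):
        """Patch tokens only, shape (N, T, d_model) - before cls/pos."""
        x = _as_batch(x)
        edge = x.shape[2]
        if any(s != edge for s in x.shape[2:]) or edge % self.cfg.patch_size:
            raise ValueError(
                f"MLFE input must be cubic with edge divisible by patch_size "
                f"{self.cfg.patch_size}, got {x.shape[2:]}")
        emb = self.patch_embed.forward(x)  # (N, d, e, e, e)
        n, d = emb.shape[:2]
        return np.ascontiguousarray(
            emb.reshape(n, d, -1).transpose(0, 2, 1))

    def forward(self, x):
        tok = self.tokenize(x)
        n, t, d = tok.shape
        if t + 1 != self.pos_embed.shape[1]:
            raise ValueError(
                f"input yields {t} patch tokens but positional encodings "
                f"expect {self.pos_embed.shape[1] - 1}")
        cls = np.broadcast_to(self.cls_token.value, (n, 1, d))
        seq = np.concatenate([cls, tok], axis=1) + self.pos_embed.value
        for layer in self.layers:
            seq = layer.forward(seq)
        if self.training:
            self._n = n
            self._emb_spatial = round(t ** (1 / 3))
        return seq[:, 0, :]

    def backward(self, grad):
        n = self._n
        n_tok = self.pos_embed.shape[1]
        g = np.zeros((n, n_tok, self.cfg.d_model), dtype=nn.DTYPE)
        g[:, 0, :] = grad
        for layer in reversed(self.layers):
            g = layer.backward(g)
        self.pos_embed.grad += g.sum(axis=0, keepdims=True)
        self.cls_token.grad += g[:, :1, :].sum(axis=0, keepdims=True)
        gtok = g[:, 1:, :]  # (N, T, d)
        e = round((n_tok - 1) ** (1 / 3))
        gemb = np.ascontiguousarray(
            gtok.transpose(0, 2, 1)).reshape(n, self.cfg.d_model, e, e, e)
        return self.patch_embed.backward(gemb)


class FCMLP(nn.Module):
    """Three-layer perceptron on the strictly-upper-triangle FC vector."""

    def __init__(self, cfg: EncoderConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.tri = np.triu_indices(cfg.n_rois, k=1)
        h = cfg.mlp_hidden
        self.l1 = nn.Linear(cfg.n_tri, h, rng)
        self.l2 = nn.Linear(h, h, rng)
        self.l3 = nn.Linear(h, 1, rng)
        self.relu1, self.relu2 = nn.ReLU(), nn.ReLU()
        self.drop1 = nn.Dropout(cfg.dropout_rate, rng)
        self.drop2 = nn.Dropout(cfg.dropout_rate, rng)

    def vectorize(self, fc):
        fc = np.asarray(fc, dtype=nn.DTYPE)
        if fc.ndim == 2:
            fc = fc[None]
        if fc.ndim != 3 or fc.shape[1] != fc.shape[2]:
            raise ValueError(f"FC input must be square, got shape {fc.shape}")
        if fc.shape[1] != self.cfg.n_rois:
            raise ValueError(
                f"FC matrix is {fc.shape[1]}x{fc.shape[2]} but the model is "
                f"configured for {self.cfg.n_rois} ROIs")
        return fc[:, self.tri[0], self.tri[1]]

    def forward(self, fc):
        x = self.vectorize(fc)
        x = self.drop1.forward(self.relu1.forward(self.l1.forward(x)))
        x = self.drop2.forward(self.relu2.forward(self.l2.forward(x)))
        return self.l3.forward(x)[:, 0]

    def backward(self, grad):
        g = self.l3.backward(np.asarray(grad, dtype=nn.DTYPE)[:, None])
        g = self.l2.backward(self.relu2.backward(self.drop2.backward(g)))
        g = self.l1.backward(self.relu1.backward(self.drop1.backward(g)))
        return g


# -- functional conveniences (fresh seed-controlled weights) -----------------

def mhfe_forward(volume, cfg: EncoderConfig, seed=0):
    """One MHFE forward pass with freshly initialized weights (eval mode)."""
    enc = MHFE(cfg, np.random.default_rng(seed)).eval()
    return enc.forward(volume)


def mlfe_forward(volume, cfg: EncoderConfig, seed=0):
    """One MLFE forward pass with freshly initialized weights (eval mode)."""
    enc = MLFE(cfg, np.random.default_rng(seed)).eval()
    return enc.forward(volume)


def fc_mlp_forward(fc, cfg: EncoderConfig, seed=0):
    """One FC-MLP forward pass with freshly initialized weights (eval mode)."""
    enc = FCMLP(cfg, np.random.default_rng(seed)).eval()
    return enc.forward(fc)
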