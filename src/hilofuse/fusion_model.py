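"""Cross-fusion of the four frequency features, the seven-head probability
septet, and threshold majority voting.

The four volume-derived features - sMRI-high (s_high), sMRI-low (s_low),
FAM-high (f_high), FAM-low (f_low) - are fused pairwise (all C(4,2) = 6
unordered pairs) by concatenation, each pair feeding an independent linear
head that emits one logit.  Together with the FC-MLP logit this gives seven
sigmoid probabilities; the diagnosis is the majority of the seven thresholded
votes.  Head order is fixed:

    1. HH   s_high x f_high   (high-high, across modalities)
    2. LL   s_low  x f_low    (low-low, across modalities)
    3.      s_high x s_low    (high-low, within sMRI)
    4.      f_high x f_low    (high-low, within FAM)
    5.      s_high x f_low    (high-low, across modalities)
    6.      s_low  x f_high   (high-low, across modalities)
    7.      FC-MLP head (fMRI)
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .encoders import MHFE, MLFE, FCMLP, EncoderConfig

CHECKPOINT_VERSION = "hilofuse-checkpoint-1"

FUSION_PAIRS = (
    ("s_high", "f_high"),
    ("s_low", "f_low"),
    ("s_high", "s_low"),
    ("f_high", "f_low"),
    ("s_high", "f_low"),
    ("s_low", "f_high"),
)

#: inputs required by each of the 7 voting heads (6 fusion heads + fMRI head)
HEAD_REQUIREMENTS = tuple(
    [frozenset(pair) for pair in FUSION_PAIRS] + [frozenset({"fc"})]
)


@dataclass
class FeatureBundle:
    """The four volume-derived feature matrices (N x len) plus the fMRI
    logit vector (N,)."""

    s_high: np.ndarray
    s_low: np.ndarray
    f_high: np.ndarray
    f_low: np.ndarray
    fc_logit: np.ndarray

    def __getitem__(self, name):
        return getattr(self, name)


@dataclass(frozen=True)
class VoteConfig:
    threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(
                f"threshold must be strictly inside (0, 1), got {self.threshold}")


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cross_fuse(bundle: FeatureBundle):
    """Concatenate the six unordered feature pairs in the fixed head order."""
    fused = []
    for a, b in FUSION_PAIRS:
        fa, fb = bundle[a], bundle[b]
        if fa.ndim != 2 or fb.ndim != 2 or fa.shape[0] != fb.shape[0]:
            raise ValueError(
                f"features {a} {fa.shape} and {b} {fb.shape} are not "
                f"batch-aligned 2D arrays")
        fused.append(np.concatenate([fa, fb], axis=1))
    return fused


def majority_vote(probs, threshold=0.5):
    """Threshold each probability (strict '>'), take the majority.

    Works for any voter count: a label of 1 requires strictly more than half
    the votes, so even-count ties resolve to HC (0).  Accepts a single septet
    or an (N, k) batch.
    """
    if isinstance(threshold, VoteConfig):
        threshold = threshold.threshold
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    p = np.asarray(probs, dtype=np.float64)
    squeeze = p.ndim == 1
    if squeeze:
        p = p[None, :]
    if p.ndim != 2 or p.shape[1] < 1:
        raise ValueError(f"expected a vector or batch of probabilities, got {p.shape}")
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probabilities must be finite and within [0, 1]")
    votes = (p > threshold).sum(axis=1)
    labels = (votes > p.shape[1] // 2).astype(int)
    return int(labels[0]) if squeeze else labels


def validate_septet(probs):
    p = np.asarray(probs, dtype=np.float64)
    if p.shape != (7,) and (p.ndim != 2 or p.shape[1] != 7):
        raise ValueError(f"a probability septet has 7 entries, got shape {p.shape}")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("septet entries must be finite probabilities in [0, 1]")
    return p


class FusionHeads(nn.Module):
    """Six independent linear heads, one per fused pair."""

    def __init__(self, dims, rng):
        super().__init__()
        self.heads = [nn.Linear(d, 1, rng) for d in dims]
        self.dims = tuple(dims)

    def forward(self, fused):
        if len(fused) != len(self.heads):
            raise ValueError(
                f"expected {len(self.heads)} fused vectors, got {len(fused)}")
        logits = []
        for x, head, d in zip(fused, self.heads, self.dims):
            if x.shape[-1] != d:
                raise ValueError(
                    f"fused vector has length {x.shape[-1]}, head expects {d}")
            logits.append(head.forward(x.astype(nn.DTYPE))[:, 0])
        return np.stack(logits, axis=1)  # (N, 6)

    def backward(self, grad):
        return [head.backward(grad[:, k:k + 1])
                for k, head in enumerate(self.heads)]


class FusionModel(nn.Module):
    """End-to-end model: shared meta-encoders, FC-MLP, six fusion heads.

    Both volumes pass through the *same* MHFE and MLFE instances (they are
    meta-encoders applied per modality); the two modalities are stacked along
    the batch axis so the shared encoders see them jointly.
    """

    def __init__(self, cfg: EncoderConfig, rng=None, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed) if rng is None else rng
        self.cfg = cfg
        self.mhfe = MHFE(cfg, rng)
        self.mlfe = MLFE(cfg, rng)
        self.fc_mlp = FCMLP(cfg, rng)
        hi, lo = self.mhfe.out_dim, self.mlfe.out_dim
        dim = {"s_high": hi, "f_high": hi, "s_low": lo, "f_low": lo}
        self.heads = FusionHeads(
            [dim[a] + dim[b] for a, b in FUSION_PAIRS], rng)

    # -- forward -----------------------------------------------------------
    def extract_features(self, smri, fam, fc) -> FeatureBundle:
        smri = np.asarray(smri, dtype=nn.DTYPE)
        fam = np.asarray(fam, dtype=nn.DTYPE)
        if smri.ndim == 3:
            smri, fam = smri[None], fam[None]
            fc = np.asarray(fc)[None]
        n = smri.shape[0]
        vols = np.concatenate([smri, fam], axis=0)
        high = self.mhfe.forward(vols)
        low = self.mlfe.forward(vols)
        fc_logit = self.fc_mlp.forward(fc)
        return FeatureBundle(
            s_high=high[:n], f_high=high[n:],
            s_low=low[:n], f_low=low[n:], fc_logit=fc_logit)

    def forward_logits(self, smri, fam, fc):
        bundle = self.extract_features(smri, fam, fc)
        if self.training:
            self._n = bundle.s_high.shape[0]
        fused = cross_fuse(bundle)
        logits6 = self.heads.forward(fused)
        return np.concatenate([logits6, bundle.fc_logit[:, None]], axis=1)

    def forward(self, batch):
        return self.forward_logits(*batch)

    def predict_proba(self, smri, fam, fc):
        """Seven sigmoid probabilities per subject, shape (N, 7)."""
        return sigmoid(self.forward_logits(smri, fam, fc))

    def predict(self, smri, fam, fc, threshold=0.5):
        return majority_vote(self.predict_proba(smri, fam, fc), threshold)

    # -- backward ----------------------------------------------------------
    def backward(self, grad_logits):
        """grad_logits: (N, 7) gradient w.r.t. the seven raw logits."""
        n = self._n
        g = np.asarray(grad_logits, dtype=nn.DTYPE)
        self.fc_mlp.backward(g[:, 6])
        gfused = self.heads.backward(g[:, :6])
        hi = self.mhfe.out_dim
        gfeat = {k: 0.0 for k in ("s_high", "s_low", "f_high", "f_low")}
        for (a, b), gf in zip(FUSION_PAIRS, gfused):
            da = hi if a.endswith("high") else self.mlfe.out_dim
            gfeat[a] = gfeat[a] + gf[:, :da]
            gfeat[b] = gfeat[b] + gf[:, da:]
        ghigh = np.concatenate([gfeat["s_high"], gfeat["f_high"]], axis=0)
        glow = np.concatenate([gfeat["s_low"], gfeat["f_low"]], axis=0)
        self.mhfe.backward(ghigh)
        self.mlfe.backward(glow)


def forward_subject(record, model: FusionModel, threshold=0.5):
    """Run one SubjectRecord through the model: probabilities and the voted
    diagnosis."""
    was_training = model.training
    model.eval()
    probs = model.predict_proba(record.smri, record.fam, record.fc)[0]
    if was_training:
        model.train()
    return probs, majority_vote(probs, threshold)


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(model: FusionModel, path):
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "config": model.cfg.to_dict()})
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path) -> FusionModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('version')!r}")
        cfg = EncoderConfig.from_dict(meta["config"])
        model = FusionModel(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    model.eval()
    return model
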