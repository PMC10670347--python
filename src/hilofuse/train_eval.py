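"""Training protocol, data splits, cross-validation and the ablation harness.

Training follows the reference protocol: per-head binary cross-entropy
averaged over the seven heads, Adam (lr 9e-4, weight decay 1e-8), batch size
4.  Evaluation thresholds each head's sigmoid probability and takes the
majority vote; the continuous score used for AUC is the mean of the active
heads' probabilities (the vote itself is discrete).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .cohort_sim import CohortManifest
from .encoders import EncoderConfig
from .fusion_model import (
    FusionModel,
    HEAD_REQUIREMENTS,
    majority_vote,
    sigmoid,
)
from .metrics import ConfusionMatrix, MetricSet, confusion_metrics, metric_mean_sd, roc_auc
from .volume_io import normalize_volume

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-7

#: which abstract inputs each data modality provides
MODALITY_FEATURES = {
    "sMRI": frozenset({"s_high", "s_low"}),
    "fMRI": frozenset({"fc"}),
    "DTI": frozenset({"f_high", "f_low"}),
}

#: branch ablations: heads fed exclusively by one processing branch
BRANCH_HEADS = {
    "MHFE": (0,),        # HH fusion: s_high x f_high
    "MLFE": (1,),        # LL fusion: s_low x f_low
    "fMRI": (6,),        # FC-MLP head
}


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 4
    learning_rate: float = 9e-4
    weight_decay: float = 1e-8
    optimizer: str = "adam"
    loss: str = "bce"
    folds: int = 4
    split_ratio: tuple = (3, 1)
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.folds) < 1:
            raise ValueError("epochs, batch_size and folds must all be >= 1")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss.lower() != "bce":
            raise ValueError(f"unsupported loss {self.loss!r}")
        object.__setattr__(self, "split_ratio",
                           tuple(int(r) for r in self.split_ratio))

    @classmethod
    def smoke(cls, **overrides):
        """Short-run profile for CPU-scale synthetic cohorts."""
        base = dict(epochs=15)
        base.update(overrides)
        return cls(**base)


@dataclass
class CVSummary:
    per_fold: list
    mean: MetricSet
    sd: MetricSet


# ---------------------------------------------------------------------------
# data plumbing

def _records_of(data):
    return data.records if isinstance(data, CohortManifest) else list(data)


def prepare_arrays(records, normalize=True):
    """Stack SubjectRecords into model-ready arrays.

    Volumes are min-max normalized per volume (matching the preprocessing
    contract) unless ``normalize=False``.
    """
    def prep(v):
        return normalize_volume(v) if normalize else v
    smri = np.stack([prep(r.smri) for r in records]).astype(nn.DTYPE)[:, None]
    fam = np.stack([prep(r.fam) for r in records]).astype(nn.DTYPE)[:, None]
    fc = np.stack([r.fc for r in records]).astype(nn.DTYPE)
    y = np.array([r.label for r in records], dtype=np.float64)
    return smri, fam, fc, y


def split_train_test(data, ratio=(3, 1), seed=0):
    """Disjoint, exhaustive shuffled split; test size = round(n * r_test/total).

    116 records at 3:1 give the canonical 87/29 partition.
    """
    records = _records_of(data)
    n = len(records)
    r_train, r_test = (int(r) for r in ratio)
    if r_train < 1 or r_test < 1:
        raise ValueError(f"split ratio parts must be >= 1, got {ratio}")
    n_test = int(round(n * r_test / (r_train + r_test)))
    n_train = n - n_test
    if n_test < 1 or n_train < 1:
        raise ValueError(
            f"ratio {r_train}:{r_test} infeasible for n={n} records")
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [records[i] for i in range(n) if i not in test_idx]
    test = [records[i] for i in sorted(test_idx)]
    return train, test


def make_folds(n, folds, seed=0):
    """Shuffled partition into ``folds`` near-equal index arrays."""
    if n < folds:
        raise ValueError(f"cannot make {folds} folds from {n} records")
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(order, folds)]


# ---------------------------------------------------------------------------
# loss

def compute_loss(probs, label):
    """Mean binary cross-entropy over the seven heads for one subject (or a
    batch), with probabilities clamped at 1e-7."""
    p = np.clip(np.asarray(probs, dtype=np.float64), PROB_CLAMP, 1 - PROB_CLAMP)
    y = np.asarray(label, dtype=np.float64)
    if p.ndim == 1:
        p = p[None, :]
        y = np.atleast_1d(y)
    ll = y[:, None] * np.log(p) + (1 - y[:, None]) * np.log(1 - p)
    return float(-ll.mean())


def _bce_logits_loss_grad(logits, y):
    """Numerically stable BCE-with-logits; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64)
    yb = y[:, None]
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    loss = np.maximum(z, 0) - z * yb + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - yb) / z.size
    return float(loss.mean()), grad


# ---------------------------------------------------------------------------
# training

def train(data, model_cfg: EncoderConfig, train_cfg: TrainConfig,
          normalize=True):
    """Train a FusionModel on a cohort; returns (model, history).

    History is a list of dicts with epoch, step and loss; an additional
    per-epoch summary row has step = -1.  Deterministic given
    ``train_cfg.seed`` (weight init, shuffling and dropout all derive from
    it).  A non-finite loss aborts with :class:`TrainingDivergedError`.
    """
    records = _records_of(data)
    smri, fam, fc, y = prepare_arrays(records, normalize=normalize)
    rng = np.random.default_rng(train_cfg.seed)
    model = FusionModel(model_cfg, rng=rng)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate,
                  weight_decay=train_cfg.weight_decay)
    n = len(records)
    bs = train_cfg.batch_size
    history = []
    model.train()
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for step, start in enumerate(range(0, n, bs)):
            idx = order[start:start + bs]
            logits = model.forward_logits(smri[idx], fam[idx], fc[idx])
            loss, grad = _bce_logits_loss_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
            history.append({"epoch": epoch, "step": step, "loss": loss})
            logger.debug("epoch=%d step=%d loss=%.5f", epoch, step, loss)
        history.append({"epoch": epoch, "step": -1,
                        "loss": float(np.mean(epoch_losses))})
    model.eval()
    return model, history


def evaluate(model: FusionModel, records, threshold=0.5, voters=None,
             normalize=True):
    """Evaluate on records; returns (predictions DataFrame, MetricSet).

    ``voters`` restricts the vote to a subset of head indices (ablations);
    the AUC score is the mean probability of the active voters.
    """
    voters = tuple(range(7)) if voters is None else tuple(voters)
    if not voters:
        raise ValueError("need at least one voting head")
    smri, fam, fc, y = prepare_arrays(records, normalize=normalize)
    model.eval()
    probs = sigmoid(model.forward_logits(smri, fam, fc))
    active = probs[:, list(voters)]
    preds = majority_vote(active, threshold)
    scores = active.mean(axis=1)
    rows = []
    for i, rec in enumerate(records):
        row = {"subject_id": rec.subject_id}
        row.update({f"p{k + 1}": probs[i, k] for k in range(7)})
        row["votes"] = int((active[i] > threshold).sum())
        row["label_pred"] = int(preds[i])
        row["label_true"] = int(y[i])
        rows.append(row)
    cm = ConfusionMatrix.from_predictions(y.astype(int), preds)
    ms = confusion_metrics(cm)
    if len(set(y.astype(int))) == 2:
        ms.auc = roc_auc(scores, y.astype(int))
    return pd.DataFrame(rows), ms


def cross_validate(data, model_cfg: EncoderConfig, train_cfg: TrainConfig,
                   threshold=0.5, voters=None) -> CVSummary:
    """k-fold cross-validation: each fold serves once as the test set; the
    fold metrics are summarized as mean and SD."""
    records = _records_of(data)
    folds = make_folds(len(records), train_cfg.folds, seed=train_cfg.seed)
    per_fold = []
    for k, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_recs = [r for i, r in enumerate(records) if i not in test_set]
        test_recs = [records[i] for i in test_idx]
        model, _ = train(train_recs, model_cfg, train_cfg)
        _, ms = evaluate(model, test_recs, threshold=threshold, voters=voters)
        logger.info("fold %d: acc=%.3f", k, ms.acc)
        per_fold.append(ms)
    mean, sd = metric_mean_sd(per_fold)
    return CVSummary(per_fold=per_fold, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# ablations

def voters_for_modalities(modalities):
    """Head indices whose required inputs are all provided by the given
    modality subset (e.g. sMRI alone keeps only the s_high x s_low head)."""
    modalities = set(modalities)
    unknown = modalities - set(MODALITY_FEATURES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    if not modalities:
        raise ValueError("empty modality subset")
    available = frozenset().union(*(MODALITY_FEATURES[m] for m in modalities))
    return tuple(k for k, req in enumerate(HEAD_REQUIREMENTS)
                 if req <= available)


def voters_for_branches(branches):
    """Head indices for branch ablations over {MHFE, MLFE, fMRI}."""
    branches = list(branches)
    unknown = set(branches) - set(BRANCH_HEADS)
    if unknown:
        raise ValueError(f"unknown branches: {sorted(unknown)}")
    if not branches:
        raise ValueError("empty branch subset")
    out = []
    for b in branches:
        out.extend(BRANCH_HEADS[b])
    return tuple(sorted(set(out)))


def run_ablation(model: FusionModel, records, subsets, kind="modalities",
                 threshold=0.5):
    """Evaluate a trained model under voter-restricted ablations.

    ``subsets`` is an iterable of modality tuples (kind='modalities') or
    branch tuples (kind='branches').  Returns {subset name: MetricSet}.
    """
    resolve = {"modalities": voters_for_modalities,
               "branches": voters_for_branches}[kind]
    results = {}
    for subset in subsets:
        subset = (subset,) if isinstance(subset, str) else tuple(subset)
        voters = resolve(subset)
        if not voters:
            raise ValueError(f"subset {subset} leaves no voting heads")
        _, ms = evaluate(model, records, threshold=threshold, voters=voters)
        results["+".join(subset)] = ms
    return results


# ---------------------------------------------------------------------------
# single-branch diagnostic probes

class BranchClassifier(nn.Module):
    """One volume encoder (MHFE or MLFE) plus a linear head.

    A diagnostic model for asking which frequency band a planted class effect
    lives in: each branch is trained end-to-end as a stand-alone classifier on
    one volume modality and their test accuracies are compared.
    """

    def __init__(self, model_cfg: EncoderConfig, branch: str, rng):
        super().__init__()
        from .encoders import MHFE, MLFE

        if branch not in ("mhfe", "mlfe"):
            raise ValueError(f"branch must be 'mhfe' or 'mlfe', got {branch!r}")
        self.branch = branch
        self.enc = (MHFE if branch == "mhfe" else MLFE)(model_cfg, rng)
        self.head = nn.Linear(self.enc.out_dim, 1, rng)

    def forward(self, vols):
        return self.head.forward(self.enc.forward(vols))[:, 0]

    def backward(self, grad):
        g = self.head.backward(np.asarray(grad, dtype=nn.DTYPE)[:, None])
        self.enc.backward(g)


def train_branch_classifier(records, model_cfg: EncoderConfig,
                            train_cfg: TrainConfig, branch: str,
                            modality: str = "smri", normalize: bool = False):
    """Train a single-branch classifier on one volume modality.

    Volumes default to raw (un-normalized) intensities so the planted
    frequency content is not redistributed by per-volume min-max scaling.
    """
    records = _records_of(records)
    vols = _modality_volumes(records, modality, normalize)
    y = np.array([r.label for r in records], dtype=np.float64)
    rng = np.random.default_rng(train_cfg.seed)
    model = BranchClassifier(model_cfg, branch, rng)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate,
                  weight_decay=train_cfg.weight_decay)
    n = len(records)
    model.train()
    for _ in range(train_cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            z = model.forward(vols[idx])
            loss, grad = _bce_logits_loss_grad(z[:, None], y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(-1)
            opt.zero_grad()
            model.backward(grad[:, 0])
            opt.step()
    model.eval()
    return model


def branch_accuracy(model: BranchClassifier, records, modality: str = "smri",
                    normalize: bool = False) -> float:
    """Test accuracy of a single-branch classifier at threshold 0.5."""
    records = _records_of(records)
    vols = _modality_volumes(records, modality, normalize)
    y = np.array([r.label for r in records], dtype=int)
    model.eval()
    pred = (sigmoid(model.forward(vols)) > 0.5).astype(int)
    return float((pred == y).mean())


def _modality_volumes(records, modality, normalize):
    if modality not in ("smri", "fam"):
        raise ValueError(f"modality must be 'smri' or 'fam', got {modality!r}")
    def prep(v):
        return normalize_volume(v) if normalize else v
    return np.stack(
        [prep(getattr(r, modality)) for r in records]).astype(nn.DTYPE)[:, None]
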