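"""Confusion-matrix classification metrics, an inverse solver that
reconstructs integer confusion matrices from printed 3-decimal metric rows,
and rank-based ROC AUC.

All metric arithmetic is exact (``fractions.Fraction``); rounding happens
only at presentation.  Zero-denominator metrics are defined as 0 and flagged
rather than raised, so degenerate ablation rows still tabulate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import rankdata


class InconsistentRowError(ValueError):
    """No integer confusion matrix reproduces the given rounded metrics."""


class AmbiguousRowError(ValueError):
    """Multiple confusion matrices reproduce the given rounded metrics."""

    def __init__(self, msg, candidates):
        super().__init__(msg)
        self.candidates = candidates


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self):
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred):
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass
class MetricSet:
    """ACC / PREC / REC / SPE / F1 / MCC (+ optional AUC).

    ``flags`` lists metrics whose denominator was zero and were defined as 0.
    """

    acc: float
    prec: float
    rec: float
    spe: float
    f1: float
    mcc: float
    auc: float | None = None
    flags: tuple = ()

    def as_dict(self):
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d


def _ratio(num, den, name, flags):
    if den == 0:
        flags.append(name)
        return Fraction(0)
    return Fraction(num, den)


def confusion_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Exact metrics from integer counts.

    F1 is computed as 2TP / (2TP + FP + FN), algebraically identical to
    2*PREC*REC / (PREC + REC) on exact values.  MCC uses the standard
    covariance form; a zero product in its denominator yields 0 (flagged).
    """
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    if cm.total == 0:
        raise ValueError("confusion matrix with zero total has no metrics")
    flags: list = []
    acc = Fraction(tp + tn, cm.total)
    prec = _ratio(tp, tp + fp, "prec", flags)
    rec = _ratio(tp, tp + fn, "rec", flags)
    spe = _ratio(tn, tn + fp, "spe", flags)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", flags)
    denom_sq = (tn + fp) * (fn + tp) * (tn + fn) * (tp + fp)
    if denom_sq == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tn * tp - fn * fp) / np.sqrt(float(denom_sq))
    return MetricSet(acc=float(acc), prec=float(prec), rec=float(rec),
                     spe=float(spe), f1=float(f1), mcc=float(mcc),
                     flags=tuple(flags))


def round_half_away(x, dp=3):
    """Round half away from zero at ``dp`` decimals (print-style rounding).

    Exact for Fraction/int input; floats are converted through Fraction.
    """
    f = Fraction(x).limit_denominator(10 ** 12) if isinstance(x, float) else Fraction(x)
    scale = 10 ** dp
    scaled = f * scale
    if scaled >= 0:
        q = (scaled + Fraction(1, 2)).__floor__()
    else:
        q = -((-scaled + Fraction(1, 2)).__floor__())
    return q / Fraction(scale)


def _exact_metrics_fraction(tp, fn, fp, tn):
    n = tp + fn + fp + tn
    acc = Fraction(tp + tn, n)
    prec = Fraction(tp, tp + fp) if tp + fp else Fraction(0)
    rec = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
    spe = Fraction(tn, tn + fp) if tn + fp else Fraction(0)
    return acc, prec, rec, spe


def solve_confusion(acc, prec, rec, spe, n, dp=3) -> ConfusionMatrix:
    """Recover the integer confusion matrix behind a printed metric row.

    Exhaustively enumerates all non-negative quadruples (TP, FN, FP, TN)
    summing to ``n`` and keeps those whose exact ACC/PREC/REC/SPE round (half
    away from zero) to the given ``dp``-decimal values.  Raises
    :class:`InconsistentRowError` if none match and :class:`AmbiguousRowError`
    (listing candidates) if more than one does.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    targets = tuple(round_half_away(v, dp) for v in (acc, prec, rec, spe))
    hits = []
    for tp in range(n + 1):
        for fn in range(n + 1 - tp):
            for fp in range(n + 1 - tp - fn):
                tn = n - tp - fn - fp
                got = _exact_metrics_fraction(tp, fn, fp, tn)
                if all(round_half_away(g, dp) == t
                       for g, t in zip(got, targets)):
                    hits.append(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
    if not hits:
        raise InconsistentRowError(
            f"inconsistent row: no confusion matrix with n={n} rounds to "
            f"ACC={acc}, PREC={prec}, REC={rec}, SPE={spe} at {dp} dp")
    if len(hits) > 1:
        raise AmbiguousRowError(
            f"ambiguous row: {len(hits)} matrices match "
            f"(e.g. {hits[0]} and {hits[1]})", hits)
    return hits[0]


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic P(score+ > score-) + 0.5 P(tie),
    computed by midrank summation."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1D arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metric_mean_sd(metric_sets):
    """Elementwise mean and (population) SD over a list of MetricSets."""
    if not metric_sets:
        raise ValueError("need at least one MetricSet")
    keys = ["acc", "prec", "rec", "spe", "f1", "mcc"]
    has_auc = all(m.auc is not None for m in metric_sets)
    if has_auc:
        keys.append("auc")
    arr = np.array([[getattr(m, k) for k in keys] for m in metric_sets])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    def build(vals):
        d = dict(zip(keys, (float(v) for v in vals)))
        d.setdefault("auc", None)
        return MetricSet(**d)
    return build(mean), build(sd)


def audit_table(rows, n, dp=3):
    """Validate printed metric rows by reconstruction.

    ``rows`` is an iterable of dicts with keys name, acc, prec, rec, spe and
    optionally f1, mcc.  For each row the solver recovers the confusion
    matrix (or reports why it cannot) and, when f1/mcc are given, checks them
    at ``dp`` decimals against the reconstruction.
    """
    report = []
    for row in rows:
        entry = {"name": row.get("name", "?")}
        try:
            cm = solve_confusion(row["acc"], row["prec"], row["rec"],
                                 row["spe"], n=n, dp=dp)
        except (InconsistentRowError, AmbiguousRowError) as exc:
            entry.update(status=type(exc).__name__, detail=str(exc))
            report.append(entry)
            continue
        ms = confusion_metrics(cm)
        entry.update(status="ok", tp=cm.tp, fn=cm.fn, fp=cm.fp, tn=cm.tn,
                     f1=round(ms.f1, dp), mcc=round(ms.mcc, dp))
        for key in ("f1", "mcc"):
            if key in row and row[key] is not None:
                match = float(round_half_away(getattr(ms, key), dp)) == float(
                    round_half_away(float(row[key]), dp))
                entry[f"{key}_matches"] = bool(match)
        report.append(entry)
    return report
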