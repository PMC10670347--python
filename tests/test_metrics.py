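"""Exact confusion-matrix metrics, the inverse row solver, and rank AUC.

Independent oracles: sklearn.metrics on expanded label arrays, a plain
float-formula evaluation, and O(n^2) pairwise AUC counting.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from hilofuse.metrics import (
    AmbiguousRowError,
    ConfusionMatrix,
    InconsistentRowError,
    audit_table,
    confusion_metrics,
    metric_mean_sd,
    roc_auc,
    round_half_away,
    solve_confusion,
)


def expand(cm):
    y_true = [1] * (cm.tp + cm.fn) + [0] * (cm.fp + cm.tn)
    y_pred = [1] * cm.tp + [0] * cm.fn + [1] * cm.fp + [0] * cm.tn
    return np.array(y_true), np.array(y_pred)


class TestConfusionMetrics:
    def test_random_matrices_match_float_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            tp, fn, fp, tn = rng.integers(0, 51, size=4)
            if tp + fn + fp + tn == 0:
                continue
            ms = confusion_metrics(ConfusionMatrix(tp, fn, fp, tn))
            n = tp + fn + fp + tn
            assert abs(ms.acc - (tp + tn) / n) < 1e-12
            assert abs(ms.prec - (tp / (tp + fp) if tp + fp else 0)) < 1e-12
            assert abs(ms.rec - (tp / (tp + fn) if tp + fn else 0)) < 1e-12
            assert abs(ms.spe - (tn / (tn + fp) if tn + fp else 0)) < 1e-12
            f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0
            assert abs(ms.f1 - f1) < 1e-12
            den = (tn + fp) * (fn + tp) * (tn + fn) * (tp + fp)
            mcc = (tn * tp - fn * fp) / np.sqrt(den) if den else 0.0
            assert abs(ms.mcc - mcc) < 1e-12

    def test_random_matrices_match_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            tp, fn, fp, tn = rng.integers(1, 40, size=4)
            cm = ConfusionMatrix(tp, fn, fp, tn)
            ms = confusion_metrics(cm)
            y_true, y_pred = expand(cm)
            assert abs(ms.acc - skm.accuracy_score(y_true, y_pred)) < 1e-12
            assert abs(ms.prec - skm.precision_score(y_true, y_pred)) < 1e-12
            assert abs(ms.rec - skm.recall_score(y_true, y_pred)) < 1e-12
            assert abs(ms.f1 - skm.f1_score(y_true, y_pred)) < 1e-12
            assert abs(ms.mcc - skm.matthews_corrcoef(y_true, y_pred)) < 1e-10

    def test_perfect_classifier(self):
        ms = confusion_metrics(ConfusionMatrix(3, 0, 0, 5))
        assert (ms.acc, ms.prec, ms.rec, ms.spe, ms.f1, ms.mcc) == (1,) * 6

    def test_degenerate_column_flagged_zeros(self):
        ms = confusion_metrics(ConfusionMatrix(0, 5, 0, 5))
        assert ms.rec == 0.0 and ms.prec == 0.0 and ms.mcc == 0.0
        assert {"prec", "mcc"} <= set(ms.flags)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_mcc_sign_iff_diagonal_dominance(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(1, 30, size=4)
            ms = confusion_metrics(ConfusionMatrix(tp, fn, fp, tn))
            if tn * tp < fn * fp:
                assert ms.mcc < 0
            elif tn * tp > fn * fp:
                assert ms.mcc > 0


class TestSolveConfusion:
    @pytest.mark.parametrize("row,expected", [
        ((0.724, 0.750, 0.500, 0.882), (6, 6, 2, 15)),
        ((0.517, 0.444, 0.667, 0.412), (8, 4, 10, 7)),
        ((0.517, 0.400, 0.333, 0.647), (4, 8, 6, 11)),
        ((0.690, 0.667, 0.500, 0.824), (6, 6, 3, 14)),
    ])
    def test_published_rows_reconstruct_uniquely(self, row, expected):
        cm = solve_confusion(*row, n=29)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == expected

    def test_inverse_of_confusion_metrics(self):
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(200):
            parts = rng.multinomial(29, [0.25] * 4)
            cm = ConfusionMatrix(*[int(v) for v in parts])
            ms = confusion_metrics(cm)
            try:
                back = solve_confusion(ms.acc, ms.prec, ms.rec, ms.spe, n=29)
            except AmbiguousRowError:
                continue  # 3-dp rounding not injective for this row
            assert back == cm
            checked += 1
        assert checked > 150

    def test_designed_ambiguity_flagged(self):
        with pytest.raises(AmbiguousRowError) as exc:
            solve_confusion(1.0, 1.0, 1.0, 1.0, n=4)
        assert len(exc.value.candidates) >= 2

    def test_inconsistent_row_flagged(self):
        with pytest.raises(InconsistentRowError):
            solve_confusion(0.9, 0.1, 0.9, 0.1, n=5)

    def test_rounding_half_away_from_zero(self):
        from fractions import Fraction
        assert round_half_away(Fraction(1, 2), 0) == 1
        assert round_half_away(Fraction(-1, 2), 0) == -1
        assert float(round_half_away(Fraction(7241, 10000), 3)) == 0.724


class TestRocAuc:
    def test_perfect_and_reversed(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_tied_scores_match_pairwise_oracle(self):
        scores = np.array([0.1, 0.4, 0.4, 0.6, 0.6, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, labels) == wins / (len(pos) * len(neg))

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(4, 40)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 1)  # force ties
            assert abs(roc_auc(scores, labels)
                       - skm.roc_auc_score(labels, scores)) < 1e-12

    @given(st.floats(0.01, 5.0), st.floats(-3.0, 3.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transform(self, a, b):
        rng = np.random.default_rng(5)
        scores = rng.random(20)
        labels = np.array([0, 1] * 10)
        assert abs(roc_auc(scores, labels)
                   - roc_auc(a * scores + b, labels)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestMeanSd:
    def test_matches_hand_computation(self):
        sets = [confusion_metrics(ConfusionMatrix(5, 2, 1, 7)),
                confusion_metrics(ConfusionMatrix(4, 3, 2, 6))]
        mean, sd = metric_mean_sd(sets)
        accs = [m.acc for m in sets]
        assert abs(mean.acc - np.mean(accs)) < 1e-12
        assert abs(sd.acc - np.std(accs)) < 1e-12


class TestAuditTable:
    def test_reports_reconstruction_and_f1_mcc_agreement(self):
        rows = [
            dict(name="full", acc=0.724, prec=0.750, rec=0.500, spe=0.882,
                 f1=0.600, mcc=0.421),
            dict(name="broken", acc=0.9, prec=0.1, rec=0.9, spe=0.1),
        ]
        report = audit_table(rows, n=29)
        assert report[0]["status"] == "ok"
        assert report[0]["f1_matches"] and report[0]["mcc_matches"]
        assert report[1]["status"] == "InconsistentRowError"
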