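"""Reconstruct the integer confusion matrices behind published metric rows.

A row printed as (ACC, PREC, REC, SPE) at three decimals over a known test
set size usually pins down a unique integer confusion matrix; the remaining
metrics (F1, MCC) then follow exactly and can be cross-checked against the
printed values.
"""

from hilofuse.metrics import confusion_metrics, solve_confusion

rows = {
    "sMRI + fMRI + DTI": (0.724, 0.750, 0.500, 0.882),
    "sMRI + fMRI": (0.690, 0.667, 0.500, 0.824),
    "fMRI": (0.517, 0.444, 0.667, 0.412),
    "DTI": (0.517, 0.400, 0.333, 0.647),
}

for name, row in rows.items():
    cm = solve_confusion(*row, n=29)
    ms = confusion_metrics(cm)
    print(f"{name:18s} -> TP={cm.tp:2d} FN={cm.fn:2d} FP={cm.fp:2d} "
          f"TN={cm.tn:2d}   F1={ms.f1:.3f}  MCC={ms.mcc:+.3f}")
print("each quadruple is the unique one whose exact metrics round to the "
      "printed values; F1/MCC are derived, not fitted")
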