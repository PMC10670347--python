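"""Volume and connectivity I/O: NIfTI read/write, nearest-neighbor resampling
to the model's cubic input, min-max normalization, and Pearson functional
connectivity from ROI time series.

All geometry is handled in array-index (voxel) coordinates; NIfTI affines are
passed through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORM_EPS = 1e-9

MANIFEST_COLUMNS = ["subject_id", "smri_path", "fam_path", "fc_path", "label"]


@dataclass
class SubjectRecord:
    """One subject's three modalities plus the diagnostic label (MDD=1, HC=0)."""

    subject_id: str
    smri: np.ndarray
    fam: np.ndarray
    fc: np.ndarray
    label: int

    def __post_init__(self):
        self.label = int(self.label)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        for name, vol in (("smri", self.smri), ("fam", self.fam)):
            if vol.ndim != 3:
                raise ValueError(f"{name} must be a 3D volume, got ndim={vol.ndim}")
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"{name} contains non-finite values")
        if self.fc.ndim != 2 or self.fc.shape[0] != self.fc.shape[1]:
            raise ValueError(f"fc must be square, got shape {self.fc.shape}")


def resample_nearest(volume: np.ndarray, target_shape) -> np.ndarray:
    """Nearest-neighbor resampling with the floor index contract
    ``i_src = floor(i_out * src / target)`` applied independently per axis.

    The output value set is a subset of the input value set (no interpolation).
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ValueError(f"target shape must be 3 positive ints, got {target_shape}")
    if any(s < 1 for s in volume.shape):
        raise ValueError(f"source volume has a zero-size axis: {volume.shape}")
    idx = [
        np.floor(np.arange(t) * s / t).astype(np.intp)
        for s, t in zip(volume.shape, target_shape)
    ]
    return volume[np.ix_(*idx)]


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Per-volume min-max scaling ``(x - min) / (max - min + 1e-9)``.

    The epsilon keeps constant volumes finite (they map to all zeros) and
    bounds the output in [0, 1).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    lo = volume.min()
    hi = volume.max()
    return (volume - lo) / (hi - lo + NORM_EPS)


def pearson_fc(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of ROI time series (rows = ROIs).

    Returns an R x R symmetric matrix with unit diagonal, entries clipped to
    [-1, 1] against floating-point overshoot.
    """
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError(f"time series must be 2D (rois x time), got {ts.shape}")
    n_rois, n_t = ts.shape
    if n_t < 3:
        raise ValueError(f"need at least 3 time points, got {n_t}")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ValueError(
            f"constant time series at ROI index {bad[0]}: correlation undefined")
    fc = np.corrcoef(ts)
    fc = np.clip(fc, -1.0, 1.0)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return fc


def check_fc(fc: np.ndarray, atol=1e-9):
    """Validate FC-matrix invariants: square, symmetric, diag 1, range [-1, 1]."""
    fc = np.asarray(fc)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"FC matrix must be square, got {fc.shape}")
    if not np.allclose(fc, fc.T, atol=atol):
        raise ValueError("FC matrix is not symmetric")
    if fc.min() < -1 - atol or fc.max() > 1 + atol:
        raise ValueError("FC entries outside [-1, 1]")
    return fc


# ---------------------------------------------------------------------------
# file helpers

def save_nifti(volume: np.ndarray, path, affine=None):
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64)


def save_fc_csv(fc: np.ndarray, path):
    np.savetxt(str(path), np.asarray(fc), delimiter=",")


def load_fc_csv(path) -> np.ndarray:
    return np.loadtxt(str(path), delimiter=",", ndmin=2)


def load_manifest(path, target_shape=None, normalize=True) -> list[SubjectRecord]:
    """Load a cohort manifest CSV into SubjectRecords.

    Each row names the three per-subject files.  Volumes are resampled to
    ``target_shape`` (if given) and min-max normalized.  Rows with a missing
    modality are excluded with a logged reason rather than failing the load.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    if len(df) == 0:
        logger.warning("manifest %s is empty", path)
        return []
    records = []
    for _, row in df.iterrows():
        paths = {}
        ok = True
        for col in ("smri_path", "fam_path", "fc_path"):
            val = row[col]
            p = path.parent / str(val) if pd.notna(val) else None
            if p is None or not p.exists():
                logger.warning(
                    "excluding subject %s: missing modality %s (%s)",
                    row["subject_id"], col, val)
                ok = False
                break
            paths[col] = p
        if not ok:
            continue
        smri = load_nifti(paths["smri_path"])
        fam = load_nifti(paths["fam_path"])
        if target_shape is not None:
            smri = resample_nearest(smri, target_shape)
            fam = resample_nearest(fam, target_shape)
        if normalize:
            smri = normalize_volume(smri)
            fam = normalize_volume(fam)
        fc = check_fc(load_fc_csv(paths["fc_path"]))
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), smri=smri, fam=fam, fc=fc,
            label=int(row["label"])))
    return records
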