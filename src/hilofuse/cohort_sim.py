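"""Synthetic multimodal cohort generator with planted, frequency-specific
class effects.

Each subject gets two 3D volumes (a stand-in gray-matter map and a stand-in
fractional-anisotropy map), an ROI x ROI functional-connectivity matrix
derived from simulated time series, and a binary label (MDD=1, HC=0).  The
class signal is decomposed by spatial frequency so the two volume encoders can
be tested for frequency specialization:

* low-frequency effect - a fixed smooth global field (Gaussian-filtered white
  noise at length-scale ``smoothness``, standardized to unit variance) added
  with amplitude ``low_effect`` to MDD volumes only;
* high-frequency effect - a fixed alternating-sign voxel texture inside a
  centered cube of edge ``D // 2`` (about 1/8 of the volume), added with
  amplitude ``high_effect`` to MDD volumes only;
* connectivity effect - a latent-factor loading shift of ``fc_effect`` on a
  designated ROI block (the first quarter of ROIs) for MDD subjects, raising
  that block's pairwise correlations in expectation.

All subjects share a smooth "anatomy" background per modality, and i.i.d.
Gaussian noise of scale ``noise_sd`` is added everywhere, so with all effects
at zero the two classes are voxel-for-voxel identically distributed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume_io import (
    SubjectRecord,
    pearson_fc,
    save_fc_csv,
    save_nifti,
)

# latent-factor loadings shared by both classes
_GLOBAL_LOADING = 0.5
_BLOCK_BASE_LOADING = 0.2


@dataclass(frozen=True)
class SimParams:
    """Study conditions for a synthetic cohort.

    Defaults mirror the target dataset: 54 MDD + 62 HC, volumes at
    112 x 112 x 112, 116-ROI connectivity.  ``tiny()`` gives a 16-voxel-edge
    profile sized for CPU test runs.
    """

    n_mdd: int = 54
    n_hc: int = 62
    volume_shape: tuple = (112, 112, 112)
    n_rois: int = 116
    ts_length: int = 180
    low_effect: float = 1.5
    high_effect: float = 1.5
    fc_effect: float = 0.6
    noise_sd: float = 1.0
    smoothness: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_mdd", "n_hc", "n_rois", "ts_length"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        shape = tuple(int(s) for s in self.volume_shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(
                f"volume_shape must be 3 positive ints, got {self.volume_shape!r}")
        object.__setattr__(self, "volume_shape", shape)
        for name in ("low_effect", "high_effect", "fc_effect", "noise_sd",
                     "smoothness"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.smoothness < 0:
            raise ValueError(f"smoothness must be >= 0, got {self.smoothness}")

    @classmethod
    def tiny(cls, **overrides):
        """Small-volume profile for CPU-scale training and tests."""
        base = dict(
            n_mdd=32, n_hc=32, volume_shape=(16, 16, 16), n_rois=16,
            ts_length=60, low_effect=2.0, high_effect=2.0, fc_effect=0.8,
            noise_sd=1.0, smoothness=2.0, seed=0)
        base.update(overrides)
        return cls(**base)

    @property
    def n_subjects(self):
        return self.n_mdd + self.n_hc

    def roi_block(self):
        """ROI indices of the block carrying the connectivity effect."""
        return np.arange(max(self.n_rois // 4, 2))


@dataclass
class CohortManifest:
    """An in-memory cohort: ordered subject records plus the generating
    parameters (MDD subjects first, then HC)."""

    records: list
    seed: int
    params: SimParams

    @property
    def labels(self):
        return np.array([r.label for r in self.records], dtype=int)

    def __len__(self):
        return len(self.records)


def _smooth_unit_field(rng, shape, smoothness):
    """Gaussian-filtered white noise standardized to zero mean, unit SD."""
    f = rng.standard_normal(shape)
    if smoothness > 0:
        f = gaussian_filter(f, sigma=smoothness, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def high_frequency_texture(shape):
    """Fixed-phase alternating-sign voxel texture inside a centered cube of
    edge ``D // 2`` (zero outside).  Zero mean by construction on even edges."""
    d, h, w = shape
    ii, jj, kk = np.meshgrid(
        np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    tex = np.where((ii + jj + kk) % 2 == 0, 1.0, -1.0)
    mask = np.zeros(shape, dtype=bool)
    e = [max(s // 2, 1) for s in shape]
    start = [(s - ei) // 2 for s, ei in zip(shape, e)]
    mask[start[0]:start[0] + e[0],
         start[1]:start[1] + e[1],
         start[2]:start[2] + e[2]] = True
    return tex * mask, mask


def simulate_timeseries(params: SimParams, label: int, rng=None) -> np.ndarray:
    """ROI time series from a latent-factor model, shape (n_rois, ts_length).

    Every ROI loads on a shared global factor; the designated ROI block also
    loads on a block factor with loading ``_BLOCK_BASE_LOADING`` plus
    ``fc_effect`` for MDD subjects, which shifts within-block correlations.
    """
    if params.ts_length < 3:
        raise ValueError(
            f"ts_length must be >= 3 for correlations, got {params.ts_length}")
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    t = params.ts_length
    g = rng.standard_normal(t)
    b = rng.standard_normal(t)
    noise = rng.standard_normal((params.n_rois, t))
    loadings = np.zeros(params.n_rois)
    block = params.roi_block()
    loadings[block] = _BLOCK_BASE_LOADING + (params.fc_effect if label else 0.0)
    ts = _GLOBAL_LOADING * g[None, :] + loadings[:, None] * b[None, :] + noise
    return ts


def generate_cohort(params: SimParams) -> CohortManifest:
    """Generate a full synthetic cohort, deterministically from the seed.

    MDD subjects come first.  FC matrices are always computed from simulated
    time series via :func:`pearson_fc`, so symmetry and unit diagonal hold by
    construction.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.volume_shape
    # cohort-level fixed structure
    anatomy = {m: _smooth_unit_field(rng, shape, params.smoothness)
               for m in ("smri", "fam")}
    low_field = {m: _smooth_unit_field(rng, shape, params.smoothness)
                 for m in ("smri", "fam")}
    texture, _ = high_frequency_texture(shape)

    records = []
    labels = [1] * params.n_mdd + [0] * params.n_hc
    for i, label in enumerate(labels):
        vols = {}
        for m in ("smri", "fam"):
            v = anatomy[m].copy()
            if label == 1:
                v += params.low_effect * low_field[m]
                v += params.high_effect * texture
            if params.noise_sd > 0:
                v += params.noise_sd * rng.standard_normal(shape)
            vols[m] = v
        ts = simulate_timeseries(params, label, rng=rng)
        fc = pearson_fc(ts)
        records.append(SubjectRecord(
            subject_id=f"sub-{i + 1:04d}", smri=vols["smri"], fam=vols["fam"],
            fc=fc, label=label))
    return CohortManifest(records=records, seed=params.seed, params=params)


def write_cohort(cohort: CohortManifest, out_dir) -> Path:
    """Write a cohort to disk (NIfTI volumes, header-less FC CSVs, manifest
    CSV with relative paths).  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        smri = f"{rec.subject_id}_smri.nii.gz"
        fam = f"{rec.subject_id}_fam.nii.gz"
        fc = f"{rec.subject_id}_fc.csv"
        save_nifti(rec.smri, out_dir / smri)
        save_nifti(rec.fam, out_dir / fam)
        save_fc_csv(rec.fc, out_dir / fc)
        rows.append(dict(subject_id=rec.subject_id, smri_path=smri,
                         fam_path=fam, fc_path=fc, label=rec.label))
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
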