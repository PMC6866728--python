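"""Volumes, masks, atlases and the cohort data matrix.

Everything downstream operates on a :class:`CohortStack`: an ``n_subjects x
n_voxels`` matrix of grey-matter density values restricted to a brain mask,
aligned row-wise with a subject table. Volumes are modulated, smoothed
partial-volume grey-matter maps in a common template space; this module never
resamples — all inputs must share one grid and affine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: value carried by out-of-mask voxels in unmasked statistic volumes
SENTINEL = np.nan


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    return affine


def _grids_match(affine_a, affine_b, shape_a, shape_b, atol=1e-4) -> bool:
    return shape_a == shape_b and np.allclose(affine_a, affine_b, atol=atol)


@dataclass
class GreyMatterVolume:
    """A single subject's modulated grey-matter density map.

    Values are unitless partial-volume densities (>= 0 up to noise); the
    affine maps 0-based voxel indices to template (MNI) mm coordinates.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def load(cls, path) -> "GreyMatterVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))


@dataclass
class BrainMask:
    """Binary analysis mask on the cohort grid. Also used for ROIs/seeds."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def load(cls, path) -> "BrainMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), img.affine)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))


# an ROI is structurally a mask; keep the domain name available
ROIMask = BrainMask


@dataclass
class AtlasLabelMap:
    """Integer parcellation volume with an id -> region-name lookup.

    0 means unlabelled; every nonzero id in the volume must appear in the
    lookup (AAL-style, e.g. 116 named regions).
    """

    labels: np.ndarray
    affine: np.ndarray
    lookup: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(int(k) for k in self.lookup)
        if missing:
            raise ValueError(f"atlas ids missing from lookup: {sorted(missing)}")

    def name_at(self, ijk) -> str:
        lab = int(self.labels[tuple(int(i) for i in ijk)])
        return self.lookup.get(lab, "unlabelled") if lab != 0 else "unlabelled"

    @classmethod
    def load(cls, volume_path, lookup_path) -> "AtlasLabelMap":
        img = nib.load(str(volume_path))
        table = pd.read_csv(lookup_path)
        id_col, name_col = table.columns[:2]
        lookup = {int(r[id_col]): str(r[name_col]) for _, r in table.iterrows()}
        return cls(np.asarray(img.dataobj).astype(np.int32), img.affine, lookup)

    def save(self, volume_path, lookup_path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.affine),
                 str(volume_path))
        pd.DataFrame(
            {"id": list(self.lookup), "name": list(self.lookup.values())}
        ).to_csv(lookup_path, index=False)


@dataclass
class StatMap:
    """A 3D statistic volume (t, slope, r or p) with provenance metadata.

    Out-of-mask voxels carry ``SENTINEL`` (NaN).
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str = "stat"
    df: float | None = None
    contrast: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be 3D")
        self.affine = _check_affine(self.affine)

    @classmethod
    def load(cls, path, **meta) -> "StatMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, **meta)

    def save(self, path) -> None:
        try:
            nib.save(nib.Nifti1Image(self.data, self.affine), str(path))
        except OSError as exc:  # unwritable path is a contract violation
            raise OSError(f"cannot write statistic map to {path}: {exc}") from exc


@dataclass
class CohortStack:
    """Masked grey-matter values for a cohort, aligned with a subject table.

    ``values[i, j]`` is subject ``i``'s GM density at in-mask voxel ``j``;
    ``voxel_indices[j]`` holds that voxel's (i, j, k) grid coordinate.
    """

    values: np.ndarray
    mask: BrainMask
    voxel_indices: np.ndarray
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects x voxels)")
        if self.values.shape[0] != len(self.subjects):
            raise ValueError("row count must equal subject count")
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError("column count must equal mask voxel count")
        if np.isnan(self.values).any():
            raise ValueError("cohort stack contains NaN")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset(self, row_indices) -> "CohortStack":
        """Row-subset (e.g. one group), keeping subject alignment."""
        rows = np.asarray(row_indices)
        return CohortStack(self.values[rows], self.mask, self.voxel_indices,
                           self.subjects.iloc[rows].reset_index(drop=True))

    def unmask(self, vector: np.ndarray, fill: float = SENTINEL) -> np.ndarray:
        """Scatter a per-voxel vector back into a 3D volume."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_voxels,):
            raise ValueError("vector length must equal mask voxel count")
        out = np.full(self.mask.data.shape, fill, dtype=float)
        out[self.mask.data] = vector
        return out

    def to_stat_map(self, vector, kind="stat", **kw) -> StatMap:
        return StatMap(self.unmask(vector), self.mask.affine, kind=kind, **kw)


def load_cohort(manifest: pd.DataFrame, mask: BrainMask,
                path_column: str = "volume_path") -> CohortStack:
    """Read per-subject volumes named in a manifest into a CohortStack.

    The manifest must carry one row per subject (id, group, age, sex, ...)
    plus a column of NIfTI paths. Every volume must share the mask's grid and
    affine; a NaN inside the mask is a hard error naming the subject.
    """
    if path_column not in manifest.columns:
        raise ValueError(f"manifest lacks a '{path_column}' column")
    flat_mask = mask.data
    rows = []
    for _, rec in manifest.iterrows():
        path = rec[path_column]
        try:
            vol = GreyMatterVolume.load(path)
        except Exception as exc:
            raise IOError(f"cannot read volume for subject "
                          f"{rec.get('subject_id', '?')}: {path} ({exc})") from exc
        if not _grids_match(vol.affine, mask.affine, vol.data.shape,
                            flat_mask.shape):
            raise ValueError(f"grid/affine mismatch for {path}")
        vals = vol.data[flat_mask]
        if np.isnan(vals).any():
            raise ValueError(
                f"NaN inside mask for subject {rec.get('subject_id', '?')} "
                f"({path})")
        rows.append(vals)
    voxel_indices = np.argwhere(flat_mask)
    return CohortStack(np.asarray(rows), mask, voxel_indices,
                       manifest.reset_index(drop=True))


def stack_from_array(volumes: np.ndarray, mask: BrainMask,
                     subjects: pd.DataFrame) -> CohortStack:
    """Build a CohortStack from an in-memory 4D (subject, x, y, z) array."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.shape[1:] != mask.data.shape:
        raise ValueError("volume grid does not match mask grid")
    values = volumes[:, mask.data]
    return CohortStack(values, mask, np.argwhere(mask.data),
                       subjects.reset_index(drop=True))


def extract_roi_mean(stack: CohortStack, roi: BrainMask) -> np.ndarray:
    """Per-subject mean GM density over an ROI, e.g. the amygdala seed.

    ROI voxels outside the cohort mask are dropped with a logged warning
    (seed masks cut from statistic maps may slightly exceed the analysis
    mask); an empty intersection is a hard error.
    """
    if not _grids_match(roi.affine, stack.mask.affine, roi.data.shape,
                        stack.mask.data.shape):
        raise ValueError("ROI grid/affine does not match cohort mask")
    inside = roi.data & stack.mask.data
    n_dropped = int(roi.data.sum() - inside.sum())
    if n_dropped:
        logger.warning("ROI: dropped %d voxel(s) outside the cohort mask",
                       n_dropped)
    if not inside.any():
        raise ValueError("ROI does not intersect the cohort mask")
    cols = inside[stack.mask.data]
    return stack.values[:, cols].mean(axis=1)
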