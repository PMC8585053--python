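"""Volumes, label maps, and the coordinate convention used throughout.

Grid convention
---------------
Images are 3-D scalar grids with voxel-center addressing and 0-based
indices.  Axis roles are fixed for the whole package:

* axis 0 — sagittal index (left–right),
* axis 1 — coronal index (anterior–posterior),
* axis 2 — axial index (inferior–superior; increasing index = more
  superior).

The physical position of voxel ``(i, j, k)`` is ``origin + index * spacing``
(mm).  An *axial plane* is a slice at fixed axis-2 index with in-plane axes
(0, 1); a *sagittal plane* is a slice at fixed axis-0 index with in-plane
axes (1, 2).  Hounsfield units are stored as given — no modality rescale
slope/intercept is applied (phantoms are authored directly in HU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "ROLES",
    "DEFAULT_LABEL_TABLE",
    "AXIS_SAGITTAL",
    "AXIS_CORONAL",
    "AXIS_AXIAL",
    "Volume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "validate_pair",
]

#: Anatomical roles every label table must be able to name.
ROLES = (
    "air",
    "graft",
    "tooth_mesial",
    "tooth_distal",
    "cortical",
    "pogonion_marrow",
    "other_bone",
)

DEFAULT_LABEL_TABLE: dict[str, int] = {
    "air": 0,
    "graft": 1,
    "tooth_mesial": 2,
    "tooth_distal": 3,
    "cortical": 4,
    "pogonion_marrow": 5,
    "other_bone": 6,
}

AXIS_SAGITTAL, AXIS_CORONAL, AXIS_AXIAL = 0, 1, 2


def _check_grid(data: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D shape {data.shape}")
    if min(data.shape) < 1:
        raise ValueError(f"grid must have >= 1 voxel along every axis, got {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must have 3 components")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacing values must be > 0 (pixdim), got {spacing}")
    return spacing, origin


@dataclass
class Volume:
    """A 3-D scalar image in Hounsfield units on a regular grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_physical(self, index) -> np.ndarray:
        """Physical mm position of (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, position) -> np.ndarray:
        """Fractional voxel index of a physical mm position."""
        return (np.asarray(position, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class LabelMap:
    """A co-registered integer image naming anatomical regions.

    ``label_table`` maps role names (see :data:`ROLES`) to the integers
    used in ``data``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_table: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_TABLE))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(np.int32)
            if not np.array_equal(as_int, self.data):
                raise ValueError("label map values must be integers")
            self.data = as_int
        if self.data.min() < 0:
            raise ValueError("label map values must be non-negative")
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)
        self.label_table = dict(self.label_table)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def label_for(self, role: str) -> int:
        try:
            return self.label_table[role]
        except KeyError:
            raise KeyError(
                f"role {role!r} missing from label table (has {sorted(self.label_table)})"
            ) from None

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of the voxels carrying ``role``."""
        return self.data == self.label_for(role)

    index_to_physical = Volume.index_to_physical
    physical_to_index = Volume.physical_to_index


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> Volume:
    """Read a NIfTI scalar image as a :class:`Volume`.

    Spacing comes from the header zooms; data are interpreted as HU
    without rescaling.  Rejects non-3-D images and non-positive spacings.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D (header dim = {data.shape})")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in header field pixdim: {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_labelmap(path, label_table: Mapping[str, int] | None = None) -> LabelMap:
    """Read a NIfTI integer image as a :class:`LabelMap`.

    Any voxel value not present in ``label_table`` triggers a warning
    naming the unknown values; missing *roles* only become errors at the
    point a measurement actually requests them.
    """
    if label_table is None:
        label_table = DEFAULT_LABEL_TABLE
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D label map, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in header field pixdim: {spacing}")
    data = np.asarray(data).astype(np.int32)
    known = set(int(v) for v in label_table.values())
    present = set(int(v) for v in np.unique(data))
    unknown = sorted(present - known)
    if unknown:
        warnings.warn(
            f"label map contains values not in the label table: {unknown}",
            stacklevel=2,
        )
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelMap(data, spacing, origin, dict(label_table))


def write_labelmap(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int32), _affine(labels.spacing, labels.origin))
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))


def validate_pair(volume: Volume, labels: LabelMap, *, tol_mm: float = 1e-6) -> tuple[Volume, LabelMap]:
    """Check that a volume and its label map live on the same grid.

    Passes iff shapes are equal and spacings/origins agree within
    ``tol_mm``; raises naming the offending axis otherwise.
    """
    for ax in range(3):
        if volume.shape[ax] != labels.shape[ax]:
            raise ValueError(
                f"shape mismatch on axis {ax}: volume {volume.shape[ax]} vs labels {labels.shape[ax]}"
            )
        if abs(volume.spacing[ax] - labels.spacing[ax]) > tol_mm:
            raise ValueError(
                f"spacing mismatch on axis {ax}: volume {volume.spacing[ax]} vs labels {labels.spacing[ax]}"
            )
        if abs(volume.origin[ax] - labels.origin[ax]) > tol_mm:
            raise ValueError(
                f"origin mismatch on axis {ax}: volume {volume.origin[ax]} vs labels {labels.origin[ax]}"
            )
    return volume, labels
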