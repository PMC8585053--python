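"""Graft volume from a segmentation label map by exact voxel counting.

No partial-volume correction or surface smoothing is applied — the volume
is the voxel count times the voxel volume, which is what a label-map
export from interactive segmentation yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import LabelMap

__all__ = ["VolumeResult", "mask_volume"]


@dataclass(frozen=True)
class VolumeResult:
    role: str
    voxel_count: int
    volume_mm3: float


def mask_volume(labels: LabelMap, role: str) -> VolumeResult:
    """Volume (mm^3) of the region carrying ``role``: count x voxel volume."""
    count = int(np.count_nonzero(labels.mask(role)))
    voxel_mm3 = float(np.prod(labels.spacing))
    return VolumeResult(role=role, voxel_count=count, volume_mm3=count * voxel_mm3)
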