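"""Synthetic CBCT phantoms of an alveolar-cleft graft site with known truth.

The phantom emulates the geometry a graft-density protocol needs, not real
anatomy: two parallel tooth cylinders (circular cross-section in axial
planes) separated by a surface gap wider than the 2.5 mm plane-eligibility
bound, graft tissue filling the inter-tooth slab over a given axial slice
range, a cortical shell bounding the graft anteriorly and posteriorly, air
outside, and a disjoint pogonion bone-marrow ellipsoid embedded in a
mandibular bone block well inferior to the graft.  Each region receives a
constant HU mean plus i.i.d. zero-mean Gaussian noise; the noise-free
assignment yields the ground truth (true graft / pogonion HU, true adjusted
BMD, true graft volume).

The anterior–posterior half-thickness of the defect relative to half the
inter-tooth gap decides which constraint binds the largest in-defect
circle: with the default geometry (gap 6 mm, defect thickness 8 mm) the
teeth bind (the B2 regime); narrowing the defect below the gap makes the
cortical shell bind (B1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .imaging_io import DEFAULT_LABEL_TABLE, LabelMap, Volume

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom", "generate_longitudinal_pair"]

#: Minimum admissible inter-tooth surface gap (mm); planes narrower than
#: this are ineligible for measurement, so the generator refuses them.
MIN_GAP_MM = 2.5

# Offset added to the seed for the second member of a longitudinal pair so
# the two noise fields are independent but still fully determined by one
# integer.  Kept small so derived seeds stay below 2**31.
_T2_SEED_OFFSET = 10007


@dataclass
class PhantomSpec:
    """Parameters of one synthetic graft-site volume.

    Distances are mm, densities HU.  ``graft_slices`` is the inclusive
    axial (axis-2) index range the graft occupies.
    """

    shape: tuple[int, int, int] = (80, 80, 88)
    spacing_mm: float = 0.4
    tooth_radius_mm: float = 3.0
    gap_mm: float = 6.0
    graft_slices: tuple[int, int] = (44, 68)
    defect_thickness_mm: float = 8.0
    cortical_thickness_mm: float = 1.2
    graft_hu: float = 293.88
    pogonion_hu: float = 312.86
    cortical_hu: float = 1200.0
    tooth_hu: float = 1500.0
    air_hu: float = -1000.0
    other_bone_hu: float = 600.0
    noise_sd_hu: float = 50.0
    seed: int = 0
    pogonion_center_mm: tuple[float, float, float] = (16.0, 16.0, 4.8)
    pogonion_semiaxes_mm: tuple[float, float, float] = (4.8, 6.0, 3.2)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.graft_slices = (int(self.graft_slices[0]), int(self.graft_slices[1]))
        if self.gap_mm <= MIN_GAP_MM:
            raise ValueError(
                f"inter-tooth gap must exceed {MIN_GAP_MM} mm, got {self.gap_mm} mm"
            )
        if self.noise_sd_hu < 0:
            raise ValueError("noise sd must be >= 0")
        for name in ("graft_hu", "pogonion_hu", "cortical_hu", "tooth_hu", "air_hu", "other_bone_hu"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        lo, hi = self.graft_slices
        if not (0 <= lo <= hi < self.shape[2]):
            raise ValueError(
                f"graft slice range {self.graft_slices} outside grid of depth {self.shape[2]}"
            )
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("shape", "graft_slices", "pogonion_center_mm", "pogonion_semiaxes_mm"):
            d[key] = list(d[key])
        return d


@dataclass
class GroundTruth:
    """Noise-free quantities implied by a :class:`PhantomSpec`."""

    graft_hu: float
    pogonion_hu: float
    bmd_a_pct: float
    graft_volume_mm3: float
    enhancement_rate_pct: float | None = None
    volume_change_pct: float | None = None

    def __post_init__(self) -> None:
        expected = 100.0 * self.graft_hu / self.pogonion_hu
        if abs(self.bmd_a_pct - expected) > 1e-9:
            raise ValueError("bmd_a_pct inconsistent with graft/pogonion HU")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _region_labels(spec: PhantomSpec) -> np.ndarray:
    """Noise-free label assignment; every voxel gets exactly one label."""
    t = DEFAULT_LABEL_TABLE
    nx, ny, nz = spec.shape
    s = spec.spacing_mm
    x = (np.arange(nx) * s)[:, None, None]
    y = (np.arange(ny) * s)[None, :, None]
    z_idx = np.arange(nz)[None, None, :]

    xc = (nx - 1) * s / 2.0  # mid-sagittal
    yc = (ny - 1) * s / 2.0
    half_gap = spec.gap_mm / 2.0
    half_def = spec.defect_thickness_mm / 2.0
    rt = spec.tooth_radius_mm

    labels = np.full(spec.shape, t["air"], dtype=np.int32)

    # Mandibular block with pogonion marrow ellipsoid (inferior region).
    pcx, pcy, pcz = spec.pogonion_center_mm
    pax, pay, paz = spec.pogonion_semiaxes_mm
    z = z_idx * s
    block = (
        (np.abs(x - pcx) <= pax + 2.0)
        & (np.abs(y - pcy) <= pay + 2.0)
        & (np.abs(z - pcz) <= paz + 2.0)
    )
    labels[np.broadcast_to(block, spec.shape)] = t["other_bone"]
    marrow = ((x - pcx) / pax) ** 2 + ((y - pcy) / pay) ** 2 + ((z - pcz) / paz) ** 2 < 1.0
    labels[np.broadcast_to(marrow, spec.shape)] = t["pogonion_marrow"]

    # Graft site: cortical slabs, graft slab, tooth cylinders.
    g_lo, g_hi = spec.graft_slices
    graft_z = (z_idx >= g_lo) & (z_idx <= g_hi)
    tooth_z = (z_idx >= max(0, g_lo - 4)) & (z_idx <= min(nz - 1, g_hi + 8))

    cortical = (
        (np.abs(y - yc) >= half_def)
        & (np.abs(y - yc) < half_def + spec.cortical_thickness_mm)
        & (np.abs(x - xc) < half_gap + 2 * rt + 1.0)
        & graft_z
    )
    labels[np.broadcast_to(cortical, spec.shape)] = t["cortical"]

    # Graft packs the whole defect channel up to the tooth surfaces (the
    # tooth cylinders are carved out afterwards), as a packed cancellous
    # graft does; without the corner fill a central disc reaching the
    # tooth surface would sample air.
    graft = (np.abs(x - xc) < half_gap + rt) & (np.abs(y - yc) < half_def) & graft_z
    labels[np.broadcast_to(graft, spec.shape)] = t["graft"]

    for role, sign in (("tooth_mesial", -1.0), ("tooth_distal", +1.0)):
        tx = xc + sign * (half_gap + rt)
        tooth = ((x - tx) ** 2 + (y - yc) ** 2 < rt**2) & tooth_z
        labels[np.broadcast_to(tooth, spec.shape)] = t[role]

    return labels


def _hu_lookup(spec: PhantomSpec) -> dict[int, float]:
    t = DEFAULT_LABEL_TABLE
    return {
        t["air"]: spec.air_hu,
        t["graft"]: spec.graft_hu,
        t["tooth_mesial"]: spec.tooth_hu,
        t["tooth_distal"]: spec.tooth_hu,
        t["cortical"]: spec.cortical_hu,
        t["pogonion_marrow"]: spec.pogonion_hu,
        t["other_bone"]: spec.other_bone_hu,
    }


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap, GroundTruth]:
    """Generate one phantom: HU volume, label map, and its ground truth.

    Deterministic for a fixed ``spec.seed``; with ``noise_sd_hu = 0`` the
    mean HU over any label's voxels equals that label's specified mean
    exactly.
    """
    labels = _region_labels(spec)
    if not (labels == DEFAULT_LABEL_TABLE["graft"]).any():
        raise ValueError("phantom geometry produced no graft voxels")

    hu = np.empty(spec.shape, dtype=np.float64)
    for value, mean in _hu_lookup(spec).items():
        hu[labels == value] = mean

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)

    spacing = (spec.spacing_mm,) * 3
    vol = Volume(hu, spacing)
    lmap = LabelMap(labels, spacing, label_table=dict(DEFAULT_LABEL_TABLE))

    n_graft = int((labels == DEFAULT_LABEL_TABLE["graft"]).sum())
    truth = GroundTruth(
        graft_hu=spec.graft_hu,
        pogonion_hu=spec.pogonion_hu,
        bmd_a_pct=100.0 * spec.graft_hu / spec.pogonion_hu,
        graft_volume_mm3=n_graft * spec.spacing_mm**3,
    )
    return vol, lmap, truth


def generate_longitudinal_pair(
    spec_t1: PhantomSpec,
    enhancement_rate_pct: float,
    volume_change_pct: float = 0.0,
    pogonion_drift_hu: float = 0.0,
):
    """Generate a T1/T2 phantom pair realising a programmed density change.

    The T2 graft HU mean is set so that the *noise-free* enhancement rate
    — the relative change in pogonion-adjusted BMD — equals
    ``enhancement_rate_pct`` exactly, even when the pogonion reference is
    allowed to drift by ``pogonion_drift_hu``.  The T2 graft axial extent
    is rescaled to approximate ``volume_change_pct``; both ground truths
    record the programmed rate and the realised volume change.

    Returns ``((vol1, labels1, truth1), (vol2, labels2, truth2))``.
    """
    if enhancement_rate_pct <= -100.0:
        raise ValueError("enhancement rate must be > -100%")
    factor = 1.0 + enhancement_rate_pct / 100.0
    pog_t2 = spec_t1.pogonion_hu + pogonion_drift_hu
    graft_t2 = spec_t1.graft_hu * factor * pog_t2 / spec_t1.pogonion_hu
    if not np.isfinite(graft_t2):
        raise ValueError("programmed T2 graft HU is non-finite")

    lo, hi = spec_t1.graft_slices
    n1 = hi - lo + 1
    n2 = int(round(n1 * (1.0 + volume_change_pct / 100.0)))
    if n2 < 1:
        raise ValueError("volume change would leave the graft empty")
    hi2 = lo + n2 - 1
    if hi2 >= spec_t1.shape[2]:
        raise ValueError("T2 graft extent exceeds the grid")

    spec_t2 = replace(
        spec_t1,
        graft_hu=graft_t2,
        pogonion_hu=pog_t2,
        graft_slices=(lo, hi2),
        seed=(spec_t1.seed + _T2_SEED_OFFSET) % 2**31,
    )

    vol1, lab1, truth1 = generate_phantom(spec_t1)
    vol2, lab2, truth2 = generate_phantom(spec_t2)

    realised_vc = 100.0 * (truth2.graft_volume_mm3 - truth1.graft_volume_mm3) / truth1.graft_volume_mm3
    for tr in (truth1, truth2):
        tr.enhancement_rate_pct = float(enhancement_rate_pct)
        tr.volume_change_pct = realised_vc
    return (vol1, lab1, truth1), (vol2, lab2, truth2)
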