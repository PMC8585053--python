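"""Measurement-plane selection and circular ROI placement.

Implements the three circle-placement schemes used to sample graft
density on axial planes, plus the pogonion reference circle:

* **Method A** — the largest circle centred at the inter-tooth midpoint
  whose boundary keeps a 1 mm clearance to the nearer tooth
  (radius = nearest-tooth distance − 1 mm).
* **Method B** — the largest circle centred at the midpoint that just
  transects the two adjacent teeth or is tangent to the surrounding
  cortical bone, whichever binds first (radius = min of the tooth and
  cortical clearances); the binding constraint is reported
  (``"tooth"`` — the B2 regime; ``"cortical"`` — B1).
* **Method C** — a fixed circle of 2 mm diameter at the midpoint.
* **Pogonion** — the largest circle inscribed in the pogonion bone-marrow
  mask on the sagittal slice through the marrow centroid, found at the
  maximum of the interior Euclidean distance transform.

All distances are Euclidean distances in mm to voxel *centers* of the
labelled regions (not sub-voxel surfaces); geometric assertions elsewhere
therefore carry half-voxel tolerances.  Planes are eligible only when the
inter-tooth gap at the midpoint exceeds 2.5 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .imaging_io import AXIS_AXIAL, AXIS_SAGITTAL, LabelMap

__all__ = [
    "MIN_GAP_MM",
    "PlaneTriplet",
    "CircleROI",
    "select_planes",
    "tooth_anchor",
    "clearances",
    "plane_gap",
    "circle_method_a",
    "circle_method_b",
    "circle_method_c",
    "pogonion_circle",
    "oracle_largest_disc",
]

MIN_GAP_MM = 2.5

# In-plane axes for each plane orientation (indices into the 3-D grid).
_PLANE_AXES = {"axial": (0, 1), "sagittal": (1, 2)}
_PLANE_NORMAL = {"axial": AXIS_AXIAL, "sagittal": AXIS_SAGITTAL}


@dataclass(frozen=True)
class CircleROI:
    """An in-plane disc produced by a placement method.

    ``center_mm`` is in the physical coordinates of the plane's two
    in-plane axes (axial plane: axes 0, 1; sagittal plane: axes 1, 2).
    """

    plane_axis: str  # "axial" | "sagittal"
    plane_index: int
    center_mm: tuple[float, float]
    radius_mm: float
    method: str  # "A" | "B" | "C" | "pogonion"
    binding_constraint: str | None = None

    def __post_init__(self) -> None:
        if self.plane_axis not in _PLANE_AXES:
            raise ValueError(f"unknown plane axis {self.plane_axis!r}")
        if not self.radius_mm > 0:
            raise ValueError(f"circle radius must be > 0, got {self.radius_mm}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center_mm"] = list(d["center_mm"])
        return d


@dataclass
class PlaneTriplet:
    """The superior / middle / inferior axial measurement planes."""

    superior: int
    middle: int
    inferior: int
    gaps_mm: dict[int, float] = field(default_factory=dict)
    substitutions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.inferior <= self.middle <= self.superior):
            raise ValueError("plane ordering must satisfy inferior <= middle <= superior")

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.superior, self.middle, self.inferior)


def _inplane_spacing(labels: LabelMap, plane_axis: str) -> float:
    a, b = _PLANE_AXES[plane_axis]
    sa, sb = labels.spacing[a], labels.spacing[b]
    if abs(sa - sb) > 1e-9:
        raise ValueError(
            f"in-plane spacings must be equal for circular ROIs on a {plane_axis} "
            f"plane, got {sa} vs {sb} mm"
        )
    return sa


def _slice_mask(labels: LabelMap, plane_axis: str, plane_index: int, role: str) -> np.ndarray:
    normal = _PLANE_NORMAL[plane_axis]
    if not (0 <= plane_index < labels.shape[normal]):
        raise IndexError(f"plane index {plane_index} outside grid axis {normal}")
    return np.take(labels.mask(role), plane_index, axis=normal)


def _inplane_coords(labels: LabelMap, plane_axis: str, mask2d: np.ndarray) -> np.ndarray:
    """Physical (mm) in-plane coordinates of True voxel centers, N x 2."""
    a, b = _PLANE_AXES[plane_axis]
    ia, ib = np.nonzero(mask2d)
    return np.column_stack(
        (
            labels.origin[a] + ia * labels.spacing[a],
            labels.origin[b] + ib * labels.spacing[b],
        )
    )


def tooth_anchor(labels: LabelMap, plane_index: int):
    """In-plane centroids of both teeth and their midpoint on an axial plane.

    Returns ``(centroid_mesial, centroid_distal, midpoint)``, each a 2-vector
    in mm.  The midpoint of the inter-centroid segment is the circle center
    shared by Methods A, B and C.
    """
    cents = []
    for role in ("tooth_mesial", "tooth_distal"):
        mask = _slice_mask(labels, "axial", plane_index, role)
        if not mask.any():
            raise ValueError(f"tooth role {role!r} absent on axial plane {plane_index}")
        cents.append(_inplane_coords(labels, "axial", mask).mean(axis=0))
    c_m, c_d = cents
    return c_m, c_d, (c_m + c_d) / 2.0


def clearances(labels: LabelMap, plane_index: int, point_mm) -> dict[str, float]:
    """Distances (mm) from an in-plane point to the nearest voxel center of
    each constraint label on an axial plane.

    Exact Euclidean minimisation over the labelled voxel centers; returns
    ``inf`` for a label with no voxels on the plane.
    """
    point = np.asarray(point_mm, dtype=float)
    out = {}
    for key, role in (
        ("dist_tooth_m", "tooth_mesial"),
        ("dist_tooth_d", "tooth_distal"),
        ("dist_cortical", "cortical"),
    ):
        mask = _slice_mask(labels, "axial", plane_index, role)
        if not mask.any():
            out[key] = math.inf
            continue
        coords = _inplane_coords(labels, "axial", mask)
        out[key] = float(np.sqrt(((coords - point) ** 2).sum(axis=1)).min())
    return out


def plane_gap(labels: LabelMap, plane_index: int) -> float:
    """Inter-tooth gap (mm) available at the midpoint of an axial plane.

    Measured as the sum of the midpoint's clearances to the two teeth —
    the diameter of inter-tooth space the midpoint actually sees.
    """
    _, _, mid = tooth_anchor(labels, plane_index)
    c = clearances(labels, plane_index, mid)
    return c["dist_tooth_m"] + c["dist_tooth_d"]


def _plane_eligible(labels: LabelMap, plane_index: int, min_gap_mm: float) -> tuple[bool, float]:
    try:
        gap = plane_gap(labels, plane_index)
    except ValueError:
        return False, math.nan
    return gap > min_gap_mm, gap


def select_planes(labels: LabelMap, min_gap_mm: float = MIN_GAP_MM) -> PlaneTriplet:
    """Pick the superior, middle and inferior measurement planes.

    Superior = highest axial index containing graft voxels, inferior =
    lowest, middle = floor of their midpoint.  A selected plane must have
    an inter-tooth gap exceeding ``min_gap_mm``; an extreme plane that
    fails steps one slice inward until one passes, and the substitution is
    recorded.  An ineligible middle plane is replaced by the nearest
    eligible slice within the graft extent (ties toward inferior).
    """
    graft = labels.mask("graft")
    zs = np.nonzero(graft.any(axis=(0, 1)))[0]
    if zs.size == 0:
        raise ValueError("no graft voxels in label map")
    inferior, superior = int(zs.min()), int(zs.max())

    subs: list[str] = []
    gaps: dict[int, float] = {}

    def step(start: int, direction: int, name: str) -> int:
        idx = start
        while inferior <= idx <= superior:
            ok, gap = _plane_eligible(labels, idx, min_gap_mm)
            if ok:
                gaps[idx] = gap
                if idx != start:
                    subs.append(f"{name} plane moved from {start} to {idx} (gap <= {min_gap_mm} mm)")
                return idx
            idx += direction
        raise ValueError("no eligible plane: no axial slice has inter-tooth gap > "
                         f"{min_gap_mm} mm")

    sup = step(superior, -1, "superior")
    inf = step(inferior, +1, "inferior")
    if inf > sup:
        raise ValueError(f"no eligible plane: gap bound {min_gap_mm} mm never satisfied")

    mid0 = (sup + inf) // 2
    mid = None
    for offset in range(0, sup - inf + 1):
        for cand in (mid0 - offset, mid0 + offset):
            if inf <= cand <= sup:
                ok, gap = _plane_eligible(labels, cand, min_gap_mm)
                if ok:
                    gaps[cand] = gap
                    mid = cand
                    if cand != mid0:
                        subs.append(f"middle plane moved from {mid0} to {cand}")
                    break
        if mid is not None:
            break
    if mid is None:
        raise ValueError("no eligible plane for the middle position")

    return PlaneTriplet(superior=sup, middle=mid, inferior=inf, gaps_mm=gaps, substitutions=subs)


def _check_inside_grid(labels: LabelMap, plane_axis: str, center, radius: float) -> None:
    a, b = _PLANE_AXES[plane_axis]
    half = 0.5
    for ax, c in zip((a, b), center):
        lo = labels.origin[ax] - half * labels.spacing[ax]
        hi = labels.origin[ax] + (labels.shape[ax] - 1 + half) * labels.spacing[ax]
        if c - radius < lo or c + radius > hi:
            raise ValueError(f"circle of radius {radius:.3f} mm leaves the grid along axis {ax}")


def _require_eligible(labels: LabelMap, plane_index: int) -> tuple[np.ndarray, dict[str, float]]:
    _, _, mid = tooth_anchor(labels, plane_index)
    c = clearances(labels, plane_index, mid)
    gap = c["dist_tooth_m"] + c["dist_tooth_d"]
    if not gap > MIN_GAP_MM:
        raise ValueError(
            f"plane {plane_index} ineligible: inter-tooth gap {gap:.2f} mm <= {MIN_GAP_MM} mm"
        )
    return mid, c


def circle_method_a(labels: LabelMap, plane_index: int) -> CircleROI:
    """Method A: maximal circle keeping 1 mm clearance to the nearer tooth."""
    _inplane_spacing(labels, "axial")
    mid, c = _require_eligible(labels, plane_index)
    radius = min(c["dist_tooth_m"], c["dist_tooth_d"]) - 1.0
    if radius <= 0:
        raise ValueError(
            f"gap too small for Method A on plane {plane_index}: "
            f"nearest-tooth distance {min(c['dist_tooth_m'], c['dist_tooth_d']):.2f} mm leaves no room "
            "after the 1 mm margin"
        )
    _check_inside_grid(labels, "axial", mid, radius)
    return CircleROI("axial", int(plane_index), (float(mid[0]), float(mid[1])), float(radius), "A")


def circle_method_b(labels: LabelMap, plane_index: int) -> CircleROI:
    """Method B: largest circle transecting the teeth or tangent to cortical bone."""
    s = _inplane_spacing(labels, "axial")
    mid, c = _require_eligible(labels, plane_index)
    d_tooth = min(c["dist_tooth_m"], c["dist_tooth_d"])
    radius = min(d_tooth, c["dist_cortical"])
    if not np.isfinite(radius) or radius <= s / 2.0:
        raise ValueError(f"degenerate Method B circle on plane {plane_index} (radius {radius:.3f} mm)")
    binding = "tooth" if d_tooth <= c["dist_cortical"] else "cortical"
    _check_inside_grid(labels, "axial", mid, radius)
    return CircleROI(
        "axial", int(plane_index), (float(mid[0]), float(mid[1])), float(radius), "B",
        binding_constraint=binding,
    )


def circle_method_c(labels: LabelMap, plane_index: int) -> CircleROI:
    """Method C: fixed 2 mm-diameter circle at the inter-tooth midpoint."""
    _inplane_spacing(labels, "axial")
    mid, c = _require_eligible(labels, plane_index)
    if min(c["dist_tooth_m"], c["dist_tooth_d"]) < 1.0:
        raise ValueError(
            f"Method C circle intersects tooth on plane {plane_index}: midpoint clearance "
            f"{min(c['dist_tooth_m'], c['dist_tooth_d']):.2f} mm < 1.0 mm"
        )
    _check_inside_grid(labels, "axial", mid, 1.0)
    return CircleROI("axial", int(plane_index), (float(mid[0]), float(mid[1])), 1.0, "C")


def pogonion_circle(labels: LabelMap) -> CircleROI:
    """Largest circle inscribed in the pogonion marrow on its mid-sagittal slice.

    The slice is the sagittal plane through the marrow centroid; the disc
    center is the argmax of the interior Euclidean distance transform of
    the marrow mask (ties broken toward the lowest index pair) and the
    radius is that maximum distance.
    """
    s = _inplane_spacing(labels, "sagittal")
    marrow = labels.mask("pogonion_marrow")
    if not marrow.any():
        raise ValueError("pogonion_marrow label absent from label map")
    xs = np.nonzero(marrow.any(axis=(1, 2)))[0]
    centroid_i = np.nonzero(marrow)[0].mean()
    plane_index = int(round(centroid_i))
    plane_index = int(np.clip(plane_index, xs.min(), xs.max()))
    mask2d = np.take(marrow, plane_index, axis=AXIS_SAGITTAL)
    if not mask2d.any():
        raise ValueError(f"pogonion marrow empty on sagittal slice {plane_index}")

    a, b = _PLANE_AXES["sagittal"]
    edt = ndimage.distance_transform_edt(
        mask2d, sampling=(labels.spacing[a], labels.spacing[b])
    )
    flat = int(np.argmax(edt))  # first occurrence = lowest (row, col) index
    ij = np.unravel_index(flat, edt.shape)
    radius = float(edt[ij])
    if radius < s / 2.0:
        raise ValueError(f"pogonion marrow too thin for a circle (max radius {radius:.3f} mm)")
    center = (
        float(labels.origin[a] + ij[0] * labels.spacing[a]),
        float(labels.origin[b] + ij[1] * labels.spacing[b]),
    )
    return CircleROI("sagittal", plane_index, center, radius, "pogonion")


def oracle_largest_disc(mask2d: np.ndarray, spacing=(1.0, 1.0), fixed_center=None):
    """Exhaustive-search reference for the largest inscribed disc.

    The admissible region is the continuous footprint of the True voxels
    (union of their voxel squares); everything outside the grid counts as
    background.  For a ``fixed_center`` (in mm, index * spacing
    coordinates) only the radius is searched; otherwise every in-mask
    voxel center is a candidate.  Intended for small grids — this is a
    test oracle, O(N^2) in the free-center case.

    Returns ``(center_mm, radius_mm)``.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("empty mask")
    sp = (float(spacing[0]), float(spacing[1]))
    bg = np.column_stack(np.nonzero(~mask2d)).astype(float)
    bg_mm = bg * np.asarray(sp)

    def radius_at(pt) -> float:
        r = math.inf
        # grid boundary acts as background
        for ax in range(2):
            lo = -0.5 * sp[ax]
            hi = (mask2d.shape[ax] - 1 + 0.5) * sp[ax]
            r = min(r, pt[ax] - lo, hi - pt[ax])
        if len(bg_mm):
            dx = np.maximum(0.0, np.abs(pt[0] - bg_mm[:, 0]) - sp[0] / 2.0)
            dy = np.maximum(0.0, np.abs(pt[1] - bg_mm[:, 1]) - sp[1] / 2.0)
            r = min(r, float(np.hypot(dx, dy).min()))
        return max(r, 0.0)

    if fixed_center is not None:
        pt = (float(fixed_center[0]), float(fixed_center[1]))
        return pt, radius_at(pt)

    best_pt, best_r = None, -1.0
    for i, j in np.argwhere(mask2d):
        pt = (i * sp[0], j * sp[1])
        r = radius_at(pt)
        if r > best_r:  # strict: ties keep the lowest index order
            best_pt, best_r = pt, r
    return best_pt, best_r
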