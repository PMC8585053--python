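"""Density sampling, adjusted BMD, enhancement rate, and session averaging.

The measured quantity is the mean Hounsfield value inside circular ROIs on
three axial planes (graft) and one sagittal plane (pogonion marrow
reference).  Adjusted BMD expresses graft density as a percentage of the
pogonion marrow density of the same scan:

    BMD_a (%) = 100 * HU_selected / HU_pogonion

which normalises out scanner-level HU variation and age-related density
drift.  The density enhancement rate between two follow-ups T1 and T2 is

    rate (%) = 100 * (BMD_a(T2) - BMD_a(T1)) / BMD_a(T1)

and the volume change of the graft is reported with the analogous signed
formula (negative = shrinkage).

Cohort aggregation caveat: a cohort mean enhancement rate is the mean of
per-subject rates, *not* the rate computed from cohort-mean BMDs — the two
differ whenever baselines vary.  :func:`enhancement_rate` operates on one
subject's pair of values; aggregate per-subject outputs afterwards.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .imaging_io import LabelMap, Volume, validate_pair
from .roi_geometry import (
    CircleROI,
    PlaneTriplet,
    circle_method_a,
    circle_method_b,
    circle_method_c,
    pogonion_circle,
    select_planes,
    _PLANE_AXES,
    _PLANE_NORMAL,
    _inplane_spacing,
)

__all__ = [
    "MeasurementRecord",
    "FinalMeasurement",
    "DensityReport",
    "mean_hu",
    "adjusted_bmd",
    "enhancement_rate",
    "volume_loss",
    "average_sessions",
    "run_measurement",
    "records_to_csv",
]

METHODS = ("A", "B", "C")

_CIRCLE_FN = {"A": circle_method_a, "B": circle_method_b, "C": circle_method_c}

#: Column order of the measurement CSV.
CSV_COLUMNS = [
    "method", "timepoint", "session",
    "plane_hu_1", "plane_hu_2", "plane_hu_3",
    "graft_hu", "pogonion_hu", "bmd_a_pct",
    "enhancement_rate_pct", "volume_t1_mm3", "volume_t2_mm3", "volume_loss_pct",
]


@dataclass
class MeasurementRecord:
    """One method's densities for one timepoint and measurement session."""

    method: str
    timepoint: str
    session: int
    plane_hu: tuple[float, float, float]
    graft_hu: float
    pogonion_hu: float
    bmd_a_pct: float
    plane_indices: tuple[int, int, int] | None = None
    rois: list[CircleROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.graft_hu - float(np.mean(self.plane_hu))) > 1e-9:
            raise ValueError("graft_hu must equal the mean of the three plane means")
        if abs(self.bmd_a_pct - adjusted_bmd(self.graft_hu, self.pogonion_hu)) > 1e-9:
            raise ValueError("bmd_a_pct inconsistent with graft/pogonion HU")


@dataclass
class FinalMeasurement:
    """Session-averaged final values for one (method, timepoint)."""

    method: str
    timepoint: str
    graft_hu: float
    pogonion_hu: float
    bmd_a_pct: float
    n_sessions: int = 2


@dataclass
class DensityReport:
    """Longitudinal per-method synthesis of a T1/T2 pair."""

    bmd_a_t1_pct: dict[str, float]
    bmd_a_t2_pct: dict[str, float]
    enhancement_rate_pct: dict[str, float]
    volume_t1_mm3: float | None = None
    volume_t2_mm3: float | None = None
    volume_loss_pct: float | None = None

    def __post_init__(self) -> None:
        for m, rate in self.enhancement_rate_pct.items():
            expected = enhancement_rate(self.bmd_a_t1_pct[m], self.bmd_a_t2_pct[m])
            if abs(rate - expected) > 1e-9:
                raise ValueError(f"enhancement rate for method {m} inconsistent with its BMD fields")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def mean_hu(volume: Volume, roi: CircleROI) -> tuple[float, int]:
    """Mean HU over voxel centers strictly inside the disc.

    Inclusion is strict (distance < radius), with a 1 nm guard so voxels
    lying exactly on the boundary are excluded regardless of
    floating-point rounding.  Returns ``(mean, voxel_count)``; raises if
    no voxel center falls inside the disc.
    """
    normal = _PLANE_NORMAL[roi.plane_axis]
    a, b = _PLANE_AXES[roi.plane_axis]
    if not (0 <= roi.plane_index < volume.shape[normal]):
        raise IndexError(f"ROI plane index {roi.plane_index} outside grid")
    plane = np.take(volume.data, roi.plane_index, axis=normal)
    ca = volume.origin[a] + np.arange(volume.shape[a]) * volume.spacing[a]
    cb = volume.origin[b] + np.arange(volume.shape[b]) * volume.spacing[b]
    d2 = (ca[:, None] - roi.center_mm[0]) ** 2 + (cb[None, :] - roi.center_mm[1]) ** 2
    inside = d2 < (roi.radius_mm - 1e-9) ** 2
    n = int(inside.sum())
    if n == 0:
        raise ValueError(f"empty disc: no voxel center strictly inside radius {roi.radius_mm} mm")
    return float(plane[inside].mean()), n


def adjusted_bmd(hu_selected: float, hu_pogonion: float) -> float:
    """Adjusted BMD (%): graft HU as a percentage of the pogonion HU."""
    if abs(hu_pogonion) < 1e-6:
        raise ValueError("pogonion HU is (near) zero; adjusted BMD undefined")
    return 100.0 * hu_selected / hu_pogonion


def enhancement_rate(bmd_a_t1: float, bmd_a_t2: float) -> float:
    """Relative change (%) of adjusted BMD from T1 to T2."""
    if bmd_a_t1 <= 0:
        raise ValueError(f"baseline adjusted BMD must be > 0, got {bmd_a_t1}")
    return 100.0 * (bmd_a_t2 - bmd_a_t1) / bmd_a_t1


def volume_loss(vol_t1: float, vol_t2: float) -> float:
    """Signed relative volume change (%) of the graft; negative = shrinkage."""
    if vol_t1 <= 0:
        raise ValueError(f"baseline volume must be > 0, got {vol_t1}")
    return 100.0 * (vol_t2 - vol_t1) / vol_t1


def average_sessions(records: Iterable[MeasurementRecord]) -> list[FinalMeasurement]:
    """Average the two measurement sessions of each (method, timepoint).

    The final graft HU is the mean of the six plane means (2 sessions x 3
    planes), the final pogonion HU the mean of the two session values, and
    the final adjusted BMD is recomputed from those finals.
    """
    groups: dict[tuple[str, str], dict[int, MeasurementRecord]] = {}
    for rec in records:
        groups.setdefault((rec.method, rec.timepoint), {})[rec.session] = rec

    finals = []
    for (method, timepoint), sessions in sorted(groups.items()):
        missing = sorted({1, 2} - set(sessions))
        if missing:
            raise ValueError(
                f"method {method} / {timepoint}: missing session(s) {missing}"
            )
        plane_means = [hu for s in (1, 2) for hu in sessions[s].plane_hu]
        if len(plane_means) != 6:
            raise ValueError(f"method {method} / {timepoint}: expected 6 plane means")
        graft = float(np.mean(plane_means))
        pog = float(np.mean([sessions[s].pogonion_hu for s in (1, 2)]))
        finals.append(
            FinalMeasurement(method, timepoint, graft, pog, adjusted_bmd(graft, pog))
        )
    return finals


def run_measurement(
    volume: Volume,
    labels: LabelMap,
    methods: Sequence[str] = METHODS,
    timepoint: str = "T1",
    session: int = 1,
    planes: PlaneTriplet | None = None,
) -> list[MeasurementRecord]:
    """End-to-end measurement of one scan: planes, circles, HU, adjusted BMD.

    Fully deterministic — repeated runs on the same inputs give identical
    records; measurement-session variability only enters through perturbed
    inputs or configs.
    """
    validate_pair(volume, labels)
    _inplane_spacing(labels, "axial")
    unknown = [m for m in methods if m not in _CIRCLE_FN]
    if unknown:
        raise ValueError(f"unknown method(s) {unknown}; choose from {list(_CIRCLE_FN)}")
    if planes is None:
        planes = select_planes(labels)

    pog_roi = pogonion_circle(labels)
    pog_hu, _ = mean_hu(volume, pog_roi)

    records = []
    for method in methods:
        plane_hu = []
        rois = []
        for plane_index in planes.indices:
            try:
                roi = _CIRCLE_FN[method](labels, plane_index)
                hu, _ = mean_hu(volume, roi)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"method {method}, plane {plane_index}: {exc}") from exc
            plane_hu.append(hu)
            rois.append(roi)
        graft = float(np.mean(plane_hu))
        records.append(
            MeasurementRecord(
                method=method,
                timepoint=timepoint,
                session=int(session),
                plane_hu=tuple(plane_hu),
                graft_hu=graft,
                pogonion_hu=pog_hu,
                bmd_a_pct=adjusted_bmd(graft, pog_hu),
                plane_indices=planes.indices,
                rois=rois + [pog_roi],
            )
        )
    return records


def records_to_csv(records: Iterable[MeasurementRecord], path, report: DensityReport | None = None) -> None:
    """Write records (one row per method x timepoint x session) as CSV.

    Longitudinal columns are filled from ``report`` when given and left
    empty otherwise.
    """
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        w.writeheader()
        for rec in records:
            row = {
                "method": rec.method,
                "timepoint": rec.timepoint,
                "session": rec.session,
                "plane_hu_1": rec.plane_hu[0],
                "plane_hu_2": rec.plane_hu[1],
                "plane_hu_3": rec.plane_hu[2],
                "graft_hu": rec.graft_hu,
                "pogonion_hu": rec.pogonion_hu,
                "bmd_a_pct": rec.bmd_a_pct,
                "enhancement_rate_pct": "",
                "volume_t1_mm3": "",
                "volume_t2_mm3": "",
                "volume_loss_pct": "",
            }
            if report is not None and rec.method in report.enhancement_rate_pct:
                row["enhancement_rate_pct"] = report.enhancement_rate_pct[rec.method]
                row["volume_t1_mm3"] = "" if report.volume_t1_mm3 is None else report.volume_t1_mm3
                row["volume_t2_mm3"] = "" if report.volume_t2_mm3 is None else report.volume_t2_mm3
                row["volume_loss_pct"] = "" if report.volume_loss_pct is None else report.volume_loss_pct
            w.writerow(row)


def build_report(
    finals_t1: Sequence[FinalMeasurement],
    finals_t2: Sequence[FinalMeasurement],
    volume_t1_mm3: float | None = None,
    volume_t2_mm3: float | None = None,
) -> DensityReport:
    """Combine final T1/T2 measurements into a longitudinal report.

    Refuses to mix methods: the two timepoints must cover exactly the same
    method set.
    """
    t1 = {f.method: f for f in finals_t1}
    t2 = {f.method: f for f in finals_t2}
    if set(t1) != set(t2):
        raise ValueError(
            f"method mismatch between timepoints: T1 has {sorted(t1)}, T2 has {sorted(t2)}"
        )
    vloss = None
    if volume_t1_mm3 is not None and volume_t2_mm3 is not None:
        vloss = volume_loss(volume_t1_mm3, volume_t2_mm3)
    return DensityReport(
        bmd_a_t1_pct={m: t1[m].bmd_a_pct for m in t1},
        bmd_a_t2_pct={m: t2[m].bmd_a_pct for m in t1},
        enhancement_rate_pct={
            m: enhancement_rate(t1[m].bmd_a_pct, t2[m].bmd_a_pct) for m in t1
        },
        volume_t1_mm3=volume_t1_mm3,
        volume_t2_mm3=volume_t2_mm3,
        volume_loss_pct=vloss,
    )
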