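import math

import numpy as np
import pytest

from graftdens import (
    DEFAULT_LABEL_TABLE,
    PhantomSpec,
    circle_method_a,
    circle_method_b,
    circle_method_c,
    clearances,
    generate_phantom,
    oracle_largest_disc,
    pogonion_circle,
    select_planes,
    tooth_anchor,
)
from conftest import make_labelmap

T = DEFAULT_LABEL_TABLE


def paint_block(labels, role, x_mm, y_mm, z_idx):
    """Set label over voxel centers with x in x_mm, y in y_mm (inclusive, mm)."""
    s = labels.spacing[0]
    nx, ny, _ = labels.shape
    cx = np.arange(nx) * s
    cy = np.arange(ny) * s
    sel = np.ix_(
        np.nonzero((cx >= x_mm[0] - 1e-9) & (cx <= x_mm[1] + 1e-9))[0],
        np.nonzero((cy >= y_mm[0] - 1e-9) & (cy <= y_mm[1] + 1e-9))[0],
        np.atleast_1d(z_idx),
    )
    labels.data[sel] = T[role]


def two_block_teeth(gap_left_mm, gap_right_mm, z_idx=(5,), spacing=0.4,
                    shape=(48, 49, 32), width_mm=2.0):
    """Equal-width rectangular teeth spanning all y.

    Inner surfaces (outermost tooth voxel centers) sit at ``gap_left_mm``
    and ``gap_right_mm``; equal widths put the centroid midpoint exactly
    at the channel center.
    """
    lm = make_labelmap(shape, spacing)
    ymax = (shape[1] - 1) * spacing
    paint_block(lm, "tooth_mesial", (gap_left_mm - width_mm, gap_left_mm), (0.0, ymax), z_idx)
    paint_block(lm, "tooth_distal", (gap_right_mm, gap_right_mm + width_mm), (0.0, ymax), z_idx)
    paint_block(lm, "graft", (gap_left_mm + spacing, gap_right_mm - spacing), (0.0, ymax), z_idx)
    return lm


class TestSelectPlanes:
    def test_extremes_and_floor_middle(self):
        _, labels, _ = generate_phantom(PhantomSpec(noise_sd_hu=0, graft_slices=(10, 20)))
        planes = select_planes(labels)
        assert planes.indices == (20, 15, 10)
        assert all(g > 2.5 for g in planes.gaps_mm.values())

    def test_single_slice_collapses(self):
        _, labels, _ = generate_phantom(PhantomSpec(noise_sd_hu=0, graft_slices=(12, 12)))
        assert select_planes(labels).indices == (12, 12, 12)

    def test_no_eligible_plane_raises(self):
        # teeth leave only a 2.0 mm channel at the midpoint: below the bound
        lm = two_block_teeth(6.0, 8.0, z_idx=[5, 6, 7])
        with pytest.raises(ValueError, match="no eligible plane"):
            select_planes(lm)

    def test_no_graft_raises(self, blank_labels):
        with pytest.raises(ValueError, match="graft"):
            select_planes(blank_labels)


class TestToothAnchor:
    def test_symmetric_midpoint(self):
        lm = two_block_teeth(4.0, 10.0)
        c_m, c_d, mid = tooth_anchor(lm, 5)
        assert mid[0] == pytest.approx((c_m[0] + c_d[0]) / 2, abs=1e-12)
        assert c_m[1] == pytest.approx(c_d[1], abs=1e-9)  # same y span

    def test_centroid_of_digitized_disc_matches_analytic_center(self):
        lm = make_labelmap((64, 64, 8), 0.4)
        cx, cy, r = 10.0, 12.6, 3.0
        c = np.arange(64) * 0.4
        inside = (c[:, None] - cx) ** 2 + (c[None, :] - cy) ** 2 < r**2
        lm.data[:, :, 3][inside] = T["tooth_mesial"]
        lm.data[40:50, 40:50, 3] = T["tooth_distal"]
        got, _, _ = tooth_anchor(lm, 3)
        assert abs(got[0] - cx) < 0.2 and abs(got[1] - cy) < 0.2  # half a voxel

    def test_missing_tooth_names_role(self, blank_labels):
        blank_labels.data[2:5, 2:5, 1] = T["tooth_mesial"]
        with pytest.raises(ValueError, match="tooth_distal"):
            tooth_anchor(blank_labels, 1)


class TestClearances:
    def test_point_on_tooth_voxel_is_zero(self):
        lm = two_block_teeth(4.0, 10.0)
        c = clearances(lm, 5, (4.0, 2.0))
        assert c["dist_tooth_m"] == 0.0

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(3)
        lm = make_labelmap((64, 64, 4), 0.4)
        lm.data[:, :, 2] = rng.integers(0, 7, (64, 64))
        point = (7.13, 11.91)
        got = clearances(lm, 2, point)
        for key, role in (("dist_tooth_m", "tooth_mesial"),
                          ("dist_tooth_d", "tooth_distal"),
                          ("dist_cortical", "cortical")):
            best = math.inf
            for i in range(64):
                for j in range(64):
                    if lm.data[i, j, 2] == T[role]:
                        best = min(best, math.hypot(i * 0.4 - point[0], j * 0.4 - point[1]))
            assert got[key] == pytest.approx(best, abs=1e-9)

    def test_absent_label_gives_infinity(self, blank_labels):
        blank_labels.data[1, 1, 1] = T["tooth_mesial"]
        assert clearances(blank_labels, 1, (0.0, 0.0))["dist_cortical"] == math.inf


class TestMethodA:
    def test_symmetric_4mm_gap_gives_radius_1(self):
        # inner tooth surfaces (voxel centers) at 6.0 and 10.0 mm: clearance 2.0 each
        lm = two_block_teeth(6.0, 10.0)
        roi = circle_method_a(lm, 5)
        assert roi.radius_mm == pytest.approx(1.0, abs=1e-9)
        assert roi.center_mm[0] == pytest.approx(8.0, abs=1e-9)

    def test_narrow_26mm_gap_gives_radius_03(self):
        lm = two_block_teeth(6.0, 8.6, spacing=0.1, shape=(160, 41, 12), z_idx=(5,))
        roi = circle_method_a(lm, 5)
        assert roi.radius_mm == pytest.approx(0.3, abs=1e-9)

    def test_minimum_clearance_governs_asymmetric_case(self):
        # unequal tooth widths: mesial centroid 5.0, distal centroid 12.0
        # -> midpoint 8.5 with clearances 2.5 (mesial) and 0.5 + 2.0 ...
        lm = make_labelmap((48, 49, 32))
        ymax = 48 * 0.4
        paint_block(lm, "tooth_mesial", (4.0, 6.0), (0.0, ymax), (5,))    # centroid 5.0
        paint_block(lm, "tooth_distal", (10.0, 14.0), (0.0, ymax), (5,))  # centroid 12.0
        paint_block(lm, "graft", (6.4, 9.6), (0.0, ymax), (5,))
        roi = circle_method_a(lm, 5)  # midpoint 8.5: clearances 2.5 / 1.5
        assert roi.radius_mm == pytest.approx(min(2.5, 1.5) - 1.0, abs=1e-9)

    def test_non_positive_radius_raises(self):
        # asymmetric widths put the midpoint 0.5 mm from the distal tooth
        # while the total gap (3.0 mm) stays eligible
        lm = make_labelmap((64, 49, 32))
        ymax = 48 * 0.4
        paint_block(lm, "tooth_mesial", (4.0, 6.0), (0.0, ymax), (5,))   # centroid 5.0
        paint_block(lm, "tooth_distal", (9.0, 15.0), (0.0, ymax), (5,))  # centroid 12.0
        paint_block(lm, "graft", (6.4, 8.6), (0.0, ymax), (5,))
        with pytest.raises(ValueError, match="Method A"):
            circle_method_a(lm, 5)


class TestMethodB:
    def test_default_phantom_is_tooth_limited(self):
        _, labels, _ = generate_phantom(PhantomSpec(noise_sd_hu=0))
        roi = circle_method_b(labels, 56)
        assert roi.binding_constraint == "tooth"

    def test_thin_defect_is_cortical_limited(self):
        _, labels, _ = generate_phantom(PhantomSpec(noise_sd_hu=0, defect_thickness_mm=4.0))
        roi = circle_method_b(labels, 56)
        assert roi.binding_constraint == "cortical"
        # cortical wall at 2 mm from the channel axis; voxel-center convention
        assert roi.radius_mm == pytest.approx(2.0, abs=0.4)

    def test_radius_matches_exhaustive_disc_search(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            spec = PhantomSpec(
                noise_sd_hu=0,
                gap_mm=float(rng.uniform(3.5, 7.0)),
                defect_thickness_mm=float(rng.uniform(3.0, 9.0)),
                seed=trial,
            )
            _, labels, _ = generate_phantom(spec)
            roi = circle_method_b(labels, 56)
            forbidden = (
                labels.mask("tooth_mesial") | labels.mask("tooth_distal") | labels.mask("cortical")
            )[:, :, 56]
            _, r_oracle = oracle_largest_disc(
                ~forbidden, spacing=labels.spacing[:2], fixed_center=roi.center_mm
            )
            # voxel-center clearances vs continuous-footprint oracle can
            # differ by at most half the in-plane voxel diagonal
            half_diag = 0.5 * math.hypot(*labels.spacing[:2])
            assert 0 <= roi.radius_mm - r_oracle <= half_diag + 1e-9

    def test_disc_contains_no_tooth_or_cortical_center(self):
        _, labels, _ = generate_phantom(PhantomSpec(noise_sd_hu=0))
        roi = circle_method_b(labels, 56)
        s = labels.spacing[0]
        c = np.arange(labels.shape[0]) * s
        d2 = (c[:, None] - roi.center_mm[0]) ** 2 + (c[None, :] - roi.center_mm[1]) ** 2
        inside = d2 < (roi.radius_mm - 1e-9) ** 2
        slab = labels.data[:, :, 56]
        bad = {T["tooth_mesial"], T["tooth_distal"], T["cortical"]}
        assert not np.isin(slab[inside], list(bad)).any()


class TestMethodC:
    def test_radius_is_always_one_mm(self):
        _, labels, _ = generate_phantom(PhantomSpec(noise_sd_hu=0))
        for plane in (44, 56, 68):
            assert circle_method_c(labels, plane).radius_mm == 1.0

    def test_narrow_but_eligible_gap_succeeds(self):
        lm = two_block_teeth(6.0, 8.6, spacing=0.1, shape=(160, 41, 12), z_idx=(5,))
        assert circle_method_c(lm, 5).radius_mm == 1.0  # clearance 1.3 mm

    def test_midpoint_too_close_to_tooth_raises(self):
        # eligible 3 mm gap, but asymmetric widths leave the midpoint only
        # 0.5 mm from the distal tooth: the fixed circle would enter it
        lm = make_labelmap((64, 49, 32))
        ymax = 48 * 0.4
        paint_block(lm, "tooth_mesial", (4.0, 6.0), (0.0, ymax), (5,))
        paint_block(lm, "tooth_distal", (9.0, 15.0), (0.0, ymax), (5,))
        paint_block(lm, "graft", (6.4, 8.6), (0.0, ymax), (5,))
        with pytest.raises(ValueError, match="intersects tooth"):
            circle_method_c(lm, 5)


class TestPogonionCircle:
    def test_recovers_digitized_disc(self):
        lm = make_labelmap((16, 64, 64), 0.4)
        cy, cz, r = 12.0, 12.0, 5.0
        c = np.arange(64) * 0.4
        inside = (c[:, None] - cy) ** 2 + (c[None, :] - cz) ** 2 < r**2
        lm.data[8, :, :][inside] = T["pogonion_marrow"]
        roi = pogonion_circle(lm)
        assert roi.plane_axis == "sagittal" and roi.plane_index == 8
        assert abs(roi.radius_mm - r) <= 0.5 * 0.4
        assert abs(roi.center_mm[0] - cy) <= 0.2 and abs(roi.center_mm[1] - cz) <= 0.2

    def test_matches_free_center_oracle_on_random_blobs(self):
        from scipy import ndimage

        rng = np.random.default_rng(21)
        for trial in range(20):
            mask = rng.random((28, 28)) < 0.35
            mask = ndimage.binary_closing(ndimage.binary_opening(mask))
            mask[[0, -1], :] = False
            mask[:, [0, -1]] = False  # keep blobs off the grid boundary
            if not mask.any():
                continue
            lm = make_labelmap((8, 28, 28), 0.4)
            lm.data[4][mask] = T["pogonion_marrow"]
            try:
                roi = pogonion_circle(lm)
            except ValueError:
                continue  # mask too thin for any circle
            _, r_oracle = oracle_largest_disc(mask, spacing=(0.4, 0.4))
            assert 0 <= roi.radius_mm - r_oracle <= 0.5 * math.hypot(0.4, 0.4) + 1e-9

    def test_missing_marrow_raises(self, blank_labels):
        with pytest.raises(ValueError, match="pogonion_marrow"):
            pogonion_circle(blank_labels)


class TestOracle:
    def test_full_mask_center_and_radius(self):
        center, radius = oracle_largest_disc(np.ones((21, 21), dtype=bool))
        assert center == (10.0, 10.0)
        assert abs(radius - 10.0) <= 0.5

    def test_single_voxel_mask(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        _, radius = oracle_largest_disc(mask)
        assert radius <= 0.5 + 1e-9

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            oracle_largest_disc(np.zeros((4, 4), dtype=bool))


class TestPlacementInvariants:
    def test_radius_ordering_on_tooth_limited_phantoms(self):
        # On tooth-limited (B2) geometry, B's constraint set is A's without
        # the 1 mm margin, so radius_A < radius_B and the fixed C fits in B.
        for seed in range(5):
            rng = np.random.default_rng(seed)
            spec = PhantomSpec(noise_sd_hu=0, gap_mm=float(rng.uniform(4.5, 7.0)), seed=seed)
            _, labels, _ = generate_phantom(spec)
            a = circle_method_a(labels, 56).radius_mm
            b = circle_method_b(labels, 56)
            c = circle_method_c(labels, 56).radius_mm
            if b.binding_constraint == "tooth":
                assert a <= b.radius_mm
            assert c <= b.radius_mm

    def test_placements_are_deterministic(self):
        _, labels, _ = generate_phantom(PhantomSpec(seed=2))
        assert circle_method_b(labels, 56) == circle_method_b(labels, 56)
        assert pogonion_circle(labels) == pogonion_circle(labels)
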