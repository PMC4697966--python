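"""Measurement operators: BV/TV, plate thickness, cortical thickness."""

import numpy as np
import pytest
import shapely.geometry as sgeom

from humeromorph.errors import MeasurementError
from humeromorph.geometry import polygon_to_mask
from humeromorph.model import SectionImage
from humeromorph.morphometry import (
    bv_tv,
    cortical_thickness,
    measure_section,
    plate_thickness,
)


def _section(bone, cart=None, mmpp=0.05, medial="left"):
    if cart is None:
        cart = np.zeros_like(bone)
    return SectionImage(bone, cart, mmpp, medial)


def _rect(x0, y0, x1, y1):
    return sgeom.box(x0, y0, x1, y1)


class TestBVTV:
    def test_saturated_and_empty_regions(self):
        bone = np.zeros((50, 50), bool)
        bone[:25] = True
        s = _section(bone)
        assert bv_tv(s, _rect(4.5, 4.5, 20.5, 20.5)) == 100.0
        assert bv_tv(s, _rect(29.5, 29.5, 45.5, 45.5)) == 0.0

    def test_matches_direct_pixel_count(self):
        rng = np.random.default_rng(3)
        bone = rng.random((120, 120)) < 0.37
        s = _section(bone)
        poly = _rect(9.5, 19.5, 80.5, 100.5)
        # independent oracle: enumerate pixel centres inside the box
        xs = np.arange(10, 81)
        ys = np.arange(20, 101)
        sub = bone[np.ix_(ys, xs)]
        want = 100.0 * sub.sum() / sub.size
        assert bv_tv(s, poly) == want

    def test_half_filled_square_is_fifty_percent(self):
        bone = np.zeros((120, 120), bool)
        bone[10:60, 10:110] = True  # 50 of 100 rows of the region
        s = _section(bone)
        poly = _rect(9.5, 9.5, 109.5, 109.5)  # 100x100 px region
        assert bv_tv(s, poly) == 50.0

    def test_zero_area_region_rejected(self):
        s = _section(np.zeros((50, 50), bool))
        with pytest.raises(MeasurementError):
            bv_tv(s, _rect(10.2, 10.2, 10.4, 10.4))

    def test_region_outside_image_rejected(self):
        s = _section(np.zeros((50, 50), bool))
        with pytest.raises(MeasurementError, match="outside"):
            bv_tv(s, _rect(100, 100, 120, 120))

    def test_monotone_under_adding_bone_inside(self):
        bone = np.zeros((60, 60), bool)
        bone[20:30, 20:30] = True
        s = _section(bone)
        poly = _rect(14.5, 14.5, 40.5, 40.5)
        v0 = bv_tv(s, poly)
        bone2 = bone.copy()
        bone2[35, 35] = True  # inside region
        assert bv_tv(_section(bone2), poly) > v0
        bone3 = bone.copy()
        bone3[50, 50] = True  # outside region
        assert bv_tv(_section(bone3), poly) == v0

    def test_additivity_over_partition(self, section_bundle, regions):
        section, _, _ = section_bundle
        h = bv_tv(section, regions.regions["h"])
        parts = {k: bv_tv(section, regions.regions[k]) for k in ("subchondral", "inner")}
        areas = {
            k: polygon_to_mask(regions.regions[k], section.shape).sum()
            for k in ("subchondral", "inner")
        }
        weighted = sum(parts[k] * areas[k] for k in parts) / sum(areas.values())
        # exact up to the handful of boundary pixels where the shared
        # chord meets the fan arcs
        assert h == pytest.approx(weighted, abs=0.05)


class TestPlateThickness:
    def _strip_phantom(self, mmpp=0.05):
        """Layers from deep to superficial (walking up the image):
        marrow | plate 12 px | cartilage 20 px | air, probed by an
        upward ray."""
        bone = np.zeros((200, 60), bool)
        cart = np.zeros((200, 60), bool)
        cart[100:120] = True  # superficial cartilage band
        bone[120:132] = True  # subchondral plate beneath it
        return _section(bone, cart, mmpp)

    def test_strip_phantom_recovers_band(self):
        s = self._strip_phantom()
        t = plate_thickness(s, origin=(30.0, 150.0), direction=(0.0, -1.0))
        assert t == pytest.approx(12 * 0.05, abs=0.05)

    def test_ray_without_cartilage_is_missing(self):
        s = self._strip_phantom()
        assert plate_thickness(s, origin=(30.0, 150.0), direction=(0.0, 1.0)) is None

    def test_trabecula_below_plate_not_included(self):
        s = self._strip_phantom()
        s.bone_mask[136:141] = True  # a separate trabecular band deeper in
        t = plate_thickness(s, origin=(30.0, 150.0), direction=(0.0, -1.0))
        assert t == pytest.approx(12 * 0.05, abs=0.05)


class TestCorticalThickness:
    def test_constant_vertical_strip(self):
        bone = np.zeros((200, 100), bool)
        bone[:, 20:32] = True  # 12 px wall on the left
        bone[:, 70:82] = True  # closing wall so the envelope fills
        s = _section(bone, mmpp=0.05)
        for y in (50.0, 100.0, 150.0):
            t = cortical_thickness(s, "medial", (50.0, y), (0.0, -1.0))
            assert t == pytest.approx(0.6, abs=0.05)

    def test_annulus_phantom_matches_analytic_wall(self):
        h = w = 240
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(xx - 120, yy - 120)
        bone = (r <= 100) & (r > 90)  # half-open: a 10 px wall
        s = _section(bone, mmpp=0.05)
        for dy in (-50.0, 0.0, 50.0):
            for side in ("medial", "lateral"):
                t = cortical_thickness(s, side, (120.0, 120.0 + dy), (0.0, -1.0))
                assert t == pytest.approx(10 * 0.05, abs=0.06), (side, dy)

    def test_invariant_under_translation_and_rotation(self):
        # annulus phantom: translating the image (with the site moved
        # along) or rotating it by 90 degrees (with the axis rotated)
        # leaves the measured wall thickness unchanged
        h = w = 240
        yy, xx = np.mgrid[0:h, 0:w]
        bone = (np.hypot(xx - 110, yy - 120) <= 100) & (np.hypot(xx - 110, yy - 120) > 90)
        s = _section(bone, mmpp=0.05)
        base = cortical_thickness(s, "medial", (110.0, 120.0), (0.0, -1.0))

        moved = _section(np.roll(bone, (7, 9), axis=(0, 1)), mmpp=0.05)
        t_moved = cortical_thickness(moved, "medial", (119.0, 127.0), (0.0, -1.0))
        assert t_moved == pytest.approx(base, abs=1e-9)

        rot = _section(np.rot90(bone), mmpp=0.05)  # (x, y) -> (y, w-1-x)
        t_rot = cortical_thickness(rot, "medial", (120.0, w - 1 - 110.0), (-1.0, 0.0))
        assert t_rot == pytest.approx(base, abs=0.06)

    def test_plate_invariant_under_translation(self):
        s = TestPlateThickness()._strip_phantom()
        base = plate_thickness(s, origin=(30.0, 150.0), direction=(0.0, -1.0))
        moved = _section(
            np.roll(s.bone_mask, (11, 4), axis=(0, 1)),
            np.roll(s.cartilage_mask, (11, 4), axis=(0, 1)),
            mmpp=0.05,
        )
        t_moved = plate_thickness(moved, origin=(34.0, 161.0), direction=(0.0, -1.0))
        assert t_moved == pytest.approx(base, abs=1e-9)

    def test_tapering_cortex_slope_recovered(self, section_bundle, landmarks, sites):
        # the generated medial wall tapers linearly with depth; the
        # recovered taper slope must match the prescribed one within 10%
        section, _, truth = section_bundle
        med = [(k, lp) for side, k, lp in sites.cortical_levels if side == "medial"]
        vals = [cortical_thickness(section, "medial", lp, sites.axis_direction) for _, lp in med]
        ks = np.array([k for k, _ in med], dtype=float)
        slope = np.polyfit(ks, vals, 1)[0]
        truth_vals = [truth.cortical_thickness_mm[("medial", int(k))] for k in ks]
        slope_true = np.polyfit(ks, truth_vals, 1)[0]
        assert slope == pytest.approx(slope_true, rel=0.10)


class TestMeasureSection:
    def test_cardinality_and_determinism(self, section_bundle, regions, sites):
        section, _, _ = section_bundle
        res1 = measure_section(section, regions, sites)
        res2 = measure_section(section, regions, sites)
        assert len(res1.bvtv_by_region) == 7
        assert len(res1.plate_thickness_by_angle) == 19
        assert len(res1.cortical_thickness) == 18
        assert res1.bvtv_by_region == res2.bvtv_by_region
        assert res1.plate_thickness_by_angle == res2.plate_thickness_by_angle
        assert res1.cortical_thickness == res2.cortical_thickness

    def test_ground_truth_recovery_within_tolerances(self, section_bundle, regions, sites):
        section, _, truth = section_bundle
        res = measure_section(section, regions, sites)
        px = section.mm_per_pixel
        for label, v in res.bvtv_by_region.items():
            assert v == pytest.approx(truth.achieved_bvtv[label], abs=2.0), label
        for a, v in res.plate_thickness_by_angle.items():
            assert v is not None, f"plate missing at {a}"
            want = truth.plate_thickness_mm[a]
            assert abs(v - want) <= max(px, 0.05 * want) + 1e-9, f"plate at {a}"
        for key, v in res.cortical_thickness.items():
            want = truth.cortical_thickness_mm[key]
            assert abs(v - want) <= max(px, 0.05 * want) + 1e-9, f"cortex at {key}"

    def test_resolution_consistency(self):
        # super-sampling the rasters 2x while halving mm/px changes
        # BV/TV by < 0.5 pp and thickness by < 1 original px
        from conftest import small_section_spec
        from humeromorph.model import Annotation
        from humeromorph.pipeline import measure_one
        from humeromorph.synth import generate_section

        section, ann, _ = generate_section(small_section_spec(seed=9))
        res1 = measure_one(section, ann)
        big = SectionImage(
            np.kron(section.bone_mask, np.ones((2, 2), bool)),
            np.kron(section.cartilage_mask, np.ones((2, 2), bool)),
            section.mm_per_pixel / 2.0,
            section.medial_side,
        )
        ann2 = Annotation(
            (2.0 * ann.cranial_cartilage_end[0] + 0.5, 2.0 * ann.cranial_cartilage_end[1] + 0.5),
            (2.0 * ann.caudal_cartilage_end[0] + 0.5, 2.0 * ann.caudal_cartilage_end[1] + 0.5),
        )
        res2 = measure_one(big, ann2)
        for label in res1.bvtv_by_region:
            assert abs(res1.bvtv_by_region[label] - res2.bvtv_by_region[label]) < 0.5
        for a in res1.plate_thickness_by_angle:
            v1, v2 = res1.plate_thickness_by_angle[a], res2.plate_thickness_by_angle[a]
            if v1 is not None and v2 is not None:
                assert abs(v1 - v2) < section.mm_per_pixel
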