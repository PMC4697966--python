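"""Landmark construction, region partition and site construction."""

import numpy as np
import pytest
import shapely

from conftest import small_section_spec
from humeromorph.errors import GeometryError, ParameterError
from humeromorph.geometry import (
    REGION_LABELS,
    build_thickness_sites,
    construct_landmarks,
    fit_long_axis,
    partition_regions,
    polygon_to_mask,
)
from humeromorph.model import Annotation, SectionImage
from humeromorph.synth import generate_section


def _rect_section(angle_deg=0.0, shape=(300, 300)):
    """A rotated 200 x 40 px rectangle as a bone mask."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2, w / 2
    a = np.radians(angle_deg)
    u = (xx - cx) * np.sin(a) + (yy - cy) * np.cos(a)  # along the long axis
    v = (xx - cx) * np.cos(a) - (yy - cy) * np.sin(a)
    bone = (np.abs(u) <= 100) & (np.abs(v) <= 20)
    cart = np.zeros(shape, bool)
    return SectionImage(bone, cart, 0.05, "left")


class TestFitLongAxis:
    def test_axis_aligned_rectangle_gives_vertical_axis(self):
        s = _rect_section(0.0)
        line = fit_long_axis(s, None, shaft_fraction=0.5)
        assert abs(line.direction[0]) < 1e-6
        assert line.direction[1] == pytest.approx(-1.0)
        assert line.point[0] == pytest.approx(150.0, abs=0.5)

    @pytest.mark.parametrize("angle", [30.0, -20.0])
    def test_rotated_rectangle_matches_covariance_eigenvector(self, angle):
        s = _rect_section(angle)
        line = fit_long_axis(s, None, shaft_fraction=0.6)
        # independent oracle: principal eigenvector of the full-shape
        # pixel covariance (the rectangle is homogeneous, so the distal
        # band and the full shape share the axis direction)
        ys, xs = np.nonzero(s.bone_mask)
        pts = np.column_stack([xs, ys]).astype(float)
        cov = np.cov((pts - pts.mean(0)).T)
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]
        got = np.degrees(np.arctan2(line.direction[0], -line.direction[1]))
        want = np.degrees(np.arctan2(v[0], -v[1])) % 180.0
        assert abs((got % 180.0) - want) < 0.5

    def test_override_passthrough(self):
        s = _rect_section(0.0)
        ann = Annotation((10, 0), (11, 100), shaft_axis_override=((10.0, 0.0), (10.0, 100.0)))
        line = fit_long_axis(s, ann)
        assert line.point[0] == pytest.approx(10.0)
        assert abs(line.direction[0]) < 1e-12

    def test_degenerate_mask_rejected(self):
        bone = np.zeros((50, 50), bool)
        bone[10:13, 10:13] = True
        s = SectionImage(bone, np.zeros((50, 50), bool), 0.05, "left")
        with pytest.raises(GeometryError, match="degenerate"):
            fit_long_axis(s, None)

    @pytest.mark.parametrize("frac", [0.0, 0.7, -0.1])
    def test_shaft_fraction_range_enforced(self, frac):
        with pytest.raises(ParameterError):
            fit_long_axis(_rect_section(), None, shaft_fraction=frac)


class TestLandmarks:
    def test_all_invariants_hold(self, landmarks):
        landmarks.validate()  # raises on violation

    def test_s_lengths_are_thirds(self, landmarks):
        med = landmarks.line_c.intersect(landmarks.line_d)
        med_seg = float(np.hypot(*(med - landmarks.caudal_end)))
        assert 3.0 * landmarks.s1_length == pytest.approx(med_seg, abs=0.5)
        assert 3.0 * landmarks.s2_length == pytest.approx(landmarks.e_length, abs=0.5)

    def test_line_e_matches_generator_truth(self, section_bundle, landmarks):
        _, _, truth = section_bundle
        assert landmarks.e_length == pytest.approx(truth.landmarks.e_length, abs=2.0)

    def test_head_height_matches_generator_truth(self, section_bundle, landmarks):
        _, _, truth = section_bundle
        assert landmarks.head_height == pytest.approx(truth.landmarks.head_height, abs=2.0)

    def test_invariants_hold_over_many_random_sections(self):
        # sampled geometry jitter: radius, tilt and mounting vary
        rng = np.random.default_rng(42)
        for i in range(12):
            spec = small_section_spec(seed=100 + i,
                                      medial_side="left" if i % 2 else "right")
            spec.head_radius = float(10.0 * rng.uniform(0.9, 1.1))
            spec.cap_tilt_deg = float(rng.uniform(40.0, 50.0))
            section, ann, _ = generate_section(spec)
            lm = construct_landmarks(section, ann, fit_long_axis(section, ann))
            lm.validate()


class TestPartition:
    def test_region_inventory(self, regions):
        assert set(regions.regions) == set(REGION_LABELS)

    def test_jaccard_against_ground_truth_stencils(self, section_bundle, regions):
        section, _, truth = section_bundle
        for label in REGION_LABELS:
            a = polygon_to_mask(truth.regions.regions[label], section.shape)
            b = polygon_to_mask(regions.regions[label], section.shape)
            jac = (a & b).sum() / (a | b).sum()
            assert jac >= 0.90, f"{label}: Jaccard {jac:.3f}"

    def test_subchondral_plus_inner_equals_head(self, regions):
        h = regions.regions["h"]
        union = regions.regions["subchondral"].union(regions.regions["inner"])
        assert abs(h.area - union.area) < 1e-3 * h.area

    def test_regions_pairwise_interior_disjoint(self, regions):
        import itertools

        labels = ["sc1", "sc2", "m1", "m2", "subchondral", "inner"]
        for a, b in itertools.combinations(labels, 2):
            inter = regions.regions[a].intersection(regions.regions[b]).area
            assert inter < 1.0, f"{a} and {b} overlap by {inter:.1f} px^2"

    def test_regions_exclude_cartilage_and_compact_bone(self, section_bundle, regions):
        section, _, truth = section_bundle
        cart = section.cartilage_mask
        # compact bone: bone pixels outside every trabecular ground-truth
        # stencil that sit within 1.05 * plate/cortex depth of the surface
        for label in REGION_LABELS:
            m = polygon_to_mask(regions.regions[label], section.shape)
            assert not (m & cart).any(), f"{label} contains cartilage pixels"

    def test_deterministic(self, section_bundle, landmarks):
        section, _, _ = section_bundle
        r1 = partition_regions(section, landmarks)
        r2 = partition_regions(section, landmarks)
        for label in REGION_LABELS:
            assert r1.regions[label].equals_exact(r2.regions[label], 0.0)

    def test_translation_invariance(self, section_bundle):
        section, ann, _ = section_bundle
        dy, dx = 9, 7
        bone = np.roll(section.bone_mask, (dy, dx), axis=(0, 1))
        cart = np.roll(section.cartilage_mask, (dy, dx), axis=(0, 1))
        moved = SectionImage(bone, cart, section.mm_per_pixel, section.medial_side)
        ann2 = Annotation(
            (ann.cranial_cartilage_end[0] + dx, ann.cranial_cartilage_end[1] + dy),
            (ann.caudal_cartilage_end[0] + dx, ann.caudal_cartilage_end[1] + dy),
        )
        r0 = partition_regions(section, construct_landmarks(section, ann, fit_long_axis(section, ann)))
        r1 = partition_regions(moved, construct_landmarks(moved, ann2, fit_long_axis(moved, ann2)))
        for label in REGION_LABELS:
            assert r1.regions[label].area == pytest.approx(r0.regions[label].area, rel=1e-3)

    def test_mirror_invariance(self, section_bundle):
        section, ann, _ = section_bundle
        w = section.shape[1]
        bone = np.fliplr(section.bone_mask)
        cart = np.fliplr(section.cartilage_mask)
        mirrored = SectionImage(bone, cart, section.mm_per_pixel, "right")
        ann2 = Annotation(
            (w - 1 - ann.cranial_cartilage_end[0], ann.cranial_cartilage_end[1]),
            (w - 1 - ann.caudal_cartilage_end[0], ann.caudal_cartilage_end[1]),
        )
        r0 = partition_regions(section, construct_landmarks(section, ann, fit_long_axis(section, ann)))
        r1 = partition_regions(mirrored, construct_landmarks(mirrored, ann2, fit_long_axis(mirrored, ann2)))
        for label in REGION_LABELS:
            assert r1.regions[label].area == pytest.approx(r0.regions[label].area, rel=1e-2)

    def test_shrinking_s2_shrinks_subchondral_band(self, section_bundle, landmarks):
        import dataclasses

        section, _, _ = section_bundle
        base = partition_regions(section, landmarks)
        lm_small = dataclasses.replace(landmarks, s2_length=0.5 * landmarks.s2_length)
        small = partition_regions(section, lm_small)
        assert small.regions["subchondral"].area < base.regions["subchondral"].area


class TestThicknessSites:
    @pytest.mark.parametrize("step,n_rays", [(10.0, 19), (90.0, 3), (180.0, 2)])
    def test_ray_count_inclusive_endpoints(self, landmarks, step, n_rays):
        sites = build_thickness_sites(landmarks, angular_step=step)
        assert len(sites.plate_rays) == n_rays
        angles = [a for a, _, _ in sites.plate_rays]
        assert angles[0] == 0.0 and angles[-1] == 180.0

    def test_levels_per_side_and_spacing(self, landmarks):
        sites = build_thickness_sites(landmarks, n_segments=8)
        med = [lp for s, _, lp in sites.cortical_levels if s == "medial"]
        lat = [lp for s, _, lp in sites.cortical_levels if s == "lateral"]
        assert len(med) == 9 and len(lat) == 9
        gaps = [float(np.hypot(*(med[i + 1] - med[i]))) for i in range(8)]
        assert all(abs(g - landmarks.head_height / 8.0) < 0.5 for g in gaps)

    def test_invalid_angular_step_rejected(self, landmarks):
        with pytest.raises(ParameterError):
            build_thickness_sites(landmarks, angular_step=7.0)
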