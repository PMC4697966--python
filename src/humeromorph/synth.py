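"""Synthetic frontal sections of the proximal humerus with known ground
truth.

The generator draws an idealized frontal section: a circular humeral
head whose articular semicircle (tilted ``cap_tilt_deg`` towards
medial-proximal) carries a hyaline-cartilage band and a subchondral
plate of prescribed angular thickness profile; a flaring metaphysis and
a parallel-sided shaft carry medial and lateral cortical walls of
prescribed thickness-by-level profiles; the trabecular interior is
filled with a seeded dead-leaves process of oriented elongated ellipses,
independently per ground-truth region, until each region's bone-area
fraction is within 0.5 percentage points of its target.

The trabecular compartment is kept separated from the plate and the
cortical walls by a small marrow collar (default 2 px) so that plate and
wall thickness have an unambiguous ground truth; real sections, where
trabeculae merge into the compact bone, are harder than this phantom.

Everything the measurement chain consumes (landmarks, region stencils,
achieved fractions, thickness fields) is returned as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .errors import SpecError
from .geometry import (
    LandmarkSet,
    Line,
    RegionSet,
    partition_regions,
    polygon_to_mask,
)
from .model import Annotation, DonorRecord, SectionImage
from .stats import allocate_group

__all__ = [
    "SectionSpec",
    "CohortSpec",
    "SectionGroundTruth",
    "CohortDonor",
    "generate_section",
    "generate_cohort",
    "DEFAULT_BVTV_TARGETS",
    "DEFAULT_EFFECT_MAP",
]

#: fill-order for the dead-leaves process (fixed so that child RNG
#: streams are reproducible and order-independent per region)
FILL_LABELS = ("subchondral", "inner", "sc1", "sc2", "m1", "m2", "rest")

#: group template: bone-area fraction targets (%) for a normal-like
#: section; the head emerges as the area-weighted union of its
#: subchondral and inner parts
DEFAULT_BVTV_TARGETS: Dict[str, float] = {
    "subchondral": 25.2,
    "inner": 24.8,
    "sc1": 18.0,
    "sc2": 20.0,
    "m1": 25.0,
    "m2": 25.0,
    "rest": 20.0,
}

#: multiplicative reduction of the targets for the osteoporotic-like
#: group: strongest loss in the first subcapital band and the medial
#: metaphysis, mildest directly under the subchondral plate
DEFAULT_EFFECT_MAP: Dict[str, float] = {
    "subchondral": 0.75,
    "inner": 0.60,
    "sc1": 0.55,
    "sc2": 0.65,
    "m1": 0.50,
    "m2": 0.55,
    "rest": 0.65,
}


def _default_plate_profile() -> Dict[float, float]:
    """Plate thickness (mm) by articular angle: slightly thicker centrally."""
    return {float(a): 0.85 + 0.15 * math.sin(math.radians(a)) for a in range(0, 181, 10)}


def _default_cortical_profile() -> Dict[str, List[Tuple[float, float]]]:
    """Cortical wall thickness (mm) by side and normalized level
    (0 = line c, 1 = one head height further distal); walls thicken
    towards the shaft.

    The medial value at level 0 equals the plate thickness at the caudal
    end of the articular arc: the two structures meet at the caudal
    cartilage end, so the compact bone there must have a single
    well-defined thickness.
    """
    return {
        "medial": [(0.0, 0.85), (1.0, 3.5)],
        "lateral": [(0.0, 0.8), (1.0, 3.0)],
    }


@dataclass
class SectionSpec:
    """Geometry, texture and calibration of one synthetic section.

    Lengths in mm.  ``plate_thickness_profile`` maps articular angle
    (degrees, 0 = caudal end, 180 = cranial end) to plate thickness;
    ``cortical_thickness_profile`` maps side to a list of
    (normalized level, thickness) breakpoints, linearly interpolated and
    clamped at the ends.  ``region_bvtv_targets`` are bone-area-fraction
    targets in percent per ground-truth region (``rest`` is the
    cancellous background outside the named regions).
    """

    head_radius: float = 22.0
    shaft_width: float = 18.0
    cartilage_thickness: float = 1.2
    plate_thickness_profile: Dict[float, float] = field(default_factory=_default_plate_profile)
    cortical_thickness_profile: Dict[str, List[Tuple[float, float]]] = field(
        default_factory=_default_cortical_profile
    )
    region_bvtv_targets: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BVTV_TARGETS)
    )
    trabecular_width: Tuple[float, float] = (0.15, 0.03)  # (mean, sd) mm
    mm_per_pixel: float = 0.025
    seed: int = 0
    # layout details
    shaft_offset: float = 8.0  # lateral offset of the shaft axis from the head centre
    cap_tilt_deg: float = 45.0  # articular cap axis tilt towards medial-proximal
    medial_side: str = "left"
    margin_mm: float = 1.5
    tail_mm: float = 22.0  # shaft continues this far below the last cortical level
    collar_px: float = 2.0  # marrow separation between trabeculae and compact bone
    donor_id: str = "synthetic"

    def validate(self) -> None:
        for name in ("head_radius", "shaft_width", "cartilage_thickness", "mm_per_pixel"):
            if not (getattr(self, name) > 0):
                raise SpecError(f"{name} must be > 0")
        for label, t in self.region_bvtv_targets.items():
            if not (0.0 < t <= 95.0):
                raise SpecError(
                    f"BV/TV target for {label} must be in (0, 95] %, got {t}"
                )
        if any(v <= 0 for v in self.plate_thickness_profile.values()):
            raise SpecError("plate thickness profile must be positive")
        if self.trabecular_width[0] <= 0:
            raise SpecError("trabecular width must be positive")
        if self.medial_side not in ("left", "right"):
            raise SpecError("medial_side must be 'left' or 'right'")
        if not (10.0 <= self.cap_tilt_deg <= 80.0):
            raise SpecError("cap_tilt_deg must stay in [10, 80] degrees")


@dataclass
class SectionGroundTruth:
    """Everything the generator knows about one section."""

    landmarks: LandmarkSet
    regions: RegionSet
    achieved_bvtv: Dict[str, float]  # %, by region label (incl. 'h' and 'rest')
    targets: Dict[str, float]  # the requested %, by fill label
    plate_thickness_mm: Dict[float, float]  # by articular angle (10 deg grid)
    cortical_thickness_mm: Dict[Tuple[str, int], float]  # by (side, level 0..8)
    spec: SectionSpec


def _interp_profile(profile: Dict[float, float], angles: np.ndarray) -> np.ndarray:
    xs = np.array(sorted(profile))
    ys = np.array([profile[a] for a in xs])
    return np.interp(angles, xs, ys)


def _interp_cortical(breaks: List[Tuple[float, float]], level: np.ndarray) -> np.ndarray:
    b = sorted(breaks)
    xs = np.array([p[0] for p in b])
    ys = np.array([p[1] for p in b])
    return np.interp(level, xs, ys)


def generate_section(spec: SectionSpec):
    """Draw one section; returns ``(SectionImage, Annotation,
    SectionGroundTruth)``.

    Deterministic for a fixed spec (seed included); the achieved
    per-region bone fractions are recorded by direct pixel counting on
    the final mask, so the declared ground truth is self-consistent by
    construction.
    """
    spec.validate()
    s = 1.0 / spec.mm_per_pixel  # px per mm
    R = spec.head_radius * s
    cart_t = spec.cartilage_thickness * s
    w = spec.shaft_width * s
    off = spec.shaft_offset * s
    margin = spec.margin_mm * s
    tail = spec.tail_mm * s
    alpha = math.radians(spec.cap_tilt_deg)
    sin_a, cos_a = math.sin(alpha), math.cos(alpha)

    med = -1.0 if spec.medial_side == "left" else 1.0  # medial x sign

    cx = R + margin if med < 0 else None
    W = int(math.ceil(2 * R + 2 * margin))
    if med > 0:
        cx = W - (R + margin)
    cy = R + margin
    # the annotated cartilage ends sit at mid-thickness of the band, as
    # an annotator would click the centre of the tapering cartilage end
    rc = R - 0.5 * cart_t
    y_c = cy + rc * sin_a
    head_height = rc * sin_a + R
    y_bot = y_c + head_height + tail
    H = int(math.ceil(y_bot + margin))
    cx_shaft = cx - med * off  # shaft axis is lateral of the head centre

    u_cap = np.array([med * sin_a, -cos_a])
    v_caudal = np.array([med * cos_a, sin_a])
    C = np.array([cx, cy])
    caudal = C + rc * v_caudal
    cranial = C - rc * v_caudal

    shape = (H, W)
    Y, X = np.ogrid[0:H, 0:W]
    dx = X - cx
    dy = Y - cy
    r2 = dx * dx + dy * dy

    # ---- outer envelope ---------------------------------------------------
    # head disc, a flaring metaphysis whose medial contour runs nearly
    # vertically below the caudal cartilage end (the calcar) before
    # tapering to the shaft, and a parallel-sided shaft
    disc = r2 <= R * R
    # medial envelope point at the level of line c (on the disc)
    x_caud = cx + med * math.sqrt(max(R * R - (y_c - cy) ** 2, 0.0))
    x_wall_med = cx_shaft + med * (w / 2)
    x_wall_lat = cx_shaft - med * (w / 2)
    calcar_slope = 0.12  # inward drift of the calcar per unit depth
    y_calcar = y_c + 0.5 * R
    y_f1 = cy + 1.8 * R  # metaphysis reaches the shaft here
    # the calcar leaves the articular margin at an oblique take-off and
    # straightens to calcar_slope over a short fillet; the take-off
    # angle stays well clear of both the articular-cap edge (so the
    # level-0 wall normal runs through clean cortex) and the vertical
    # (so the contour has no sharp corner at the caudal end)
    takeoff_slope = 0.55
    fillet_depth = 0.2 * R
    n_fil = 8
    d_fil = np.linspace(0.0, fillet_depth, n_fil + 1)
    slope_fil = takeoff_slope + (calcar_slope - takeoff_slope) * (d_fil / fillet_depth)
    x_fil = x_caud - med * np.concatenate(
        [[0.0], np.cumsum(0.5 * (slope_fil[1:] + slope_fil[:-1]) * np.diff(d_fil))]
    )
    chain = [[float(x), float(y_c + d)] for x, d in zip(x_fil, d_fil)]
    x_B = x_fil[-1] - med * calcar_slope * (y_calcar - (y_c + fillet_depth))
    B = [float(x_B), y_calcar]
    Cm = [x_wall_med, y_f1]
    D = [x_wall_lat, y_f1]
    E = [cx - med * 0.8 * R, cy + 0.6 * R]  # lateral flare anchored on the disc
    flare = np.array(chain + [B, Cm, D, E])
    rr, cc = skdraw.polygon(flare[:, 1], flare[:, 0], shape=shape)
    env = disc.copy()
    env[rr, cc] = True
    shaft = (np.abs(X - cx_shaft) <= w / 2) & (Y > y_f1) & (Y <= y_bot)
    env |= shaft

    # ---- articular cap: cartilage band and subchondral plate ---------------
    # angle across the semicircle: 0 at the caudal ray, 180 at the cranial
    dot = dx * v_caudal[0] + dy * v_caudal[1]
    cross = v_caudal[0] * dy - v_caudal[1] * dx
    theta = np.degrees(np.arctan2(med * -1.0 * cross, dot))
    # sweep sign: rotating v_caudal onto u_cap; chosen so theta in [0, 180]
    # covers the cap for either mounting
    in_cap = (theta >= 0.0) & (theta <= 180.0)
    r = np.sqrt(r2)
    cart_mask = in_cap & (r >= R - cart_t) & (r <= R)
    max_p = max(spec.plate_thickness_profile.values()) * s
    near_band = in_cap & (r >= R - cart_t - max_p - 2.0) & (r < R - cart_t)
    plate_mask = np.zeros(shape, dtype=bool)
    band_iy, band_ix = np.nonzero(near_band)
    p_band = _interp_profile(
        spec.plate_thickness_profile, np.clip(theta[band_iy, band_ix], 0.0, 180.0)
    ) * s
    plate_mask[band_iy, band_ix] = r[band_iy, band_ix] >= R - cart_t - p_band

    # ---- cortical walls ----------------------------------------------------
    pad_n = max(int(0.1 * R), 20)
    env_pad = np.vstack([env, np.tile(env[-1], (pad_n, 1))])
    edt, (iy_n, ix_n) = ndimage.distance_transform_edt(env_pad, return_indices=True)
    edt = edt[:H]
    iy_n = iy_n[:H]
    ix_n = ix_n[:H]
    max_t = max(
        max(th for _, th in pts) for pts in spec.cortical_thickness_profile.values()
    ) * s
    # only pixels within reach of a wall need their thickness evaluated
    cand_iy, cand_ix = np.nonzero(env & (edt <= max_t + 1.0))
    level = np.clip((iy_n[cand_iy, cand_ix] - y_c) / head_height, -0.5, 1.5)
    t_med = _interp_cortical(spec.cortical_thickness_profile["medial"], level) * s
    t_lat = _interp_cortical(spec.cortical_thickness_profile["lateral"], level) * s
    is_medial = (ix_n[cand_iy, cand_ix] - cx_shaft) * med > 0
    t_wall = np.where(is_medial, t_med, t_lat)
    shell = np.zeros(shape, dtype=bool)
    shell[cand_iy, cand_ix] = edt[cand_iy, cand_ix] <= t_wall
    distal_of_b = (dx * u_cap[0] + dy * u_cap[1]) <= 0.0
    shell &= distal_of_b & ~cart_mask & ~plate_mask

    bone = plate_mask | shell

    # ---- true landmarks ----------------------------------------------------
    y_top = cy - R
    y3 = y_top + (2.0 / 3.0) * (y_bot - y_top)
    if y3 < y_calcar:
        raise SpecError("section too short: distal third reaches into the calcar")
    if y3 >= y_f1:
        x_d = x_wall_med
    else:  # medial taper between calcar and shaft
        frac = (y3 - y_calcar) / (y_f1 - y_calcar)
        x_d = B[0] + frac * (x_wall_med - B[0])
    p90 = _interp_profile(spec.plate_thickness_profile, np.array([90.0]))[0] * s
    r_e = R - cart_t - p90
    u_lat = np.array([-med, 0.0])
    true_lm = LandmarkSet(
        line_a=Line(point=np.array([cx_shaft, cy]), direction=np.array([0.0, -1.0])),
        line_b=(cranial, caudal),
        line_c=Line(point=caudal, direction=u_lat),
        line_d=Line(point=np.array([x_d, y3]), direction=np.array([0.0, -1.0])),
        line_e=(C.copy(), C + r_e * u_cap),
        s1_length=abs(x_d - caudal[0]) / 3.0,
        s2_length=r_e / 3.0,
        head_center=C.copy(),
        head_height=head_height,
    )

    pre_section = SectionImage(
        bone_mask=bone,
        cartilage_mask=cart_mask,
        mm_per_pixel=spec.mm_per_pixel,
        medial_side=spec.medial_side,
        donor_id=spec.donor_id,
    )
    true_regions = partition_regions(pre_section, true_lm)

    # ---- trabecular fill ----------------------------------------------------
    solid = bone | cart_mask | ~env
    n_dilate = max(int(round(spec.collar_px)), 1)
    collar = ndimage.binary_dilation(solid, structure=np.ones((3, 3), bool), iterations=n_dilate)
    s1 = true_lm.s1_length
    y_floor = y_c + 2.0 * s1 + 4.0 * s  # m strips end well above this
    fillable = env & ~collar & (Y < y_floor)

    stencils = {
        label: polygon_to_mask(true_regions.regions[label], shape)
        for label in ("subchondral", "inner", "sc1", "sc2", "m1", "m2")
    }
    named = np.zeros(shape, dtype=bool)
    for m in stencils.values():
        named |= m
    stencils["rest"] = env & ~cart_mask & ~plate_mask & ~shell & ~named & (Y < y_floor)

    mean_w = spec.trabecular_width[0] * s
    sd_w = spec.trabecular_width[1] * s
    children = np.random.SeedSequence(spec.seed).spawn(len(FILL_LABELS))
    targets = dict(spec.region_bvtv_targets)
    for label, child in zip(FILL_LABELS, children):
        target = targets.get(label)
        if target is None:
            continue
        _fill_region(
            bone, stencils[label], fillable, target, mean_w, sd_w,
            np.random.default_rng(child), label,
        )

    # ---- bookkeeping --------------------------------------------------------
    achieved: Dict[str, float] = {}
    for label, stencil in stencils.items():
        n = int(stencil.sum())
        achieved[label] = 100.0 * int(np.count_nonzero(bone & stencil)) / max(n, 1)
    h_mask = polygon_to_mask(true_regions.regions["h"], shape)
    achieved["h"] = 100.0 * int(np.count_nonzero(bone & h_mask)) / max(int(h_mask.sum()), 1)

    plate_truth = {
        float(a): float(_interp_profile(spec.plate_thickness_profile, np.array([float(a)]))[0])
        for a in range(0, 181, 10)
    }
    cort_truth = {}
    for side in ("medial", "lateral"):
        vals = _interp_cortical(
            spec.cortical_thickness_profile[side], np.arange(9) / 8.0
        )
        for k in range(9):
            cort_truth[(side, k)] = float(vals[k])

    section = SectionImage(
        bone_mask=bone,
        cartilage_mask=cart_mask,
        mm_per_pixel=spec.mm_per_pixel,
        medial_side=spec.medial_side,
        donor_id=spec.donor_id,
    )
    annotation = Annotation(
        cranial_cartilage_end=(float(cranial[0]), float(cranial[1])),
        caudal_cartilage_end=(float(caudal[0]), float(caudal[1])),
    )
    truth = SectionGroundTruth(
        landmarks=true_lm,
        regions=true_regions,
        achieved_bvtv=achieved,
        targets=targets,
        plate_thickness_mm=plate_truth,
        cortical_thickness_mm=cort_truth,
        spec=spec,
    )
    return section, annotation, truth


def _fill_region(
    bone: np.ndarray,
    stencil: np.ndarray,
    fillable: np.ndarray,
    target_pct: float,
    mean_w: float,
    sd_w: float,
    rng: np.random.Generator,
    label: str,
    tol_pp: float = 0.4,
    max_iter: int = 300_000,
) -> None:
    """Dead-leaves ellipse fill of one region to its target fraction.

    Ellipses are clipped to the region stencil and to the fillable
    compartment (marrow collar respected), so region fractions can be
    controlled independently.
    """
    total = int(stencil.sum())
    if total == 0:
        raise SpecError(f"region {label} has no pixels to fill")
    region_fill = stencil & fillable
    idxs = np.flatnonzero(region_fill)
    if idxs.size == 0:
        raise SpecError(f"region {label} has no fillable pixels")
    shape = bone.shape
    ncols = shape[1]
    target_n = target_pct / 100.0 * total
    count = int(np.count_nonzero(bone & stencil))
    typical = math.pi * (mean_w / 2.0) * (mean_w * 5.0 / 2.0)
    stall = 0
    for _ in range(max_iter):
        deficit = target_n - count
        # stop once within a fraction of the tolerance band (the last
        # ellipse is sized to the deficit, so overshoot stays small too)
        if deficit <= max(0.3 * tol_pp / 100.0 * total, 6.0):
            break
        flat = int(idxs[rng.integers(idxs.size)])
        cy_e, cx_e = divmod(flat, ncols)
        width = min(max(rng.normal(mean_w, sd_w), 0.35 * mean_w), 2.5 * mean_w)
        if deficit < 2.0 * typical:
            # final trim: small round-ish leaves sized to the deficit
            aspect = 1.5
            width = min(max(math.sqrt(deficit / 1.2), 1.5), mean_w)
        else:
            aspect = rng.uniform(3.0, 8.0)
        rot = rng.uniform(0.0, math.pi)
        rr, cc = skdraw.ellipse(
            cy_e, cx_e, aspect * width / 2.0, width / 2.0, shape=shape, rotation=rot
        )
        keep = region_fill[rr, cc]
        rr, cc = rr[keep], cc[keep]
        new = int(np.count_nonzero(~bone[rr, cc]))
        if new == 0:
            stall += 1
            if stall > 5000:
                raise SpecError(
                    f"region {label}: cannot reach BV/TV target {target_pct}% "
                    f"(stalled at {100.0 * count / total:.2f}%)"
                )
            continue
        stall = 0
        bone[rr, cc] = True
        count += new
    else:
        raise SpecError(f"region {label}: fill did not converge to {target_pct}%")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Two-group study design mirroring a 6 + 6 donor cohort.

    ``effect_map`` multiplies the normal-like BV/TV targets per region
    for the osteoporotic-like group.  Per-donor variation: a shared
    logit-scale shift plus independent per-region logit noise on the
    targets (Gaussian on the logit of the bone fraction, so jittered
    targets stay in range), mild scaling of the head radius, and one
    common scale factor on the plate and cortical profiles per donor
    drawn identically in both groups (the plate null is preserved by
    design).
    """

    n_per_group: int = 6
    base_section: SectionSpec = field(default_factory=SectionSpec)
    effect_map: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    t_score_normal: Tuple[float, float] = (0.3, 0.8)  # mean, sd; truncated to [-0.9, 1.6]
    t_score_osteoporotic: Tuple[float, float] = (-3.8, 1.0)  # truncated to [-6.5, -2.7]
    jitter_logit_shared: float = 0.06
    jitter_logit_region: float = 0.05
    radius_jitter_rel: float = 0.04
    profile_jitter_rel: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise SpecError("statistics need at least 3 donors per group")
        if self.t_score_normal[0] < -1.0:
            raise SpecError("normal-like T-score mean must be >= -1.0")
        if self.t_score_osteoporotic[0] > -2.5:
            raise SpecError("osteoporotic-like T-score mean must be <= -2.5")
        for k, v in self.effect_map.items():
            if not (0.0 < v <= 1.5):
                raise SpecError(f"effect multiplier for {k} out of range: {v}")


@dataclass
class CohortDonor:
    record: DonorRecord
    section: SectionImage
    annotation: Annotation
    truth: SectionGroundTruth


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _logit_jitter(pct: float, shift: float) -> float:
    f = np.clip(pct / 100.0, 1e-4, 1 - 1e-4)
    z = math.log(f / (1 - f)) + shift
    return 100.0 / (1.0 + math.exp(-z))


def generate_cohort(spec: CohortSpec) -> List[CohortDonor]:
    """Generate a full two-group cohort with per-donor sections.

    ``n_per_group`` donors per group; osteoporotic-like targets are the
    normal-like template times ``effect_map``.  Deterministic for a
    fixed seed.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    donors: List[CohortDonor] = []
    groups = [("normal", "N"), ("osteoporotic", "O")]
    section_children = root.spawn(2 * spec.n_per_group + 1)[1:]
    child_i = 0
    for group, prefix in groups:
        for i in range(spec.n_per_group):
            donor_id = f"{prefix}{i + 1}"
            if group == "normal":
                t = _truncated_normal(meta_rng, *spec.t_score_normal, -0.9, 1.6)
                age = float(np.clip(meta_rng.normal(59.0, 29.0), 19.0, 90.0))
            else:
                t = _truncated_normal(meta_rng, *spec.t_score_osteoporotic, -6.5, -2.7)
                age = float(np.clip(meta_rng.normal(79.0, 9.0), 60.0, 95.0))
            sex = "F" if (i % 2 == 0) else "M"
            record = DonorRecord(
                donor_id=donor_id, age=round(age, 1), sex=sex, t_score=round(t, 1),
                group=allocate_group(round(t, 1)),
            )

            shared = meta_rng.normal(0.0, spec.jitter_logit_shared)
            targets = {}
            base = spec.base_section.region_bvtv_targets
            for label, pct in base.items():
                mult = spec.effect_map.get(label, 1.0) if group == "osteoporotic" else 1.0
                eps = meta_rng.normal(0.0, spec.jitter_logit_region)
                targets[label] = _logit_jitter(pct * mult, shared + eps)

            r_factor = float(
                np.clip(1.0 + meta_rng.normal(0.0, spec.radius_jitter_rel), 0.9, 1.1)
            )
            # one compact-bone scale per donor, shared by plate and
            # cortex so the two stay matched where they meet caudally
            p_factor = float(
                np.clip(1.0 + meta_rng.normal(0.0, spec.profile_jitter_rel), 0.85, 1.15)
            )
            c_factor = p_factor
            plate_profile = {
                a: v * p_factor for a, v in spec.base_section.plate_thickness_profile.items()
            }
            cort_profile = {
                side: [(lvl, th * c_factor) for lvl, th in pts]
                for side, pts in spec.base_section.cortical_thickness_profile.items()
            }
            child_seed = int(section_children[child_i].generate_state(1)[0] % (2**31))
            child_i += 1
            sec_spec = replace(
                spec.base_section,
                head_radius=spec.base_section.head_radius * r_factor,
                plate_thickness_profile=plate_profile,
                cortical_thickness_profile=cort_profile,
                region_bvtv_targets=targets,
                seed=child_seed,
                donor_id=donor_id,
            )
            section, annotation, truth = generate_section(sec_spec)
            donors.append(CohortDonor(record, section, annotation, truth))
    return donors
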