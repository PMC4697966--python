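"""Measurement core: BV/TV inside region polygons, subchondral-plate
thickness along articular rays, cortical thickness along periosteal
normals.

BV/TV is a pure pixel count (pixel-centre point-in-polygon rule, no
partial-pixel weighting), matching counting-based histomorphometry and
making the operator exactly testable against direct enumeration.  All
thickness values are reported in millimetres; a ray that crosses no
articular cartilage yields an explicit missing value, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import MeasurementError
from .geometry import (
    RegionSet,
    ThicknessSites,
    polygon_to_mask,
    ray_points,
    sample_mask,
    _runs,
)
from .model import SectionImage

__all__ = [
    "MorphometryResult",
    "bv_tv",
    "plate_thickness",
    "cortical_thickness",
    "measure_section",
]


@dataclass
class MorphometryResult:
    """All measurements for one section.

    ``plate_thickness_by_angle`` maps the ray angle (degrees across the
    articular semicircle) to mm, with ``None`` where the ray crossed no
    cartilage.  ``cortical_thickness`` maps (side, level index) to mm;
    levels whose measurement failed are absent and listed in ``notes``.
    """

    donor_id: str
    bvtv_by_region: Dict[str, float]
    plate_thickness_by_angle: Dict[float, Optional[float]]
    cortical_thickness: Dict[Tuple[str, int], float]
    parameters: Dict[str, float] = field(default_factory=dict)
    notes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, v in self.bvtv_by_region.items():
            if not (0.0 <= v <= 100.0):
                raise MeasurementError(f"BV/TV out of [0, 100] for {label}: {v}")
        for a, v in self.plate_thickness_by_angle.items():
            if v is not None and v < 0:
                raise MeasurementError(f"negative plate thickness at {a} deg")
        for k, v in self.cortical_thickness.items():
            if v < 0:
                raise MeasurementError(f"negative cortical thickness at {k}")


def bv_tv(section: SectionImage, region) -> float:
    """Bone area fraction inside ``region`` (a shapely polygon), in %.

    100 x (bone pixels inside region) / (total pixels inside region),
    counting a pixel as inside when its centre is (pixel-centre rule).
    """
    minx, miny, maxx, maxy = region.bounds
    h, w = section.shape
    if maxx < -0.5 or maxy < -0.5 or minx > w - 0.5 or miny > h - 0.5:
        raise MeasurementError("region lies outside the image")
    mask = polygon_to_mask(region, section.shape)
    total = int(mask.sum())
    if total == 0:
        raise MeasurementError("zero-area region (no pixel centres inside)")
    bone = int(np.count_nonzero(section.bone_mask & mask))
    return 100.0 * bone / total


def plate_thickness(
    section: SectionImage,
    origin,
    direction,
    step: float = 0.25,
) -> Optional[float]:
    """Subchondral-plate thickness along one outward articular ray, mm.

    Walking outward, the outermost cartilage run marks the deep end of
    the articular cartilage; walking back inward from there, the plate
    extends to the first unstained (marrow) sample.  Thickness is the
    distance between the two interfaces.  Returns None when the ray
    crosses no cartilage.
    """
    h, w = section.shape
    t = np.arange(0.0, float(np.hypot(h, w)), step)
    pts = ray_points(np.asarray(origin, float), np.asarray(direction, float), t)
    cart_v = sample_mask(section.cartilage_mask, pts)
    runs = _runs(cart_v)
    if not runs:
        return None
    start, _ = runs[-1]  # outermost cartilage run
    bone_v = sample_mask(section.bone_mask, pts)
    j = start - 1
    while j >= 0 and bone_v[j]:
        j -= 1
    # interfaces at sample midpoints: cartilage onset and marrow onset
    outer = 0.5 * (t[start] + t[start - 1]) if start > 0 else t[0]
    inner = 0.5 * (t[j + 1] + t[j]) if j >= 0 else t[0]
    return float(max(outer - inner, 0.0) * section.mm_per_pixel)


def _envelope(section: SectionImage) -> np.ndarray:
    return ndimage.binary_fill_holes(section.tissue_mask())


def _surface_point(
    env: np.ndarray,
    level_point: np.ndarray,
    outward: np.ndarray,
    t_max: float,
    step: float = 0.5,
) -> Optional[Tuple[np.ndarray, float]]:
    """Outermost envelope crossing along ``outward`` from a level point.

    Returns the sub-pixel surface point and its parameter, or None if the
    line misses the envelope on that side."""
    t = np.arange(0.0, t_max, step)
    pts = ray_points(level_point, outward, t)
    v = sample_mask(env, pts)
    if not v.any():
        return None
    idx = np.flatnonzero(v)
    entry = idx[-1]  # outermost filled sample
    t_surf = t[entry] + 0.5 * step
    return level_point + outward * t_surf, float(t_surf)


def cortical_thickness(
    section: SectionImage,
    side: str,
    level_point,
    axis_direction,
    step: float = 0.25,
    normal_window_px: float = 3.0,
    min_run_px: float = 3.0,
    env: Optional[np.ndarray] = None,
) -> float:
    """Cortical-wall thickness at one (side, level) site, mm.

    The measurement line is the inward periosteal normal at the contour
    point nearest the level: the surface point is found by entering the
    section from outside along the perpendicular of line a, the local
    contour direction is estimated from surface points one window above
    and below, and the thickness is the first contiguous bone run along
    the inward normal.  Falls back to the perpendicular chord when the
    local normal is undefined (flat or missing contour).
    """
    if side not in ("medial", "lateral"):
        raise MeasurementError(f"unknown side {side!r}")
    if env is None:
        env = _envelope(section)
    h, w = section.shape
    diag = float(np.hypot(h, w))
    lp = np.asarray(level_point, dtype=float)
    u_a = np.asarray(axis_direction, dtype=float)
    perp = np.array([-u_a[1], u_a[0]])
    sign = section.medial_x_direction if side == "medial" else -section.medial_x_direction
    if perp[0] * sign < 0:
        perp = -perp
    # perp now points towards the requested side (outward)
    found = _surface_point(env, lp, perp, diag)
    if found is None:
        raise MeasurementError(f"no periosteal contour on the {side} side at this level")
    surf, _ = found

    up = _surface_point(env, lp + u_a * normal_window_px, perp, diag)
    dn = _surface_point(env, lp - u_a * normal_window_px, perp, diag)
    if up is not None and dn is not None:
        tangent = up[0] - dn[0]
        norm = float(np.hypot(*tangent))
    else:
        norm = 0.0
    if norm > 1e-6:
        tangent = tangent / norm
        normal = np.array([-tangent[1], tangent[0]])
        if float(np.dot(normal, perp)) > 0:
            normal = -normal  # inward
    else:
        normal = -perp  # fallback: horizontal chord

    t = np.arange(-1.0, diag, step)
    pts = ray_points(surf, normal, t)
    bone_v = sample_mask(section.bone_mask, pts)
    runs = _runs(bone_v)
    # the wall is the first substantial run from the surface; slivers
    # shorter than min_run_px (grazing artefacts at tissue junctions)
    # are skipped
    min_samples = max(1, int(round(min_run_px / step)))
    runs = [r for r in runs if (r[1] - r[0]) >= min_samples]
    if not runs:
        return 0.0
    i0, i1 = runs[0]
    # interface midpoints
    lo = 0.5 * (t[i0] + t[i0 - 1]) if i0 > 0 else t[0]
    hi = 0.5 * (t[i1 - 1] + t[i1]) if i1 < len(t) else t[-1]
    return float(max(hi - lo, 0.0) * section.mm_per_pixel)


def measure_section(
    section: SectionImage,
    regions: RegionSet,
    sites: ThicknessSites,
) -> MorphometryResult:
    """Run all three operators over one section; deterministic."""
    bvtv = {label: bv_tv(section, poly) for label, poly in regions.regions.items()}

    def _rot(v: np.ndarray, degrees: float) -> np.ndarray:
        a = math.radians(degrees)
        c, s = math.cos(a), math.sin(a)
        return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])

    plate: Dict[float, Optional[float]] = {}
    angles = [a for a, _, _ in sites.plate_rays]
    lo, hi = min(angles), max(angles)
    for angle, origin, direction in sites.plate_rays:
        inward = sites.sweep_sign * (1.0 if angle < 0.5 * (lo + hi) else -1.0)
        # the two end rays run along the cartilage margin itself and
        # would graze it; they are measured just inside the semicircle
        deltas = (0.5, 1.0, 1.5) if angle in (lo, hi) else (0.0, 0.5, 1.0, 1.5)
        value = None
        for delta in deltas:
            value = plate_thickness(section, origin, _rot(direction, inward * delta))
            if value is not None:
                break
        plate[float(angle)] = value
    cortical: Dict[Tuple[str, int], float] = {}
    notes: List[str] = []
    env = _envelope(section)
    for side, k, lp in sites.cortical_levels:
        try:
            cortical[(side, k)] = cortical_thickness(
                section, side, lp, sites.axis_direction, env=env
            )
        except MeasurementError as exc:
            notes.append(f"cortical ({side}, level {k}): {exc}")
    return MorphometryResult(
        donor_id=section.donor_id,
        bvtv_by_region=bvtv,
        plate_thickness_by_angle=plate,
        cortical_thickness=cortical,
        parameters={
            "mm_per_pixel": section.mm_per_pixel,
            "level_spacing_px": sites.level_spacing,
        },
        notes=notes,
    )
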