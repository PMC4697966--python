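"""Landmark construction and region partition on a frontal section.

The construction mirrors standard interactive histomorphometry practice
for the proximal humerus:

* **line a** - central long axis of the humerus (principal axis of the
  distal shaft, or a manual override),
* **line b** - chord joining the cranial and caudal ends of the hyaline
  articular cartilage (a reproducible stand-in for the anatomical neck),
* **line c** - perpendicular to line a through the caudal end of line b,
* **line d** - parallel to line a, tangent to the distal-medial
  periosteal contour,
* **line e** - perpendicular bisector of line b, running from the centre
  of line b towards the joint surface and ending at the inner surface of
  the subchondral plate.

One third of the medial segment of line c is ``s1`` (width of the medial
metaphyseal strips m1/m2); one third of line e is ``s2`` (width of the
subcapital bands sc1/sc2 and of the subchondral band of the head).  The
partition yields seven cancellous regions: ``h`` (humeral head without
plate), its ``subchondral``/``inner`` split, ``sc1``, ``sc2``, ``m1``
and ``m2``.  Cortical lamellae and the subchondral plate are excluded
from every region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely.geometry as sgeom
from scipy import ndimage
from skimage import measure as skmeasure

from .errors import GeometryError, ParameterError, ValidationError
from .model import Annotation, SectionImage

__all__ = [
    "Line",
    "LandmarkSet",
    "RegionSet",
    "ThicknessSites",
    "fit_long_axis",
    "construct_landmarks",
    "partition_regions",
    "build_thickness_sites",
    "polygon_to_mask",
    "REGION_LABELS",
]

REGION_LABELS = ("h", "sc1", "sc2", "m1", "m2", "subchondral", "inner")

_Vec = np.ndarray


def _unit(v: Sequence[float]) -> _Vec:
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(*v))
    if n == 0:
        raise GeometryError("zero-length direction")
    return v / n


def _perp(v: _Vec) -> _Vec:
    """90 degree rotation (x, y) -> (-y, x)."""
    return np.array([-v[1], v[0]])


def _rot(v: _Vec, degrees: float) -> _Vec:
    a = math.radians(degrees)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


@dataclass
class Line:
    """Infinite oriented line: point + unit direction, pixel units."""

    point: _Vec
    direction: _Vec

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = _unit(self.direction)

    def intersect(self, other: "Line") -> _Vec:
        p, u = self.point, self.direction
        q, v = other.point, other.direction
        denom = u[0] * v[1] - u[1] * v[0]
        if abs(denom) < 1e-12:
            raise GeometryError("lines are parallel; no intersection")
        w = q - p
        t = (w[0] * v[1] - w[1] * v[0]) / denom
        return p + t * u

    def signed_distance(self, pt: Sequence[float]) -> float:
        """Signed perpendicular distance, positive on the +perp side."""
        n = _perp(self.direction)
        return float(np.dot(np.asarray(pt, dtype=float) - self.point, n))


@dataclass
class LandmarkSet:
    """The full landmark system for one section (pixel units)."""

    line_a: Line
    line_b: Tuple[_Vec, _Vec]  # (cranial end, caudal end)
    line_c: Line
    line_d: Line
    line_e: Tuple[_Vec, _Vec]  # (head centre, inner plate surface)
    s1_length: float
    s2_length: float
    head_center: _Vec
    head_height: float

    def __post_init__(self) -> None:
        self.line_b = tuple(np.asarray(p, dtype=float) for p in self.line_b)
        self.line_e = tuple(np.asarray(p, dtype=float) for p in self.line_e)
        self.head_center = np.asarray(self.head_center, dtype=float)

    # -- derived quantities -------------------------------------------------
    @property
    def cranial_end(self) -> _Vec:
        return self.line_b[0]

    @property
    def caudal_end(self) -> _Vec:
        return self.line_b[1]

    @property
    def b_direction(self) -> _Vec:
        return _unit(self.cranial_end - self.caudal_end)

    @property
    def cap_direction(self) -> _Vec:
        """Unit vector from the head centre towards the joint surface."""
        return _unit(self.line_e[1] - self.line_e[0])

    @property
    def e_length(self) -> float:
        return float(np.hypot(*(self.line_e[1] - self.line_e[0])))

    @property
    def caudal_ray(self) -> _Vec:
        """Unit vector from head centre towards the caudal cartilage end."""
        return _unit(self.caudal_end - self.head_center)

    @property
    def sweep_sign(self) -> float:
        """Rotation sense that carries the caudal ray onto the cap axis."""
        plus = _rot(self.caudal_ray, 90.0)
        return 1.0 if float(np.dot(plus, self.cap_direction)) >= 0 else -1.0

    def articular_ray(self, angle_deg: float) -> _Vec:
        """Direction at ``angle_deg`` across the articular semicircle.

        0 degrees points at the caudal cartilage end, 180 at the cranial
        end, sweeping through the cap axis.
        """
        return _rot(self.caudal_ray, self.sweep_sign * angle_deg)

    def validate(self, tol_px: float = 0.5, tol_dir: float = 1e-9) -> None:
        """Assert the perpendicularity / parallelism / subdivision
        invariants of the construction."""
        if abs(float(np.dot(self.line_c.direction, self.line_a.direction))) > tol_dir:
            raise ValidationError("line c is not perpendicular to line a")
        cross = float(
            self.line_d.direction[0] * self.line_a.direction[1]
            - self.line_d.direction[1] * self.line_a.direction[0]
        )
        if abs(cross) > tol_dir:
            raise ValidationError("line d is not parallel to line a")
        e_dir = self.cap_direction
        if abs(float(np.dot(e_dir, self.b_direction))) > 1e-6:
            raise ValidationError("line e is not perpendicular to line b")
        mid = 0.5 * (self.cranial_end + self.caudal_end)
        if float(np.hypot(*(self.line_e[0] - mid))) > tol_px:
            raise ValidationError("line e does not start at the midpoint of line b")
        if abs(3.0 * self.s2_length - self.e_length) > tol_px:
            raise ValidationError("3*s2 does not reproduce |line e|")
        med = self.line_c.intersect(self.line_d)
        med_seg = float(np.hypot(*(med - self.caudal_end)))
        if abs(3.0 * self.s1_length - med_seg) > tol_px:
            raise ValidationError("3*s1 does not reproduce the medial segment of line c")


@dataclass
class RegionSet:
    """Labelled cancellous region polygons plus their provenance."""

    regions: Dict[str, sgeom.base.BaseGeometry]
    provenance: LandmarkSet

    def areas(self) -> Dict[str, float]:
        return {k: float(v.area) for k, v in self.regions.items()}


@dataclass
class ThicknessSites:
    """Measurement sites for plate and cortical thickness.

    ``plate_rays``: list of (angle in degrees, origin, unit direction).
    ``cortical_levels``: list of (side, level index, level point on
    line a); level spacing is head_height / n_segments starting at
    line c and proceeding distally.
    """

    plate_rays: List[Tuple[float, _Vec, _Vec]]
    cortical_levels: List[Tuple[str, int, _Vec]]
    axis_direction: _Vec  # oriented distal -> proximal
    level_spacing: float
    sweep_sign: float = 1.0  # rotation sense caudal ray -> cap axis


# ---------------------------------------------------------------------------
# raster sampling helpers
# ---------------------------------------------------------------------------


def sample_mask(mask: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Nearest-pixel values of ``mask`` at float (x, y) points.

    Pixel (row i, col j) has its centre at (x=j, y=i); points outside the
    raster sample False.
    """
    x = np.rint(points[:, 0]).astype(int)
    y = np.rint(points[:, 1]).astype(int)
    h, w = mask.shape
    ok = (x >= 0) & (x < w) & (y >= 0) & (y < h)
    out = np.zeros(len(points), dtype=bool)
    out[ok] = mask[y[ok], x[ok]]
    return out


def ray_points(origin: _Vec, direction: _Vec, t: np.ndarray) -> np.ndarray:
    return np.asarray(origin, dtype=float)[None, :] + t[:, None] * np.asarray(direction, dtype=float)[None, :]


def _runs(values: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    if not values.any():
        return []
    v = values.astype(np.int8)
    d = np.diff(np.concatenate([[0], v, [0]]))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _articular_radii(
    bone: np.ndarray,
    cart: np.ndarray,
    origin: _Vec,
    direction: _Vec,
    t_max: float,
    step: float = 0.25,
    plate_min_run: float = 3.0,
) -> Optional[Tuple[float, float]]:
    """(inner plate surface, outer cartilage surface) distances from
    ``origin`` along one outward ray.

    The outermost cartilage run on the ray anchors the search; walking
    back inward from its inner edge, the first bone run of length >=
    ``plate_min_run`` pixels is the plate, and the inner radius is the
    midpoint between the last bone sample of that run and the first
    marrow sample beneath it.  Returns None if the ray crosses no
    cartilage.
    """
    t = np.arange(0.0, t_max, step)
    pts = ray_points(origin, direction, t)
    cart_v = sample_mask(cart, pts)
    runs = _runs(cart_v)
    if not runs:
        return None
    start, stop = runs[-1]  # outermost cartilage run
    r_outer = float(t[stop - 1] + 0.5 * step)
    bone_v = sample_mask(bone, pts)
    i = start - 1
    min_samples = max(1, int(round(plate_min_run / step)))
    while i >= 0:
        # skip any non-bone gap, then measure the next bone run inward
        while i >= 0 and not bone_v[i]:
            i -= 1
        if i < 0:
            break
        j = i
        while j >= 0 and bone_v[j]:
            j -= 1
        if (i - j) >= min_samples:
            # inner surface: midpoint between last bone (j+1) and marrow (j)
            return float(0.5 * (t[j + 1] + t[max(j, 0)])), r_outer
        i = j
    # no plate-like run found: degenerate, plate thickness ~ 0
    return float(t[start]), r_outer


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fit_long_axis(
    section: SectionImage,
    annotation: Optional[Annotation] = None,
    shaft_fraction: float = 0.30,
) -> Line:
    """Central long axis of the humerus (line a), oriented distal to
    proximal.

    If the annotation carries a shaft-axis override the line simply
    passes through the two annotated points.  Otherwise the axis is the
    principal second-moment axis of the most distal ``shaft_fraction`` of
    the bone envelope.  Sections are assumed mounted proximal-side up.
    """
    if not (0.0 < shaft_fraction <= 0.6):
        raise ParameterError(f"shaft_fraction must be in (0, 0.6], got {shaft_fraction}")
    if annotation is not None and annotation.shaft_axis_override is not None:
        p, q = (np.asarray(pt, dtype=float) for pt in annotation.shaft_axis_override)
        d = q - p
        if d[1] > 0:  # orient distal -> proximal, i.e. towards smaller y
            d = -d
        return Line(point=p, direction=d)

    env = ndimage.binary_fill_holes(section.tissue_mask())
    if int(env.sum()) < 100:
        raise GeometryError("degenerate bone mask (envelope < 100 px)")
    ys, xs = np.nonzero(env)
    pts_all = np.column_stack([xs, ys]).astype(float)

    def _fit(proj: np.ndarray) -> Tuple[_Vec, _Vec]:
        # keep the most distal shaft_fraction along the projection axis
        lo, hi = proj.min(), proj.max()
        sel = proj >= hi - shaft_fraction * (hi - lo)
        if int(sel.sum()) < 20:
            raise GeometryError("distal shaft band too small for an axis fit")
        band = pts_all[sel]
        centroid = band.mean(axis=0)
        cov = np.cov((band - centroid).T)
        evals, evecs = np.linalg.eigh(cov)
        d = evecs[:, int(np.argmax(evals))]
        if d[1] > 0:  # orient distal -> proximal (proximal mounted up)
            d = -d
        return centroid, d

    # two passes: the first band is cut by image rows, which biases the
    # axis of a tilted shaft; the second band is cut perpendicular to
    # the first-pass axis, removing that bias
    centroid, d = _fit(pts_all[:, 1])
    centroid, d = _fit(pts_all @ (-d))
    return Line(point=centroid, direction=d)


def construct_landmarks(
    section: SectionImage,
    annotation: Annotation,
    line_a: Line,
    plate_min_run: float = 3.0,
    distal_fraction_for_d: float = 1.0 / 3.0,
) -> LandmarkSet:
    """Build the complete landmark system from the fitted long axis and
    the annotated cartilage endpoints.

    Line e terminates at the inner surface of the subchondral plate: the
    first bone run of length >= ``plate_min_run`` px met when walking
    inward from the deep edge of the articular cartilage along the
    perpendicular bisector of line b.  Anchoring the search at the
    cartilage (rather than walking blindly outward from the head centre)
    keeps trabeculae of comparable width from masquerading as the plate.
    """
    annotation.validate_on_section(section)
    cranial = np.asarray(annotation.cranial_cartilage_end, dtype=float)
    caudal = np.asarray(annotation.caudal_cartilage_end, dtype=float)
    center = 0.5 * (cranial + caudal)
    h, w = section.shape
    diag = float(np.hypot(h, w))

    # line c: perpendicular to a through the caudal cartilage end,
    # directed medial -> lateral
    u_lat = _perp(line_a.direction)
    if u_lat[0] * section.medial_x_direction > 0:
        u_lat = -u_lat
    line_c = Line(point=caudal, direction=u_lat)

    # line d: parallel to a, tangent to the medial periosteal contour in
    # the distal part of the section; tangency at the extreme medial
    # pixel, ties broken by the more distal point
    env = ndimage.binary_fill_holes(section.tissue_mask())
    ys, xs = np.nonzero(env)
    y0, y1 = ys.min(), ys.max()
    cutoff = y1 - distal_fraction_for_d * (y1 - y0)
    sel = ys >= cutoff
    if not sel.any():
        raise GeometryError("no envelope pixels in the distal band for line d")
    xs_d, ys_d = xs[sel], ys[sel]
    med_coord = xs_d * section.medial_x_direction
    extreme = med_coord.max()
    at_ext = med_coord == extreme
    iy = int(np.max(ys_d[at_ext]))  # more distal tie-break
    ix = int(extreme * section.medial_x_direction)
    line_d = Line(point=np.array([float(ix), float(iy)]), direction=line_a.direction)

    # line e: perpendicular bisector of b towards the articular cap
    n = _perp(_unit(cranial - caudal))
    cart_idx = np.nonzero(section.cartilage_mask)
    cart_centroid = np.array([cart_idx[1].mean(), cart_idx[0].mean()])
    if float(np.dot(cart_centroid - center, n)) < 0:
        n = -n
    found = _articular_radii(
        section.bone_mask, section.cartilage_mask, center, n, t_max=diag,
        plate_min_run=plate_min_run,
    )
    r_e = found[0] if found is not None else None
    if r_e is None:
        raise GeometryError(
            "line e found no articular cartilage walking from the centre of "
            f"line b at {tuple(np.round(center, 1))} along {tuple(np.round(n, 3))}"
        )
    e_end = center + r_e * n

    # s1: a third of the medial segment of line c (caudal end -> line d)
    p_lat = line_c.intersect(line_d)
    med_seg = float(np.hypot(*(p_lat - caudal)))
    if med_seg < 1.0:
        raise GeometryError("medial segment of line c is degenerate")
    if float(np.dot(p_lat - caudal, u_lat)) < 0:
        raise GeometryError("line d lies medial of the caudal cartilage end")

    # head height: line c to the most proximal articular-surface point,
    # measured along line a
    proj = (cart_idx[1] - caudal[0]) * line_a.direction[0] + (
        cart_idx[0] - caudal[1]
    ) * line_a.direction[1]
    head_height = float(proj.max())
    if head_height <= 0:
        raise GeometryError("articular cartilage does not extend proximal of line c")

    return LandmarkSet(
        line_a=line_a,
        line_b=(cranial, caudal),
        line_c=line_c,
        line_d=line_d,
        line_e=(center, e_end),
        s1_length=med_seg / 3.0,
        s2_length=r_e / 3.0,
        head_center=center,
        head_height=head_height,
    )


# -- region partition -------------------------------------------------------


def _envelope_polygon(section: SectionImage, subsample: int = 3) -> sgeom.Polygon:
    env = ndimage.binary_fill_holes(section.tissue_mask())
    contours = skmeasure.find_contours(env.astype(float), 0.5)
    if not contours:
        raise GeometryError("no periosteal contour found")
    best, best_area = None, -1.0
    for c in contours:
        xy = np.column_stack([c[:, 1], c[:, 0]])  # (row, col) -> (x, y)
        if len(xy) < 4:
            continue
        poly = sgeom.Polygon(xy[::subsample])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.area > best_area:
            best, best_area = poly, poly.area
    if best is None or best.is_empty:
        raise GeometryError("periosteal contour is degenerate")
    if isinstance(best, sgeom.MultiPolygon):
        best = max(best.geoms, key=lambda g: g.area)
    return best


def _lamella_run(
    bone: np.ndarray,
    env: np.ndarray,
    origin: _Vec,
    direction: _Vec,
    t_max: float,
    step: float = 0.5,
) -> float:
    """Thickness of the outer bone lamella met when entering the envelope
    from outside along ``direction`` (both senses give one value each;
    this helper handles a single sense).  Returns 0 if nothing is met."""
    t = np.arange(0.0, t_max, step)
    pts = ray_points(origin, direction, t)
    env_v = sample_mask(env, pts)
    if not env_v.any():
        return 0.0
    # outermost crossing: scan from far end towards origin
    idx = np.flatnonzero(env_v)
    entry = idx[-1]
    bone_v = sample_mask(bone, pts)
    i = entry
    while i >= 0 and not bone_v[i] and env_v[i]:
        i -= 1
    j = i
    while j >= 0 and bone_v[j]:
        j -= 1
    return float((i - j) * step)


def _largest_polygon(geom: sgeom.base.BaseGeometry) -> sgeom.Polygon:
    if isinstance(geom, sgeom.Polygon):
        return geom
    if isinstance(geom, sgeom.MultiPolygon) and len(geom.geoms):
        return max(geom.geoms, key=lambda g: g.area)
    if isinstance(geom, sgeom.base.BaseGeometry) and hasattr(geom, "geoms"):
        polys = [g for g in geom.geoms if isinstance(g, sgeom.Polygon)]
        if polys:
            return max(polys, key=lambda g: g.area)
    raise GeometryError("expected a polygonal geometry, got " + geom.geom_type)


def partition_regions(
    section: SectionImage,
    lm: LandmarkSet,
    m_length_factor: float = 2.0,
    margin_mm: float = 0.06,
    fan_step_deg: float = 1.0,
    plate_min_run: float = 3.0,
    erosion_margin_mm: float = 0.05,
) -> RegionSet:
    """Partition the section into the seven cancellous regions.

    * ``h``: head cancellous bone proximal of line b, bounded by the
      inner surface of the subchondral plate (found per angle by the same
      cartilage-anchored walk used for line e), inset by ``margin_mm``
      (margins are physical lengths so that the partition is stable
      under resampling of the same section).
    * ``subchondral`` / ``inner``: the band of ``h`` within ``s2`` of the
      plate inner surface, and the remainder.
    * ``sc1`` / ``sc2``: two bands of width ``s2`` parallel to and distal
      of line b, clipped to the periosteal envelope eroded by the locally
      measured lamella thickness (cortical lamellae excluded).
    * ``m1`` / ``m2``: medial metaphyseal strips of width ``s1`` distal
      of line c (m1 medial-most), extending ``m_length_factor * s1``
      distally, clipped to the eroded envelope and kept disjoint from the
      subcapital bands.
    """
    center = lm.head_center
    s1, s2 = float(lm.s1_length), float(lm.s2_length)
    h_img, w_img = section.shape
    diag = float(np.hypot(h_img, w_img))
    bone, cart = section.bone_mask, section.cartilage_mask
    margin_px = margin_mm / section.mm_per_pixel
    erosion_margin_px = erosion_margin_mm / section.mm_per_pixel

    # ---- head fan: plate inner surface per articular angle -----------------
    r_est = float(np.hypot(*(lm.caudal_end - center)))
    t_max_fan = min(diag, 1.5 * r_est + 20.0)
    angles = np.arange(0.0, 180.0 + 1e-9, fan_step_deg)
    radii = np.full(len(angles), np.nan)
    radii_outer = np.full(len(angles), np.nan)
    for i, a in enumerate(angles):
        d = lm.articular_ray(a)
        found = _articular_radii(bone, cart, center, d, t_max=t_max_fan,
                                 plate_min_run=plate_min_run)
        if found is not None:
            radii[i], radii_outer[i] = found
    if np.isnan(radii).all():
        raise GeometryError("no articular cartilage found on any head fan ray")
    # interpolate the occasional missing ray from its neighbours
    if np.isnan(radii).any():
        ok = ~np.isnan(radii)
        radii = np.interp(angles, angles[ok], radii[ok])
        radii_outer = np.interp(angles, angles[ok], radii_outer[ok])

    def _fan_points(rr: np.ndarray) -> List[np.ndarray]:
        return [center + lm.articular_ray(a) * max(r, 1.0) for a, r in zip(angles, rr)]

    def _polygon(pts) -> sgeom.Polygon:
        poly = sgeom.Polygon(pts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return _largest_polygon(poly)

    outer_pts = _fan_points(np.maximum(radii - margin_px, 1.0))
    inner_pts = _fan_points(np.maximum(radii - s2, 1.0))
    h_poly = _polygon(outer_pts)
    inner_poly = _polygon(inner_pts)
    # the subchondral band is built as an explicit crescent sharing its
    # vertices with h and inner, so that rasterized h = subchondral
    # union inner pixel-exactly
    subchondral = _polygon(outer_pts + inner_pts[::-1])
    if subchondral.is_empty:
        raise ValidationError("empty region: subchondral")
    # everything articular (cartilage + plate + head cancellous bone),
    # subtracted from the bands and strips so none of them reach under
    # the joint surface
    cap_poly = _polygon(_fan_points(radii_outer + 3.0))

    # ---- envelope and erosion ---------------------------------------------
    env_poly = _envelope_polygon(section)
    env_mask = ndimage.binary_fill_holes(section.tissue_mask())
    # lamella runs are measured on stained tissue (bone or cartilage) so
    # that band ends brushing the articular margin erode past it too
    tissue = section.tissue_mask()

    v_ch = lm.b_direction
    n_dist = -lm.cap_direction
    half_len = 1.6 * 0.5 * float(np.hypot(*(lm.cranial_end - lm.caudal_end)))

    def _band(k: int) -> sgeom.base.BaseGeometry:
        off0, off1 = k * s2, (k + 1) * s2
        mid = center + n_dist * (0.5 * (off0 + off1))
        t_lam = max(
            _lamella_run(tissue, env_mask, mid, v_ch, half_len * 2.0),
            _lamella_run(tissue, env_mask, mid, -v_ch, half_len * 2.0),
        )
        c00 = center + n_dist * off0 - v_ch * half_len
        c01 = center + n_dist * off0 + v_ch * half_len
        c11 = center + n_dist * off1 + v_ch * half_len
        c10 = center + n_dist * off1 - v_ch * half_len
        rect = sgeom.Polygon([c00, c01, c11, c10])
        clipped = rect.intersection(env_poly.buffer(-(t_lam + erosion_margin_px)))
        if clipped.is_empty:
            raise ValidationError(f"empty region: sc{k + 1}")
        return _largest_polygon(clipped)

    # ---- medial metaphyseal strips -----------------------------------------
    # built before the subcapital bands: where the oblique sc bands dip
    # distal of line c on the medial side, the metaphyseal strips take
    # precedence and the bands are clipped around them
    u_lat = lm.line_c.direction  # medial -> lateral along line c
    u_dist = -lm.line_a.direction  # proximal -> distal
    x0 = lm.caudal_end
    m_len = m_length_factor * s1
    # probe from the marrow interior (line d's offset) so the medial
    # wall run is measured in full, not truncated at the probe
    probe = x0 + u_lat * (3.0 * s1) + u_dist * (0.5 * m_len)
    t_med = _lamella_run(tissue, env_mask, probe, -u_lat, diag)

    env_eroded_m = env_poly.buffer(-(t_med + erosion_margin_px))
    strips: List[sgeom.base.BaseGeometry] = []
    for j in range(2):
        q00 = x0 + u_lat * (j * s1)
        q01 = x0 + u_lat * ((j + 1) * s1)
        q11 = q01 + u_dist * m_len
        q10 = q00 + u_dist * m_len
        quad = sgeom.Polygon([q00, q01, q11, q10])
        clipped = quad.intersection(env_eroded_m).difference(cap_poly)
        if clipped.is_empty:
            raise ValidationError(f"empty region: m{j + 1}")
        strips.append(_largest_polygon(clipped))
    m1, m2 = strips

    sc1 = _band(0).difference(m1).difference(m2).difference(cap_poly)
    sc2 = _band(1).difference(m1).difference(m2).difference(cap_poly)
    for k, g in (("sc1", sc1), ("sc2", sc2)):
        if g.is_empty:
            raise ValidationError(f"empty region: {k}")
    sc1 = _largest_polygon(sc1)
    sc2 = _largest_polygon(sc2)

    regions = {
        "h": h_poly,
        "sc1": sc1,
        "sc2": sc2,
        "m1": m1,
        "m2": m2,
        "subchondral": subchondral,
        "inner": inner_poly,
    }
    for label, poly in regions.items():
        if poly.is_empty or poly.area <= 0:
            raise ValidationError(f"empty region: {label}")
        if not poly.is_valid:
            raise GeometryError(f"self-intersecting region polygon: {label}")
    return RegionSet(regions=regions, provenance=lm)


def build_thickness_sites(
    lm: LandmarkSet,
    angular_step: float = 10.0,
    n_segments: int = 8,
) -> ThicknessSites:
    """Plate rays and cortical levels from the landmark system.

    Plate rays sample the articular semicircle every ``angular_step``
    degrees from the head centre, endpoints included (19 rays at the
    default 10 degree step).  Cortical levels: ``n_segments + 1`` per
    side at a spacing of ``head_height / n_segments`` along line a,
    starting at line c and proceeding distally.
    """
    if angular_step <= 0 or abs(180.0 / angular_step - round(180.0 / angular_step)) > 1e-9:
        raise ParameterError(f"angular_step must divide 180, got {angular_step}")
    if int(n_segments) < 1:
        raise ParameterError(f"n_segments must be >= 1, got {n_segments}")
    n_rays = int(round(180.0 / angular_step)) + 1
    rays = [
        (i * angular_step, lm.head_center.copy(), lm.articular_ray(i * angular_step))
        for i in range(n_rays)
    ]
    spacing = float(lm.head_height) / int(n_segments)
    u_dist = -lm.line_a.direction
    base = lm.line_c.intersect(lm.line_a)
    levels: List[Tuple[str, int, _Vec]] = []
    for side in ("medial", "lateral"):
        for k in range(int(n_segments) + 1):
            levels.append((side, k, base + u_dist * (k * spacing)))
    return ThicknessSites(
        plate_rays=rays,
        cortical_levels=levels,
        axis_direction=lm.line_a.direction.copy(),
        level_spacing=spacing,
        sweep_sign=lm.sweep_sign,
    )


# ---------------------------------------------------------------------------
# rasterization (pixel-centre rule)
# ---------------------------------------------------------------------------


def _ring_mask(coords: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Scanline fill of a simple closed ring, pixel-centre rule.

    A pixel centre (x=j, y=r) is inside when a horizontal ray from it
    crosses the boundary an odd number of times; edges are treated
    half-open in y so shared vertices are counted once.
    """
    m = np.zeros(shape, dtype=bool)
    x = np.asarray(coords[:, 0], dtype=float)
    y = np.asarray(coords[:, 1], dtype=float)
    if not (np.allclose(x[0], x[-1]) and np.allclose(y[0], y[-1])):
        x = np.append(x, x[0])
        y = np.append(y, y[0])
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    keep = y0 != y1
    x0, x1, y0, y1 = x0[keep], x1[keep], y0[keep], y1[keep]
    if x0.size == 0:
        return m
    ylo = np.minimum(y0, y1)
    yhi = np.maximum(y0, y1)
    r0 = np.ceil(ylo).astype(np.int64)
    r1 = np.ceil(yhi).astype(np.int64)  # exclusive (half-open at the top)
    counts = np.maximum(r1 - r0, 0)
    if counts.sum() == 0:
        return m
    edge_idx = np.repeat(np.arange(x0.size), counts)
    offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    rows = r0[edge_idx] + offs
    t = (rows - y0[edge_idx]) / (y1[edge_idx] - y0[edge_idx])
    xs = x0[edge_idx] + t * (x1[edge_idx] - x0[edge_idx])
    order = np.lexsort((xs, rows))
    rows, xs = rows[order], xs[order]
    h, w = shape
    for i in range(0, len(rows) - 1, 2):
        r = rows[i]
        if r < 0 or r >= h or rows[i + 1] != r:
            continue
        j0 = int(np.floor(xs[i])) + 1
        j1 = int(np.ceil(xs[i + 1])) - 1
        if j1 < j0:
            continue
        m[r, max(j0, 0) : min(j1, w - 1) + 1] = True
    return m


def polygon_to_mask(poly: sgeom.base.BaseGeometry, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose integer-coordinate centres fall inside
    the polygon (holes subtracted, multi-parts united)."""
    if isinstance(poly, sgeom.MultiPolygon):
        out = np.zeros(shape, dtype=bool)
        for g in poly.geoms:
            out |= polygon_to_mask(g, shape)
        return out
    if isinstance(poly, sgeom.base.BaseGeometry) and not isinstance(poly, sgeom.Polygon):
        polys = [g for g in getattr(poly, "geoms", []) if isinstance(g, sgeom.Polygon)]
        out = np.zeros(shape, dtype=bool)
        for g in polys:
            out |= polygon_to_mask(g, shape)
        return out
    ext = np.asarray(poly.exterior.coords)
    m = _ring_mask(ext, shape)
    for hole in poly.interiors:
        m &= ~_ring_mask(np.asarray(hole.coords), shape)
    return m
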