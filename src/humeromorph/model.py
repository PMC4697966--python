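"""Core data model for calibrated frontal sections of the proximal humerus.

A section is represented by two aligned binary rasters: a *bone* mask
(mineralized tissue, stained) and a *cartilage* mask (hyaline articular
cartilage).  The pair stands in for a stained histological section after
segmentation.  Geometry is done in pixel units on the raster grid (origin
top-left, x rightward, y downward, 0-based) and converted to millimetres
only at reporting time through ``mm_per_pixel``.

Anatomical orientation is explicit metadata: sections are assumed mounted
proximal-side up, and ``medial_side`` records which image side is
anatomically medial, because frontal sections may be mounted mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import ValidationError

__all__ = ["SectionImage", "Annotation", "DonorRecord", "Point"]

Point = Tuple[float, float]  # (x, y) in pixel units


@dataclass
class SectionImage:
    """Calibrated pair of aligned binary masks for one frontal section.

    Parameters
    ----------
    bone_mask :
        2D boolean array, ``True`` where mineralized bone is present.
    cartilage_mask :
        2D boolean array of identical shape, ``True`` on hyaline cartilage.
    mm_per_pixel :
        Isotropic length calibration in mm per pixel (> 0).  There is no
        default: the scan resolution is a property of the acquisition and
        must always be supplied.
    medial_side :
        ``"left"`` or ``"right"``: which image side is anatomically medial.
    donor_id :
        Opaque identifier used in result tables.
    """

    bone_mask: np.ndarray
    cartilage_mask: np.ndarray
    mm_per_pixel: float
    medial_side: str
    donor_id: str = ""

    def __post_init__(self) -> None:
        self.bone_mask = np.asarray(self.bone_mask, dtype=bool)
        self.cartilage_mask = np.asarray(self.cartilage_mask, dtype=bool)
        if self.bone_mask.ndim != 2:
            raise ValidationError("bone_mask must be 2D")
        if self.bone_mask.shape != self.cartilage_mask.shape:
            raise ValidationError(
                f"mask shapes differ: bone {self.bone_mask.shape} vs "
                f"cartilage {self.cartilage_mask.shape}"
            )
        overlap = int(np.count_nonzero(self.bone_mask & self.cartilage_mask))
        if overlap:
            raise ValidationError(
                f"{overlap} pixels are labelled both bone and cartilage; "
                "a pixel is one tissue or the other"
            )
        if not (float(self.mm_per_pixel) > 0):
            raise ValidationError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")
        self.mm_per_pixel = float(self.mm_per_pixel)
        if self.medial_side not in ("left", "right"):
            raise ValidationError(f"medial_side must be 'left' or 'right', got {self.medial_side!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.bone_mask.shape

    @property
    def medial_x_direction(self) -> int:
        """+1 if medial is towards increasing x, else -1."""
        return -1 if self.medial_side == "left" else 1

    def tissue_mask(self) -> np.ndarray:
        """Bone or cartilage (any stained tissue)."""
        return self.bone_mask | self.cartilage_mask


@dataclass
class Annotation:
    """Manual landmark annotation accompanying a section.

    ``cranial_cartilage_end`` and ``caudal_cartilage_end`` are the two ends
    of the hyaline articular cartilage in pixel coordinates; their
    connection approximates the anatomical neck.  ``shaft_axis_override``
    optionally pins the humeral long axis to a user-drawn line instead of
    the automatic principal-axis fit.
    """

    cranial_cartilage_end: Point
    caudal_cartilage_end: Point
    shaft_axis_override: Optional[Tuple[Point, Point]] = None
    notes: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.cranial_cartilage_end, dtype=float)
        b = np.asarray(self.caudal_cartilage_end, dtype=float)
        if a.shape != (2,) or b.shape != (2,):
            raise ValidationError("cartilage endpoints must be 2D points (x, y)")
        if np.allclose(a, b):
            raise ValidationError("cranial and caudal cartilage ends must be distinct")
        self.cranial_cartilage_end = (float(a[0]), float(a[1]))
        self.caudal_cartilage_end = (float(b[0]), float(b[1]))
        if self.shaft_axis_override is not None:
            p, q = (np.asarray(p, dtype=float) for p in self.shaft_axis_override)
            if np.allclose(p, q):
                raise ValidationError("shaft_axis_override points must be distinct")
            self.shaft_axis_override = (
                (float(p[0]), float(p[1])),
                (float(q[0]), float(q[1])),
            )

    def validate_on_section(self, section: SectionImage, tol_px: float = 2.0) -> None:
        """Check that both cartilage endpoints lie on or within ``tol_px``
        of the cartilage-mask boundary."""
        cart = section.cartilage_mask
        if not cart.any():
            raise ValidationError("section has no cartilage pixels to anchor the annotation")
        ys, xs = np.nonzero(cart)
        for name, (x, y) in (
            ("cranial", self.cranial_cartilage_end),
            ("caudal", self.caudal_cartilage_end),
        ):
            d2 = (xs - x) ** 2 + (ys - y) ** 2
            if float(np.min(d2)) > tol_px**2:
                raise ValidationError(
                    f"{name} cartilage end ({x:.1f}, {y:.1f}) is more than "
                    f"{tol_px} px from the cartilage mask"
                )


#: WHO T-score bands (DXA): osteoporosis at T <= -2.5, normal at T >= -1.0.
GROUPS = ("normal", "osteopenia", "osteoporotic")


@dataclass
class DonorRecord:
    """One donor: identity, demographics and DXA T-score group."""

    donor_id: str
    age: float
    sex: str
    t_score: float
    group: str = field(default="")

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        # late import to avoid a cycle at module load
        from .stats import allocate_group

        expected = allocate_group(self.t_score)
        if not self.group:
            self.group = expected
        elif self.group != expected:
            raise ValidationError(
                f"donor {self.donor_id}: group {self.group!r} inconsistent with "
                f"T-score {self.t_score} (WHO rule gives {expected!r})"
            )
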