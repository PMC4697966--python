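"""Readers and writers for sections, annotations, donor tables and
result tables.

Raster masks are 8-bit PNG or TIFF with nonzero meaning mask-true.
Annotations are JSON; donor tables and results are CSV.  Result CSVs
round-trip bit-exactly (shortest round-trip float formatting on write,
plain float parsing on read).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, List, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError
from .model import Annotation, DonorRecord, SectionImage
from .morphometry import MorphometryResult
from .stats import allocate_group

__all__ = [
    "read_section",
    "write_section",
    "read_annotation",
    "write_annotation",
    "read_donor_table",
    "write_donor_table",
    "write_results",
    "read_results",
    "naive_threshold",
]

PathLike = Union[str, os.PathLike]

BVTV_COLUMNS = ["donor_id", "region", "bvtv_pct"]
PLATE_COLUMNS = ["donor_id", "angle_deg", "thickness_mm"]
CORTICAL_COLUMNS = ["donor_id", "side", "level", "thickness_mm"]


def _read_mask(path: PathLike) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable raster
        raise FormatError(f"could not decode raster {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse any colour/alpha channels
        arr = arr[..., : min(arr.shape[-1], 3)].max(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"mask raster must be 2D, got shape {arr.shape} in {path}")
    return arr != 0


def read_section(
    bone_path: PathLike,
    cartilage_path: PathLike,
    calibration: float,
    medial_side: str,
    donor_id: str = "",
) -> SectionImage:
    """Load a bone/cartilage mask pair into a validated SectionImage.

    Nonzero pixels are mask-true; the two rasters must decode to
    identical dimensions and must not overlap.
    """
    bone = _read_mask(bone_path)
    cart = _read_mask(cartilage_path)
    if bone.shape != cart.shape:
        raise FormatError(
            f"mask dimensions differ: {bone.shape} ({bone_path}) vs "
            f"{cart.shape} ({cartilage_path})"
        )
    return SectionImage(
        bone_mask=bone,
        cartilage_mask=cart,
        mm_per_pixel=calibration,
        medial_side=medial_side,
        donor_id=donor_id or Path(bone_path).parent.name,
    )


def write_section(section: SectionImage, bone_path: PathLike, cartilage_path: PathLike) -> None:
    """Write the mask pair as 8-bit rasters (format from the extension)."""
    iio.imwrite(bone_path, (section.bone_mask.astype(np.uint8)) * 255)
    iio.imwrite(cartilage_path, (section.cartilage_mask.astype(np.uint8)) * 255)


# -- annotations ------------------------------------------------------------


def read_annotation(path: PathLike) -> Annotation:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"annotation {path} is not valid JSON: {exc}") from exc
    try:
        cranial = tuple(data["cranial_cartilage_end"])
        caudal = tuple(data["caudal_cartilage_end"])
    except KeyError as exc:
        raise FormatError(f"annotation {path} misses key {exc}") from exc
    override = data.get("shaft_axis_override")
    if override is not None:
        override = (tuple(override[0]), tuple(override[1]))
    return Annotation(
        cranial_cartilage_end=cranial,
        caudal_cartilage_end=caudal,
        shaft_axis_override=override,
        notes=data.get("notes", ""),
    )


def write_annotation(annotation: Annotation, path: PathLike) -> None:
    data = {
        "cranial_cartilage_end": list(annotation.cranial_cartilage_end),
        "caudal_cartilage_end": list(annotation.caudal_cartilage_end),
        "shaft_axis_override": (
            [list(p) for p in annotation.shaft_axis_override]
            if annotation.shaft_axis_override
            else None
        ),
        "notes": annotation.notes,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


# -- donor table ------------------------------------------------------------


def read_donor_table(path: PathLike) -> List[DonorRecord]:
    """CSV with header ``id,age,sex,t_score``; group is filled from the
    WHO T-score rule."""
    df = pd.read_csv(path, comment="#")
    missing = {"id", "age", "sex", "t_score"} - set(df.columns)
    if missing:
        raise FormatError(f"donor table {path} misses columns: {sorted(missing)}")
    records: List[DonorRecord] = []
    for i, row in df.iterrows():
        t = pd.to_numeric(pd.Series([row["t_score"]]), errors="coerce").iloc[0]
        if pd.isna(t):
            raise FormatError(
                f"donor table {path}, row {i} (id={row['id']}): "
                f"unparsable t_score {row['t_score']!r}"
            )
        records.append(
            DonorRecord(
                donor_id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]).strip(),
                t_score=float(t),
                group=allocate_group(float(t)),
            )
        )
    return records


def write_donor_table(records: Sequence[DonorRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "id": [r.donor_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "t_score": [r.t_score for r in records],
        }
    ).to_csv(path, index=False)


# -- results ----------------------------------------------------------------


def results_to_frames(results: Sequence[MorphometryResult]):
    """Tidy (bvtv, plate, cortical) DataFrames for a list of results."""
    return _results_frames(results)


def _results_frames(results: Sequence[MorphometryResult]):
    bvtv_rows, plate_rows, cort_rows = [], [], []
    for res in results:
        for region in sorted(res.bvtv_by_region):
            bvtv_rows.append((res.donor_id, region, res.bvtv_by_region[region]))
        for angle in sorted(res.plate_thickness_by_angle):
            plate_rows.append((res.donor_id, angle, res.plate_thickness_by_angle[angle]))
        for side, level in sorted(res.cortical_thickness):
            cort_rows.append((res.donor_id, side, level, res.cortical_thickness[(side, level)]))
    return (
        pd.DataFrame(bvtv_rows, columns=BVTV_COLUMNS),
        pd.DataFrame(plate_rows, columns=PLATE_COLUMNS),
        pd.DataFrame(cort_rows, columns=CORTICAL_COLUMNS),
    )


def write_results(
    results: Union[MorphometryResult, Sequence[MorphometryResult]],
    out_dir: PathLike,
    header_comment: str = "",
) -> Dict[str, Path]:
    """Write ``bvtv.csv``, ``plate_thickness.csv`` and
    ``cortical_thickness.csv`` under ``out_dir``.

    One row per (donor, region), (donor, angle) and (donor, side, level)
    respectively; missing plate values are written as empty cells, never
    as zero.  An optional comment line (e.g. a config hash) is embedded
    at the top of each file.
    """
    if isinstance(results, MorphometryResult):
        results = [results]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = dict(
        zip(
            ("bvtv.csv", "plate_thickness.csv", "cortical_thickness.csv"),
            _results_frames(results),
        )
    )
    paths = {}
    for name, df in frames.items():
        p = out / name
        with open(p, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)
        paths[name] = p
    return paths


def read_results(out_dir: PathLike) -> Dict[str, pd.DataFrame]:
    """Read back the three result CSVs (values round-trip bit-exactly)."""
    out = Path(out_dir)
    frames = {}
    for name in ("bvtv.csv", "plate_thickness.csv", "cortical_thickness.csv"):
        frames[name] = pd.read_csv(out / name, comment="#")
    return frames


# -- plumbing utility (not part of the measured pipeline) -------------------


def naive_threshold(gray: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Naive grayscale band threshold, a convenience for roughing out a
    mask from a scan; real inputs are expected as pre-segmented masks."""
    g = np.asarray(gray, dtype=float)
    return (g >= lo) & (g <= hi)
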