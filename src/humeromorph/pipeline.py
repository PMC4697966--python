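"""Study orchestration: synth -> measure -> stats, as reproducible steps.

Each step can be driven from Python (in-memory objects) or from the CLI
(directories of mask rasters and CSV tables).  Every results file embeds
a hash of the configuration that produced it, and two runs with equal
config hash are bit-identical.

Comparison families
-------------------
Bonferroni correction is applied *within* each comparison family, not
across all families:

* within-group regional BV/TV: ``head_subcapital`` (h, sc1, sc2),
  ``head_metaphysis`` (h, m1, m2) and ``head_split`` (subchondral,
  inner), one family per group;
* between-group BV/TV: the same three groupings with each region tested
  once (h with the subcapital family);
* between-group plate thickness: one family over all articular angles;
* between-group cortical thickness: one family per side over its levels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .errors import HumeroMorphError, InsufficientDataError
from .geometry import build_thickness_sites, construct_landmarks, fit_long_axis, partition_regions
from .io import (
    read_annotation,
    read_donor_table,
    read_results,
    read_section,
    write_annotation,
    write_donor_table,
    write_results,
    write_section,
)
from .model import Annotation, DonorRecord, SectionImage
from .morphometry import MorphometryResult, measure_section
from .stats import ComparisonTable, compare_groups, compare_regions_within_group, tables_to_frame
from .synth import CohortDonor, CohortSpec, generate_cohort

__all__ = [
    "RunConfig",
    "measure_one",
    "run_synth",
    "run_measure",
    "run_study",
    "run_all",
    "study_from_frames",
    "WITHIN_FAMILIES",
    "BETWEEN_FAMILIES",
]

log = logging.getLogger("humeromorph")

WITHIN_FAMILIES: Dict[str, Tuple[str, ...]] = {
    "head_subcapital": ("h", "sc1", "sc2"),
    "head_metaphysis": ("h", "m1", "m2"),
    "head_split": ("subchondral", "inner"),
}

#: between-group families; each region appears exactly once
BETWEEN_FAMILIES: Dict[str, Tuple[str, ...]] = {
    "head_subcapital": ("h", "sc1", "sc2"),
    "metaphysis": ("m1", "m2"),
    "head_split": ("subchondral", "inner"),
}


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run."""

    calibration: float = 0.025  # mm / px
    medial_side: str = "left"
    angular_step: float = 10.0  # degrees between plate rays
    n_segments: int = 8  # head-height segments -> n_segments + 1 levels
    plate_min_run: float = 3.0  # px, minimum bone run accepted as plate
    m_length_factor: float = 2.0  # m1/m2 strip length in units of s1
    shaft_fraction: float = 0.30  # distal fraction used for the axis fit
    alpha: float = 0.05
    alpha_gate: float = 0.05  # Shapiro-Wilk gate level
    n_per_group: int = 6
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def measure_one(
    section: SectionImage,
    annotation: Annotation,
    config: Optional[RunConfig] = None,
) -> MorphometryResult:
    """Full measurement of a single section: axis fit, landmark
    construction, region partition, site construction, measurement."""
    cfg = config or RunConfig()
    axis = fit_long_axis(section, annotation, cfg.shaft_fraction)
    lm = construct_landmarks(section, annotation, axis, plate_min_run=cfg.plate_min_run)
    regions = partition_regions(
        section, lm, m_length_factor=cfg.m_length_factor, plate_min_run=cfg.plate_min_run
    )
    sites = build_thickness_sites(lm, cfg.angular_step, cfg.n_segments)
    return measure_section(section, regions, sites)


# ---------------------------------------------------------------------------
# file-based steps
# ---------------------------------------------------------------------------


def run_synth(config: RunConfig, out_dir, cohort_spec: Optional[CohortSpec] = None) -> List[CohortDonor]:
    """Generate a synthetic cohort and write it out as mask rasters,
    annotations and a donor table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort_spec or CohortSpec(n_per_group=config.n_per_group, seed=config.seed)
    if cohort_spec is None:
        spec.base_section = dataclasses.replace(
            spec.base_section,
            mm_per_pixel=config.calibration,
            medial_side=config.medial_side,
        )
    donors = generate_cohort(spec)
    truth_summary = {}
    for d in donors:
        ddir = out / d.record.donor_id
        ddir.mkdir(exist_ok=True)
        write_section(d.section, ddir / "bone.png", ddir / "cartilage.png")
        write_annotation(d.annotation, ddir / "annotation.json")
        truth_summary[d.record.donor_id] = {
            "achieved_bvtv": d.truth.achieved_bvtv,
            "targets": d.truth.targets,
        }
    write_donor_table([d.record for d in donors], out / "donors.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_summary, fh, indent=1)
    config.to_yaml(out / "config.yaml")
    return donors


def run_measure(config: RunConfig, sections_dir, out_dir) -> List[MorphometryResult]:
    """Measure every donor directory under ``sections_dir``.

    A donor directory holds ``bone.png``, ``cartilage.png`` and
    ``annotation.json``.  Per-donor failures are logged and skipped; the
    step fails only if no donor succeeds.
    """
    sections = Path(sections_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: List[MorphometryResult] = []
    lines = [f"{_now()} run_measure start config={config.hash()}"]
    for ddir in sorted(p for p in sections.iterdir() if p.is_dir()):
        t0 = time.perf_counter()
        try:
            section = read_section(
                ddir / "bone.png", ddir / "cartilage.png",
                calibration=config.calibration, medial_side=config.medial_side,
                donor_id=ddir.name,
            )
            annotation = read_annotation(ddir / "annotation.json")
            results.append(measure_one(section, annotation, config))
            lines.append(
                f"{_now()} {ddir.name} ok ({time.perf_counter() - t0:.2f}s)"
            )
        except (HumeroMorphError, OSError) as exc:
            lines.append(f"{_now()} {ddir.name} FAILED: {exc}")
            log.warning("donor %s failed: %s", ddir.name, exc)
    lines.append(f"{_now()} run_measure end: {len(results)} donors measured")
    (out / "run.log").write_text("\n".join(lines) + "\n")
    if not results:
        raise HumeroMorphError(f"no donor in {sections_dir} could be measured")
    write_results(results, out, header_comment=f"config_hash={config.hash()}")
    return results


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


# ---------------------------------------------------------------------------
# statistics over a measured cohort
# ---------------------------------------------------------------------------


def _group_of(donors: Sequence[DonorRecord]) -> Dict[str, str]:
    return {d.donor_id: d.group for d in donors}


def study_from_frames(
    donors: Sequence[DonorRecord],
    bvtv: pd.DataFrame,
    plate: Optional[pd.DataFrame] = None,
    cortical: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    alpha_gate: float = 0.05,
) -> pd.DataFrame:
    """Run the full comparison workflow over tidy result frames.

    Returns one tidy frame with columns scope, group, family,
    comparison, test_used, raw_p, adjusted_p, n_comparisons,
    significant.  Donors in the osteopenia band are excluded from
    between-group comparisons (logged).
    """
    groups = _group_of(donors)
    osteopenic = [d for d, g in groups.items() if g == "osteopenia"]
    if osteopenic:
        log.warning("excluding %d osteopenic donors from group comparisons: %s",
                    len(osteopenic), osteopenic)
    wide = bvtv.pivot_table(index="donor_id", columns="region", values="bvtv_pct")
    wide["group"] = wide.index.map(groups)

    rows: List[dict] = []

    def _add(scope: str, group: str, family: str, tables: Sequence[ComparisonTable]) -> None:
        frame = tables_to_frame(tables)
        frame.insert(0, "family", family)
        frame.insert(0, "group", group)
        frame.insert(0, "scope", scope)
        rows.append(frame)

    # within-group regional comparisons
    for group in ("normal", "osteoporotic"):
        sub = wide[wide["group"] == group]
        for family, regions in WITHIN_FAMILIES.items():
            cols = [r for r in regions if r in sub.columns]
            if len(cols) < 2 or len(sub) < 3:
                continue
            tables = compare_regions_within_group(sub[cols], alpha=alpha, alpha_gate=alpha_gate)
            _add("within", group, family, tables)

    # between-group BV/TV, one family per region grouping
    g1 = wide[wide["group"] == "normal"]
    g2 = wide[wide["group"] == "osteoporotic"]
    if len(g1) >= 3 and len(g2) >= 3:
        for family, regions in BETWEEN_FAMILIES.items():
            m = len([r for r in regions if r in wide.columns])
            tables = []
            for r in regions:
                if r not in wide.columns:
                    continue
                tables.append(
                    compare_groups(
                        g1[r], g2[r], alpha=alpha, alpha_gate=alpha_gate,
                        n_comparisons=m,
                        comparison=f"{r}: normal vs osteoporotic",
                    )
                )
            _add("between", "normal vs osteoporotic", f"bvtv_{family}", tables)

        # plate thickness per angle, one family
        if plate is not None and len(plate):
            p = plate.dropna(subset=["thickness_mm"]).copy()
            p["group"] = p["donor_id"].map(groups)
            angles = sorted(p["angle_deg"].unique())
            usable = []
            for a in angles:
                pa = p[p["angle_deg"] == a]
                va = pa[pa["group"] == "normal"]["thickness_mm"]
                vb = pa[pa["group"] == "osteoporotic"]["thickness_mm"]
                if len(va) >= 3 and len(vb) >= 3:
                    usable.append((a, va, vb))
            m = len(usable)
            tables = [
                compare_groups(
                    va, vb, alpha=alpha, alpha_gate=alpha_gate, n_comparisons=m,
                    comparison=f"plate @ {a:g} deg: normal vs osteoporotic",
                )
                for a, va, vb in usable
            ]
            if tables:
                _add("between", "normal vs osteoporotic", "plate_thickness", tables)

        # cortical thickness per level, one family per side
        if cortical is not None and len(cortical):
            c = cortical.copy()
            c["group"] = c["donor_id"].map(groups)
            for side in ("medial", "lateral"):
                cs = c[c["side"] == side]
                levels = sorted(cs["level"].unique())
                usable = []
                for lv in levels:
                    cl = cs[cs["level"] == lv]
                    va = cl[cl["group"] == "normal"]["thickness_mm"]
                    vb = cl[cl["group"] == "osteoporotic"]["thickness_mm"]
                    if len(va) >= 3 and len(vb) >= 3:
                        usable.append((lv, va, vb))
                m = len(usable)
                tables = [
                    compare_groups(
                        va, vb, alpha=alpha, alpha_gate=alpha_gate, n_comparisons=m,
                        comparison=f"cortex {side} level {lv}: normal vs osteoporotic",
                    )
                    for lv, va, vb in usable
                ]
                if tables:
                    _add("between", "normal vs osteoporotic", f"cortical_{side}", tables)

    if not rows:
        raise InsufficientDataError("no comparison family had enough donors")
    return pd.concat(rows, ignore_index=True)


def run_study(config: RunConfig, donors_csv, results_dir, out_dir) -> pd.DataFrame:
    """File-based wrapper: donor table + measurement CSVs -> comparison
    tables plus a plain-text summary of the test path per family."""
    donors = read_donor_table(donors_csv)
    frames = read_results(results_dir)
    table = study_from_frames(
        donors,
        frames["bvtv.csv"],
        frames["plate_thickness.csv"],
        frames["cortical_thickness.csv"],
        alpha=config.alpha,
        alpha_gate=config.alpha_gate,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "comparisons.csv", "w") as fh:
        fh.write(f"# config_hash={config.hash()}\n")
        table.to_csv(fh, index=False)
    lines = [f"study summary (config {config.hash()})"]
    for (scope, group, family), sub in table.groupby(["scope", "group", "family"]):
        paths = ", ".join(sorted(sub["test_used"].unique()))
        n_sig = int(sub["significant"].sum())
        lines.append(
            f"{scope:8s} {group:24s} {family:18s} path={paths} "
            f"significant={n_sig}/{len(sub)}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return table


def run_all(config: RunConfig, out_root) -> pd.DataFrame:
    """synth -> measure -> study under one output root."""
    root = Path(out_root)
    run_synth(config, root / "sections")
    run_measure(config, root / "sections", root / "measurements")
    return run_study(
        config, root / "sections" / "donors.csv", root / "measurements", root / "study"
    )
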