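"""Shared fixtures: a small, fast synthetic section (0.05 mm/px, 10 mm
head) used by most unit tests, plus its measured landmarks and regions."""

import numpy as np
import pytest

from humeromorph.geometry import (
    build_thickness_sites,
    construct_landmarks,
    fit_long_axis,
    partition_regions,
)
from humeromorph.synth import CohortSpec, SectionSpec, generate_section


def small_section_spec(seed: int = 1, medial_side: str = "left") -> SectionSpec:
    """A scaled-down section that keeps all structures but runs fast."""
    return SectionSpec(
        head_radius=10.0,
        shaft_width=9.0,
        shaft_offset=4.0,
        cartilage_thickness=0.8,
        plate_thickness_profile={0.0: 0.6, 90.0: 0.7, 180.0: 0.6},
        cortical_thickness_profile={
            "medial": [(0.0, 0.6), (1.0, 2.0)],
            "lateral": [(0.0, 0.7), (1.0, 1.8)],
        },
        mm_per_pixel=0.05,
        trabecular_width=(0.2, 0.04),
        tail_mm=10.0,
        medial_side=medial_side,
        seed=seed,
    )


def small_cohort_spec(seed: int = 5, n_per_group: int = 3) -> CohortSpec:
    return CohortSpec(n_per_group=n_per_group, base_section=small_section_spec(), seed=seed)


@pytest.fixture(scope="session")
def section_bundle():
    """(section, annotation, ground truth) for the standard small section."""
    return generate_section(small_section_spec(seed=1))


@pytest.fixture(scope="session")
def landmarks(section_bundle):
    section, annotation, _ = section_bundle
    axis = fit_long_axis(section, annotation)
    return construct_landmarks(section, annotation, axis)


@pytest.fixture(scope="session")
def regions(section_bundle, landmarks):
    section, _, _ = section_bundle
    return partition_regions(section, landmarks)


@pytest.fixture(scope="session")
def sites(landmarks):
    return build_thickness_sites(landmarks)
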