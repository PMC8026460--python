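"""Default calibration targets for the synthetic cohort generator.

Means and standard deviations of the 21 pelvimetric measures in a
reference adult cohort of 100 female and 100 male subjects (age ~60,
CT-based measurements; distances in mm, angles in degrees, ratio
dimensionless).  These are the default targets the template optimiser
and the cohort sampler aim at; users can substitute their own tables.
"""

from __future__ import annotations

import pandas as pd

from .measures import MEASURE_REGISTRY

__all__ = ["FEMALE_TARGETS", "MALE_TARGETS", "REFERENCE_N", "targets_for_sex", "targets_frame"]

REFERENCE_N = 100  # subjects per sex group in the reference cohort

# measure -> (mean, sd)
FEMALE_TARGETS: dict[str, tuple[float, float]] = {
    "obstetric_conjugate": (126.2, 8.6),
    "true_conjugate": (122.1, 8.8),
    "diagonal_conjugate": (131.8, 8.8),
    "transverse_diameter": (133.8, 7.7),
    "oblique_diameter": (130.0, 7.2),
    "straight_conjugate": (99.9, 10.6),
    "median_conjugate": (112.3, 9.9),
    "bis_ischiatic_diameter": (118.0, 10.1),
    "pubic_tubercle_height": (30.7, 3.7),
    "promontory_to_coccyx": (119.0, 12.3),
    "pelvic_depth": (102.8, 9.8),
    "promontory_to_s3s4": (77.2, 6.7),
    "s3s4_to_coccyx": (63.4, 7.7),
    "ischial_spines_distance": (116.7, 9.3),
    "pelvic_tilt": (64.7, 7.7),
    "offset_alpha": (32.1, 3.5),
    "inlet_beta": (47.1, 8.2),
    "angle_chi": (59.0, 7.1),
    "angle_delta": (72.7, 8.9),
    "angle_epsilon": (116.4, 11.8),
    "inlet_depth_ratio": (1.2, 0.1),
}

MALE_TARGETS: dict[str, tuple[float, float]] = {
    "obstetric_conjugate": (119.4, 9.9),
    "true_conjugate": (114.0, 10.0),
    "diagonal_conjugate": (127.9, 10.3),
    "transverse_diameter": (128.2, 8.0),
    "oblique_diameter": (125.7, 6.3),
    "straight_conjugate": (97.4, 8.4),
    "median_conjugate": (109.7, 8.4),
    "bis_ischiatic_diameter": (102.2, 10.4),
    "pubic_tubercle_height": (34.8, 4.0),
    "promontory_to_coccyx": (128.7, 11.8),
    "pelvic_depth": (111.5, 8.8),
    "promontory_to_s3s4": (80.6, 7.8),
    "s3s4_to_coccyx": (69.6, 8.6),
    "ischial_spines_distance": (100.5, 8.6),
    "pelvic_tilt": (61.0, 9.0),
    "offset_alpha": (27.5, 3.2),
    "inlet_beta": (52.9, 8.1),
    "angle_chi": (60.1, 5.9),
    "angle_delta": (67.6, 6.9),
    "angle_epsilon": (118.5, 10.0),
    "inlet_depth_ratio": (1.1, 0.1),
}

assert set(FEMALE_TARGETS) == set(MALE_TARGETS) == set(MEASURE_REGISTRY)


def targets_for_sex(sex: str) -> dict[str, tuple[float, float]]:
    sex = sex.lower()
    if sex in {"f", "female"}:
        return dict(FEMALE_TARGETS)
    if sex in {"m", "male"}:
        return dict(MALE_TARGETS)
    raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")


def targets_frame() -> pd.DataFrame:
    """Both target tables as a tidy frame (measure, sex, mean, sd)."""
    rows = []
    for sex, table in (("female", FEMALE_TARGETS), ("male", MALE_TARGETS)):
        for m in MEASURE_REGISTRY:
            mean, sd = table[m]
            rows.append({"measure": m, "sex": sex, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)
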