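"""The 21-measure pelvimetry suite.

Given a set of bony-pelvis fiducials (see :mod:`pelvimetry3d.landmarks`)
this module computes the standard pelvic-inlet, pelvic-outlet, depth and
angle measurements used to characterise pelvic shape for colorectal and
obstetric purposes.  Distances are in millimetres, angles in degrees, and
the inlet/depth ratio is dimensionless.

Conjugate naming convention
---------------------------
The three anteroposterior inlet conjugates are lines from the superior,
middle and inferior pubic symphysis to the sacral promontory, named here
*obstetric*, *true* and *diagonal* in that order.  Classical obstetric
usage attaches "obstetric" to the mid-symphysis line; this suite follows
the superior/middle/inferior ordering instead (the only ordering under
which the obstetric conjugate exceeds the true conjugate, as reference
cohort values require).  The binding is fixed here and documented rather
than configurable.

Two angle definitions, the offset angle α and the pelvic inlet angle β,
are reconstructions: α is taken as the angle at the promontory between the
true-conjugate line and the upper sacral line (promontory → S3/S4), and β
as the inclination of the obstetric-conjugate line to the transverse
plane.  Both can be overridden through :class:`MeasureConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet, validate_schema

__all__ = [
    "MEASURE_REGISTRY",
    "DISTANCE_MEASURES",
    "ANGLE_MEASURES",
    "RATIO_MEASURES",
    "MEASURE_UNITS",
    "MeasureConfig",
    "PelvimetryRecord",
    "point_distance",
    "three_point_angle",
    "line_axis_angle",
    "derived_points",
    "compute_pelvimetry",
    "records_to_frame",
]

#: All 21 measures, in fixed registry (reporting) order.
MEASURE_REGISTRY: tuple[str, ...] = (
    # pelvic inlet
    "obstetric_conjugate",
    "true_conjugate",
    "diagonal_conjugate",
    "transverse_diameter",
    "oblique_diameter",
    # pelvic outlet
    "straight_conjugate",
    "median_conjugate",
    "bis_ischiatic_diameter",
    # other measurements
    "pubic_tubercle_height",
    "promontory_to_coccyx",
    "pelvic_depth",
    "promontory_to_s3s4",
    "s3s4_to_coccyx",
    "ischial_spines_distance",
    # angles
    "pelvic_tilt",
    "offset_alpha",
    "inlet_beta",
    "angle_chi",
    "angle_delta",
    "angle_epsilon",
    # ratio
    "inlet_depth_ratio",
)

DISTANCE_MEASURES: tuple[str, ...] = MEASURE_REGISTRY[:14]
ANGLE_MEASURES: tuple[str, ...] = MEASURE_REGISTRY[14:20]
RATIO_MEASURES: tuple[str, ...] = ("inlet_depth_ratio",)

MEASURE_UNITS: dict[str, str] = {
    **{m: "mm" for m in DISTANCE_MEASURES},
    **{m: "deg" for m in ANGLE_MEASURES},
    "inlet_depth_ratio": "",
}


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def point_distance(a, b) -> float:
    """Euclidean distance between two points, in mm."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


def three_point_angle(a, vertex, b) -> float:
    """Interior angle (degrees, in [0, 180]) at ``vertex`` of triangle a-vertex-b."""
    a = np.asarray(a, float)
    vertex = np.asarray(vertex, float)
    b = np.asarray(b, float)
    u = a - vertex
    v = b - vertex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("angle undefined: point coincides with the vertex")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def line_axis_angle(p, q, axis) -> float:
    """Angle (degrees, [0, 90]) between line p→q and the plane orthogonal to ``axis``.

    Equivalently ``90° − angle(direction, axis)`` folded into [0, 90]:
    a line lying in the plane gives 0, a line along the axis gives 90.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    axis = np.asarray(axis, float)
    d = q - p
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise ValueError("angle undefined: zero-length line")
    na = np.linalg.norm(axis)
    if abs(na - 1.0) > 1e-6:
        raise ValueError("axis must be a unit vector")
    s = abs(float(np.dot(d, axis))) / nd
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONJUGATE_ENDPOINT = {"obstetric": "PS_SUP", "true": "PS_MID", "diagonal": "PS_INF"}


@dataclass(frozen=True)
class MeasureConfig:
    """Choices left open by the measurement definitions.

    Parameters
    ----------
    inlet_conjugate:
        Which conjugate defines the pelvic-inlet midpoint (hence the pelvic
        depth) and the numerator of the inlet/depth ratio.  Default
        ``"obstetric"``: with reference cohort means only the obstetric
        conjugate reproduces the printed inlet/depth ratios for both sexes.
    oblique_side:
        Side of the oblique diameter (sacroiliac joint to the contralateral
        iliopubic eminence): ``"left"``, ``"right"`` or ``"mean"``.
    vertical_axis:
        Unit vector of the gravity direction for a supine patient in the
        LPS frame; default the anterior–posterior axis (0, 1, 0).  Used
        only by the pelvic tilt and the inlet angle β.
    """

    inlet_conjugate: str = "obstetric"
    oblique_side: str = "left"
    vertical_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    transverse_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    alpha_definition: str = "true_conjugate_vs_upper_sacrum"
    beta_definition: str = "obstetric_conjugate_vs_transverse_plane"

    def __post_init__(self) -> None:
        if self.inlet_conjugate not in _CONJUGATE_ENDPOINT:
            raise ValueError(f"inlet_conjugate must be one of {sorted(_CONJUGATE_ENDPOINT)}")
        if self.oblique_side not in {"left", "right", "mean"}:
            raise ValueError("oblique_side must be 'left', 'right' or 'mean'")
        for name in ("vertical_axis", "transverse_axis"):
            v = np.asarray(getattr(self, name), float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")


DEFAULT_CONFIG = MeasureConfig()


# ---------------------------------------------------------------------------
# the record
# ---------------------------------------------------------------------------

@dataclass
class PelvimetryRecord:
    """The 21 scalar pelvimetric measures for one subject."""

    obstetric_conjugate: float
    true_conjugate: float
    diagonal_conjugate: float
    transverse_diameter: float
    oblique_diameter: float
    straight_conjugate: float
    median_conjugate: float
    bis_ischiatic_diameter: float
    pubic_tubercle_height: float
    promontory_to_coccyx: float
    pelvic_depth: float
    promontory_to_s3s4: float
    s3s4_to_coccyx: float
    ischial_spines_distance: float
    pelvic_tilt: float
    offset_alpha: float
    inlet_beta: float
    angle_chi: float
    angle_delta: float
    angle_epsilon: float
    inlet_depth_ratio: float
    subject_id: str = "unknown"

    def as_dict(self) -> dict[str, float]:
        """Measure name → value, in registry order (21 entries)."""
        return {m: float(getattr(self, m)) for m in MEASURE_REGISTRY}

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_dict(), name=self.subject_id)

    def __getitem__(self, measure: str) -> float:
        if measure not in MEASURE_REGISTRY:
            raise KeyError(measure)
        return float(getattr(self, measure))


assert tuple(f.name for f in dc_fields(PelvimetryRecord))[:21] == MEASURE_REGISTRY


def records_to_frame(records: Iterable[PelvimetryRecord]) -> pd.DataFrame:
    """Stack records into a DataFrame with the 21 registry columns in order."""
    rows = [r.as_dict() for r in records]
    df = pd.DataFrame(rows, columns=list(MEASURE_REGISTRY))
    df.index = [r.subject_id for r in records]
    return df


# ---------------------------------------------------------------------------
# derived points and the suite
# ---------------------------------------------------------------------------

def derived_points(lset: LandmarkSet, config: MeasureConfig = DEFAULT_CONFIG) -> dict[str, np.ndarray]:
    """Auxiliary points used by the suite.

    ``inlet_midpoint`` is the midpoint of the configured conjugate segment,
    ``femoral_centre`` the midpoint between the femoral head centres, and
    ``sacral_platform`` the platform-centre fiducial (defaulting to the
    sacral promontory when not placed).
    """
    ps = lset[_CONJUGATE_ENDPOINT[config.inlet_conjugate]]
    promontory = lset["SACRAL_PROMONTORY"]
    return {
        "inlet_midpoint": (ps + promontory) / 2.0,
        "femoral_centre": (lset["FEMORAL_HEAD_CENTER_L"] + lset["FEMORAL_HEAD_CENTER_R"]) / 2.0,
        "sacral_platform": lset["SACRAL_PLATFORM_CENTER"],
    }


def _oblique_diameter(lset: LandmarkSet, side: str) -> float:
    left = point_distance(lset["SACROILIAC_L"], lset["ILIOPUB_EMINENCE_R"])
    right = point_distance(lset["SACROILIAC_R"], lset["ILIOPUB_EMINENCE_L"])
    if side == "left":
        return left
    if side == "right":
        return right
    return 0.5 * (left + right)


def compute_pelvimetry(
    lset: LandmarkSet,
    config: MeasureConfig = DEFAULT_CONFIG,
    validate: bool = True,
) -> PelvimetryRecord:
    """Compute all 21 measures from a landmark set.

    Raises ``ValueError`` naming the offending measure if any constituent
    computation fails (e.g. coincident landmarks).
    """
    if validate:
        report = validate_schema(lset)
        if report.missing:
            raise ValueError(f"landmark set fails validation: {report}")

    aux = derived_points(lset, config)
    vertical = np.asarray(config.vertical_axis, float)
    transverse = np.asarray(config.transverse_axis, float)

    def measure(name: str, fn: Callable[[], float]) -> float:
        try:
            return fn()
        except Exception as exc:
            raise ValueError(f"failed to compute {name}: {exc}") from exc

    prom = lset["SACRAL_PROMONTORY"]
    coccyx = lset["COCCYX_TIP"]
    s3s4 = lset["S3S4_DISC"]

    values: dict[str, float] = {}
    values["obstetric_conjugate"] = measure(
        "obstetric_conjugate", lambda: point_distance(lset["PS_SUP"], prom))
    values["true_conjugate"] = measure(
        "true_conjugate", lambda: point_distance(lset["PS_MID"], prom))
    values["diagonal_conjugate"] = measure(
        "diagonal_conjugate", lambda: point_distance(lset["PS_INF"], prom))
    values["transverse_diameter"] = measure(
        "transverse_diameter", lambda: point_distance(lset["ILIOPECT_L"], lset["ILIOPECT_R"]))
    values["oblique_diameter"] = measure(
        "oblique_diameter", lambda: _oblique_diameter(lset, config.oblique_side))
    values["straight_conjugate"] = measure(
        "straight_conjugate", lambda: point_distance(lset["PS_INF"], coccyx))
    values["median_conjugate"] = measure(
        "median_conjugate", lambda: point_distance(lset["PS_INF"], lset["SACRUM_LOWER"]))
    values["bis_ischiatic_diameter"] = measure(
        "bis_ischiatic_diameter",
        lambda: point_distance(lset["ISCHIAL_TUBEROSITY_L"], lset["ISCHIAL_TUBEROSITY_R"]))
    values["pubic_tubercle_height"] = measure(
        "pubic_tubercle_height", lambda: point_distance(lset["PS_SUP"], lset["PS_INF"]))
    values["promontory_to_coccyx"] = measure(
        "promontory_to_coccyx", lambda: point_distance(prom, coccyx))
    values["pelvic_depth"] = measure(
        "pelvic_depth", lambda: point_distance(aux["inlet_midpoint"], coccyx))
    values["promontory_to_s3s4"] = measure(
        "promontory_to_s3s4", lambda: point_distance(prom, s3s4))
    values["s3s4_to_coccyx"] = measure(
        "s3s4_to_coccyx", lambda: point_distance(s3s4, coccyx))
    values["ischial_spines_distance"] = measure(
        "ischial_spines_distance",
        lambda: point_distance(lset["ISCHIAL_SPINE_L"], lset["ISCHIAL_SPINE_R"]))
    values["pelvic_tilt"] = measure(
        "pelvic_tilt",
        lambda: line_axis_angle(aux["sacral_platform"], aux["femoral_centre"], vertical))
    values["offset_alpha"] = measure(
        "offset_alpha", lambda: three_point_angle(lset["PS_MID"], prom, s3s4))
    values["inlet_beta"] = measure(
        "inlet_beta", lambda: line_axis_angle(lset["PS_SUP"], prom, transverse))
    values["angle_chi"] = measure(
        "angle_chi", lambda: three_point_angle(lset["PS_SUP"], prom, coccyx))
    values["angle_delta"] = measure(
        "angle_delta", lambda: three_point_angle(prom, coccyx, lset["PS_INF"]))
    values["angle_epsilon"] = measure(
        "angle_epsilon", lambda: three_point_angle(prom, s3s4, coccyx))
    values["inlet_depth_ratio"] = measure(
        "inlet_depth_ratio",
        lambda: values[f"{config.inlet_conjugate}_conjugate"] / values["pelvic_depth"])

    return PelvimetryRecord(subject_id=lset.subject_id, **values)
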