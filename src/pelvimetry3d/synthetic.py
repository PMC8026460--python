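"""Synthetic pelvis generation.

The measurement, segmentation and statistics stages all need inputs, but
pelvic CT scans with ground-truth landmarks are rarely shareable.  This
module builds them synthetically, in three layers:

1. **Template fitting** — starting from a hand-drawn, anatomically
   plausible landmark configuration, a least-squares optimiser moves the
   landmarks (midline points constrained to the mid-sagittal plane, left
   points mirrored from right) until the realized pelvimetric measures
   match a table of target means.  Only measure-level summaries are
   published for reference cohorts, never coordinates, so calibration by
   optimisation is the natural construction.
2. **Cohort sampling** — zero-mean Gaussian perturbations of the template
   landmarks, with per-landmark standard deviations calibrated (via the
   measure Jacobian plus a pilot Monte-Carlo run) so the realized measure
   SDs approximate the target SDs.
3. **Rasterisation** — a bone-like solid (a union of capsules sweeping
   the pelvic rings plus femoral-head spheres) is voxelised at high
   contrast against the background, emulating the property real CT
   exploits: bone is the brightest, most clearly bounded tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import calibration
from .landmarks import (
    ALL_LANDMARKS,
    MIDLINE_LANDMARKS,
    PAIRED_LANDMARKS,
    REQUIRED_LANDMARKS,
    LandmarkSet,
    validate_schema,
    write_landmarks,
)
from .measures import (
    ANGLE_MEASURES,
    DISTANCE_MEASURES,
    MEASURE_REGISTRY,
    DEFAULT_CONFIG,
    MeasureConfig,
    compute_pelvimetry,
)
from .volume import VoxelVolume

__all__ = [
    "PhantomParams",
    "TemplateFitReport",
    "TemplateFitError",
    "InfeasibleTargetsError",
    "TemplateModel",
    "build_template",
    "sample_landmark_cohort",
    "rasterize_phantom",
    "phantom_solid_volume",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# initial template (rough anatomy, female-like, LPS mm; x = Left)
# ---------------------------------------------------------------------------

_INITIAL_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "PS_SUP": (0.0, -48.0, -25.0),
    "PS_MID": (0.0, -50.0, -40.0),
    "PS_INF": (0.0, -52.0, -55.0),
    "SACRAL_PROMONTORY": (0.0, 55.0, 48.0),
    "S3S4_DISC": (0.0, 82.0, -8.0),
    "SACRUM_LOWER": (0.0, 74.0, -42.0),
    "COCCYX_TIP": (0.0, 55.0, -68.0),
    "ILIOPECT_R": (-67.0, 5.0, 12.0),
    "SACROILIAC_R": (-36.0, 52.0, 38.0),
    "ILIOPUB_EMINENCE_R": (-45.0, -28.0, -6.0),
    "ISCHIAL_SPINE_R": (-58.0, 18.0, -48.0),
    "ISCHIAL_TUBEROSITY_R": (-59.0, 22.0, -84.0),
    "FEMORAL_HEAD_CENTER_R": (-84.0, -4.0, -8.0),
}

_RIGHT_FREE = tuple(n for n in _INITIAL_TEMPLATE if n.endswith("_R"))


def _params_to_landmarks(x: np.ndarray, subject_id: str = "template") -> LandmarkSet:
    """Unpack the optimisation vector into a mirror-symmetric landmark set."""
    pts: dict[str, np.ndarray] = {}
    i = 0
    for name in MIDLINE_LANDMARKS:
        pts[name] = np.array([0.0, x[i], x[i + 1]])
        i += 2
    for name in _RIGHT_FREE:
        p = np.array([x[i], x[i + 1], x[i + 2]])
        pts[name] = p
        pts[name[:-2] + "_L"] = p * np.array([-1.0, 1.0, 1.0])
        i += 3
    return LandmarkSet(pts, subject_id=subject_id)


def _landmarks_to_params(lset: LandmarkSet) -> np.ndarray:
    x: list[float] = []
    for name in MIDLINE_LANDMARKS:
        x.extend(lset[name][1:])
    for name in _RIGHT_FREE:
        x.extend(lset[name])
    return np.array(x)


def _initial_params() -> np.ndarray:
    return _landmarks_to_params(LandmarkSet(dict(_INITIAL_TEMPLATE)))


# ---------------------------------------------------------------------------
# template fitting
# ---------------------------------------------------------------------------


class InfeasibleTargetsError(ValueError):
    """Raised when the target table is geometrically impossible."""


class TemplateFitError(RuntimeError):
    """Raised when the optimiser cannot meet the distance-residual guarantee.

    Carries the best-so-far :class:`TemplateFitReport` in ``.report``.
    """

    def __init__(self, message: str, report: "TemplateFitReport"):
        super().__init__(message)
        self.report = report


@dataclass
class TemplateFitReport:
    """Per-measure fit residuals for a calibrated template."""

    table: pd.DataFrame           # measure, target, realized, rel_residual, weight
    objective: float
    converged: bool
    n_iterations: int

    @property
    def max_distance_residual(self) -> float:
        d = self.table[self.table["measure"].isin(DISTANCE_MEASURES)]
        return float(d["rel_residual"].abs().max())

    def __str__(self) -> str:
        status = "converged" if self.converged else "NOT converged"
        return (
            f"TemplateFitReport: {status}, objective={self.objective:.3e}, "
            f"max |distance residual| = {100 * self.max_distance_residual:.3f}%"
        )


def _normalize_targets(targets) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, v in dict(targets).items():
        if name not in MEASURE_REGISTRY:
            raise ValueError(f"unknown measure {name!r} in targets")
        val = float(v[0]) if isinstance(v, (tuple, list)) else float(v)
        out[name] = val
    missing = [m for m in DISTANCE_MEASURES if m not in out]
    if missing:
        raise ValueError(f"targets must cover all distance measures; missing {missing}")
    bad = [m for m in out if m in DISTANCE_MEASURES and out[m] <= 0]
    if bad:
        raise ValueError(f"distance targets must be positive: {bad}")
    return out


def check_target_feasibility(targets: dict[str, float]) -> None:
    """Triangle-inequality screens over landmark chains shared by measures."""
    t = targets

    def tri(whole: str, a: str, b: str) -> None:
        if whole in t and a in t and b in t:
            if t[whole] > t[a] + t[b]:
                raise InfeasibleTargetsError(
                    f"infeasible targets: {whole} ({t[whole]:.1f}) exceeds "
                    f"{a} + {b} ({t[a] + t[b]:.1f})"
                )
            if t[whole] < abs(t[a] - t[b]):
                raise InfeasibleTargetsError(
                    f"infeasible targets: {whole} ({t[whole]:.1f}) is below "
                    f"|{a} - {b}| ({abs(t[a] - t[b]):.1f})"
                )

    # sacral chain: promontory -> S3/S4 -> coccyx
    tri("promontory_to_coccyx", "promontory_to_s3s4", "s3s4_to_coccyx")
    # pelvic depth is the median from the coccyx to the inlet conjugate:
    # it must lie within obstetric/2 of the promontory–coccyx distance
    if all(m in t for m in ("pelvic_depth", "promontory_to_coccyx", "obstetric_conjugate")):
        half = t["obstetric_conjugate"] / 2.0
        lo, hi = t["promontory_to_coccyx"] - half, t["promontory_to_coccyx"] + half
        if not (lo <= t["pelvic_depth"] <= hi):
            raise InfeasibleTargetsError(
                "infeasible targets: pelvic_depth "
                f"({t['pelvic_depth']:.1f}) outside [{lo:.1f}, {hi:.1f}] permitted by "
                "promontory_to_coccyx and obstetric_conjugate"
            )
    # symphysis height is bounded by the conjugate triangle at the promontory
    if all(m in t for m in ("pubic_tubercle_height", "obstetric_conjugate", "diagonal_conjugate")):
        if t["pubic_tubercle_height"] < abs(t["obstetric_conjugate"] - t["diagonal_conjugate"]):
            raise InfeasibleTargetsError(
                "infeasible targets: pubic_tubercle_height "
                f"({t['pubic_tubercle_height']:.1f}) below "
                "|obstetric_conjugate - diagonal_conjugate| "
                f"({abs(t['obstetric_conjugate'] - t['diagonal_conjugate']):.1f})"
            )


_REG_WEIGHT = 1e-4       # soft pull toward the initial anatomy (relative, per parameter)
_PARAM_SCALE = 100.0     # mm; typical landmark coordinate magnitude
_DISTANCE_GUARANTEE = 0.05


def build_template(
    targets,
    seed: int = 0,
    config: MeasureConfig = DEFAULT_CONFIG,
    angle_weight: float = 0.25,
    max_nfev: int = 2000,
    n_restarts: int = 3,
) -> tuple[LandmarkSet, TemplateFitReport]:
    """Fit a mirror-symmetric landmark template to a measure-target table.

    Minimises the weighted sum of squared *relative* errors between the
    realized measures and their targets (distances weight 1, angles and the
    ratio weight ``angle_weight``), with a very weak regulariser toward the
    initial anatomy that keeps the under-determined problem well posed.

    Returns the fitted landmark set and a report listing every residual.
    Distance residuals above 5% raise :class:`TemplateFitError` carrying
    the best report; geometrically impossible targets raise
    :class:`InfeasibleTargetsError` naming the conflicting measures.
    """
    tgt = _normalize_targets(targets)
    check_target_feasibility(tgt)

    names = [m for m in MEASURE_REGISTRY if m in tgt]
    weights = np.array([1.0 if m in DISTANCE_MEASURES else angle_weight for m in names])
    tvals = np.array([tgt[m] for m in names])
    x0 = _initial_params()
    rng = np.random.default_rng(seed)

    def fit_residuals(x: np.ndarray) -> np.ndarray:
        lset = _params_to_landmarks(x)
        rec = compute_pelvimetry(lset, config, validate=False)
        realized = np.array([rec[m] for m in names])
        return (realized - tvals) / tvals * np.sqrt(weights)

    def residuals(x: np.ndarray) -> np.ndarray:
        reg = np.sqrt(_REG_WEIGHT) * (x - x0) / _PARAM_SCALE
        return np.concatenate([fit_residuals(x), reg])

    best = None
    start = x0.copy()
    for attempt in range(n_restarts + 1):
        sol = optimize.least_squares(
            residuals, start, method="trf", max_nfev=max_nfev,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        lset = _params_to_landmarks(best.x)
        rec = compute_pelvimetry(lset, config, validate=False)
        max_res = max(abs(rec[m] - tgt[m]) / tgt[m] for m in names if m in DISTANCE_MEASURES)
        if max_res <= _DISTANCE_GUARANTEE:
            break
        # jittered restart from the initial anatomy
        start = x0 + rng.normal(0.0, 5.0, size=x0.shape)

    # polish: drop the regulariser so exactly-attainable targets are met to
    # numerical precision (the fixed-point property of the calibration)
    polish = optimize.least_squares(
        fit_residuals, best.x, method="trf", max_nfev=max_nfev,
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if polish.cost <= 0.5 * float(np.sum(fit_residuals(best.x) ** 2)) or polish.cost < 1e-14:
        best = polish

    lset = _params_to_landmarks(best.x)
    rec = compute_pelvimetry(lset, config, validate=False)
    rows = []
    for m, t, w in zip(names, tvals, weights):
        r = rec[m]
        rows.append({
            "measure": m, "target": t, "realized": r,
            "rel_residual": (r - t) / t, "weight": w,
        })
    report = TemplateFitReport(
        table=pd.DataFrame(rows),
        objective=float(best.cost),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
    )
    if report.max_distance_residual > _DISTANCE_GUARANTEE:
        worst = report.table.loc[report.table["rel_residual"].abs().idxmax(), "measure"]
        raise TemplateFitError(
            f"template fit did not reach the 5% distance guarantee "
            f"(worst: {worst}, {100 * report.max_distance_residual:.2f}%)",
            report,
        )
    vreport = validate_schema(lset)
    if not vreport.passed:
        raise TemplateFitError(f"fitted template fails schema validation: {vreport}", report)
    return lset, report


class TemplateModel:
    """Model-style wrapper: ``TemplateModel(targets).fit()`` → fitted template.

    ``fit`` returns the :class:`TemplateFitReport`; the fitted landmark set
    is available as ``report_.landmarks`` / ``model.landmarks_``.
    """

    def __init__(self, targets, config: MeasureConfig = DEFAULT_CONFIG):
        self.targets = _normalize_targets(targets)
        self.config = config
        self.landmarks_: LandmarkSet | None = None
        self.report_: TemplateFitReport | None = None

    @classmethod
    def for_sex(cls, sex: str, config: MeasureConfig = DEFAULT_CONFIG) -> "TemplateModel":
        return cls(calibration.targets_for_sex(sex), config=config)

    def fit(self, seed: int = 0, **kwargs) -> TemplateFitReport:
        self.landmarks_, self.report_ = build_template(
            self.targets, seed=seed, config=self.config, **kwargs
        )
        return self.report_


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


@dataclass
class PhantomParams:
    """Conditions for one synthetic sex group."""

    sex_label: str
    measure_targets: dict[str, tuple[float, float]] = field(default_factory=dict)
    landmark_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex_label.lower() not in {"female", "male", "f", "m"}:
            raise ValueError(f"sex_label must be female or male, got {self.sex_label!r}")
        if not self.measure_targets:
            self.measure_targets = calibration.targets_for_sex(self.sex_label)
        for name, (mean, sd) in self.measure_targets.items():
            if name not in MEASURE_REGISTRY:
                raise ValueError(f"unknown measure {name!r}")
            if sd < 0:
                raise ValueError(f"target_sd must be >= 0 for {name}")
            if name in DISTANCE_MEASURES and mean <= 0:
                raise ValueError(f"target_mean must be > 0 for distance measure {name}")
        if self.landmark_noise_scale < 0:
            raise ValueError("landmark_noise_scale must be >= 0")


def _measure_jacobian(template: LandmarkSet, config: MeasureConfig, eps: float = 1e-4):
    """Numeric d(measure)/d(coordinate) for every stored landmark coordinate."""
    names = list(template.names())
    base = compute_pelvimetry(template, config, validate=False)
    base_vals = np.array([base[m] for m in MEASURE_REGISTRY])
    jac = np.zeros((len(MEASURE_REGISTRY), len(names), 3))
    for li, lname in enumerate(names):
        for axis in range(3):
            delta = np.zeros(3)
            delta[axis] = eps
            pert = template.replace(**{lname: template[lname] + delta})
            rec = compute_pelvimetry(pert, config, validate=False)
            vals = np.array([rec[m] for m in MEASURE_REGISTRY])
            jac[:, li, axis] = (vals - base_vals) / eps
    return names, jac


def _calibrate_sigmas(
    template: LandmarkSet,
    targets: dict[str, tuple[float, float]],
    config: MeasureConfig,
    seed: int,
    n_pilot: int = 300,
) -> dict[str, float]:
    """Per-landmark isotropic noise SDs matched to the target measure SDs.

    First-order: with independent isotropic displacement of variance v_l on
    landmark l, Var(measure m) ≈ Σ_l v_l · Σ_axis J[m,l,axis]².  Solved for
    v ≥ 0 by non-negative least squares on SD-normalised rows, then refined
    by a single global factor from a pilot Monte-Carlo run.
    """
    names, jac = _measure_jacobian(template, config)
    # only distance SDs constrain the allocation: the target table is
    # structurally over-constrained and the distance SDs carry the guarantee;
    # angle and ratio spreads are emergent properties of the landmark noise
    midx = [
        i for i, m in enumerate(MEASURE_REGISTRY)
        if m in targets and targets[m][1] > 0 and m in DISTANCE_MEASURES
    ]
    if not midx:
        return {n: 0.0 for n in names}
    sens = (jac ** 2).sum(axis=2)          # (n_measures, n_landmarks)
    s = np.array([targets[MEASURE_REGISTRY[i]][1] for i in midx])
    sub = sens[midx]
    a = sub / (s ** 2)[:, None]
    v0, _ = optimize.nnls(a, np.ones(len(midx)))

    def sd_residuals(v: np.ndarray) -> np.ndarray:
        # relative error in SD space, first-order variance model
        pred = np.sqrt(np.maximum(sub @ v, 1e-12))
        return (pred - s) / s

    sol = optimize.least_squares(
        sd_residuals, np.maximum(v0, 1e-6), bounds=(0.0, np.inf), max_nfev=500,
    )
    sigmas = np.sqrt(sol.x)

    # pilot run: one global factor absorbs the (small) nonlinear correction
    rng = np.random.default_rng(seed)
    coords = template.coordinates(names)
    realized = []
    for _ in range(n_pilot):
        noise = rng.normal(0.0, sigmas[:, None], size=coords.shape)
        lset = LandmarkSet(dict(zip(names, coords + noise)))
        rec = compute_pelvimetry(lset, config, validate=False)
        realized.append([rec[m] for m in MEASURE_REGISTRY])
    realized_sd = np.std(np.array(realized), axis=0, ddof=1)[midx]
    ratios = s / np.maximum(realized_sd, 1e-9)
    factor = float(np.median(ratios))
    return dict(zip(names, sigmas * factor))


@dataclass
class _CalibratedGenerator:
    template: LandmarkSet
    sigmas: dict[str, float]
    report: TemplateFitReport


def _calibrate_generator(params: PhantomParams, config: MeasureConfig) -> _CalibratedGenerator:
    targets = params.measure_targets
    means = {m: v[0] for m, v in targets.items()}
    cal_seed = params.seed % (2**31)
    template, report = build_template(means, seed=cal_seed, config=config)
    sigmas = _calibrate_sigmas(template, targets, config, seed=cal_seed + 1)

    # one Newton step on the means: sampling distances under noise biases
    # them upward (convexity), so refit the template to bias-corrected
    # targets estimated from a pilot run
    rng = np.random.default_rng(cal_seed + 2)
    names = list(template.names())
    coords = template.coordinates(names)
    sig = np.array([sigmas[n] for n in names]) * params.landmark_noise_scale
    if np.any(sig > 0):
        pilot = []
        for _ in range(800):
            noise = rng.normal(0.0, sig[:, None], size=coords.shape)
            rec = compute_pelvimetry(
                LandmarkSet(dict(zip(names, coords + noise))), config, validate=False
            )
            pilot.append([rec[m] for m in MEASURE_REGISTRY])
        pilot_mean = dict(zip(MEASURE_REGISTRY, np.mean(pilot, axis=0)))
        adjusted = {
            m: max(2.0 * means[m] - pilot_mean[m], 0.25 * means[m])
            for m in means
            if m in DISTANCE_MEASURES
        }
        adjusted.update({m: means[m] for m in means if m not in DISTANCE_MEASURES})
        try:
            template, report = build_template(adjusted, seed=cal_seed, config=config)
        except (TemplateFitError, InfeasibleTargetsError):
            pass  # keep the uncorrected template; bias is second-order anyway
    return _CalibratedGenerator(template=template, sigmas=sigmas, report=report)


_MAX_RESAMPLE = 10


def sample_landmark_cohort(
    params: PhantomParams,
    n: int,
    config: MeasureConfig = DEFAULT_CONFIG,
    generator: _CalibratedGenerator | None = None,
) -> list[tuple[LandmarkSet, str]]:
    """Draw ``n`` landmark sets for one sex group.

    Reproducible given ``params.seed``; ``landmark_noise_scale = 0`` yields
    identical copies of the calibrated template.  Degenerate draws (any two
    landmarks closer than 1 mm) are resampled up to a bounded retry count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = generator or _calibrate_generator(params, config)
    names = list(gen.template.names())
    coords = gen.template.coordinates(names)
    sig = np.array([gen.sigmas[nm] for nm in names]) * params.landmark_noise_scale
    rng = np.random.default_rng((params.seed + 1000) % (2**31))

    cohort: list[tuple[LandmarkSet, str]] = []
    for i in range(n):
        for attempt in range(_MAX_RESAMPLE):
            noise = rng.normal(0.0, sig[:, None], size=coords.shape) if np.any(sig > 0) else 0.0
            pts = coords + noise
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() >= 1.0:
                break
        else:
            raise RuntimeError(
                f"could not draw a non-degenerate landmark set after {_MAX_RESAMPLE} tries"
            )
        lset = LandmarkSet(
            dict(zip(names, pts)), subject_id=f"{params.sex_label}_{i:04d}"
        )
        report = validate_schema(lset)
        if not report.passed:
            raise RuntimeError(f"sampled landmark set fails validation: {report}")
        cohort.append((lset, params.sex_label))
    return cohort


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

#: Capsule sweep graph: pelvic inlet ring, symphysis, sacrum chain, side chains.
_CAPSULE_EDGES: tuple[tuple[str, str], ...] = (
    ("PS_SUP", "ILIOPECT_L"), ("ILIOPECT_L", "SACROILIAC_L"),
    ("SACROILIAC_L", "SACRAL_PROMONTORY"), ("SACRAL_PROMONTORY", "SACROILIAC_R"),
    ("SACROILIAC_R", "ILIOPECT_R"), ("ILIOPECT_R", "PS_SUP"),
    ("PS_SUP", "PS_MID"), ("PS_MID", "PS_INF"),
    ("SACRAL_PROMONTORY", "S3S4_DISC"), ("S3S4_DISC", "SACRUM_LOWER"),
    ("SACRUM_LOWER", "COCCYX_TIP"),
    ("ILIOPECT_L", "ILIOPUB_EMINENCE_L"), ("ILIOPUB_EMINENCE_L", "PS_SUP"),
    ("ILIOPECT_R", "ILIOPUB_EMINENCE_R"), ("ILIOPUB_EMINENCE_R", "PS_SUP"),
    ("SACROILIAC_L", "ISCHIAL_SPINE_L"), ("ISCHIAL_SPINE_L", "ISCHIAL_TUBEROSITY_L"),
    ("ISCHIAL_TUBEROSITY_L", "PS_INF"),
    ("SACROILIAC_R", "ISCHIAL_SPINE_R"), ("ISCHIAL_SPINE_R", "ISCHIAL_TUBEROSITY_R"),
    ("ISCHIAL_TUBEROSITY_R", "PS_INF"),
)

_SPHERE_LANDMARKS: tuple[str, ...] = ("FEMORAL_HEAD_CENTER_L", "FEMORAL_HEAD_CENTER_R")

DEFAULT_CAPSULE_RADIUS = 9.0   # mm; bone half-thickness of the solid model
DEFAULT_SPHERE_RADIUS = 22.0   # mm; femoral head


def _solid_mask(points: np.ndarray, lset: LandmarkSet,
                capsule_radius: float, sphere_radius: float) -> np.ndarray:
    """Boolean in/out of the capsule-union solid for an (n, 3) point array."""
    inside = np.zeros(len(points), dtype=bool)
    for a_name, b_name in _CAPSULE_EDGES:
        a = lset[a_name]
        b = lset[b_name]
        ab = b - a
        denom = float(np.dot(ab, ab))
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, points.shape)
        inside |= np.linalg.norm(points - closest, axis=1) <= capsule_radius
    for name in _SPHERE_LANDMARKS:
        inside |= np.linalg.norm(points - lset[name], axis=1) <= sphere_radius
    return inside


def rasterize_phantom(
    landmarks: LandmarkSet,
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    bone_intensity: float = 1000.0,
    background_intensity: float = 0.0,
    noise_sd: float = 20.0,
    seed: int = 0,
    capsule_radius: float = DEFAULT_CAPSULE_RADIUS,
    sphere_radius: float = DEFAULT_SPHERE_RADIUS,
    margin_voxels: int = 12,
) -> VoxelVolume:
    """Voxelise the bone-like solid swept through the landmark rings.

    The grid covers all landmarks with at least a 10-voxel margin; bone
    voxels take ``bone_intensity`` and everything else
    ``background_intensity``, each plus optional Gaussian noise.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing components must be positive")
    if bone_intensity <= background_intensity:
        raise ValueError("bone_intensity must exceed background_intensity")
    if capsule_radius < 2.0 * max(spacing):
        raise ValueError(
            f"spacing {max(spacing):.1f} mm too coarse for a {capsule_radius:.1f} mm "
            "bone shell (< 2 voxels thickness); use finer spacing"
        )
    if margin_voxels < 10:
        raise ValueError("margin_voxels must be >= 10")

    sx, sy, sz = (float(s) for s in spacing)
    coords = landmarks.coordinates()
    pad = np.array([margin_voxels * sx, margin_voxels * sy, margin_voxels * sz])
    pad = np.maximum(pad, sphere_radius + 2.0 * np.array([sx, sy, sz]))
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    nx = int(np.ceil((hi[0] - lo[0]) / sx)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / sy)) + 1
    nz = int(np.ceil((hi[2] - lo[2]) / sz)) + 1

    xs = lo[0] + sx * np.arange(nx)
    ys = lo[1] + sy * np.arange(ny)
    zs = lo[2] + sz * np.arange(nz)

    rng = np.random.default_rng(seed % (2**31))
    vol = np.empty((nz, ny, nx), dtype=np.float32)
    # slab-wise to bound memory
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    flat_yx = np.stack([gx.ravel(), gy.ravel()], axis=1)
    for k, z in enumerate(zs):
        pts = np.column_stack([flat_yx, np.full(len(flat_yx), z)])
        inside = _solid_mask(pts, landmarks, capsule_radius, sphere_radius)
        slab = np.where(inside, bone_intensity, background_intensity)
        vol[k] = slab.reshape(ny, nx)
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=vol.shape).astype(np.float32)
    return VoxelVolume(
        intensities=vol,
        spacing=(sx, sy, sz),
        origin=(float(lo[0]), float(lo[1]), float(lo[2])),
    )


def phantom_solid_volume(
    landmarks: LandmarkSet,
    capsule_radius: float = DEFAULT_CAPSULE_RADIUS,
    sphere_radius: float = DEFAULT_SPHERE_RADIUS,
    n_samples: int = 2**21,
    seed: int = 0,
) -> float:
    """Volume (mm³) of the generating solid by quasi-Monte-Carlo quadrature.

    Integrates the exact analytic in/out indicator of the capsule union with
    a scrambled Sobol' sequence over the bounding box; independent of any
    voxel rasterisation.
    """
    from scipy.stats import qmc

    coords = landmarks.coordinates()
    pad = max(capsule_radius, sphere_radius) + 1.0
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    sampler = qmc.Sobol(d=3, scramble=True, rng=np.random.default_rng(seed % (2**31)))
    pts = qmc.scale(sampler.random(n_samples), lo, hi)
    inside = _solid_mask(pts, landmarks, capsule_radius, sphere_radius)
    box = float(np.prod(hi - lo))
    return box * float(inside.mean())


# ---------------------------------------------------------------------------
# cohort output
# ---------------------------------------------------------------------------


def write_cohort(
    cohort: list[tuple[LandmarkSet, str]],
    outdir: str | Path,
    dialect: str = "plain_csv",
    params: PhantomParams | None = None,
) -> Path:
    """Write one landmark file per subject plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "fcsv" if dialect == "slicer_fcsv" else "csv"
    entries = []
    for lset, sex in cohort:
        fname = f"{lset.subject_id}.{ext}"
        write_landmarks(lset, outdir / fname, dialect=dialect)
        entries.append({"file": fname, "subject_id": lset.subject_id, "sex": sex})
    manifest = {
        "dialect": dialect,
        "n": len(cohort),
        "subjects": entries,
    }
    if params is not None:
        manifest["params"] = {
            "sex_label": params.sex_label,
            "landmark_noise_scale": params.landmark_noise_scale,
            "seed": params.seed,
            "measure_targets": {m: list(v) for m, v in params.measure_targets.items()},
        }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
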