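"""Fiducial landmark schema and file I/O.

A :class:`LandmarkSet` holds named anatomical fiducials for one subject in
patient LPS millimetre coordinates (x = Left, y = Posterior, z = Superior;
right-handed).  Two on-disk dialects are supported:

* ``slicer_fcsv`` — 3D Slicer markups fiducial CSV.  Slicer stores point
  coordinates in RAS by default; they are converted to the internal LPS
  frame by negating x and y.
* ``plain_csv`` — a minimal ``name,x,y,z,frame`` table.

The schema names 20 landmarks.  19 are required; ``SACRAL_PLATFORM_CENTER``
is optional because the centre of the S1 endplate is, to measurement
precision, interchangeable with the sacral promontory marker and defaults
to it when absent.  With that identification the required marker count
drops to the 18 fiducials a reader would place manually.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "REQUIRED_LANDMARKS",
    "OPTIONAL_LANDMARKS",
    "ALL_LANDMARKS",
    "PAIRED_LANDMARKS",
    "MIDLINE_LANDMARKS",
    "LandmarkSet",
    "ValidationReport",
    "validate_schema",
    "read_landmarks",
    "write_landmarks",
]

#: Landmarks that must be present exactly once.
REQUIRED_LANDMARKS: tuple[str, ...] = (
    "PS_SUP",                 # superior border of the pubic symphysis
    "PS_MID",                 # mid-point of the pubic symphysis
    "PS_INF",                 # inferior border of the pubic symphysis
    "SACRAL_PROMONTORY",      # anterior-superior edge of S1
    "S3S4_DISC",              # S3/S4 intervertebral disc
    "SACRUM_LOWER",           # lower border of the sacrum
    "COCCYX_TIP",             # tip of the coccyx
    "ILIOPECT_L", "ILIOPECT_R",            # widest points on the iliopectineal lines
    "SACROILIAC_L", "SACROILIAC_R",        # sacroiliac joints
    "ILIOPUB_EMINENCE_L", "ILIOPUB_EMINENCE_R",  # iliopubic (iliopectineal) eminences
    "ISCHIAL_SPINE_L", "ISCHIAL_SPINE_R",
    "ISCHIAL_TUBEROSITY_L", "ISCHIAL_TUBEROSITY_R",
    "FEMORAL_HEAD_CENTER_L", "FEMORAL_HEAD_CENTER_R",
)

#: Landmarks that may be absent; each has a documented default.
OPTIONAL_LANDMARKS: tuple[str, ...] = ("SACRAL_PLATFORM_CENTER",)

ALL_LANDMARKS: tuple[str, ...] = REQUIRED_LANDMARKS + OPTIONAL_LANDMARKS

#: Left/right pairs, used by symmetry checks and the side-swap heuristic.
PAIRED_LANDMARKS: tuple[tuple[str, str], ...] = (
    ("ILIOPECT_L", "ILIOPECT_R"),
    ("SACROILIAC_L", "SACROILIAC_R"),
    ("ILIOPUB_EMINENCE_L", "ILIOPUB_EMINENCE_R"),
    ("ISCHIAL_SPINE_L", "ISCHIAL_SPINE_R"),
    ("ISCHIAL_TUBEROSITY_L", "ISCHIAL_TUBEROSITY_R"),
    ("FEMORAL_HEAD_CENTER_L", "FEMORAL_HEAD_CENTER_R"),
)

#: Landmarks that lie on the mid-sagittal plane in a symmetric template.
MIDLINE_LANDMARKS: tuple[str, ...] = (
    "PS_SUP", "PS_MID", "PS_INF", "SACRAL_PROMONTORY",
    "S3S4_DISC", "SACRUM_LOWER", "COCCYX_TIP",
)

#: Common alternative spellings mapped onto schema names.
DEFAULT_ALIASES: dict[str, str] = {
    "PUBIC_SYMPHYSIS_SUP": "PS_SUP",
    "PUBIC_SYMPHYSIS_MID": "PS_MID",
    "PUBIC_SYMPHYSIS_INF": "PS_INF",
    "PROMONTORY": "SACRAL_PROMONTORY",
    "SACRAL_PLATFORM": "SACRAL_PLATFORM_CENTER",
    "COCCYX": "COCCYX_TIP",
}


class LandmarkError(ValueError):
    """Raised for malformed landmark files or invalid landmark sets."""


@dataclass
class LandmarkSet:
    """Named fiducials for one subject, in patient LPS millimetres."""

    points: dict[str, np.ndarray]
    subject_id: str = "unknown"
    frame: str = "LPS"

    def __post_init__(self) -> None:
        self.points = {
            name: np.asarray(p, dtype=float).reshape(3)
            for name, p in self.points.items()
        }

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "SACRAL_PLATFORM_CENTER" and name not in self.points:
            # documented default: the platform centre doubles as the promontory
            return self.points["SACRAL_PROMONTORY"]
        try:
            return self.points[name]
        except KeyError:
            raise LandmarkError(f"missing required landmark {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def coordinates(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Stack coordinates into an (n, 3) array, in the given name order."""
        names = tuple(names) if names is not None else self.names()
        return np.stack([self[n] for n in names])

    def replace(self, **updates: np.ndarray) -> "LandmarkSet":
        pts = dict(self.points)
        pts.update({k: np.asarray(v, float) for k, v in updates.items()})
        return LandmarkSet(pts, subject_id=self.subject_id, frame=self.frame)

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn(point) -> point`` to every landmark."""
        return LandmarkSet(
            {k: np.asarray(fn(v), float) for k, v in self.points.items()},
            subject_id=self.subject_id,
            frame=self.frame,
        )


@dataclass
class ValidationReport:
    missing: list[str] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (self.missing or self.duplicates or self.flags)

    def __str__(self) -> str:
        if self.passed and not self.warnings:
            return "ValidationReport: pass"
        parts = []
        if self.missing:
            parts.append(f"missing={self.missing}")
        if self.duplicates:
            parts.append(f"duplicates={self.duplicates}")
        if self.flags:
            parts.append(f"flags={self.flags}")
        if self.warnings:
            parts.append(f"warnings={self.warnings}")
        status = "pass" if self.passed else "FAIL"
        return f"ValidationReport: {status} ({'; '.join(parts)})"


def validate_schema(
    lset: LandmarkSet, duplicates: Iterable[str] = ()
) -> ValidationReport:
    """Check a landmark set against the schema.

    Absence of ``SACRAL_PLATFORM_CENTER`` is a warning (it is derivable);
    absence of any required landmark is a failure.  Paired left/right
    landmarks closer than 1 mm, non-finite coordinates, and sides that
    appear swapped relative to the LPS frame are flagged.
    """
    report = ValidationReport(duplicates=sorted(duplicates))
    for name in REQUIRED_LANDMARKS:
        if name not in lset.points:
            report.missing.append(name)
    for name in OPTIONAL_LANDMARKS:
        if name not in lset.points:
            report.warnings.append(f"{name} absent; defaulting to SACRAL_PROMONTORY")
    for name, p in lset.points.items():
        if not np.all(np.isfinite(p)):
            report.flags.append(f"non-finite coordinates for {name}")

    swapped = 0
    comparable = 0
    for left, right in PAIRED_LANDMARKS:
        if left in lset.points and right in lset.points:
            d = float(np.linalg.norm(lset[left] - lset[right]))
            if d < 1.0:
                report.flags.append(
                    f"paired landmarks {left}/{right} are {d:.3f} mm apart (< 1 mm)"
                )
            comparable += 1
            # LPS: +x is the patient's left
            if lset[left][0] < lset[right][0]:
                swapped += 1
    if comparable and swapped > comparable / 2:
        report.flags.append(
            f"left/right sides appear swapped for {swapped}/{comparable} pairs"
        )
    return report


def _resolve_name(raw: str, aliases: Mapping[str, str] | None) -> str:
    name = raw.strip().upper()
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({k.upper(): v for k, v in aliases.items()})
    name = table.get(name, name)
    if name not in ALL_LANDMARKS:
        raise LandmarkError(
            f"unknown landmark name {raw!r} with no alias; "
            f"known names: {', '.join(ALL_LANDMARKS)}"
        )
    return name


def read_landmarks(
    path: str | Path,
    dialect: str = "plain_csv",
    aliases: Mapping[str, str] | None = None,
    subject_id: str | None = None,
) -> LandmarkSet:
    """Read a landmark file into the internal LPS frame.

    ``slicer_fcsv`` files carry coordinates in the RAS convention unless
    their header says otherwise; RAS input is converted by negating the
    first two coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plain_csv":
        points, dupes = _read_plain_csv(path, aliases)
    elif dialect == "slicer_fcsv":
        points, dupes = _read_fcsv(path, aliases)
    else:
        raise ValueError(f"unknown landmark dialect {dialect!r}")
    if dupes:
        raise LandmarkError(f"duplicate landmark names in {path.name}: {sorted(dupes)}")
    return LandmarkSet(points, subject_id=subject_id or path.stem)


def _read_plain_csv(path: Path, aliases) -> tuple[dict, set]:
    points: dict[str, np.ndarray] = {}
    dupes: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:4]] != ["name", "x", "y", "z"]:
            raise LandmarkError(f"{path.name}: expected header 'name,x,y,z[,frame]'")
        frame = "LPS"
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 4:
                raise LandmarkError(f"{path.name}:{lineno}: malformed row {row!r}")
            name = _resolve_name(row[0], aliases)
            try:
                xyz = np.array([float(row[1]), float(row[2]), float(row[3])])
            except ValueError as exc:
                raise LandmarkError(f"{path.name}:{lineno}: {exc}") from None
            if len(row) >= 5 and row[4].strip():
                frame = row[4].strip().upper()
            if frame == "RAS":
                xyz = np.array([-xyz[0], -xyz[1], xyz[2]])
            elif frame != "LPS":
                raise LandmarkError(f"{path.name}:{lineno}: unsupported frame {frame!r}")
            if name in points:
                dupes.add(name)
            points[name] = xyz
    return points, dupes


def _read_fcsv(path: Path, aliases) -> tuple[dict, set]:
    points: dict[str, np.ndarray] = {}
    dupes: set[str] = set()
    coordinate_system = "RAS"  # Slicer markups default
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line:
                    coordinate_system = line.split("=")[-1].strip().upper()
                    if coordinate_system == "0":
                        coordinate_system = "RAS"
                    elif coordinate_system == "1":
                        coordinate_system = "LPS"
                continue
            row = next(csv.reader([line]))
            if len(row) < 12:
                raise LandmarkError(f"{path.name}:{lineno}: malformed fcsv row {row!r}")
            try:
                xyz = np.array([float(row[1]), float(row[2]), float(row[3])])
            except ValueError as exc:
                raise LandmarkError(f"{path.name}:{lineno}: {exc}") from None
            name = _resolve_name(row[11], aliases)
            if coordinate_system == "RAS":
                xyz = np.array([-xyz[0], -xyz[1], xyz[2]])
            elif coordinate_system != "LPS":
                raise LandmarkError(
                    f"{path.name}: unsupported CoordinateSystem {coordinate_system!r}"
                )
            if name in points:
                dupes.add(name)
            points[name] = xyz
    return points, dupes


def write_landmarks(lset: LandmarkSet, path: str | Path, dialect: str = "plain_csv") -> None:
    """Write a validated landmark set; round-trips through :func:`read_landmarks`."""
    report = validate_schema(lset)
    if not report.passed:
        raise LandmarkError(f"refusing to write invalid landmark set: {report}")
    path = Path(path)
    if dialect == "plain_csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y", "z", "frame"])
            for name in ALL_LANDMARKS:
                if name in lset.points:
                    x, y, z = lset[name]
                    writer.writerow([name, f"{x:.9f}", f"{y:.9f}", f"{z:.9f}", "LPS"])
    elif dialect == "slicer_fcsv":
        with open(path, "w", newline="") as fh:
            fh.write("# Markups fiducial file version = 4.11\n")
            fh.write("# CoordinateSystem = RAS\n")
            fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
            for i, name in enumerate(ALL_LANDMARKS, start=1):
                if name in lset.points:
                    x, y, z = lset[name]
                    # internal LPS -> file RAS
                    fh.write(
                        f"vtkMRMLMarkupsFiducialNode_{i},{-x:.9f},{-y:.9f},{z:.9f},"
                        f"0,0,0,1,1,1,0,{name},,\n"
                    )
    else:
        raise ValueError(f"unknown landmark dialect {dialect!r}")
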