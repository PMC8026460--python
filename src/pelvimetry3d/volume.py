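"""CT-like voxel volume container and I/O.

Arrays are indexed ``(slice, row, col)``, i.e. axial slices stacked along
the first axis.  In the patient LPS frame the array axes map to physical
axes ``(z, y, x)`` = (Superior, Posterior, Left); ``spacing`` and
``origin`` are stored world-ordered as ``(x, y, z)`` to match SimpleITK,
which natively works in LPS and backs all file I/O here (NRRD, NIfTI,
MetaImage, DICOM series).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["VoxelVolume", "read_volume", "write_volume"]


@dataclass
class VoxelVolume:
    """A 3D scalar grid with geometry, the input to segmentation."""

    intensities: np.ndarray           # (n_slices, n_rows, n_cols) == (z, y, x)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)   # mm, (x, y, z)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)    # mm, LPS, voxel (0,0,0)
    axis_labels: tuple[str, str, str] = ("S", "P", "L")     # array-axis anatomical labels

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if any(d < 2 for d in self.intensities.shape):
            raise ValueError("grid dimensions must be >= 2 on all axes")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    def slice(self, k: int) -> np.ndarray:
        return self.intensities[k]

    def index_to_world(self, index) -> np.ndarray:
        """Voxel index (slice, row, col) → LPS point (x, y, z) in mm."""
        k, i, j = np.asarray(index, float).T
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        return np.stack([ox + j * sx, oy + i * sy, oz + k * sz], axis=-1)

    def world_to_index(self, point) -> np.ndarray:
        """LPS point (x, y, z) → fractional voxel index (slice, row, col)."""
        x, y, z = np.asarray(point, float).T
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        return np.stack([(z - oz) / sz, (y - oy) / sy, (x - ox) / sx], axis=-1)

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return float(sx * sy * sz)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write as NRRD/NIfTI/MetaImage (by extension) with correct geometry."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.intensities))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a volume file, or a directory containing a DICOM series."""
    import SimpleITK as sitk

    path = Path(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise ValueError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    return VoxelVolume(
        intensities=arr,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )
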