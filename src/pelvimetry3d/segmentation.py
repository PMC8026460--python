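"""Slice-wise seeded level-tracing segmentation.

Starting from a seed pixel, level tracing collects the connected set of
pixels whose grey level matches the seed's and draws a closed line around
it.  On real CT data strict grey-level equality is useless, so membership
uses a symmetric intensity window ``|I(p) − I(seed)| ≤ tolerance``;
``tolerance = 0`` reproduces the literal equal-grey-level rule.  Region
membership uses 4-connectivity; the boundary is the outer crack contour —
the closed polygon of pixel edges separating filled from unfilled pixels —
traced with the region on a fixed side, so a 5-pixel plus shape yields a
12-edge outline.

Volumes are processed strictly slice by slice (axial); per-slice regions
are stacked into a 3D binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume import VoxelVolume

__all__ = [
    "TracedRegion",
    "BinaryMask",
    "level_trace",
    "segment_volume",
    "suggest_bone_seeds",
    "default_tolerance",
]


@dataclass
class TracedRegion:
    """One traced region on one axial slice."""

    slice_index: int
    seed: tuple[int, int]                  # (row, col)
    boundary: np.ndarray                   # (k, 2) closed corner-vertex contour
    mask: np.ndarray                       # 2D boolean filled region
    tolerance: float

    @property
    def perimeter_edges(self) -> int:
        """Length of the outer boundary, in pixel-edge units."""
        return len(self.boundary) - 1

    @property
    def area_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class BinaryMask:
    """3D boolean mask aligned to a source volume, with provenance."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))


def _grow_region(window: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """4-connected component of ``window`` containing ``seed`` (vectorised BFS)."""
    region = np.zeros_like(window, dtype=bool)
    region[seed] = True
    while True:
        grown = region.copy()
        grown[1:, :] |= region[:-1, :]
        grown[:-1, :] |= region[1:, :]
        grown[:, 1:] |= region[:, :-1]
        grown[:, :-1] |= region[:, 1:]
        grown &= window
        if grown.sum() == region.sum():
            return region
        region = grown


# crack-boundary steps: side → (start corner offset, end corner offset)
# each exposed pixel side becomes a directed edge with the region kept on
# a fixed side, so loops close and never cross
_SIDE_EDGES = (
    # (neighbor dr, dc), (edge start corner), (edge end corner) relative to pixel (r, c)
    ((-1, 0), (0, 0), (0, 1)),   # north side: left-to-right
    ((0, 1), (0, 1), (1, 1)),    # east side: top-to-bottom
    ((1, 0), (1, 1), (1, 0)),    # south side: right-to-left
    ((0, -1), (1, 0), (0, 0)),   # west side: bottom-to-top
)


def _trace_outer_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered, closed outer crack contour of a non-empty 2D mask.

    Vertices are pixel-corner coordinates (row, col).  The loop through the
    topmost-leftmost filled pixel's north edge is the outer contour.
    """
    rows, cols = np.nonzero(mask)
    h, w = mask.shape

    def filled(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    # directed edges start_vertex -> [(end_vertex), ...]
    outgoing: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in zip(rows.tolist(), cols.tolist()):
        for (dr, dc), (sr, sc), (er, ec) in _SIDE_EDGES:
            if not filled(r + dr, c + dc):
                start = (r + sr, c + sc)
                end = (r + er, c + ec)
                outgoing.setdefault(start, []).append(end)

    # outer loop entry point: north edge of the topmost, then leftmost pixel
    top = rows.min()
    left = cols[rows == top].min()
    start = (int(top), int(left))
    contour = [start]
    prev = (start[0], start[1] - 1)  # pretend we arrived moving east
    current = start
    while True:
        candidates = outgoing[current]
        if len(candidates) == 1:
            nxt = candidates[0]
        else:
            # corner-touch ambiguity: prefer the sharpest left turn relative
            # to the incoming direction so the loop hugs the filled pixels
            din = (current[0] - prev[0], current[1] - prev[1])
            def turn_key(cand):
                dout = (cand[0] - current[0], cand[1] - current[1])
                cross = din[0] * dout[1] - din[1] * dout[0]
                dot = din[0] * dout[0] + din[1] * dout[1]
                return np.arctan2(cross, dot)
            nxt = min(candidates, key=turn_key)
        candidates.remove(nxt)
        contour.append(nxt)
        prev, current = current, nxt
        if current == start:
            break
    return np.array(contour)


def level_trace(
    image: np.ndarray,
    seed: tuple[int, int],
    tolerance: float,
    slice_index: int = 0,
) -> TracedRegion:
    """Trace the level region of ``seed`` on one slice.

    The filled mask is the 4-connected component, containing the seed, of
    pixels within ``tolerance`` of the seed's grey level; the boundary is
    its closed outer contour (regions touching the image border are closed
    along the border).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("level_trace operates on a single 2D slice")
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"seed {seed} outside image of shape {image.shape}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    window = np.abs(image.astype(float) - float(image[r, c])) <= tolerance
    mask = _grow_region(window, (r, c))
    boundary = _trace_outer_boundary(mask)
    return TracedRegion(
        slice_index=slice_index,
        seed=(r, c),
        boundary=boundary,
        mask=mask,
        tolerance=float(tolerance),
    )


def segment_volume(
    volume: VoxelVolume,
    seeds: Sequence[tuple[int, tuple[int, int]]],
    tolerance: float,
) -> BinaryMask:
    """Stack per-slice traced regions into a 3D bone mask.

    ``seeds`` is a list of ``(slice_index, (row, col))``.  Slices without
    seeds stay empty.  A traced region covering more than half its slice —
    the signature of a seed dropped on background when bone is expected
    compact — is recorded as a warning in the provenance, not an error.
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    mask3d = np.zeros(volume.shape, dtype=bool)
    warnings: list[str] = []
    seed_log: list[dict] = []
    for slice_index, pixel in seeds:
        if not (0 <= slice_index < volume.n_slices):
            raise ValueError(f"seed slice index {slice_index} out of range")
        region = level_trace(volume.slice(slice_index), pixel, tolerance, slice_index)
        slice_area = volume.shape[1] * volume.shape[2]
        if region.area_pixels > 0.5 * slice_area:
            warnings.append(
                f"slice {slice_index}: traced region covers "
                f"{100 * region.area_pixels / slice_area:.0f}% of the slice; "
                "seed may be on background"
            )
        mask3d[slice_index] |= region.mask
        seed_log.append({
            "slice": int(slice_index),
            "pixel": [int(pixel[0]), int(pixel[1])],
            "area_pixels": region.area_pixels,
        })
    return BinaryMask(
        mask=mask3d,
        spacing=volume.spacing,
        origin=volume.origin,
        provenance={"tolerance": float(tolerance), "seeds": seed_log, "warnings": warnings},
    )


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def suggest_bone_seeds(
    volume: VoxelVolume, bone_threshold: float
) -> list[tuple[int, tuple[int, int]]]:
    """One seed per supra-threshold 4-connected component per slice.

    Each seed is the component's intensity-weighted centroid snapped to the
    nearest in-component pixel.  Returns an empty list when no voxel
    reaches the threshold.
    """
    # a threshold above the global maximum simply yields no seeds; below the
    # minimum every slice is one supra-threshold component with one seed
    seeds: list[tuple[int, tuple[int, int]]] = []
    for k in range(volume.n_slices):
        sl = volume.slice(k)
        supra = sl >= bone_threshold
        if not supra.any():
            continue
        labels, n = ndimage.label(supra, structure=_CROSS)
        for lab in range(1, n + 1):
            comp = labels == lab
            rr, cc = np.nonzero(comp)
            w = sl[rr, cc].astype(float) - bone_threshold
            if w.sum() <= 0:
                w = np.ones_like(w)
            cr = float(np.average(rr, weights=w))
            cgc = float(np.average(cc, weights=w))
            i = int(np.argmin((rr - cr) ** 2 + (cc - cgc) ** 2))
            seeds.append((k, (int(rr[i]), int(cc[i]))))
    return seeds


def default_tolerance(image: np.ndarray) -> float:
    """Half the gap between the two Otsu intensity classes of a slice."""
    from skimage.filters import threshold_otsu

    image = np.asarray(image, float)
    t = threshold_otsu(image)
    low = image[image < t]
    high = image[image >= t]
    if low.size == 0 or high.size == 0:
        return 0.0
    return float(high.mean() - low.mean()) / 2.0
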