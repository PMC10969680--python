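"""Circular ROI rasterization and VOI statistics.

ROIs are single-slice circles specified in millimetres (the convention
for manual brain ROIs: a 20 mm circle in frontoparietal white matter and
a 10 mm circle in the CSF of the lateral ventricle, drawn on the b=1000
image and transferred to the ADC map at identical voxel indices).
A voxel belongs to an ROI iff its center lies strictly inside the circle.

``voi_statistics`` is mask-shape agnostic: it accepts any boolean mask
over a 3-D volume, so single-slice circles and multi-slice vial
footprints share the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ROISpec", "VOIStats", "rasterize_roi", "voi_statistics"]


@dataclass(frozen=True)
class ROISpec:
    """A circular single-slice region of interest."""

    label: str
    slice_index: int
    center: tuple[float, float]  # (row, col), voxel units
    diameter_mm: float
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"ROI {self.label!r}: diameter must be > 0")


@dataclass(frozen=True)
class VOIStats:
    """Summary statistics of the finite voxels inside one VOI."""

    label: str
    n_voxels: int
    mean: float
    sd: float
    min: float
    max: float
    hist_edges: tuple[float, ...] = ()
    hist_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("VOI must contain at least one voxel")
        # tolerance: summation rounding can put the mean an ULP outside
        tol = 1e-9 * max(abs(self.min), abs(self.max), 1.0)
        if not (self.min - tol <= self.mean <= self.max + tol):
            raise ValueError("mean must lie within [min, max]")


def rasterize_roi(roi: ROISpec, voxel_size_mm: float,
                  grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize a circular ROI to a boolean 3-D mask.

    Raises when the ROI slice is outside the volume or when no voxel
    center falls inside the circle (diameter below the voxel pitch at an
    unlucky position).
    """
    n_slices, n_rows, n_cols = grid_shape
    if not (0 <= roi.slice_index < n_slices):
        raise ValueError(f"ROI {roi.label!r}: slice {roi.slice_index} "
                         f"outside volume of {n_slices} slices")
    row0, col0 = roi.center
    if not (-0.5 <= row0 < n_rows - 0.5 and -0.5 <= col0 < n_cols - 0.5):
        raise ValueError(f"ROI {roi.label!r}: center outside grid")
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    r_vox = roi.diameter_mm / 2.0 / voxel_size_mm
    inside = ((rr - row0) ** 2 + (cc - col0) ** 2) < r_vox ** 2
    if not inside.any():
        raise ValueError(f"ROI {roi.label!r}: rasterizes to an empty mask "
                         f"(diameter {roi.diameter_mm} mm vs voxel "
                         f"{voxel_size_mm} mm)")
    mask = np.zeros(grid_shape, dtype=bool)
    mask[roi.slice_index] = inside
    return mask


def voi_statistics(volume: np.ndarray, mask: np.ndarray,
                   label: str = "voi", n_bins: int = 32) -> VOIStats:
    """Sample mean/SD (n-1 denominator), extrema and histogram in a mask.

    NaN voxels are excluded; ``n_voxels`` counts finite in-mask voxels
    only.  Raises when the mask is empty or all in-mask voxels are NaN.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    vals = volume[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"VOI {label!r}: no finite voxels in mask")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    counts, edges = np.histogram(vals, bins=n_bins)
    return VOIStats(
        label=label,
        n_voxels=int(vals.size),
        mean=float(np.mean(vals)),
        sd=sd,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        hist_edges=tuple(float(e) for e in edges),
        hist_counts=tuple(int(c) for c in counts),
    )
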