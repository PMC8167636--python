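"""Voxel Hounsfield-unit phantom and threshold segmentation.

A synthetic CT stand-in: the dentition solids are rasterized onto a regular
voxel grid and assigned radiodensities in Hounsfield units (HU) that mimic
the tissue classes seen on a mandibular scan — enamel/dentin near 3000 HU,
alveolar bone in the 150-1800 HU band, soft tissue below 150 HU.  Raising
the lower segmentation threshold to 1000 HU then isolates the teeth from
bone and soft tissue exactly as in threshold-based CT segmentation, and
26-connected component labelling recovers one blob per tooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .geometry import Dentition

__all__ = [
    "VoxelPhantom",
    "SegmentationResult",
    "generate_phantom",
    "segment_phantom",
    "HU_TOOTH_MEAN",
    "HU_BONE_RANGE",
    "HU_SOFT_MAX",
]

#: Tissue radiodensity targets (HU).
HU_TOOTH_MEAN = 2900.0
HU_BONE_RANGE = (150.0, 1800.0)
HU_SOFT_MAX = 150.0


@dataclass(frozen=True)
class VoxelPhantom:
    """A 3-D grid of Hounsfield units on a regular voxel lattice."""

    hu_values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.20, 0.20, 0.20)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.hu_values.ndim != 3:
            raise ValueError("hu_values must be a 3-D array")
        if not np.all(np.isfinite(self.hu_values)):
            raise ValueError("hu_values must be finite")
        if min(self.voxel_size_mm) <= 0.0:
            raise ValueError("voxel sizes must be positive")

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate (mm) centre of every voxel, as three 1-D axes."""
        axes = []
        for n, h, o in zip(self.hu_values.shape, self.voxel_size_mm, self.origin_mm):
            axes.append(o + (np.arange(n) + 0.5) * h)
        return tuple(axes)


@dataclass(frozen=True)
class SegmentationResult:
    """Connected components of the thresholded phantom."""

    label_grid: np.ndarray
    component_count: int
    hu_window: tuple[float, float]

    def __post_init__(self) -> None:
        labels = np.unique(self.label_grid)
        labels = labels[labels > 0]
        expected = np.arange(1, self.component_count + 1)
        if not np.array_equal(labels, expected):
            raise ValueError("labels must be consecutive 1..component_count")


def generate_phantom(
    dentition: Dentition,
    voxel_size_mm: float = 0.20,
    margin_mm: float = 1.0,
    seed: int | None = None,
) -> VoxelPhantom:
    """Rasterize a dentition into an HU phantom.

    Deterministic given ``seed`` (defaults to the dentition spec's seed).
    Tooth-interior voxels draw HU near 3000 (clipped to stay above the bone
    band and at most 3000); a bone slab occupies the root region outside the
    teeth and PDL; everything else is soft tissue below 150 HU.

    Bone is drawn from the lower part of the 150-1800 HU bone band so that
    raising the lower segmentation threshold to 1000 HU cleanly isolates the
    teeth; the interactive mask editing a real scan needs (where cortical
    bone overlaps the window) is deliberately not emulated.
    """
    if seed is None:
        seed = dentition.spec.random_seed
    rng = np.random.default_rng(seed)

    lo, hi = dentition.bounding_box
    lo = lo - margin_mm
    hi = hi + margin_mm
    h = float(voxel_size_mm)
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / h)) for k in range(3))

    ax = [lo[k] + (np.arange(shape[k]) + 0.5) * h for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    tooth_mask = np.zeros(len(pts), dtype=bool)
    for tooth in dentition.teeth:
        inside = tooth.contains(pts)
        if not inside.any():
            raise ValueError(f"tooth {tooth.fdi} rasterizes to zero voxels")
        tooth_mask |= inside

    pdl_mask = np.zeros(len(pts), dtype=bool)
    for shell in dentition.pdl_shells:
        pdl_mask |= shell.contains(pts)
    pdl_mask &= ~tooth_mask

    # bone slab: root region below the cervical plane, outside teeth and PDL
    bone_mask = (pts[:, 2] < 0.0) & ~tooth_mask & ~pdl_mask

    hu = rng.normal(40.0, 25.0, size=len(pts))          # soft-tissue background
    hu = np.clip(hu, -200.0, HU_SOFT_MAX - 10.0)
    bone = rng.uniform(200.0, 900.0, size=int(bone_mask.sum()))
    hu[bone_mask] = bone
    tooth = rng.normal(HU_TOOTH_MEAN, 50.0, size=int(tooth_mask.sum()))
    hu[tooth_mask] = np.clip(tooth, 2600.0, 3000.0)

    return VoxelPhantom(
        hu_values=hu.reshape(shape),
        voxel_size_mm=(h, h, h),
        origin_mm=(float(lo[0]), float(lo[1]), float(lo[2])),
    )


def segment_phantom(
    phantom: VoxelPhantom, lo: float = 1000.0, hi: float = 3000.0
) -> SegmentationResult:
    """Threshold the phantom to [lo, hi] HU and label 26-connected blobs.

    An empty foreground yields component_count 0, not an error.
    """
    if lo >= hi:
        raise ValueError(f"require lo < hi, got ({lo}, {hi})")
    mask = (phantom.hu_values >= lo) & (phantom.hu_values <= hi)
    labels, n = measure.label(mask, connectivity=3, return_num=True)
    return SegmentationResult(label_grid=labels, component_count=int(n), hu_window=(lo, hi))
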