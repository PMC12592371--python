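"""ROI mask construction, masking, quality control, and downsampling of
binary sulcal-skeleton volumes.

Volumes are assumed already co-registered on a common grid (the synthetic
generator produces them that way; affine normalization of real data is out
of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import SkeletonVolume


@dataclass
class RoiMask:
    grid: np.ndarray
    dilation_mm: float = 0.0
    source_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if not self.grid.any():
            raise ValueError("ROI mask is empty")


def _ball_structure(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Euclidean ball on voxel centers: offsets whose center distance <= radius."""
    r_vox = int(np.floor(radius_mm / voxel_size_mm + 1e-9))
    if r_vox < 1:
        return np.ones((1, 1, 1), dtype=bool)
    ax = np.arange(-r_vox, r_vox + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    dist = voxel_size_mm * np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    return dist <= radius_mm + 1e-9


def build_roi_mask(volumes, dilation_mm: float = 5.0) -> RoiMask:
    """Union of labeled skeletons followed by a spherical dilation.

    Mirrors the construction of a regional mask from annotated subjects: the
    voxelwise union of their skeletons, then a morphological dilation by a
    Euclidean ball of ``dilation_mm`` (converted to voxels via the volumes'
    voxel size).
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    shape = volumes[0].grid.shape
    vox = volumes[0].voxel_size_mm
    union = np.zeros(shape, dtype=bool)
    for v in volumes:
        if v.grid.shape != shape:
            raise ValueError("all volumes must share one grid")
        union |= v.grid.astype(bool)
    if dilation_mm > 0:
        union = ndimage.binary_dilation(union, structure=_ball_structure(dilation_mm, vox))
    return RoiMask(grid=union, dilation_mm=dilation_mm,
                   source_ids=[v.subject_id for v in volumes])


def apply_mask(volume: SkeletonVolume, mask: RoiMask) -> SkeletonVolume:
    """Elementwise AND of skeleton and ROI mask."""
    if volume.grid.shape != mask.grid.shape:
        raise ValueError("volume and mask shapes differ")
    return SkeletonVolume(grid=(volume.grid.astype(bool) & mask.grid).astype(np.uint8),
                          voxel_size_mm=volume.voxel_size_mm,
                          affine=volume.affine, subject_id=volume.subject_id)


def qc_filter(voxel_counts) -> tuple[np.ndarray, float]:
    """Remove subjects whose skeleton has too many voxels.

    The threshold is 1.2 times the 90th percentile (ninth decile boundary,
    linear interpolation) of the voxel-count distribution; subjects strictly
    above it are removed.  Returns (kept_indices, threshold).
    """
    counts = np.asarray(voxel_counts, dtype=float)
    if counts.size < 10:
        raise ValueError("QC decile undefined for fewer than 10 subjects")
    threshold = 1.2 * np.percentile(counts, 90)
    kept = np.flatnonzero(counts <= threshold)
    return kept, float(threshold)


def qc_report(volumes, kept: np.ndarray, threshold: float) -> pd.DataFrame:
    counts = [v.count() for v in volumes]
    kept_set = set(kept.tolist())
    return pd.DataFrame({
        "subject_id": [v.subject_id for v in volumes],
        "voxel_count": counts,
        "kept": [i in kept_set for i in range(len(volumes))],
        "threshold": threshold,
    })


def downsample(volume: SkeletonVolume, factor: int = 2) -> SkeletonVolume:
    """Block-max pooling: output voxel is set iff any voxel of its
    factor³ block is set.  Grids not divisible by ``factor`` are zero-padded.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return volume
    g = volume.grid
    pad = [(0, (-s) % factor) for s in g.shape]
    if any(p[1] for p in pad):
        g = np.pad(g, pad)
    s0, s1, s2 = (s // factor for s in g.shape)
    blocks = g.reshape(s0, factor, s1, factor, s2, factor)
    out = blocks.max(axis=(1, 3, 5))
    return SkeletonVolume(grid=out.astype(np.uint8),
                          voxel_size_mm=volume.voxel_size_mm * factor,
                          subject_id=volume.subject_id)
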