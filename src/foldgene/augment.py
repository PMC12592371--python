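"""Binary-volume augmentations for self-supervised twin training.

All augmentations map binary arrays to binary arrays of the same shape and
never create voxels that were absent from the input (translations drop
voxels at the border; cut-in/cut-out/trimming only delete).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AugmentationConfig:
    """Sampling ranges for the random view-generating transform.

    max_shift_voxels: per-axis translation amplitude.
    trim_fraction_range: uniform range for the fraction of occupied depth
        levels deleted from the deep end (depth trimming).
    cutin_min_fraction: minimum per-axis extent kept by a cut-in box.
    cutout_max_fraction: maximum per-axis extent deleted by a cut-out box.
    depth_axis: the fixed grid axis along which depth is measured; index 0
        of that axis is the superficial face.
    """

    max_shift_voxels: int = 2
    trim_fraction_range: tuple = (0.0, 0.3)
    cutin_min_fraction: float = 0.7
    cutout_max_fraction: float = 0.3
    depth_axis: int = 0
    p_cutout: float = 0.5  # otherwise cut-in

    def __post_init__(self) -> None:
        if self.max_shift_voxels < 0:
            raise ValueError("max_shift_voxels must be >= 0")
        for v in (*self.trim_fraction_range, self.cutin_min_fraction,
                  self.cutout_max_fraction):
            if not (0.0 <= v <= 1.0):
                raise ValueError("fractions must lie in [0,1]")


def augment_translate(grid: np.ndarray, max_shift_voxels: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Integer shift per axis, uniform in [-max_shift, max_shift]; voxels
    shifted out of the grid are dropped and vacated voxels are zero."""
    if max_shift_voxels < 0:
        raise ValueError("max_shift_voxels must be >= 0")
    if max_shift_voxels == 0:
        return grid.copy()
    shifts = rng.integers(-max_shift_voxels, max_shift_voxels + 1, grid.ndim)
    return translate(grid, shifts)


def translate(grid: np.ndarray, shifts) -> np.ndarray:
    out = np.zeros_like(grid)
    src, dst = [], []
    for s, n in zip(shifts, grid.shape):
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = grid[tuple(src)]
    return out


def _box_slices(box) -> tuple:
    return tuple(slice(int(lo), int(hi)) for lo, hi in box)


def augment_cutin(grid: np.ndarray, box) -> np.ndarray:
    """Keep only voxels inside the parallelepiped ``box`` ((lo, hi) per axis,
    half-open); everything outside is zeroed.  An empty box yields an empty
    volume."""
    for (lo, hi), n in zip(box, grid.shape):
        if not (0 <= lo and hi <= n):
            raise ValueError("box exceeds grid")
    out = np.zeros_like(grid)
    sl = _box_slices(box)
    out[sl] = grid[sl]
    return out


def augment_cutout(grid: np.ndarray, box) -> np.ndarray:
    """Delete voxels inside ``box``, keeping only those outside."""
    for (lo, hi), n in zip(box, grid.shape):
        if not (0 <= lo and hi <= n):
            raise ValueError("box exceeds grid")
    out = grid.copy()
    out[_box_slices(box)] = 0
    return out


def augment_trim_depth(grid: np.ndarray, trim_fraction: float,
                       depth_axis: int = 0) -> np.ndarray:
    """Delete the deepest ``trim_fraction`` of occupied depth levels.

    Depth of a voxel is its index along ``depth_axis`` (distance from the
    superficial face).  Levels along that axis containing at least one voxel
    are counted; the deepest ``round(trim_fraction * n_occupied)`` of them
    are zeroed, forcing invariance of downstream representations to fold
    depth.
    """
    if not (0.0 <= trim_fraction <= 1.0):
        raise ValueError("trim_fraction must be in [0,1]")
    occupied = np.flatnonzero(grid.sum(axis=tuple(i for i in range(grid.ndim)
                                                  if i != depth_axis)))
    n_occ = occupied.size
    n_trim = int(np.floor(trim_fraction * n_occ + 1e-9))
    if n_trim == 0:
        return grid.copy()
    out = grid.copy()
    deepest = occupied[n_occ - n_trim:]
    idx = [slice(None)] * grid.ndim
    idx[depth_axis] = deepest
    out[tuple(idx)] = 0
    return out


def random_view(grid: np.ndarray, cfg: AugmentationConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Compose the random transform T: translate, depth-trim, then one of
    cut-in / cut-out with a random box."""
    out = augment_translate(grid, cfg.max_shift_voxels, rng)
    lo, hi = cfg.trim_fraction_range
    out = augment_trim_depth(out, float(rng.uniform(lo, hi)), cfg.depth_axis)
    if rng.random() < cfg.p_cutout:
        box = []
        for n in out.shape:
            ext = int(rng.integers(0, max(1, int(cfg.cutout_max_fraction * n)) + 1))
            start = int(rng.integers(0, n - ext + 1))
            box.append((start, start + ext))
        out = augment_cutout(out, box)
    else:
        box = []
        for n in out.shape:
            ext = int(rng.integers(int(np.ceil(cfg.cutin_min_fraction * n)), n + 1))
            start = int(rng.integers(0, n - ext + 1))
            box.append((start, start + ext))
        out = augment_cutin(out, box)
    return out
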