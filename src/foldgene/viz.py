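"""Rendering of occupancy maps: NIfTI export and PNG montages with the
5%/35% display scale (voxels present in <5% of batch subjects are hidden;
the color scale saturates at 35%)."""

from __future__ import annotations

import numpy as np


def save_frequency_map(fmap, path: str, voxel_size_mm: float = 2.0) -> None:
    import nibabel as nib
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(fmap.values.astype(np.float32), affine), path)


def montage_png(maps, path: str, axis: int = 2, low: float = 0.05,
                high: float = 0.35, titles=None) -> None:
    """One row per map, one column per slice along ``axis``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_maps = len(maps)
    n_slices = maps[0].values.shape[axis]
    fig, axes = plt.subplots(n_maps, n_slices,
                             figsize=(1.1 * n_slices, 1.2 * n_maps),
                             squeeze=False)
    for r, fmap in enumerate(maps):
        v = np.ma.masked_less(fmap.values, low)
        for c in range(n_slices):
            sl = np.take(v, c, axis=axis)
            ax = axes[r][c]
            ax.imshow(sl.T, origin="lower", cmap="viridis",
                      vmin=low, vmax=high, interpolation="nearest")
            ax.set_xticks([])
            ax.set_yticks([])
        label = titles[r] if titles else f"map {r}"
        axes[r][0].set_ylabel(label, fontsize=7)
    fig.tight_layout(pad=0.2)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_points(pvals) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(pvals, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return expected[::-1], observed[::-1]
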