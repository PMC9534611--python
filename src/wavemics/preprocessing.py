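"""Volume preprocessing: isotropic resampling and fixed-bin-width discretization.

The preprocessing chain mirrors the common radiomics convention: resample the
volume and its mask to an isotropic grid first (trilinear for intensities,
nearest-neighbour for the binary mask), then discretize the in-mask
intensities with a fixed bin width anchored at the ROI minimum.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import DiscretizedROI, ImageVolume, ROIMask


def resample_isotropic(
    volume: ImageVolume,
    mask: ROIMask,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[ImageVolume, ROIMask]:
    """Resample volume + mask onto a grid with the requested spacing.

    Intensities are interpolated trilinearly, the mask with nearest-neighbour
    so it stays binary. When the input already has the target spacing the
    voxel values pass through unchanged.
    """
    target = tuple(float(t) for t in target_spacing)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ValueError("target_spacing must be three positive values")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")

    if np.allclose(volume.spacing, target):
        return volume, mask

    in_shape = np.array(volume.shape)
    scale = np.array(target) / np.array(volume.spacing)  # output step in input index units
    out_shape = np.maximum(1, np.round(in_shape / scale).astype(int))

    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(out_shape, scale)), indexing="ij"
    )
    coords = np.stack(grids)

    out_vox = ndimage.map_coordinates(volume.voxels, coords, order=1, mode="nearest")
    out_mask = ndimage.map_coordinates(
        mask.voxels.astype(np.uint8), coords, order=0, mode="nearest"
    ).astype(bool)

    if not out_mask.any():
        raise ValueError("mask is empty after resampling (degenerate ROI)")

    return (
        ImageVolume(out_vox, target, volume.origin),
        ROIMask(out_mask),
    )


def discretize(volume: ImageVolume, mask: ROIMask, bin_width: float = 64.0) -> DiscretizedROI:
    """Fixed-bin-width discretization of the in-mask intensities.

    level(v) = floor((v - min_ROI) / bin_width) + 1, so levels are consecutive
    integers starting at 1 and ``n_levels`` is the level of the ROI maximum.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    m = mask.voxels
    if volume.shape != m.shape:
        raise ValueError("volume and mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    roi = volume.voxels[m]
    if not np.all(np.isfinite(roi)):
        raise ValueError("non-finite intensities inside mask")

    lo = roi.min()
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[m] = np.floor((volume.voxels[m] - lo) / bin_width).astype(np.int64) + 1
    n_levels = int(levels[m].max())
    return DiscretizedROI(levels=levels, mask=m, n_levels=n_levels, bin_width=float(bin_width))
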