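"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical MRI sequence order used everywhere (column prefixes, row assembly).
SEQUENCES = ("T1W", "T2W", "T1C", "FLAIR")


@dataclass
class ImageVolume:
    """A single MRI sequence: a 3D voxel grid with physical spacing.

    Axes are (z, y, x) = (slice, row, column); ``spacing`` is mm per axis in
    the same order; ``origin`` is the physical position of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROIMask:
    """Binary tumor mask aligned voxel-for-voxel to an :class:`ImageVolume`."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class DiscretizedROI:
    """Gray levels after fixed-bin-width discretization, restricted to the mask.

    ``levels`` holds integer levels 1..n_levels inside the mask and 0 outside.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float

    @property
    def roi_levels(self) -> np.ndarray:
        """Flat array of the in-mask gray levels."""
        return self.levels[self.mask]


@dataclass
class PatientCase:
    """One patient: four co-registered sequences, repeated masks, class label.

    ``masks[(reader, session)]`` are the repeated segmentations (0-based
    indices); ``reference_mask`` is the noise-free ground-truth ROI used for
    feature extraction.
    """

    patient_id: str
    volumes: dict[str, ImageVolume]
    reference_mask: ROIMask
    masks: dict[tuple[int, int], ROIMask]
    label: int
    meta: dict = field(default_factory=dict)
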