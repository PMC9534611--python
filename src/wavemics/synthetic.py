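"""Synthetic two-class cohorts for exercising the pipeline end to end.

Real patient MRI cannot be redistributed, so this module generates cohorts
with the study's structure: two tumor classes (label 1 = primary tumor,
label 0 = metastasis), four co-registered sequences per patient, ellipsoidal
ROIs with class-dependent size and intensity texture, and repeated
segmentations (readers x sessions) with small boundary perturbations so the
reliability analysis has genuine variation to measure.

Texture inside the ROI is Gaussian-filtered white noise with a class-specific
spatial correlation length, so gray-level texture families genuinely differ
between classes; shape differs through the per-class radius distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import SEQUENCES, ImageVolume, PatientCase, ROIMask


@dataclass
class SequenceTexture:
    """Intensity model of one class on one sequence (arbitrary units)."""

    mean: float
    sd: float
    corr_length_mm: float  # Gaussian smoothing length of the in-ROI texture


def _default_textures() -> dict[int, dict[str, SequenceTexture]]:
    # class 1: larger, more heterogeneous lesions with longer-range texture;
    # class 0: smaller, finer-grained texture
    return {
        1: {
            "T1W": SequenceTexture(140.0, 40.0, 2.5),
            "T2W": SequenceTexture(170.0, 45.0, 2.5),
            "T1C": SequenceTexture(190.0, 50.0, 3.0),
            "FLAIR": SequenceTexture(160.0, 40.0, 2.5),
        },
        0: {
            "T1W": SequenceTexture(125.0, 22.0, 1.0),
            "T2W": SequenceTexture(155.0, 25.0, 1.0),
            "T1C": SequenceTexture(210.0, 28.0, 1.2),
            "FLAIR": SequenceTexture(145.0, 22.0, 1.0),
        },
    }


@dataclass
class CohortConfig:
    """Parameters of a synthetic imaging cohort."""

    n_patients: int = 16
    class_balance: float = 51.0 / 91.0  # fraction in class 1
    volume_shape: tuple[int, int, int] = (24, 32, 32)
    voxel_spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    tumor_radius_range_per_class: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (7.0, 11.0), 0: (5.0, 9.0)}
    )
    intensity_texture_params_per_class: dict[int, dict[str, SequenceTexture]] = field(
        default_factory=_default_textures
    )
    background_mean: float = 100.0
    background_sd: float = 15.0
    reader_jitter: float = 0.15  # boundary-voxel flip probability
    n_readers: int = 2
    n_sessions: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be strictly between 0 and 1")
        if any(n < 8 for n in self.volume_shape):
            raise ValueError("each volume axis needs >= 8 voxels")
        fov = [n * s for n, s in zip(self.volume_shape, self.voxel_spacing)]
        for cls, (lo, hi) in self.tumor_radius_range_per_class.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid radius range for class {cls}")
            if hi >= min(fov) / 2:
                raise ValueError("tumor radius must be below half the field of view")
        if not 0.0 <= self.reader_jitter <= 1.0:
            raise ValueError("reader_jitter must be a probability")


@dataclass
class FeatureTableConfig:
    """Parameters of a synthetic feature table with planted class structure."""

    n_patients: int = 91
    n_features_per_sequence: int = 107
    n_sequences: int = 4
    n_informative: int = 10
    effect_size: float = 1.0  # class-conditional mean difference, in noise-sd units
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        total = self.n_features_per_sequence * self.n_sequences
        if self.n_informative > total:
            raise ValueError("n_informative exceeds the number of columns")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _class_labels(n: int, balance: float) -> np.ndarray:
    n_pos = int(round(n * balance))
    n_pos = min(max(n_pos, 1), n - 1)
    return np.array([1] * n_pos + [0] * (n - n_pos))


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm))
    return q <= 1.0


def _textured_volume(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    mask: np.ndarray,
    tex: SequenceTexture,
    bg_mean: float,
    bg_sd: float,
) -> np.ndarray:
    bg = bg_mean + bg_sd * rng.standard_normal(shape)
    sigma_vox = [max(tex.corr_length_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    vol = bg.copy()
    vol[mask] = tex.mean + tex.sd * smooth[mask]
    return vol


def _perturb_once(base: np.ndarray, jitter: float, rng: np.random.Generator) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, 1)
    inner = base & ~ndimage.binary_erosion(base, struct)
    outer = ndimage.binary_dilation(base, struct) & ~base
    out = base.copy()
    out[inner] ^= rng.random(int(inner.sum())) < jitter / 2
    out[outer] ^= rng.random(int(outer.sum())) < jitter / 2
    if rng.random() < jitter:
        # localized one-voxel dilation/erosion patch around a boundary voxel
        pts = np.argwhere(inner | outer)
        if len(pts):
            c = pts[rng.integers(len(pts))]
            zz, yy, xx = np.ogrid[: base.shape[0], : base.shape[1], : base.shape[2]]
            patch = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= 4
            if rng.random() < 0.5:
                out |= ndimage.binary_dilation(base, struct) & patch
            else:
                out &= ~(inner & patch)
    if not out.any():
        out = base.copy()
    return out


def _perturb_mask(base: np.ndarray, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """A plausible re-segmentation: independent boundary-voxel flips plus a
    localized one-voxel dilation/erosion patch, all confined to the one-voxel
    boundary shells.

    The perturbation strength is halved and redrawn until the Dice overlap
    with the base mask stays >= 0.92, so any two re-segmentations of the same
    tumor overlap by >= 0.8 Dice by construction.
    """
    if jitter <= 0:
        return base.copy()
    scale = 1.0
    for _ in range(6):
        out = _perturb_once(base, jitter * scale, rng)
        inter = np.logical_and(base, out).sum()
        if 2.0 * inter / (base.sum() + out.sum()) >= 0.92:
            return out
        scale /= 2.0
    return base.copy()


def generate_cohort(config: CohortConfig) -> list[PatientCase]:
    """Generate the synthetic cohort; identical config gives identical output."""
    config.validate()
    labels = _class_labels(config.n_patients, config.class_balance)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    shape, spacing = config.volume_shape, config.voxel_spacing
    fov = np.array([n * s for n, s in zip(shape, spacing)])

    cases: list[PatientCase] = []
    for idx, (label, ss) in enumerate(zip(labels, seeds)):
        rng = np.random.default_rng(ss)
        lo, hi = config.tumor_radius_range_per_class[int(label)]
        r = rng.uniform(lo, hi)
        semi = r * rng.uniform(0.7, 1.0, size=3)
        semi = np.maximum(semi, 2.0 * np.asarray(spacing))  # at least 2 voxels thick
        center = fov / 2 + rng.uniform(-2.0, 2.0, size=3)
        base = _ellipsoid_mask(shape, spacing, center, semi)

        volumes = {
            seq: ImageVolume(
                _textured_volume(
                    rng, shape, spacing, base,
                    config.intensity_texture_params_per_class[int(label)][seq],
                    config.background_mean, config.background_sd,
                ),
                spacing,
            )
            for seq in SEQUENCES
        }
        masks = {
            (reader, session): ROIMask(_perturb_mask(base, config.reader_jitter, rng))
            for reader in range(config.n_readers)
            for session in range(config.n_sessions)
        }
        cases.append(
            PatientCase(
                patient_id=f"P{idx:03d}",
                volumes=volumes,
                reference_mask=ROIMask(base),
                masks=masks,
                label=int(label),
                meta={"radius_mm": float(r)},
            )
        )
    return cases


def generate_feature_table(config: FeatureTableConfig) -> pd.DataFrame:
    """Feature table with planted class structure.

    Exactly ``n_informative`` columns receive a class-conditional mean
    difference of ``effect_size`` (in units of ``noise_sd``, added before the
    Gaussian noise); all other columns are pure noise. Column names encode
    sequence and feature family; a trailing ``label`` column holds the class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_features_per_sequence * config.n_sequences

    names = []
    from .extract import FEATURE_NAMES_107  # local import to avoid cycle

    for s in range(config.n_sequences):
        seq = SEQUENCES[s] if s < len(SEQUENCES) else f"SEQ{s}"
        if config.n_features_per_sequence == len(FEATURE_NAMES_107):
            names.extend(f"{seq}_{n}" for n in FEATURE_NAMES_107)
        else:
            names.extend(
                f"{seq}_generic_f{i:03d}" for i in range(config.n_features_per_sequence)
            )

    labels = _class_labels(config.n_patients, 0.5)
    X = config.noise_sd * rng.standard_normal((config.n_patients, n_total))
    informative = rng.choice(n_total, size=config.n_informative, replace=False)
    shift = config.effect_size * config.noise_sd
    X[np.ix_(labels == 1, informative)] += shift

    df = pd.DataFrame(X, columns=names, index=[f"P{i:03d}" for i in range(config.n_patients)])
    df["label"] = labels
    df.attrs["informative_columns"] = [names[i] for i in informative]
    return df
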