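"""Per-sequence 107-feature extraction and per-patient row assembly.

Each MRI sequence yields 107 named features — shape (14), first-order (18),
GLCM (24), GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5) — and the four
sequences are concatenated into a single 428-column row per patient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import SEQUENCES, ImageVolume, PatientCase, ROIMask
from .firstorder import FIRSTORDER_FEATURE_NAMES, firstorder_features
from .preprocessing import discretize, resample_isotropic
from .shape import SHAPE_FEATURE_NAMES, shape_features
from .texture import (
    GLCM_FEATURE_NAMES,
    GLDM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

FAMILY_FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURE_NAMES,
    "firstorder": FIRSTORDER_FEATURE_NAMES,
    "glcm": GLCM_FEATURE_NAMES,
    "glrlm": GLRLM_FEATURE_NAMES,
    "glszm": GLSZM_FEATURE_NAMES,
    "gldm": GLDM_FEATURE_NAMES,
    "ngtdm": NGTDM_FEATURE_NAMES,
}

FAMILY_SIZES = {fam: len(names) for fam, names in FAMILY_FEATURE_NAMES.items()}

#: canonical per-sequence feature names, e.g. "shape_Elongation"
FEATURE_NAMES_107 = tuple(
    f"{fam}_{name}" for fam, names in FAMILY_FEATURE_NAMES.items() for name in names
)

N_FEATURES_PER_SEQUENCE = len(FEATURE_NAMES_107)  # 107


def extract_sequence_features(
    volume: ImageVolume,
    mask: ROIMask,
    bin_width: float = 64.0,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    resample: bool = True,
) -> dict[str, float]:
    """Extract the 107 features for one sequence (one volume + mask)."""
    if resample:
        volume, mask = resample_isotropic(volume, mask, target_spacing)
    droi = discretize(volume, mask, bin_width)
    raw = volume.voxels[mask.voxels]
    voxel_volume = float(np.prod(volume.spacing))

    out: dict[str, float] = {}
    out.update({f"shape_{k}": v for k, v in shape_features(mask, volume.spacing).items()})
    out.update(
        {f"firstorder_{k}": v for k, v in firstorder_features(droi, raw, voxel_volume).items()}
    )
    out.update({f"glcm_{k}": v for k, v in glcm_features(droi).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(droi).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(droi).items()})
    out.update({f"gldm_{k}": v for k, v in gldm_features(droi).items()})
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(droi).items()})
    assert tuple(out) == FEATURE_NAMES_107
    return out


def extract_all(
    case: PatientCase,
    bin_width: float = 64.0,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask: ROIMask | None = None,
) -> dict[str, float]:
    """One 428-column feature row for a patient (sequence-prefixed names).

    Uses the case's reference mask unless an explicit mask is given (the
    repeated reader/session masks feed the reliability analysis).
    """
    roi = mask if mask is not None else case.reference_mask
    row: dict[str, float] = {}
    for seq in SEQUENCES:
        if seq not in case.volumes:
            raise KeyError(f"missing sequence {seq!r} for patient {case.patient_id}")
        feats = extract_sequence_features(case.volumes[seq], roi, bin_width, target_spacing)
        row.update({f"{seq}_{k}": v for k, v in feats.items()})
    return row


def extract_cohort_table(
    cases: list[PatientCase],
    bin_width: float = 64.0,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Feature table (patients x 428) with a trailing ``label`` column."""
    rows = []
    for case in cases:
        row = extract_all(case, bin_width, target_spacing)
        row["label"] = case.label
        rows.append(pd.Series(row, name=case.patient_id))
    return pd.DataFrame(rows)
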