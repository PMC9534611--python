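"""NIfTI and CSV interchange for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import SEQUENCES, ImageVolume, PatientCase, ROIMask


def _affine(spacing: tuple[float, float, float], origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: ImageVolume, path: Path) -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def load_volume(path: Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def save_mask(mask: ROIMask, spacing, path: Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(spacing, (0, 0, 0)))
    nib.save(img, str(path))


def load_mask(path: Path) -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(np.asarray(img.dataobj) > 0)


def save_cohort(cases: list[PatientCase], out_dir: Path) -> None:
    """Write a cohort as NIfTI volumes/masks plus a labels CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = {}
    for case in cases:
        pdir = out_dir / case.patient_id
        pdir.mkdir(exist_ok=True)
        for seq, vol in case.volumes.items():
            save_volume(vol, pdir / f"{seq}.nii.gz")
        sp = case.volumes[SEQUENCES[0]].spacing
        save_mask(case.reference_mask, sp, pdir / "mask_reference.nii.gz")
        for (reader, session), mask in case.masks.items():
            save_mask(mask, sp, pdir / f"mask_r{reader}s{session}.nii.gz")
        labels[case.patient_id] = case.label
    pd.Series(labels, name="label").rename_axis("patient_id").to_csv(out_dir / "labels.csv")


def load_cohort(in_dir: Path) -> list[PatientCase]:
    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "labels.csv", index_col=0)["label"]
    cases = []
    for pid, label in labels.items():
        pdir = in_dir / str(pid)
        volumes = {seq: load_volume(pdir / f"{seq}.nii.gz") for seq in SEQUENCES}
        reference = load_mask(pdir / "mask_reference.nii.gz")
        masks = {}
        for mpath in sorted(pdir.glob("mask_r*s*.nii.gz")):
            stem = mpath.name.split(".")[0]  # mask_r{reader}s{session}
            reader, session = int(stem[6]), int(stem[8])
            masks[(reader, session)] = load_mask(mpath)
        cases.append(PatientCase(str(pid), volumes, reference, masks, int(label)))
    return cases


def save_table(table: pd.DataFrame, path: Path) -> None:
    table.rename_axis("patient_id").to_csv(path)


def load_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def save_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
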