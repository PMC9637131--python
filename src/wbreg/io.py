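"""NIfTI and tabular I/O for images, masks, fields and landmarks.

Axis-aligned volumes only: the NIfTI affine must be diagonal with
positive spacing (oblique or flipped orientations are rejected — a
documented limitation, since every container in this package assumes
``world = origin + index * spacing``).  Displacement fields are stored as
4-D NIfTI with three components on the last axis, in mm, world axes.
"""

from __future__ import annotations

import csv
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DisplacementField, MaskSet, VolumetricImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "read_mask_set",
    "write_mask_set",
    "read_landmarks",
    "write_landmarks",
]


def _check_affine(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    diag = np.diag(affine)[:3]
    off = affine[:3, :3] - np.diag(diag)
    if np.any(np.abs(off) > 1e-6) or np.any(diag <= 0):
        raise ValueError(
            f"{path}: only axis-aligned volumes with positive spacing are "
            "supported (diagonal affine); reorient the image first")
    return diag.astype(float), affine[:3, 3].astype(float)


def _affine(spacing, origin) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing)
    A[:3, 3] = origin
    return A


def read_volume(path) -> VolumetricImage:
    """Read a (gzipped) NIfTI scalar volume."""
    img = nib.load(str(path))
    spacing, origin = _check_affine(img.affine, path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VolumetricImage(data, spacing, origin)


def write_volume(image: VolumetricImage, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(image.values), _affine(image.spacing,
                                                               image.origin)),
             str(path))


def read_field(path) -> DisplacementField:
    """Read a displacement field (4-D NIfTI, 3 vector components, mm)."""
    img = nib.load(str(path))
    spacing, origin = _check_affine(img.affine, path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:   # NIfTI vector convention
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: displacement fields need exactly 3 components on the "
            f"last axis, got shape {data.shape}")
    return DisplacementField(data, spacing, origin)


def write_field(field: DisplacementField, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(field.vectors.astype(np.float64),
                             _affine(field.spacing, field.origin)),
             str(path))


_MASK_NAMES = ("body", "bone", "lean", "adipose", "inside_sat")


def write_mask_set(masks: MaskSet, out_dir, spacing, origin=(0, 0, 0)) -> None:
    """Write the five masks as uint8 NIfTI files named after each mask."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, m in masks.items():
        nib.save(nib.Nifti1Image(m.astype(np.uint8), _affine(spacing, origin)),
                 str(out / f"{name}.nii.gz"))


def read_mask_set(in_dir) -> tuple[MaskSet, np.ndarray, np.ndarray]:
    vols = {n: read_volume(Path(in_dir) / f"{n}.nii.gz") for n in _MASK_NAMES}
    first = vols["body"]
    return (MaskSet(**{n: v.values > 0 for n, v in vols.items()}),
            first.spacing, first.origin)


def write_landmarks(landmarks: np.ndarray, path) -> None:
    """Write paired landmarks as a 6-column CSV (x_a,y_a,z_a,x_b,y_b,z_b), mm."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lm = np.asarray(landmarks, dtype=float).reshape(-1, 6)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_a", "y_a", "z_a", "x_b", "y_b", "z_b"])
        w.writerows(lm.tolist())


def read_landmarks(path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)][1:]
    return np.asarray(rows, dtype=float).reshape(-1, 2, 3)
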