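"""Registration evaluation: inverse consistency, overlap, folding, stats.

For a pair of images i, j registered in both directions, the forward and
reverse transforms T_ij, T_ji would ideally be exact inverses.  The
inverse-consistency errors quantify the deviation over a body region
Omega:

    VME_ij = (1/|Omega|) sum_{x in Omega} || x - (T_ji o T_ij)(x) ||
    IME_ij = (1/|Omega|) sum_{x in Omega} | I_i(x) - I_i((T_ji o T_ij)(x)) |

in mm and HU respectively; the pair value averages both compositions.
Tissue overlap under the composite (round-trip) transform is measured
with the Dice coefficient, and transform regularity via the Jacobian
determinant (negative values = folding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DisplacementField, VolumetricImage, compose_fields, warp_image

__all__ = [
    "RegionOfInterest",
    "ConsistencyReport",
    "vme",
    "ime",
    "composite_dice",
    "jacobian_determinant",
    "folding_fraction",
    "template_voxel_stats",
    "evaluate_pair",
]


@dataclass
class RegionOfInterest:
    """Binary evaluation region Omega on the field lattice."""

    omega: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega).astype(bool)
        if not self.omega.any():
            raise ValueError("empty region of interest")

    @property
    def voxel_count(self) -> int:
        return int(self.omega.sum())


@dataclass
class ConsistencyReport:
    """Whole-body registration performance metrics of one image pair."""

    vme_mm: float
    ime_hu: float
    dice_adipose: float
    dice_lean: float
    folding_pct: float
    per_direction: dict

    def as_dict(self) -> dict:
        return {
            "vme_mm": self.vme_mm,
            "ime_hu": self.ime_hu,
            "dice_adipose": self.dice_adipose,
            "dice_lean": self.dice_lean,
            "folding_pct": self.folding_pct,
        }


def _roundtrip_points(t_ij: DisplacementField, t_ji: DisplacementField,
                      pts: np.ndarray) -> np.ndarray:
    """(T_ji o T_ij)(x) for world points x."""
    mid = pts + t_ij.sample(pts)
    return mid + t_ji.sample(mid)


def vme(t_ij: DisplacementField, t_ji: DisplacementField,
        omega: RegionOfInterest) -> float:
    """Mean round-trip displacement magnitude (mm) over Omega."""
    pts = t_ij.lattice_points()[omega.omega]
    rt = _roundtrip_points(t_ij, t_ji, pts)
    return float(np.mean(np.linalg.norm(rt - pts, axis=-1)))


def ime(image_i: VolumetricImage, t_ij: DisplacementField,
        t_ji: DisplacementField, omega: RegionOfInterest) -> float:
    """Mean absolute round-trip intensity difference (HU) over Omega."""
    pts = t_ij.lattice_points()[omega.omega]
    rt = _roundtrip_points(t_ij, t_ji, pts)
    vals_rt = image_i.sample_world(rt, order=1)
    vals = image_i.values[omega.omega].astype(float)
    return float(np.mean(np.abs(vals - vals_rt)))


def composite_dice(mask_i: np.ndarray, t_ij: DisplacementField,
                   t_ji: DisplacementField) -> float:
    """Dice overlap of a tissue mask with its round-trip warp."""
    comp = compose_fields(t_ji, t_ij)
    m = np.asarray(mask_i).astype(bool)
    rt = warp_image(VolumetricImage(m.astype(np.uint8), comp.spacing,
                                    comp.origin), comp, order=0,
                    fill=0).values.astype(bool)
    denom = int(m.sum()) + int(rt.sum())
    if denom == 0:
        raise ValueError("both masks empty")
    return float(2.0 * np.sum(m & rt) / denom)


def jacobian_determinant(disp: DisplacementField) -> np.ndarray:
    """det(I + du/dx) per voxel (central differences, mm; one-sided at
    the boundary)."""
    grad = np.empty(disp.shape + (3, 3))
    for c in range(3):
        gx, gy, gz = np.gradient(disp.vectors[..., c], *disp.spacing)
        grad[..., c, 0] = gx
        grad[..., c, 1] = gy
        grad[..., c, 2] = gz
    grad[..., 0, 0] += 1.0
    grad[..., 1, 1] += 1.0
    grad[..., 2, 2] += 1.0
    return np.linalg.det(grad)


def folding_fraction(jac: np.ndarray, omega: RegionOfInterest) -> float:
    """Percentage of Omega voxels with negative Jacobian determinant."""
    return float(100.0 * np.sum(jac[omega.omega] < 0) / omega.voxel_count)


def template_voxel_stats(warped_images: list, template: VolumetricImage
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-wise median, IQR (P75 - P25, linear quantiles) and mean
    absolute error of registered images in a template space."""
    if not warped_images:
        raise ValueError("template_voxel_stats needs at least one image")
    stack = np.stack([np.asarray(getattr(w, "values", w), dtype=float)
                      for w in warped_images])
    if stack.shape[1:] != template.shape:
        raise ValueError("images and template lattices differ")
    med = np.median(stack, axis=0)
    q75, q25 = np.percentile(stack, [75, 25], axis=0)
    mae = np.mean(np.abs(stack - template.values.astype(float)), axis=0)
    return med, q75 - q25, mae


def evaluate_pair(image_i: VolumetricImage, image_j: VolumetricImage,
                  masks_i, masks_j, t_ij: DisplacementField,
                  t_ji: DisplacementField) -> ConsistencyReport:
    """Table-style metrics for one registered pair, both directions
    averaged.

    Omega for the ij direction is the body mask of image i (and vice
    versa); Dice is computed on adipose and lean masks of each image and
    averaged; folding is averaged over the forward and inverse transforms.
    """
    om_i = RegionOfInterest(masks_i.body)
    om_j = RegionOfInterest(masks_j.body)
    per = {
        "vme_ij": vme(t_ij, t_ji, om_i),
        "vme_ji": vme(t_ji, t_ij, om_j),
        "ime_ij": ime(image_i, t_ij, t_ji, om_i),
        "ime_ji": ime(image_j, t_ji, t_ij, om_j),
        "dice_adipose_i": composite_dice(masks_i.adipose, t_ij, t_ji),
        "dice_adipose_j": composite_dice(masks_j.adipose, t_ji, t_ij),
        "dice_lean_i": composite_dice(masks_i.lean, t_ij, t_ji),
        "dice_lean_j": composite_dice(masks_j.lean, t_ji, t_ij),
        "folding_ij": folding_fraction(jacobian_determinant(t_ij), om_j),
        "folding_ji": folding_fraction(jacobian_determinant(t_ji), om_i),
    }
    return ConsistencyReport(
        vme_mm=0.5 * (per["vme_ij"] + per["vme_ji"]),
        ime_hu=0.5 * (per["ime_ij"] + per["ime_ji"]),
        dice_adipose=0.5 * (per["dice_adipose_i"] + per["dice_adipose_j"]),
        dice_lean=0.5 * (per["dice_lean_i"] + per["dice_lean_j"]),
        folding_pct=0.5 * (per["folding_ij"] + per["folding_ji"]),
        per_direction=per,
    )
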