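"""CT pre-processing: the five masks and voxel-spacing harmonization.

From each CT scan five binary masks are derived for use as registration
channels and constraint sources: a body mask (largest connected component
above an air cut, hole-filled per axial slice, CT-table remnants removed
morphologically), three Hounsfield-window tissue masks (bone > +200 HU,
lean soft tissue -29..+150 HU, adipose -190..-30 HU), and an "inside SAT"
mask -- the body region strictly enclosed by the subcutaneous fat shell.

Before registering two scans, their voxel spacings are harmonized per axis
to the larger of the two whenever they differ by more than eps = 0.1 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import MaskSet, VolumetricImage, world_points

__all__ = [
    "TissueThresholds",
    "ResamplePolicy",
    "make_body_mask",
    "make_tissue_masks",
    "make_inside_sat_mask",
    "make_mask_set",
    "harmonize_spacing",
    "resample_to_spacing",
    "fat_percentage",
]


@dataclass(frozen=True)
class TissueThresholds:
    """HU windows of the three tissue classes plus the body-mask air cut.

    Window endpoints are inclusive; bone is a strict lower bound.
    """

    bone_min: float = 200.0
    lean_lo: float = -29.0
    lean_hi: float = 150.0
    adipose_lo: float = -190.0
    adipose_hi: float = -30.0
    body_air_cut: float = -500.0

    def __post_init__(self):
        if not (self.adipose_hi < self.lean_lo and self.lean_hi < self.bone_min):
            raise ValueError("tissue windows must be ordered and disjoint")


@dataclass(frozen=True)
class ResamplePolicy:
    epsilon_mm: float = 0.1

    def __post_init__(self):
        if self.epsilon_mm <= 0:
            raise ValueError("epsilon_mm must be positive")


def make_body_mask(image: VolumetricImage,
                   thresholds: TissueThresholds = TissueThresholds()) -> np.ndarray:
    """Body mask: thresholded largest component, slice-wise hole fill.

    Thin table-like objects are detached by a one-voxel morphological
    opening before component selection; the body itself is kept unshaved by
    selecting, from the raw threshold mask, the component that contains the
    largest opened component.  Axial holes (lungs, bowel gas) are filled
    per slice so the body mask is solid.
    """
    raw = image.values > thresholds.body_air_cut
    if not raw.any():
        raise ValueError("no body found: image is entirely below the air cut")
    opened = ndi.binary_opening(raw, structure=ndi.generate_binary_structure(3, 1))
    seed = opened if opened.any() else raw
    lab_seed, n_seed = ndi.label(seed)
    largest = np.argmax(ndi.sum_labels(seed, lab_seed, range(1, n_seed + 1))) + 1
    lab_raw, _ = ndi.label(raw)
    body_labels = np.unique(lab_raw[(lab_seed == largest)])
    body = np.isin(lab_raw, body_labels[body_labels > 0])
    for k in range(body.shape[2]):
        body[:, :, k] = ndi.binary_fill_holes(body[:, :, k])
    if not body.any():
        raise ValueError("no body found after table removal")
    return body


def make_tissue_masks(image: VolumetricImage, thresholds: TissueThresholds,
                      body: np.ndarray) -> MaskSet:
    """Threshold the CT into bone/lean/adipose inside the body mask.

    The inside-SAT entry is left empty; use :func:`make_inside_sat_mask`
    (or :func:`make_mask_set`) to complete the set.
    """
    hu = image.values
    bone = body & (hu > thresholds.bone_min)
    lean = body & (hu >= thresholds.lean_lo) & (hu <= thresholds.lean_hi)
    adipose = body & (hu >= thresholds.adipose_lo) & (hu <= thresholds.adipose_hi)
    return MaskSet(body=body, bone=bone, lean=lean, adipose=adipose,
                   inside_sat=np.zeros_like(body))


def _slice_inside_sat(body2d: np.ndarray, adipose2d: np.ndarray) -> np.ndarray:
    """Interior-of-shell computation for one axial slice."""
    out = np.zeros_like(body2d)
    lab_b, n_b = ndi.label(body2d)
    for bi in range(1, n_b + 1):
        part = lab_b == bi
        ring = part & ~ndi.binary_erosion(part)
        sat = adipose2d & part
        lab_s, n_s = ndi.label(sat)
        if n_s:
            near_ring = np.unique(lab_s[ndi.binary_dilation(ring) & sat])
            shell = np.isin(lab_s, near_ring[near_ring > 0])
        else:
            shell = np.zeros_like(part)
        cand = part & ~shell
        lab_c, n_c = ndi.label(cand)
        best, best_size = 0, 0
        for ci in range(1, n_c + 1):
            comp = lab_c == ci
            if (comp & ring).any():     # touches the body boundary: not enclosed
                continue
            size = int(comp.sum())
            if size > best_size:
                best, best_size = ci, size
        if best:
            out |= lab_c == best
        elif part.any():                 # no closed shell on this slice: fall back
            out |= ndi.binary_erosion(part, iterations=2)
    return out


def make_inside_sat_mask(masks: MaskSet) -> np.ndarray:
    """Body region strictly enclosed by the subcutaneous adipose shell.

    Per axial slice and per body component: the adipose component(s)
    adjacent to the body boundary form the SAT shell; the largest interior
    component not touching the boundary is the inside-SAT region.  Slices
    without a closed shell fall back to an eroded body.
    """
    inside = np.zeros_like(masks.body)
    for k in range(masks.body.shape[2]):
        if masks.body[:, :, k].any():
            inside[:, :, k] = _slice_inside_sat(masks.body[:, :, k],
                                                masks.adipose[:, :, k])
    return inside


def make_mask_set(image: VolumetricImage,
                  thresholds: TissueThresholds = TissueThresholds()) -> MaskSet:
    """Full five-mask pre-processing of one CT scan."""
    body = make_body_mask(image, thresholds)
    masks = make_tissue_masks(image, thresholds, body)
    masks.inside_sat = make_inside_sat_mask(masks)
    return masks


def resample_to_spacing(image: VolumetricImage, new_spacing,
                        order: int = 1, fill=None) -> VolumetricImage:
    """Resample onto a lattice with the given spacing (same origin/extent)."""
    new_spacing = np.asarray(new_spacing, dtype=float)
    if np.allclose(new_spacing, image.spacing):
        return image
    extent = (np.asarray(image.shape) - 1) * image.spacing
    new_shape = np.maximum(np.floor(extent / new_spacing + 1e-9).astype(int) + 1, 2)
    pts = world_points(tuple(new_shape), new_spacing, image.origin)
    vals = image.sample_world(pts, order=order, fill=fill)
    if order == 0:
        vals = vals.astype(image.values.dtype)
    return VolumetricImage(vals, new_spacing, image.origin)


def harmonize_spacing(a: VolumetricImage, b: VolumetricImage,
                      policy: ResamplePolicy = ResamplePolicy()
                      ) -> tuple[VolumetricImage, VolumetricImage]:
    """Resample both images to the larger voxel spacing, per axis.

    An axis is only touched when the spacing difference exceeds the policy
    tolerance; untouched inputs are returned as-is (bit-identical).
    """
    target = np.where(np.abs(a.spacing - b.spacing) > policy.epsilon_mm,
                      np.maximum(a.spacing, b.spacing), np.nan)
    out = []
    for img in (a, b):
        sp = np.where(np.isnan(target), img.spacing, target)
        out.append(img if np.allclose(sp, img.spacing) else
                   resample_to_spacing(img, sp, order=1))
    return tuple(out)


def fat_percentage(image: VolumetricImage, masks: MaskSet) -> float:
    """Adipose fraction of the body mask (surrogate of fat body mass)."""
    n_body = int(masks.body.sum())
    if n_body == 0:
        raise ValueError("empty body mask")
    return float((masks.adipose & masks.body).sum() / n_body)
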