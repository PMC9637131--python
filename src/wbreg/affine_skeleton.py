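"""Piece-wise affine registration of the skeleton.

The skeleton is aligned first because bone is rigid and sparse: a global
no-shear affine fit of the torso bone mask initializes five subregion
refinements (right arm, head, left arm, chest, pelvis), whose transforms
are blended into one smooth displacement field with Gaussian weights.
That field initializes the first deformable step of the pipeline.

The affine model has exactly nine free parameters -- translation, Euler
rotation (x->y->z order, about the region centroid) and per-axis scale --
with no shear terms.  The similarity metric is the sum of squared
differences between the (linearly interpolated) warped source bone mask
and the target bone mask, optimized coarse-to-fine over pyramid levels
4 -> 2 by Powell's method with a center-of-mass multi-start at the
coarsest level.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.optimize import minimize

from .core import DisplacementField, VolumetricImage, downsample_volume, world_points

__all__ = [
    "NoShearAffine",
    "SubregionSet",
    "affine_register",
    "split_subregions",
    "blend_piecewise",
    "piecewise_affine_field",
]

SUBREGION_NAMES = ("right_arm", "head", "left_arm", "chest", "pelvis")


@dataclass
class NoShearAffine:
    """Nine-parameter affine: translation (mm), rotation (deg), scale.

    The point map is ``A(x) = C + R S (x - C) + t`` with rotation applied
    after per-axis scaling, both about the center ``C``; there are no shear
    terms.
    """

    translation: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = dfield(default_factory=lambda: np.ones(3))
    center: np.ndarray = dfield(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float).copy()
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).copy()
        self.scale = np.asarray(self.scale, dtype=float).copy()
        self.center = np.asarray(self.center, dtype=float).copy()
        if np.any(self.scale <= 0):
            raise ValueError("scale components must be positive")

    @property
    def matrix(self) -> np.ndarray:
        a, b, c = np.deg2rad(self.rotation_deg)
        ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
        Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        Rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx @ np.diag(self.scale)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        return self.apply(pts) - np.asarray(pts, dtype=float)

    def to_params(self) -> np.ndarray:
        # scale enters the optimizer in log space so it stays positive
        return np.concatenate([self.translation, self.rotation_deg, np.log(self.scale)])

    def with_params(self, p: np.ndarray) -> "NoShearAffine":
        return NoShearAffine(p[:3].copy(), p[3:6].copy(), np.exp(p[6:9]),
                             self.center.copy())


@dataclass
class SubregionSet:
    """Index-space boxes of the five skeletal subregions plus the torso.

    Each box is a pair (lo, hi) of inclusive/exclusive voxel bounds; boxes
    of anatomy missing from the field of view are ``None``.
    """

    boxes: dict
    torso: tuple

    def names(self):
        return [n for n in SUBREGION_NAMES if self.boxes.get(n) is not None]


def _ssd(params, template: NoShearAffine, src: VolumetricImage,
         tgt_vals: np.ndarray, pts: np.ndarray) -> float:
    aff = template.with_params(params)
    warped = src.sample_world(aff.apply(pts), order=1, fill=0.0)
    return float(np.mean((warped - tgt_vals) ** 2))


def _level_image(img: VolumetricImage, level: int) -> VolumetricImage:
    f = 2 ** level
    return VolumetricImage(downsample_volume(img.values, f),
                           img.spacing * f, img.origin)


def _center_of_mass(img: VolumetricImage) -> np.ndarray:
    w = np.maximum(img.values, 0.0)
    tot = w.sum()
    if tot == 0:
        return img.index_to_world((np.asarray(img.shape) - 1) / 2.0)
    idx = np.array([np.sum(w * np.arange(n).reshape([-1 if a == i else 1 for i in range(3)]))
                    for a, n in enumerate(img.shape)]) / tot
    return img.index_to_world(idx)


#: (image pyramid level, cost-lattice stride) stages, coarse to fine.  The
#: terminal stage keeps the level-2 cost lattice (stride 2 of level 1) but
#: evaluates sharper level-1 images: heavy pyramid blur does not commute
#: with affine scaling and would bias the recovered scale.
DEFAULT_STAGES = ((4, 1), (3, 1), (1, 2))


def _stage_cost_data(mask_img: VolumetricImage, level: int, stride: int,
                     roi_box):
    lvl = _level_image(mask_img, level)
    f = 2 ** level
    if roi_box is not None:
        lo = np.maximum(np.asarray(roi_box[0]) // f, 0)
        hi = np.minimum(-(-np.asarray(roi_box[1]) // f), np.asarray(lvl.shape))
    else:
        lo = np.zeros(3, int)
        hi = np.asarray(lvl.shape)
    sl = tuple(slice(a, b, stride) for a, b in zip(lo, hi))
    vals = lvl.values[sl]
    pts = world_points(vals.shape, lvl.spacing * stride,
                       lvl.origin + lo * lvl.spacing)
    return lvl, vals.reshape(-1), pts.reshape(-1, 3)


def affine_register(source_mask: VolumetricImage, target_mask: VolumetricImage,
                    init: NoShearAffine | None = None,
                    stages: tuple = DEFAULT_STAGES,
                    roi_box: tuple | None = None,
                    capture_range: tuple[float, float, float] = (30.0, 15.0, 0.25),
                    min_roi_points: int = 48) -> NoShearAffine:
    """Fit a no-shear affine minimizing mask SSD, coarse to fine.

    ``source_mask``/``target_mask`` are binary (or fuzzy) bone-mask images
    on harmonized lattices; the returned transform maps target-frame
    points to source-frame points (pull-back convention).  ``roi_box``
    restricts the cost to an index box of the target lattice.

    ``capture_range`` bounds the search around the initialization
    (translation mm, rotation deg, log-scale); sparse featureless bone
    masks otherwise admit degenerate optima (e.g. scale collapse onto a
    bone-dense spot).  Stages whose ROI holds fewer than
    ``min_roi_points`` cost samples are skipped.  The result never has a
    higher cost than ``init`` at the terminal stage.
    """
    if not np.asarray(source_mask.values).any() or not np.asarray(target_mask.values).any():
        raise ValueError("affine_register requires non-empty bone masks")
    if init is None:
        lo, hi = ((np.zeros(3, int), np.asarray(target_mask.shape)) if roi_box is None
                  else (np.asarray(roi_box[0]), np.asarray(roi_box[1])))
        center = target_mask.index_to_world((lo + hi - 1) / 2.0)
        init = NoShearAffine(center=center)
    best = init
    dt, drot, dlogs = capture_range
    p_init = init.to_params()
    bounds = list(zip(p_init - np.r_[[dt] * 3, [drot] * 3, [dlogs] * 3],
                      p_init + np.r_[[dt] * 3, [drot] * 3, [dlogs] * 3]))

    for si, (level, stride) in enumerate(stages):
        src_l = _level_image(source_mask, level)
        tgt_l, tgt_flat, pts = _stage_cost_data(target_mask, level, stride,
                                                roi_box)
        if pts.shape[0] < min_roi_points:
            continue

        def cost(p):
            return _ssd(p, best, src_l, tgt_flat, pts)

        starts = [best.to_params()]
        if si == 0:
            com_shift = _center_of_mass(src_l) - _center_of_mass(tgt_l)
            p = np.clip(np.r_[com_shift, best.to_params()[3:]],
                        [b[0] for b in bounds], [b[1] for b in bounds])
            starts.append(p)
        results = []
        for p0 in starts:
            res = minimize(cost, p0, method="Powell", bounds=bounds,
                           options={"xtol": 2e-4, "ftol": 1e-8, "maxiter": 60})
            results.append(res)
        res = min(results, key=lambda r: r.fun)
        if res.fun <= cost(best.to_params()):
            best = best.with_params(res.x)

    # descent guarantee at the terminal stage
    level, stride = stages[-1]
    src_f = _level_image(source_mask, level)
    _, tgt_flat_f, pts_f = _stage_cost_data(target_mask, level, stride, roi_box)
    if _ssd(best.to_params(), best, src_f, tgt_flat_f, pts_f) > _ssd(
            init.to_params(), init, src_f, tgt_flat_f, pts_f):
        best = init
    return best


def split_subregions(bone_mask: np.ndarray, body_mask: np.ndarray,
                     spacing) -> SubregionSet:
    """Locate the five skeletal subregion boxes from mask geometry.

    The torso lateral extent is read from the body width at a low torso
    level (arms-up images have no arms there); bone lateral of it forms the
    arm regions.  The shoulder line is the widest gap in the central bone
    z-profile's upper half; central bone above it is the head, below it is
    split at mid-height into chest and pelvis.
    """
    bone_idx = np.argwhere(bone_mask)
    if bone_idx.size == 0:
        raise ValueError("empty bone mask")
    zs = np.argwhere(body_mask.any(axis=(0, 1))).ravel()
    z_low = int(zs[0] + 0.25 * (zs[-1] - zs[0]))
    xs = np.argwhere(body_mask[:, :, z_low].any(axis=1)).ravel()
    if xs.size == 0:
        xs = np.argwhere(body_mask.any(axis=(1, 2))).ravel()
    x_lo, x_hi = int(xs[0]) - 1, int(xs[-1]) + 1

    central = bone_idx[(bone_idx[:, 0] >= x_lo) & (bone_idx[:, 0] <= x_hi)]
    right = bone_idx[bone_idx[:, 0] < x_lo]
    left = bone_idx[bone_idx[:, 0] > x_hi]

    def bbox(idx, pad=1):
        if idx.shape[0] == 0:
            return None
        lo = np.maximum(idx.min(axis=0) - pad, 0)
        hi = np.minimum(idx.max(axis=0) + pad + 1, np.asarray(bone_mask.shape))
        return (lo, hi)

    # shoulder line: largest empty run in the central-bone z histogram
    zc = np.zeros(bone_mask.shape[2], bool)
    zc[np.unique(central[:, 2])] = True
    z0, z1 = np.argwhere(zc).ravel()[[0, -1]]
    gaps, start = [], None
    for z in range(z0, z1 + 1):
        if not zc[z] and start is None:
            start = z
        elif zc[z] and start is not None:
            gaps.append((z - start, start, z))
            start = None
    upper = [g for g in gaps if g[1] > z0 + (z1 - z0) // 2]
    if upper:
        glen, gs, ge = max(upper)
        z_shoulder = (gs + ge) // 2
    else:
        z_shoulder = int(z0 + 0.75 * (z1 - z0))

    head = central[central[:, 2] >= z_shoulder]
    trunk = central[central[:, 2] < z_shoulder]
    z_mid = int((trunk[:, 2].min() + z_shoulder) / 2) if trunk.shape[0] else z_shoulder
    chest = trunk[trunk[:, 2] >= z_mid] if trunk.shape[0] else trunk
    pelvis = trunk[trunk[:, 2] < z_mid] if trunk.shape[0] else trunk

    boxes = {
        "right_arm": bbox(right),
        "left_arm": bbox(left),
        "head": bbox(head),
        "chest": bbox(chest),
        "pelvis": bbox(pelvis),
    }
    torso = bbox(central if central.shape[0] else bone_idx)
    return SubregionSet(boxes=boxes, torso=torso)


def blend_piecewise(transforms: dict, regions: SubregionSet,
                    lattice: VolumetricImage, sigma_blend_mm: float = 30.0
                    ) -> DisplacementField:
    """Gaussian-blended piece-wise affine displacement field.

    Per voxel the displacement is the normalized Gaussian-weighted sum of
    each subregion transform's displacement; the weight is a Gaussian of
    the distance (mm) to the subregion box, so inside a box's core the own
    transform dominates and transitions are smooth.
    """
    names = [n for n in regions.names() if n in transforms]
    if not names:
        raise ValueError("blend_piecewise needs at least one transform")
    shape = lattice.shape
    pts = lattice.lattice_points()
    disp = np.zeros(shape + (3,))
    wsum = np.zeros(shape)
    for n in names:
        lo, hi = regions.boxes[n]
        lo_mm = lattice.index_to_world(lo)
        hi_mm = lattice.index_to_world(hi - 1)
        d = np.linalg.norm(np.maximum(lo_mm - pts, 0.0) + np.maximum(pts - hi_mm, 0.0),
                           axis=-1)
        w = np.exp(-0.5 * (d / sigma_blend_mm) ** 2) + 1e-290
        disp += w[..., None] * transforms[n].displacement(pts)
        wsum += w
    return DisplacementField(disp / wsum[..., None], lattice.spacing, lattice.origin)


def piecewise_affine_field(source_bone: VolumetricImage, target_bone: VolumetricImage,
                           source_body: np.ndarray, target_body: np.ndarray,
                           sigma_blend_mm: float = 30.0
                           ) -> tuple[DisplacementField, dict]:
    """Full skeleton initialization: torso fit, subregion refinements, blend.

    Returns the blended field on the target lattice and a report with the
    torso transform, the per-subregion transforms and the subregion boxes.
    Subregions without bone inherit the torso transform.
    """
    regions = split_subregions(target_bone.values > 0.5, target_body,
                               target_bone.spacing)
    torso_aff = affine_register(source_bone, target_bone, roi_box=regions.torso)
    transforms = {}
    for name in SUBREGION_NAMES:
        box = regions.boxes.get(name)
        if box is None:
            continue
        transforms[name] = affine_register(source_bone, target_bone,
                                           init=torso_aff, roi_box=box,
                                           capture_range=(15.0, 8.0, 0.12))
    field = blend_piecewise(transforms, regions, target_bone, sigma_blend_mm)
    report = {"torso": torso_aff, "subregions": transforms, "boxes": regions}
    return field, report
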