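"""End-to-end registration pipeline and cohort orchestration.

One pair registration runs five steps, locking already-aligned tissue
between steps so later steps cannot disturb it:

1. piece-wise affine skeleton alignment (initialization),
2. ``bone_deform``  -- channels CT (Pearson) + bone mask (SSD); bone
   voxels are then constrained,
3. ``soft1``        -- CT + inside-SAT mask + adipose mask; the outer
   boundary shell of the inside-SAT mask is then constrained,
4. ``soft2``        -- CT + lean mask + adipose mask; non-adipose tissue
   excluding the skin is then constrained,
5. ``sat``          -- body mask only, completing subcutaneous fat.

Constraint masks are derived from the *source* image's masks warped
through the field as it stands when the constraint is imposed, so the
locked set only ever grows.  Optional cost-function masking down-weights
lesion (MTV) neighborhoods in every data term.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .affine_skeleton import piecewise_affine_field
from .core import DisplacementField, MaskSet, VolumetricImage, warp_image
from .deformable import Channel, EnergyModel, solve_step
from .preprocess import fat_percentage

__all__ = [
    "StepSpec",
    "CostMaskConfig",
    "RegistrationOptions",
    "register_pair",
    "build_cost_mask",
    "run_cohort",
    "choose_template",
]

STEP_ORDER = ("bone_deform", "soft1", "soft2", "sat")

#: per-step channel recipes: (grid name, metric, weight)
STEP_CHANNELS = {
    "bone_deform": (("ct", "pearson", 1.0), ("bone", "ssd", 1.0)),
    "soft1": (("ct", "pearson", 1.0), ("inside_sat", "ssd", 1.0),
              ("adipose", "ssd", 1.0)),
    "soft2": (("ct", "pearson", 1.0), ("lean", "ssd", 1.0),
              ("adipose", "ssd", 1.0)),
    "sat": (("body", "ssd", 1.0),),
}

#: tissue-specific regularization weights (low elasticity = high weight)
DEFAULT_REG_WEIGHTS = {"bone": 1.0, "lean": 0.4, "adipose": 0.1, "air": 0.05}


@dataclass
class StepSpec:
    """One deformable step: channels, constraint rule, solver settings."""

    name: str
    channels: tuple
    move_step_vox: float = 2.0
    min_step_vox: float = 0.5
    max_sweeps: int = 20
    pyramid: tuple[int, int] = (4, 2)

    def __post_init__(self):
        if self.name not in STEP_ORDER:
            raise ValueError(f"unknown step {self.name!r}")


@dataclass
class CostMaskConfig:
    """Gaussian-softened lesion mask for cost-function masking."""

    mtv_mask: np.ndarray
    sigma_mm: float = 3.0

    def __post_init__(self):
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be positive")
        self.mtv_mask = np.asarray(self.mtv_mask).astype(bool)


@dataclass
class RegistrationOptions:
    """Pipeline defaults; every knob of the five steps in one place."""

    reg_weights: dict = dfield(default_factory=lambda: dict(DEFAULT_REG_WEIGHTS))
    sigma_blend_mm: float = 30.0
    pyramid: tuple[int, int] = (4, 2)
    move_step_vox: float = 2.0
    min_step_vox: float = 0.5
    max_sweeps: int = 20
    skin_shells: int = 2           # inner body shells counted as skin
    cost_mask_sigma_mm: float = 3.0
    keep_step_fields: bool = False   # snapshot the field after every step

    def steps(self) -> list[StepSpec]:
        return [StepSpec(name=n, channels=STEP_CHANNELS[n],
                         move_step_vox=self.move_step_vox,
                         min_step_vox=self.min_step_vox,
                         max_sweeps=self.max_sweeps, pyramid=self.pyramid)
                for n in STEP_ORDER]


def build_cost_mask(cfg: CostMaskConfig, spacing) -> np.ndarray:
    """Data-term weights in [0, 1]: ~0 inside lesions, 1 far away.

    The binary MTV is blurred with a 3 mm Gaussian (in physical units) and
    subtracted from one, so voxels near lesions contribute less to every
    matching term.
    """
    spacing = np.asarray(spacing, dtype=float)
    sigma_vox = cfg.sigma_mm / spacing
    soft = gaussian_filter(cfg.mtv_mask.astype(float), sigma=sigma_vox,
                           mode="nearest")
    return 1.0 - np.clip(soft, 0.0, 1.0)


def _mask_boundary(mask: np.ndarray) -> np.ndarray:
    """One-voxel (6-connectivity) outer boundary shell of a mask."""
    return mask & ~binary_erosion(mask)


def _grids(image: VolumetricImage, masks: MaskSet) -> dict:
    return {
        "ct": image.values.astype(float),
        "bone": masks.bone.astype(float),
        "lean": masks.lean.astype(float),
        "adipose": masks.adipose.astype(float),
        "inside_sat": masks.inside_sat.astype(float),
        "body": masks.body.astype(float),
    }


def _reg_weight_map(masks: MaskSet, weights: dict) -> np.ndarray:
    w = np.full(masks.body.shape, weights["air"], dtype=float)
    w[masks.adipose] = weights["adipose"]
    w[masks.lean] = weights["lean"]
    w[masks.bone] = weights["bone"]
    return w


def _warp_masks(masks: MaskSet, disp: DisplacementField) -> MaskSet:
    spacing = disp.spacing
    warped = {
        name: warp_image(VolumetricImage(m.astype(np.uint8), spacing),
                         disp, order=0, fill=0).values.astype(bool)
        for name, m in masks.items()
    }
    return MaskSet(**warped)


def register_pair(source: VolumetricImage, source_masks: MaskSet,
                  target: VolumetricImage, target_masks: MaskSet,
                  options: RegistrationOptions | None = None,
                  source_mtv: np.ndarray | None = None,
                  target_mtv: np.ndarray | None = None
                  ) -> tuple[DisplacementField, dict]:
    """Full five-step registration of a source scan onto a target scan.

    Inputs must be on harmonized lattices (see
    :func:`wbreg.preprocess.harmonize_spacing`).  Returns the final
    pull-back field on the target lattice (point map target -> source) and
    a report dict with per-step energy trajectories, wall times and the
    affine skeleton transforms.
    """
    options = options or RegistrationOptions()
    if source.shape != target.shape or not np.allclose(source.spacing,
                                                       target.spacing):
        raise ValueError("register_pair requires harmonized lattices")
    spacing, origin = target.spacing, target.origin
    report = {"steps": [], "energies": {}, "times": {}}

    t0 = time.perf_counter()
    src_bone = VolumetricImage(source_masks.bone.astype(float), spacing, origin)
    tgt_bone = VolumetricImage(target_masks.bone.astype(float), spacing, origin)
    field, affine_report = piecewise_affine_field(
        src_bone, tgt_bone, source_masks.body, target_masks.body,
        sigma_blend_mm=options.sigma_blend_mm)
    report["affine"] = affine_report
    report["times"]["affine"] = time.perf_counter() - t0
    report["steps"].append("affine")

    cost_mask = None
    if source_mtv is not None or target_mtv is not None:
        cost_mask = np.ones(target.shape)
        if target_mtv is not None:
            cost_mask *= build_cost_mask(
                CostMaskConfig(target_mtv, options.cost_mask_sigma_mm), spacing)

    src_grids = _grids(source, source_masks)
    tgt_grids = _grids(target, target_masks)
    locked = np.zeros(target.shape, dtype=bool)

    for step in options.steps():
        t0 = time.perf_counter()
        # source-derived maps follow the field as it stands before the step
        warped_src_masks = _warp_masks(source_masks, field)
        reg_map = _reg_weight_map(warped_src_masks, options.reg_weights)
        step_cost_mask = cost_mask
        if source_mtv is not None:
            warped_mtv = warp_image(
                VolumetricImage(source_mtv.astype(np.uint8), spacing, origin),
                field, order=0, fill=0).values.astype(bool)
            m = build_cost_mask(CostMaskConfig(warped_mtv,
                                               options.cost_mask_sigma_mm),
                                spacing)
            step_cost_mask = m if step_cost_mask is None else step_cost_mask * m

        channels = [Channel(source=src_grids[g], target=tgt_grids[g],
                            metric=metric, weight=wt,
                            fill=(-1000.0 if g == "ct" else 0.0))
                    for g, metric, wt in step.channels]
        model = EnergyModel(channels=channels, reg_weight_map=reg_map,
                            spacing=spacing, origin=origin,
                            constraint_mask=locked if locked.any() else None,
                            cost_mask=step_cost_mask,
                            move_step_vox=step.move_step_vox,
                            min_step_vox=step.min_step_vox,
                            max_sweeps=step.max_sweeps, pyramid=step.pyramid)
        prev_vectors = field.vectors.copy()
        elog: list = []
        field = solve_step(model, field, log=elog)
        if locked.any():    # constraint fidelity is bitwise at native scale
            field.vectors[locked] = prev_vectors[locked]
        report["energies"][step.name] = elog
        report["times"][step.name] = time.perf_counter() - t0
        report["steps"].append(step.name)
        if options.keep_step_fields:
            report.setdefault("fields", {})[step.name] = field.vectors.copy()
            report.setdefault("locked_before", {})[step.name] = locked.copy()

        # grow the locked set per the step's constraint rule
        warped_src_masks = _warp_masks(source_masks, field)
        if step.name == "bone_deform":
            locked = locked | warped_src_masks.bone
        elif step.name == "soft1":
            locked = locked | _mask_boundary(warped_src_masks.inside_sat)
        elif step.name == "soft2":
            body = warped_src_masks.body
            skin = body & ~binary_erosion(body, iterations=options.skin_shells)
            locked = locked | (body & ~warped_src_masks.adipose & ~skin)
    return field, report


def choose_template(fat_fractions: dict, neutral: dict | None = None) -> object:
    """Template subject: neutral positioning, fat fraction nearest the median.

    ``fat_fractions`` maps subject id -> fat fraction; ``neutral`` maps id
    -> bool (default: all neutral).  Ties go to the lower id.
    """
    ids = sorted(fat_fractions)
    if neutral is not None:
        ids = [i for i in ids if neutral.get(i, False)]
    if not ids:
        raise ValueError("no eligible (neutral) subject for template")
    med = float(np.median([fat_fractions[i] for i in ids]))
    return min(ids, key=lambda i: (abs(fat_fractions[i] - med), i))


def run_cohort(subjects: dict, template_id=None,
               options: RegistrationOptions | None = None,
               mtvs: dict | None = None) -> dict:
    """Register every subject to the template and back.

    ``subjects`` maps id -> (VolumetricImage, MaskSet) on a common
    lattice.  When ``template_id`` is None it is chosen by fat fraction.
    Returns {id: {"forward": field, "reverse": field, "report": ...}};
    per-subject failures are isolated under an "error" key.
    """
    if template_id is None:
        fats = {i: fat_percentage(img, m) for i, (img, m) in subjects.items()}
        template_id = choose_template(fats, {i: True for i in subjects})
    t_img, t_masks = subjects[template_id]
    mtvs = mtvs or {}
    out = {"template_id": template_id}
    for sid, (img, masks) in subjects.items():
        if sid == template_id:
            continue
        try:
            fwd, rep_f = register_pair(img, masks, t_img, t_masks, options,
                                       source_mtv=mtvs.get(sid),
                                       target_mtv=mtvs.get(template_id))
            rev, rep_r = register_pair(t_img, t_masks, img, masks, options,
                                       source_mtv=mtvs.get(template_id),
                                       target_mtv=mtvs.get(sid))
            out[sid] = {"forward": fwd, "reverse": rev,
                        "report": {"forward": rep_f, "reverse": rep_r}}
        except Exception as exc:   # isolate per-subject failures
            out[sid] = {"error": f"{type(exc).__name__}: {exc}"}
    return out
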