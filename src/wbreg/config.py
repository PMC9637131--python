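"""Declarative run configuration (YAML) with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .pipeline import DEFAULT_REG_WEIGHTS, RegistrationOptions

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every pipeline default in one serializable object.

    Unknown keys are rejected on load; a config round-trips losslessly
    through YAML.
    """

    seed: int = 0
    output_dir: str = "."
    # pre-processing
    bone_min_hu: float = 200.0
    lean_lo_hu: float = -29.0
    lean_hi_hu: float = 150.0
    adipose_lo_hu: float = -190.0
    adipose_hi_hu: float = -30.0
    body_air_cut_hu: float = -500.0
    resample_epsilon_mm: float = 0.1
    # affine skeleton
    sigma_blend_mm: float = 30.0
    # deformable
    reg_weights: dict = field(default_factory=lambda: dict(DEFAULT_REG_WEIGHTS))
    pyramid_start: int = 4
    pyramid_stop: int = 2
    move_step_vox: float = 2.0
    min_step_vox: float = 0.5
    max_sweeps: int = 20
    skin_shells: int = 2
    # cost-function masking and applications
    cost_mask_sigma_mm: float = 3.0
    volume_floor_q: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def registration_options(self) -> RegistrationOptions:
        return RegistrationOptions(
            reg_weights=dict(self.reg_weights),
            sigma_blend_mm=self.sigma_blend_mm,
            pyramid=(self.pyramid_start, self.pyramid_stop),
            move_step_vox=self.move_step_vox,
            min_step_vox=self.min_step_vox,
            max_sweeps=self.max_sweeps,
            skin_shells=self.skin_shells,
            cost_mask_sigma_mm=self.cost_mask_sigma_mm,
        )

    def thresholds(self):
        from .preprocess import TissueThresholds

        return TissueThresholds(
            bone_min=self.bone_min_hu, lean_lo=self.lean_lo_hu,
            lean_hi=self.lean_hi_hu, adipose_lo=self.adipose_lo_hu,
            adipose_hi=self.adipose_hi_hu, body_air_cut=self.body_air_cut_hu)
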