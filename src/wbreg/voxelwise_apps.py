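"""Voxel-wise cohort applications of the registration pipeline.

Two applications are supported, mirroring how a registered oncological
cohort is summarized in template space:

* **Tumor distribution maps** -- each subject's binary lesion (MTV) mask
  is transferred to the template space through the between-subject
  transform; voxel-wise occurrence counts normalized by cohort size give
  the percentage of subjects with tumor at each location.
* **Volume-change / tissue-loss maps** -- the Jacobian determinant of the
  within-subject (post-to-pre therapy) transform is the local volume
  change map; summed over the body it yields whole-body volume change.
  Subject maps transferred to template space and averaged (after flooring
  at q = 0.05 to correct for local folding) give the local average volume
  factor, whose reversed positive log is the average tissue-loss map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DisplacementField, VolumetricImage, warp_image
from .metrics import RegionOfInterest, jacobian_determinant

__all__ = [
    "DistributionMap",
    "VolumeChangeConfig",
    "mtv_to_template",
    "tumor_distribution",
    "volume_change_map",
    "whole_body_volume_change",
    "average_volume_factor",
    "tissue_loss_map",
]


@dataclass
class DistributionMap:
    """Voxel-wise tumor occurrence percentages over a cohort."""

    values: np.ndarray      # percent, in [0, 100]
    n_subjects: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")


@dataclass(frozen=True)
class VolumeChangeConfig:
    """Folding-correction floor applied before cohort averaging."""

    floor_q: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.floor_q < 1.0):
            raise ValueError("floor_q must lie in (0, 1)")


def mtv_to_template(mtv: np.ndarray,
                    template_to_subject: DisplacementField) -> np.ndarray:
    """Pull a subject-space MTV onto the template lattice (stays binary).

    ``template_to_subject`` is the field produced by registering the
    subject (source) to the template (target): it lives on the template
    lattice and maps template points into the subject frame, which is
    exactly the pull-back sampling needed here.
    """
    m = np.asarray(mtv).astype(np.uint8)
    out = warp_image(VolumetricImage(m, template_to_subject.spacing,
                                     template_to_subject.origin),
                     template_to_subject, order=0, fill=0)
    return out.values.astype(bool)


def tumor_distribution(warped_mtvs: list) -> DistributionMap:
    """Percentage of subjects with tumor occurrence per template voxel."""
    if not warped_mtvs:
        raise ValueError("tumor_distribution needs at least one MTV")
    stack = np.stack([np.asarray(m).astype(bool) for m in warped_mtvs])
    return DistributionMap(100.0 * stack.sum(axis=0) / stack.shape[0],
                           n_subjects=stack.shape[0])


def volume_change_map(within_field: DisplacementField) -> np.ndarray:
    """Local volume change: Jacobian determinant of the within-subject
    (post-to-pre) transform."""
    return jacobian_determinant(within_field)


def whole_body_volume_change(jac: np.ndarray, body: RegionOfInterest,
                             spacing) -> tuple[float, float]:
    """Whole-body volume change: (Delta V in mm^3, fractional change).

    Delta V sums (J - 1) times the voxel volume over body voxels; the
    fraction normalizes by the body volume.
    """
    voxel_volume = float(np.prod(np.asarray(spacing, dtype=float)))
    delta = float(np.sum(jac[body.omega] - 1.0) * voxel_volume)
    total = body.voxel_count * voxel_volume
    return delta, delta / total


def average_volume_factor(template_maps: list,
                          cfg: VolumeChangeConfig = VolumeChangeConfig()
                          ) -> np.ndarray:
    """Voxel-wise mean of template-space volume-change maps.

    Each map is floored at q before averaging, correcting for local
    folding (non-positive or tiny Jacobians).
    """
    if not template_maps:
        raise ValueError("average_volume_factor needs at least one map")
    stack = np.stack([np.maximum(np.asarray(m, dtype=float), cfg.floor_q)
                      for m in template_maps])
    return stack.mean(axis=0)


def tissue_loss_map(avg_map: np.ndarray) -> np.ndarray:
    """Average tissue loss: reversed log Jacobian, clamped at zero.

    L(x) = max(-log Jbar(x), 0): positive where tissue shrank on average.
    """
    avg_map = np.asarray(avg_map, dtype=float)
    if np.any(avg_map <= 0):
        raise ValueError("average volume factor must be positive (floor it)")
    return np.maximum(-np.log(avg_map), 0.0)
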