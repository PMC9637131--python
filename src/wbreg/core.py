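"""Shared grid containers for whole-body CT registration.

Everything in this package lives on axis-aligned rectilinear lattices:
``world = origin + index * spacing`` with 0-based indices, millimetre units,
and array axis order (x, y, z).  Three containers are shared by all modules:

``VolumetricImage``
    a scalar Hounsfield-unit grid plus spacing/origin,
``MaskSet``
    the five binary masks derived from one CT scan (body, bone, lean,
    adipose, inside-SAT),
``DisplacementField``
    a per-voxel 3-vector grid in mm; displacement fields are pull-back
    fields: warping samples the source image at ``x + u(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "VolumetricImage",
    "MaskSet",
    "DisplacementField",
    "world_axes",
    "world_points",
    "downsample_volume",
    "warp_image",
    "compose_fields",
]


def _as_vec3(x, dtype=float) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=dtype)).ravel()
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3:
        raise ValueError(f"expected a scalar or length-3 vector, got shape {v.shape}")
    return v.copy()


def world_axes(shape, spacing, origin) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis world coordinates (1-D arrays) of the voxel centers."""
    return tuple(
        origin[a] + spacing[a] * np.arange(shape[a], dtype=float) for a in range(3)
    )


def world_points(shape, spacing, origin) -> np.ndarray:
    """Dense (nx, ny, nz, 3) array of voxel-center world coordinates."""
    ax = world_axes(shape, spacing, origin)
    pts = np.empty(tuple(shape) + (3,), dtype=float)
    pts[..., 0] = ax[0][:, None, None]
    pts[..., 1] = ax[1][None, :, None]
    pts[..., 2] = ax[2][None, None, :]
    return pts


def _sample(values: np.ndarray, idx_pts: np.ndarray, order: int, fill) -> np.ndarray:
    """Interpolate ``values`` at fractional index coordinates (..., 3)."""
    idx_pts = np.asarray(idx_pts, dtype=float)
    if idx_pts.ndim == 1:
        return _sample(values, idx_pts[None], order, fill)[0]
    coords = np.moveaxis(idx_pts, -1, 0)
    if fill is None:
        return map_coordinates(values, coords, order=order, mode="nearest")
    return map_coordinates(values, coords, order=order, mode="grid-constant", cval=fill)


@dataclass
class VolumetricImage:
    """Scalar HU grid with voxel spacing and origin (both mm, per axis)."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VolumetricImage.values must be a 3-D array")
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(pts_mm, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def lattice_points(self) -> np.ndarray:
        return world_points(self.shape, self.spacing, self.origin)

    def sample_world(self, pts_mm: np.ndarray, order: int = 1, fill=None) -> np.ndarray:
        """Interpolate the image at world points; out-of-grid lookups clamp
        unless ``fill`` is given."""
        return _sample(self.values.astype(float, copy=False),
                       self.world_to_index(pts_mm), order, fill)

    def with_values(self, values: np.ndarray) -> "VolumetricImage":
        return replace(self, values=values)


@dataclass
class MaskSet:
    """The five binary masks of one CT scan.

    bone/lean/adipose are pairwise disjoint subsets of body; inside_sat is
    the body region enclosed by the subcutaneous fat shell (shell excluded).
    """

    body: np.ndarray
    bone: np.ndarray
    lean: np.ndarray
    adipose: np.ndarray
    inside_sat: np.ndarray

    _NAMES = ("body", "bone", "lean", "adipose", "inside_sat")

    def __post_init__(self):
        for name in self._NAMES:
            setattr(self, name, np.asarray(getattr(self, name)).astype(bool))
        shapes = {getattr(self, n).shape for n in self._NAMES}
        if len(shapes) != 1:
            raise ValueError("all masks must share one lattice")

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return ((n, getattr(self, n)) for n in self._NAMES)

    def validate(self) -> None:
        for name in ("bone", "lean", "adipose", "inside_sat"):
            if np.any(getattr(self, name) & ~self.body):
                raise ValueError(f"{name} mask is not contained in body")
        for a, b in (("bone", "lean"), ("bone", "adipose"), ("lean", "adipose")):
            if np.any(getattr(self, a) & getattr(self, b)):
                raise ValueError(f"{a} and {b} masks overlap")

    def tissue_class(self) -> np.ndarray:
        """Integer class map: 0 air/other, 1 adipose, 2 lean, 3 bone."""
        cls = np.zeros(self.body.shape, dtype=np.uint8)
        cls[self.adipose] = 1
        cls[self.lean] = 2
        cls[self.bone] = 3
        return cls


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm, world axes) on a lattice.

    The field is a pull-back map: the point map is ``x -> x + u(x)`` with
    ``u`` trilinearly interpolated; out-of-lattice lookups clamp to the
    boundary value.
    """

    vectors: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("DisplacementField.vectors must have shape (nx,ny,nz,3)")
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")

    @classmethod
    def zero(cls, shape, spacing, origin=(0.0, 0.0, 0.0)) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (3,)), spacing, origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def world_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(pts_mm, dtype=float) - self.origin) / self.spacing

    def lattice_points(self) -> np.ndarray:
        return world_points(self.shape, self.spacing, self.origin)

    def sample(self, pts_mm: np.ndarray) -> np.ndarray:
        """Trilinear displacement lookup at world points (clamped)."""
        idx = self.world_to_index(pts_mm)
        out = np.empty(np.asarray(pts_mm).shape, dtype=float)
        for c in range(3):
            out[..., c] = _sample(self.vectors[..., c], idx, order=1, fill=None)
        return out

    def point_map(self, pts_mm: np.ndarray) -> np.ndarray:
        return np.asarray(pts_mm, dtype=float) + self.sample(pts_mm)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))

    def resample_to(self, shape, spacing, origin) -> "DisplacementField":
        """Vector field on another lattice (trilinear, mm preserved)."""
        pts = world_points(shape, _as_vec3(spacing), _as_vec3(origin))
        return DisplacementField(self.sample(pts), spacing, origin)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy(), self.spacing, self.origin)


def warp_image(image: VolumetricImage, disp: DisplacementField,
               order: int = 1, fill=None) -> VolumetricImage:
    """Resample ``image`` through ``disp``: output(x) = image(x + u(x)).

    The output lives on the field's lattice.  ``order=0`` for masks/labels,
    ``order=1`` for intensities.  ``fill`` sets the out-of-grid value
    (default: clamp).
    """
    pts = disp.lattice_points() + disp.vectors
    vals = _sample(image.values.astype(float, copy=False),
                   image.world_to_index(pts), order, fill)
    if order == 0:
        vals = vals.astype(image.values.dtype)
    return VolumetricImage(vals, disp.spacing, disp.origin)


def compose_fields(first: DisplacementField, second: DisplacementField) -> DisplacementField:
    """Composite pull-back field: T(x) = x + u2(x) + u1(x + u2(x)).

    Applying the composite is equivalent to warping by ``second`` and then
    warping the result by ``first``; the output lives on second's lattice.
    """
    pts = second.lattice_points()
    u2 = second.vectors
    u1 = first.sample(pts + u2)
    return DisplacementField(u2 + u1, second.spacing, second.origin)


def downsample_volume(values: np.ndarray, factor: int, smooth: bool = True,
                      method: str = "gaussian") -> np.ndarray:
    """Downsample by ``factor`` per axis.

    ``method="gaussian"``: anti-alias filter then strided pick (images for
    coarse search).  ``method="mean"``: exact box average, which preserves
    partial-volume fractions of binary masks -- a sub-voxel boundary shift
    still changes the coarse value proportionally.
    """
    v = np.asarray(values, dtype=float)
    if factor == 1:
        return v.copy()
    if method == "mean":
        pad = [(0, (-n) % factor) for n in v.shape]
        v = np.pad(v, pad, mode="edge")
        nx, ny, nz = (n // factor for n in v.shape)
        return v.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))
    if smooth:
        v = gaussian_filter(v, sigma=factor / 3.0, mode="nearest")
    return v[::factor, ::factor, ::factor].copy()
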