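"""Synthetic whole-body CT phantoms with exact ground-truth deformations.

The phantoms are stylized (elliptical torso, tubular limbs, ellipsoidal
head), not anatomical: what matters for exercising the registration method
is the Hounsfield-unit class structure (air ~ -1000 HU, adipose -190..-30,
lean -29..+150, bone > +200), the topology (a closed subcutaneous fat shell
around a lean interior with an internal skeleton and air-filled lungs), and
an analytically known deformation between paired volumes.

Field of view mimics clinical whole-body PET-CT: mid-thigh to skull base,
arms up.  Two pair generators provide test substrates:

``make_between_pair``
    two subjects differing in fat-shell thickness, torso radius and
    skeletal pose; the truth map composes Gaussian-blended per-subregion
    rigid offsets with an exact ray-wise elliptical shell remap.
``make_longitudinal_pair``
    one subject before/after smooth therapy-related tissue loss; the
    contraction has a closed-form Jacobian determinant and its amplitude is
    calibrated so the imposed whole-body volume change is exact.

All randomness flows from the single integer seed of each spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .core import (
    DisplacementField,
    MaskSet,
    VolumetricImage,
    world_axes,
    world_points,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "make_between_pair",
    "make_longitudinal_pair",
    "between_cohort_specs",
    "longitudinal_cohort_params",
]

SUBREGIONS = ("right_arm", "head", "left_arm", "chest", "pelvis")

# Class base HU and clip windows (kept strictly inside the thresholds used
# for tissue segmentation so interior class purity is exact).
_CLASS_HU = {
    "air": (-1000.0, (-1100.0, -800.0)),
    "lung": (-880.0, (-1000.0, -750.0)),
    "adipose": (-110.0, (-189.0, -31.0)),
    "lean": (45.0, (-28.0, 149.0)),
    "bone": (420.0, (210.0, 1200.0)),
}


@dataclass
class PhantomSpec:
    """Geometry, acquisition and randomness parameters of one phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 128)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    fat_shell_mm: float = 12.0
    torso_radius_mm: float = 46.0   # lean-core radius; outer = core + fat shell
    skeleton_pose: dict = dfield(default_factory=dict)
    lesion_list: tuple = ()          # ((cx, cy, cz) mm, radius mm) pairs
    contrast_offset_hu: float = 0.0  # additive lean-tissue offset
    noise_sd_hu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in np.atleast_1d(self.grid_shape))
        sp = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if sp.size == 1:
            sp = np.repeat(sp, 3)
        self.spacing = tuple(float(s) for s in sp)

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be three axes, each >= 16")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on every axis")
        if self.fat_shell_mm < min(self.spacing):
            raise ValueError("fat_shell_mm must be at least one voxel")
        for key in self.skeleton_pose:
            if key not in SUBREGIONS:
                raise ValueError(f"unknown skeleton_pose subregion {key!r}")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")


@dataclass
class PhantomTruth:
    """A generated phantom pair plus its exact ground truth.

    ``true_field_ab`` is the pull-back field on image_b's lattice: warping
    image_a through it reproduces image_b (up to interpolation and noise).
    ``landmarks`` holds paired world coordinates (N, 2, 3): column 0 is the
    point in image_a, column 1 the matching point in image_b; pairs satisfy
    x_a = x_b + u(x_b) exactly for the stored field.
    """

    image_a: VolumetricImage
    image_b: VolumetricImage
    true_field_ab: DisplacementField
    landmarks: np.ndarray
    masks_a: MaskSet
    masks_b: MaskSet
    mtv_a: np.ndarray | None = None
    true_jacobian: np.ndarray | None = None   # det of the a->b point map on a's lattice
    shrink_fraction: float | None = None

    def landmark_error_mm(self, disp: DisplacementField | None = None) -> float:
        """Mean |phi(x_b) - x_a| for a candidate target->source field.

        With ``disp=None`` the identity is used, i.e. the pre-registration
        landmark distance.
        """
        xb = self.landmarks[:, 1]
        mapped = xb if disp is None else disp.point_map(xb)
        return float(np.mean(np.linalg.norm(mapped - self.landmarks[:, 0], axis=1)))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


class _Geometry:
    """Analytic a-frame geometry derived from a PhantomSpec (world mm)."""

    def __init__(self, spec: PhantomSpec):
        nx, ny, nz = spec.grid_shape
        sx, sy, sz = spec.spacing
        self.extent = np.array([nx * sx, ny * sy, nz * sz])
        self.cx, self.cy = self.extent[0] / 2.0, self.extent[1] / 2.0
        Lz = self.extent[2]
        self.Lz = Lz
        s = spec.fat_shell_mm
        self.shell = s
        # outer torso semi-axes = lean core + subcutaneous fat shell
        self.rx = spec.torso_radius_mm + s
        self.ry = 0.72 * spec.torso_radius_mm + s
        # z bands (mm)
        self.torso_z = (0.02 * Lz, 0.68 * Lz)
        self.neck_z = (0.64 * Lz, 0.80 * Lz)
        self.neck_r = 20.0
        self.head_c = np.array([self.cx, self.cy, 0.85 * Lz])
        self.head_r = np.array([26.0, 26.0, 0.09 * Lz])
        # arms-up: vertical lateral tubes joined by shoulder bridges
        self.arm_r = 14.0
        self.arm_x = 80.0
        self.arm_z = (0.70 * Lz, 0.96 * Lz)
        self.shoulder_c_z = 0.67 * Lz
        self.shoulder_r = np.array([28.0, 13.0, 13.0])
        # skeleton (vertebral/periodic radius modulation gives z texture)
        self.spine_c = (self.cx, self.cy + 18.0)
        self.spine_r = 9.0
        self.spine_z = (0.05 * Lz, 0.66 * Lz)
        self.pelvis_c = np.array([self.cx, self.cy + 4.0, 0.16 * Lz])
        self.pelvis_r = np.array([24.0, 14.0, 20.0])
        self.femur_x = 17.0
        self.femur_r = 7.0
        self.femur_z = (0.02 * Lz, 0.18 * Lz)
        skull_core = max(self.head_r[0] - s, 6.0)
        self.skull_r = max(0.75 * skull_core, 4.0)
        self.armbone_r = 4.5
        self.armbone_z = (0.72 * Lz, 0.92 * Lz)
        # lungs
        self.lung_dx = 0.30 * spec.torso_radius_mm
        self.lung_c_z = 0.50 * Lz
        self.lung_r = np.array([12.0, 14.0, 40.0])

    # --- primitive shape tests on broadcastable world coordinates ---------

    def _ellipse_rho(self, X, Y, rx, ry):
        return np.sqrt(((X - self.cx) / rx) ** 2 + ((Y - self.cy) / ry) ** 2)

    def torso(self, X, Y, Z, inset=0.0):
        rho = self._ellipse_rho(X, Y, self.rx - inset, self.ry - inset)
        return (rho <= 1.0) & (Z >= self.torso_z[0]) & (Z <= self.torso_z[1])

    def neck(self, X, Y, Z, inset=0.0):
        r = max(self.neck_r - inset, 4.0)
        d = np.sqrt((X - self.cx) ** 2 + (Y - (self.cy + 4.0)) ** 2)
        return (d <= r) & (Z >= self.neck_z[0]) & (Z <= self.neck_z[1])

    def head(self, X, Y, Z, inset=0.0):
        r = np.maximum(self.head_r - inset, 5.0)
        d = (((X - self.head_c[0]) / r[0]) ** 2
             + ((Y - self.head_c[1]) / r[1]) ** 2
             + ((Z - self.head_c[2]) / r[2]) ** 2)
        return d <= 1.0

    def arm(self, X, Y, Z, side, inset=0.0):
        r = max(self.arm_r - inset, 5.0)
        d = np.sqrt((X - (self.cx + side * self.arm_x)) ** 2 + (Y - self.cy) ** 2)
        return (d <= r) & (Z >= self.arm_z[0]) & (Z <= self.arm_z[1])

    def shoulder(self, X, Y, Z, side, inset=0.0):
        r = np.maximum(self.shoulder_r - inset, 5.0)
        d = (((X - (self.cx + side * 58.0)) / r[0]) ** 2
             + ((Y - self.cy) / r[1]) ** 2
             + ((Z - self.shoulder_c_z) / r[2]) ** 2)
        return d <= 1.0

    def body(self, X, Y, Z, inset=0.0):
        m = self.torso(X, Y, Z, inset) | self.neck(X, Y, Z, inset) | self.head(X, Y, Z, inset)
        for side in (-1.0, 1.0):
            m |= self.arm(X, Y, Z, side, inset)
            m |= self.shoulder(X, Y, Z, side, inset)
        return m

    def bone(self, X, Y, Z):
        # vertebra-like periodic radius modulation breaks the z-translation
        # degeneracy of featureless tubes
        r_sp = self.spine_r * (0.72 + 0.28 * np.cos(2 * np.pi * Z / 26.0))
        d_sp = np.sqrt((X - self.spine_c[0]) ** 2 + (Y - self.spine_c[1]) ** 2)
        m = (d_sp <= r_sp) & (Z >= self.spine_z[0]) & (Z <= self.spine_z[1])
        d_pv = (((X - self.pelvis_c[0]) / self.pelvis_r[0]) ** 2
                + ((Y - self.pelvis_c[1]) / self.pelvis_r[1]) ** 2
                + ((Z - self.pelvis_c[2]) / self.pelvis_r[2]) ** 2)
        m |= d_pv <= 1.0
        r_ab = self.armbone_r * (0.75 + 0.25 * np.cos(2 * np.pi * Z / 34.0))
        for side in (-1.0, 1.0):
            d_fm = np.sqrt((X - (self.cx + side * self.femur_x)) ** 2 + (Y - self.cy) ** 2)
            r_fm = self.femur_r * (0.8 + 0.2 * np.cos(2 * np.pi * Z / 30.0))
            m |= (d_fm <= r_fm) & (Z >= self.femur_z[0]) & (Z <= self.femur_z[1])
            d_ab = np.sqrt((X - (self.cx + side * self.arm_x)) ** 2 + (Y - self.cy) ** 2)
            m |= (d_ab <= r_ab) & (Z >= self.armbone_z[0]) & (Z <= self.armbone_z[1])
        d_sk = np.sum(((np.stack(np.broadcast_arrays(X, Y, Z), axis=-1)
                        - self.head_c) / self.skull_r) ** 2, axis=-1)
        m |= d_sk <= 1.0
        return m

    def lungs(self, X, Y, Z):
        m = np.zeros(np.broadcast_shapes(np.shape(X), np.shape(Y), np.shape(Z)), bool)
        for side in (-1.0, 1.0):
            d = (((X - (self.cx + side * self.lung_dx)) / self.lung_r[0]) ** 2
                 + ((Y - (self.cy - 6.0)) / self.lung_r[1]) ** 2
                 + ((Z - self.lung_c_z) / self.lung_r[2]) ** 2)
            m |= d <= 1.0
        return m

    # --- landmark/subregion anchors ---------------------------------------

    def landmark_points(self) -> np.ndarray:
        pts = [
            (self.spine_c[0], self.spine_c[1], 0.5 * sum(self.spine_z)),
            tuple(self.pelvis_c),
            tuple(self.head_c),
            (self.cx + self.lung_dx, self.cy - 6.0, self.lung_c_z),
            (self.cx - self.lung_dx, self.cy - 6.0, self.lung_c_z),
        ]
        for side in (-1.0, 1.0):
            pts.append((self.cx + side * self.femur_x, self.cy, 0.5 * sum(self.femur_z)))
            pts.append((self.cx + side * self.arm_x, self.cy, 0.5 * sum(self.armbone_z)))
        # mid-shell rings at two torso levels
        for zf in (0.15, 0.45):
            z = zf * self.Lz
            for th in np.linspace(0.0, 2 * np.pi, 8, endpoint=False):
                pts.append((self.cx + (self.rx - self.shell / 2) * np.cos(th),
                            self.cy + (self.ry - self.shell / 2) * np.sin(th), z))
        return np.asarray(pts, dtype=float)

    def subregion_boxes(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Approximate world-mm bounding boxes of the five skeletal subregions."""
        z_sh = 0.74 * self.Lz   # between spine top and skull bottom
        z_mid = 0.5 * (self.torso_z[0] + z_sh)
        lo_t = np.array([self.cx - self.rx, self.cy - self.ry, 0.0])
        hi_t = np.array([self.cx + self.rx, self.cy + self.ry, z_sh])
        boxes = {
            "head": (np.array([self.head_c[0] - self.head_r[0],
                               self.head_c[1] - self.head_r[1],
                               self.head_c[2] - self.head_r[2]]),
                     np.array([self.head_c[0] + self.head_r[0],
                               self.head_c[1] + self.head_r[1],
                               self.head_c[2] + self.head_r[2]])),
            "chest": (np.array([lo_t[0], lo_t[1], z_mid]), np.array([hi_t[0], hi_t[1], z_sh])),
            "pelvis": (lo_t, np.array([hi_t[0], hi_t[1], z_mid])),
        }
        for name, side in (("right_arm", -1.0), ("left_arm", 1.0)):
            x0 = self.cx + side * (self.arm_x - self.arm_r)
            x1 = self.cx + side * (self.arm_x + self.arm_r)
            boxes[name] = (np.array([min(x0, x1), self.cy - self.arm_r, self.arm_z[0]]),
                          np.array([max(x0, x1), self.cy + self.arm_r, self.arm_z[1]]))
        return boxes


def _synthesize(spec: PhantomSpec, table: bool = False):
    """Noiseless base image + ground-truth masks for one spec."""
    spec.validate()
    geo = _Geometry(spec)
    ax = world_axes(spec.grid_shape, np.asarray(spec.spacing), np.zeros(3))
    X, Y, Z = ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :]

    body = geo.body(X, Y, Z)
    interior = geo.body(X, Y, Z, inset=spec.fat_shell_mm)
    shell = body & ~interior
    bone = geo.bone(X, Y, Z) & interior
    lung = geo.lungs(X, Y, Z) & interior & ~bone
    lean = interior & ~bone & ~lung

    base = np.full(spec.grid_shape, _CLASS_HU["air"][0], dtype=float)
    base[lung] = _CLASS_HU["lung"][0]
    base[shell] = _CLASS_HU["adipose"][0]
    base[lean] = _CLASS_HU["lean"][0] + spec.contrast_offset_hu
    base[bone] = _CLASS_HU["bone"][0]

    mtv = None
    if spec.lesion_list:
        mtv = np.zeros(spec.grid_shape, bool)
        for center, radius in spec.lesion_list:
            c = np.asarray(center, dtype=float)
            d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
            mtv |= d <= radius
        mtv &= lean
        base[mtv] = 70.0 + spec.contrast_offset_hu

    if table:
        # CT-table analog: a thin slab under the body, separated by a gap
        y_lo = geo.cy + geo.ry + 2.5 * spec.spacing[1]
        slab = (Y >= y_lo) & (Y <= y_lo + 2.0 * spec.spacing[1]) & (Z >= 0) & (Z <= geo.Lz)
        slab = slab & np.ones_like(body)
        base[slab & ~body] = 150.0

    masks = MaskSet(body=body, bone=bone, lean=lean, adipose=shell, inside_sat=interior)
    return base, masks, mtv, geo


def _apply_noise(base: np.ndarray, masks: MaskSet, lung_hint: np.ndarray | None,
                 spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Partial-volume smoothing + clipped class noise (purity-preserving)."""
    img = gaussian_filter(base, sigma=0.35, mode="nearest")
    if spec.noise_sd_hu > 0:
        img = img + rng.normal(0.0, spec.noise_sd_hu, size=base.shape)
    cls = masks.tissue_class()
    lo, hi = _CLASS_HU["air"][1]
    out = np.clip(img, lo, hi)
    windows = {1: "adipose", 2: "lean", 3: "bone"}
    for ci, name in windows.items():
        lo, hi = _CLASS_HU[name][1]
        sel = cls == ci
        out[sel] = np.clip(img[sel], lo, hi)
    if lung_hint is not None:
        lo, hi = _CLASS_HU["lung"][1]
        out[lung_hint] = np.clip(img[lung_hint], lo, hi)
    return out.astype(np.float32)


def generate_phantom(spec: PhantomSpec, table: bool = False
                     ) -> tuple[VolumetricImage, MaskSet]:
    """Build one phantom image plus its ground-truth mask set.

    The returned masks are the exact class map used to paint the image, not
    a re-thresholding of it.
    """
    base, masks, _, _ = _synthesize(spec, table=table)
    lung = (base > -950) & (base < -800)
    rng = np.random.default_rng(spec.seed)
    img = VolumetricImage(_apply_noise(base, masks, lung, spec, rng),
                          np.asarray(spec.spacing))
    return img, masks


# ---------------------------------------------------------------------------
# ground-truth maps
# ---------------------------------------------------------------------------


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _rot_mat(deg: np.ndarray) -> np.ndarray:
    a, b, c = np.deg2rad(np.asarray(deg, dtype=float))
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _blended_rigid_map(pose: dict, boxes: dict, sigma: float = 15.0) -> Callable:
    """Gaussian-blended piece-wise rigid map of world points (N,3)->(N,3)."""
    names = [n for n in SUBREGIONS if n in boxes]
    mats, trans, centers, lods, hids = [], [], [], [], []
    for n in names:
        lo, hi = boxes[n]
        rot, t = pose.get(n, ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)))
        mats.append(_rot_mat(np.asarray(rot)))
        trans.append(np.asarray(t, dtype=float))
        centers.append(0.5 * (lo + hi))
        lods.append(lo)
        hids.append(hi)

    def apply(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        disp = np.zeros_like(pts)
        wsum = np.zeros(pts.shape[:-1])
        for M, t, c, lo, hi in zip(mats, trans, centers, lods, hids):
            d = np.linalg.norm(np.maximum(lo - pts, 0) + np.maximum(pts - hi, 0), axis=-1)
            w = np.exp(-0.5 * (d / sigma) ** 2) + 1e-290
            u = (pts - c) @ M.T + c + t - pts
            disp += w[..., None] * u
            wsum += w
        return pts + disp / wsum[..., None]

    return apply


def _shell_remap(geo_b: _Geometry, geo_a: _Geometry) -> Callable:
    """Exact ray-wise elliptical remap sending b-frame torso radii to a-frame.

    Along each ray from the torso axis the interior [0, R_in] and shell
    [R_in, R_out] intervals of geometry b are mapped linearly onto those of
    geometry a; outside the body the offset decays exponentially (20 mm
    scale) so the map stays monotone and bounded.  A smooth z-feather
    confines the remap to the torso band.
    """
    tau = 20.0

    def apply(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        x = pts[..., 0] - geo_b.cx
        y = pts[..., 1] - geo_b.cy
        z = pts[..., 2]
        r = np.sqrt(x**2 + y**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_out = np.sqrt((x / geo_b.rx) ** 2 + (y / geo_b.ry) ** 2)
            rho_in = np.sqrt((x / (geo_b.rx - geo_b.shell)) ** 2
                             + (y / (geo_b.ry - geo_b.shell)) ** 2)
            R_out_b = np.where(rho_out > 0, r / rho_out, geo_b.rx)
            R_in_b = np.where(rho_in > 0, r / rho_in, geo_b.rx - geo_b.shell)
            rho_out_a = np.sqrt((x / geo_a.rx) ** 2 + (y / geo_a.ry) ** 2)
            rho_in_a = np.sqrt((x / (geo_a.rx - geo_a.shell)) ** 2
                               + (y / (geo_a.ry - geo_a.shell)) ** 2)
            R_out_a = np.where(rho_out_a > 0, r / rho_out_a, geo_a.rx)
            R_in_a = np.where(rho_in_a > 0, r / rho_in_a, geo_a.rx - geo_a.shell)
        r1 = np.where(r <= R_in_b,
                      r * R_in_a / np.maximum(R_in_b, 1e-9),
                      np.where(r <= R_out_b,
                               R_in_a + (r - R_in_b) * (R_out_a - R_in_a)
                               / np.maximum(R_out_b - R_in_b, 1e-9),
                               r + (R_out_a - R_out_b) * np.exp(-(r - R_out_b) / tau)))
        # z-feather: identity outside the torso band
        z0, z1 = geo_b.torso_z
        lam = (_smoothstep((z - z0) / 20.0) * _smoothstep((z1 + 6.0 - z) / 26.0))
        r_new = r + lam * (r1 - r)
        scale = np.where(r > 1e-9, r_new / np.maximum(r, 1e-9), 1.0)
        out = pts.copy()
        out[..., 0] = geo_b.cx + x * scale
        out[..., 1] = geo_b.cy + y * scale
        return out

    return apply


def _invert_pointwise(fn: Callable, targets: np.ndarray, n_iter: int = 40) -> np.ndarray:
    """Newton inversion of a smooth R^3 map at isolated points."""
    x = targets.copy().astype(float)
    h = 0.25
    for _ in range(n_iter):
        f = fn(x) - targets
        if np.max(np.abs(f)) < 1e-10:
            break
        J = np.empty(x.shape[:-1] + (3, 3))
        for c in range(3):
            dx = np.zeros(3)
            dx[c] = h
            J[..., :, c] = (fn(x + dx) - fn(x - dx)) / (2 * h)
        x = x - np.linalg.solve(J, f[..., None])[..., 0]
    return x


def _snap_landmarks(points_a: np.ndarray, psi: Callable,
                    disp: DisplacementField) -> np.ndarray:
    """Pair a-frame feature points with b-lattice voxel centers.

    The b-side point is the lattice voxel nearest to psi^-1(x_a); the a-side
    point is re-derived through the *stored* field so pairs are exactly
    consistent with it.
    """
    xb = _invert_pointwise(psi, points_a)
    idx = np.rint(disp.world_to_index(xb)).astype(int)
    idx = np.clip(idx, 0, np.asarray(disp.shape) - 1)
    xb_snap = disp.origin + idx * disp.spacing
    xa = xb_snap + disp.vectors[idx[:, 0], idx[:, 1], idx[:, 2]]
    return np.stack([xa, xb_snap], axis=1)


def _pullback_pair(base_a, masks_a, mtv_a, psi, spec_b, lung_sel):
    """Warp the noiseless a-phantom through psi and re-noise as image_b."""
    shape = spec_b.grid_shape
    spacing = np.asarray(spec_b.spacing)
    pts = world_points(shape, spacing, np.zeros(3))
    mapped = psi(pts.reshape(-1, 3)).reshape(pts.shape)
    u = mapped - pts
    disp = DisplacementField(u, spacing)
    idx = np.moveaxis((mapped - 0.0) / spacing, -1, 0)
    from scipy.ndimage import map_coordinates

    base_b = map_coordinates(base_a, idx, order=1, mode="grid-constant",
                             cval=_CLASS_HU["air"][0])
    warped = {}
    for name, m in masks_a.items():
        warped[name] = map_coordinates(m.astype(np.uint8), idx, order=0,
                                       mode="grid-constant", cval=0).astype(bool)
    masks_b = MaskSet(**warped)
    mtv_b = None
    if mtv_a is not None:
        mtv_b = map_coordinates(mtv_a.astype(np.uint8), idx, order=0,
                                mode="grid-constant", cval=0).astype(bool)
    lung_b = map_coordinates(lung_sel.astype(np.uint8), idx, order=0,
                             mode="grid-constant", cval=0).astype(bool)
    rng = np.random.default_rng(spec_b.seed)
    img_b = VolumetricImage(_apply_noise(base_b, masks_b, lung_b, spec_b, rng), spacing)
    return img_b, masks_b, disp, mtv_b


def make_between_pair(spec_a: PhantomSpec, spec_b: PhantomSpec) -> PhantomTruth:
    """Two between-subject phantoms with an analytic ground-truth map.

    ``spec_b`` may differ from ``spec_a`` in fat-shell thickness, torso
    radius, skeleton pose, contrast offset, noise and seed; grids must
    agree.  The truth map from b-frame to a-frame points composes the
    Gaussian-blended inverse rigid pose offsets with the exact elliptical
    shell remap.
    """
    spec_a.validate()
    spec_b.validate()
    if spec_a.grid_shape != spec_b.grid_shape or not np.allclose(
            spec_a.spacing, spec_b.spacing, atol=0.1):
        raise ValueError("between-pair specs must share grid shape and spacing")

    base_a, masks_a, mtv_a, geo_a = _synthesize(spec_a)
    geo_b = _Geometry(spec_b)
    lung_sel = (base_a > -950) & (base_a < -800)

    remap = _shell_remap(geo_b, geo_a)
    # pose offsets stated on spec_b are the b->a rigid offsets per subregion
    rigid = _blended_rigid_map(spec_b.skeleton_pose, geo_a.subregion_boxes())

    def psi(pts):
        return rigid(remap(pts))

    img_b, masks_b, disp, _ = _pullback_pair(base_a, masks_a, mtv_a, psi,
                                             spec_b, lung_sel)
    rng = np.random.default_rng(spec_a.seed)
    img_a = VolumetricImage(_apply_noise(base_a, masks_a, lung_sel, spec_a, rng),
                            np.asarray(spec_a.spacing))
    landmarks = _snap_landmarks(geo_a.landmark_points(), psi, disp)
    return PhantomTruth(image_a=img_a, image_b=img_b, true_field_ab=disp,
                        landmarks=landmarks, masks_a=masks_a, masks_b=masks_b,
                        mtv_a=mtv_a)


# ---------------------------------------------------------------------------
# longitudinal contraction
# ---------------------------------------------------------------------------


def _contraction(geo: _Geometry, alpha: float, r0: float = 18.0, r1: float = 48.0):
    """Radial x-y contraction about the torso axis sparing the skeletal core.

    Forward map (pre -> post): r' = r * sqrt(1 - alpha * w(r)) with w a
    smoothstep ramp from r0 to r1.  Returns (forward_r, jacobian_det) as
    functions of radius; the map is identity in z.
    """
    dr = r1 - r0

    def w(r):
        return _smoothstep((r - r0) / dr)

    def wprime(r):
        t = np.clip((r - r0) / dr, 0.0, 1.0)
        return 6.0 * t * (1.0 - t) / dr

    def fwd(r):
        return r * np.sqrt(1.0 - alpha * w(r))

    def jac(r):
        s = np.sqrt(1.0 - alpha * w(r))
        gp = s - alpha * wprime(r) * r / (2.0 * s)
        g_over_r = np.where(r > 1e-12, fwd(r) / np.maximum(r, 1e-12), s)
        return gp * g_over_r

    return fwd, jac


def make_longitudinal_pair(spec: PhantomSpec, shrink_fraction: float,
                           seed: int | None = None) -> PhantomTruth:
    """Pre/post pair with smooth, foldless volume loss of known magnitude.

    ``image_a`` is the pre-therapy phantom, ``image_b`` the post-therapy one
    obtained by a radial contraction of the soft-tissue compartments.  The
    contraction amplitude is calibrated so that the analytic Jacobian
    integrates to ``-shrink_fraction`` times the body volume exactly.
    """
    spec.validate()
    if not (0.0 <= shrink_fraction < 0.5):
        raise ValueError("shrink_fraction must lie in [0, 0.5)")
    base_a, masks_a, mtv_a, geo = _synthesize(spec)
    lung_sel = (base_a > -950) & (base_a < -800)
    spacing = np.asarray(spec.spacing)
    pts = world_points(spec.grid_shape, spacing, np.zeros(3))
    r_grid = np.sqrt((pts[..., 0] - geo.cx) ** 2 + (pts[..., 1] - geo.cy) ** 2)
    r_body = r_grid[masks_a.body]

    if shrink_fraction == 0.0:
        alpha = 0.0
    else:
        def vol_err(a):
            _, jac = _contraction(geo, a)
            return float(np.mean(jac(r_body) - 1.0)) + shrink_fraction

        hi = min(0.55, 3.5 * shrink_fraction)
        alpha = brentq(vol_err, 1e-6, hi, xtol=1e-10)
    fwd, jacfun = _contraction(geo, alpha)

    # exact Jacobian of the pre->post point map on the pre lattice
    true_jac = jacfun(r_grid)

    def psi(p):   # post-frame -> pre-frame (inverse of the contraction)
        p = np.asarray(p, dtype=float)
        x = p[..., 0] - geo.cx
        y = p[..., 1] - geo.cy
        rp = np.sqrt(x**2 + y**2)
        r = rp / max(np.sqrt(1.0 - alpha), 1e-6)
        for _ in range(30):   # Newton on the monotone radial profile
            r = r - (fwd(r) - rp) / np.maximum(jacfun(r) / np.maximum(
                np.where(r > 1e-9, fwd(r) / np.maximum(r, 1e-9), 1.0), 1e-9), 1e-9)
            r = np.maximum(r, 0.0)
        scale = np.where(rp > 1e-9, r / np.maximum(rp, 1e-9), 1.0)
        out = p.copy()
        out[..., 0] = geo.cx + x * scale
        out[..., 1] = geo.cy + y * scale
        return out

    spec_b = replace(spec, seed=(seed if seed is not None else spec.seed + 1))
    img_b, masks_b, disp, mtv_b = _pullback_pair(base_a, masks_a, mtv_a, psi,
                                                 spec_b, lung_sel)
    rng = np.random.default_rng(spec.seed)
    img_a = VolumetricImage(_apply_noise(base_a, masks_a, lung_sel, spec, rng),
                            spacing)
    landmarks = _snap_landmarks(geo.landmark_points(), psi, disp)
    return PhantomTruth(image_a=img_a, image_b=img_b, true_field_ab=disp,
                        landmarks=landmarks, masks_a=masks_a, masks_b=masks_b,
                        mtv_a=mtv_a, true_jacobian=true_jac,
                        shrink_fraction=shrink_fraction)


# ---------------------------------------------------------------------------
# study cohorts
# ---------------------------------------------------------------------------


def between_cohort_specs(n_pairs: int = 5, seed: int = 1
                         ) -> list[tuple[PhantomSpec, PhantomSpec]]:
    """Spec pairs for the between-subject analog cohort.

    Pair k uses phantom seeds (seed+k) for both subjects of the pair; the
    fat-shell difference spans 4-10 mm across the cohort, head/arm pose
    offsets are drawn up to 8 mm / 5 deg and torso offsets up to 4 mm /
    3 deg, and lean contrast offsets up to +-20 HU emulate inconsistent
    contrast enhancement.
    """
    rng = np.random.default_rng(seed)
    shell_deltas = np.linspace(4.0, 10.0, n_pairs)
    pairs = []
    for k in range(n_pairs):
        def draw(mag_t, mag_r):
            t = rng.uniform(-1.0, 1.0, 3)
            t = t / max(np.linalg.norm(t), 1e-9) * rng.uniform(0.5, 1.0) * mag_t
            r = rng.uniform(-mag_r, mag_r, 3)
            return (tuple(r), tuple(t))

        pose = {
            "head": draw(8.0, 5.0),
            "right_arm": draw(8.0, 5.0),
            "left_arm": draw(8.0, 5.0),
            "chest": draw(4.0, 3.0),
            "pelvis": draw(4.0, 3.0),
        }
        spec_a = PhantomSpec(fat_shell_mm=10.0, seed=seed + k)
        spec_b = PhantomSpec(
            fat_shell_mm=10.0 + shell_deltas[k],
            torso_radius_mm=46.0 + rng.uniform(-3.0, 3.0),
            skeleton_pose=pose,
            contrast_offset_hu=float(rng.uniform(-20.0, 20.0)),
            seed=10_000 + seed + k,
        )
        pairs.append((spec_a, spec_b))
    return pairs


def longitudinal_cohort_params(n_pairs: int = 5, seed: int = 11
                               ) -> list[tuple[PhantomSpec, float]]:
    """(spec, shrink_fraction) list for the within-subject analog cohort.

    Shrink fractions span 5-15%; phantom seeds are seed..seed+n-1.
    """
    fracs = np.linspace(0.05, 0.15, n_pairs)
    return [(PhantomSpec(fat_shell_mm=12.0, seed=seed + k), float(fracs[k]))
            for k in range(n_pairs)]
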