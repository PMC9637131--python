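"""Discrete move-making deformable registration (CPU graph cuts).

The deformation is optimized as a Markov random field over per-voxel
displacement vectors.  The energy combines a weighted multi-channel data
term with a per-voxel-weighted first-order smoothness term:

    E(u) = sum_c w_c * sum_x m(x) * D_c(x; u)
         + sum_{(x,y) in N6} (w(x)+w(y))/2 * |u(x)-u(y)|^2 / |x-y|^2

where D_c is either the squared difference (M1, for tissue masks) or one
minus a windowed Pearson correlation coefficient (M2, for CT intensities,
robust to linear intensity changes), m(x) is an optional cost-function
mask in [0, 1], and w(x) are tissue-specific regularization weights (stiff
bone, elastic adipose/air).

Optimization sweeps binary "move" proposals: for a step vector delta each
voxel keeps its displacement or adds delta; the optimal binary labeling is
a min-cut (the pairwise terms of this move family are always submodular).
A Gaussian pyramid (coarse level 4 down to level 2) with within-level step
annealing gives a coarse-to-fine search; hard constraint voxels never
move.  Every accepted move is verified to lower the true energy, so the
energy trajectory is monotone non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .core import DisplacementField, VolumetricImage, downsample_volume, world_points

__all__ = [
    "Channel",
    "EnergyModel",
    "energy",
    "solve_step",
    "compose",
    "warp",
]

_AIR_HU = -1000.0
_CAP_SCALE = 1.0e6      # fixed-point scale for int32 min-cut capacities
_CAP_LOCK = 1.0e3       # pre-scale "infinite" cost pinning constraint voxels


@dataclass
class Channel:
    """One registration channel: a source/target grid pair plus a metric.

    ``metric`` is ``"ssd"`` (M1, sum of squared differences; masks) or
    ``"pearson"`` (M2, windowed Pearson correlation; CT).  ``fill`` is the
    value assumed outside the source grid (air HU for CT, 0 for masks).

    The target grid defines the cost lattice; the source grid may live on
    a different (e.g. finer) lattice, described by ``source_spacing`` /
    ``source_origin`` -- during multi-resolution search the source is
    sampled at full resolution so sub-voxel partial-volume information is
    not lost to pyramid pooling.
    """

    source: np.ndarray
    target: np.ndarray
    metric: str = "ssd"
    weight: float = 1.0
    window_radius: int = 2
    fill: float = 0.0
    source_spacing: np.ndarray | None = None
    source_origin: np.ndarray | None = None

    def __post_init__(self):
        if self.metric not in ("ssd", "pearson"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError("channel weight must be finite and >= 0")
        self.source = np.asarray(self.source, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.source_spacing is not None:
            self.source_spacing = np.asarray(self.source_spacing, dtype=float)
            self.source_origin = np.asarray(
                np.zeros(3) if self.source_origin is None else self.source_origin,
                dtype=float)
        elif self.source.shape != self.target.shape:
            raise ValueError("channel source/target must share the lattice "
                             "unless source_spacing is given")


@dataclass
class EnergyModel:
    """Channels, regularization weights, constraints and solver settings."""

    channels: list
    reg_weight_map: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    constraint_mask: np.ndarray | None = None
    cost_mask: np.ndarray | None = None          # [0,1] data-term weights
    move_step_vox: float = 2.0                   # start step, in voxels
    min_step_vox: float = 0.5                    # anneal until below this
    max_sweeps: int = 20
    pyramid: tuple[int, int] = (4, 2)            # start/stop level

    def __post_init__(self):
        if not self.channels:
            raise ValueError("EnergyModel needs at least one channel")
        self.reg_weight_map = np.asarray(self.reg_weight_map, dtype=float)
        if np.any(self.reg_weight_map <= 0):
            raise ValueError("reg_weight_map must be positive everywhere")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        shape = self.channels[0].target.shape
        for ch in self.channels:
            if ch.target.shape != shape:
                raise ValueError("all channel targets must share the lattice")
        if self.reg_weight_map.shape != shape:
            raise ValueError("reg_weight_map must live on the channel lattice")

    @property
    def shape(self):
        return self.channels[0].target.shape


def _local_pearson(a: np.ndarray, b: np.ndarray, radius: int) -> np.ndarray:
    """Pearson correlation of two grids over cubic windows, per voxel.

    Windows where both grids are constant count as perfectly correlated;
    windows where only one is constant count as uncorrelated.
    """
    size = 2 * radius + 1
    f = lambda x: uniform_filter(x, size=size, mode="nearest")
    ma, mb = f(a), f(b)
    va = np.maximum(f(a * a) - ma * ma, 0.0)
    vb = np.maximum(f(b * b) - mb * mb, 0.0)
    cov = f(a * b) - ma * mb
    tol = 1e-8
    flat_both = (va < tol) & (vb < tol)
    denom = np.sqrt(np.maximum(va * vb, tol * tol))
    r = np.clip(cov / denom, -1.0, 1.0)
    r[flat_both] = 1.0
    return r


def _warp_grid(values: np.ndarray, pts_mm: np.ndarray, spacing, origin, fill) -> np.ndarray:
    from scipy.ndimage import map_coordinates

    idx = np.moveaxis((pts_mm - origin) / spacing, -1, 0)
    return map_coordinates(values, idx, order=1, mode="grid-constant", cval=fill)


def _data_cost_maps(model: EnergyModel, vectors: np.ndarray,
                    pts: np.ndarray) -> np.ndarray:
    """Per-voxel weighted data cost for the displacement grid ``vectors``."""
    mapped = pts + vectors
    total = np.zeros(model.shape)
    for ch in model.channels:
        if ch.weight == 0:
            continue
        src_sp = model.spacing if ch.source_spacing is None else ch.source_spacing
        src_or = model.origin if ch.source_spacing is None else ch.source_origin
        warped = _warp_grid(ch.source, mapped, src_sp, src_or, ch.fill)
        if ch.metric == "ssd":
            cost = (warped - ch.target) ** 2
        else:
            cost = 1.0 - _local_pearson(warped, ch.target, ch.window_radius)
        total += ch.weight * cost
    if model.cost_mask is not None:
        total *= model.cost_mask
    return total


def _smoothness(model: EnergyModel, vectors: np.ndarray) -> float:
    w = model.reg_weight_map
    e = 0.0
    for ax in range(3):
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[ax] = slice(None, -1)
        sl1[ax] = slice(1, None)
        du = vectors[tuple(sl0)] - vectors[tuple(sl1)]
        wp = 0.5 * (w[tuple(sl0)] + w[tuple(sl1)])
        e += float(np.sum(wp * np.sum(du * du, axis=-1)) / model.spacing[ax] ** 2)
    return e


def energy(disp: DisplacementField, model: EnergyModel) -> float:
    """Total registration energy of a field under a model (same lattice)."""
    if tuple(disp.shape) != tuple(model.shape):
        raise ValueError("field and model lattices differ")
    pts = world_points(model.shape, model.spacing, model.origin)
    data = float(np.sum(_data_cost_maps(model, disp.vectors, pts)))
    e = data + _smoothness(model, disp.vectors)
    if not np.isfinite(e):
        for ch in model.channels:
            if not np.isfinite(ch.source).all() or not np.isfinite(ch.target).all():
                raise ValueError(f"non-finite energy from channel {ch.metric!r}")
        raise ValueError("non-finite energy")
    return e


# ---------------------------------------------------------------------------
# one binary move via min-cut
# ---------------------------------------------------------------------------


class _MoveGraph:
    """Reusable s-t graph structure for one lattice (nodes = voxels + s,t)."""

    def __init__(self, shape):
        self.shape = tuple(shape)
        self.n = int(np.prod(shape))
        flat = np.arange(self.n).reshape(shape)
        pairs = []
        for ax in range(3):
            sl0 = [slice(None)] * 3
            sl1 = [slice(None)] * 3
            sl0[ax] = slice(None, -1)
            sl1[ax] = slice(1, None)
            pairs.append(np.stack([flat[tuple(sl0)].ravel(),
                                   flat[tuple(sl1)].ravel()]))
        self.pairs = np.concatenate(pairs, axis=1)      # (2, m)
        self.axis_of_pair = np.concatenate([
            np.full(p.shape[1], ax) for ax, p in enumerate(pairs)])
        s, t = self.n, self.n + 1
        self.s, self.t = s, t
        i, j = self.pairs
        self.rows = np.concatenate([np.full(self.n, s), np.arange(self.n), i, j])
        self.cols = np.concatenate([np.arange(self.n), np.full(self.n, t), j, i])

    def solve(self, cap_s: np.ndarray, cap_t: np.ndarray,
              cap_edge: np.ndarray) -> np.ndarray:
        """Min-cut labels (True = take the move) for given capacities.

        ``cap_edge`` is placed on the directed i->j arcs only; the reverse
        arcs exist with zero capacity (residual arcs are handled by the
        solver).
        """
        data = np.concatenate([cap_s, cap_t, cap_edge, np.zeros_like(cap_edge)])
        data = np.rint(data * _CAP_SCALE).astype(np.int64)
        np.clip(data, 0, np.iinfo(np.int32).max - 1, out=data)
        g = csr_matrix((data.astype(np.int32), (self.rows, self.cols)),
                       shape=(self.n + 2, self.n + 2))
        res = maximum_flow(g, self.s, self.t)
        # residual capacities; the flow matrix is antisymmetric, so reverse
        # residual arcs appear automatically
        residual = (g - res.flow).tocsr()
        residual.data = (residual.data > 0).astype(np.int32)
        residual.eliminate_zeros()
        reach = breadth_first_order(residual, self.s, directed=True,
                                    return_predecessors=False)
        labels = np.ones(self.n + 2, dtype=bool)       # sink side = take move
        labels[reach] = False
        return labels[: self.n]


def _pair_weights(model: EnergyModel) -> np.ndarray:
    """(w(x)+w(y))/2 / h^2 for every neighbor pair, in graph pair order."""
    w = model.reg_weight_map
    out = []
    for ax in range(3):
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[ax] = slice(None, -1)
        sl1[ax] = slice(1, None)
        out.append((0.5 * (w[tuple(sl0)] + w[tuple(sl1)])
                    / model.spacing[ax] ** 2).ravel())
    return np.concatenate(out)


def _try_move(model: EnergyModel, graph: _MoveGraph, vectors: np.ndarray,
              pts: np.ndarray, delta: np.ndarray, d0_map: np.ndarray,
              pair_w: np.ndarray, locked_flat: np.ndarray) -> np.ndarray | None:
    """Candidate acceptance mask for the move ``u -> u + delta`` (or None)."""
    d1_map = _data_cost_maps(model, vectors + delta, pts)
    d0 = d0_map.ravel()
    d1 = d1_map.ravel()

    i, j = graph.pairs
    uflat = vectors.reshape(-1, 3)
    d_vec = uflat[i] - uflat[j]
    dd = d_vec @ delta
    d2 = float(delta @ delta)
    # Kolmogorov-Zabih reparameterization of the (always submodular) pairwise
    # terms: V(Li,Lj) = V00 + (V10-V00) Li + (V11-V10) Lj
    #                 + (V01+V10-V00-V11) [Li=0][Lj=1]
    edge = 2.0 * pair_w * d2
    add_i = pair_w * (2.0 * dd + d2)      # V10 - V00
    add_j = pair_w * (-2.0 * dd - d2)     # V11 - V10

    theta1 = d1.copy()
    theta1[locked_flat] += _CAP_LOCK
    np.add.at(theta1, i, add_i)
    np.add.at(theta1, j, add_j)
    theta0 = d0

    # source side = label 0 (keep); sink side = label 1 (take the move)
    net = theta1 - theta0
    cap_s = np.maximum(net, 0.0)
    cap_t = np.maximum(-net, 0.0)
    take = graph.solve(cap_s, cap_t, edge)
    take &= ~locked_flat
    if not take.any():
        return None
    return take.reshape(model.shape)


def solve_step(model: EnergyModel, init_field: DisplacementField,
               log: list | None = None) -> DisplacementField:
    """Minimize the model energy by multi-resolution binary move-making.

    Runs pyramid levels ``pyramid[0]`` down to ``pyramid[1]``; at each
    level the move step anneals from ``move_step_vox`` voxels down to
    ``min_step_vox`` (0.25 voxel at the terminal level), sweeping the six
    axis-aligned proposals until no move lowers the energy.  Constraint
    voxels keep their initial displacement exactly.  Returns the field at
    the model's native lattice; energies are appended to ``log`` if given.
    """
    start, stop = model.pyramid
    native_shape = model.shape
    native_sp = model.spacing
    native_or = model.origin
    field = init_field.resample_to(native_shape, native_sp, native_or)
    if model.constraint_mask is not None:
        locked_native = np.asarray(model.constraint_mask, dtype=bool)
        init_native = field.vectors.copy()
    else:
        locked_native = None

    for level in range(start, stop - 1, -1):
        f = 2 ** level
        lvl_sp = native_sp * f
        lvl_shape = tuple(-(-n // f) for n in native_shape)
        # box averages are centered mid-box: shift the level origin so the
        # level lattice coordinates match the pooled content
        lvl_or = native_or + (f - 1) / 2.0 * native_sp
        # both sides are box-averaged onto the level lattice; trilinear
        # interpolation of the pooled source keeps sub-voxel sensitivity
        channels = [
            Channel(downsample_volume(ch.source, f, method="mean"),
                    downsample_volume(ch.target, f, method="mean"),
                    metric=ch.metric, weight=ch.weight,
                    window_radius=ch.window_radius, fill=ch.fill,
                    source_spacing=lvl_sp, source_origin=lvl_or)
            for ch in model.channels
        ]
        reg = np.maximum(downsample_volume(model.reg_weight_map, f,
                                           method="mean"), 1e-6)
        cost_mask = (None if model.cost_mask is None
                     else np.clip(downsample_volume(model.cost_mask, f,
                                                    method="mean"), 0.0, 1.0))
        locked = (None if locked_native is None
                  else downsample_volume(locked_native.astype(float), f,
                                         method="mean") > 0.5)
        lvl_model = EnergyModel(channels=channels, reg_weight_map=reg,
                                spacing=lvl_sp, origin=lvl_or,
                                constraint_mask=locked, cost_mask=cost_mask,
                                move_step_vox=model.move_step_vox,
                                min_step_vox=model.min_step_vox,
                                max_sweeps=model.max_sweeps, pyramid=(0, 0))
        field = field.resample_to(lvl_shape, lvl_sp, lvl_or)
        if locked_native is not None and locked is not None and locked.any():
            # re-impose locked displacements on the level lattice
            src = DisplacementField(init_native, native_sp, native_or)
            field.vectors[locked] = src.resample_to(lvl_shape, lvl_sp,
                                                    lvl_or).vectors[locked]
        # the terminal level anneals three extra halvings so the displacement
        # quantization (in mm) stays well below the level spacing
        min_step = model.min_step_vox if level > stop else model.min_step_vox / 8.0
        level_log: list = [] if log is not None else None
        field = _solve_level(lvl_model, field, min_step, level_log)
        if log is not None:
            log.append({"level": level, "energies": level_log})

    field = field.resample_to(native_shape, native_sp, native_or)
    if locked_native is not None and locked_native.any():
        field.vectors[locked_native] = init_native[locked_native]
    return field


def _solve_level(model: EnergyModel, field: DisplacementField,
                 min_step_vox: float, log: list | None) -> DisplacementField:
    graph = _MoveGraph(model.shape)
    pair_w = _pair_weights(model)
    pts = world_points(model.shape, model.spacing, model.origin)
    locked_flat = (np.zeros(graph.n, bool) if model.constraint_mask is None
                   else np.asarray(model.constraint_mask, bool).ravel())
    vectors = field.vectors
    d0_map = _data_cost_maps(model, vectors, pts)
    e_cur = float(np.sum(d0_map)) + _smoothness(model, vectors)
    if log is not None:
        log.append(e_cur)

    step_vox = model.move_step_vox
    while step_vox >= min_step_vox - 1e-9:
        for _ in range(model.max_sweeps):
            improved = False
            for ax in range(3):
                for sign in (1.0, -1.0):
                    delta = np.zeros(3)
                    delta[ax] = sign * step_vox * model.spacing[ax]
                    take = _try_move(model, graph, vectors, pts, delta,
                                     d0_map, pair_w, locked_flat)
                    if take is None:
                        continue
                    cand = vectors.copy()
                    cand[take] += delta
                    d_cand = _data_cost_maps(model, cand, pts)
                    e_cand = float(np.sum(d_cand)) + _smoothness(model, cand)
                    if e_cand < e_cur - 1e-9:
                        vectors, d0_map, e_cur = cand, d_cand, e_cand
                        improved = True
                        if log is not None:
                            log.append(e_cur)
            if not improved:
                break
        step_vox *= 0.5
    return DisplacementField(vectors, model.spacing, model.origin)


def compose(first: DisplacementField, second: DisplacementField) -> DisplacementField:
    """T(x) = x + u2(x) + u1(x + u2(x)) on second's lattice."""
    from .core import compose_fields

    return compose_fields(first, second)


def warp(image: VolumetricImage, disp: DisplacementField,
         interpolation: str = "linear", fill=None) -> VolumetricImage:
    """Warp an image through a field (``linear`` or ``nearest``)."""
    from .core import warp_image

    order = {"linear": 1, "nearest": 0}[interpolation]
    return warp_image(image, disp, order=order, fill=fill)
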