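"""Deformable engine: energy oracle, move optimality, field algebra."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from wbreg.core import DisplacementField, VolumetricImage, world_points
from wbreg.deformable import (Channel, EnergyModel, compose, energy,
                              solve_step, warp)
from wbreg.deformable import (_MoveGraph, _data_cost_maps, _pair_weights,
                              _smoothness, _try_move)

SP = np.array([2.0, 2.0, 2.0])


def brute_force_energy(model, vectors):
    """Direct summation oracle: data term + neighbor smoothness, by loops."""
    shape = model.shape
    pts = world_points(shape, model.spacing, model.origin)
    data = float(np.sum(_data_cost_maps(model, vectors, pts)))
    smooth = 0.0
    w = model.reg_weight_map
    for x in np.ndindex(shape):
        for ax in range(3):
            y = list(x)
            y[ax] += 1
            if y[ax] >= shape[ax]:
                continue
            y = tuple(y)
            du = vectors[x] - vectors[y]
            smooth += (0.5 * (w[x] + w[y]) * float(du @ du)
                       / model.spacing[ax] ** 2)
    return data + smooth


class TestEnergy:
    def test_zero_field_identical_images_ssd_is_zero(self):
        rng = np.random.default_rng(0)
        src = rng.normal(size=(4, 4, 4))
        model = EnergyModel(channels=[Channel(src, src.copy(), "ssd")],
                            reg_weight_map=np.ones((4, 4, 4)), spacing=SP)
        assert energy(DisplacementField.zero((4, 4, 4), SP), model) == 0.0

    def test_pearson_invariant_to_linear_intensity_maps(self):
        rng = np.random.default_rng(1)
        tgt = gaussian_filter(rng.normal(size=(8, 8, 8)), 1.0)
        src = 3.0 * tgt + 100.0
        model = EnergyModel(channels=[Channel(src, tgt, "pearson")],
                            reg_weight_map=np.ones((8, 8, 8)), spacing=SP)
        assert energy(DisplacementField.zero((8, 8, 8), SP), model) < 1e-6

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(2)
        shape = (3, 3, 3)
        model = EnergyModel(
            channels=[Channel(rng.normal(size=shape), rng.normal(size=shape),
                              "ssd", weight=0.7)],
            reg_weight_map=rng.uniform(0.1, 1.0, shape), spacing=SP)
        vec = rng.normal(scale=0.8, size=shape + (3,))
        disp = DisplacementField(vec, SP)
        assert energy(disp, model) == pytest.approx(
            brute_force_energy(model, vec), abs=1e-9)

    def test_lattice_mismatch_rejected(self):
        src = np.zeros((4, 4, 4))
        model = EnergyModel(channels=[Channel(src, src, "ssd")],
                            reg_weight_map=np.ones((4, 4, 4)), spacing=SP)
        with pytest.raises(ValueError):
            energy(DisplacementField.zero((5, 4, 4), SP), model)


class TestMoveOptimality:
    @pytest.mark.parametrize("trial", range(8))
    def test_single_move_equals_exhaustive_minimum(self, trial):
        """Each binary move labeling matches the 2^8 brute-force optimum."""
        rng = np.random.default_rng(trial)
        shape = (2, 2, 2)
        model = EnergyModel(
            channels=[Channel(rng.normal(size=shape), rng.normal(size=shape),
                              "ssd")],
            reg_weight_map=rng.uniform(0.1, 1.0, shape), spacing=np.ones(3))
        vec = rng.normal(scale=0.5, size=shape + (3,))
        delta = np.zeros(3)
        delta[rng.integers(3)] = rng.choice([-1.0, 1.0]) * 0.7
        pts = world_points(shape, model.spacing, model.origin)
        d0 = _data_cost_maps(model, vec, pts)
        graph = _MoveGraph(shape)
        locked = np.zeros(8, bool)
        locked[rng.integers(8)] = rng.random() < 0.4
        take = _try_move(model, graph, vec, pts, delta, d0,
                         _pair_weights(model), locked)

        def move_energy(lab):
            v = vec.copy()
            v[lab.reshape(shape)] += delta
            return (float(np.sum(_data_cost_maps(model, v, pts)))
                    + _smoothness(model, v))

        best = min(move_energy(np.array(bits))
                   for bits in itertools.product([False, True], repeat=8)
                   if not (np.array(bits) & locked).any())
        got = np.zeros(8, bool) if take is None else take.ravel()
        assert move_energy(got) == pytest.approx(best, abs=1e-5)


class TestSolveStep:
    def _ramp_model(self, tgt_shift_mm, reg=0.02, shape=(12, 12, 12)):
        rng = np.random.default_rng(3)
        src = gaussian_filter(rng.normal(size=shape), 1.5)
        img = VolumetricImage(src, SP)
        shift = DisplacementField.zero(shape, SP)
        shift.vectors[..., 0] = tgt_shift_mm
        tgt = warp(img, shift, fill=0.0).values
        return EnergyModel(channels=[Channel(src, tgt, "ssd", fill=0.0)],
                           reg_weight_map=np.full(shape, reg), spacing=SP,
                           pyramid=(0, 0))

    def test_identical_images_stay_at_zero(self):
        rng = np.random.default_rng(4)
        src = gaussian_filter(rng.normal(size=(8, 8, 8)), 1.0)
        model = EnergyModel(channels=[Channel(src, src.copy(), "ssd")],
                            reg_weight_map=np.full((8, 8, 8), 0.1), spacing=SP,
                            pyramid=(0, 0))
        out = solve_step(model, DisplacementField.zero((8, 8, 8), SP))
        assert np.max(np.abs(out.vectors)) == 0.0

    def test_recovers_uniform_shift(self):
        model = self._ramp_model(-4.0)
        out = solve_step(model, DisplacementField.zero((12, 12, 12), SP))
        interior = out.vectors[3:-3, 3:-3, 3:-3]
        assert np.allclose(interior.reshape(-1, 3).mean(axis=0),
                           [-4.0, 0.0, 0.0], atol=0.4)

    def test_energy_trajectory_is_monotone(self):
        model = self._ramp_model(-4.0)
        log = []
        solve_step(model, DisplacementField.zero((12, 12, 12), SP), log=log)
        for level in log:
            assert all(np.diff(level["energies"]) <= 1e-9)

    def test_constraint_voxels_frozen_bitwise(self):
        model = self._ramp_model(-4.0)
        locked = np.zeros((12, 12, 12), bool)
        locked[5:7, 5:7, 5:7] = True
        model.constraint_mask = locked
        init = DisplacementField.zero((12, 12, 12), SP)
        init.vectors[locked] = [1.25, -0.5, 0.75]
        out = solve_step(model, init)
        assert np.array_equal(out.vectors[locked], init.vectors[locked])
        assert np.any(out.vectors[~locked] != 0)

    def test_stronger_regularization_gives_smoother_solution(self):
        rng = np.random.default_rng(5)
        shape = (10, 10, 10)
        src = gaussian_filter(rng.normal(size=shape), 1.0)
        tgt = gaussian_filter(rng.normal(size=shape), 1.0)
        smooth_terms = []
        for reg in (0.01, 1.0):
            model = EnergyModel(channels=[Channel(src, tgt, "ssd", fill=0.0)],
                                reg_weight_map=np.full(shape, reg), spacing=SP,
                                pyramid=(0, 0))
            out = solve_step(model, DisplacementField.zero(shape, SP))
            unit = EnergyModel(channels=model.channels,
                               reg_weight_map=np.ones(shape), spacing=SP)
            smooth_terms.append(_smoothness(unit, out.vectors))
        assert smooth_terms[1] <= smooth_terms[0] + 1e-12


class TestComposeAndWarp:
    def test_zero_is_identity_element(self):
        rng = np.random.default_rng(6)
        f = DisplacementField(rng.normal(size=(6, 6, 6, 3)), SP)
        zero = DisplacementField.zero((6, 6, 6), SP)
        assert np.allclose(compose(zero, f).vectors, f.vectors, atol=1e-12)
        assert np.allclose(compose(f, zero).vectors, f.vectors, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(-5, 5) for _ in range(6)]))
    def test_uniform_shifts_add(self, shifts):
        a = DisplacementField.zero((5, 5, 5), SP)
        b = DisplacementField.zero((5, 5, 5), SP)
        a.vectors[:] = shifts[:3]
        b.vectors[:] = shifts[3:]
        comp = compose(a, b)
        assert np.allclose(comp.vectors,
                           np.asarray(shifts[:3]) + np.asarray(shifts[3:]),
                           atol=1e-9)

    def test_compose_matches_two_step_sampling_oracle(self):
        rng = np.random.default_rng(7)
        smooth = lambda: np.stack([gaussian_filter(rng.normal(size=(8, 8, 8)), 2.0)
                                   for _ in range(3)], axis=-1) * 3.0
        f1 = DisplacementField(smooth(), SP)
        f2 = DisplacementField(smooth(), SP)
        comp = compose(f1, f2)
        pts = f2.lattice_points()
        oracle = f1.point_map(f2.point_map(pts))
        assert np.allclose(pts + comp.vectors, oracle, atol=1e-6)

    def test_warp_zero_field_is_identity(self):
        rng = np.random.default_rng(8)
        img = VolumetricImage(rng.normal(size=(6, 6, 6)), SP)
        zero = DisplacementField.zero((6, 6, 6), SP)
        assert np.array_equal(warp(img, zero, "nearest").values, img.values)
        assert np.allclose(warp(img, zero).values, img.values, atol=1e-12)

    def test_warp_shifts_ramp_exactly(self):
        ramp = np.tile(np.arange(8, dtype=float)[:, None, None], (1, 8, 8))
        img = VolumetricImage(ramp, SP)
        disp = DisplacementField.zero((8, 8, 8), SP)
        disp.vectors[..., 0] = SP[0]   # +1 voxel
        out = warp(img, disp)
        assert np.allclose(out.values[:-1], ramp[1:], atol=1e-12)

    def test_nearest_warp_keeps_masks_binary(self):
        rng = np.random.default_rng(9)
        mask = rng.random((6, 6, 6)) > 0.5
        img = VolumetricImage(mask.astype(np.uint8), SP)
        disp = DisplacementField(rng.normal(scale=1.5, size=(6, 6, 6, 3)), SP)
        out = warp(img, disp, "nearest").values
        assert set(np.unique(out)) <= {0, 1}
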