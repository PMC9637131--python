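"""Evaluation metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

from wbreg.affine_skeleton import NoShearAffine
from wbreg.core import DisplacementField, VolumetricImage
from wbreg.metrics import (RegionOfInterest, composite_dice, folding_fraction,
                           ime, jacobian_determinant, template_voxel_stats,
                           vme)

SP = np.array([2.0, 2.0, 2.0])
SHAPE = (6, 6, 6)


def uniform(d):
    f = DisplacementField.zero(SHAPE, SP)
    f.vectors[:] = d
    return f


@pytest.fixture
def omega():
    m = np.zeros(SHAPE, bool)
    m[1:-1, 1:-1, 1:-1] = True
    return RegionOfInterest(m)


class TestVme:
    def test_zero_fields_give_zero(self, omega):
        assert vme(uniform(0), uniform(0), omega) == 0.0

    def test_exact_inverses_give_zero(self, omega):
        d = np.array([3.0, -1.0, 2.0])
        assert vme(uniform(d), uniform(-d), omega) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_shift_vs_zero_gives_shift_norm(self, omega):
        d = np.array([3.0, 4.0, 0.0])
        assert vme(uniform(d), uniform(0), omega) == pytest.approx(5.0, abs=1e-12)

    def test_matches_brute_force_summation(self, omega):
        rng = np.random.default_rng(0)
        f1 = DisplacementField(rng.normal(size=SHAPE + (3,)), SP)
        f2 = DisplacementField(rng.normal(size=SHAPE + (3,)), SP)
        acc = []
        for idx in np.argwhere(omega.omega):
            x = idx * SP
            y = x + f1.sample(x)
            z = y + f2.sample(y)
            acc.append(np.linalg.norm(z - x))
        assert vme(f1, f2, omega) == pytest.approx(np.mean(acc), abs=1e-9)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest(np.zeros(SHAPE, bool))


class TestIme:
    def test_constant_image_gives_zero(self, omega):
        img = VolumetricImage(np.full(SHAPE, 50.0), SP)
        assert ime(img, uniform((3, 0, 0)), uniform(0), omega) == pytest.approx(
            0.0, abs=1e-9)

    def test_zero_fields_give_zero(self, omega):
        rng = np.random.default_rng(1)
        img = VolumetricImage(rng.normal(size=SHAPE), SP)
        assert ime(img, uniform(0), uniform(0), omega) == 0.0

    def test_ramp_with_uniform_shift_gives_shift_component(self):
        ramp = np.tile(np.arange(6, dtype=float)[:, None, None] * SP[0],
                       (1, 6, 6))
        img = VolumetricImage(ramp, SP)
        # keep the round trip inside the lattice so the ramp is exact
        m = np.zeros(SHAPE, bool)
        m[1:4, 1:-1, 1:-1] = True
        assert ime(img, uniform((3.0, 0, 0)), uniform(0),
                   RegionOfInterest(m)) == pytest.approx(3.0, abs=1e-9)


class TestCompositeDice:
    def test_zero_fields_give_one(self):
        mask = np.zeros(SHAPE, bool)
        mask[2:4, 2:4, 2:4] = True
        assert composite_dice(mask, uniform(0), uniform(0)) == 1.0

    def test_disjoint_round_trip_gives_zero(self):
        mask = np.zeros(SHAPE, bool)
        mask[:2] = True
        assert composite_dice(mask, uniform((8.0, 0, 0)), uniform(0)) == 0.0

    def test_formula_on_hand_built_example(self):
        # shift one voxel: |A| = 4, |round trip| = 4, overlap = 2
        mask = np.zeros((3, 3, 4), bool)
        mask[0, 0, 1:3] = True
        mask[1, 0, 1:3] = True
        f = DisplacementField.zero((3, 3, 4), (1.0, 1.0, 1.0))
        f.vectors[..., 2] = 1.0
        zero = DisplacementField.zero((3, 3, 4), (1.0, 1.0, 1.0))
        assert composite_dice(mask, f, zero) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        mask = rng.random(SHAPE) > 0.6
        f1 = DisplacementField(rng.normal(size=SHAPE + (3,)) * 0.5, SP)
        f2 = DisplacementField(rng.normal(size=SHAPE + (3,)) * 0.5, SP)
        comp_ab = composite_dice(mask, f1, f2)

        # Dice itself is symmetric in its two mask arguments
        from wbreg.core import compose_fields, warp_image
        comp = compose_fields(f2, f1)
        rt = warp_image(VolumetricImage(mask.astype(np.uint8), SP), comp,
                        order=0, fill=0).values.astype(bool)
        d1 = 2 * np.sum(mask & rt) / (mask.sum() + rt.sum())
        assert comp_ab == pytest.approx(d1)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            composite_dice(np.zeros(SHAPE, bool), uniform(0), uniform(0))


class TestJacobian:
    def test_zero_field_gives_one(self):
        jac = jacobian_determinant(uniform(0))
        assert np.allclose(jac, 1.0, atol=1e-12)

    def test_uniform_scale_gives_cubed_factor(self):
        s = 1.1
        aff = NoShearAffine(scale=(s, s, s), center=(6.0, 6.0, 6.0))
        f = DisplacementField.zero(SHAPE, SP)
        pts = f.lattice_points()
        f.vectors[:] = aff.displacement(pts)
        jac = jacobian_determinant(f)
        assert np.allclose(jac[1:-1, 1:-1, 1:-1], s**3, atol=1e-6)

    def test_local_fold_gives_negative_determinant(self):
        f = DisplacementField.zero(SHAPE, SP)
        f.vectors[3, :, :, 0] = -6.0   # reverses x-order locally
        jac = jacobian_determinant(f)
        # the central-difference stencil sees the order reversal on the
        # plane preceding the displaced one
        assert jac[2].min() < 0


class TestFolding:
    def test_all_positive_gives_zero_percent(self, omega):
        assert folding_fraction(np.ones(SHAPE), omega) == 0.0

    def test_counting(self):
        m = np.zeros(SHAPE, bool)
        m.ravel()[:200] = True
        jac = np.ones(SHAPE)
        jac.ravel()[0] = -0.5
        assert folding_fraction(jac, RegionOfInterest(m)) == pytest.approx(0.5)


class TestTemplateStats:
    def test_single_identical_image(self):
        rng = np.random.default_rng(3)
        t = VolumetricImage(rng.normal(size=SHAPE), SP)
        med, iqr, mae = template_voxel_stats([t.values.copy()], t)
        assert np.allclose(mae, 0.0) and np.allclose(iqr, 0.0)
        assert np.allclose(med, t.values)

    def test_median_of_two(self):
        t = VolumetricImage(np.zeros(SHAPE), SP)
        med, _, _ = template_voxel_stats([np.full(SHAPE, 100.0),
                                          np.full(SHAPE, 200.0)], t)
        assert np.allclose(med, 150.0)

    def test_iqr_linear_quantile_rule(self):
        t = VolumetricImage(np.zeros(SHAPE), SP)
        vals = [np.full(SHAPE, v) for v in (0.0, 10.0, 20.0, 30.0)]
        _, iqr, _ = template_voxel_stats(vals, t)
        assert np.allclose(iqr, 15.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            template_voxel_stats([], VolumetricImage(np.zeros(SHAPE), SP))
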