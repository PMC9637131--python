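"""Mask generation and spacing harmonization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wbreg.core import VolumetricImage
from wbreg.phantom import PhantomSpec, generate_phantom
from wbreg.preprocess import (ResamplePolicy, TissueThresholds, fat_percentage,
                              harmonize_spacing, make_body_mask,
                              make_inside_sat_mask, make_mask_set,
                              make_tissue_masks)
from tests.conftest import COARSE


class TestBodyMask:
    def test_matches_truth_without_table(self, coarse_phantom):
        _, img, truth = coarse_phantom
        body = make_body_mask(img)
        assert (body == truth.body).mean() >= 0.99

    def test_table_slab_removed(self):
        img, truth = generate_phantom(PhantomSpec(seed=9, **COARSE), table=True)
        body = make_body_mask(img)
        table_voxels = (img.values > 100) & ~truth.body
        assert not (body & table_voxels).any()
        assert (body == truth.body).mean() >= 0.99

    def test_all_air_raises(self):
        img = VolumetricImage(np.full((16, 16, 16), -1000.0), (3.0, 3.0, 3.0))
        with pytest.raises(ValueError):
            make_body_mask(img)


class TestTissueMasks:
    def test_equals_brute_force_classifier(self, coarse_phantom):
        """Window masks agree with a per-voxel oracle on every voxel."""
        _, img, truth = coarse_phantom
        thr = TissueThresholds()
        masks = make_tissue_masks(img, thr, truth.body)
        hu = img.values
        for name, oracle in (
            ("bone", truth.body & (hu > 200.0)),
            ("lean", truth.body & (hu >= -29.0) & (hu <= 150.0)),
            ("adipose", truth.body & (hu >= -190.0) & (hu <= -30.0)),
        ):
            assert np.array_equal(getattr(masks, name), oracle)

    @pytest.mark.parametrize("hu,tissue", [(300.0, "bone"), (-100.0, "adipose"),
                                           (150.0, "lean"), (-29.0, "lean")])
    def test_window_endpoints(self, hu, tissue):
        img = VolumetricImage(np.full((16, 16, 16), hu), (2.0, 2.0, 2.0))
        body = np.ones((16, 16, 16), bool)
        masks = make_tissue_masks(img, TissueThresholds(), body)
        assert getattr(masks, tissue).all()

    def test_air_in_no_tissue_mask(self):
        img = VolumetricImage(np.full((16, 16, 16), -1000.0), (2.0, 2.0, 2.0))
        masks = make_tissue_masks(img, TissueThresholds(),
                                  np.ones((16, 16, 16), bool))
        assert not (masks.bone | masks.lean | masks.adipose).any()

    def test_disordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            TissueThresholds(adipose_hi=0.0)


class TestInsideSat:
    def test_matches_truth_on_phantom(self, coarse_phantom):
        _, img, truth = coarse_phantom
        masks = make_mask_set(img)
        assert (masks.inside_sat == truth.inside_sat).mean() >= 0.98

    def test_excludes_the_sat_shell(self, coarse_phantom):
        """The interior leaves out the shell except for stray
        partial-volume adipose voxels at the inner shell boundary."""
        _, img, truth = coarse_phantom
        masks = make_mask_set(img)
        overlap = (masks.inside_sat & truth.adipose).sum()
        assert overlap <= 0.01 * masks.inside_sat.sum()

    def test_fallback_without_adipose(self):
        body = np.zeros((24, 24, 8), bool)
        body[6:18, 6:18, :] = True
        from wbreg.core import MaskSet
        masks = MaskSet(body=body, bone=np.zeros_like(body),
                        lean=body.copy(), adipose=np.zeros_like(body),
                        inside_sat=np.zeros_like(body))
        inside = make_inside_sat_mask(masks)
        assert inside.any() and not (inside & ~body).any()


class TestHarmonizeSpacing:
    def test_resamples_to_larger_spacing_per_axis(self):
        rng = np.random.default_rng(0)
        a = VolumetricImage(rng.normal(size=(20, 20, 30)), (1.0, 1.0, 3.0))
        b = VolumetricImage(rng.normal(size=(20, 20, 24)), (1.0, 1.0, 3.75))
        a2, b2 = harmonize_spacing(a, b)
        assert np.allclose(a2.spacing, [1.0, 1.0, 3.75])
        assert np.allclose(b2.spacing, [1.0, 1.0, 3.75])
        assert np.array_equal(b2.values, b.values)   # b untouched

    def test_small_difference_within_tolerance_untouched(self):
        a = VolumetricImage(np.zeros((16, 16, 16)), (0.98, 1.0, 3.0))
        b = VolumetricImage(np.ones((16, 16, 16)), (1.00, 1.0, 3.0))
        a2, b2 = harmonize_spacing(a, b)
        assert a2 is a and b2 is b

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        a = VolumetricImage(rng.normal(size=(20, 20, 20)), (1.0, 1.2, 2.0))
        b = VolumetricImage(rng.normal(size=(20, 20, 20)), (1.5, 1.2, 3.0))
        a1, b1 = harmonize_spacing(a, b)
        a2, b2 = harmonize_spacing(a1, b1)
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(b1.values, b2.values)


class TestFatPercentage:
    def test_ratio_definition(self):
        body = np.zeros((10, 10, 10), bool)
        body[:10] = True
        adipose = np.zeros_like(body)
        adipose[:, :, :5] = True   # half the grid; intersect body
        from wbreg.core import MaskSet
        masks = MaskSet(body=body, bone=np.zeros_like(body),
                        lean=np.zeros_like(body), adipose=adipose & body,
                        inside_sat=np.zeros_like(body))
        img = VolumetricImage(np.zeros(body.shape), (1, 1, 1))
        assert fat_percentage(img, masks) == pytest.approx(0.5)

    def test_monotone_in_fat_shell(self):
        fracs = []
        for shell in (8.0, 12.0, 16.0):
            img, masks = generate_phantom(PhantomSpec(fat_shell_mm=shell,
                                                      seed=1, **COARSE))
            fracs.append(fat_percentage(img, masks))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_empty_body_raises(self):
        from wbreg.core import MaskSet
        z = np.zeros((8, 8, 8), bool)
        masks = MaskSet(body=z, bone=z, lean=z, adipose=z, inside_sat=z)
        with pytest.raises(ValueError):
            fat_percentage(VolumetricImage(np.zeros(z.shape), (1, 1, 1)), masks)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=0.5, max_value=5.0),
       st.floats(min_value=0.5, max_value=5.0))
def test_harmonize_tolerance_rule(sa, sz):
    """Axes are touched iff spacings differ by more than epsilon."""
    a = VolumetricImage(np.zeros((16, 16, 16)), (sa, 1.0, sz))
    b = VolumetricImage(np.zeros((16, 16, 16)), (1.0, 1.0, 3.0))
    a2, b2 = harmonize_spacing(a, b, ResamplePolicy())
    for ax, (x, y) in enumerate(zip((sa, 1.0, sz), (1.0, 1.0, 3.0))):
        expected = max(x, y) if abs(x - y) > 0.1 else None
        if expected is not None:
            assert a2.spacing[ax] == pytest.approx(expected)
            assert b2.spacing[ax] == pytest.approx(expected)
        else:
            assert a2.spacing[ax] == pytest.approx(x)
            assert b2.spacing[ax] == pytest.approx(y)
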