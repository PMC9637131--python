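"""Shared fixtures.

Unit tests use a coarse (4 mm) phantom for speed; the two cohort fixtures
run the full five-step pipeline in both directions on the study-size
phantoms (64x64x128 at 3 mm) and are session-scoped so the registration
work is done once and shared by all evaluation tests.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from wbreg.metrics import evaluate_pair
from wbreg.phantom import (PhantomSpec, between_cohort_specs, generate_phantom,
                           longitudinal_cohort_params, make_between_pair,
                           make_longitudinal_pair)
from wbreg.pipeline import register_pair

COARSE = dict(grid_shape=(48, 48, 96), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def coarse_phantom():
    spec = PhantomSpec(seed=5, **COARSE)
    img, masks = generate_phantom(spec)
    return spec, img, masks


@pytest.fixture(scope="session")
def small_between_truth():
    """One coarse between-subject pair for fast ground-truth tests."""
    spec_a = PhantomSpec(fat_shell_mm=10.0, seed=21, **COARSE)
    spec_b = PhantomSpec(fat_shell_mm=18.0, seed=22,
                         skeleton_pose={"head": ((0.0, 0.0, 2.0), (0.0, 3.0, -5.0)),
                                        "left_arm": ((0.0, 0.0, 0.0), (4.0, 0.0, 0.0))},
                         **COARSE)
    return make_between_pair(spec_a, spec_b)


@pytest.fixture(scope="session")
def instrumented_coarse_run(small_between_truth):
    """One coarse pair registered with per-step field snapshots."""
    from wbreg.pipeline import RegistrationOptions

    tr = small_between_truth
    opts = RegistrationOptions(keep_step_fields=True)
    field, report = register_pair(tr.image_a, tr.masks_a, tr.image_b,
                                  tr.masks_b, opts)
    return field, report


def _run_pair(truth):
    t0 = time.perf_counter()
    fwd, rep_f = register_pair(truth.image_a, truth.masks_a,
                               truth.image_b, truth.masks_b)
    rev, rep_r = register_pair(truth.image_b, truth.masks_b,
                               truth.image_a, truth.masks_a)
    elapsed = time.perf_counter() - t0
    report = evaluate_pair(truth.image_a, truth.image_b, truth.masks_a,
                           truth.masks_b, fwd, rev)
    return {"truth": truth, "forward": fwd, "reverse": rev, "metrics": report,
            "reports": (rep_f, rep_r), "seconds": elapsed}


@pytest.fixture(scope="session")
def between_runs():
    """Five between-subject analog pairs, registered in both directions."""
    truths = [make_between_pair(*s) for s in between_cohort_specs(5, seed=1)]
    return [_run_pair(t) for t in truths]


@pytest.fixture(scope="session")
def longitudinal_runs():
    """Five longitudinal analog pairs (5-15% shrink), both directions."""
    truths = [make_longitudinal_pair(spec, frac)
              for spec, frac in longitudinal_cohort_params(5, seed=11)]
    return [_run_pair(t) for t in truths]
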