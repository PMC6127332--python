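"""Shared fixtures.

The expensive session fixtures run the optimisation pipeline once and are
shared across the analysis, perturbation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import wusham as wm
from wusham.optimize import OptimizerSettings, run_pipeline


@pytest.fixture(scope="session")
def template30():
    return wm.build_2d_template(30)


@pytest.fixture(scope="session")
def targets30(template30):
    return wm.make_target_domains(template30)


@pytest.fixture(scope="session")
def template10():
    return wm.build_2d_template(10)


@pytest.fixture(scope="session")
def targets10(template10):
    return wm.make_target_domains(template10)


@pytest.fixture()
def default_params():
    return wm.ModelParameters()


@pytest.fixture(scope="session")
def pipeline_batch(template30, targets30):
    """Pipeline runs on the standard template: seeds 0.. until two accepted.

    Returns the list of all completed runs (accepted and not), states kept.
    """
    results = []
    n_accepted = 0
    for seed in range(6):
        res = run_pipeline(seed, template30, targets30, keep_state=True)
        results.append(res)
        n_accepted += res.accepted
        if n_accepted >= 2:
            break
    return results


@pytest.fixture(scope="session")
def accepted_runs(pipeline_batch):
    accepted = [r for r in pipeline_batch if r.accepted]
    if not accepted:
        pytest.fail("no accepted parameter set found in the pipeline batch")
    return accepted


@pytest.fixture(scope="session")
def synthetic3d_run():
    """One pipeline run on a small synthetic 3D template (smoke scale)."""
    from wusham.optimize import run_pipeline_3d

    template = wm.generate_synthetic_3d_template(100, seed=1)
    targets = wm.make_target_domains(template)
    best = None
    for seed in range(3):
        res = run_pipeline_3d(seed, template, targets)
        if best is None or res.final_clv3_error < best.final_clv3_error:
            best = res
        if best.failure_stage is None and np.isfinite(best.final_clv3_error):
            break
    return best


@pytest.fixture(scope="session")
def optimized10(template10, targets10):
    """A parameter set optimised on the radius-10 template (best of 2 seeds)."""
    best = None
    for seed in range(2):
        res = run_pipeline(seed, template10, targets10, keep_state=True)
        if best is None or res.final_clv3_error < best.final_clv3_error:
            best = res
    assert np.isfinite(best.final_clv3_error)
    return best
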