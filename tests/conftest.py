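"""Shared fixtures: the mixed-curvature phantom and one full pipeline run.

The expensive end-to-end run (tracking the five-radius curvature sweep and
fitting every model) is done once per session and reused by the ensemble,
tract and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from enstract.ensemble import curvature_sweep, run_ensemble_pipeline
from enstract.phantom import mixed_phantom

PHANTOM_SEED = 1
SWEEP_SEED = 100


@pytest.fixture(scope="session")
def phantom():
    return mixed_phantom(seed=PHANTOM_SEED)


@pytest.fixture(scope="session")
def pipeline(phantom):
    sweep = curvature_sweep(seed=SWEEP_SEED)
    return run_ensemble_pipeline(phantom.field, phantom.repeat1, phantom.repeat2, sweep)


@pytest.fixture(scope="session")
def sweep_params():
    return curvature_sweep(seed=SWEEP_SEED)


def radius_label(radius: float) -> str:
    return f"probabilistic:r{radius:g}mm"


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
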