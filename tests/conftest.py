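"""Shared fixtures.

The three production-style disc runs are expensive relative to everything
else, so they are computed once per session at a moderate grid resolution and
shared between the solver, front-analysis, imaging and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from gelfront import (
    ModelParameters,
    SolverOptions,
    build_trajectory,
    integrate,
    make_disc_scenario,
)

#: Grid resolution for the shared disc runs: coarse enough to keep the suite
#: fast, fine enough for every property under test (grid-robustness is
#: checked separately at 400/800 nodes).
SHARED_DISC_NODES = 300


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters.default()


@pytest.fixture(scope="session")
def disc_runs(params):
    """{bath_mM: (scenario, result, trajectory)} for 10/20/40 mM discs."""
    out = {}
    for mM in (10, 20, 40):
        scenario = make_disc_scenario(mM, params, n_nodes=SHARED_DISC_NODES)
        result = integrate(scenario, params, SolverOptions())
        traj = build_trajectory(result, params)
        out[mM] = (scenario, result, traj)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
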