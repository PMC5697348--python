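"""Shared fixtures: the reference parameter set and cached line runs.

The expensive 24-h batch integrations are session-scoped so every test
module reuses the same trajectories.
"""

import numpy as np
import pytest

from ppgppsim import ModelParameters, Scenario
from ppgppsim.experiments import run_line
from ppgppsim.simulate import apply_upshift


@pytest.fixture(scope="session")
def ref_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def line0_run(ref_params):
    return run_line("line0", ref_params)


@pytest.fixture(scope="session")
def line1_run(ref_params):
    return run_line("line1", ref_params)


@pytest.fixture(scope="session")
def line3_run(ref_params):
    return run_line("line3", ref_params)


@pytest.fixture(scope="session")
def upshift_run(ref_params):
    """Reference upshift run: (trajectory, event time), 0.5-min grid."""
    scen = Scenario(params=ref_params, t_end=700.0, output_dt=0.5)
    return apply_upshift(scen)


@pytest.fixture()
def rng():
    return np.random.default_rng(20171121)
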