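"""Shared fixtures: small synthetic heads and neuron rosters.

Everything is generated at test time; fixtures favor a 24 kHz rate and short
stimuli to keep the suite fast while staying above the 20 kHz floor.
"""

import numpy as np
import pytest

from owlspace.hrtf_io import GridSpec
from owlspace.synthetic_data import HeadModelParams, make_head_model_hrirs


@pytest.fixture(scope="session")
def head_params():
    return HeadModelParams(sample_rate_hz=24_000.0, hrir_len=128)


@pytest.fixture(scope="session")
def head_params_48k():
    return HeadModelParams(sample_rate_hz=48_000.0, hrir_len=256)


@pytest.fixture(scope="session")
def az_grid():
    return GridSpec.standard_azimuth()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec((-80.0, -40.0, 0.0, 40.0, 80.0))


@pytest.fixture(scope="session")
def normal_head(head_params, az_grid):
    return make_head_model_hrirs(head_params, "normal", az_grid, seed=1)


@pytest.fixture(scope="session")
def ruffless_head(head_params, az_grid):
    return make_head_model_hrirs(head_params, "ruff_removed", az_grid, seed=1)


@pytest.fixture(scope="session")
def normal_head_48k(head_params_48k, az_grid):
    return make_head_model_hrirs(head_params_48k, "normal", az_grid, seed=1)


@pytest.fixture(scope="session")
def small_normal_head(head_params, small_grid):
    return make_head_model_hrirs(head_params, "normal", small_grid, seed=2)


@pytest.fixture(scope="session")
def small_ruffless_head(head_params, small_grid):
    return make_head_model_hrirs(head_params, "ruff_removed", small_grid, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
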