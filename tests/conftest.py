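"""Shared fixtures.

Synthetic cells are generated once per session at desk-scale sampling
rates (1 ms for the step protocols, 0.5 ms for the fluctuating ones);
tests that need the full 0.1 ms rate build their own data.
"""

from __future__ import annotations

import numpy as np
import pytest

from ikrfit.model import IonicConditions, ModelParameters
from ikrfit.protocols import build_default_protocols
from ikrfit.synthetic import (
    default_conditions,
    default_fixture,
    default_params,
    generate_ap_waveform,
    generate_cell,
)

TEST_DT = {"Pr2": 1.0, "Pr3": 1.0, "Pr4": 1.0, "Pr5": 1.0, "Pr6": 1.0, "Pr7": 0.5}


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return default_params()


@pytest.fixture(scope="session")
def conditions() -> IonicConditions:
    return default_conditions()


@pytest.fixture(scope="session")
def protocols():
    protos = build_default_protocols()
    protos["Pr6"] = generate_ap_waveform(seed=0)
    return protos


@pytest.fixture(scope="session")
def noiseless_cell(protocols):
    spec = default_fixture(seed=0, noise_sigma=0.0)
    return generate_cell(spec, protocols=protocols, dt=TEST_DT, cell_id="clean")


@pytest.fixture(scope="session")
def noisy_cell(protocols):
    spec = default_fixture(seed=1)
    return generate_cell(spec, protocols=protocols, dt=TEST_DT, cell_id="noisy")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
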