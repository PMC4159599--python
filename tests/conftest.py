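"""Shared fixtures.

The limit cycle, PRC and designed stimuli are expensive; they are computed
once per session through the workbench memo layer so every test file shares
them.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurodesync.electrode import CircuitParams
from neurodesync.neuron import NeuronParams


@pytest.fixture(scope="session")
def params() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def circuit() -> CircuitParams:
    return CircuitParams()


@pytest.fixture(scope="session")
def phase_model():
    """(params, limit_cycle, prc) for the default neuron, computed once."""
    from neurodesync.workbench import get_phase_model

    return get_phase_model()


@pytest.fixture(scope="session")
def lc(phase_model):
    return phase_model[1]


@pytest.fixture(scope="session")
def prc(phase_model):
    return phase_model[2]


@pytest.fixture(scope="session")
def design_g8():
    from neurodesync.workbench import get_design

    return get_design(8.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140605)
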