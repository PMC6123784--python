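"""Shared fixtures: small parameter sets, topologies, reference traces."""

from __future__ import annotations

import numpy as np
import pytest

from luxlink.circuit import ModelParams, build_configuration, get_params
from luxlink.traces import TraceSet


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return get_params("default-v1")


@pytest.fixture(scope="session")
def osc_a():
    return build_configuration("OSC_A")


@pytest.fixture(scope="session")
def osc_a_trace(osc_a, default_params):
    """One long oscillator run shared by the slower analysis tests."""
    from luxlink.solver import simulate

    return simulate(osc_a, default_params, t_end=1800.0)


@pytest.fixture
def sine_trace() -> TraceSet:
    """Clean 60-min-period sine sampled every 3 min over [0, 180]."""
    t = np.arange(0.0, 181.0, 3.0)
    return TraceSet(
        t,
        {"F_sender": 50.0 + 40.0 * np.sin(2.0 * np.pi * t / 60.0)},
        {"topology": "synthetic-sine"},
    )
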