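"""Shared fixtures: small, fast network instances generated at test time."""

import numpy as np
import pytest

from canmf import (
    CalciumParams,
    NodalConfig,
    ProcessConfig,
    normalize_global,
    simulate_nodal,
    simulate_process,
)


@pytest.fixture(scope="session")
def small_nodal_config() -> NodalConfig:
    """A 25-neuron, 5-node network over 20 s — fast but structurally complete."""
    return NodalConfig(n_neurons=25, n_nodes=5, n_steps=600, seed=7)


@pytest.fixture(scope="session")
def small_process_config() -> ProcessConfig:
    return ProcessConfig(n_neurons=40, n_processes=5, n_steps=600, seed=7)


@pytest.fixture(scope="session")
def small_nodal_data(small_nodal_config):
    traces, raster, truth = simulate_nodal(small_nodal_config)
    return {
        "traces": traces,
        "raster": raster,
        "truth": truth,
        "X": normalize_global(traces),
        "config": small_nodal_config,
    }


@pytest.fixture(scope="session")
def small_process_data(small_process_config):
    calcium = CalciumParams(dt=small_process_config.dt)
    traces, raster, truth = simulate_process(small_process_config, calcium)
    return {
        "traces": traces,
        "raster": raster,
        "truth": truth,
        "X": normalize_global(traces),
        "config": small_process_config,
        "calcium": calcium,
    }


@pytest.fixture(scope="session")
def noisefree_nodal_traces(small_nodal_config):
    """Noise-free traces of the small nodal network (calcium kernel only)."""
    calcium = CalciumParams(dt=small_nodal_config.dt).noiseless()
    traces, raster, truth = simulate_nodal(small_nodal_config, calcium)
    return traces, raster, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
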