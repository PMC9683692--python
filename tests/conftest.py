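"""Shared fixtures: parameter table, fast solver settings, synthetic patients.

The forward solver is numba-compiled once per session; the first fixture
use pays the compilation cost.
"""

from __future__ import annotations

import numpy as np
import pytest

from cvcalib.ga import GAConfig, ga_optimize
from cvcalib.parameters import default_parameters
from cvcalib.pipeline import PIPELINE_SIM
from cvcalib.synthetic import generate_patient


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def sim_cfg():
    """Coarse pipeline solver settings (accuracy ~1e-4 relative)."""
    return PIPELINE_SIM


@pytest.fixture(scope="session")
def nominal_run(params, sim_cfg):
    """One forward solve at the nominal parameters."""
    from cvcalib.model import simulate

    out = simulate(params, sim_cfg)
    assert out.solver_ok
    return out


@pytest.fixture(scope="session")
def noisy_patient(params, sim_cfg):
    """Synthetic patient with the full 15-observable set and table CVs."""
    return generate_patient(params, seed=42, sim_config=sim_cfg)


@pytest.fixture(scope="session")
def noise_free_patient(params, sim_cfg):
    return generate_patient(params, seed=0, noise_scale=0.0,
                            sim_config=sim_cfg)


@pytest.fixture(scope="session")
def scaled_ga_optimizer():
    """A deterministic, session-cheap GA optimizer factory for reduction."""
    counter = {"i": 0}

    def optimizer(objective, bounds):
        cfg = GAConfig(population_size=32, generations=40,
                       stall_generations=15, seed=5000 + counter["i"])
        counter["i"] += 1
        return ga_optimize(objective, bounds, cfg)

    return optimizer
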