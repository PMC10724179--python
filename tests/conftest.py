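"""Shared fixtures: reduced-scale trained agents and planted populations.

Training fixtures are session-scoped and built lazily, so cheap tests do
not pay for them.  All seeds are fixed for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

from tempocells.agent import build_agent
from tempocells.envs import make_env
from tempocells.pipelines import task_preset
from tempocells.recording import normalize_units, record_activity
from tempocells.synth import PlantedPopulationSpec, generate
from tempocells.training import train_agent

SEED = 1


def _train_preset(task: str, delay: int | None = None):
    tc, ac, trc, n_rec = task_preset(task, "REDUCED", SEED)
    if delay is not None:
        tc.delay_length = delay
    env = make_env(tc)
    params = build_agent(ac)
    params, curve = train_agent(env, params, trc, ac)
    return {"env": env, "params": params, "ac": ac, "tc": tc, "curve": curve}


@pytest.fixture(scope="session")
def dnms_agent():
    """Mnemonic DNMS agent at the reduced preset (delay 10, 64 units)."""
    return _train_preset("DNMS")


@pytest.fixture(scope="session")
def ddc_agent():
    """DDC agent at the reduced preset (durations 3..9, delay 6)."""
    return _train_preset("DDC")


@pytest.fixture(scope="session")
def dnms40_agents():
    """Mnemonic and non-mnemonic DNMS agents at the original 40-step delay."""
    return {task: _train_preset(task, delay=40)
            for task in ("DNMS", "DNMS_NONMNEMONIC")}


@pytest.fixture(scope="session")
def dnms_delay_tensor(dnms_agent):
    tensor = record_activity(dnms_agent["params"], dnms_agent["env"],
                             dnms_agent["ac"], n_episodes=1000,
                             window_tag="DELAY", seed=SEED + 90_000)
    return normalize_units(tensor)


@pytest.fixture(scope="session")
def dnms_cell_table(dnms_delay_tensor):
    from tempocells.cellclass import classify_population
    return classify_population(dnms_delay_tensor, seed=SEED)


@pytest.fixture(scope="session")
def ddc_stim_tensor(ddc_agent):
    tensor = record_activity(ddc_agent["params"], ddc_agent["env"],
                             ddc_agent["ac"], n_episodes=2000,
                             window_tag="STIM1", seed=SEED + 90_000)
    return normalize_units(tensor)


@pytest.fixture(scope="session")
def recovery_population():
    """The central calibration population: 30/20/10/68 units, sigma=0.1."""
    spec = PlantedPopulationSpec(
        n_trials=500, n_time=40, n_units=128,
        counts={"TIME_CELL": 30, "RAMPING_CELL": 20, "BOTH": 10, "NOISE": 68},
        noise_sd=0.1, rng_seed=7)
    tensor, truth = generate(spec)
    return tensor, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
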