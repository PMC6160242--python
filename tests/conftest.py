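"""Shared fixtures: geometry, small trained agents, and the replicated
variant grid used by the acceptance-level behavioral tests."""

from __future__ import annotations

import numpy as np
import pytest

from mbnav import ExperimentConfig, MazeGeometry
from mbnav.agent import Agent
from mbnav.maze import Phase
from mbnav.protocol import (
    run_experiment,
    run_phase,
    variant_config,
)

ACCEPTANCE_SEED = 1
N_ACCEPTANCE_LEARNERS = 3


@pytest.fixture(scope="session")
def geometry() -> MazeGeometry:
    return MazeGeometry()


@pytest.fixture(scope="session")
def default_config() -> ExperimentConfig:
    return ExperimentConfig().validate()


@pytest.fixture(scope="session")
def tiny_trained(geometry, default_config):
    """A lightly trained full-sweep agent plus its trial logs (shared by
    the analysis and control tests)."""
    cfg = variant_config(default_config, "swcr")
    agent = Agent(cfg, geometry, np.random.SeedSequence(5))
    logs = run_phase(
        agent, geometry, Phase.CUE, cfg, n_trials=150, record_steps=True
    )
    return agent, logs


@pytest.fixture(scope="session")
def cue_grid(default_config, geometry):
    """Cue-phase replication of all four agent variants (the reduced
    acceptance-scale study: 3 learners each, full 2,000-trial phase);
    the full-sweep variant additionally runs the context phase and both
    free-run probes."""
    runs = {}
    runs["swcr"] = run_experiment(
        "swcr", default_config, n_learners=N_ACCEPTANCE_LEARNERS, seed=ACCEPTANCE_SEED
    )
    for variant in ("swcontrol", "swreward", "baseline"):
        cfg = variant_config(default_config, variant)
        learners = []
        root = np.random.SeedSequence(ACCEPTANCE_SEED)
        for ss in root.spawn(N_ACCEPTANCE_LEARNERS):
            agent = Agent(cfg, geometry, ss)
            learners.append(run_phase(agent, geometry, Phase.CUE, cfg))
        runs[variant] = learners
    return runs
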