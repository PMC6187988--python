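"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from painarb.simulation import AgentParameters, simulate_agent
from painarb.task_env import TaskConfig, build_environment, generate_session_plan


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def env(config):
    return build_environment(config)


@pytest.fixture(scope="session")
def default_plan(config):
    return generate_session_plan(config, np.random.default_rng(11))


@pytest.fixture(scope="session")
def default_sim(env, default_plan):
    """One arbitrating agent at reference parameters (trials, trace)."""
    return simulate_agent(env, AgentParameters(), default_plan, seed=12)


def expectimax_q(T: np.ndarray, succ: np.ndarray, tv: np.ndarray) -> np.ndarray:
    """Exhaustive expectimax over the two-level tree, written independently.

    Enumerates every root-to-leaf path explicitly: second-stage action values
    are leaf sums, intermediate state values are the max over actions, and
    root action values weight those maxima by the first transition.
    """
    q = np.zeros((5, 2))
    for s in (1, 2, 3, 4):
        for a in (0, 1):
            total = 0.0
            for k in (0, 1):
                leaf = succ[s, a, k]
                total += T[s, a, k] * tv[leaf - 5]
            q[s, a] = total
    for a in (0, 1):
        total = 0.0
        for k in (0, 1):
            mid = succ[0, a, k]
            total += T[0, a, k] * max(q[mid, 0], q[mid, 1])
        q[0, a] = total
    return q
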