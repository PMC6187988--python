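"""Synthetic-behaviour engine: run agents through generated sessions.

This module stands in for human subjects: it produces trial logs (one row per
trial) together with latent traces (per-trial Q tables, prediction errors,
reliabilities and the controller weight p_MB) for arbitrating, model-free-only,
model-based-only, ideal and random agents.

Default agent parameters are the package's reference study conditions; see
docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .task_env import (
    ACTIONS,
    COLOURS,
    Environment,
    SessionPlan,
    TaskConfig,
    WHITE,
    build_environment,
    deliver_outcome,
    generate_session_plan,
)

__all__ = [
    "AgentParameters",
    "simulate_agent",
    "simulate_cohort",
    "ideal_agent_policy",
    "CohortMember",
]

AGENT_KINDS = {
    "arbitrating": _kernel.KIND_ARBITRATING,
    "mf_only": _kernel.KIND_MF_ONLY,
    "mb_only": _kernel.KIND_MB_ONLY,
    "ideal": _kernel.KIND_IDEAL,
    "random": _kernel.KIND_RANDOM,
}

#: free parameters fitted from behaviour, in canonical order
FREE_PARAMETERS = ("alpha", "eta", "omega", "a_mf_to_mb", "a_mb_to_mf", "beta")


@dataclass(frozen=True)
class AgentParameters:
    """The six free model parameters plus fixed arbitration constants.

    alpha: shared learning rate of both value systems, in (0, 1].
    eta: learning rate of the reliability estimators, in (0, 1].
    omega: zero-SPE threshold for the model-based reliability, in (0, 1).
    a_mf_to_mb / a_mb_to_mf: amplitudes of the MF→MB and MB→MF transition
        rates, positive.
    beta: softmax inverse temperature, non-negative.
    steepness, mf_bias, omega_max: fixed constants of the arbitration model.
    """

    alpha: float = 0.25
    eta: float = 0.3
    omega: float = 0.5
    a_mf_to_mb: float = 0.7
    a_mb_to_mf: float = 0.5
    beta: float = 2.5
    steepness: float = 10.0
    mf_bias: float = 1.5
    omega_max: float = 4.0
    kind: str = "arbitrating"

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0.0 < self.eta <= 1.0:
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        if not 0.0 < self.omega < 1.0:
            raise ValueError(f"omega must be in (0, 1), got {self.omega}")
        if self.a_mf_to_mb <= 0.0 or self.a_mb_to_mf <= 0.0:
            raise ValueError("transition-rate amplitudes must be positive")
        if self.beta < 0.0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FREE_PARAMETERS])

    @classmethod
    def from_vector(cls, vector: Sequence[float], **fixed) -> "AgentParameters":
        kwargs = dict(zip(FREE_PARAMETERS, (float(v) for v in vector)))
        kwargs.update(fixed)
        return cls(**kwargs)


def default_param_sampler(rng: np.random.Generator) -> AgentParameters:
    """Reference between-subject parameter distribution for cohort studies.

    Uniform boxes straddling the default agent, wide enough that recovery
    correlations are informative but inside the fitting bounds.
    """
    return AgentParameters(
        alpha=rng.uniform(0.1, 0.5),
        eta=rng.uniform(0.1, 0.5),
        omega=rng.uniform(0.2, 0.7),
        a_mf_to_mb=rng.uniform(0.2, 0.9),
        a_mb_to_mf=rng.uniform(0.2, 0.9),
        beta=rng.uniform(0.5, 5.0),
    )


#: columns of a latent trace (plus flattened Q_MF / Q_MB / T snapshots)
TRACE_SCALARS = (
    "p_left0", "p_left1", "p_action0", "p_action1",
    "ope1", "ope2", "spe1", "spe2",
    "omega", "chi_mf", "chi_mb", "p_mb",
)


def _plan_arrays(plan: SessionPlan) -> pd.DataFrame:
    frame = plan.to_frame()
    if frame.empty:
        raise ValueError("session plan holds no trials")
    return frame


def _encode_trials(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    cond = (frame["condition"] == "specific").to_numpy(np.int64)
    unc = (frame["uncertainty"] == "high").to_numpy(np.int64)
    goal = np.array(
        [COLOURS.index(g) if g != WHITE else -1 for g in frame["goal"]], np.int64
    )
    training = frame["training"].to_numpy(np.int64)
    return {"cond": cond, "unc": unc, "goal": goal, "training": training}


def _run_kernel(
    env: Environment,
    params: AgentParameters,
    enc: dict[str, np.ndarray],
    *,
    miss: np.ndarray,
    forced: dict[str, np.ndarray] | None,
    u: np.ndarray,
    initial_T: np.ndarray | None = None,
    initial_q_mf: np.ndarray | None = None,
):
    n = enc["cond"].shape[0]
    none = np.full(n, -1, np.int64)
    forced = forced or {}
    q_mf = np.zeros((5, 2)) if initial_q_mf is None else initial_q_mf.astype(float).copy()
    T = np.full((5, 2, 2), 0.5) if initial_T is None else initial_T.astype(float).copy()
    return _kernel.run_trials(
        enc["cond"], enc["unc"], enc["goal"], enc["training"], miss,
        forced.get("a0", none), forced.get("s1", none),
        forced.get("a1", none), forced.get("out", none),
        forced.get("shocks", none),
        u, env.succ, env.outcome_shocks,
        env.p_likely_low, env.p_likely_high,
        params.alpha, params.eta, params.omega,
        params.a_mf_to_mb, params.a_mb_to_mf, params.beta,
        params.steepness, params.mf_bias, params.omega_max,
        AGENT_KINDS[params.kind],
        q_mf, T, 0.0, 0.5, 0.5,
    )


def _trace_frame(out, n: int) -> pd.DataFrame:
    (a0, s1, a1, out_state, shocks,
     p_left0, p_left1, p_taken0, p_taken1,
     ope1, ope2, spe1, spe2,
     omega_tr, chi_mf_tr, chi_mb_tr, p_mb_tr,
     q_mf_tr, q_mb_tr, t_likely_tr, *_) = out
    data = {
        "p_left0": p_left0, "p_left1": p_left1,
        "p_action0": p_taken0, "p_action1": p_taken1,
        "ope1": ope1, "ope2": ope2, "spe1": spe1, "spe2": spe2,
        "omega": omega_tr, "chi_mf": chi_mf_tr, "chi_mb": chi_mb_tr,
        "p_mb": p_mb_tr,
    }
    from .task_env import STATE_NAMES

    for s in range(5):
        for a in range(2):
            suffix = f"{STATE_NAMES[s]}_{ACTIONS[a]}"
            data[f"q_mf_{suffix}"] = q_mf_tr[:, s, a]
            data[f"q_mb_{suffix}"] = q_mb_tr[:, s, a]
            data[f"T_likely_{suffix}"] = t_likely_tr[:, s, a]
    return pd.DataFrame(data)


def simulate_agent(
    env: Environment,
    params: AgentParameters,
    plan: SessionPlan,
    seed: int,
    *,
    subject: str = "sim-0",
    miss_probability: float = 0.0,
    initial_T: np.ndarray | None = None,
    initial_q_mf: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one agent through a session plan.

    Returns ``(trials, trace)``: the trial log (schema
    :data:`painarb.task_env.TRIAL_COLUMNS`) and the aligned latent trace.
    Fully reproducible from the seed. ``miss_probability`` inserts
    computer-chosen random trials flagged ``excluded`` (penalising trials).
    Optional ``initial_T`` / ``initial_q_mf`` override the uniform/zero
    initial learner state (e.g. to hand an agent the true transition model).
    """
    frame = _plan_arrays(plan)
    enc = _encode_trials(frame)
    n = len(frame)
    rng = np.random.default_rng(seed)
    miss = (rng.random(n) < miss_probability).astype(np.int64)
    u = rng.random((n, 4))
    out = _run_kernel(
        env, params, enc, miss=miss, forced=None, u=u,
        initial_T=initial_T, initial_q_mf=initial_q_mf,
    )
    a0, s1, a1, out_state, shocks = out[:5]

    trials = frame.copy()
    trials.insert(0, "subject", subject)
    trials["state0"] = "S0"
    trials["action0"] = [ACTIONS[a] for a in a0]
    trials["state1"] = [env.states[s] for s in s1]
    trials["action1"] = [ACTIONS[a] for a in a1]
    trials["outcome_state"] = [env.states[o] for o in out_state]
    trials["coin_colour"] = [env.outcome_map[env.states[o]][0] for o in out_state]
    trials["coin_value"] = [env.outcome_map[env.states[o]][1] for o in out_state]
    trials["shocks"] = shocks.astype(int)
    trials["excluded"] = miss.astype(bool)
    trace = _trace_frame(out, n)
    return trials, trace


@dataclass(frozen=True)
class CohortMember:
    subject: str
    seed: int
    params: AgentParameters
    trials: pd.DataFrame
    trace: pd.DataFrame


def simulate_cohort(
    n_subjects: int,
    param_sampler: Callable[[np.random.Generator], AgentParameters],
    config: TaskConfig | None = None,
    seed: int = 0,
    *,
    env: Environment | None = None,
) -> list[CohortMember]:
    """Simulate independent subjects with per-subject seeds and plans.

    ``param_sampler`` draws each subject's true parameters; they are stored
    alongside the data for parameter-recovery studies. Child seeds derive
    deterministically from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    config = config or TaskConfig()
    env = env or build_environment(config)
    members = []
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        params = param_sampler(rng)
        plan = generate_session_plan(config, rng)
        trials, trace = simulate_agent(
            env, params, plan, seed=sub_seed + 1,
            subject=f"sim-{i}", miss_probability=config.miss_probability,
        )
        members.append(
            CohortMember(
                subject=f"sim-{i}", seed=sub_seed, params=params,
                trials=trials, trace=trace,
            )
        )
    return members


def enumerate_policy(
    env: Environment,
    condition: str,
    uncertainty: str,
    goal_colour: str,
    policy: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Exact outcome distribution of a (possibly uniform) policy.

    ``policy`` maps (choice state, action) to the probability of taking that
    action; ``None`` means the uniform random policy. Returns one row per
    root-to-leaf path with its probability and delivered shocks — the
    enumeration oracle behind the random- and ideal-agent baselines.
    """
    p_likely = env.p_likely_low if uncertainty == "low" else env.p_likely_high
    rows = []
    for a0, k1, a1, k2 in itertools.product(ACTIONS, range(2), ACTIONS, range(2)):
        pa0 = 0.5 if policy is None else policy[("S0", a0)]
        s1 = env.states[env.succ[0, ACTIONS.index(a0), k1]]
        p_s1 = p_likely if k1 == 0 else 1.0 - p_likely
        pa1 = 0.5 if policy is None else policy[(s1, a1)]
        o = env.states[env.succ[env.state_index(s1), ACTIONS.index(a1), k2]]
        p_o = p_likely if k2 == 0 else 1.0 - p_likely
        colour, value = env.outcome_map[o]
        shocks = deliver_outcome(colour, value, condition, goal_colour)
        rows.append(
            {
                "action0": a0, "state1": s1, "action1": a1, "outcome_state": o,
                "prob": pa0 * p_s1 * pa1 * p_o, "shocks": shocks,
            }
        )
    return pd.DataFrame(rows)


def ideal_agent_policy(
    env: Environment,
    condition: str,
    uncertainty: str,
    goal_colour: str,
) -> dict[str, str]:
    """Expectimax-optimal action per choice state under the true dynamics.

    Pure-Python enumeration independent of the learning kernel; ties break in
    fixed action order (LEFT first). Used as the optimal-choice reference in
    the behavioural analyses.
    """
    p_likely = env.p_likely_low if uncertainty == "low" else env.p_likely_high
    tv = {}
    for o, (colour, value) in env.outcome_map.items():
        tv[o] = -float(deliver_outcome(colour, value, condition, goal_colour))

    policy: dict[str, str] = {}
    state_value: dict[str, float] = {}
    for s in env.choice_states[1:]:
        best_a, best_v = None, -np.inf
        for a in ACTIONS:
            vec = env.transition_table[
                (s, a, uncertainty)
            ]
            v = sum(p * tv[o] for o, p in vec.items())
            if v > best_v:  # strict: earlier action wins ties
                best_a, best_v = a, v
        policy[s] = best_a
        state_value[s] = best_v
    best_a, best_v = None, -np.inf
    for a in ACTIONS:
        vec = env.transition_table[("S0", a, uncertainty)]
        v = sum(p * state_value[s1] for s1, p in vec.items())
        if v > best_v:
            best_a, best_v = a, v
    policy["S0"] = best_a
    return policy
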