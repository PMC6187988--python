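"""Model-free (SARSA) and model-based (FORWARD) value-learning systems.

The model-free system maintains Q_MF(s, a), updated by the outcome prediction
error OPE = r + Q_MF(s′, a′) − Q_MF(s, a) with a single learning rate α shared
by both systems. It learns purely from experienced (devalued) outcomes and is
blind to the goal rule.

The model-based system maintains a transition model T(s, a, s′), updated by
the state prediction error SPE = 1 − T(s, a, s_observed), and computes
Q_MB by exact backward induction over the two-level tree. When the goal
changes, backward planning devalues mismatching outcome states before values
are recomputed, which is what lets this system adapt instantly to the
specific-goal rule.

Both states are small immutable-by-convention dataclasses; the update
operations return modified copies and delegate the arithmetic to the compiled
primitives in :mod:`painarb._kernel` — the same code the trial-loop kernel
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernel
from .task_env import COLOURS, Environment

__all__ = [
    "ModelFreeState",
    "ModelBasedState",
    "mf_update",
    "mb_update_transition",
    "mb_compute_values",
    "devalue_outcomes",
]


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"learning rate alpha must be in (0, 1], got {alpha}")


@dataclass(frozen=True)
class ModelFreeState:
    """SARSA learner state: Q_MF over (choice state, action) plus α."""

    env: Environment
    q: np.ndarray  # (5, 2) float64
    alpha: float

    @classmethod
    def zeros(cls, env: Environment, alpha: float) -> "ModelFreeState":
        _check_alpha(alpha)
        return cls(env=env, q=np.zeros((5, 2)), alpha=alpha)

    def value(self, state: str, action: str) -> float:
        return float(self.q[self.env.state_index(state), self.env.actions.index(action)])


@dataclass(frozen=True)
class ModelBasedState:
    """FORWARD learner state: transition model, terminal values and Q_MB.

    ``T[s, a, k]`` is the probability of the k-th configured successor of
    (s, a) (slot order follows ``env.succ``); each row sums to 1.
    ``terminal_values`` holds the current (possibly devalued) signed value of
    each outcome state, indexed by coin colour.
    """

    env: Environment
    T: np.ndarray  # (5, 2, 2) float64, row-stochastic
    terminal_values: np.ndarray  # (4,) float64 by colour index
    q: np.ndarray  # (5, 2) float64
    alpha: float

    @classmethod
    def uniform(cls, env: Environment, alpha: float) -> "ModelBasedState":
        """Uniform transition model and flexible-rule terminal values."""
        _check_alpha(alpha)
        state = cls(
            env=env,
            T=np.full((5, 2, 2), 0.5),
            terminal_values=-env.outcome_shocks.copy(),
            q=np.zeros((5, 2)),
            alpha=alpha,
        )
        return mb_compute_values(state)

    def transition_prob(self, state: str, action: str, successor: str) -> float:
        s = self.env.state_index(state)
        a = self.env.actions.index(action)
        target = self.env.state_index(successor)
        for k in range(2):
            if self.env.succ[s, a, k] == target:
                return float(self.T[s, a, k])
        raise KeyError(f"{successor!r} is not a configured successor of ({state}, {action})")

    def value(self, state: str, action: str) -> float:
        return float(self.q[self.env.state_index(state), self.env.actions.index(action)])


def mf_update(
    mf: ModelFreeState,
    state: str,
    action: str,
    r: float,
    next_state: str | None = None,
    next_action: str | None = None,
) -> tuple[ModelFreeState, float]:
    """One SARSA step on (state, action); returns the new state and the OPE.

    For the first-stage transition pass r = 0 with the chosen next pair; at
    the terminal transition omit the next pair (the bootstrap term is 0).
    """
    _check_alpha(mf.alpha)
    s = mf.env.state_index(state)
    a = mf.env.actions.index(action)
    if next_state is None:
        q_next = 0.0
    else:
        q_next = mf.q[
            mf.env.state_index(next_state), mf.env.actions.index(next_action)
        ]
    q = mf.q.copy()
    q[s, a], ope = _kernel.sarsa_update(q[s, a], q_next, r, mf.alpha)
    return replace(mf, q=q), float(ope)


def mb_update_transition(
    mb: ModelBasedState, state: str, action: str, observed: str
) -> tuple[ModelBasedState, float]:
    """SPE update of T toward the observed successor; row renormalised.

    Raises ``KeyError`` if the observed state is not a configured successor.
    """
    s = mb.env.state_index(state)
    a = mb.env.actions.index(action)
    target = mb.env.state_index(observed)
    slot = -1
    for k in range(2):
        if mb.env.succ[s, a, k] == target:
            slot = k
    if slot < 0:
        raise KeyError(
            f"{observed!r} is not a configured successor of ({state}, {action})"
        )
    T = mb.T.copy()
    spe = _kernel.spe_update(T[s, a], slot, mb.alpha)
    return replace(mb, T=T), float(spe)


def mb_compute_values(mb: ModelBasedState) -> ModelBasedState:
    """Recompute Q_MB by exact backward induction over the two-level tree."""
    q = np.zeros_like(mb.q)
    _kernel.mb_values(mb.T, mb.env.succ, mb.terminal_values, q)
    return replace(mb, q=q)


def devalue_outcomes(
    mb: ModelBasedState, condition: str, goal_colour: str | None = None
) -> ModelBasedState:
    """Reset terminal values under the goal rule and replan.

    Specific condition: the goal-matching coin keeps −(its shock count),
    every other coin is devalued to −4. Flexible condition: face values.
    Q_MB is recomputed afterwards (backward planning).
    """
    tv = np.empty(4)
    if condition == "specific":
        if goal_colour not in ("red", "yellow", "blue"):
            raise ValueError(
                f"specific-condition goal must be red/yellow/blue, got {goal_colour!r}"
            )
        _kernel.devalued_terminal_values(
            mb.env.outcome_shocks, 1, COLOURS.index(goal_colour), tv
        )
    elif condition == "flexible":
        _kernel.devalued_terminal_values(mb.env.outcome_shocks, 0, -1, tv)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return mb_compute_values(replace(mb, terminal_values=tv))
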