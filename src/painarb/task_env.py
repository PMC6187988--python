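"""Two-step pain-avoidance task: states, transitions, outcomes and session plans.

The task is a sequential two-choice Markov decision problem. Each trial starts
in a single initial choice state; a LEFT/RIGHT choice leads stochastically to
one of four intermediate choice states, where a second LEFT/RIGHT choice leads
stochastically to one of four outcome states. Outcome states are coloured coins
(red, yellow, blue, grey) carrying 0, 1, 2 or 4 electric shocks. Transition
probabilities are (0.9, 0.1) in low-uncertainty blocks and (0.5, 0.5) in
high-uncertainty ones.

Two goal conditions manipulate outcome value. In the *flexible* condition all
coins keep their face value (the 0-shock red coin is always best). In the
*specific* condition a goal colour (red, yellow or blue — never grey) is shown
and changes every trial: only the matching coin keeps its value, every other
coin delivers the default maximum of 4 shocks. This is an outcome-devaluation
manipulation that favours goal-directed (model-based) control, while the
flexible condition favours habitual (model-free) control.

Sessions are organised in blocks crossing goal condition with transition
uncertainty: low-uncertainty blocks run 3–5 trials, high-uncertainty blocks
5–7. A default experiment holds a 100-trial training session (flexible goal,
high uncertainty, no shocks delivered) followed by two experimental sessions
of 24 blocks each (6 per condition × uncertainty cell), 48 blocks in total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

COLOURS: tuple[str, ...] = ("red", "yellow", "blue", "grey")
MAGNITUDES: tuple[int, ...] = (0, 1, 2, 4)
ACTIONS: tuple[str, str] = ("LEFT", "RIGHT")
CONDITIONS: tuple[str, str] = ("flexible", "specific")
UNCERTAINTIES: tuple[str, str] = ("low", "high")
WHITE = "white"
GOAL_COLOURS: tuple[str, ...] = ("red", "yellow", "blue")

#: canonical state names: 1 initial, 4 intermediate, 4 outcome states
INITIAL_STATE = "S0"
INTERMEDIATE_STATES: tuple[str, ...] = ("I1", "I2", "I3", "I4")
OUTCOME_STATES: tuple[str, ...] = tuple(f"O_{c}" for c in COLOURS)
STATE_NAMES: tuple[str, ...] = (INITIAL_STATE,) + INTERMEDIATE_STATES + OUTCOME_STATES

# Default (state, action) -> (likely successor, unlikely successor) assignment.
# Chosen so that, in the flexible condition, the optimal first-stage action
# (RIGHT) is the same under both uncertainty levels while the optimal
# second-stage action at the likely intermediate state I3 flips between
# uncertainty levels (RIGHT under low, LEFT under high).
DEFAULT_LAYOUT: dict[tuple[str, str], tuple[str, str]] = {
    ("S0", "LEFT"): ("I1", "I2"),
    ("S0", "RIGHT"): ("I3", "I4"),
    ("I1", "LEFT"): ("O_blue", "O_grey"),
    ("I1", "RIGHT"): ("O_yellow", "O_grey"),
    ("I2", "LEFT"): ("O_grey", "O_red"),
    ("I2", "RIGHT"): ("O_blue", "O_yellow"),
    ("I3", "LEFT"): ("O_yellow", "O_blue"),
    ("I3", "RIGHT"): ("O_red", "O_grey"),
    ("I4", "LEFT"): ("O_grey", "O_yellow"),
    ("I4", "RIGHT"): ("O_blue", "O_red"),
}

DEFAULT_OUTCOME_VALUES: dict[str, int] = {
    "red": 0,
    "yellow": 1,
    "blue": 2,
    "grey": 4,
}

#: column schema of a trial log (one row per trial, delimited text, header row)
TRIAL_COLUMNS: tuple[str, ...] = (
    "subject",
    "session",
    "block",
    "trial",
    "condition",
    "uncertainty",
    "goal",
    "training",
    "state0",
    "action0",
    "state1",
    "action1",
    "outcome_state",
    "coin_colour",
    "coin_value",
    "shocks",
    "excluded",
)


class TaskConfigError(ValueError):
    """Raised when a task configuration violates the task design."""


@dataclass
class TaskConfig:
    """Structured configuration of the avoidance task.

    Defaults reproduce the published design; every field can be overridden,
    e.g. from a YAML file via :meth:`from_yaml`.
    """

    colours: tuple[str, ...] = COLOURS
    outcome_values: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_VALUES)
    )
    layout: Mapping[tuple[str, str], tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_LAYOUT)
    )
    p_likely_low: float = 0.9
    p_likely_high: float = 0.5
    n_sessions: int = 2
    blocks_per_cell_per_session: int = 6
    total_blocks: int | None = None  # optional cross-check of the block budget
    low_trial_range: tuple[int, int] = (3, 5)
    high_trial_range: tuple[int, int] = (5, 7)
    training_trials: int = 100
    include_training: bool = True
    miss_probability: float = 0.0  # per-trial no-response ("penalising") rate

    def __post_init__(self) -> None:
        if tuple(self.colours) != COLOURS:
            raise TaskConfigError(f"coin colours must be {COLOURS}")
        values = sorted(self.outcome_values[c] for c in self.colours)
        if values != sorted(MAGNITUDES):
            raise TaskConfigError(
                f"outcome magnitudes must be {MAGNITUDES}, got {values}"
            )
        if self.outcome_values["red"] != 0:
            raise TaskConfigError("the 0-shock coin must be red")
        if self.outcome_values["grey"] != 4:
            raise TaskConfigError("the 4-shock default coin must be grey")
        for p in (self.p_likely_low, self.p_likely_high):
            if not 0.5 <= p <= 1.0:
                raise TaskConfigError("likely-successor probability must be in [0.5, 1]")
        if self.total_blocks is not None:
            implied = 4 * self.blocks_per_cell_per_session * self.n_sessions
            if self.total_blocks != implied:
                raise TaskConfigError(
                    f"total_blocks={self.total_blocks} is not divisible over the "
                    f"four condition cells: sessions imply {implied} blocks"
                )
        lo, hi = self.low_trial_range
        if not (lo <= hi and lo >= 1):
            raise TaskConfigError("invalid low-uncertainty trial range")
        lo, hi = self.high_trial_range
        if not (lo <= hi and lo >= 1):
            raise TaskConfigError("invalid high-uncertainty trial range")
        if not 0.0 <= self.miss_probability < 1.0:
            raise TaskConfigError("miss_probability must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "layout" in raw:
            raw["layout"] = {
                (s, a): tuple(v) for (s, a), v in
                ((tuple(k.split("/")), v) for k, v in raw["layout"].items())
            }
        for key in ("low_trial_range", "high_trial_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["colours"] = list(self.colours)
        raw["layout"] = {f"{s}/{a}": list(v) for (s, a), v in self.layout.items()}
        raw["low_trial_range"] = list(self.low_trial_range)
        raw["high_trial_range"] = list(self.high_trial_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class Environment:
    """Validated two-step task tree.

    ``transition_table`` maps (choice state, action, uncertainty) to a
    probability vector over that pair's configured successors;
    ``outcome_map`` maps each outcome state to its (coin colour, shock count).
    Integer-coded arrays for the fast simulation kernel are exposed as
    ``succ`` (choice-state × action × {likely, unlikely} successor indices)
    and ``outcome_shocks`` (shock count per coin colour index).
    """

    states: tuple[str, ...]
    actions: tuple[str, str]
    transition_table: Mapping[tuple[str, str, str], Mapping[str, float]]
    outcome_map: Mapping[str, tuple[str, int]]
    p_likely_low: float
    p_likely_high: float
    succ: np.ndarray  # (5, 2, 2) int64, slot 0 = likely successor
    outcome_shocks: np.ndarray  # (4,) float64 indexed by colour

    @property
    def choice_states(self) -> tuple[str, ...]:
        return self.states[:5]

    @property
    def outcome_states(self) -> tuple[str, ...]:
        return self.states[5:]

    def state_index(self, name: str) -> int:
        return self.states.index(name)

    def colour_index(self, colour: str) -> int:
        return COLOURS.index(colour)

    def likely_successor(self, state: str, action: str) -> str:
        s, a = self.state_index(state), self.actions.index(action)
        return self.states[self.succ[s, a, 0]]


def build_environment(config: TaskConfig | None = None) -> Environment:
    """Build and validate the task tree from a configuration.

    Raises :class:`TaskConfigError` on duplicate states, probability vectors
    not summing to one, or missing outcome mappings.
    """
    config = config or TaskConfig()
    states = STATE_NAMES
    if len(set(states)) != len(states):
        raise TaskConfigError("duplicate state identifiers")

    layout = dict(config.layout)
    for s in states[:5]:
        for a in ACTIONS:
            if (s, a) not in layout:
                raise TaskConfigError(f"layout missing successors for ({s}, {a})")
            likely, unlikely = layout[(s, a)]
            for nxt in (likely, unlikely):
                if nxt not in states:
                    raise TaskConfigError(f"unknown successor state {nxt!r}")
            expected = INTERMEDIATE_STATES if s == INITIAL_STATE else OUTCOME_STATES
            if not {likely, unlikely} <= set(expected):
                raise TaskConfigError(
                    f"({s}, {a}) must lead to {'intermediate' if s == INITIAL_STATE else 'outcome'} states"
                )
            if likely == unlikely:
                raise TaskConfigError(f"({s}, {a}) successors must be distinct")

    outcome_map = {}
    for colour in config.colours:
        outcome_map[f"O_{colour}"] = (colour, int(config.outcome_values[colour]))
    for o in OUTCOME_STATES:
        if o not in outcome_map:
            raise TaskConfigError(f"missing outcome mapping for {o}")

    transition_table: dict[tuple[str, str, str], dict[str, float]] = {}
    for (s, a), (likely, unlikely) in layout.items():
        for unc, p in (("low", config.p_likely_low), ("high", config.p_likely_high)):
            vec = {likely: p, unlikely: 1.0 - p}
            if abs(sum(vec.values()) - 1.0) > 1e-12:
                raise TaskConfigError("transition probabilities must sum to 1")
            transition_table[(s, a, unc)] = vec

    succ = np.zeros((5, 2, 2), dtype=np.int64)
    for si, s in enumerate(states[:5]):
        for ai, a in enumerate(ACTIONS):
            likely, unlikely = layout[(s, a)]
            succ[si, ai, 0] = states.index(likely)
            succ[si, ai, 1] = states.index(unlikely)
    outcome_shocks = np.array(
        [float(config.outcome_values[c]) for c in COLOURS], dtype=np.float64
    )

    return Environment(
        states=states,
        actions=ACTIONS,
        transition_table=transition_table,
        outcome_map=outcome_map,
        p_likely_low=config.p_likely_low,
        p_likely_high=config.p_likely_high,
        succ=succ,
        outcome_shocks=outcome_shocks,
    )


def sample_transition(
    env: Environment,
    state: str,
    action: str,
    uncertainty: str,
    rng: np.random.Generator,
) -> str:
    """Draw a successor state from the configured transition vector."""
    if state not in env.choice_states:
        raise ValueError(f"{state!r} is not a choice state")
    vec = env.transition_table[(state, action, uncertainty)]
    names = list(vec)
    probs = np.array([vec[n] for n in names])
    return names[int(rng.choice(len(names), p=probs))]


def deliver_outcome(
    coin_colour: str,
    coin_value: int,
    condition: str,
    goal_colour: str,
) -> int:
    """Number of shocks delivered for acquiring a coin under the goal rule.

    Flexible condition: every coin keeps its face value. Specific condition:
    the coin matching the goal colour keeps its value, any other coin delivers
    the default maximum of 4 shocks.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "specific":
        if goal_colour not in GOAL_COLOURS:
            raise ValueError(
                f"specific-condition goal must be one of {GOAL_COLOURS}, got {goal_colour!r}"
            )
        return coin_value if coin_colour == goal_colour else 4
    return coin_value


@dataclass(frozen=True)
class BlockSpec:
    """One block: a goal condition × uncertainty cell with per-trial goals."""

    condition: str
    uncertainty: str
    n_trials: int
    goal_colours: tuple[str, ...]
    session: int
    training: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.uncertainty not in UNCERTAINTIES:
            raise ValueError(f"unknown uncertainty {self.uncertainty!r}")
        if len(self.goal_colours) != self.n_trials:
            raise ValueError("one goal colour per trial required")
        if self.condition == "specific":
            bad = set(self.goal_colours) - set(GOAL_COLOURS)
            if bad:
                raise ValueError(f"illegal specific-condition goals: {bad}")
        else:
            if set(self.goal_colours) != {WHITE} and self.n_trials > 0:
                raise ValueError("flexible blocks use the white collection box")


@dataclass(frozen=True)
class SessionPlan:
    """Ordered blocks of a training-plus-experiment schedule."""

    blocks: tuple[BlockSpec, ...]

    @property
    def experimental_blocks(self) -> tuple[BlockSpec, ...]:
        return tuple(b for b in self.blocks if not b.training)

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def training_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks if b.training)

    def validate(self, config: TaskConfig) -> None:
        for b in self.experimental_blocks:
            lo, hi = (
                config.low_trial_range
                if b.uncertainty == "low"
                else config.high_trial_range
            )
            if not lo <= b.n_trials <= hi:
                raise ValueError(
                    f"{b.uncertainty}-uncertainty block with {b.n_trials} trials "
                    f"outside [{lo}, {hi}]"
                )

    def to_frame(self) -> pd.DataFrame:
        """One row per trial with block/condition/goal metadata."""
        rows = []
        block_no = 0
        for b in self.blocks:
            for t in range(b.n_trials):
                rows.append(
                    {
                        "session": b.session,
                        "block": block_no,
                        "trial": t,
                        "condition": b.condition,
                        "uncertainty": b.uncertainty,
                        "goal": b.goal_colours[t],
                        "training": b.training,
                    }
                )
            block_no += 1
        return pd.DataFrame(rows)


def generate_session_plan(
    config: TaskConfig, rng: np.random.Generator
) -> SessionPlan:
    """Randomised block schedule for one simulated subject.

    Each experimental session interleaves ``blocks_per_cell_per_session``
    blocks of every condition × uncertainty cell in random order; trial counts
    are drawn per block from the configured ranges and specific-goal colours
    are resampled every trial. A training session (flexible goal, high
    uncertainty, no shocks) is prepended when configured.
    """
    if config.blocks_per_cell_per_session < 1:
        raise TaskConfigError("need at least one block per condition cell")
    blocks: list[BlockSpec] = []
    if config.include_training:
        blocks.append(
            BlockSpec(
                condition="flexible",
                uncertainty="high",
                n_trials=config.training_trials,
                goal_colours=(WHITE,) * config.training_trials,
                session=0,
                training=True,
            )
        )
    cells = [(c, u) for c in CONDITIONS for u in UNCERTAINTIES]
    for session in range(1, config.n_sessions + 1):
        cell_seq = cells * config.blocks_per_cell_per_session
        order = rng.permutation(len(cell_seq))
        for idx in order:
            condition, uncertainty = cell_seq[idx]
            lo, hi = (
                config.low_trial_range
                if uncertainty == "low"
                else config.high_trial_range
            )
            n_trials = int(rng.integers(lo, hi + 1))
            if condition == "specific":
                goals = tuple(
                    GOAL_COLOURS[int(rng.integers(len(GOAL_COLOURS)))]
                    for _ in range(n_trials)
                )
            else:
                goals = (WHITE,) * n_trials
            blocks.append(
                BlockSpec(
                    condition=condition,
                    uncertainty=uncertainty,
                    n_trials=n_trials,
                    goal_colours=goals,
                    session=session,
                )
            )
    plan = SessionPlan(blocks=tuple(blocks))
    plan.validate(config)
    return plan


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial log as tab-separated text with a header row."""
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return trials
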