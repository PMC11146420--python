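"""Two-step Markov decision task: state graph, reward rules, block design.

The task is a two-stage binary decision tree. From the start state the agent
presses left or right, transitions (stochastically) to one of two second-stage
states, chooses again, and lands on one of four terminal states, each carrying
a coloured coin worth 40, 20, 10 or 0 points. Reward depends on the block's
goal condition: under a *specific* goal only coins matching the trial's goal
colour pay out; under the *universal* goal (white box) every coin pays its
face value. Transition noise is manipulated per block: the action-congruent
successor is reached with probability 0.9 (low uncertainty) or 0.5 (high
uncertainty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

ACTIONS = ("left", "right")
#: state index layout: 0 = start, 1/2 = second-stage left/right,
#: 3..6 = terminals, one per (second-stage state, action), congruent first.
STATE_NAMES = ("S1", "S2L", "S2R", "T_LL", "T_LR", "T_RL", "T_RR")
DECISION_STATES = (0, 1, 2)
TERMINAL_STATES = (3, 4, 5, 6)

#: SUCC[s, a, slot] -> successor index; slot 0 is the action-congruent branch.
SUCC = np.array(
    [
        [[1, 2], [2, 1]],  # S1: left -> S2L, right -> S2R
        [[3, 4], [4, 3]],  # S2L: left -> T_LL, right -> T_LR
        [[5, 6], [6, 5]],  # S2R: left -> T_RL, right -> T_RR
    ],
    dtype=np.int64,
)

COLOURS = ("red", "yellow", "blue")
WHITE = "white"
COIN_VALUES = (40, 20, 10, 0)

GOAL_TYPES = ("specific", "universal")
UNCERTAINTY_LEVELS = ("high", "low")

P_COMMON_LOW = 0.9
P_COMMON_HIGH = 0.5


class TaskError(ValueError):
    """Domain error raised for invalid states, actions or conditions."""


def action_index(action: str) -> int:
    try:
        return ACTIONS.index(action)
    except ValueError:
        raise TaskError(f"unknown action {action!r}") from None


def state_index(state: str) -> int:
    try:
        return STATE_NAMES.index(state)
    except ValueError:
        raise TaskError(f"unknown state {state!r}") from None


@dataclass(frozen=True)
class Coin:
    colour: str
    value: int

    def __post_init__(self) -> None:
        if self.colour not in COLOURS:
            raise TaskError(f"coin colour must be one of {COLOURS}, got {self.colour!r}")
        if self.value not in COIN_VALUES:
            raise TaskError(f"coin value must be one of {COIN_VALUES}, got {self.value!r}")


#: default coin layout: each face value used once; colours chosen so that every
#: specific goal colour devalues at least one subtree.
DEFAULT_COINS = (
    Coin("red", 40),
    Coin("blue", 20),
    Coin("yellow", 10),
    Coin("red", 0),
)


@dataclass(frozen=True)
class TaskGraph:
    """The binary two-step decision tree with its terminal coins."""

    coins: tuple[Coin, Coin, Coin, Coin] = DEFAULT_COINS

    def __post_init__(self) -> None:
        if len(self.coins) != len(TERMINAL_STATES):
            raise TaskError("exactly one coin per terminal state is required")

    @property
    def terminal_colours(self) -> np.ndarray:
        return np.array([COLOURS.index(c.colour) for c in self.coins], dtype=np.int64)

    @property
    def terminal_values(self) -> np.ndarray:
        return np.array([c.value for c in self.coins], dtype=np.float64)

    def reward_vector(self, goal: str) -> np.ndarray:
        """Points paid by each terminal state under ``goal`` (a colour or white)."""
        return np.array(
            [outcome_reward((c.colour, c.value), goal) for c in self.coins],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class BlockCondition:
    """One task block: goal specificity crossed with transition uncertainty."""

    goal: str
    uncertainty: str

    def __post_init__(self) -> None:
        if self.goal not in GOAL_TYPES:
            raise TaskError(f"goal must be one of {GOAL_TYPES}")
        if self.uncertainty not in UNCERTAINTY_LEVELS:
            raise TaskError(f"uncertainty must be one of {UNCERTAINTY_LEVELS}")

    @property
    def p_common(self) -> float:
        return P_COMMON_LOW if self.uncertainty == "low" else P_COMMON_HIGH

    @property
    def label(self) -> str:
        return f"{self.goal}_{self.uncertainty}"


#: the four block conditions; (specific, low) favours model-based control,
#: (universal, high) favours model-free control.
BLOCK_CONDITIONS = (
    BlockCondition("specific", "low"),
    BlockCondition("specific", "high"),
    BlockCondition("universal", "high"),
    BlockCondition("universal", "low"),
)
MB_FAVOURED = BlockCondition("specific", "low")
MF_FAVOURED = BlockCondition("universal", "high")


class TaskConfig(BaseModel):
    """Experiment layout: session/block structure and optional mechanisms."""

    sessions: int = Field(default=6, ge=0)
    block_repeats: int = Field(default=2, ge=1, description="slots per condition per session")
    trials_per_slot: int = Field(default=5, ge=1)
    pretrain_trials: int = Field(default=100, ge=0)
    pretrain_universal: int = Field(default=80, ge=0)
    include_pretraining: bool = True
    timeout_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    timeout_penalty: float = Field(default=5.0, ge=0.0)
    # onset metadata (seconds); recorded for regressor export only
    iti: float = 2.0
    stage_interval: float = 2.5
    reward_duration: float = 2.0
    action_latency: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "TaskConfig":
        if self.pretrain_universal > self.pretrain_trials:
            raise ValueError("pretrain_universal cannot exceed pretrain_trials")
        return self


@dataclass
class SessionDesign:
    """Ordered block schedule expanded to one row per trial.

    ``trials`` columns: phase, session, block, goal_type, uncertainty,
    p_common, new_session.
    """

    trials: pd.DataFrame
    config: TaskConfig
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_main_trials(self) -> int:
        return int((self.trials["phase"] == "main").sum())


def build_design(config: TaskConfig | None = None, seed: int = 0) -> SessionDesign:
    """Randomized block schedule for one subject; deterministic given ``seed``.

    Each session holds every block condition ``block_repeats`` times in a
    shuffled order, with ``trials_per_slot`` trials per slot. An optional
    pretraining session precedes the main sessions: mostly universal-goal /
    high-uncertainty trials with a specific-goal tail.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    if config.include_pretraining and config.pretrain_trials:
        for i in range(config.pretrain_trials):
            cond = (
                BlockCondition("universal", "high")
                if i < config.pretrain_universal
                else BlockCondition("specific", "high")
            )
            rows.append(
                {
                    "phase": "pretrain",
                    "session": 0,
                    "block": cond.label,
                    "goal_type": cond.goal,
                    "uncertainty": cond.uncertainty,
                    "p_common": cond.p_common,
                    "new_session": i == 0,
                }
            )

    for sess in range(1, config.sessions + 1):
        slots = list(BLOCK_CONDITIONS) * config.block_repeats
        rng.shuffle(slots)
        first = True
        for cond in slots:
            for _ in range(config.trials_per_slot):
                rows.append(
                    {
                        "phase": "main",
                        "session": sess,
                        "block": cond.label,
                        "goal_type": cond.goal,
                        "uncertainty": cond.uncertainty,
                        "p_common": cond.p_common,
                        "new_session": first,
                    }
                )
                first = False

    columns = ["phase", "session", "block", "goal_type", "uncertainty", "p_common", "new_session"]
    trials = pd.DataFrame(rows, columns=columns)
    return SessionDesign(trials=trials, config=config, seed=seed)


def transition(state: str, action: str, p_common: float, draw: float) -> str:
    """Successor of (state, action): congruent branch iff ``draw < p_common``."""
    s = state_index(state)
    if s not in DECISION_STATES:
        raise TaskError(f"{state!r} is not a decision state")
    a = action_index(action)
    if not 0.0 <= draw < 1.0:
        raise TaskError("draw must lie in [0, 1)")
    slot = 0 if draw < p_common else 1
    return STATE_NAMES[SUCC[s, a, slot]]


def outcome_reward(coin: tuple[str, int] | Coin, goal: str) -> float:
    """Points paid by ``coin`` under ``goal``.

    A specific goal pays the face value only when the colours match; the
    universal (white) goal pays every coin its face value.
    """
    if isinstance(coin, Coin):
        colour, value = coin.colour, coin.value
    else:
        colour, value = coin
    if colour not in COLOURS:
        raise TaskError(f"unknown coin colour {colour!r}")
    if goal == WHITE:
        return float(value)
    if goal not in COLOURS:
        raise TaskError(f"unknown goal {goal!r}")
    return float(value) if colour == goal else 0.0


def sample_goal(condition: BlockCondition, rng: np.random.Generator) -> str:
    """Goal colour for one trial: white under the universal goal, otherwise a
    colour drawn uniformly from the three coin colours."""
    if condition.goal == "universal":
        return WHITE
    return COLOURS[int(rng.integers(len(COLOURS)))]


def sample_goals(design: SessionDesign, rng: np.random.Generator) -> list[str]:
    """Per-trial goal colours for a whole design (one draw per specific trial)."""
    return [
        sample_goal(BlockCondition(row.goal_type, row.uncertainty), rng)
        for row in design.trials.itertuples()
    ]
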