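"""Trial-log serialization and kernel encoding.

A trial log is a delimiter-separated table (UTF-8, header row) with one row
per trial: block/goal metadata, the visited states and chosen actions, the
obtained points, stage-onset metadata in seconds, and the model's per-trial
latent traces. Logs round-trip losslessly through ``write_trial_log`` /
``read_trial_log``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._engine import COL
from .arbitration import TRACE_COLUMNS
from .task import ACTIONS, COLOURS, STATE_NAMES, SessionDesign, TaskError, WHITE

#: goal colour encoding used by the kernel: coin colours then white
GOAL_CODES = {**{c: i for i, c in enumerate(COLOURS)}, WHITE: len(COLOURS)}

META_COLUMNS = (
    "subject", "phase", "session", "block", "trial",
    "goal_type", "uncertainty", "p_common", "goal_colour",
)
BEHAVIOUR_COLUMNS = (
    "s1", "a1", "s2", "a2", "terminal", "reward", "timeout1", "timeout2",
)
ONSET_COLUMNS = ("onset_s1", "onset_a1", "onset_s2", "onset_a2", "onset_reward")
LATENT_COLUMNS = tuple(c for c in TRACE_COLUMNS if c not in
                       ("a1", "s2", "a2", "terminal", "reward", "timeout1", "timeout2"))
LOG_COLUMNS = META_COLUMNS + BEHAVIOUR_COLUMNS + ONSET_COLUMNS + LATENT_COLUMNS


def compute_onsets(design: SessionDesign) -> pd.DataFrame:
    """Deterministic stage/action onset metadata (seconds, continuous clock)."""
    c = design.config
    n = design.n_trials
    trial_len = c.iti + 2 * c.stage_interval + c.reward_duration
    start = np.arange(n) * trial_len
    onset_s1 = start + c.iti
    onset_s2 = onset_s1 + c.stage_interval
    onset_rw = onset_s2 + c.stage_interval
    return pd.DataFrame(
        {
            "onset_s1": onset_s1,
            "onset_a1": onset_s1 + c.action_latency,
            "onset_s2": onset_s2,
            "onset_a2": onset_s2 + c.action_latency,
            "onset_reward": onset_rw,
        }
    )


def trace_to_log(
    trace: np.ndarray,
    design: SessionDesign,
    goals: list[str],
    subject: str = "s0",
) -> pd.DataFrame:
    """Assemble a full trial log from a kernel trace matrix and its design."""
    meta = design.trials.reset_index(drop=True)
    n = len(meta)
    df = pd.DataFrame(
        {
            "subject": subject,
            "phase": meta["phase"],
            "session": meta["session"],
            "block": meta["block"],
            "trial": np.arange(n),
            "goal_type": meta["goal_type"],
            "uncertainty": meta["uncertainty"],
            "p_common": meta["p_common"],
            "goal_colour": goals,
            "s1": STATE_NAMES[0],
            "a1": [ACTIONS[int(v)] for v in trace[:, COL["a1"]]],
            "s2": [STATE_NAMES[int(v)] for v in trace[:, COL["s2"]]],
            "a2": [ACTIONS[int(v)] for v in trace[:, COL["a2"]]],
            "terminal": [STATE_NAMES[int(v)] for v in trace[:, COL["terminal"]]],
            "reward": trace[:, COL["reward"]],
            "timeout1": trace[:, COL["timeout1"]].astype(int),
            "timeout2": trace[:, COL["timeout2"]].astype(int),
        }
    )
    df = pd.concat([df, compute_onsets(design)], axis=1)
    for name in LATENT_COLUMNS:
        df[name] = trace[:, COL[name]]
    return df


def encode_for_replay(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Flatten a trial log into the integer/float arrays the kernel replays.

    Also returns ``include``: main-phase trials without a timeout, the rows
    that enter likelihoods and summaries.
    """
    required = set(META_COLUMNS[1:]) | set(BEHAVIOUR_COLUMNS)
    missing = required - set(df.columns) - {"subject", "trial", "s1"}
    if missing:
        raise TaskError(f"trial log is missing columns: {sorted(missing)}")
    try:
        goal_code = df["goal_colour"].map(GOAL_CODES).to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise TaskError(f"unknown goal colour in log: {exc}") from exc
    state_idx = {name: i for i, name in enumerate(STATE_NAMES)}
    action_idx = {a: i for i, a in enumerate(ACTIONS)}
    sessions = df["session"].to_numpy()
    new_session = np.zeros(len(df), dtype=np.int64)
    if len(df):
        new_session[0] = 1
        new_session[1:] = (sessions[1:] != sessions[:-1]).astype(np.int64)
    timeout1 = df.get("timeout1", pd.Series(0, index=df.index))
    timeout2 = df.get("timeout2", pd.Series(0, index=df.index))
    include = (
        (df["phase"].to_numpy() == "main")
        & (np.asarray(timeout1) == 0)
        & (np.asarray(timeout2) == 0)
    )
    return {
        "p_common": df["p_common"].to_numpy(dtype=np.float64),
        "goal_code": goal_code,
        "new_session": new_session,
        "a1": df["a1"].map(action_idx).to_numpy(dtype=np.int64),
        "s2": df["s2"].map(state_idx).to_numpy(dtype=np.int64),
        "a2": df["a2"].map(action_idx).to_numpy(dtype=np.int64),
        "terminal": df["terminal"].map(state_idx).to_numpy(dtype=np.int64),
        "reward": df["reward"].to_numpy(dtype=np.float64),
        "timeout1": np.asarray(timeout1, dtype=np.int64),
        "timeout2": np.asarray(timeout2, dtype=np.int64),
        "include": include,
    }


def write_trial_log(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_trial_log(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = {"block", "a1", "a2", "s2", "terminal", "reward"} - set(df.columns)
    if missing:
        raise TaskError(f"trial log {path} is missing columns: {sorted(missing)}")
    return df
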