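"""Export of model latents as onset-locked parametric modulators.

Four GLM designs are supported, each written as a BIDS-style events table
(tab-separated; columns onset, duration, trial_type, block, then one column
per modulator):

* GLM 1 — task events: decision-stage events modulated by response speed
  (only when the log carries reaction times) and reward-stage events
  modulated by the obtained reward, split by block.
* GLM 2 — prediction errors at all three stage onsets. Values are aligned to
  when each error is computed: the stage-2 onset carries the first
  transition's SPE and the first-stage RPE, the reward onset the second
  transition's SPE and the outcome RPE, and the stage-1 onset the previous
  trial's reward-stage errors (zero on each run's first trial).
* GLM 3 — uncertainty estimates chi_MB and chi_MF (the trial's values at all
  three stage onsets), or their maximum when the replication flag is set.
* GLM 4 — action values at the two choice times: chosen Q_MB, chosen Q_MF,
  and chosen-minus-unchosen Q_Arb.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

GLM_IDS = (1, 2, 3, 4)
EVENT_DURATION = 0.0  # impulse events

_BLOCK_INDEX = {
    "specific_low": 1,
    "specific_high": 2,
    "universal_high": 3,
    "universal_low": 4,
}


class RegressorError(ValueError):
    """Raised when a log lacks the traces or onsets an export needs."""


def _require(log: pd.DataFrame, columns: list[str], glm_id: int) -> None:
    missing = [c for c in columns if c not in log.columns]
    if missing:
        raise RegressorError(f"GLM {glm_id} export needs missing columns: {missing}")
    for c in columns:
        bad = log.index[~np.isfinite(pd.to_numeric(log[c], errors="coerce"))]
        if len(bad):
            raise RegressorError(f"GLM {glm_id}: non-finite {c} at rows {list(bad[:5])}")


def _chosen(log: pd.DataFrame, stem: str, action_col: str) -> np.ndarray:
    left = log[f"{stem}_left"].to_numpy()
    right = log[f"{stem}_right"].to_numpy()
    is_left = (log[action_col] == "left").to_numpy()
    return np.where(is_left, left, right)


def _gap(log: pd.DataFrame, stem: str, action_col: str) -> np.ndarray:
    """Chosen minus unchosen value; +/- the action-value gap by chosen side."""
    left = log[f"{stem}_left"].to_numpy()
    right = log[f"{stem}_right"].to_numpy()
    is_left = (log[action_col] == "left").to_numpy()
    return np.where(is_left, left - right, right - left)


def export_modulators(
    log: pd.DataFrame,
    glm_id: int,
    replication_max: bool = False,
    mean_center: bool = False,
) -> pd.DataFrame:
    """Event table for one GLM design; rows sorted by onset."""
    if glm_id not in GLM_IDS:
        raise RegressorError(f"glm_id must be one of {GLM_IDS}")
    onset_cols = ["onset_s1", "onset_s2", "onset_reward", "onset_a1", "onset_a2"]
    _require(log, [c for c in onset_cols if True], glm_id)
    blocks = log["block"].map(_BLOCK_INDEX)
    if blocks.isna().any():
        raise RegressorError(f"unknown block labels at rows {list(log.index[blocks.isna()][:5])}")

    frames = []
    if glm_id == 1:
        has_rt = "rt1" in log.columns and "rt2" in log.columns
        if has_rt:
            _require(log, ["rt1", "rt2"], glm_id)
            for stage, onset, rt in (("Stage 1", "onset_s1", "rt1"), ("Stage 2", "onset_s2", "rt2")):
                frames.append(
                    pd.DataFrame(
                        {
                            "onset": log[onset], "trial_type": stage, "block": blocks,
                            "response_speed": 1.0 / log[rt],
                        }
                    )
                )
        else:
            warnings.warn(
                "log has no reaction times; GLM 1 export carries obtained reward only",
                stacklevel=2,
            )
        _require(log, ["reward"], glm_id)
        frames.append(
            pd.DataFrame(
                {
                    "onset": log["onset_reward"], "trial_type": "Reward stage",
                    "block": blocks, "obtained_reward": log["reward"],
                }
            )
        )
    elif glm_id == 2:
        _require(log, ["spe1", "spe2", "rpe1", "rpe2"], glm_id)
        run = log["session"] if "session" in log.columns else pd.Series(0, index=log.index)
        first_of_run = run.ne(run.shift()).to_numpy()
        spe_lag = np.where(first_of_run, 0.0, log["spe2"].shift().to_numpy())
        rpe_lag = np.where(first_of_run, 0.0, log["rpe2"].shift().to_numpy())
        for stage, onset, spe, rpe in (
            ("Stage 1", "onset_s1", spe_lag, rpe_lag),
            ("Stage 2", "onset_s2", log["spe1"].to_numpy(), log["rpe1"].to_numpy()),
            ("Reward stage", "onset_reward", log["spe2"].to_numpy(), log["rpe2"].to_numpy()),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "onset": log[onset], "trial_type": stage, "block": blocks,
                        "spe": spe, "rpe": rpe,
                    }
                )
            )
    elif glm_id == 3:
        _require(log, ["chi_mb", "chi_mf"], glm_id)
        for stage, onset in (("Stage 1", "onset_s1"), ("Stage 2", "onset_s2"),
                             ("Reward stage", "onset_reward")):
            if replication_max:
                mod = {"max_uncertainty": np.maximum(log["chi_mb"], log["chi_mf"])}
            else:
                mod = {"chi_mb": log["chi_mb"], "chi_mf": log["chi_mf"]}
            frames.append(
                pd.DataFrame({"onset": log[onset], "trial_type": stage, "block": blocks, **mod})
            )
    else:  # GLM 4
        value_cols = [f"{s}_{side}" for s in ("qmb1", "qmb2", "qmf1", "qmf2", "qarb1", "qarb2")
                      for side in ("left", "right")]
        _require(log, value_cols, glm_id)
        for stage, onset, idx in (("Action 1", "onset_a1", 1), ("Action 2", "onset_a2", 2)):
            frames.append(
                pd.DataFrame(
                    {
                        "onset": log[onset], "trial_type": stage, "block": blocks,
                        "qmb_chosen": _chosen(log, f"qmb{idx}", f"a{idx}"),
                        "qmf_chosen": _chosen(log, f"qmf{idx}", f"a{idx}"),
                        "qarb_chosen_minus_unchosen": _gap(log, f"qarb{idx}", f"a{idx}"),
                    }
                )
            )

    events = pd.concat(frames, ignore_index=True)
    events.insert(1, "duration", EVENT_DURATION)
    events = events.sort_values(["onset", "trial_type"], kind="stable").reset_index(drop=True)
    mod_cols = [c for c in events.columns if c not in ("onset", "duration", "trial_type", "block")]
    if mean_center:
        for c in mod_cols:
            events[c] = events[c] - events[c].mean()
    for c in mod_cols:
        if np.isclose(events[c].var(), 0.0):
            warnings.warn(f"modulator {c!r} has (near-)zero variance in GLM {glm_id}",
                          stacklevel=2)
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write a BIDS-style events TSV (tab-separated, period decimals)."""
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps the written doubles bit-exact
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
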