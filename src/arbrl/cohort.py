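"""Synthetic cohorts: parameter sampling, simulation, and behavioural summaries.

Group profiles emulate the qualitative parameter structure reported for the
clinical contrast this model family is used for: an OCD-like profile with a
lower softmax inverse temperature tau (less value-guided choice) and a larger
MB->MF transition-rate amplitude A_beta (faster abandonment of goal-directed
control) than the healthy-control-like profile, all other parameter
distributions shared. Parameters are drawn from truncated normals on each
parameter's bounded scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from ._engine import pack_params, simulate_arrays
from .arbitration import AgentParams
from .io import GOAL_CODES, encode_for_replay, trace_to_log
from .task import SessionDesign, TaskConfig, TaskGraph, build_design, sample_goals


class ParamDist(BaseModel):
    """Truncated-normal sampling spec for one parameter."""

    mean: float
    sd: float = Field(ge=0.0)
    low: float = 1e-3
    high: float = 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.low >= self.high:
            raise ValueError("infeasible bounds: low >= high")
        if self.sd == 0:
            if not self.low <= self.mean <= self.high:
                raise ValueError("degenerate distribution outside bounds")
            return np.full(n, self.mean)
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


class CohortSpec(BaseModel):
    """Group-level generating distributions for a synthetic cohort."""

    label: str
    n_subjects: int = Field(ge=0)
    dists: dict[str, ParamDist]
    fixed: dict[str, float] = Field(default_factory=dict)


_SHARED = {
    "eta_mb": ParamDist(mean=0.4, sd=0.12),
    "eta_mf": ParamDist(mean=0.4, sd=0.12),
    "eta_ph": ParamDist(mean=0.3, sd=0.10),
    "a_alpha": ParamDist(mean=0.35, sd=0.10),
}


def hc_like(n_subjects: int = 30) -> CohortSpec:
    """Healthy-control-like profile: value-sensitive, moderate MB->MF leakage."""
    return CohortSpec(
        label="hc",
        n_subjects=n_subjects,
        dists={
            **_SHARED,
            "a_beta": ParamDist(mean=0.5, sd=0.10),
            "tau": ParamDist(mean=0.15, sd=0.05, low=0.02),
        },
    )


def ocd_like(n_subjects: int = 30) -> CohortSpec:
    """OCD-like profile: lower tau, higher MB->MF amplitude A_beta."""
    return CohortSpec(
        label="ocd",
        n_subjects=n_subjects,
        dists={
            **_SHARED,
            "a_beta": ParamDist(mean=0.85, sd=0.08),
            "tau": ParamDist(mean=0.08, sd=0.03, low=0.02),
        },
    )


def recovery_spec(n_subjects: int = 30) -> CohortSpec:
    """Broad generating distributions for parameter-recovery studies."""
    return CohortSpec(
        label="recovery",
        n_subjects=n_subjects,
        dists={
            "eta_mb": ParamDist(mean=0.5, sd=0.25),
            "eta_mf": ParamDist(mean=0.5, sd=0.25),
            "eta_ph": ParamDist(mean=0.4, sd=0.2),
            "a_beta": ParamDist(mean=0.5, sd=0.25),
            "tau": ParamDist(mean=0.2, sd=0.1, low=0.02),
        },
    )


def sample_cohort(spec: CohortSpec, seed: int = 0) -> list[AgentParams]:
    """Draw one AgentParams per subject; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    draws = {name: dist.sample(spec.n_subjects, rng) for name, dist in spec.dists.items()}
    cohort = []
    for i in range(spec.n_subjects):
        values = {name: float(arr[i]) for name, arr in draws.items()}
        values.update(spec.fixed)
        cohort.append(AgentParams(**values))
    return cohort


def simulate_dataset(
    params: AgentParams,
    design: SessionDesign,
    seed: int = 0,
    graph: TaskGraph | None = None,
    subject: str = "s0",
) -> pd.DataFrame:
    """Simulate one subject through ``design``; returns the full trial log.

    All randomness (goal colours, action sampling, transitions, timeouts)
    derives from ``seed``.
    """
    graph = graph or TaskGraph()
    rng = np.random.default_rng(seed)
    goals = sample_goals(design, rng)
    n = design.n_trials
    draws = rng.random((n, 6))
    meta = design.trials
    pvec = pack_params(
        params,
        "arb",
        timeout_prob=design.config.timeout_prob,
        timeout_penalty=design.config.timeout_penalty,
    )
    trace = simulate_arrays(
        pvec,
        graph.terminal_colours,
        graph.terminal_values,
        meta["p_common"].to_numpy(dtype=np.float64),
        np.array([GOAL_CODES[g] for g in goals], dtype=np.int64),
        meta["new_session"].to_numpy(dtype=np.int64),
        draws,
    )
    return trace_to_log(trace, design, goals, subject=subject)


def simulate_cohort(
    cohort: list[AgentParams],
    config: TaskConfig | None = None,
    seed: int = 0,
    label: str = "s",
) -> list[pd.DataFrame]:
    """Simulate every subject on an independently randomized design.

    Subject i gets design seed ``seed + 1000 + i`` and simulation seed
    ``seed + 2000 + i`` (documented counter scheme).
    """
    config = config or TaskConfig()
    logs = []
    for i, params in enumerate(cohort):
        design = build_design(config, seed=seed + 1000 + i)
        logs.append(
            simulate_dataset(params, design, seed=seed + 2000 + i, subject=f"{label}{i:03d}")
        )
    return logs


def block_summaries(log: pd.DataFrame) -> pd.DataFrame:
    """Per-block mean obtained reward and mean P_MB for one subject.

    A trial's P_MB is the arbitrator's state after assimilating that trial's
    uncertainties (the ``pmb_next`` trace), so the block attribution reflects
    the evidence collected in the block; the pre-update value is also in the
    log. Pretraining and timeout trials are excluded. Blocks absent from the
    log appear with ``n_trials = 0`` and missing means rather than fabricated
    values.
    """
    if "block" not in log.columns:
        raise ValueError("log has no block labels")
    enc = encode_for_replay(log)
    main = log.loc[enc["include"]]
    grouped = main.groupby("block").agg(
        n_trials=("reward", "size"),
        mean_reward=("reward", "mean"),
        mean_pmb=("pmb_next", "mean"),
    )
    all_blocks = ["specific_low", "specific_high", "universal_high", "universal_low"]
    out = grouped.reindex(all_blocks)
    out["n_trials"] = out["n_trials"].fillna(0).astype(int)
    out.index.name = "block"
    out = out.reset_index()
    out.insert(0, "subject", log["subject"].iloc[0] if len(log) else "")
    return out


@dataclass
class GroupContrast:
    """Direction-and-effect table comparing two cohorts' block summaries."""

    table: pd.DataFrame

    def direction(self, measure: str, block: str) -> int:
        row = self.table[(self.table["measure"] == measure) & (self.table["block"] == block)]
        return int(np.sign(row["mean_diff"].iloc[0]))


def group_contrast(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    measures: tuple[str, ...] = ("mean_reward", "mean_pmb"),
) -> GroupContrast:
    """Welch tests of group A minus group B per block and measure.

    Inputs are stacked per-subject ``block_summaries`` tables; the groups must
    not share subjects.
    """
    if set(summaries_a["subject"]) & set(summaries_b["subject"]):
        raise ValueError("groups share subjects")
    rows = []
    for block in summaries_a["block"].unique():
        for measure in measures:
            a = summaries_a.loc[summaries_a["block"] == block, measure].dropna().to_numpy()
            b = summaries_b.loc[summaries_b["block"] == block, measure].dropna().to_numpy()
            diff = a.mean() - b.mean()
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
            d = diff / pooled if pooled > 0 else 0.0
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "block": block,
                    "measure": measure,
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "mean_diff": diff,
                    "cohens_d": d,
                    "t": float(t),
                    "p": float(p),
                }
            )
    return GroupContrast(table=pd.DataFrame(rows))
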