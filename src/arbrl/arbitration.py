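"""Uncertainty-based arbitration between model-based and model-free control.

Control is allocated by a two-state transition model over {MB, MF}. The
MF->MB rate alpha grows with model-free uncertainty chi_MF and the MB->MF
rate beta with model-based uncertainty chi_MB, each through a sigmoidal
transition-rate function

    alpha = A_alpha / (1 + exp(B_alpha * (1 - chi_MF)))
    beta  = A_beta  / (1 + exp(B_beta  * (1 - chi_MB)))

and the probability of model-based control P_MB follows

    dP_MB/dt = alpha * (1 - P_MB) - beta * P_MB,

integrated once per trial (forward Euler). Action values of the two systems
are mixed as Q_Arb = P_MB * Q_MB + (1 - P_MB) * Q_MF and fed to a softmax
with inverse temperature tau.

This module holds the arbitration primitives and a plain-Python reference
agent assembled from the per-module operations; ``arbrl._engine`` provides a
numerically identical compiled kernel used by simulation and fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .learners import QTableMF, TransitionModel, backward_plan, sarsa_update, update_transition_model
from .task import COLOURS, SUCC, SessionDesign, TaskGraph, WHITE
from .uncertainty import (
    Associability,
    DEFAULT_FORGETTING,
    DEFAULT_SPE_EDGES,
    R_MAX,
    SpePosterior,
    max_uncertainty,
    update_mb_uncertainty,
    update_mf_uncertainty,
)

#: arbitration variants: dynamic P_MB, MB-only (P_MB = 1), MF-only (P_MB = 0)
VARIANTS = ("arb", "mb", "mf")


@dataclass(frozen=True)
class AgentParams:
    """Free and structural parameters of the arbitration agent.

    Learning rates and amplitudes live on (0, 1]; tau is the softmax inverse
    temperature on the points scale (values up to 40), so fitted tau values
    are an order of magnitude below what reward-normalized tasks report.
    """

    eta_mb: float = 0.4
    eta_mf: float = 0.4
    eta_ph: float = 0.3
    a_alpha: float = 0.35
    b_alpha: float = 1.5
    a_beta: float = 0.5
    b_beta: float = 4.0
    tau: float = 0.15
    # structural settings (not fitted by default)
    lam: float = DEFAULT_FORGETTING
    spe_edges: tuple[float, ...] = DEFAULT_SPE_EDGES
    r_max: float = R_MAX
    pmb0: float = 0.5
    assoc0: float = 0.5
    n_substeps: int = 1
    reset_pmb_per_session: bool = True

    def with_values(self, **kwargs) -> "AgentParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def transition_rates(chi_mf: float, chi_mb: float, params: AgentParams) -> tuple[float, float]:
    """MF->MB rate alpha and MB->MF rate beta for the current uncertainties.

    Each rate is sigmoidal in its own strategy's uncertainty, saturating at
    half its amplitude when that strategy is maximally uncertain.
    """
    if not (0.0 <= chi_mf <= 1.0 and 0.0 <= chi_mb <= 1.0):
        raise ValueError("uncertainties must lie in [0, 1]")
    alpha = params.a_alpha / (1.0 + np.exp(params.b_alpha * (1.0 - chi_mf)))
    beta = params.a_beta / (1.0 + np.exp(params.b_beta * (1.0 - chi_mb)))
    return float(alpha), float(beta)


def update_pmb(pmb: float, alpha: float, beta: float, n_substeps: int = 1) -> float:
    """One unit of P_MB dynamics by forward Euler with ``n_substeps`` steps.

    The fixed point for constant rates is alpha / (alpha + beta); the result
    is clipped to [0, 1].
    """
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise ValueError("transition rates must be finite")
    dt = 1.0 / n_substeps
    for _ in range(n_substeps):
        pmb = pmb + dt * (alpha * (1.0 - pmb) - beta * pmb)
    return float(min(max(pmb, 0.0), 1.0))


def integrate_values(q_mb: np.ndarray, q_mf: np.ndarray, pmb: float) -> np.ndarray:
    """Q_Arb = P_MB * Q_MB + (1 - P_MB) * Q_MF, per action."""
    q_mb = np.asarray(q_mb, dtype=float)
    q_mf = np.asarray(q_mf, dtype=float)
    if q_mb.shape != q_mf.shape:
        raise ValueError("action sets of the two learners must match")
    return pmb * q_mb + (1.0 - pmb) * q_mf


def action_probabilities(q_arb: np.ndarray, tau: float) -> np.ndarray:
    """Softmax choice probabilities with inverse temperature ``tau``.

    Computed with max-subtraction; tau = 0 gives the uniform policy.
    """
    if tau < 0:
        raise ValueError("inverse temperature must be non-negative")
    z = tau * np.asarray(q_arb, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# trace column layout shared with the compiled kernel
TRACE_COLUMNS = (
    "a1", "s2", "a2", "terminal", "reward", "timeout1", "timeout2",
    "spe1", "spe2", "rpe1", "rpe2", "chi_mb", "chi_mf", "alpha", "beta",
    "pmb", "pmb_next",
    "qmb1_left", "qmb1_right", "qmb2_left", "qmb2_right",
    "qmf1_left", "qmf1_right", "qmf2_left", "qmf2_right",
    "qarb1_left", "qarb1_right", "qarb2_left", "qarb2_right",
    "p1_left", "p2_left", "logp1", "logp2",
)

#: per-choice probability floor applied before taking logs
LIKELIHOOD_FLOOR = 1e-10


class ArbitrationAgent:
    """Reference arbitration agent walking one trial at a time.

    Composes the transition-model, planner, SARSA, and uncertainty updates in
    a fixed within-trial order:

    1. optionally reset P_MB at a session boundary, plan Q_MB for the trial's
       goal, mix values and choose at stage 1;
    2. observe the stage-2 state, update the transition model (SPE) and the
       SPE posterior (chi_MB), re-plan stage-2 values, choose at stage 2;
    3. observe the terminal state, update the transition model and posterior
       again, collect the reward;
    4. SARSA backups for both stages (stage 1 first, on-policy), Pearce-Hall
       updates from both |RPE|s;
    5. one P_MB integration step from the trial's final uncertainties.

    With ``pmb_mode`` "mb" or "mf" the mixing weight is pinned to 1 or 0 and
    the dynamics are skipped, giving the single-system model variants.
    """

    def __init__(
        self,
        params: AgentParams,
        graph: TaskGraph | None = None,
        pmb_mode: str = "arb",
        timeout_prob: float = 0.0,
        timeout_penalty: float = 0.0,
    ) -> None:
        if pmb_mode not in VARIANTS:
            raise ValueError(f"pmb_mode must be one of {VARIANTS}")
        self.params = params
        self.graph = graph or TaskGraph()
        self.pmb_mode = pmb_mode
        self.timeout_prob = timeout_prob
        self.timeout_penalty = timeout_penalty
        self.tmodel = TransitionModel(eta=params.eta_mb)
        self.qmf = QTableMF(eta=params.eta_mf)
        self.posterior = SpePosterior(lam=params.lam, edges=params.spe_edges)
        self.assoc = Associability(a=params.assoc0, eta_ph=params.eta_ph, r_max=params.r_max)
        self.pmb = params.pmb0

    @property
    def pmb_effective(self) -> float:
        if self.pmb_mode == "mb":
            return 1.0
        if self.pmb_mode == "mf":
            return 0.0
        return self.pmb

    def _choose(self, probs: np.ndarray, u_act: float, u_to: float) -> tuple[int, int]:
        timeout = int(u_to < self.timeout_prob)
        if timeout:
            action = 0 if u_act < 0.5 else 1
        else:
            action = 0 if u_act < probs[0] else 1
        return action, timeout

    def run_trial(
        self,
        goal: str,
        p_common: float,
        new_session: bool,
        draws: np.ndarray,
        replay: dict | None = None,
    ) -> dict:
        """Simulate (``replay=None``) or replay one trial; returns the trace.

        ``draws`` holds six uniforms: stage-1 action, stage-1 timeout, stage-1
        transition, stage-2 action, stage-2 timeout, stage-2 transition. In
        replay mode actions, states and reward come from ``replay`` and the
        draws are ignored.
        """
        p = self.params
        if new_session and p.reset_pmb_per_session:
            self.pmb = p.pmb0
        pmb_eff = self.pmb_effective

        plan = backward_plan(self.tmodel, self.graph, goal)
        qarb1 = integrate_values(plan["q1"], self.qmf.Q[0], pmb_eff)
        probs1 = action_probabilities(qarb1, p.tau)
        qmf1 = self.qmf.Q[0].copy()

        if replay is None:
            a1, to1 = self._choose(probs1, draws[0], draws[1])
            slot1 = 0 if draws[2] < p_common else 1
            s2 = int(SUCC[0, a1, slot1])
        else:
            a1, to1 = replay["a1"], replay.get("timeout1", 0)
            s2 = replay["s2"]
        logp1 = np.log(max(probs1[a1], LIKELIHOOD_FLOOR))

        spe1 = update_transition_model(self.tmodel, 0, a1, s2, p.eta_mb)
        update_mb_uncertainty(self.posterior, spe1)

        plan2 = backward_plan(self.tmodel, self.graph, goal)
        qmb2 = plan2["q2"][s2 - 1]
        qmf2 = self.qmf.Q[s2].copy()
        qarb2 = integrate_values(qmb2, qmf2, pmb_eff)
        probs2 = action_probabilities(qarb2, p.tau)

        if replay is None:
            a2, to2 = self._choose(probs2, draws[3], draws[4])
            slot2 = 0 if draws[5] < p_common else 1
            terminal = int(SUCC[s2, a2, slot2])
        else:
            a2, to2 = replay["a2"], replay.get("timeout2", 0)
            terminal = replay["terminal"]
        logp2 = np.log(max(probs2[a2], LIKELIHOOD_FLOOR))

        spe2 = update_transition_model(self.tmodel, s2, a2, terminal, p.eta_mb)
        chi_mb = update_mb_uncertainty(self.posterior, spe2)

        if replay is None:
            reward = plan["r_term"][terminal - 3] - self.timeout_penalty * (to1 + to2)
        else:
            reward = replay["reward"]

        rpe1 = sarsa_update(self.qmf, (0, a1, 0.0, s2, a2), p.eta_mf)
        rpe2 = sarsa_update(self.qmf, (s2, a2, reward), p.eta_mf, terminal=True)
        update_mf_uncertainty(self.assoc, rpe1)
        chi_mf = update_mf_uncertainty(self.assoc, rpe2)

        alpha, beta = transition_rates(chi_mf, chi_mb, p)
        pmb_next = self.pmb
        if self.pmb_mode == "arb":
            pmb_next = update_pmb(self.pmb, alpha, beta, p.n_substeps)
            self.pmb = pmb_next

        return {
            "a1": a1, "s2": s2, "a2": a2, "terminal": terminal, "reward": float(reward),
            "timeout1": to1, "timeout2": to2,
            "spe1": spe1, "spe2": spe2, "rpe1": rpe1, "rpe2": rpe2,
            "chi_mb": chi_mb, "chi_mf": chi_mf,
            "max_uncertainty": max_uncertainty(chi_mb, chi_mf),
            "alpha": alpha, "beta": beta, "pmb": pmb_eff, "pmb_next": pmb_next,
            "qmb1_left": plan["q1"][0], "qmb1_right": plan["q1"][1],
            "qmb2_left": qmb2[0], "qmb2_right": qmb2[1],
            "qmf1_left": qmf1[0], "qmf1_right": qmf1[1],
            "qmf2_left": qmf2[0], "qmf2_right": qmf2[1],
            "qarb1_left": qarb1[0], "qarb1_right": qarb1[1],
            "qarb2_left": qarb2[0], "qarb2_right": qarb2[1],
            "p1_left": probs1[0], "p2_left": probs2[0],
            "logp1": float(logp1), "logp2": float(logp2),
        }

    def run_design(
        self,
        design: SessionDesign,
        goals: list[str],
        draws: np.ndarray,
    ) -> pd.DataFrame:
        """Simulate a full design; returns one trace row per trial."""
        rows = []
        for i, trial in enumerate(design.trials.itertuples()):
            rows.append(
                self.run_trial(goals[i], trial.p_common, bool(trial.new_session), draws[i])
            )
        return pd.DataFrame(rows)
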