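"""Model-based and model-free learners.

The model-based (MB) learner maintains an estimated transition model T(s, a, s')
updated from state-prediction errors (SPE = 1 - T of the observed successor) and
plans action values Q_MB by backward induction through the two-step tree. The
model-free (MF) learner caches action values Q_MF with on-policy SARSA backups
driven by reward-prediction errors (RPE). No temporal discounting is applied:
the horizon is two steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import SUCC, TERMINAL_STATES, TaskGraph, TaskError


@dataclass
class TransitionModel:
    """Estimated transition probabilities T[s, a, slot] over the two candidate
    successors of every decision (state, action); slot 0 is action-congruent.

    Rows are probability vectors and stay normalized under the SPE update.
    """

    eta: float = 0.2
    T: np.ndarray = field(default_factory=lambda: np.full((3, 2, 2), 0.5))

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("learning rate must lie in (0, 1]")

    def row(self, s: int, a: int) -> np.ndarray:
        return self.T[s, a]

    def copy(self) -> "TransitionModel":
        return TransitionModel(eta=self.eta, T=self.T.copy())


def update_transition_model(
    model: TransitionModel, s: int, a: int, s_obs: int, eta: float | None = None
) -> float:
    """Observe successor ``s_obs`` of (s, a); returns the SPE.

    SPE is 1 minus the pre-update probability of the observed successor. The
    observed entry moves toward 1 by ``eta * SPE`` and the complementary branch
    is rescaled so the row remains a probability vector. Updates in place.
    """
    eta = model.eta if eta is None else eta
    succ = SUCC[s, a]
    matches = np.nonzero(succ == s_obs)[0]
    if len(matches) == 0:
        raise TaskError(f"state {s_obs} is not a candidate successor of ({s}, {a})")
    slot = int(matches[0])
    spe = 1.0 - model.T[s, a, slot]
    model.T[s, a, slot] += eta * spe
    model.T[s, a, 1 - slot] = 1.0 - model.T[s, a, slot]
    return spe


def backward_plan(model: TransitionModel, graph: TaskGraph, goal: str) -> dict[str, np.ndarray]:
    """Q_MB by backward induction: terminal rewards under ``goal``, then
    Q_MB(s, a) = sum_s' T(s, a, s') * [R(s') + max_a' Q_MB(s', a')] from the
    second stage back to the start state.

    Returns ``{"q1": (2,), "q2": (2, 2), "r_term": (4,)}`` with q2 indexed by
    [second-stage state - 1, action].
    """
    rows = model.T.sum(axis=2)
    if not np.allclose(rows, 1.0, atol=1e-9):
        raise ValueError("transition model rows must sum to 1")
    r_term = graph.reward_vector(goal)
    q2 = np.empty((2, 2))
    for s in (1, 2):
        for a in (0, 1):
            q2[s - 1, a] = (
                model.T[s, a, 0] * r_term[SUCC[s, a, 0] - TERMINAL_STATES[0]]
                + model.T[s, a, 1] * r_term[SUCC[s, a, 1] - TERMINAL_STATES[0]]
            )
    v2 = q2.max(axis=1)
    q1 = np.empty(2)
    for a in (0, 1):
        q1[a] = model.T[0, a, 0] * v2[SUCC[0, a, 0] - 1] + model.T[0, a, 1] * v2[SUCC[0, a, 1] - 1]
    return {"q1": q1, "q2": q2, "r_term": r_term}


@dataclass
class QTableMF:
    """SARSA-learned action values Q_MF[s, a] over the three decision states."""

    eta: float = 0.3
    Q: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("learning rate must lie in [0, 1]")

    def copy(self) -> "QTableMF":
        return QTableMF(eta=self.eta, Q=self.Q.copy())


def sarsa_update(
    q: QTableMF,
    transition_tuple: tuple,
    eta: float | None = None,
    terminal: bool = False,
) -> float:
    """One SARSA backup; returns the RPE.

    Non-terminal: ``(s, a, r, s', a')`` with r = 0 (points arrive only at the
    reward stage) gives RPE = r + Q(s', a') - Q(s, a). Terminal: ``(s, a, r)``
    gives RPE = r - Q(s, a). Undiscounted. Updates in place.
    """
    eta = q.eta if eta is None else eta
    if terminal:
        if len(transition_tuple) != 3:
            raise ValueError("terminal backup takes (s, a, r)")
        s, a, r = transition_tuple
        rpe = r - q.Q[s, a]
    else:
        if len(transition_tuple) != 5:
            raise ValueError("non-terminal backup takes (s, a, r, s_next, a_next)")
        s, a, r, s_next, a_next = transition_tuple
        rpe = r + q.Q[s_next, a_next] - q.Q[s, a]
    q.Q[s, a] += eta * rpe
    return float(rpe)
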