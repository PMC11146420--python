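"""Compiled trial-loop kernel.

One njit function walks a whole experiment either forward (sampling actions
and transitions from pre-drawn uniforms) or in replay mode (stepping through
logged actions/states/rewards and accumulating choice log-probabilities).
The arithmetic and its order mirror ``arbrl.arbitration.ArbitrationAgent``
exactly; an equivalence test keeps the two paths locked together.

All per-trial latents are written to a dense trace matrix whose column
layout is ``arbrl.arbitration.TRACE_COLUMNS``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .arbitration import LIKELIHOOD_FLOOR, TRACE_COLUMNS, AgentParams
from .task import SUCC

N_TRACE = len(TRACE_COLUMNS)
COL = {name: i for i, name in enumerate(TRACE_COLUMNS)}

# packed parameter vector layout
(
    P_ETA_MB, P_ETA_MF, P_ETA_PH, P_A_ALPHA, P_B_ALPHA, P_A_BETA, P_B_BETA,
    P_TAU, P_LAM, P_PMB0, P_ASSOC0, P_NSUB, P_EDGE1, P_EDGE2, P_RMAX,
    P_TIMEOUT_PROB, P_TIMEOUT_PENALTY, P_RESET, P_MODE,
) = range(19)

MODE_ARB, MODE_MB, MODE_MF = 0, 1, 2
_MODE_CODE = {"arb": MODE_ARB, "mb": MODE_MB, "mf": MODE_MF}


def pack_params(
    params: AgentParams,
    pmb_mode: str = "arb",
    timeout_prob: float = 0.0,
    timeout_penalty: float = 0.0,
) -> np.ndarray:
    """Flatten an AgentParams (+ run options) into the kernel's float vector."""
    v = np.empty(19)
    v[P_ETA_MB] = params.eta_mb
    v[P_ETA_MF] = params.eta_mf
    v[P_ETA_PH] = params.eta_ph
    v[P_A_ALPHA] = params.a_alpha
    v[P_B_ALPHA] = params.b_alpha
    v[P_A_BETA] = params.a_beta
    v[P_B_BETA] = params.b_beta
    v[P_TAU] = params.tau
    v[P_LAM] = params.lam
    v[P_PMB0] = params.pmb0
    v[P_ASSOC0] = params.assoc0
    v[P_NSUB] = params.n_substeps
    v[P_EDGE1] = params.spe_edges[0]
    v[P_EDGE2] = params.spe_edges[1]
    v[P_RMAX] = params.r_max
    v[P_TIMEOUT_PROB] = timeout_prob
    v[P_TIMEOUT_PENALTY] = timeout_penalty
    v[P_RESET] = 1.0 if params.reset_pmb_per_session else 0.0
    v[P_MODE] = _MODE_CODE[pmb_mode]
    return v


@njit(cache=True)
def _softmax2(q0, q1, tau):
    z0 = tau * q0
    z1 = tau * q1
    m = z0 if z0 > z1 else z1
    e0 = math.exp(z0 - m)
    e1 = math.exp(z1 - m)
    s = e0 + e1
    return e0 / s, e1 / s


@njit(cache=True)
def run_kernel(
    pvec,          # float64[19]
    succ,          # int64[3, 2, 2]
    term_colour,   # int64[4]
    term_value,    # float64[4]
    p_common,      # float64[n]
    goal_code,     # int64[n]  colour index 0..2 or 3 for white
    new_session,   # int64[n]
    replay,        # 0 simulate / 1 replay
    a1_in, s2_in, a2_in, term_in, r_in, to1_in, to2_in,  # replay inputs
    draws,         # float64[n, 6]  simulate inputs
    out,           # float64[n, N_TRACE]
):
    n = p_common.shape[0]
    eta_mb = pvec[P_ETA_MB]
    eta_mf = pvec[P_ETA_MF]
    eta_ph = pvec[P_ETA_PH]
    a_alpha = pvec[P_A_ALPHA]
    b_alpha = pvec[P_B_ALPHA]
    a_beta = pvec[P_A_BETA]
    b_beta = pvec[P_B_BETA]
    tau = pvec[P_TAU]
    lam = pvec[P_LAM]
    pmb0 = pvec[P_PMB0]
    n_sub = int(pvec[P_NSUB])
    e1 = pvec[P_EDGE1]
    e2 = pvec[P_EDGE2]
    r_max = pvec[P_RMAX]
    p_to = pvec[P_TIMEOUT_PROB]
    penalty = pvec[P_TIMEOUT_PENALTY]
    reset = pvec[P_RESET] > 0.5
    mode = int(pvec[P_MODE])

    T = np.full((3, 2, 2), 0.5)
    qmf = np.zeros((3, 2))
    counts = np.ones(3)
    assoc = pvec[P_ASSOC0]
    pmb = pmb0

    r_term = np.zeros(4)
    q2 = np.zeros((2, 2))
    q1 = np.zeros(2)

    for t in range(n):
        if new_session[t] == 1 and reset:
            pmb = pmb0

        goal = goal_code[t]
        for k in range(4):
            if goal == 3 or term_colour[k] == goal:
                r_term[k] = term_value[k]
            else:
                r_term[k] = 0.0

        # backward plan: stage-2 values then stage-1 values
        for s in range(1, 3):
            for a in range(2):
                q2[s - 1, a] = (
                    T[s, a, 0] * r_term[succ[s, a, 0] - 3]
                    + T[s, a, 1] * r_term[succ[s, a, 1] - 3]
                )
        for a in range(2):
            v_l = q2[succ[0, a, 0] - 1, 0]
            v_r = q2[succ[0, a, 0] - 1, 1]
            v0 = v_l if v_l > v_r else v_r
            v_l = q2[succ[0, a, 1] - 1, 0]
            v_r = q2[succ[0, a, 1] - 1, 1]
            v1 = v_l if v_l > v_r else v_r
            q1[a] = T[0, a, 0] * v0 + T[0, a, 1] * v1

        if mode == MODE_MB:
            pmb_eff = 1.0
        elif mode == MODE_MF:
            pmb_eff = 0.0
        else:
            pmb_eff = pmb

        qarb1_l = pmb_eff * q1[0] + (1.0 - pmb_eff) * qmf[0, 0]
        qarb1_r = pmb_eff * q1[1] + (1.0 - pmb_eff) * qmf[0, 1]
        p1_l, p1_r = _softmax2(qarb1_l, qarb1_r, tau)
        qmf1_l = qmf[0, 0]
        qmf1_r = qmf[0, 1]

        if replay == 1:
            a1 = a1_in[t]
            to1 = to1_in[t]
            s2 = s2_in[t]
        else:
            to1 = 1 if draws[t, 1] < p_to else 0
            if to1 == 1:
                a1 = 0 if draws[t, 0] < 0.5 else 1
            else:
                a1 = 0 if draws[t, 0] < p1_l else 1
            slot1 = 0 if draws[t, 2] < p_common[t] else 1
            s2 = succ[0, a1, slot1]
        prob1 = p1_l if a1 == 0 else p1_r
        if prob1 < LIKELIHOOD_FLOOR:
            prob1 = LIKELIHOOD_FLOOR
        logp1 = math.log(prob1)

        # SPE update for the first transition
        slot = 0 if succ[0, a1, 0] == s2 else 1
        spe1 = 1.0 - T[0, a1, slot]
        T[0, a1, slot] += eta_mb * spe1
        T[0, a1, 1 - slot] = 1.0 - T[0, a1, slot]
        k1 = 0 if spe1 < e1 else (1 if spe1 < e2 else 2)
        counts[0] *= lam
        counts[1] *= lam
        counts[2] *= lam
        counts[k1] += 1.0

        # replan stage-2 values at the visited state with the updated model
        qmb2_l = (
            T[s2, 0, 0] * r_term[succ[s2, 0, 0] - 3]
            + T[s2, 0, 1] * r_term[succ[s2, 0, 1] - 3]
        )
        qmb2_r = (
            T[s2, 1, 0] * r_term[succ[s2, 1, 0] - 3]
            + T[s2, 1, 1] * r_term[succ[s2, 1, 1] - 3]
        )
        qmf2_l = qmf[s2, 0]
        qmf2_r = qmf[s2, 1]
        qarb2_l = pmb_eff * qmb2_l + (1.0 - pmb_eff) * qmf2_l
        qarb2_r = pmb_eff * qmb2_r + (1.0 - pmb_eff) * qmf2_r
        p2_l, p2_r = _softmax2(qarb2_l, qarb2_r, tau)

        if replay == 1:
            a2 = a2_in[t]
            to2 = to2_in[t]
            term = term_in[t]
        else:
            to2 = 1 if draws[t, 4] < p_to else 0
            if to2 == 1:
                a2 = 0 if draws[t, 3] < 0.5 else 1
            else:
                a2 = 0 if draws[t, 3] < p2_l else 1
            slot2 = 0 if draws[t, 5] < p_common[t] else 1
            term = succ[s2, a2, slot2]
        prob2 = p2_l if a2 == 0 else p2_r
        if prob2 < LIKELIHOOD_FLOOR:
            prob2 = LIKELIHOOD_FLOOR
        logp2 = math.log(prob2)

        # SPE update for the second transition
        slot = 0 if succ[s2, a2, 0] == term else 1
        spe2 = 1.0 - T[s2, a2, slot]
        T[s2, a2, slot] += eta_mb * spe2
        T[s2, a2, 1 - slot] = 1.0 - T[s2, a2, slot]
        k2 = 0 if spe2 < e1 else (1 if spe2 < e2 else 2)
        counts[0] *= lam
        counts[1] *= lam
        counts[2] *= lam
        counts[k2] += 1.0
        csum = counts[0] + counts[1] + counts[2]
        chi_mb = 1.0 - counts[0] / csum

        if replay == 1:
            reward = r_in[t]
        else:
            reward = r_term[term - 3] - penalty * (to1 + to2)

        # SARSA backups: stage 1 (on-policy, r = 0) then terminal stage 2
        rpe1 = qmf[s2, a2] - qmf[0, a1]
        qmf[0, a1] += eta_mf * rpe1
        rpe2 = reward - qmf[s2, a2]
        qmf[s2, a2] += eta_mf * rpe2

        # Pearce-Hall associability from both surprise magnitudes
        u = abs(rpe1) / r_max
        if u > 1.0:
            u = 1.0
        assoc += eta_ph * (u - assoc)
        u = abs(rpe2) / r_max
        if u > 1.0:
            u = 1.0
        assoc += eta_ph * (u - assoc)
        chi_mf = assoc

        alpha = a_alpha / (1.0 + math.exp(b_alpha * (1.0 - chi_mf)))
        beta = a_beta / (1.0 + math.exp(b_beta * (1.0 - chi_mb)))
        pmb_next = pmb
        if mode == MODE_ARB:
            dt = 1.0 / n_sub
            for _ in range(n_sub):
                pmb_next = pmb_next + dt * (alpha * (1.0 - pmb_next) - beta * pmb_next)
            if pmb_next < 0.0:
                pmb_next = 0.0
            elif pmb_next > 1.0:
                pmb_next = 1.0
            pmb = pmb_next

        o = out[t]
        o[0] = a1
        o[1] = s2
        o[2] = a2
        o[3] = term
        o[4] = reward
        o[5] = to1
        o[6] = to2
        o[7] = spe1
        o[8] = spe2
        o[9] = rpe1
        o[10] = rpe2
        o[11] = chi_mb
        o[12] = chi_mf
        o[13] = alpha
        o[14] = beta
        o[15] = pmb_eff
        o[16] = pmb_next
        o[17] = q1[0]
        o[18] = q1[1]
        o[19] = qmb2_l
        o[20] = qmb2_r
        o[21] = qmf1_l
        o[22] = qmf1_r
        o[23] = qmf2_l
        o[24] = qmf2_r
        o[25] = qarb1_l
        o[26] = qarb1_r
        o[27] = qarb2_l
        o[28] = qarb2_r
        o[29] = p1_l
        o[30] = p2_l
        o[31] = logp1
        o[32] = logp2


_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


def simulate_arrays(
    pvec: np.ndarray,
    term_colour: np.ndarray,
    term_value: np.ndarray,
    p_common: np.ndarray,
    goal_code: np.ndarray,
    new_session: np.ndarray,
    draws: np.ndarray,
) -> np.ndarray:
    """Forward-simulate; returns the (n, N_TRACE) trace matrix."""
    n = len(p_common)
    out = np.empty((n, N_TRACE))
    run_kernel(
        pvec, SUCC, term_colour, term_value,
        p_common, goal_code, new_session,
        0, _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_F, _EMPTY_I, _EMPTY_I,
        draws, out,
    )
    return out


def replay_arrays(
    pvec: np.ndarray,
    term_colour: np.ndarray,
    term_value: np.ndarray,
    p_common: np.ndarray,
    goal_code: np.ndarray,
    new_session: np.ndarray,
    a1: np.ndarray,
    s2: np.ndarray,
    a2: np.ndarray,
    term: np.ndarray,
    reward: np.ndarray,
    timeout1: np.ndarray,
    timeout2: np.ndarray,
) -> np.ndarray:
    """Replay logged behaviour; returns the (n, N_TRACE) trace matrix."""
    n = len(p_common)
    out = np.empty((n, N_TRACE))
    draws = np.zeros((n, 6))
    run_kernel(
        pvec, SUCC, term_colour, term_value,
        p_common, goal_code, new_session,
        1, a1, s2, a2, term, reward, timeout1, timeout2,
        draws, out,
    )
    return out
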