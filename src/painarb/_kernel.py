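"""Numba-compiled update rules and the shared trial loop.

Every learning-rule primitive lives here exactly once: the Python-facing
operations in :mod:`painarb.learners` and :mod:`painarb.arbitration` call the
same compiled functions that :func:`run_trials` chains per trial, so
simulation and teacher-forced likelihood replay cannot diverge.

State coding: 0 = initial choice state, 1–4 = intermediate choice states,
5–8 = outcome states (colour index = state − 5, ordered red/yellow/blue/grey).
Outcomes are signed values r = −shocks, so both controllers maximise value.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# agent kinds understood by run_trials
KIND_ARBITRATING = 0
KIND_MF_ONLY = 1
KIND_MB_ONLY = 2
KIND_IDEAL = 3
KIND_RANDOM = 4

N_CHOICE_STATES = 5
N_OUTCOMES = 4


@njit(cache=True)
def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def softmax_left(q_left, q_right, beta):
    """P(LEFT) under a softmax with inverse temperature beta (overflow-safe)."""
    m = q_left if q_left > q_right else q_right
    e0 = np.exp(beta * (q_left - m))
    e1 = np.exp(beta * (q_right - m))
    return e0 / (e0 + e1)


@njit(cache=True)
def sarsa_update(q_sa, q_next, r, alpha):
    """One SARSA step: returns (updated Q(s,a), outcome prediction error)."""
    ope = r + q_next - q_sa
    return q_sa + alpha * ope, ope


@njit(cache=True)
def spe_update(t_row, slot, alpha):
    """State-prediction-error update of one transition row (in place).

    The observed successor's probability moves toward 1 by alpha·SPE; the
    remaining successors are rescaled multiplicatively so the row still sums
    to 1. Returns the SPE = 1 − T(s, a, s_observed).
    """
    old = t_row[slot]
    spe = 1.0 - old
    new = old + alpha * spe
    if spe > 0.0:
        scale = (1.0 - new) / (1.0 - old)
        for k in range(t_row.shape[0]):
            if k != slot:
                t_row[k] *= scale
    t_row[slot] = new
    return spe


@njit(cache=True)
def omega_update(omega, ope, eta):
    """Move the absolute-OPE estimator Ω toward |OPE| by fraction η."""
    return omega + eta * (abs(ope) - omega)


@njit(cache=True)
def chi_mf_from_omega(omega, omega_max):
    """Model-free reliability: 1 at Ω = 0, linearly down to 0 at Ω_max."""
    c = 1.0 - omega / omega_max
    if c < 0.0:
        return 0.0
    return c

@njit(cache=True)
def zero_spe_update(rate, spe, omega_threshold, eta):
    """Exponentially weighted rate of transitions counted as zero-SPE."""
    ind = 1.0 if spe < omega_threshold else 0.0
    return rate + eta * (ind - rate)


@njit(cache=True)
def weight_update(p_mb, chi_mf, chi_mb, a_mf_to_mb, a_mb_to_mf, steepness, mf_bias):
    """One step of the two-state controller-weight dynamics, clipped to [0, 1].

    Transition rates are logistic in the reliability difference; the MB→MF
    rate carries a fixed multiplicative bias favouring model-free control
    when reliabilities are equal.
    """
    tau_fm = a_mf_to_mb * sigmoid(steepness * (chi_mb - chi_mf))
    tau_mf = mf_bias * a_mb_to_mf * sigmoid(steepness * (chi_mf - chi_mb))
    p = p_mb + tau_fm * (1.0 - p_mb) - tau_mf * p_mb
    if p < 0.0:
        p = 0.0
    elif p > 1.0:
        p = 1.0
    return p


@njit(cache=True)
def mb_values(T, succ, terminal_values, q_mb):
    """Exact backward induction over the two-level tree (fills q_mb in place).

    Q_MB(s1, a) = Σ_o T(s1, a, o) · v(o) at intermediate states and
    Q_MB(s0, a) = Σ_s1 T(s0, a, s1) · max_a' Q_MB(s1, a') at the root.
    """
    for s in range(1, N_CHOICE_STATES):
        for a in range(2):
            v = 0.0
            for k in range(2):
                v += T[s, a, k] * terminal_values[succ[s, a, k] - N_CHOICE_STATES]
            q_mb[s, a] = v
    for a in range(2):
        v = 0.0
        for k in range(2):
            sp = succ[0, a, k]
            best = q_mb[sp, 0] if q_mb[sp, 0] > q_mb[sp, 1] else q_mb[sp, 1]
            v += T[0, a, k] * best
        q_mb[0, a] = v


@njit(cache=True)
def devalued_terminal_values(outcome_shocks, condition, goal, terminal_values):
    """Signed terminal values under the current goal rule (in place).

    condition: 0 = flexible (face values), 1 = specific (mismatching coins
    devalued to −4); goal is a colour index 0–3 (ignored when flexible).
    """
    for c in range(N_OUTCOMES):
        terminal_values[c] = -outcome_shocks[c]
    if condition == 1:
        for c in range(N_OUTCOMES):
            if c != goal:
                terminal_values[c] = -4.0


@njit(cache=True)
def run_trials(
    cond,  # (n,) int64: 0 flexible, 1 specific
    unc,  # (n,) int64: 0 low, 1 high
    goal,  # (n,) int64: colour index 0-3, -1 for white
    training,  # (n,) int64: 1 during the training session
    miss,  # (n,) int64: 1 on penalising trials (computer picks randomly)
    f_a0, f_s1, f_a1, f_out, f_shocks,  # (n,) int64 forced values, -1 = sample
    u,  # (n, 4) float64 uniforms for a0 / s1 / a1 / outcome draws
    succ,  # (5, 2, 2) int64 environment successors, slot 0 = likely
    outcome_shocks,  # (4,) float64 shocks per colour
    p_low, p_high,  # likely-successor probabilities per uncertainty level
    alpha, eta, omega_threshold, a_mf_to_mb, a_mb_to_mf, beta,  # free params
    steepness, mf_bias, omega_max,  # fixed constants
    kind,  # agent kind (KIND_* above)
    q_mf,  # (5, 2) float64 initial model-free values (mutated)
    T,  # (5, 2, 2) float64 initial transition model (mutated)
    omega0, zero_spe0, p_mb0,  # initial arbitration scalars
):
    """Run or replay a sequence of trials with one shared code path.

    Per trial: devalue terminal values under the displayed goal and recompute
    Q_MB → first choice by softmax on the integrated Q → first transition →
    SPE update of T (+ MB reliability) → second choice → SARSA update of the
    first-stage Q_MF bootstrapped on the chosen second-stage pair (+ MF
    reliability) → outcome transition and delivery → terminal SARSA update
    (+ reliabilities) → one controller-weight update.

    Forced entries (≥ 0) override sampling, which turns the same loop into
    teacher-forced likelihood replay. Returns per-trial records, choice
    probabilities, latent traces and the final learner/arbitration state.
    """
    n = cond.shape[0]
    a0 = np.empty(n, np.int64)
    s1 = np.empty(n, np.int64)
    a1 = np.empty(n, np.int64)
    out_state = np.empty(n, np.int64)
    shocks = np.empty(n, np.float64)
    p_left0 = np.empty(n, np.float64)
    p_left1 = np.empty(n, np.float64)
    p_taken0 = np.empty(n, np.float64)
    p_taken1 = np.empty(n, np.float64)
    ope1 = np.empty(n, np.float64)
    ope2 = np.empty(n, np.float64)
    spe1 = np.empty(n, np.float64)
    spe2 = np.empty(n, np.float64)
    omega_tr = np.empty(n, np.float64)
    chi_mf_tr = np.empty(n, np.float64)
    chi_mb_tr = np.empty(n, np.float64)
    p_mb_tr = np.empty(n, np.float64)
    q_mf_tr = np.empty((n, N_CHOICE_STATES, 2), np.float64)
    q_mb_tr = np.empty((n, N_CHOICE_STATES, 2), np.float64)
    t_likely_tr = np.empty((n, N_CHOICE_STATES, 2), np.float64)

    q_mb = np.zeros((N_CHOICE_STATES, 2), np.float64)
    tv = np.zeros(N_OUTCOMES, np.float64)
    t_true = np.empty((N_CHOICE_STATES, 2, 2), np.float64)
    q_star = np.empty((N_CHOICE_STATES, 2), np.float64)

    omega = omega0
    zero_spe = zero_spe0
    p_mb = p_mb0

    for t in range(n):
        devalued_terminal_values(outcome_shocks, cond[t], goal[t], tv)
        mb_values(T, succ, tv, q_mb)

        if kind == KIND_MF_ONLY:
            w = 0.0
        elif kind == KIND_MB_ONLY:
            w = 1.0
        else:
            w = p_mb

        p_likely = p_low if unc[t] == 0 else p_high
        if kind == KIND_IDEAL:
            for s in range(N_CHOICE_STATES):
                for a in range(2):
                    t_true[s, a, 0] = p_likely
                    t_true[s, a, 1] = 1.0 - p_likely
            mb_values(t_true, succ, tv, q_star)

        # ---- first-stage choice
        ql = w * q_mb[0, 0] + (1.0 - w) * q_mf[0, 0]
        qr = w * q_mb[0, 1] + (1.0 - w) * q_mf[0, 1]
        if kind == KIND_RANDOM:
            pl = 0.5
        elif kind == KIND_IDEAL:
            pl = 1.0 if q_star[0, 0] >= q_star[0, 1] else 0.0
        else:
            pl = softmax_left(ql, qr, beta)
        if f_a0[t] >= 0:
            act0 = f_a0[t]
        elif miss[t] == 1:
            act0 = 0 if u[t, 0] < 0.5 else 1
        else:
            act0 = 0 if u[t, 0] < pl else 1
        p_left0[t] = pl
        p_taken0[t] = pl if act0 == 0 else 1.0 - pl

        # ---- first transition
        if f_s1[t] >= 0:
            st1 = f_s1[t]
            slot1 = 0 if succ[0, act0, 0] == st1 else 1
        else:
            slot1 = 0 if u[t, 1] < p_likely else 1
            st1 = succ[0, act0, slot1]
        sp1 = spe_update(T[0, act0], slot1, alpha)
        zero_spe = zero_spe_update(zero_spe, sp1, omega_threshold, eta)
        mb_values(T, succ, tv, q_mb)

        # ---- second-stage choice
        ql = w * q_mb[st1, 0] + (1.0 - w) * q_mf[st1, 0]
        qr = w * q_mb[st1, 1] + (1.0 - w) * q_mf[st1, 1]
        if kind == KIND_RANDOM:
            pl = 0.5
        elif kind == KIND_IDEAL:
            pl = 1.0 if q_star[st1, 0] >= q_star[st1, 1] else 0.0
        else:
            pl = softmax_left(ql, qr, beta)
        if f_a1[t] >= 0:
            act1 = f_a1[t]
        elif miss[t] == 1:
            act1 = 0 if u[t, 2] < 0.5 else 1
        else:
            act1 = 0 if u[t, 2] < pl else 1
        p_left1[t] = pl
        p_taken1[t] = pl if act1 == 0 else 1.0 - pl

        # ---- first-stage SARSA update (r = 0, bootstrap on chosen pair)
        q_new, e1 = sarsa_update(q_mf[0, act0], q_mf[st1, act1], 0.0, alpha)
        q_mf[0, act0] = q_new
        omega = omega_update(omega, e1, eta)

        # ---- outcome transition and delivery
        if f_out[t] >= 0:
            o = f_out[t]
            slot2 = 0 if succ[st1, act1, 0] == o else 1
        else:
            slot2 = 0 if u[t, 3] < p_likely else 1
            o = succ[st1, act1, slot2]
        sp2 = spe_update(T[st1, act1], slot2, alpha)
        zero_spe = zero_spe_update(zero_spe, sp2, omega_threshold, eta)

        colour = o - N_CHOICE_STATES
        if training[t] == 1:
            # displayed magnitudes drive learning; no shocks are delivered
            sh = 0.0
            r = -outcome_shocks[colour]
        elif f_shocks[t] >= 0:
            sh = float(f_shocks[t])
            r = -sh
        else:
            if cond[t] == 1 and colour != goal[t]:
                sh = 4.0
            else:
                sh = outcome_shocks[colour]
            r = -sh

        # ---- terminal SARSA update
        q_new, e2 = sarsa_update(q_mf[st1, act1], 0.0, r, alpha)
        q_mf[st1, act1] = q_new
        omega = omega_update(omega, e2, eta)

        chi_mf = chi_mf_from_omega(omega, omega_max)
        chi_mb = zero_spe
        if kind == KIND_ARBITRATING:
            p_mb = weight_update(
                p_mb, chi_mf, chi_mb, a_mf_to_mb, a_mb_to_mf, steepness, mf_bias
            )

        a0[t] = act0
        s1[t] = st1
        a1[t] = act1
        out_state[t] = o
        shocks[t] = sh
        ope1[t] = e1
        ope2[t] = e2
        spe1[t] = sp1
        spe2[t] = sp2
        omega_tr[t] = omega
        chi_mf_tr[t] = chi_mf
        chi_mb_tr[t] = chi_mb
        p_mb_tr[t] = p_mb
        for s in range(N_CHOICE_STATES):
            for a in range(2):
                q_mf_tr[t, s, a] = q_mf[s, a]
                q_mb_tr[t, s, a] = q_mb[s, a]
                t_likely_tr[t, s, a] = T[s, a, 0]

    return (
        a0, s1, a1, out_state, shocks,
        p_left0, p_left1, p_taken0, p_taken1,
        ope1, ope2, spe1, spe2,
        omega_tr, chi_mf_tr, chi_mb_tr, p_mb_tr,
        q_mf_tr, q_mb_tr, t_likely_tr,
        omega, zero_spe, p_mb,
    )
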