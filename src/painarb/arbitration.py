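"""Reliability estimation and the two-state arbitration dynamics.

Each controller earns a reliability χ ∈ [0, 1] from its recent prediction
errors. The model-free reliability derives from an estimator Ω of the
absolute outcome prediction error, ΔΩ = η(|OPE| − Ω): if Ω predicts zero OPE
the reliability is maximal, falling linearly to 0 at the outcome-range bound
Ω_max. The model-based reliability is the exponentially weighted rate of
transitions whose state prediction error fell below the threshold ω (counted
as "zero SPE").

Controller weighting follows a dynamical two-state model over (p_MF, p_MB)
with p_MF + p_MB = 1. The transition rates are logistic functions of the
reliability difference, scaled by two free amplitudes; the MB→MF rate carries
a fixed bias so model-free control wins when reliabilities are equal, the
signature of emerging habits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernel

__all__ = [
    "ReliabilityState",
    "ArbitrationState",
    "update_mf_reliability",
    "update_mb_reliability",
    "update_controller_weight",
    "equilibrium_p_mb",
    "integrate_values",
    "softmax_choice_prob",
]


@dataclass(frozen=True)
class ReliabilityState:
    """Running reliabilities of the two controllers.

    omega: current estimate Ω of the absolute OPE (≥ 0).
    eta: learning rate η of the estimator and of the zero-SPE rate.
    omega_threshold: ω, the SPE level below which a transition counts as
        perfectly predicted.
    zero_spe_rate: exponentially weighted fraction of recent zero-SPE
        transitions (this *is* the model-based reliability).
    omega_max: |OPE| at which the model-free reliability bottoms out.
    """

    eta: float
    omega_threshold: float
    omega: float = 0.0
    zero_spe_rate: float = 0.5
    omega_max: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        if not 0.0 < self.omega_threshold < 1.0:
            raise ValueError(
                f"omega_threshold must be in (0, 1), got {self.omega_threshold}"
            )
        if self.omega < 0.0:
            raise ValueError("omega must be non-negative")
        if self.omega_max <= 0.0:
            raise ValueError("omega_max must be positive")

    @property
    def chi_mf(self) -> float:
        return float(_kernel.chi_mf_from_omega(self.omega, self.omega_max))

    @property
    def chi_mb(self) -> float:
        return float(self.zero_spe_rate)


@dataclass(frozen=True)
class ArbitrationState:
    """Two-state weight dynamics over (p_MF, p_MB)."""

    a_mf_to_mb: float
    a_mb_to_mf: float
    p_mb: float = 0.5
    steepness: float = 10.0
    mf_bias: float = 1.5

    def __post_init__(self) -> None:
        if self.a_mf_to_mb <= 0.0 or self.a_mb_to_mf <= 0.0:
            raise ValueError("transition-rate amplitudes must be positive")
        if not 0.0 <= self.p_mb <= 1.0:
            raise ValueError("p_mb must lie in [0, 1]")
        if self.mf_bias < 1.0:
            raise ValueError("mf_bias must be >= 1")

    @property
    def p_mf(self) -> float:
        return 1.0 - self.p_mb


def update_mf_reliability(rel: ReliabilityState, ope: float) -> ReliabilityState:
    """Move Ω toward |OPE| by fraction η."""
    return replace(rel, omega=float(_kernel.omega_update(rel.omega, ope, rel.eta)))


def update_mb_reliability(rel: ReliabilityState, spe: float) -> ReliabilityState:
    """Update the zero-SPE rate with the indicator of SPE < ω."""
    if not 0.0 <= spe <= 1.0:
        raise ValueError(f"SPE must lie in [0, 1], got {spe}")
    rate = _kernel.zero_spe_update(
        rel.zero_spe_rate, spe, rel.omega_threshold, rel.eta
    )
    return replace(rel, zero_spe_rate=float(rate))


def update_controller_weight(
    arb: ArbitrationState, chi_mf: float, chi_mb: float
) -> ArbitrationState:
    """One step of the two-state dynamics given current reliabilities."""
    for chi in (chi_mf, chi_mb):
        if not 0.0 <= chi <= 1.0:
            raise ValueError(f"reliabilities must lie in [0, 1], got {chi}")
    p = _kernel.weight_update(
        arb.p_mb, chi_mf, chi_mb,
        arb.a_mf_to_mb, arb.a_mb_to_mf, arb.steepness, arb.mf_bias,
    )
    return replace(arb, p_mb=float(p))


def equilibrium_p_mb(arb: ArbitrationState, chi_mf: float, chi_mb: float) -> float:
    """Fixed point τ_MF→MB / (τ_MF→MB + τ_MB→MF) of the weight dynamics."""
    tau_fm = arb.a_mf_to_mb * float(
        _kernel.sigmoid(arb.steepness * (chi_mb - chi_mf))
    )
    tau_mf = arb.mf_bias * arb.a_mb_to_mf * float(
        _kernel.sigmoid(arb.steepness * (chi_mf - chi_mb))
    )
    return tau_fm / (tau_fm + tau_mf)


def integrate_values(
    q_mf: np.ndarray, q_mb: np.ndarray, p_mb: float
) -> np.ndarray:
    """Elementwise convex combination Q = p_MB·Q_MB + (1 − p_MB)·Q_MF."""
    q_mf = np.asarray(q_mf, dtype=float)
    q_mb = np.asarray(q_mb, dtype=float)
    if q_mf.shape != q_mb.shape:
        raise ValueError(f"value tables differ in shape: {q_mf.shape} vs {q_mb.shape}")
    if not 0.0 <= p_mb <= 1.0:
        raise ValueError(f"p_mb must lie in [0, 1], got {p_mb}")
    return p_mb * q_mb + (1.0 - p_mb) * q_mf


def softmax_choice_prob(q_row: np.ndarray, beta: float) -> np.ndarray:
    """Softmax action probabilities with inverse temperature β.

    Shift-invariant and overflow-safe; β = 0 yields the uniform policy.
    """
    q = np.asarray(q_row, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("action values must be finite")
    if beta < 0.0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    z = beta * (q - q.max())
    e = np.exp(z)
    return e / e.sum()
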