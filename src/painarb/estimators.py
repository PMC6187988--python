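"""Scikit-learn-style maximum-likelihood estimator for the arbitration model.

``ArbitrationModelEstimator`` treats a trial log (the DataFrame produced by
:mod:`painarb.simulation` or read from a delimited trial file) as ``X`` and
fits the model's free parameters by multi-start Nelder–Mead minimisation of
the negative log-likelihood of the observed choices. It follows sklearn
conventions: constructor stores hyperparameters verbatim, ``fit`` sets
trailing-underscore attributes, ``get_params``/``set_params`` work with
``sklearn.base.clone`` and model-selection utilities.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from . import _kernel
from .simulation import (
    AGENT_KINDS,
    AgentParameters,
    FREE_PARAMETERS,
    _encode_trials,
    _run_kernel,
    _trace_frame,
)
from .task_env import ACTIONS, Environment, build_environment

__all__ = ["ArbitrationModelEstimator", "DEFAULT_BOUNDS", "replay_trials"]

#: default box constraints of the free parameters (searched in logit space)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.01, 1.0),
    "eta": (0.01, 1.0),
    "omega": (0.01, 0.99),
    "a_mf_to_mb": (0.01, 1.0),
    "a_mb_to_mf": (0.01, 1.0),
    "beta": (0.01, 20.0),
}

#: parameters that actually shape the likelihood per model variant; pinning
#: p_MB makes the reliability/arbitration parameters inert for mf/mb-only
VARIANT_FREE: dict[str, tuple[str, ...]] = {
    "arbitrating": FREE_PARAMETERS,
    "mf_only": ("alpha", "beta"),
    "mb_only": ("alpha", "beta"),
}

LIKELIHOOD_FLOOR = 1e-12


def _forced_arrays(trials: pd.DataFrame, env: Environment) -> dict[str, np.ndarray]:
    state_idx = {name: i for i, name in enumerate(env.states)}
    action_idx = {name: i for i, name in enumerate(ACTIONS)}
    return {
        "a0": trials["action0"].map(action_idx).to_numpy(np.int64),
        "s1": trials["state1"].map(state_idx).to_numpy(np.int64),
        "a1": trials["action1"].map(action_idx).to_numpy(np.int64),
        "out": trials["outcome_state"].map(state_idx).to_numpy(np.int64),
        "shocks": trials["shocks"].to_numpy(np.int64),
    }


def replay_trials(
    trials: pd.DataFrame,
    params: AgentParameters,
    env: Environment,
) -> pd.DataFrame:
    """Teacher-forced replay of a trial log; returns the latent trace.

    The model is driven along the observed choices, transitions and outcomes
    using the same compiled trial loop as the simulator, so the trace of a
    replayed simulation is bit-identical to the simulated one.
    """
    enc = _encode_trials(trials)
    n = len(trials)
    out = _run_kernel(
        env, params, enc,
        miss=np.zeros(n, np.int64),
        forced=_forced_arrays(trials, env),
        u=np.zeros((n, 4)),
    )
    return _trace_frame(out, n)


def _choice_log_likelihood(
    trials: pd.DataFrame, trace: pd.DataFrame
) -> np.ndarray:
    """Per-trial log-likelihood of both observed choices (floored)."""
    p0 = np.maximum(trace["p_action0"].to_numpy(), LIKELIHOOD_FLOOR)
    p1 = np.maximum(trace["p_action1"].to_numpy(), LIKELIHOOD_FLOOR)
    return np.log(p0) + np.log(p1)


def _included_mask(trials: pd.DataFrame, include_training: bool) -> np.ndarray:
    mask = ~trials["excluded"].to_numpy(bool)
    if not include_training:
        mask &= ~trials["training"].to_numpy(bool)
    return mask


class ArbitrationModelEstimator(BaseEstimator):
    """Maximum-likelihood fit of the dual-system avoidance-learning model.

    Parameters
    ----------
    variant : {"arbitrating", "mf_only", "mb_only"}
        Which controller mix generates choice probabilities. ``mf_only``
        pins p_MB = 0 and ``mb_only`` pins p_MB = 1; both then optimise only
        (alpha, beta).
    n_restarts : int
        Number of Nelder–Mead runs from independent uniform random starting
        points within the bounds; the best final value wins.
    random_state : int
        Master seed; restart k draws its start from a deterministic child.
    bounds : dict or None
        Per-parameter (low, high) boxes; defaults to :data:`DEFAULT_BOUNDS`.
        The search runs unconstrained in scaled-logit space.
    include_training : bool
        Whether training-session choices enter the likelihood (they are
        always replayed so the learners see the same experience the subject
        did).

    Attributes
    ----------
    params_ : AgentParameters
        Best-fitting parameters (fixed constants taken from ``fixed``).
    nll_ : float
        Best negative log-likelihood, in nats.
    restarts_ : DataFrame
        Per-restart start point, final NLL and convergence flag.
    n_choices_ : int
        Number of choices entering the likelihood (2 per included trial).
    """

    def __init__(
        self,
        variant: str = "arbitrating",
        n_restarts: int = 20,
        random_state: int = 0,
        bounds: dict[str, tuple[float, float]] | None = None,
        maxfev: int = 2000,
        fatol: float = 1e-6,
        include_training: bool = False,
        env: Environment | None = None,
        fixed: AgentParameters | None = None,
    ):
        self.variant = variant
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.bounds = bounds
        self.maxfev = maxfev
        self.fatol = fatol
        self.include_training = include_training
        self.env = env
        self.fixed = fixed

    # -- parameter transform -------------------------------------------------
    def _setup(self):
        if self.variant not in VARIANT_FREE:
            raise ValueError(f"unknown model variant {self.variant!r}")
        names = VARIANT_FREE[self.variant]
        bounds = dict(DEFAULT_BOUNDS)
        bounds.update(self.bounds or {})
        lo = np.array([bounds[n][0] for n in names])
        hi = np.array([bounds[n][1] for n in names])
        return names, lo, hi

    @staticmethod
    def _to_unconstrained(theta, lo, hi):
        frac = np.clip((theta - lo) / (hi - lo), 1e-9, 1 - 1e-9)
        return logit(frac)

    @staticmethod
    def _from_unconstrained(x, lo, hi):
        return lo + (hi - lo) * expit(x)

    def _params_from_theta(self, names, theta) -> AgentParameters:
        base = self.fixed or AgentParameters()
        kind = {"arbitrating": "arbitrating", "mf_only": "mf_only",
                "mb_only": "mb_only"}[self.variant]
        return replace(base, kind=kind, **dict(zip(names, map(float, theta))))

    # -- likelihood ----------------------------------------------------------
    def negative_log_likelihood(
        self, X: pd.DataFrame, params: AgentParameters
    ) -> float:
        """NLL of the observed choices under ``params`` (included trials)."""
        env = self._env()
        trace = replay_trials(X, params, env)
        ll = _choice_log_likelihood(X, trace)
        mask = _included_mask(X, self.include_training)
        return float(-ll[mask].sum())

    def _env(self) -> Environment:
        return self.env if self.env is not None else build_environment()

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "ArbitrationModelEstimator":
        names, lo, hi = self._setup()
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        env = self._env()
        enc = _encode_trials(X)
        forced = _forced_arrays(X, env)
        n = len(X)
        miss = np.zeros(n, np.int64)
        u = np.zeros((n, 4))
        mask = _included_mask(X, self.include_training)
        if not mask.any():
            raise ValueError("no included trials to fit")
        base = self.fixed or AgentParameters()
        kind_code = AGENT_KINDS[
            {"arbitrating": "arbitrating", "mf_only": "mf_only",
             "mb_only": "mb_only"}[self.variant]
        ]
        full = {p: getattr(base, p) for p in FREE_PARAMETERS}

        def nll_of(x: np.ndarray) -> float:
            theta = self._from_unconstrained(x, lo, hi)
            vals = dict(full)
            vals.update(zip(names, theta))
            out = _kernel.run_trials(
                enc["cond"], enc["unc"], enc["goal"], enc["training"], miss,
                forced["a0"], forced["s1"], forced["a1"], forced["out"],
                forced["shocks"],
                u, env.succ, env.outcome_shocks,
                env.p_likely_low, env.p_likely_high,
                vals["alpha"], vals["eta"], vals["omega"],
                vals["a_mf_to_mb"], vals["a_mb_to_mf"], vals["beta"],
                base.steepness, base.mf_bias, base.omega_max,
                kind_code,
                np.zeros((5, 2)), np.full((5, 2, 2), 0.5), 0.0, 0.5, 0.5,
            )
            p0 = np.maximum(out[7][mask], LIKELIHOOD_FLOOR)
            p1 = np.maximum(out[8][mask], LIKELIHOOD_FLOOR)
            return float(-(np.log(p0).sum() + np.log(p1).sum()))

        records = []
        best_x, best_nll = None, np.inf
        for k in range(self.n_restarts):
            rng = np.random.default_rng((self.random_state, k))
            theta0 = lo + (hi - lo) * rng.random(len(names))
            x0 = self._to_unconstrained(theta0, lo, hi)
            res = optimize.minimize(
                nll_of, x0, method="Nelder-Mead",
                options={"fatol": self.fatol, "maxfev": self.maxfev,
                         "xatol": 1e-4},
            )
            records.append(
                {
                    "restart": k,
                    **{f"start_{n_}": v for n_, v in zip(names, theta0)},
                    "nll": float(res.fun),
                    "converged": bool(res.success),
                    "n_evaluations": int(res.nfev),
                }
            )
            if res.fun < best_nll:
                best_nll, best_x = float(res.fun), res.x

        theta_best = self._from_unconstrained(best_x, lo, hi)
        self.free_names_ = names
        self.params_ = self._params_from_theta(names, theta_best)
        self.nll_ = best_nll
        self.restarts_ = pd.DataFrame(records)
        self.converged_ = bool(self.restarts_["converged"].any())
        self.n_trials_ = int(mask.sum())
        self.n_excluded_ = int(X["excluded"].sum())
        self.n_choices_ = 2 * self.n_trials_
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per choice (higher is better)."""
        nll = self.negative_log_likelihood(X, self.params_)
        mask = _included_mask(X, self.include_training)
        return -nll / (2 * int(mask.sum()))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-trial (LEFT, RIGHT) probabilities for both stages.

        Returns an array of shape (n_trials, 2, 2): axis 1 is the stage,
        axis 2 the action.
        """
        trace = replay_trials(X, self.params_, self._env())
        p0 = trace["p_left0"].to_numpy()
        p1 = trace["p_left1"].to_numpy()
        return np.stack(
            [np.stack([p0, 1 - p0], axis=1), np.stack([p1, 1 - p1], axis=1)],
            axis=1,
        )

    def latent_trace(self, X: pd.DataFrame) -> pd.DataFrame:
        """Latent trace of the fitted model replayed along ``X``."""
        return replay_trials(X, self.params_, self._env())
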