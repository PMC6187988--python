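"""Behavioural summaries and model-comparison diagnostics.

Three analyses mirror the standard readouts for this task family:

* condition-wise performance (shocks avoided, success rate, optimal-choice
  proportion overall and per stage) with exact random- and ideal-agent
  baselines computed by enumeration;
* the regime likelihood-ratio test — per-trial log-likelihood of an
  independently fitted model-based-only model minus a model-free-only model,
  summed separately over trials the arbitrating trace assigns to model-free
  (p_MB < 0.5) versus model-based (p_MB > 0.5) control;
* per-parameter group comparisons of fitted parameters (paired or
  two-sample t-tests).

Excluded (penalising) trials never enter any metric or likelihood sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import _choice_log_likelihood, replay_trials
from .fitting import FitResult
from .simulation import enumerate_policy, ideal_agent_policy
from .task_env import CONDITIONS, Environment, GOAL_COLOURS, UNCERTAINTIES, WHITE

__all__ = [
    "ConditionSummary",
    "RegimeLikelihoodRatio",
    "performance_metrics",
    "likelihood_ratio_regimes",
    "regime_group_test",
    "compare_parameter_groups",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Per condition × uncertainty cell performance with baselines.

    ``table`` is indexed by (condition, uncertainty) and holds means and
    across-subject standard errors of: shocks avoided per trial, success
    rate, optimal-choice proportion (overall, stage 1, stage 2), plus the
    exact random- and ideal-agent baselines for shocks avoided and success.
    ``per_subject`` holds the underlying per-subject cell means.
    """

    table: pd.DataFrame
    per_subject: pd.DataFrame


def _cell_baselines(env: Environment, condition: str, uncertainty: str):
    """Exact enumeration baselines; specific cells average over legal goals."""
    goals = GOAL_COLOURS if condition == "specific" else (WHITE,)
    rand_avoided, rand_success, ideal_avoided, ideal_success = 0.0, 0.0, 0.0, 0.0
    for goal in goals:
        paths = enumerate_policy(env, condition, uncertainty, goal, policy=None)
        rand_avoided += float((paths["prob"] * (4 - paths["shocks"])).sum())
        rand_success += float(paths.loc[paths["shocks"] == 0, "prob"].sum())
        ideal = ideal_agent_policy(env, condition, uncertainty, goal)
        pol = {
            (s, a): 1.0 if ideal[s] == a else 0.0
            for s in env.choice_states
            for a in env.actions
        }
        paths = enumerate_policy(env, condition, uncertainty, goal, policy=pol)
        ideal_avoided += float((paths["prob"] * (4 - paths["shocks"])).sum())
        ideal_success += float(paths.loc[paths["shocks"] == 0, "prob"].sum())
    k = len(goals)
    return (rand_avoided / k, rand_success / k, ideal_avoided / k, ideal_success / k)


def _mark_optimal(trials: pd.DataFrame, env: Environment) -> pd.DataFrame:
    """Annotate each trial with stage-wise optimality flags.

    Stage 1 compares the taken first action with the ideal agent's root
    action; stage 2 compares the second action with the ideal action at the
    *realised* intermediate state, both goal-dependent in specific blocks.
    """
    cache: dict[tuple[str, str, str], dict[str, str]] = {}

    def policy_for(row):
        key = (row["condition"], row["uncertainty"], row["goal"])
        if key not in cache:
            cache[key] = ideal_agent_policy(env, *key)
        return cache[key]

    out = trials.copy()
    pols = [policy_for(row) for _, row in trials.iterrows()]
    out["optimal0"] = [
        p["S0"] == row["action0"] for p, (_, row) in zip(pols, trials.iterrows())
    ]
    out["optimal1"] = [
        p[row["state1"]] == row["action1"]
        for p, (_, row) in zip(pols, trials.iterrows())
    ]
    out["optimal_both"] = out["optimal0"] & out["optimal1"]
    return out


def performance_metrics(
    trials: pd.DataFrame, env: Environment, *, success_rule: str = "zero"
) -> ConditionSummary:
    """Condition-wise behavioural summary across subjects.

    ``trials`` may pool several subjects (distinguished by the ``subject``
    column); standard errors are computed across subjects. Training trials
    and excluded (penalising) trials are dropped. ``success_rule`` is
    ``"zero"`` (a trial succeeded iff 0 shocks were delivered) or
    ``"sub_maximal"`` (succeeded iff fewer than 4).
    """
    if success_rule not in ("zero", "sub_maximal"):
        raise ValueError(f"unknown success rule {success_rule!r}")
    data = trials[~trials["excluded"] & ~trials["training"]].copy()
    if data.empty:
        raise ValueError("no included experimental trials")
    data = _mark_optimal(data, env)
    data["shocks_avoided"] = 4 - data["shocks"]
    threshold = 1 if success_rule == "zero" else 4
    data["success"] = data["shocks"] < threshold

    per_subject = (
        data.groupby(["subject", "condition", "uncertainty"])
        .agg(
            shocks_avoided=("shocks_avoided", "mean"),
            success_rate=("success", "mean"),
            optimal=("optimal_both", "mean"),
            optimal_stage1=("optimal0", "mean"),
            optimal_stage2=("optimal1", "mean"),
            n_trials=("shocks", "size"),
        )
        .reset_index()
    )

    rows = []
    for condition in CONDITIONS:
        for uncertainty in UNCERTAINTIES:
            cell = per_subject[
                (per_subject["condition"] == condition)
                & (per_subject["uncertainty"] == uncertainty)
            ]
            if cell.empty:
                raise ValueError(f"empty condition cell {(condition, uncertainty)}")
            rb_av, rb_su, id_av, id_su = _cell_baselines(env, condition, uncertainty)
            n = len(cell)
            sem = lambda col: float(cell[col].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {
                    "condition": condition,
                    "uncertainty": uncertainty,
                    "n_subjects": n,
                    "n_trials": int(cell["n_trials"].sum()),
                    "shocks_avoided": float(cell["shocks_avoided"].mean()),
                    "shocks_avoided_sem": sem("shocks_avoided"),
                    "success_rate": float(cell["success_rate"].mean()),
                    "success_rate_sem": sem("success_rate"),
                    "optimal": float(cell["optimal"].mean()),
                    "optimal_sem": sem("optimal"),
                    "optimal_stage1": float(cell["optimal_stage1"].mean()),
                    "optimal_stage1_sem": sem("optimal_stage1"),
                    "optimal_stage2": float(cell["optimal_stage2"].mean()),
                    "optimal_stage2_sem": sem("optimal_stage2"),
                    "random_shocks_avoided": rb_av,
                    "random_success_rate": rb_su,
                    "ideal_shocks_avoided": id_av,
                    "ideal_success_rate": id_su,
                }
            )
    table = pd.DataFrame(rows).set_index(["condition", "uncertainty"])
    return ConditionSummary(table=table, per_subject=per_subject)


@dataclass(frozen=True)
class RegimeLikelihoodRatio:
    """MB-minus-MF log-likelihood split by the arbitration regime.

    ``mf_regime`` / ``mb_regime`` are the summed per-trial differences over
    trials with p_MB < 0.5 and p_MB > 0.5 respectively (p_MB = 0.5 counts as
    the model-free regime); ``per_trial`` keeps the trial-level values.
    """

    mf_regime: float
    mb_regime: float
    n_mf_trials: int
    n_mb_trials: int
    per_trial: pd.DataFrame


def likelihood_ratio_regimes(
    trials: pd.DataFrame,
    trace: pd.DataFrame,
    mf_fit: FitResult,
    mb_fit: FitResult,
    env: Environment,
) -> RegimeLikelihoodRatio:
    """Per-regime log-likelihood difference of MB-only minus MF-only fits.

    ``trace`` must supply the arbitrating model's per-trial p_MB aligned with
    ``trials`` (for simulated data, the generating trace; fits of the two
    single-system models are produced independently of it to avoid
    circularity). Training and excluded trials are dropped.
    """
    if len(trace) != len(trials):
        raise ValueError("trace and trial log differ in length")
    mf_trace = replay_trials(trials, mf_fit.params, env)
    mb_trace = replay_trials(trials, mb_fit.params, env)
    diff = _choice_log_likelihood(trials, mb_trace) - _choice_log_likelihood(
        trials, mf_trace
    )
    included = (~trials["excluded"] & ~trials["training"]).to_numpy()
    p_mb = trace["p_mb"].to_numpy()
    per_trial = pd.DataFrame(
        {
            "llr": diff,
            "p_mb": p_mb,
            "regime": np.where(p_mb > 0.5, "mb", "mf"),
            "included": included,
        }
    )
    inc = per_trial[per_trial["included"]]
    mf_rows = inc[inc["regime"] == "mf"]
    mb_rows = inc[inc["regime"] == "mb"]
    return RegimeLikelihoodRatio(
        mf_regime=float(mf_rows["llr"].sum()),
        mb_regime=float(mb_rows["llr"].sum()),
        n_mf_trials=len(mf_rows),
        n_mb_trials=len(mb_rows),
        per_trial=per_trial,
    )


def regime_group_test(results: list[RegimeLikelihoodRatio]) -> pd.DataFrame:
    """One-sample tests of the regime statistics, across subjects and trials.

    Across subjects: t-test of the per-subject regime sums against zero.
    Across trials: t-test of the pooled per-trial differences against zero.
    """
    rows = []
    for regime in ("mf", "mb"):
        subject_vals = np.array(
            [r.mf_regime if regime == "mf" else r.mb_regime for r in results]
        )
        pooled = pd.concat([r.per_trial for r in results])
        pooled = pooled[(pooled["included"]) & (pooled["regime"] == regime)]
        t_sub = stats.ttest_1samp(subject_vals, 0.0) if len(subject_vals) > 1 else None
        t_tr = stats.ttest_1samp(pooled["llr"], 0.0) if len(pooled) > 1 else None
        rows.append(
            {
                "regime": regime,
                "mean_subject_statistic": float(subject_vals.mean()),
                "t_subjects": float(t_sub.statistic) if t_sub else np.nan,
                "p_subjects": float(t_sub.pvalue) if t_sub else np.nan,
                "n_subjects": len(subject_vals),
                "t_trials": float(t_tr.statistic) if t_tr else np.nan,
                "p_trials": float(t_tr.pvalue) if t_tr else np.nan,
                "n_trials": len(pooled),
            }
        )
    return pd.DataFrame(rows).set_index("regime")


def compare_parameter_groups(
    fits_a: list[FitResult],
    fits_b: list[FitResult],
    *,
    paired: bool = False,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-parameter t-tests between two groups of fitted subjects.

    Two-sample Welch test by default (``equal_var=True`` for the pooled
    variant); ``paired=True`` runs a paired test and requires matched group
    sizes. Identical groups (all differences zero) report statistic 0 and
    p-value 1 rather than an undefined test.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("each group needs at least 2 fits")
    if paired and len(fits_a) != len(fits_b):
        raise ValueError("paired comparison needs matched group sizes")
    names = set(fits_a[0].restarts.filter(like="start_").columns)
    for fit in fits_a + fits_b:
        if set(fit.restarts.filter(like="start_").columns) != names:
            raise ValueError("mismatched parameter sets between fits")
    params = [c.removeprefix("start_") for c in sorted(names)]

    rows = []
    for name in params:
        a = np.array([getattr(f.params, name) for f in fits_a])
        b = np.array([getattr(f.params, name) for f in fits_b])
        if paired:
            d = a - b
            if np.allclose(d, 0.0):
                statistic, pvalue, df = 0.0, 1.0, len(d) - 1
            else:
                res = stats.ttest_rel(a, b)
                statistic, pvalue, df = res.statistic, res.pvalue, res.df
        else:
            if np.allclose(a.mean(), b.mean()) and np.allclose(a.std(), b.std()) and np.allclose(a, b):
                statistic, pvalue, df = 0.0, 1.0, len(a) + len(b) - 2
            else:
                res = stats.ttest_ind(a, b, equal_var=equal_var)
                statistic, pvalue, df = res.statistic, res.pvalue, res.df
        rows.append(
            {
                "parameter": name,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "statistic": float(statistic),
                "df": float(df),
                "p_value": float(pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
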