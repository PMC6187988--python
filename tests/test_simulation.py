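"""Agent simulation: reproducibility, baselines, regime separation."""

import numpy as np
import pandas as pd
import pytest

from painarb.simulation import (
    AgentParameters,
    default_param_sampler,
    enumerate_policy,
    ideal_agent_policy,
    simulate_agent,
    simulate_cohort,
)
from painarb.task_env import BlockSpec, SessionPlan, TaskConfig, generate_session_plan


def flat_plan(condition="flexible", uncertainty="low", n_blocks=40, n_trials=5,
              goal="white"):
    """A plan of identical blocks for baseline comparisons (no training)."""
    return SessionPlan(
        blocks=tuple(
            BlockSpec(
                condition=condition,
                uncertainty=uncertainty,
                n_trials=n_trials,
                goal_colours=(goal,) * n_trials,
                session=1,
            )
            for _ in range(n_blocks)
        )
    )


class TestReproducibility:
    def test_same_seed_gives_identical_log(self, env, default_plan):
        params = AgentParameters()
        t1, tr1 = simulate_agent(env, params, default_plan, seed=42)
        t2, tr2 = simulate_agent(env, params, default_plan, seed=42)
        assert t1.to_csv() == t2.to_csv()
        assert tr1.to_csv() == tr2.to_csv()

    def test_different_seed_differs(self, env, default_plan):
        params = AgentParameters()
        t1, _ = simulate_agent(env, params, default_plan, seed=42)
        t2, _ = simulate_agent(env, params, default_plan, seed=43)
        assert t1.to_csv() != t2.to_csv()

    def test_cohort_reproducible_and_distinct(self, config):
        cohort_a = simulate_cohort(15, default_param_sampler, config, seed=5)
        cohort_b = simulate_cohort(15, default_param_sampler, config, seed=5)
        assert len(cohort_a) == 15
        assert len({m.seed for m in cohort_a}) == 15
        for a, b in zip(cohort_a, cohort_b):
            assert a.seed == b.seed
            pd.testing.assert_frame_equal(a.trials, b.trials)
        params = np.array([m.params.beta for m in cohort_a])
        assert len(np.unique(params)) == 15

    def test_cohort_of_one_matches_simulate_agent(self, config, env):
        member = simulate_cohort(
            1, lambda rng: AgentParameters(), config, seed=9
        )[0]
        rng = np.random.default_rng(member.seed)
        AgentParameters()  # sampler consumed no randomness from rng
        plan = generate_session_plan(config, rng)
        trials, _ = simulate_agent(
            env, AgentParameters(), plan, seed=member.seed + 1, subject="sim-0"
        )
        pd.testing.assert_frame_equal(member.trials, trials)

    def test_empty_cohort_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_cohort(0, default_param_sampler, config, seed=1)


class TestBaselines:
    def test_random_agent_matches_enumerated_success_rate(self, env):
        """Uniform-policy success rate vs. the exact path enumeration."""
        plan = flat_plan("flexible", "low", n_blocks=200)
        trials, _ = simulate_agent(
            env, AgentParameters(kind="random"), plan, seed=7
        )
        paths = enumerate_policy(env, "flexible", "low", "white")
        p_success = float(paths.loc[paths["shocks"] == 0, "prob"].sum())
        n = len(trials)
        observed = (trials["shocks"] == 0).mean()
        se = np.sqrt(p_success * (1 - p_success) / n)
        assert abs(observed - p_success) < 3 * se

    def test_random_agent_expected_shocks(self, env):
        plan = flat_plan("flexible", "high", n_blocks=200)
        trials, _ = simulate_agent(
            env, AgentParameters(kind="random"), plan, seed=8
        )
        paths = enumerate_policy(env, "flexible", "high", "white")
        expected = float((paths["prob"] * paths["shocks"]).sum())
        assert trials["shocks"].mean() == pytest.approx(expected, abs=0.15)

    def test_informed_mb_agent_is_near_optimal_in_low_uncertainty(self, env):
        """Greedy planner given the true transition model chooses optimally."""
        T_true = np.empty((5, 2, 2))
        T_true[:, :, 0] = 0.9
        T_true[:, :, 1] = 0.1
        plan = flat_plan("flexible", "low", n_blocks=60)
        params = AgentParameters(kind="mb_only", beta=20.0, alpha=0.01)
        trials, _ = simulate_agent(env, params, plan, seed=3, initial_T=T_true)
        pol = ideal_agent_policy(env, "flexible", "low", "white")
        stage1_optimal = (trials["action0"] == pol["S0"]).mean()
        stage2_optimal = np.mean(
            [row["action1"] == pol[row["state1"]] for _, row in trials.iterrows()]
        )
        assert stage1_optimal > 0.95
        assert stage2_optimal > 0.95


class TestIdealPolicy:
    def test_flexible_first_stage_invariant_to_uncertainty(self, env):
        low = ideal_agent_policy(env, "flexible", "low", "white")
        high = ideal_agent_policy(env, "flexible", "high", "white")
        assert low["S0"] == high["S0"] == "RIGHT"

    def test_flexible_second_stage_flips_with_uncertainty(self, env):
        low = ideal_agent_policy(env, "flexible", "low", "white")
        high = ideal_agent_policy(env, "flexible", "high", "white")
        likely = env.likely_successor("S0", low["S0"])
        assert low[likely] == "RIGHT"
        assert high[likely] == "LEFT"
        assert low[likely] != high[likely]

    def test_specific_goal_matches_enumeration(self, env):
        """Expectimax policy beats or ties every other policy, per goal."""
        for goal in ("red", "yellow", "blue"):
            for unc in ("low", "high"):
                pol = ideal_agent_policy(env, "specific", unc, goal)
                pol_probs = {
                    (s, a): 1.0 if pol[s] == a else 0.0
                    for s in env.choice_states
                    for a in env.actions
                }
                paths = enumerate_policy(env, "specific", unc, goal, pol_probs)
                best = float((paths["prob"] * paths["shocks"]).sum())
                rng = np.random.default_rng(1)
                for _ in range(20):  # random comparison policies
                    alt = {
                        s: env.actions[rng.integers(2)] for s in env.choice_states
                    }
                    alt_probs = {
                        (s, a): 1.0 if alt[s] == a else 0.0
                        for s in env.choice_states
                        for a in env.actions
                    }
                    paths = enumerate_policy(env, "specific", unc, goal, alt_probs)
                    assert best <= float((paths["prob"] * paths["shocks"]).sum()) + 1e-12


class TestArbitratingAgent:
    def test_regime_separation_specific_vs_flexible(self, env, config):
        """Devaluation drives more model-based control than the flexible rule."""
        p_spec, p_flex = [], []
        for s in range(5):
            plan = generate_session_plan(config, np.random.default_rng(300 + s))
            trials, trace = simulate_agent(
                env, AgentParameters(), plan, seed=400 + s
            )
            mask = ~trials["training"].to_numpy()
            cond = trials["condition"].to_numpy()[mask]
            p_mb = trace["p_mb"].to_numpy()[mask]
            p_spec.append(p_mb[cond == "specific"].mean())
            p_flex.append(p_mb[cond == "flexible"].mean())
        assert np.mean(p_spec) > np.mean(p_flex)

    def test_latent_trace_invariants(self, default_sim):
        trials, trace = default_sim
        assert len(trace) == len(trials)
        for col in ("p_action0", "p_action1", "p_mb", "chi_mf", "chi_mb"):
            assert trace[col].between(0.0, 1.0).all()
        assert (trace["spe1"].between(0.0, 1.0)).all()
        assert (trace["omega"] >= 0.0).all()
        t_cols = [c for c in trace.columns if c.startswith("T_likely_")]
        assert trace[t_cols].le(1.0).all().all()
        assert trace[t_cols].ge(0.0).all().all()

    def test_shocks_avoided_bounded(self, default_sim):
        trials, _ = default_sim
        avoided = 4 - trials.loc[~trials["training"], "shocks"]
        assert avoided.between(0, 4).all()

    def test_training_session_delivers_no_shocks(self, default_sim):
        trials, _ = default_sim
        assert (trials.loc[trials["training"], "shocks"] == 0).all()


class TestPenalisingTrials:
    def test_miss_probability_marks_excluded_trials(self, env, default_plan):
        trials, _ = simulate_agent(
            env, AgentParameters(), default_plan, seed=6, miss_probability=0.2
        )
        frac = trials["excluded"].mean()
        assert 0.1 < frac < 0.3
        trials0, _ = simulate_agent(
            env, AgentParameters(), default_plan, seed=6, miss_probability=0.0
        )
        assert not trials0["excluded"].any()
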