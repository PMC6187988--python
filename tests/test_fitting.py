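"""Likelihood, multi-start fitting, and the shared simulate/replay path."""

import math

import numpy as np
import pandas as pd
import pytest

from painarb.estimators import ArbitrationModelEstimator, replay_trials
from painarb.fitting import fit_parameters, negative_log_likelihood, parameter_recovery
from painarb.simulation import AgentParameters, simulate_agent
from painarb.task_env import COLOURS, TaskConfig, build_environment, generate_session_plan


@pytest.fixture(scope="module")
def small_config():
    return TaskConfig(n_sessions=1, blocks_per_cell_per_session=1, training_trials=10)


@pytest.fixture(scope="module")
def small_sim(small_config):
    env = build_environment(small_config)
    plan = generate_session_plan(small_config, np.random.default_rng(31))
    trials, trace = simulate_agent(env, AgentParameters(), plan, seed=32)
    return env, trials, trace


def reference_replay(trials, env, p: AgentParameters):
    """Independent pure-Python replay of the full model (lists and floats).

    Re-states the whole per-trial algorithm from scratch as an oracle for
    the compiled kernel: devalue/replan, softmax stage 1, SPE update and
    replan, softmax stage 2, bootstrap SARSA, outcome SARSA, reliability and
    weight updates.
    """
    succ = env.succ
    out_sh = [0.0, 1.0, 2.0, 4.0]
    q_mf = [[0.0, 0.0] for _ in range(5)]
    T = [[[0.5, 0.5], [0.5, 0.5]] for _ in range(5)]
    omega, z, pmb = 0.0, 0.5, 0.5
    log_liks, p_mb_trace = [], []

    def plan_values(tv):
        q2 = [
            [
                sum(T[s][a][k] * tv[succ[s, a, k] - 5] for k in range(2))
                for a in range(2)
            ]
            for s in range(5)
        ]
        for a in range(2):
            v = 0.0
            for k in range(2):
                sp = succ[0, a, k]
                v += T[0][a][k] * max(q2[sp][0], q2[sp][1])
            q2[0][a] = v
        return q2

    def p_left(ql, qr):
        return 1.0 / (1.0 + math.exp(-p.beta * (ql - qr)))

    for row in trials.itertuples():
        goal = COLOURS.index(row.goal) if row.goal != "white" else -1
        if row.condition == "specific":
            tv = [-out_sh[c] if c == goal else -4.0 for c in range(4)]
        else:
            tv = [-v for v in out_sh]
        q_mb = plan_values(tv)
        a0 = 0 if row.action0 == "LEFT" else 1
        a1 = 0 if row.action1 == "LEFT" else 1
        s1 = env.state_index(row.state1)
        o = env.state_index(row.outcome_state)

        w = pmb
        ql = w * q_mb[0][0] + (1 - w) * q_mf[0][0]
        qr = w * q_mb[0][1] + (1 - w) * q_mf[0][1]
        pl = p_left(ql, qr)
        ll = math.log(max(pl if a0 == 0 else 1 - pl, 1e-12))

        slot1 = 0 if succ[0, a0, 0] == s1 else 1
        spe1 = 1.0 - T[0][a0][slot1]
        T[0][a0][slot1] += p.alpha * spe1
        T[0][a0][1 - slot1] = 1.0 - T[0][a0][slot1]
        z = z + p.eta * ((1.0 if spe1 < p.omega else 0.0) - z)
        q_mb = plan_values(tv)

        ql = w * q_mb[s1][0] + (1 - w) * q_mf[s1][0]
        qr = w * q_mb[s1][1] + (1 - w) * q_mf[s1][1]
        pl = p_left(ql, qr)
        ll += math.log(max(pl if a1 == 0 else 1 - pl, 1e-12))

        ope1 = q_mf[s1][a1] - q_mf[0][a0]
        q_mf[0][a0] += p.alpha * ope1
        omega += p.eta * (abs(ope1) - omega)

        slot2 = 0 if succ[s1, a1, 0] == o else 1
        spe2 = 1.0 - T[s1][a1][slot2]
        T[s1][a1][slot2] += p.alpha * spe2
        T[s1][a1][1 - slot2] = 1.0 - T[s1][a1][slot2]
        z = z + p.eta * ((1.0 if spe2 < p.omega else 0.0) - z)

        r = -out_sh[o - 5] if row.training else -float(row.shocks)
        ope2 = r - q_mf[s1][a1]
        q_mf[s1][a1] += p.alpha * ope2
        omega += p.eta * (abs(ope2) - omega)

        chi_mf = max(0.0, 1.0 - omega / p.omega_max)
        tau_fm = p.a_mf_to_mb / (1.0 + math.exp(-p.steepness * (z - chi_mf)))
        tau_mf = p.mf_bias * p.a_mb_to_mf / (
            1.0 + math.exp(-p.steepness * (chi_mf - z))
        )
        pmb = min(1.0, max(0.0, pmb + tau_fm * (1 - pmb) - tau_mf * pmb))
        log_liks.append(ll)
        p_mb_trace.append(pmb)
    return np.array(log_liks), np.array(p_mb_trace)


class TestLikelihood:
    def test_matches_independent_reference_replay(self, small_sim):
        """Kernel replay agrees with a from-scratch Python implementation."""
        env, trials, _ = small_sim
        params = AgentParameters(alpha=0.3, eta=0.25, omega=0.45,
                                 a_mf_to_mb=0.6, a_mb_to_mf=0.4, beta=1.7)
        ll_ref, pmb_ref = reference_replay(trials, env, params)
        trace = replay_trials(trials, params, env)
        ll_kernel = (
            np.log(np.maximum(trace["p_action0"], 1e-12))
            + np.log(np.maximum(trace["p_action1"], 1e-12))
        ).to_numpy()
        np.testing.assert_allclose(ll_kernel, ll_ref, atol=1e-10)
        np.testing.assert_allclose(trace["p_mb"].to_numpy(), pmb_ref, atol=1e-10)
        included = ~trials["training"] & ~trials["excluded"]
        nll = negative_log_likelihood(trials, params, "arbitrating", env=env)
        assert nll == pytest.approx(-ll_ref[included].sum(), abs=1e-8)

    def test_replay_of_simulation_reproduces_latents(self, small_sim):
        """Teacher forcing the simulated choices yields the identical trace."""
        env, trials, trace = small_sim
        replayed = replay_trials(trials, AgentParameters(), env)
        pd.testing.assert_frame_equal(replayed, trace)

    def test_goal_relabelling_leaves_model_free_values_untouched(self, small_sim):
        """Holding experience fixed, permuting goals changes only the
        model-based side: Q_MF traces are identical (the MF system cannot
        see ahead to the goal rule)."""
        env, trials, _ = small_sim
        params = AgentParameters()
        base = replay_trials(trials, params, env)
        shuffled = trials.copy()
        spec = shuffled["condition"] == "specific"
        rng = np.random.default_rng(4)
        shuffled.loc[spec, "goal"] = rng.permutation(
            shuffled.loc[spec, "goal"].to_numpy()
        )
        perm = replay_trials(shuffled, params, env)
        mf_cols = [c for c in base.columns if c.startswith("q_mf_")]
        pd.testing.assert_frame_equal(base[mf_cols], perm[mf_cols])
        assert not np.allclose(
            base["q_mb_S0_LEFT"], perm["q_mb_S0_LEFT"]
        )

    def test_excluded_trials_do_not_contribute(self, env, default_plan):
        trials, _ = simulate_agent(
            env, AgentParameters(), default_plan, seed=77, miss_probability=0.25
        )
        n_included = int((~trials["excluded"] & ~trials["training"]).sum())
        params = AgentParameters(beta=0.0)
        nll = negative_log_likelihood(trials, params, "arbitrating", env=env)
        assert nll == pytest.approx(2 * n_included * np.log(2), rel=1e-12)

    def test_mf_generated_data_prefers_mf_model(self, env):
        """On flexible-only data from a model-free agent, the MF-only fit
        beats the MB-only fit in likelihood."""
        from test_simulation import flat_plan

        wins = 0
        for s in range(10):
            plan = flat_plan("flexible", "low", n_blocks=30)
            trials, _ = simulate_agent(
                env, AgentParameters(kind="mf_only"), plan, seed=500 + s
            )
            mf = fit_parameters(trials, "mf_only", n_restarts=4, seed=s, env=env)
            mb = fit_parameters(trials, "mb_only", n_restarts=4, seed=s, env=env)
            wins += mf.nll < mb.nll
        assert wins >= 9


class TestFitting:
    def test_more_restarts_never_worse(self, small_sim):
        """Restart seeds are nested, so 8 starts dominate the first 3."""
        env, trials, _ = small_sim
        fit3 = fit_parameters(trials, "mf_only", n_restarts=3, seed=0, env=env)
        fit8 = fit_parameters(trials, "mf_only", n_restarts=8, seed=0, env=env)
        assert fit8.nll <= fit3.nll + 1e-9

    def test_fit_result_invariants(self, small_sim):
        env, trials, _ = small_sim
        fit = fit_parameters(trials, "mb_only", n_restarts=3, seed=1, env=env)
        assert fit.nll == pytest.approx(fit.restarts["nll"].min())
        assert fit.nll >= 0.0
        assert fit.n_trials == int((~trials["training"] & ~trials["excluded"]).sum())
        assert fit.params.kind == "mb_only"

    def test_estimator_sklearn_contract(self, small_sim):
        from sklearn.base import clone

        env, trials, _ = small_sim
        est = ArbitrationModelEstimator(
            variant="mf_only", n_restarts=2, random_state=0, env=env
        )
        cloned = clone(est)
        assert cloned.get_params()["variant"] == "mf_only"
        est.fit(trials)
        assert hasattr(est, "params_") and hasattr(est, "nll_")
        proba = est.predict_proba(trials)
        assert proba.shape == (len(trials), 2, 2)
        np.testing.assert_allclose(proba.sum(axis=2), 1.0, atol=1e-12)
        score = est.score(trials)
        assert score == pytest.approx(-est.nll_ / est.n_choices_)

    def test_fit_serialisation(self, small_sim, tmp_path):
        env, trials, _ = small_sim
        fit = fit_parameters(trials, "mf_only", n_restarts=2, seed=3, env=env)
        out = tmp_path / "fit.yaml"
        fit.to_yaml(out)
        import yaml

        payload = yaml.safe_load(out.read_text())
        assert payload["variant"] == "mf_only"
        assert payload["nll"] == pytest.approx(fit.nll)


class TestRecovery:
    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            parameter_recovery(lambda rng: AgentParameters(), n_subjects=1)

    def test_report_structure_on_small_cohort(self, small_config):
        report = parameter_recovery(
            lambda rng: AgentParameters(
                alpha=rng.uniform(0.1, 0.5), beta=rng.uniform(1.0, 4.0)
            ),
            n_subjects=3,
            seed=2,
            config=small_config,
            variant="mf_only",
            n_restarts=3,
        )
        assert set(report.table.index) == {"alpha", "beta"}
        assert {"bias", "rmse", "pearson_r", "spearman_r"} <= set(report.table.columns)
        assert len(report.scatter) == 6
        assert len(report.fits) == 3
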