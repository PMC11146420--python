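import numpy as np
import pytest

from arbrl._engine import COL, pack_params, replay_arrays, simulate_arrays
from arbrl.arbitration import (
    TRACE_COLUMNS,
    AgentParams,
    ArbitrationAgent,
    action_probabilities,
    integrate_values,
    transition_rates,
    update_pmb,
)
from arbrl.io import GOAL_CODES
from arbrl.task import TaskConfig, TaskGraph, build_design, sample_goals


class TestTransitionRates:
    def test_maximal_mf_uncertainty_gives_half_amplitude(self):
        p = AgentParams(a_alpha=1.0, b_alpha=7.3)
        alpha, _ = transition_rates(1.0, 0.0, p)
        assert alpha == pytest.approx(0.5)
        _, beta = transition_rates(0.0, 1.0, AgentParams(a_beta=0.8))
        assert beta == pytest.approx(0.4)

    def test_reliable_mf_suppresses_alpha(self):
        p = AgentParams(a_alpha=1.0, b_alpha=10.0)
        alpha, _ = transition_rates(0.0, 0.0, p)
        assert alpha == pytest.approx(1.0 / (1.0 + np.e**10))

    def test_strict_monotonicity_on_dense_grid(self):
        p = AgentParams()
        grid = np.linspace(0.0, 1.0, 500)
        alphas = [transition_rates(x, 0.0, p)[0] for x in grid]
        betas = [transition_rates(0.0, x, p)[1] for x in grid]
        assert all(b > a for a, b in zip(alphas, alphas[1:]))
        assert all(b > a for a, b in zip(betas, betas[1:]))
        assert max(alphas) < p.a_alpha and max(betas) < p.a_beta

    def test_domain_check(self):
        with pytest.raises(ValueError):
            transition_rates(1.5, 0.0, AgentParams())


class TestPmbDynamics:
    def test_symmetric_rates_hold_the_midpoint(self):
        assert update_pmb(0.5, 0.2, 0.2) == pytest.approx(0.5)

    def test_single_euler_step(self):
        assert update_pmb(0.0, 0.3, 0.1, n_substeps=1) == pytest.approx(0.3)

    def test_converges_to_analytic_fixed_point(self):
        pmb = 0.1
        for _ in range(300):
            pmb = update_pmb(pmb, 0.3, 0.1)
        assert pmb == pytest.approx(0.75, abs=1e-9)

    def test_substeps_stay_in_bounds(self):
        pmb = update_pmb(1.0, 0.0, 0.9, n_substeps=4)
        assert 0.0 <= pmb <= 1.0

    def test_nonfinite_rates_rejected(self):
        with pytest.raises(ValueError):
            update_pmb(0.5, np.nan, 0.1)


class TestValueIntegration:
    @pytest.mark.parametrize("pmb, expected", [(1.0, [40.0, 5.0]), (0.0, [20.0, 10.0]), (0.5, [30.0, 7.5])])
    def test_weighted_average(self, pmb, expected):
        out = integrate_values([40.0, 5.0], [20.0, 10.0], pmb)
        assert out == pytest.approx(expected)

    def test_mismatched_actions_rejected(self):
        with pytest.raises(ValueError):
            integrate_values([1.0, 2.0], [1.0], 0.5)


class TestSoftmax:
    def test_zero_temperature_is_uniform(self):
        assert action_probabilities([100.0, -3.0], 0.0) == pytest.approx([0.5, 0.5])

    def test_equal_values_are_uniform(self):
        assert action_probabilities([7.0, 7.0], 2.0) == pytest.approx([0.5, 0.5])

    def test_unit_gap(self):
        p = action_probabilities([1.0, 0.0], 1.0)
        assert p[0] == pytest.approx(np.e / (1 + np.e))

    def test_numerically_safe_for_large_values(self):
        p = action_probabilities([4000.0, 0.0], 1.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            action_probabilities([1.0, 0.0], -1.0)


class TestAgentKernelEquivalence:
    def test_reference_agent_matches_compiled_kernel(self, graph):
        cfg = TaskConfig(sessions=2, timeout_prob=0.15, timeout_penalty=5.0)
        design = build_design(cfg, seed=3)
        rng = np.random.default_rng(77)
        goals = sample_goals(design, rng)
        draws = rng.random((design.n_trials, 6))
        params = AgentParams(tau=0.2)

        pvec = pack_params(params, "arb", timeout_prob=0.15, timeout_penalty=5.0)
        trace = simulate_arrays(
            pvec, graph.terminal_colours, graph.terminal_values,
            design.trials["p_common"].to_numpy(float),
            np.array([GOAL_CODES[g] for g in goals]),
            design.trials["new_session"].to_numpy(np.int64), draws,
        )
        agent = ArbitrationAgent(params, graph, timeout_prob=0.15, timeout_penalty=5.0)
        ref = agent.run_design(design, goals, draws)
        for name in TRACE_COLUMNS:
            np.testing.assert_allclose(
                trace[:, COL[name]], ref[name].to_numpy(dtype=float),
                atol=1e-12, rtol=1e-10, err_msg=name,
            )

    def test_single_system_modes_pin_the_mixture(self, graph, short_design):
        rng = np.random.default_rng(8)
        goals = sample_goals(short_design, rng)
        draws = rng.random((short_design.n_trials, 6))
        for mode, value in (("mb", 1.0), ("mf", 0.0)):
            pvec = pack_params(AgentParams(), mode)
            trace = simulate_arrays(
                pvec, graph.terminal_colours, graph.terminal_values,
                short_design.trials["p_common"].to_numpy(float),
                np.array([GOAL_CODES[g] for g in goals]),
                short_design.trials["new_session"].to_numpy(np.int64), draws,
            )
            assert (trace[:, COL["pmb"]] == value).all()

    def test_greedy_limit_chooses_argmax(self, graph):
        agent = ArbitrationAgent(AgentParams(tau=1e6), graph)
        agent.qmf.Q[0] = [10.0, 0.0]  # break the initial tie
        draws = np.array([0.999, 1.0, 0.0, 0.999, 1.0, 0.0])
        out = agent.run_trial("white", 0.9, True, draws)
        # with tau -> inf even a draw of 0.999 picks the argmax action
        qarb1 = (out["qarb1_left"], out["qarb1_right"])
        assert out["a1"] == int(np.argmax(qarb1)) == 0

    def test_full_simulation_traces_are_finite(self, hc_log):
        latent = ["spe1", "spe2", "rpe1", "rpe2", "chi_mb", "chi_mf",
                  "alpha", "beta", "pmb", "pmb_next", "logp1", "logp2"]
        assert np.isfinite(hc_log[latent].to_numpy()).all()
        assert hc_log["pmb"].between(0, 1).all()
        assert hc_log["chi_mb"].between(0, 1).all()
        assert hc_log["chi_mf"].between(0, 1).all()

    def test_seeded_simulation_is_reproducible(self, default_design, default_params):
        from arbrl.cohort import simulate_dataset
        import pandas as pd

        a = simulate_dataset(default_params, default_design, seed=9)
        b = simulate_dataset(default_params, default_design, seed=9)
        pd.testing.assert_frame_equal(a, b)


def test_mean_pmb_higher_in_mb_favoured_than_mf_favoured_block():
    """Cohort-mean P_MB is higher under (specific, low) than (universal, high)."""
    from arbrl.cohort import block_summaries, simulate_dataset

    diffs = []
    for s in range(20):
        design = build_design(TaskConfig(), seed=300 + s)
        log = simulate_dataset(AgentParams(), design, seed=400 + s)
        summ = block_summaries(log).set_index("block")
        diffs.append(summ.loc["specific_low", "mean_pmb"] - summ.loc["universal_high", "mean_pmb"])
    assert np.mean(diffs) > 0
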