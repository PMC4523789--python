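"""Tests for the grid-Bayes engine: priors, updates, entropy, selection."""

import numpy as np
import pytest

from quicksdt.engine import (
    AdaptiveSession,
    LikelihoodTable,
    ParameterGrid,
    Posterior,
    PriorSpec,
    all_expected_entropies,
    build_prior,
    entropy,
    estimate,
    expected_entropy,
    predictive_prob,
    select_stimulus,
    should_stop,
    update,
)
from quicksdt.simulate import observer_from_rates
from quicksdt.tasks import make_task, response_probabilities


def brute_force_likelihood(task, cond, grid):
    """Independent enumeration of likelihood vectors node by node."""
    nodes = grid.node_arrays()
    thetas = np.stack([nodes[n] for n in grid.names], axis=1)
    return np.stack([response_probabilities(task, cond, th) for th in thetas], axis=1)


class TestGridAndPrior:
    def test_simstudy_preset_shape(self):
        grid = ParameterGrid.from_preset("qYN", "simstudy")
        assert grid.shape == (59, 58, 56)
        assert grid.params["tau"][0] == pytest.approx(0.0025)
        assert grid.params["tau"][-1] == pytest.approx(1.25)
        assert grid.params["lam"][0] == -1.0 and grid.params["lam"][-1] == 3.0

    def test_four_parameter_layout(self):
        grid = ParameterGrid.from_preset("qYNC", "simstudy-coarse")
        assert grid.names == ("tau", "gamma", "lam_strict", "delta_lam")

    def test_non_increasing_samples_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ParameterGrid({"tau": np.array([0.1, 0.1, 0.2])})

    def test_zero_confidence_limit_is_uniform(self, small_qyn_task, small_grid):
        spec = PriorSpec({n: (small_grid.params[n][1], 0.0) for n in small_grid.names})
        post = build_prior(small_grid, spec)
        assert np.allclose(post.weights, 1.0 / small_grid.n_nodes)

    def test_prior_mode_at_nearest_node(self):
        grid = ParameterGrid({"tau": np.geomspace(0.01, 1.0, 25)})
        post = build_prior(grid, PriorSpec({"tau": (0.10, 1.6)}))
        peak = grid.params["tau"][np.argmax(post.weights)]
        nearest = grid.params["tau"][np.argmin(np.abs(np.log10(grid.params["tau"] / 0.10)))]
        assert peak == nearest

    def test_log_symmetry_of_tau_marginal(self):
        # symmetric log grid around the mode -> symmetric prior mass
        grid = ParameterGrid({"tau": 0.1 * 10.0 ** np.linspace(-1, 1, 11)})
        post = build_prior(grid, PriorSpec({"tau": (0.10, 1.6)}))
        assert np.allclose(post.weights, post.weights[::-1], atol=1e-14)

    def test_mode_outside_grid_rejected(self, small_qyn_task, small_grid):
        spec = PriorSpec({"tau": (0.9, 1.6), "gamma": (2.0, 6.1), "lam": (1.0, 2.1)})
        with pytest.raises(ValueError, match="outside grid range"):
            build_prior(small_grid, spec)


class TestUpdateAndPredictive:
    def test_predictive_degenerate_posterior(self, small_qyn_task, small_grid):
        table = LikelihoodTable(small_qyn_task, small_grid)
        w = np.zeros(small_grid.n_nodes)
        w[13] = 1.0
        post = Posterior(small_grid, w)
        cond = small_qyn_task.conditions[2]
        L = brute_force_likelihood(small_qyn_task, cond, small_grid)
        assert np.allclose(predictive_prob(post, table, cond), L[:, 13])

    def test_predictive_two_node_average(self, small_qyn_task, small_grid):
        table = LikelihoodTable(small_qyn_task, small_grid)
        w = np.zeros(small_grid.n_nodes)
        w[[2, 20]] = 0.5
        post = Posterior(small_grid, w)
        cond = small_qyn_task.conditions[0]
        L = brute_force_likelihood(small_qyn_task, cond, small_grid)
        assert np.allclose(predictive_prob(post, table, cond), 0.5 * (L[:, 2] + L[:, 20]))

    def test_update_matches_brute_force_bayes(self, small_qyn_task, small_grid, small_prior):
        table = LikelihoodTable(small_qyn_task, small_grid)
        post = small_prior
        for cond in small_qyn_task.conditions:
            for resp in small_qyn_task.response_labels:
                L = brute_force_likelihood(small_qyn_task, cond, small_grid)
                j = small_qyn_task.response_index(resp)
                expected = post.weights * L[j] / (post.weights * L[j]).sum()
                got = update(post, table, cond, resp).weights
                assert np.allclose(got, expected, atol=1e-14)
                assert got.sum() == pytest.approx(1.0, abs=1e-10)
                assert np.all(got >= 0) and np.all(np.isfinite(got))

    def test_sequential_updates_commute_with_product_likelihood(
        self, small_qyn_task, small_grid, small_prior
    ):
        table = LikelihoodTable(small_qyn_task, small_grid)
        c1, c2 = small_qyn_task.conditions[1], small_qyn_task.conditions[3]
        two_step = update(update(small_prior, table, c1, "Yes"), table, c2, "No")
        L1 = brute_force_likelihood(small_qyn_task, c1, small_grid)[0]
        L2 = brute_force_likelihood(small_qyn_task, c2, small_grid)[1]
        joint = small_prior.weights * L1 * L2
        assert np.allclose(two_step.weights, joint / joint.sum(), atol=1e-14)

    def test_constant_likelihood_leaves_posterior_unchanged(self, small_grid, small_prior):
        class FlatTable:
            task = make_task("qYN", contrasts=np.array([0.1]))
            L = np.full((1, 2, small_grid.n_nodes), 0.5)

            def condition_index(self, c):
                return 0

        post = update(small_prior, FlatTable(), 0, "Yes")
        assert np.allclose(post.weights, small_prior.weights)


class TestEntropyAndSelection:
    def test_entropy_reference_values(self, small_grid):
        n = small_grid.n_nodes
        assert entropy(Posterior(small_grid, np.ones(n))) == pytest.approx(np.log(n))
        w = np.zeros(n)
        w[0] = 1.0
        assert entropy(Posterior(small_grid, w)) == 0.0
        w2 = np.zeros(n)
        w2[0], w2[1] = 0.9, 0.1
        expected = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))  # 0.3251 nats
        assert entropy(Posterior(small_grid, w2)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3251, abs=1e-4)

    def test_expected_entropy_matches_brute_force(
        self, small_qyn_task, small_grid, small_prior
    ):
        """Oracle equivalence on a 27-node grid and 5 conditions."""
        table = LikelihoodTable(small_qyn_task, small_grid)
        post = small_prior
        # make the posterior uneven first
        post = update(post, table, small_qyn_task.conditions[2], "Yes")
        for cond in small_qyn_task.conditions:
            L = brute_force_likelihood(small_qyn_task, cond, small_grid)
            pred = L @ post.weights
            eh = 0.0
            for r in range(small_qyn_task.n_responses):
                po = post.weights * L[r] / pred[r]
                eh += pred[r] * -(po * np.log(np.maximum(po, 1e-300))).sum()
            assert expected_entropy(post, table, cond) == pytest.approx(eh, abs=1e-10)
            assert expected_entropy(post, table, cond) <= entropy(post) + 1e-12

    def test_selection_matches_exhaustive_argmin(
        self, small_qyn_task, small_grid, small_prior
    ):
        table = LikelihoodTable(small_qyn_task, small_grid)
        post = update(small_prior, table, small_qyn_task.conditions[0], "No")
        scores = [expected_entropy(post, table, c) for c in small_qyn_task.conditions]
        assert select_stimulus(post, table) == small_qyn_task.conditions[int(np.argmin(scores))]
        assert np.allclose(all_expected_entropies(post, table), scores, atol=1e-10)

    def test_single_condition_space(self, small_grid, small_prior):
        task = make_task("qYN", contrasts=np.array([0.1]))
        table = LikelihoodTable(task, small_grid)
        assert select_stimulus(small_prior, table) == task.conditions[0]

    def test_more_informative_likelihood_lowers_expected_entropy(self, small_grid):
        """A likelihood with larger separation across nodes is more informative."""
        task = make_task("qYN", contrasts=np.array([0.1]))
        n = small_grid.n_nodes
        post = Posterior(small_grid, np.ones(n))

        def fake_table(spread):
            p_yes = np.clip(0.5 + spread * np.linspace(-1, 1, n), 0.01, 0.99)
            t = LikelihoodTable(task, small_grid)
            t.L = np.stack([p_yes, 1 - p_yes])[None, :, :]
            t._LlogL = t.L * np.log(t.L)
            return t

        weak = expected_entropy(post, fake_table(0.05), 0)
        strong = expected_entropy(post, fake_table(0.4), 0)
        assert strong < weak

    def test_demo_observer_sampling_band(self):
        """Early qYN selections concentrate in the 5-20% contrast band."""
        task = make_task("qYN", stimulus_preset="demo")
        obs = observer_from_rates("qYN", {"fa": 0.10})
        from quicksdt.simulate import run_session

        session = run_session(task, obs, 20, seed=3, grid_preset="demo")
        contrasts = np.array([t.condition.contrast for t in session.trials])
        assert np.mean((contrasts >= 0.05) & (contrasts <= 0.20)) >= 0.5


class TestEstimateAndStop:
    def test_point_mass_estimate(self, small_grid):
        w = np.zeros(small_grid.n_nodes)
        w[14] = 1.0
        post = Posterior(small_grid, w)
        summ = estimate(post)
        nodes = small_grid.node_arrays()
        for name in small_grid.names:
            assert summ.estimates[name] == pytest.approx(nodes[name][14])
            lo, hi = summ.ci[name]
            assert lo == hi == pytest.approx(nodes[name][14])
        assert summ.entropy == 0.0

    def test_symmetric_two_node_tau_estimate(self):
        grid = ParameterGrid({"tau": np.array([0.01, 0.1, 1.0])})
        w = np.array([0.5, 0.0, 0.5])
        summ = estimate(Posterior(grid, w))
        assert summ.estimates["tau"] == pytest.approx(0.1)  # geometric midpoint

    def test_ci_bounds_bracket_estimate(self, small_qyn_task, small_grid, small_prior):
        summ = estimate(small_prior)
        for name in small_grid.names:
            lo, hi = summ.ci[name]
            assert lo <= hi

    def test_stop_rules(self, small_qyn_task, small_grid):
        session = AdaptiveSession(
            small_qyn_task, grid=small_grid, seed=0, stop_rule=("fixed_trials", 2)
        )
        assert not should_stop(session, ("fixed_trials", 2))
        cond = session.next_condition()
        session.observe(cond, "Yes")
        assert not should_stop(session, ("fixed_trials", 2))
        session.observe(cond, "No")
        assert should_stop(session, ("fixed_trials", 2))
        # zero-width posterior satisfies any ci-width rule
        w = np.zeros(small_grid.n_nodes)
        w[0] = 1.0
        session.posterior = Posterior(small_grid, w)
        assert should_stop(session, ("ci_width", 0.0))
        with pytest.raises(ValueError, match="unknown stop rule"):
            should_stop(session, ("nope", 1))


class TestConsistency:
    def test_long_run_threshold_consistency(self):
        """Median |bias| over 200 x 500-trial qYN sessions stays below 0.25 dB.

        Uses the full-resolution threshold axis (59 log-spaced samples) with
        coarsened nuisance axes: at 500 trials the estimate's accuracy is
        limited by threshold-grid resolution, not by the steepness or
        criterion sampling.
        """
        from quicksdt.simulate import _run_batch, study_prior

        task = make_task("qYN", stimulus_preset="simstudy-coarse")
        grid = ParameterGrid(
            {
                "tau": np.geomspace(0.0025, 1.25, 59),
                "gamma": np.geomspace(0.4, 10.0, 15),
                "lam": np.linspace(-1.0, 3.0, 14),
            }
        )
        obs = observer_from_rates("qYN", {"fa": 0.10})
        batch = _run_batch(
            task, obs, 200, 500, 7, grid, study_prior(task, obs), record_trials=[500]
        )
        bias = 10.0 * np.log10(batch.tau_hat[500] / 0.10)
        assert np.median(np.abs(bias)) < 0.25
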