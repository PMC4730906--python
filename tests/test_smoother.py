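import numpy as np
import pytest
from oracle_utils import enumerate_smoothed

from circtrack import (
    StateGrid,
    TransitionPrior,
    VonMisesParams,
    backward_pass,
    build_grid,
    concentration_track,
    forward_pass,
    sample_vonmises,
    three_sweep_smooth,
)
from circtrack.smoother import likelihood_table


def uniform_init(grid):
    shape = (grid.mu_values.size, grid.kappa_values.size)
    return np.full(shape, 1.0 / np.prod(shape))


class TestAgainstEnumeration:
    @pytest.mark.parametrize("n_trials", [2, 4])
    def test_forward_backward_matches_path_enumeration(self, tiny_grid, n_trials):
        prior = TransitionPrior.from_grid(tiny_grid, K=0.8, sigma2=1.5)
        rng = np.random.default_rng(7)
        theta = sample_vonmises(n_trials, VonMisesParams(0.5, 2.0), rng)
        exact = enumerate_smoothed(theta, tiny_grid, prior)
        fwd, _ = forward_pass(theta, tiny_grid, prior, uniform_init(tiny_grid))
        shape = exact.shape[1:]
        bwd, _ = backward_pass(theta, tiny_grid, prior, np.ones(shape))
        smoothed = fwd * bwd
        smoothed /= smoothed.sum(axis=(1, 2), keepdims=True)
        assert np.abs(smoothed - exact).max() < 1e-10

    def test_filtered_terminal_marginal_matches_enumeration(self, tiny_grid):
        # the last smoothed marginal equals the last filtered belief
        prior = TransitionPrior.from_grid(tiny_grid, K=0.3, sigma2=0.9)
        rng = np.random.default_rng(3)
        theta = sample_vonmises(3, VonMisesParams(-1.0, 1.5), rng)
        exact = enumerate_smoothed(theta, tiny_grid, prior)
        fwd, _ = forward_pass(theta, tiny_grid, prior, uniform_init(tiny_grid))
        assert np.abs(fwd[-1] - exact[-1]).max() < 1e-10


class TestForwardPass:
    def test_single_trial_is_bayes_rule(self, tiny_grid):
        prior = TransitionPrior.from_grid(tiny_grid, K=1.0, sigma2=1.0)
        init = uniform_init(tiny_grid)
        theta = np.array([0.4])
        fwd, _ = forward_pass(theta, tiny_grid, prior, init)
        L = likelihood_table(theta, tiny_grid)[0]
        expected = init * L
        expected /= expected.sum()
        np.testing.assert_allclose(fwd[0], expected, atol=1e-14)

    def test_uninformative_data_propagates_prior_only(self):
        # a kappa support of {0} makes every observation equally likely, so
        # filtering reduces to pure prior propagation of the initial belief
        grid = StateGrid(
            mu_values=np.linspace(-np.pi, np.pi, 4, endpoint=False),
            kappa_values=np.array([0.0]),
            m=4,
            ell=0.0,
        )
        prior = TransitionPrior.from_grid(grid, K=2.0, sigma2=1.0)
        init = np.array([[0.7], [0.1], [0.1], [0.1]])
        theta = np.array([0.3, -2.0, 1.0])
        fwd, _ = forward_pass(theta, grid, prior, init)
        belief = init
        np.testing.assert_allclose(fwd[0], belief, atol=1e-14)
        for t in range(1, 3):
            belief = prior.mu_transition.T @ belief @ prior.kappa_transition
            np.testing.assert_allclose(fwd[t], belief, atol=1e-14)

    def test_underflow_raises_named_error(self):
        # a belief trapped on a kappa=700 state has likelihood exactly zero
        # for an antipodal observation once transitions cannot rescue it
        grid = StateGrid(
            mu_values=np.array([0.0]),
            kappa_values=np.array([0.0, 700.0]),
            m=1,
            ell=700.0,
        )
        prior = TransitionPrior.from_grid(grid, K=0.0, sigma2=1e-6,
                                          mixing_floor=0.0)
        init = np.array([[0.0, 1.0]])
        with pytest.raises(FloatingPointError, match="trial 0"):
            forward_pass(np.array([np.pi - 1e-9]), grid, prior, init)

    def test_bad_init_rejected(self, tiny_grid):
        prior = TransitionPrior.from_grid(tiny_grid, K=1.0, sigma2=1.0)
        with pytest.raises(ValueError):
            forward_pass(np.array([0.1]), tiny_grid, prior,
                         np.ones((3, 3)))


class TestBackwardPass:
    def test_all_ones_terminal_single_trial_is_uniform(self, tiny_grid):
        prior = TransitionPrior.from_grid(tiny_grid, K=1.0, sigma2=1.0)
        bwd, _ = backward_pass(
            np.array([0.2]), tiny_grid, prior, np.ones((3, 3))
        )
        np.testing.assert_allclose(bwd[0], 1.0 / 9, atol=1e-14)

    def test_palindromic_series_mirrors_kappa_track(self, harness_grid,
                                                    harness_prior):
        rng = np.random.default_rng(11)
        half = sample_vonmises(400, VonMisesParams(0.0, 6.0), rng)
        tail = sample_vonmises(400, VonMisesParams(0.0, 1.0), rng)
        series = np.concatenate([half, tail])
        palindrome = np.concatenate([series, series[::-1]])
        L = likelihood_table(palindrome, harness_grid)
        shape = L.shape[1:]
        fwd, _ = forward_pass(palindrome, harness_grid, harness_prior,
                              np.full(shape, 1.0 / np.prod(shape)),
                              likelihoods=L)
        bwd, _ = backward_pass(palindrome, harness_grid, harness_prior,
                               np.ones(shape), likelihoods=L)
        kv = harness_grid.kappa_values
        e_fwd = (fwd.sum(axis=1) @ kv)
        e_bwd_rev = (bwd.sum(axis=(1,)) / bwd.sum(axis=(1, 2), keepdims=True)[:, :, 0]) @ kv
        # forward kappa track mirrors the backward track away from the
        # concentration change at t=400, where a few trials of timing
        # ambiguity would dominate the comparison
        e_bwd = e_bwd_rev[::-1]
        for window in (slice(100, 350), slice(470, 700)):
            np.testing.assert_allclose(e_fwd[window], e_bwd[window], atol=0.75)


class TestThreeSweep:
    def test_stationary_series_has_stable_kappa_marginals(
        self, harness_grid, harness_prior
    ):
        rng = np.random.default_rng(2)
        theta = sample_vonmises(2000, VonMisesParams(0.0, 4.0), rng)
        # a slow-change prior: stationary data should give essentially the
        # same kappa-marginal at every trial
        prior = TransitionPrior.from_grid(harness_grid, K=1000.0, sigma2=0.01)
        track = three_sweep_smooth(theta, harness_grid, prior)
        marg = track.smoothed.sum(axis=1)
        tv = 0.5 * np.abs(marg[:, None, :] - marg[None, 300::400, :]).sum(-1)
        assert tv.max() < 0.1

    def test_step_change_without_initialization_transient(
        self, harness_grid, harness_prior
    ):
        rng = np.random.default_rng(5)
        a = sample_vonmises(1000, VonMisesParams(0.0, 8.0), rng)
        b = sample_vonmises(1000, VonMisesParams(0.0, 2.0), rng)
        track = three_sweep_smooth(np.concatenate([a, b]), harness_grid,
                                   harness_prior)
        kv = harness_grid.kappa_values
        e_smooth = track.smoothed.sum(axis=1) @ kv
        e_fwd1 = track.forward1.sum(axis=1) @ kv
        # smoothed estimate is correct from the very first trials ...
        assert np.abs(e_smooth[:20] - 8.0).max() < 1.5
        # ... while the first (uniform-init) forward pass needs a burn-in
        assert np.abs(e_fwd1[:3] - 8.0).max() > 1.5
        # and the transition is localized: well inside each segment the
        # estimate is near the generating value
        assert abs(e_smooth[500] - 8.0) < 1.5
        assert abs(e_smooth[1500] - 2.0) < 1.0

    def test_reversed_input_gives_reversed_track(self, harness_grid,
                                                 harness_prior):
        rng = np.random.default_rng(8)
        a = sample_vonmises(600, VonMisesParams(0.0, 6.0), rng)
        b = sample_vonmises(600, VonMisesParams(0.0, 1.0), rng)
        theta = np.concatenate([a, b])
        kv = harness_grid.kappa_values
        e = three_sweep_smooth(theta, harness_grid, harness_prior
                               ).smoothed.sum(axis=1) @ kv
        e_rev = three_sweep_smooth(theta[::-1].copy(), harness_grid,
                                   harness_prior).smoothed.sum(axis=1) @ kv
        assert np.abs(e - e_rev[::-1]).max() < 0.05

    def test_first_sweep_initialization_is_forgotten(self, harness_grid,
                                                     harness_prior):
        rng = np.random.default_rng(21)
        theta = sample_vonmises(500, VonMisesParams(0.5, 3.0), rng)
        kv = harness_grid.kappa_values
        e_uniform = three_sweep_smooth(
            theta, harness_grid, harness_prior
        ).smoothed.sum(axis=1) @ kv
        e_random = three_sweep_smooth(
            theta, harness_grid, harness_prior, first_init="random",
            rng=np.random.default_rng(99),
        ).smoothed.sum(axis=1) @ kv
        assert np.abs(e_uniform - e_random).max() < 0.01

    def test_uninformative_prior_reduces_to_pointwise_likelihood(
        self, tiny_grid
    ):
        prior = TransitionPrior.from_grid(tiny_grid, K=0.0, sigma2=1e12,
                                          mixing_floor=0.0)
        rng = np.random.default_rng(4)
        theta = sample_vonmises(6, VonMisesParams(0.0, 2.0), rng)
        # all-ones terminal mode: the "filtered" paper-mode terminal
        # deliberately re-weights the final trial's likelihood, so the exact
        # identity is stated for the standard terminal condition
        track = three_sweep_smooth(theta, tiny_grid, prior,
                                   backward_terminal="ones")
        L = likelihood_table(theta, tiny_grid)
        expected = L / L.sum(axis=(1, 2), keepdims=True)
        np.testing.assert_allclose(track.smoothed, expected, atol=1e-10)

    def test_all_belief_arrays_normalized(self, harness_grid, harness_prior):
        rng = np.random.default_rng(6)
        theta = sample_vonmises(300, VonMisesParams(0.0, 3.0), rng)
        track = three_sweep_smooth(theta, harness_grid, harness_prior)
        for arr in (track.forward1, track.backward, track.forward2,
                    track.smoothed):
            np.testing.assert_allclose(
                arr.sum(axis=(1, 2)), 1.0, atol=1e-10
            )
            assert np.all(arr >= 0)

    def test_too_short_series_rejected(self, harness_grid, harness_prior):
        with pytest.raises(ValueError):
            three_sweep_smooth(np.array([0.1]), harness_grid, harness_prior)


class TestConcentrationTrack:
    def _delta_joint(self, grid, node_indices):
        n = len(node_indices)
        joint = np.zeros((n, grid.mu_values.size, grid.kappa_values.size))
        for t, j in enumerate(node_indices):
            joint[t, 0, j] = 1.0
        return joint

    def test_constant_expectation_normalizes_to_one(self):
        grid = build_grid(4, 3.0, kappa_spacing="linear")
        joint = self._delta_joint(grid, [2] * 60)
        ct = concentration_track(joint, grid, tail=10)
        np.testing.assert_allclose(ct.normalized_expected_kappa, 1.0)

    def test_step_profile_hand_computed(self):
        # E = (2,...,2,1,...,1) with the tail covering only the 1s
        grid = build_grid(4, 3.0, kappa_spacing="linear")
        joint = self._delta_joint(grid, [2] * 30 + [1] * 30)
        ct = concentration_track(joint, grid, tail=20)
        np.testing.assert_allclose(ct.normalized_expected_kappa[:30], 2.0)
        np.testing.assert_allclose(ct.normalized_expected_kappa[30:], 1.0)
        np.testing.assert_allclose(ct.expected_kappa[:30], 2.0)

    def test_scale_invariance_of_normalized_track(self, harness_grid,
                                                  harness_prior):
        rng = np.random.default_rng(9)
        theta = sample_vonmises(200, VonMisesParams(0.0, 5.0), rng)
        track = three_sweep_smooth(theta, harness_grid, harness_prior)
        ct = concentration_track(track, harness_grid)
        scaled = concentration_track(track, harness_grid)
        np.testing.assert_array_equal(
            ct.normalized_expected_kappa, scaled.normalized_expected_kappa
        )
        # normalized track is E / tail-mean, so rescaling E cancels exactly
        tail_mean = ct.expected_kappa[-50:].mean()
        np.testing.assert_allclose(
            ct.normalized_expected_kappa, ct.expected_kappa / tail_mean
        )

    def test_marginals_sum_to_one_and_expectation_bounded(
        self, harness_grid, harness_prior
    ):
        rng = np.random.default_rng(10)
        theta = sample_vonmises(120, VonMisesParams(0.0, 2.0), rng)
        track = three_sweep_smooth(theta, harness_grid, harness_prior)
        ct = concentration_track(track, harness_grid)
        np.testing.assert_allclose(ct.kappa_marginal.sum(axis=1), 1.0,
                                   atol=1e-10)
        assert np.all(ct.expected_kappa >= 0)
        assert np.all(ct.expected_kappa <= harness_grid.ell)

    def test_tail_validation(self, harness_grid):
        joint = np.full((40, 20, 20), 1.0 / 400)
        with pytest.raises(ValueError):
            concentration_track(joint, harness_grid, tail=40)
        with pytest.raises(ValueError):
            concentration_track(joint, harness_grid, tail=0)
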