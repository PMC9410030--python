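import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kinmap as km
from kinmap.msm import estimate
from oracles import T3, fptd_by_path_enumeration, mfpt_by_absorbing_solve


def random_stochastic(n, seed):
    rng = np.random.default_rng(seed)
    M = rng.random((n, n)) + 0.05
    return M / M.sum(axis=1, keepdims=True)


class TestCountTransitions:
    def test_hand_count_alternating(self):
        N, states = km.count_transitions(np.array([0, 1, 0, 1]), lag=1)
        assert states == [0, 1]
        assert N.tolist() == [[0, 2], [1, 0]]

    def test_lag_two_constant_sequence(self):
        N, states = km.count_transitions(np.array([0, 0, 0]), lag=2)
        assert states == [0]
        assert N.tolist() == [[1]]

    def test_unassigned_frames_become_explicit_state(self):
        lab = np.array([0, km.UNASSIGNED, 0, 0])
        N, states = km.count_transitions(lab, lag=1, include_unassigned=True)
        assert km.UNASSIGNED in states
        assert N.sum() == 3
        N2, states2 = km.count_transitions(lab, lag=1, include_unassigned=False)
        assert states2 == [0]
        assert N2.tolist() == [[1]]  # only the (0,0) pair survives
        with pytest.raises(ValueError, match="no usable"):
            km.count_transitions(np.array([0, km.UNASSIGNED, 0]), lag=1,
                                 include_unassigned=False)

    def test_long_sample_recovers_generating_matrix(self):
        spec = km.ChainSpec(2, np.array([[0.8, 0.2], [0.1, 0.9]]),
                            np.array([0.5, 0.5]), 1_000_000, seed=2)
        lab = km.sample_chain(spec)
        N, _ = km.count_transitions(lab, lag=1)
        emp = N / N.sum(axis=1, keepdims=True)
        assert np.max(np.abs(emp - spec.T_true)) < 0.005

    def test_lag_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            km.count_transitions(np.array([0, 1]), lag=2)


class TestTransitionMatrix:
    def test_direct_normalization(self):
        model = km.transition_matrix(np.array([[8, 2], [1, 9]]))
        assert np.allclose(model.T, [[0.8, 0.2], [0.1, 0.9]])

    def test_identity_counts(self):
        model = km.transition_matrix(np.array([[5, 0], [0, 5]]))
        assert np.array_equal(model.T, np.eye(2))

    def test_unvisited_state_dropped_with_warning(self):
        N = np.array([[3, 7, 0], [2, 8, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="dropping"):
            model = km.transition_matrix(N)
        assert model.n_states == 2
        assert np.allclose(model.T[0], [0.3, 0.7])

    def test_all_rows_empty_rejected(self):
        with pytest.raises(ValueError):
            km.transition_matrix(np.zeros((2, 2), dtype=int))


class TestEquilibriumPopulation:
    def test_trivial_single_state(self):
        m = km.TransitionModel.from_stochastic(np.array([[1.0]]))
        assert km.equilibrium_population(m).tolist() == [1.0]

    def test_two_state_detailed_balance_hand_solve(self):
        m = km.TransitionModel.from_stochastic([[0.8, 0.2], [0.1, 0.9]])
        assert np.allclose(km.equilibrium_population(m), [1 / 3, 2 / 3])

    def test_doubly_stochastic_gives_uniform(self):
        T = np.array([[0.5, 0.3, 0.2], [0.3, 0.5, 0.2], [0.2, 0.2, 0.6]])
        m = km.TransitionModel.from_stochastic(T)
        assert np.allclose(km.equilibrium_population(m), 1 / 3)

    def test_reducible_matrix_reports_blocks(self):
        m = km.TransitionModel.from_stochastic(np.eye(2))
        with pytest.raises(ValueError, match="reducible"):
            km.equilibrium_population(m)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_fixed_point_property(self, seed):
        T = random_stochastic(4, seed)
        m = km.TransitionModel.from_stochastic(T)
        pi = km.equilibrium_population(m)
        assert np.max(np.abs(pi @ T - pi)) < 1e-10


class TestMFPT:
    def test_geometric_two_state(self):
        m = km.TransitionModel.from_stochastic([[0.9, 0.1], [0.0, 1.0]])
        assert km.mfpt(m, 1)[0] == pytest.approx(10.0, abs=1e-12)

    def test_deterministic_hop(self):
        m = km.TransitionModel.from_stochastic([[0.0, 1.0], [1.0, 0.0]])
        assert km.mfpt(m, 1)[0] == pytest.approx(1.0)

    def test_target_entry_is_zero(self):
        m = km.TransitionModel.from_stochastic([[0.9, 0.1], [0.5, 0.5]])
        assert km.mfpt(m, 1)[1] == 0.0

    def test_physical_time_scaling(self):
        m = km.TransitionModel.from_stochastic([[0.9, 0.1], [0.0, 1.0]],
                                               lag=5, frame_interval=0.01)
        assert km.mfpt(m, 1)[0] == pytest.approx(10.0 * 5 * 0.01)

    def test_unreachable_target_reported(self):
        m = km.TransitionModel.from_stochastic([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="unreachable"):
            km.mfpt(m, 1)

    def test_linear_solve_matches_fptd_summation(self):
        T = random_stochastic(5, seed=31)
        m = km.TransitionModel.from_stochastic(T)
        for target in range(5):
            F = km.mfpt(m, target)
            for src in range(5):
                if src == target:
                    continue
                d = km.fpt_distribution(m, src, target, n_max=2000)
                direct = float(d.steps @ d.probabilities)
                assert abs(F[src] - direct) <= d.tail_mass * 2000 + 1e-9
                assert F[src] == pytest.approx(d.mean, rel=1e-9)


class TestFPTDistribution:
    def test_first_step_probability_equals_matrix_entry(self):
        T = random_stochastic(4, seed=8)
        m = km.TransitionModel.from_stochastic(T)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                d = km.fpt_distribution(m, i, j, n_max=3)
                assert d.probabilities[0] == T[i, j]

    def test_two_state_geometric_closed_form(self):
        m = km.TransitionModel.from_stochastic([[0.9, 0.1], [0.0, 1.0]])
        d = km.fpt_distribution(m, 0, 1, n_max=50)
        geo = 0.9 ** np.arange(50) * 0.1
        assert np.max(np.abs(d.probabilities - geo)) < 1e-15

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recursion_matches_path_enumeration(self, seed):
        T = random_stochastic(3, seed)
        m = km.TransitionModel.from_stochastic(T)
        d = km.fpt_distribution(m, 0, 2, n_max=6)
        for n in range(1, 7):
            brute = fptd_by_path_enumeration(T, 0, 2, n)
            assert d.probabilities[n - 1] == pytest.approx(brute, abs=1e-12)

    def test_normalization_with_tail(self):
        T = random_stochastic(4, seed=5)
        m = km.TransitionModel.from_stochastic(T)
        d = km.fpt_distribution(m, 0, 3, n_max=200)
        assert d.probabilities.sum() + d.tail_mass == pytest.approx(1.0, abs=1e-9)

    def test_tail_mass_monotone_nonincreasing_in_nmax(self):
        T = random_stochastic(4, seed=6)
        m = km.TransitionModel.from_stochastic(T)
        tails = [km.fpt_distribution(m, 0, 3, n_max=n).tail_mass
                 for n in (10, 50, 200, 1000)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        assert tails[-1] < 1e-6


class TestEstimatorConsistency:
    def test_estimated_model_mfpt_converges_to_generative(self):
        spec = km.ChainSpec(3, T3, np.ones(3) / 3, 1_000_000, seed=23)
        lab = km.sample_chain(spec)
        model = estimate(lab, lag=1)
        exact_model = km.TransitionModel.from_stochastic(T3)
        for target in range(3):
            est = km.mfpt(model, target)
            exact = km.mfpt(exact_model, target)
            mask = np.arange(3) != target
            assert np.all(np.abs(est[mask] / exact[mask] - 1) < 0.05)

    def test_mfpt_matches_independent_absorbing_solve(self):
        T = random_stochastic(5, seed=77)
        m = km.TransitionModel.from_stochastic(T)
        for target in range(5):
            F = km.mfpt(m, target)
            for src in range(5):
                if src != target:
                    assert F[src] == pytest.approx(
                        mfpt_by_absorbing_solve(T, src, target))
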