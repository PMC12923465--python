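"""Exact Ising mathematics: energies, conditionals, enumeration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import isingscape as isc
from isingscape.core import all_energies, enumerate_microstates


def three_node_net():
    # m = (-1, -1, 0), single edge w_12 = 1
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    return isc.IsingNetwork(
        labels=("a", "b", "c"), thresholds=np.array([-1.0, -1.0, 0.0]), weights=w
    )


class TestHamiltonian:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ([0, 0, 0], 0.0),  # empty state carries zero energy
            ([1, 1, 0], 1.0),  # -w_12 - (m_1 + m_2) = -1 + 2
            ([1, 0, 0], 1.0),  # -m_1
        ],
    )
    def test_worked_values(self, state, expected):
        assert isc.hamiltonian(three_node_net(), state) == pytest.approx(expected)

    def test_quadratic_form_equals_pairwise_sum(self, make_random_net):
        net = make_random_net(6, seed=3)
        for state in enumerate_microstates(6)[:: 7]:
            pairwise = -sum(
                net.weights[i, j] * state[i] * state[j]
                for i in range(6)
                for j in range(i + 1, 6)
            ) - state @ net.thresholds
            assert isc.hamiltonian(net, state) == pytest.approx(pairwise, abs=1e-12)

    @given(k=st.floats(-3, 3, allow_nan=False))
    def test_energy_linear_in_parameter_scale(self, k):
        net = isc.random_network(4, seed=9)
        scaled = isc.scale_parameters(net, k, k)
        for state in enumerate_microstates(4):
            assert isc.hamiltonian(scaled, state) == pytest.approx(
                k * isc.hamiltonian(net, state), abs=1e-9
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            isc.hamiltonian(three_node_net(), [1, 0])

    def test_non_binary_state_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            isc.hamiltonian(three_node_net(), [0.5, 0, 0])


class TestConditionalActivation:
    def test_zero_field_is_half(self):
        net = isc.IsingNetwork(
            labels=("a", "b"), thresholds=np.zeros(2), weights=np.zeros((2, 2))
        )
        assert isc.conditional_activation_probability(net, [0, 0], 0) == 0.5

    def test_threshold_plus_active_neighbour(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        net = isc.IsingNetwork(
            labels=("a", "b"), thresholds=np.array([1.0, 0.0]), weights=w
        )
        # logistic(1 + 1) with beta = 1
        assert isc.conditional_activation_probability(net, [0, 1], 0) == pytest.approx(
            0.8807970779778823, abs=1e-12
        )

    def test_beta_scales_the_field(self):
        net = isc.IsingNetwork(
            labels=("a",), thresholds=np.array([0.5]), weights=np.zeros((1, 1)),
            beta=2.0,
        )
        # logistic(2 * 0.5)
        assert isc.conditional_activation_probability(net, [0], 0) == pytest.approx(
            0.7310585786300049, abs=1e-12
        )

    def test_independent_of_own_state(self, make_random_net):
        net = make_random_net(5, seed=21)
        for state in enumerate_microstates(5)[:: 3]:
            for i in range(5):
                up, down = state.copy(), state.copy()
                up[i], down[i] = 1, 0
                assert isc.conditional_activation_probability(
                    net, up, i
                ) == pytest.approx(
                    isc.conditional_activation_probability(net, down, i), abs=1e-15
                )

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            isc.conditional_activation_probability(three_node_net(), [0, 0, 0], 3)


class TestMicrostateDistribution:
    def test_all_energies_zero_gives_uniform(self, toy_independent_net):
        dist = isc.microstate_distribution(toy_independent_net)
        np.testing.assert_allclose(dist.probabilities, 0.25, atol=1e-15)

    def test_single_edge_hand_enumeration(self, toy_coupled_net):
        dist = isc.microstate_distribution(toy_coupled_net)
        np.testing.assert_allclose(
            dist.probabilities, [0.2, 0.2, 0.2, 0.4], atol=1e-12
        )

    def test_normalization_and_boltzmann_ratios(self, make_random_net):
        net = make_random_net(5, seed=4)
        dist = isc.microstate_distribution(net)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(dist.probabilities >= 0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j = rng.integers(0, 32, size=2)
            ratio = dist.probabilities[i] / dist.probabilities[j]
            expected = np.exp(-net.beta * (dist.energies[i] - dist.energies[j]))
            assert ratio == pytest.approx(expected, rel=1e-10)

    def test_gibbs_full_conditional_consistency(self, make_random_net):
        """Conditional activation probabilities agree with the enumerated joint."""
        for seed in (0, 1, 2):
            n = 4 + seed
            net = make_random_net(n, seed=seed)
            dist = isc.microstate_distribution(net)
            for idx in range(2**n):
                state = np.array([(idx >> k) & 1 for k in range(n)], dtype=float)
                for i in range(n):
                    p_up = dist.probabilities[idx | (1 << i)]
                    p_down = dist.probabilities[idx & ~(1 << i)]
                    expected = p_up / (p_up + p_down)
                    got = isc.conditional_activation_probability(net, state, i)
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_permutation_equivariance(self, make_random_net):
        net = make_random_net(5, seed=13)
        perm = np.array([3, 0, 4, 1, 2])
        permuted = isc.IsingNetwork(
            labels=tuple(net.labels[k] for k in perm),
            thresholds=net.thresholds[perm],
            weights=net.weights[np.ix_(perm, perm)],
            beta=net.beta,
        )
        dist = isc.microstate_distribution(net)
        dist_p = isc.microstate_distribution(permuted)
        for idx in range(32):
            bits = [(idx >> k) & 1 for k in range(5)]
            # state of permuted node k equals state of original node perm[k]
            idx_orig = sum(bits[k] << perm[k] for k in range(5))
            assert dist_p.probabilities[idx] == pytest.approx(
                dist.probabilities[idx_orig], rel=1e-12
            )

    def test_enumeration_guard(self):
        n = isc.ENUMERATION_GUARD + 1
        net = isc.IsingNetwork(
            labels=tuple(f"s{i}" for i in range(n)),
            thresholds=np.zeros(n),
            weights=np.zeros((n, n)),
        )
        with pytest.raises(isc.EnumerationInfeasibleError, match="simulate"):
            isc.microstate_distribution(net)

    def test_large_energies_do_not_overflow(self):
        net = isc.IsingNetwork(
            labels=("a", "b"),
            thresholds=np.array([500.0, -500.0]),
            weights=np.zeros((2, 2)),
        )
        dist = isc.microstate_distribution(net)
        assert np.all(np.isfinite(dist.probabilities))
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestScaleParameters:
    def test_identity(self, make_random_net):
        net = make_random_net(4, seed=7)
        assert isc.scale_parameters(net, 1.0, 1.0) == net

    def test_multipliers_apply_separately(self, make_random_net):
        net = make_random_net(4, seed=7)
        scaled = isc.scale_parameters(net, 1.2, 0.8)
        np.testing.assert_allclose(scaled.thresholds, 1.2 * net.thresholds)
        np.testing.assert_allclose(scaled.weights, 0.8 * net.weights)
        assert scaled.beta == net.beta

    def test_input_unmodified(self, make_random_net):
        net = make_random_net(4, seed=7)
        before = net.weights.copy()
        isc.scale_parameters(net, 0.0, 0.0)
        np.testing.assert_array_equal(net.weights, before)

    def test_nonfinite_multiplier_rejected(self, make_random_net):
        with pytest.raises(ValueError):
            isc.scale_parameters(make_random_net(3, seed=0), np.inf, 1.0)


class TestCountMicrostates:
    @pytest.mark.parametrize(
        "n_nodes, n_active, expected",
        [(5, 2, 10), (7, 0, 1), (9, 5, 126), (9, 9, 1)],
    )
    def test_values(self, n_nodes, n_active, expected):
        assert isc.count_microstates(n_nodes, n_active) == expected

    @given(n=st.integers(1, 12))
    def test_counts_partition_all_microstates(self, n):
        assert sum(isc.count_microstates(n, k) for k in range(n + 1)) == 2**n

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            isc.count_microstates(5, 6)
        with pytest.raises(ValueError):
            isc.count_microstates(5, -1)


class TestNetworkValidation:
    def test_asymmetric_beyond_tolerance_rejected(self):
        w = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            isc.IsingNetwork(labels=("a", "b"), thresholds=np.zeros(2), weights=w)

    def test_asymmetric_within_tolerance_symmetrized(self):
        w = np.array([[0.0, 0.5], [0.5 + 1e-10, 0.0]])
        with pytest.warns(UserWarning, match="symmetrized"):
            net = isc.IsingNetwork(
                labels=("a", "b"), thresholds=np.zeros(2), weights=w
            )
        assert net.weights[0, 1] == net.weights[1, 0]

    def test_self_loop_rejected(self):
        w = np.array([[0.1, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            isc.IsingNetwork(labels=("a", "b"), thresholds=np.zeros(2), weights=w)

    @pytest.mark.parametrize("beta", [0.0, -1.0, np.nan])
    def test_bad_beta_rejected(self, beta):
        with pytest.raises(ValueError, match="beta"):
            isc.IsingNetwork(
                labels=("a",), thresholds=np.zeros(1), weights=np.zeros((1, 1)),
                beta=beta,
            )

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            isc.IsingNetwork(
                labels=("a",), thresholds=np.array([np.inf]),
                weights=np.zeros((1, 1)),
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            isc.IsingNetwork(
                labels=("a", "b"), thresholds=np.zeros(3), weights=np.zeros((2, 2))
            )

    def test_energies_match_hamiltonian_on_enumeration(self, make_random_net):
        net = make_random_net(4, seed=5)
        energies = all_energies(net)
        states = enumerate_microstates(4)
        for idx in range(16):
            assert energies[idx] == pytest.approx(
                isc.hamiltonian(net, states[idx]), abs=1e-12
            )
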