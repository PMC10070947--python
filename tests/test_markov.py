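import numpy as np
import pytest

import vatmarkov as vm
from vatmarkov.phenotypes import Pattern


BIT_SCHEME = vm.PhenotypeScheme("bit", (Pattern("off", {"A": 0}),
                                        Pattern("on", {"A": 1})))


def bit_model(single_bit, noise, seed=0, **kw):
    proto = vm.SimulationProtocol(noise=noise, seed=seed, **kw)
    system = vm.AttractorSystem(single_bit)
    return vm.estimate_markov(single_bit, None, system, BIT_SCHEME, proto)


class TestNoisyStep:
    def test_zero_noise_equals_step(self, toggle):
        rng = np.random.default_rng(0)
        for s in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            assert vm.noisy_step(toggle, s, noise=0.0, rng=rng) == \
                vm.step(toggle, s)

    def test_flip_fraction_converges_to_noise(self, single_bit):
        q = 0.08
        rng = np.random.default_rng(42)
        n, flips = 20000, 0
        s = (0,)
        for _ in range(n):
            out = vm.noisy_step(single_bit, s, noise=q, rng=rng)
            flips += out != s
            s = out
        se = np.sqrt(q * (1 - q) / n)
        assert abs(flips / n - q) < 3 * se

    def test_clamped_node_never_flips(self, toggle):
        rng = np.random.default_rng(1)
        for _ in range(200):
            out = vm.noisy_step(toggle, (0, 0), clamp={"A": 1},
                                noise=0.5, rng=rng)
            assert out[0] == 1

    def test_invalid_noise_rejected(self, single_bit):
        with pytest.raises(ValueError):
            vm.noisy_step(single_bit, (0,), noise=1.0)


class TestEstimateMarkov:
    @pytest.mark.parametrize("q", vm.NOISE_LEVELS)
    def test_single_bit_chain_recovers_analytic_matrix(self, single_bit, q):
        m = bit_model(single_bit, q, seed=123,
                      steps=2000, iterations=10, rounds=3)
        n_per_row = m.counts.sum(axis=1).min()
        se = np.sqrt(q * (1 - q) / n_per_row)
        expected = np.array([[1 - q, q], [q, 1 - q]])
        assert np.all(np.abs(m.P - expected) < 3 * se)

    def test_zero_noise_gives_identity(self, single_bit):
        m = bit_model(single_bit, 0.0, steps=200, iterations=3, rounds=2)
        assert np.array_equal(m.P, np.eye(2))

    def test_labels_sharing_phenotype_merge_to_one_state(self, single_bit):
        one = vm.PhenotypeScheme("one", (Pattern("any", {}),))
        proto = vm.SimulationProtocol(noise=0.1, steps=100, iterations=2,
                                      rounds=2, seed=0)
        system = vm.AttractorSystem(single_bit)
        m = vm.estimate_markov(single_bit, None, system, one, proto)
        assert m.labels == ("any",)
        assert m.P.shape == (1, 1) and m.P[0, 0] == 1.0

    def test_seed_reproducibility_bit_identical_counts(self, single_bit):
        m1 = bit_model(single_bit, 0.08, seed=7, steps=500, iterations=4,
                       rounds=3)
        m2 = bit_model(single_bit, 0.08, seed=7, steps=500, iterations=4,
                       rounds=3)
        assert np.array_equal(m1.counts, m2.counts)
        assert np.array_equal(m1.P, m2.P)
        m3 = bit_model(single_bit, 0.08, seed=8, steps=500, iterations=4,
                       rounds=3)
        assert not np.array_equal(m1.counts, m3.counts)

    def test_rows_stochastic(self, toggle):
        scheme = vm.PhenotypeScheme(
            "t", (Pattern("a", {"A": 1, "B": 0}), Pattern("b", {"A": 0, "B": 1})))
        proto = vm.SimulationProtocol(noise=0.08, steps=500, iterations=5,
                                      rounds=3, seed=0)
        system = vm.AttractorSystem(toggle)
        m = vm.estimate_markov(toggle, None, system, scheme, proto)
        assert np.allclose(m.P.sum(axis=1), 1.0, atol=1e-12)
        for P in m.per_round_P:
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_noise_free_trajectories_have_constant_labels(self, toggle):
        # with noise=0 every trajectory stays in its attractor: off-diagonal
        # counts are exactly zero
        scheme = vm.PhenotypeScheme(
            "t", (Pattern("a", {"A": 1, "B": 0}), Pattern("b", {"A": 0, "B": 1})))
        proto = vm.SimulationProtocol(noise=0.0, steps=300, iterations=3,
                                      rounds=2, seed=0)
        m = vm.estimate_markov(toggle, None, vm.AttractorSystem(toggle),
                               scheme, proto)
        off_diag = m.counts - np.diag(np.diag(m.counts))
        assert not off_diag.any()

    def test_error_when_no_phenotype_labeled(self, single_bit):
        never = vm.PhenotypeScheme("x", (Pattern("ghost", {"A": 2}),))
        with pytest.raises(ValueError, match="phenotype"):
            vm.estimate_markov(single_bit, None,
                               vm.AttractorSystem(single_bit), never,
                               vm.SimulationProtocol(steps=10, iterations=1,
                                                     rounds=1, seed=0))

    def test_csv_round_trip(self, single_bit):
        m = bit_model(single_bit, 0.08, steps=200, iterations=2, rounds=2)
        again = vm.MarkovModel.from_csv(m.to_csv())
        assert again.labels == m.labels
        assert np.allclose(again.P, m.P)


class TestEvolve:
    def test_identity_preserves_distribution(self):
        m = vm.MarkovModel(("a", "b"), np.zeros((2, 2)), np.eye(2))
        r = vm.evolve(m, [0.3, 0.7], 17)
        assert np.allclose(r.pi, [0.3, 0.7])

    def test_worked_two_state_chain_limit(self):
        P = [[0.9, 0.1], [0.2, 0.8]]
        r = vm.evolve(P, [1.0, 0.0], 500)
        assert np.allclose(r.pi, [2 / 3, 1 / 3], atol=1e-9)

    def test_one_step_equals_matrix_vector_product(self):
        rng = np.random.default_rng(0)
        P = rng.dirichlet(np.ones(4), size=4)
        x0 = rng.dirichlet(np.ones(4))
        r = vm.evolve(P, x0, 1)
        assert np.allclose(r.pi, P.T @ x0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vm.evolve(np.eye(2), [1.0, 0.0, 0.0], 1)


class TestStationary:
    def test_worked_chain_from_any_start(self):
        P = [[0.9, 0.1], [0.2, 0.8]]
        for x0 in ([1, 0], [0, 1], [0.5, 0.5]):
            r = vm.stationary(P, x0=np.array(x0, dtype=float))
            assert np.allclose(r.pi, [2 / 3, 1 / 3], atol=1e-9)
            assert r.unique

    def test_pi_is_left_eigenvector(self):
        rng = np.random.default_rng(5)
        P = rng.dirichlet(np.ones(5), size=5)
        r = vm.stationary(P)
        assert np.abs(r.pi @ P - r.pi).sum() < 1e-8

    def test_symmetric_bit_chain_is_uniform(self):
        for q in vm.NOISE_LEVELS:
            P = [[1 - q, q], [q, 1 - q]]
            assert np.allclose(vm.stationary(P).pi, [0.5, 0.5], atol=1e-9)

    def test_reducible_chain_depends_on_x0_and_is_flagged(self):
        P = np.eye(2)
        r1 = vm.stationary(P, x0=np.array([1.0, 0.0]))
        r2 = vm.stationary(P, x0=np.array([0.0, 1.0]))
        assert not r1.unique and not r2.unique
        assert not np.allclose(r1.pi, r2.pi)

    def test_periodic_chain_raises_then_cesaro_converges(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(RuntimeError, match="[Cc]esaro"):
            vm.stationary(P, x0=np.array([1.0, 0.0]), max_t=1000)
        r = vm.stationary(P, x0=np.array([1.0, 0.0]), cesaro=True, tol=1e-6)
        assert np.allclose(r.pi, [0.5, 0.5], atol=1e-5)


class TestAverageDistributions:
    def _d(self, pi):
        return vm.DistributionResult(("a", "b"), np.asarray(pi, dtype=float))

    def test_average_of_identical_is_identity(self):
        d = self._d([0.25, 0.75])
        assert np.allclose(vm.average_distributions([d, d, d]).pi, d.pi)

    def test_uniform_average_of_point_masses(self):
        out = vm.average_distributions([self._d([1, 0]), self._d([0, 1])])
        assert np.allclose(out.pi, [0.5, 0.5])

    def test_degenerate_weights_select_first(self):
        out = vm.average_distributions([self._d([1, 0]), self._d([0, 1])],
                                       weights=[1.0, 0.0])
        assert np.allclose(out.pi, [1.0, 0.0])

    def test_mismatched_labels_rejected(self):
        other = vm.DistributionResult(("x", "y"), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            vm.average_distributions([self._d([1, 0]), other])
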