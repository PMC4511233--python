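import numpy as np
import pytest
from scipy import integrate

from signedgroups import (
    Partition,
    SignedNetwork,
    block_counts,
    canonicalize,
    log_bayes_factor,
    log_likelihood_mle,
    log_marginal_likelihood,
    mle_rates,
    read_partition,
    restrict_partition,
    write_partition,
)
from .conftest import random_partition, random_signed_network


def block_marginal_by_quadrature(L: int, K: int, Z: int) -> float:
    """Independent oracle: numerically integrate the Bernoulli likelihood
    of one block over uniform priors on its connection and sign rates."""
    val, _ = integrate.dblquad(
        lambda pi, c: c**L * pi**K * (1 - c) ** Z * (1 - pi) ** (L - K),
        0.0, 1.0, 0.0, 1.0,
    )
    return float(np.log(val))


class TestPartition:
    def test_canonicalize_relabels_by_first_appearance(self):
        part = Partition(np.array([3, 1, 3]))
        assert np.array_equal(canonicalize(part).assignment, [1, 2, 1])

    def test_canonicalize_is_idempotent(self):
        part = canonicalize(Partition(np.array([5, 5, 2, 9])))
        assert canonicalize(part) == part

    def test_canonicalize_preserves_score(self):
        rng = np.random.default_rng(31)
        net = random_signed_network(rng, 6)
        part = Partition(rng.choice([2, 5, 9], size=6))
        assert log_marginal_likelihood(net, part) == pytest.approx(
            log_marginal_likelihood(net, canonicalize(part)), abs=1e-12
        )

    def test_restrict_partition_shrinks_groups(self):
        part = Partition(np.array([1, 2, 1, 3]), ("a", "b", "c", "d"))
        restricted = restrict_partition(part, ["a", "c", "d"])
        assert np.array_equal(restricted.assignment, [1, 1, 2])
        assert restricted.species == ("a", "c", "d")

    def test_partition_round_trip(self, tmp_path):
        part = Partition(np.array([1, 2, 1]), ("a", "b", "c"))
        path = tmp_path / "part.tsv"
        write_partition(part, path)
        assert read_partition(path) == part


class TestBlockCounts:
    def test_single_group_hand_count(self, two_species_net):
        counts = block_counts(two_species_net, Partition(np.array([1, 1])))
        assert counts.L[0, 0] == 2 and counts.K[0, 0] == 1 and counts.Z[0, 0] == 2

    def test_all_zero_network(self):
        net = SignedNetwork(("a", "b", "c"), np.zeros((3, 3), dtype=int))
        counts = block_counts(net, Partition(np.array([1, 2, 2])))
        assert np.all(counts.L == 0)
        assert np.array_equal(counts.Z, [[1, 2], [2, 4]])

    def test_three_species_two_groups_hand_count(self, three_species_net):
        counts = block_counts(three_species_net, Partition(np.array([1, 2, 2])))
        assert counts.L[0, 1] == 1 and counts.K[0, 1] == 1 and counts.Z[0, 1] == 1
        assert counts.Z[0, 0] == 1 and counts.Z[1, 0] == 2 and counts.Z[1, 1] == 4

    def test_totals_match_network(self):
        rng = np.random.default_rng(37)
        net = random_signed_network(rng, 9)
        counts = block_counts(net, random_partition(rng, 9, 3))
        assert counts.L.sum() == net.n_links
        assert counts.K.sum() == net.n_positive
        assert counts.Z.sum() == net.n_zeros

    def test_partition_length_mismatch_raises(self, two_species_net):
        with pytest.raises(ValueError, match="describes"):
            block_counts(two_species_net, Partition(np.array([1, 1, 1])))


class TestMleRates:
    def test_half_half(self, two_species_net):
        c, pi = mle_rates(block_counts(two_species_net, Partition(np.array([1, 1]))))
        assert c[0, 0] == pytest.approx(0.5)
        assert pi[0, 0] == pytest.approx(0.5)

    def test_empty_and_saturated_blocks(self):
        empty = SignedNetwork(("a", "b"), np.zeros((2, 2), dtype=int))
        c, pi = mle_rates(block_counts(empty, Partition(np.array([1, 1]))))
        assert c[0, 0] == 0.0 and pi[0, 0] == 0.0
        full = SignedNetwork(("a", "b"), np.ones((2, 2), dtype=int))
        c, pi = mle_rates(block_counts(full, Partition(np.array([1, 1]))))
        assert c[0, 0] == 1.0 and pi[0, 0] == 1.0


class TestMleLikelihood:
    def test_singleton_partition_likelihood_is_one(self):
        rng = np.random.default_rng(41)
        for n in (2, 5, 8):
            net = random_signed_network(rng, n)
            assert log_likelihood_mle(net, Partition(np.arange(1, n + 1))) == pytest.approx(0.0, abs=1e-12)

    def test_two_species_single_group(self, two_species_net):
        # L=2,K=1,Z=2 at c=pi=1/2: (1/2)^6 = 0.015625
        assert log_likelihood_mle(two_species_net, Partition(np.array([1, 1]))) == pytest.approx(
            np.log(0.015625)
        )

    def test_all_zero_network_is_certain(self):
        net = SignedNetwork(("a", "b", "c"), np.zeros((3, 3), dtype=int))
        assert log_likelihood_mle(net, Partition(np.array([1, 1, 1]))) == 0.0

    def test_mle_dominates_grid_rates(self, two_species_net):
        """The closed-form rates maximize the single-block likelihood."""
        counts = block_counts(two_species_net, Partition(np.array([1, 1])))
        L, K, Z = counts.L[0, 0], counts.K[0, 0], counts.Z[0, 0]
        best = log_likelihood_mle(two_species_net, Partition(np.array([1, 1])))
        grid = np.linspace(0.01, 0.99, 25)
        for c in grid:
            for pi in grid:
                ll = L * np.log(c) + K * np.log(pi) + Z * np.log(1 - c) + (L - K) * np.log(1 - pi)
                assert ll <= best + 1e-12

    def test_never_positive(self):
        rng = np.random.default_rng(43)
        net = random_signed_network(rng, 7)
        for _ in range(5):
            assert log_likelihood_mle(net, random_partition(rng, 7, 4)) <= 1e-12


class TestMarginalLikelihood:
    def test_one_species_empty_network(self):
        net = SignedNetwork(("a",), np.zeros((1, 1), dtype=int))
        assert log_marginal_likelihood(net, Partition(np.array([1]))) == pytest.approx(np.log(0.5))

    def test_two_species_closed_form(self, two_species_net):
        # K! Z! (L-K)! / [(1+L)(1+L+Z)!] = 1*2*1 / (3*120) = 1/180
        assert log_marginal_likelihood(two_species_net, Partition(np.array([1, 1]))) == pytest.approx(
            np.log(1 / 180)
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_quadrature_oracle(self, seed):
        """Closed form equals per-block numerical double integration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        net = random_signed_network(rng, n)
        part = random_partition(rng, n, 3)
        counts = block_counts(net, part)
        oracle = sum(
            block_marginal_by_quadrature(int(L), int(K), int(Z))
            for L, K, Z in zip(counts.L.ravel(), counts.K.ravel(), counts.Z.ravel())
        )
        assert log_marginal_likelihood(net, part) == pytest.approx(oracle, rel=1e-8, abs=1e-8)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(47)
        net = random_signed_network(rng, 8)
        transposed = SignedNetwork(net.species, net.signs.T)
        for _ in range(5):
            part = random_partition(rng, 8, 4)
            assert log_marginal_likelihood(net, part) == pytest.approx(
                log_marginal_likelihood(transposed, part), abs=1e-12
            )

    def test_group_label_permutation_invariance(self):
        rng = np.random.default_rng(53)
        net = random_signed_network(rng, 7)
        part = Partition(np.array([1, 2, 3, 1, 2, 3, 1]))
        relabeled = Partition(np.array([3, 1, 2, 3, 1, 2, 3]))
        assert log_marginal_likelihood(net, part) == pytest.approx(
            log_marginal_likelihood(net, relabeled), abs=1e-12
        )

    def test_joint_species_permutation_invariance(self):
        rng = np.random.default_rng(59)
        net = random_signed_network(rng, 7)
        part = random_partition(rng, 7, 3)
        perm = rng.permutation(7)
        permuted = SignedNetwork(
            tuple(net.species[i] for i in perm), net.signs[np.ix_(perm, perm)]
        )
        assert log_marginal_likelihood(net, part) == pytest.approx(
            log_marginal_likelihood(permuted, Partition(part.assignment[perm])), abs=1e-12
        )

    def test_block_diagonal_decomposes_over_blocks(self):
        """With the true 2-block partition, the score is the sum of the
        per-block closed forms (all four ordered blocks)."""
        rng = np.random.default_rng(61)
        a = random_signed_network(rng, 3)
        b = random_signed_network(rng, 3)
        signs = np.zeros((6, 6), dtype=int)
        signs[:3, :3] = a.signs
        signs[3:, 3:] = b.signs
        net = SignedNetwork(tuple("uvwxyz"), signs)
        part = Partition(np.array([1, 1, 1, 2, 2, 2]))
        counts = block_counts(net, part)
        oracle = sum(
            block_marginal_by_quadrature(int(L), int(K), int(Z))
            for L, K, Z in zip(counts.L.ravel(), counts.K.ravel(), counts.Z.ravel())
        )
        assert log_marginal_likelihood(net, part) == pytest.approx(oracle, abs=1e-8)


class TestBayesFactor:
    def test_identical_partitions_give_zero(self, two_species_net):
        part = Partition(np.array([1, 1]))
        assert log_bayes_factor(two_species_net, part, part) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(67)
        net = random_signed_network(rng, 6)
        p1, p2 = random_partition(rng, 6, 3), random_partition(rng, 6, 3)
        assert log_bayes_factor(net, p1, p2) == pytest.approx(
            -log_bayes_factor(net, p2, p1), abs=1e-12
        )

    def test_true_partition_beats_merged_on_planted_contrast(self):
        from signedgroups import PlantedModel, generate

        c = np.array([[0.6, 0.05], [0.05, 0.6]])
        p = np.array([[0.9, 0.5], [0.5, 0.1]])
        net, true = generate(PlantedModel((10, 10), c, p, seed=5))
        merged = Partition(np.ones(20, dtype=int))
        assert log_bayes_factor(net, true, merged) > 0
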