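"""Signed modularity, Louvain, allegiance, consensus, label matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betanet.betaseries import WeightedNetwork
from betanet.community import (
    allegiance_from_partitions,
    canonical_partition,
    consensus_partition,
    group_consensus,
    louvain_partition,
    match_labels,
    modularity_qstar,
    partitions_equal,
    subject_consensus,
)
from betanet.simulate import PlantedModel, generate_connectivity_cohort
from betanet.sweep import normalized_vi

from .conftest import brute_force_qstar, random_signed_network, set_partitions


def block_network(labels, within=1.0, between=-0.2):
    labels = np.asarray(labels, int)
    w = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w=w)


class TestQstar:
    def test_zero_matrix_gives_zero_for_any_partition(self):
        net = WeightedNetwork(w=np.zeros((5, 5)))
        for labels in ([0] * 5, [0, 1, 2, 3, 4], [0, 0, 1, 1, 2]):
            assert modularity_qstar(net, np.array(labels), 1.0) == 0.0

    def test_single_community_nonnegative_matrix_at_gamma_one(self, rng):
        w = np.abs(rng.normal(size=(6, 6)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = WeightedNetwork(w=w)
        assert modularity_qstar(net, np.zeros(6, int), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_all_partitions(self, rng):
        """Every set partition of a 6-node signed network, exact agreement."""
        net = random_signed_network(6, rng)
        for gamma in (0.7, 1.0, 1.9):
            for labels in set_partitions(6):
                lab = np.array(labels)
                assert modularity_qstar(net, lab, gamma) == pytest.approx(
                    brute_force_qstar(net.w, lab, gamma), abs=1e-10
                )

    def test_label_invariance(self, rng):
        net = random_signed_network(8, rng)
        lab = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        perm = np.array([3, 1, 0, 2])
        assert modularity_qstar(net, lab, 1.2) == pytest.approx(
            modularity_qstar(net, perm[lab], 1.2), abs=1e-12
        )

    def test_singletons_nonpositive_for_nonnegative_weights(self, rng):
        w = np.abs(rng.normal(size=(7, 7)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = WeightedNetwork(w=w)
        assert modularity_qstar(net, np.arange(7), 1.0) <= 0.0


class TestLouvain:
    def test_recovers_planted_blocks_noiselessly(self, planted_labels):
        net = block_network(planted_labels)
        mv = louvain_partition(net, gamma=1.0, seed=0)
        assert normalized_vi(mv.partition, planted_labels) == 0.0

    def test_qstar_consistent_with_partition(self, rng):
        net = random_signed_network(12, rng)
        mv = louvain_partition(net, gamma=1.1, seed=5)
        assert mv.qstar == modularity_qstar(net, mv.partition, 1.1)

    def test_beats_random_partitions(self, rng):
        net = random_signed_network(15, rng)
        mv = louvain_partition(net, gamma=1.0, seed=1)
        for _ in range(1000):
            labels = rng.integers(0, 4, size=15)
            assert mv.qstar >= modularity_qstar(net, labels, 1.0) - 1e-12

    def test_single_node_network(self):
        net = WeightedNetwork(w=np.zeros((1, 1)))
        mv = louvain_partition(net, gamma=1.0, seed=0)
        assert mv.partition.tolist() == [0]
        assert np.isfinite(mv.qstar)

    def test_deterministic_given_seed(self, rng):
        net = random_signed_network(20, rng)
        a = louvain_partition(net, 1.0, seed=42)
        b = louvain_partition(net, 1.0, seed=42)
        np.testing.assert_array_equal(a.partition, b.partition)


class TestAllegiance:
    def test_identical_partitions_give_block_indicator(self, planted_labels):
        a = allegiance_from_partitions([planted_labels] * 7)
        expected = (planted_labels[:, None] == planted_labels[None, :]).astype(float)
        np.testing.assert_array_equal(a.p, expected)

    def test_single_node_difference_gives_half(self):
        p1 = np.array([0, 0, 0, 1, 1])
        p2 = np.array([1, 0, 0, 1, 1])  # node 0 switches community
        a = allegiance_from_partitions([p1, p2])
        assert a.p[0, 1] == 0.5 and a.p[0, 3] == 0.5
        assert a.p[1, 2] == 1.0

    def test_diagonal_always_one(self, rng):
        parts = [rng.integers(0, 3, size=9) for _ in range(5)]
        a = allegiance_from_partitions(parts)
        np.testing.assert_array_equal(np.diag(a.p), 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_commutes_with_region_reordering(self, seed):
        rng = np.random.default_rng(seed)
        parts = [rng.integers(0, 3, size=8) for _ in range(4)]
        perm = rng.permutation(8)
        direct = allegiance_from_partitions([p[perm] for p in parts]).p
        reordered = allegiance_from_partitions(parts).p[np.ix_(perm, perm)]
        np.testing.assert_array_equal(direct, reordered)


class TestConsensus:
    def test_perfect_block_allegiance_is_fixed_point(self, planted_labels):
        a = allegiance_from_partitions([planted_labels] * 3)
        cons = consensus_partition(a, tau=0.5, reps=10, seed=0)
        assert partitions_equal(cons, planted_labels)

    def test_tau_zero_equals_clustering_raw_agreement(self, planted_labels):
        a = allegiance_from_partitions([planted_labels] * 3)
        cons = consensus_partition(a, tau=0.0, reps=10, seed=0)
        assert partitions_equal(cons, planted_labels)

    def test_tau_precondition(self, planted_labels):
        a = allegiance_from_partitions([planted_labels])
        with pytest.raises(ValueError):
            consensus_partition(a, tau=1.0)

    def test_noisy_louvain_allegiance_recovers_planted(self, planted_labels):
        m = PlantedModel(
            n_regions=40, partition_a=planted_labels, partition_b=planted_labels,
            rho_within=0.6, rho_between=0.05, sigma_noise=2.0, n_subjects=1, seed=0,
        )
        net = generate_connectivity_cohort(m)["A"][0]
        parts = [louvain_partition(net, 1.0, seed=i).partition for i in range(200)]
        cons = consensus_partition(allegiance_from_partitions(parts), tau=0.5,
                                   reps=20, seed=3)
        assert partitions_equal(cons, planted_labels)


class TestSubjectGroupPipelines:
    def test_single_iteration_consensus_is_that_partition(self, planted_labels):
        net = block_network(planted_labels)
        cons, _ = subject_consensus(net, gamma=1.0, n_iter=1, seed=0)
        single = louvain_partition(net, gamma=1.0, seed=0)
        assert partitions_equal(cons, single.partition)

    def test_stable_across_seeds_on_separated_network(self, planted_labels):
        net = block_network(planted_labels)
        c1, _ = subject_consensus(net, gamma=1.0, n_iter=20, seed=1)
        c2, _ = subject_consensus(net, gamma=1.0, n_iter=20, seed=99)
        assert normalized_vi(c1, c2) == 0.0

    def test_group_consensus_of_identical_subjects(self, planted_labels):
        cons, alleg = group_consensus([planted_labels] * 9, seed=0)
        assert partitions_equal(cons, planted_labels)
        assert alleg.source == "group-subjects"

    def test_one_deviant_subject_leaves_consensus_unchanged(self, planted_labels, rng):
        parts = [planted_labels.copy() for _ in range(32)]
        parts.append(rng.integers(0, 4, size=40))
        cons, _ = group_consensus(parts, seed=1)
        assert partitions_equal(cons, planted_labels)


class TestMatchLabels:
    def test_permuted_copy_matches_exactly(self, planted_labels):
        perm = np.array([2, 3, 0, 1])
        matched = match_labels(planted_labels, perm[planted_labels])
        np.testing.assert_array_equal(matched, planted_labels)

    def test_extra_communities_get_fresh_labels(self):
        ref = np.array([0, 0, 0, 0])
        tgt = np.array([0, 0, 1, 2])
        matched = match_labels(ref, tgt)
        # best-overlap community keeps label 0; others get labels > 0
        assert matched[0] == matched[1] == 0
        assert matched[2] != 0 and matched[3] != 0 and matched[2] != matched[3]

    def test_maximizes_overlap_against_permutation_brute_force(self, rng):
        for _ in range(10):
            ref = rng.integers(0, 4, size=12)
            tgt = rng.integers(0, 4, size=12)
            matched = match_labels(ref, tgt)
            achieved = np.sum(matched == ref)
            best = max(
                np.sum(np.array([perm[t] for t in tgt]) == ref)
                for perm in itertools.permutations(range(4))
            )
            assert achieved == best

    def test_canonical_partition_by_first_appearance(self):
        np.testing.assert_array_equal(
            canonical_partition(np.array([7, 7, 2, 9, 2])), [0, 0, 1, 2, 1]
        )


def test_qstar_matches_igraph_modularity_on_positive_network(rng):
    """For nonnegative weights at gamma = 1, Q* reduces to Newman modularity."""
    igraph = pytest.importorskip("igraph")
    w = np.abs(rng.normal(size=(10, 10)))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    net = WeightedNetwork(w=w)
    labels = rng.integers(0, 3, size=10)
    g = igraph.Graph.Weighted_Adjacency(w.tolist(), mode="undirected")
    expected = g.modularity(labels.tolist(), weights=g.es["weight"])
    assert modularity_qstar(net, labels, 1.0) == pytest.approx(expected, abs=1e-10)
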