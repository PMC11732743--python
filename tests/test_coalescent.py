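"""Coalescent/SMM generator: topology invariants, closed-form moments and
the conditional equilibrium-heterozygosity simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from socialdrift.coalescent import (
    MsatConfig,
    conditional_allele_states,
    drop_smm_mutations,
    expected_he_smm,
    heq_conditional,
    simulate_genealogy,
    simulate_msat_dataset,
)
from socialdrift.dataset import unbiased_gene_diversity


def harmonic(n):
    return sum(1.0 / i for i in range(1, n + 1))


class TestGenealogy:
    def test_two_genes_single_event(self, rng):
        tree = simulate_genealogy(2, rng)
        assert tree.n_nodes == 3
        t = tree.node_time[-1]
        assert t > 0
        assert tree.total_length == pytest.approx(2 * t)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(n=st.integers(2, 30))
    def test_topology_invariants(self, n):
        tree = simulate_genealogy(n, np.random.default_rng(n))
        # n-1 internal coalescence nodes, leaves at depth 0
        assert tree.n_nodes == 2 * n - 1
        assert np.all(tree.node_time[:n] == 0.0)
        assert np.all(tree.branch_length >= 0.0)
        # every non-root node has a parent with a later (or equal) time
        assert np.all(tree.parent[: 2 * n - 2] > np.arange(2 * n - 2))
        assert tree.parent[-1] == -1
        # the root subtends every leaf; each leaf row subtends itself only
        ls = tree.leaf_sets
        assert ls[-1].all()
        assert np.array_equal(ls[:n], np.eye(n, dtype=bool))

    def test_mean_total_length_matches_harmonic_sum(self):
        rng = np.random.default_rng(42)
        tot = np.array([simulate_genealogy(10, rng).total_length for _ in range(4000)])
        expected = harmonic(9)  # 2.829 in 4N units
        assert abs(tot.mean() - expected) < 3 * tot.std(ddof=1) / np.sqrt(tot.size)

    def test_final_two_lineage_phase_has_mean_half(self):
        rng = np.random.default_rng(43)
        durations = []
        for _ in range(4000):
            tree = simulate_genealogy(7, rng)
            durations.append(tree.node_time[-1] - tree.node_time[-2])
        d = np.array(durations)
        assert abs(d.mean() - 0.5) < 3 * d.std(ddof=1) / np.sqrt(d.size)

    def test_rejects_fewer_than_two_genes(self, rng):
        with pytest.raises(ValueError):
            simulate_genealogy(1, rng)


class TestSMMMutations:
    def test_zero_theta_is_monomorphic(self, rng):
        tree = simulate_genealogy(12, rng)
        states = drop_smm_mutations(tree, 0.0, rng)
        assert np.unique(states).size == 1

    def test_negative_theta_rejected(self, rng):
        tree = simulate_genealogy(4, rng)
        with pytest.raises(ValueError):
            drop_smm_mutations(tree, -0.5, rng)

    def test_mutation_count_matches_watterson(self):
        # E[mutations] = theta * sum 1/i = 2 * H_9 ~ 5.66 at n=10, theta=2
        rng = np.random.default_rng(44)
        counts = []
        for _ in range(4000):
            tree = simulate_genealogy(10, rng)
            _, c = drop_smm_mutations(tree, 2.0, rng, return_count=True)
            counts.append(c)
        c = np.array(counts, dtype=float)
        expected = 2.0 * harmonic(9)
        assert abs(c.mean() - expected) < 3 * c.std(ddof=1) / np.sqrt(c.size)

    @pytest.mark.parametrize("theta", [0.5, 2.0, 20.0])
    def test_equilibrium_gene_diversity_closed_form(self, theta):
        rng = np.random.default_rng(int(theta * 10))
        he = []
        for _ in range(2500):
            tree = simulate_genealogy(40, rng)
            states = drop_smm_mutations(tree, theta, rng)
            _, counts = np.unique(states, return_counts=True)
            he.append(unbiased_gene_diversity(counts))
        he = np.array(he)
        expected = expected_he_smm(theta)
        assert abs(he.mean() - expected) < 3 * he.std(ddof=1) / np.sqrt(he.size)

    def test_allele_number_increases_with_theta(self):
        rng = np.random.default_rng(45)
        means = []
        for theta in (0.5, 2.0, 20.0):
            ks = []
            for _ in range(400):
                tree = simulate_genealogy(20, rng)
                ks.append(np.unique(drop_smm_mutations(tree, theta, rng)).size)
            means.append(np.mean(ks))
        assert means[0] < means[1] < means[2]


class TestExpectedHeSMM:
    def test_closed_form_values(self):
        assert expected_he_smm(0.0) == 0.0
        assert expected_he_smm(2.0) == pytest.approx(1 - 1 / np.sqrt(5), abs=1e-12)
        assert expected_he_smm(20.0) == pytest.approx(1 - 1 / np.sqrt(41), abs=1e-12)

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            expected_he_smm(-1.0)


class TestDatasetGenerator:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            MsatConfig(theta=-1, n_loci=10, n_genes=40)
        with pytest.raises(ValueError):
            MsatConfig(theta=1, n_loci=0, n_genes=40)
        with pytest.raises(ValueError):
            MsatConfig(theta=1, n_loci=10, n_genes=1)

    def test_theta_zero_every_locus_monomorphic(self, rng):
        ds = simulate_msat_dataset(MsatConfig(0.0, 8, 20), rng)
        assert all(ds.n_alleles(l) == 1 for l in range(8))

    def test_diploid_pairing_preserves_gene_pool(self, rng):
        ds1 = simulate_msat_dataset(MsatConfig(2.0, 5, 40), np.random.default_rng(9))
        ds2 = simulate_msat_dataset(
            MsatConfig(2.0, 5, 40), np.random.default_rng(9), ploidy=2
        )
        assert ds2.n_individuals == 20 and ds2.ploidy == 2
        for l in range(5):
            assert np.array_equal(np.sort(ds1.genes_at(l)), np.sort(ds2.genes_at(l)))

    def test_grand_mean_he_near_closed_form(self):
        rng = np.random.default_rng(46)
        hes = [
            simulate_msat_dataset(MsatConfig(2.0, 20, 40), rng).mean_he()
            for _ in range(40)
        ]
        assert np.mean(hes) == pytest.approx(expected_he_smm(2.0), abs=0.03)


class TestHeqConditional:
    def test_monomorphic_target_gives_zero(self, rng):
        assert np.all(heq_conditional(12, 1, 50, rng) == 0.0)

    @pytest.mark.parametrize("rule", ["first_passage", "last_exit"])
    def test_all_distinct_target_gives_unit_diversity(self, rule, rng):
        vals = heq_conditional(6, 6, 30, rng, rule=rule)
        assert np.allclose(vals, 1.0)  # n/(n-1) * (1 - 1/n) = 1

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            heq_conditional(10, 11, 5, rng)
        with pytest.raises(ValueError):
            heq_conditional(10, 0, 5, rng)
        with pytest.raises(ValueError):
            heq_conditional(10, 3, 0, rng)
        with pytest.raises(ValueError):
            heq_conditional(10, 3, 5, rng, rule="nonsense")

    @pytest.mark.parametrize("rule", ["first_passage", "last_exit"])
    def test_fast_and_reference_paths_agree(self, rule):
        # same conditional distribution from the compiled kernel and the
        # numpy reference implementation (two-sample KS)
        fast = heq_conditional(20, 4, 700, np.random.default_rng(1), rule=rule)
        slow = heq_conditional(
            20, 4, 700, np.random.default_rng(2), rule=rule, fast=False
        )
        assert sps.ks_2samp(fast, slow).pvalue > 0.005

    def test_rules_bracket_the_stationary_rejection_oracle(self):
        # Oracle: unconditional stationary SMM samples across a theta grid,
        # keeping those with exactly k alleles.  First-passage retains the
        # youngest (most uneven) k-allele configurations and last-exit the
        # homoplasy-equilibrated ones, so their means bracket the oracle.
        rng = np.random.default_rng(47)
        n, k = 30, 4
        oracle = []
        for theta in (0.3, 0.7, 1.2, 2.0):
            for _ in range(900):
                tree = simulate_genealogy(n, rng)
                states = drop_smm_mutations(tree, theta, rng)
                _, counts = np.unique(states, return_counts=True)
                if counts.size == k:
                    oracle.append(unbiased_gene_diversity(counts))
        oracle_mean = np.mean(oracle)
        fp = heq_conditional(n, k, 1500, rng, rule="first_passage").mean()
        le = heq_conditional(n, k, 1500, rng, rule="last_exit").mean()
        assert fp < oracle_mean < le
        assert abs(fp - oracle_mean) < 0.10
        assert abs(le - oracle_mean) < 0.10

    def test_deterministic_under_fixed_seed(self):
        a = heq_conditional(25, 5, 200, np.random.default_rng(99))
        b = heq_conditional(25, 5, 200, np.random.default_rng(99))
        assert np.array_equal(a, b)

    def test_conditional_states_have_requested_allele_number(self, rng):
        for k in (2, 3, 5):
            states = conditional_allele_states(20, k, rng)
            assert np.unique(states).size == k
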