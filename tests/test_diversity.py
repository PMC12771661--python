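"""Rao quadratic entropy, Jost equivalent numbers, pairwise beta partition."""

import numpy as np
import pytest

from raopart.diversity import (
    AbundanceTable,
    alpha_diversity,
    jost_equivalent,
    pairwise_beta,
    pooled_gamma,
    rao_q,
    taxonomic_dissimilarity,
)
from raopart.matrices import DissimilarityMatrix
from raopart.phylo import cophenetic_distances, parse_newick, scale_unit

from conftest import naive_rao


class TestTaxonomicDissimilarity:
    def test_off_diagonal_ones(self):
        dm = taxonomic_dissimilarity(["a", "b", "c"])
        assert np.allclose(dm.values, 1 - np.eye(3))

    def test_single_species(self):
        assert taxonomic_dissimilarity(["a"]).values.shape == (1, 1)
        assert taxonomic_dissimilarity(["a"]).values[0, 0] == 0.0

    def test_trace_and_sum(self):
        dm = taxonomic_dissimilarity([f"s{i}" for i in range(7)])
        assert np.trace(dm.values) == 0.0
        assert dm.values.sum() == 7 * 6


class TestRaoQ:
    def test_equal_abundance_closed_form(self):
        for s in (2, 4, 10):
            d = taxonomic_dissimilarity([f"s{i}" for i in range(s)])
            assert rao_q(np.full(s, 1 / s), d) == pytest.approx(1 - 1 / s)

    def test_single_species_zero(self):
        assert rao_q(np.array([1.0]), taxonomic_dissimilarity(["a"])) == 0.0

    def test_two_species_unit_distance(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert rao_q(np.array([0.5, 0.5]), d) == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rao_q(np.array([0.5, 0.5]), taxonomic_dissimilarity(["a", "b", "c"]))

    def test_gini_simpson_identity_on_random_simplex(self, rng):
        """Rao with unit taxonomic distances equals 1 - sum(p^2)."""
        d = taxonomic_dissimilarity([f"s{i}" for i in range(6)])
        for _ in range(200):
            p = rng.dirichlet(np.ones(6))
            assert rao_q(p, d) == pytest.approx(1 - np.sum(p**2), abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        n = 5
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        p = rng.dirichlet(np.ones(n))
        assert rao_q(p, d) == pytest.approx(naive_rao(p, d), abs=1e-12)


class TestPooledGamma:
    def test_identical_plots_gamma_equals_alpha(self, rng):
        d = taxonomic_dissimilarity([f"s{i}" for i in range(4)])
        p = rng.dirichlet(np.ones(4))
        assert pooled_gamma(p, p, d) == pytest.approx(rao_q(p, d))

    def test_disjoint_single_species_pair(self):
        d = taxonomic_dissimilarity(["a", "b"])
        g = pooled_gamma(np.array([1.0, 0.0]), np.array([0.0, 1.0]), d)
        assert g == pytest.approx(0.5)

    def test_concavity_on_random_pairs(self, rng):
        """Q of the pooled pair is never below the mean of the plot Qs."""
        d = taxonomic_dissimilarity([f"s{i}" for i in range(5)])
        for _ in range(100):
            pa = rng.dirichlet(np.ones(5))
            pb = rng.dirichlet(np.ones(5))
            gamma = pooled_gamma(pa, pb, d)
            assert gamma >= (rao_q(pa, d) + rao_q(pb, d)) / 2 - 1e-12


class TestJostEquivalent:
    @pytest.mark.parametrize("q,expected", [(0.0, 1.0), (0.75, 4.0), (0.5, 2.0)])
    def test_examples(self, q, expected):
        assert jost_equivalent(q) == pytest.approx(expected)

    @pytest.mark.parametrize("q", [1.0, 1.5, -0.1])
    def test_out_of_domain_rejected(self, q):
        with pytest.raises(ValueError):
            jost_equivalent(q)


class TestPairwiseBeta:
    def test_identical_plots_beta_zero(self):
        t = AbundanceTable(["p1", "p2"], ["a", "b"], np.array([[3.0, 1.0], [6.0, 2.0]]))
        for jost in (True, False):
            for norm in (True, False):
                res = pairwise_beta(t, jost=jost, normalized=norm)
                assert res.beta.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_single_species_pair_hand_computed(self):
        # alpha = 0 each, mean alpha = 0 -> alpha_eq = 1; Q_gamma = 0.5 ->
        # gamma_eq = 2; beta_add = 1; beta_norm = 0.5
        t = AbundanceTable(["p1", "p2"], ["a", "b"], np.array([[5.0, 0.0], [0.0, 5.0]]))
        res = pairwise_beta(t)
        assert res.alpha == pytest.approx([0.0, 0.0])
        assert res.gamma_pairs[0, 1] == pytest.approx(0.5)
        assert res.beta_add[0, 1] == pytest.approx(1.0)
        assert res.beta_norm[0, 1] == pytest.approx(0.5)

    def test_matches_naive_per_pair_recomputation(self, random_table):
        """Oracle: re-derive every pair from scratch with explicit loops."""
        res = pairwise_beta(random_table)
        d = taxonomic_dissimilarity(random_table.species)
        P = random_table.relative()
        n = random_table.n_plots
        for i in range(n):
            for j in range(i + 1, n):
                qa = naive_rao(P[i], d.values)
                qb = naive_rao(P[j], d.values)
                qg = naive_rao((P[i] + P[j]) / 2, d.values)
                alpha_eq = 1 / (1 - (qa + qb) / 2)
                gamma_eq = 1 / (1 - qg)
                beta_add = gamma_eq - alpha_eq
                assert res.beta_add[i, j] == pytest.approx(beta_add, abs=1e-12)
                assert res.beta_norm[i, j] == pytest.approx(
                    beta_add / gamma_eq, abs=1e-12
                )

    def test_raw_beta_without_jost(self, random_table):
        res = pairwise_beta(random_table, jost=False)
        d = taxonomic_dissimilarity(random_table.species)
        P = random_table.relative()
        qa = naive_rao(P[0], d.values)
        qb = naive_rao(P[1], d.values)
        qg = naive_rao((P[0] + P[1]) / 2, d.values)
        assert res.beta_add[0, 1] == pytest.approx(qg - (qa + qb) / 2, abs=1e-12)

    def test_beta_norm_bounded(self, random_table):
        res = pairwise_beta(random_table)
        off = res.beta_norm[~np.eye(random_table.n_plots, dtype=bool)]
        assert np.all(off >= 0) and np.all(off < 1)

    def test_species_order_permutation_invariance(self, random_table, rng):
        perm = rng.permutation(random_table.n_species)
        shuffled = AbundanceTable(
            list(random_table.plot_ids),
            [random_table.species[k] for k in perm],
            random_table.values[:, perm],
        )
        r1 = pairwise_beta(random_table)
        r2 = pairwise_beta(shuffled)
        assert np.allclose(r1.alpha, r2.alpha, atol=1e-12)
        assert np.allclose(r1.beta_norm, r2.beta_norm, atol=1e-12)

    def test_needs_two_plots(self):
        t = AbundanceTable(["p1"], ["a"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="2 plots"):
            pairwise_beta(t)


class TestPhylogeneticFacet:
    def test_star_tree_reduces_to_taxonomic(self, rng):
        """Equal tip lengths from the root: scaled cophenetic d == taxonomic d."""
        phy = parse_newick("(a:1,b:1,c:1,d:1);")
        dm = scale_unit(cophenetic_distances(phy))
        t = AbundanceTable(
            ["p1", "p2"], ["a", "b", "c", "d"], rng.gamma(1, 5, (2, 4)) + 0.1
        )
        q_phy = alpha_diversity(t, dm)
        q_tax = alpha_diversity(t)
        assert np.allclose(q_phy.to_numpy(), q_tax.to_numpy(), atol=1e-12)

    def test_unit_scaled_phylo_never_exceeds_taxonomic(self, rng):
        from raopart.synth import simulate_tree

        phy = simulate_tree(8, rng=rng)
        dm = scale_unit(cophenetic_distances(phy))
        t = AbundanceTable(
            ["p1", "p2", "p3"], dm.labels, rng.gamma(1, 5, (3, 8)) + 0.1
        )
        assert np.all(
            alpha_diversity(t, dm).to_numpy() <= alpha_diversity(t).to_numpy() + 1e-12
        )

    def test_missing_species_in_distance_matrix_rejected(self, random_table):
        dm = taxonomic_dissimilarity(random_table.species[:-1])
        with pytest.raises(KeyError, match="absent"):
            alpha_diversity(random_table, dm)


class TestAbundanceTableInvariants:
    def test_negative_cover_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            AbundanceTable(["p"], ["a", "b"], np.array([[1.0, -0.5]]))

    def test_empty_plot_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            AbundanceTable(["p1", "p2"], ["a"], np.array([[1.0], [0.0]]))

    def test_relative_rows_sum_to_one(self, random_table):
        assert np.allclose(random_table.relative().sum(axis=1), 1.0, atol=1e-12)
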