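"""Substitution model, ML distances, neighbor joining, rooting and RF."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_tree_newick

from coevotree.distances import DistanceMatrix, distance_matrix, ml_distance
from coevotree.records import Alignment
from coevotree.substitution import (
    JTT_FREQUENCIES,
    SubstitutionModel,
    discrete_gamma_rates,
)
from coevotree.trees import PhyloTree, nj_tree, rf_distance, root_on_outgroup


def simulate_pair(true_d: float, n_sites: int, model: SubstitutionModel,
                  rng: np.random.Generator) -> tuple[str, str]:
    """Evolve one sequence pair at a known distance under the model itself."""
    cats = rng.integers(0, model.n_categories, size=n_sites)
    rates = model.category_rates[-model.n_categories:][cats]
    a = rng.choice(20, size=n_sites, p=model.frequencies)
    b = a.copy()
    for rate in np.unique(rates):
        sites = np.nonzero(rates == rate)[0]
        P = model.transition_matrix(true_d * rate)
        cum = P.cumsum(axis=1)
        cum[:, -1] = 1.0
        u = rng.random(len(sites))
        b[sites] = (u[:, None] > cum[a[sites]]).sum(axis=1)
    return model.decode(a), model.decode(b)


class TestSubstitutionModel:
    def test_rate_matrix_properties(self):
        m = SubstitutionModel(alpha=1.0)
        assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.isclose(-np.dot(m.frequencies, np.diag(m.Q)), 1.0)
        assert np.isclose(m.frequencies.sum(), 1.0, atol=1e-9)

    def test_transition_matrix_is_stochastic_and_reversible(self):
        m = SubstitutionModel(alpha=0.7)
        P = m.transition_matrix(0.3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        flux = m.frequencies[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_long_time_reaches_stationarity(self):
        m = SubstitutionModel(alpha=1.0)
        P = m.transition_matrix(500.0)
        assert np.allclose(P, np.tile(m.frequencies, (20, 1)), atol=1e-8)

    def test_gamma_category_means_average_to_one(self):
        for alpha in (0.3, 1.0, 1.367, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert np.isclose(rates.mean(), 1.0, atol=1e-10)
            assert (np.diff(rates) > 0).all()

    def test_invariant_fraction_categories(self):
        m = SubstitutionModel(alpha=1.0, n_categories=4, invariant_fraction=0.2)
        assert m.category_rates[0] == 0.0
        assert np.isclose(np.dot(m.category_rates, m.category_weights), 1.0)

    def test_empirical_frequencies(self):
        aln = Alignment([("a", "AAAA-"), ("b", "AARRX")])
        m = SubstitutionModel().with_empirical_frequencies(aln)
        # 6 A's and 2 R's counted; gaps and X excluded
        assert m.frequencies[0] > m.frequencies[1] > 0
        assert np.isclose(m.frequencies.sum(), 1.0)


class TestMLDistance:
    MODEL = SubstitutionModel(alpha=1.0, n_categories=4)

    def test_identical_rows_near_zero(self):
        row = "ACDEFGHIKLMNPQRSTVWY" * 5
        d, saturated = ml_distance(row, row, self.MODEL)
        assert d < 1e-6 and not saturated

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = simulate_pair(0.4, 500, self.MODEL, rng)
        dab, _ = ml_distance(a, b, self.MODEL)
        dba, _ = ml_distance(b, a, self.MODEL)
        assert dab == pytest.approx(dba, abs=1e-5)

    def test_recovery_at_half_substitution_per_site(self):
        rng = np.random.default_rng(2024)
        a, b = simulate_pair(0.5, 10_000, self.MODEL, rng)
        d, _ = ml_distance(a, b, self.MODEL)
        assert d == pytest.approx(0.5, abs=0.05)

    def test_pairwise_deletion_of_gaps_and_x(self):
        a = "AC-EFGHIKL"
        b = "ACDEXGHIKL"
        d, _ = ml_distance(a, b, self.MODEL)
        assert d < 1e-6  # comparable sites are all identical

    def test_zero_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            ml_distance("AC--", "--AC", self.MODEL)

    def test_saturation_flagged(self):
        # wildly divergent short rows: optimum at the cap
        rng = np.random.default_rng(3)
        a = self.MODEL.decode(rng.choice(20, 50, p=self.MODEL.frequencies))
        b = self.MODEL.decode(rng.choice(20, 50, p=self.MODEL.frequencies))
        d, saturated = ml_distance(a, b, self.MODEL, d_max=0.05)
        assert saturated and d == 0.05

    def test_alpha_limit_matches_equal_rates(self):
        """As alpha -> infinity the gamma model collapses to equal rates."""
        rng = np.random.default_rng(7)
        equal = SubstitutionModel(alpha=1e6, n_categories=4)
        single = SubstitutionModel(alpha=1.0, n_categories=1)
        a, b = simulate_pair(0.3, 2_000, single, rng)
        d_equal, _ = ml_distance(a, b, equal)
        d_single, _ = ml_distance(a, b, single)
        assert d_equal == pytest.approx(d_single, abs=1e-3)

    def test_monotone_in_observed_differences(self):
        base = list("ACDEFGHIKLMNPQRSTVWY" * 10)
        distances = []
        work = base[:]
        for i in (0, 20, 40, 60, 80):
            work[i] = "W" if work[i] != "W" else "F"
            d, _ = ml_distance("".join(base), "".join(work), self.MODEL)
            distances.append(d)
        assert all(x < y for x, y in zip(distances, distances[1:]))

    def test_distance_matrix_shape_and_errors(self):
        aln = Alignment([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKV"), ("c", "ACDEFGHIKL")])
        D = distance_matrix(aln, self.MODEL)
        assert D.labels == ["a", "b", "c"]
        assert np.allclose(D.matrix, D.matrix.T)
        assert np.allclose(np.diag(D.matrix), 0.0)
        aln_bad = Alignment([("a", "AC--"), ("b", "--AC"), ("c", "ACAC")])
        with pytest.raises(ValueError, match="'a', 'b'"):
            distance_matrix(aln_bad, self.MODEL)

    def test_matrix_tsv_round_trip(self, tmp_path):
        D = DistanceMatrix(labels=["a", "b"], matrix=np.array([[0.0, 0.3], [0.3, 0.0]]))
        path = tmp_path / "d.tsv"
        D.write_tsv(path)
        back = DistanceMatrix.read_tsv(path)
        assert back.labels == D.labels
        assert np.allclose(back.matrix, D.matrix)


def _patristic_matrix(newick: str) -> DistanceMatrix:
    dt = dendropy.Tree.get(data=newick, schema="newick")
    pdm = dt.phylogenetic_distance_matrix()
    taxa = sorted(dt.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels=labels, matrix=mat)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(labels=["A", "B", "C"],
                           matrix=np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        t = nj_tree(D)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in t._dtree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 5 - 6) / 2)
        assert lengths["B"] == pytest.approx((3 + 6 - 5) / 2)
        assert lengths["C"] == pytest.approx((5 + 6 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        # built from ((A:1,B:2):1,(C:3,D:1):2)
        D = DistanceMatrix(
            labels=list("ABCD"),
            matrix=np.array(
                [[0, 3, 7, 5], [3, 0, 8, 6], [7, 8, 0, 4], [5, 6, 4, 0]], float
            ),
        )
        t = nj_tree(D)
        assert t.bipartitions() == {frozenset({"C", "D"})}
        back = _patristic_matrix(t.to_newick())
        assert np.allclose(back.matrix, D.matrix, atol=1e-6)

    def test_tie_broken_deterministically(self):
        # fully symmetric matrix: every Q value ties
        n = 4
        mat = np.ones((n, n)) - np.eye(n)
        D = DistanceMatrix(labels=["d", "c", "b", "a"], matrix=mat)
        t1 = nj_tree(D)
        t2 = nj_tree(D)
        assert t1.to_newick() == t2.to_newick()
        assert t1.bipartitions() == {frozenset({"c", "d"})}  # smallest pair (a,b) joined

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["a", "b"], matrix=np.zeros((2, 2))))

    @given(st.integers(0, 10_000))
    def test_additive_matrices_recover_generating_tree(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        newick = random_tree_newick(rng, n)
        true_tree = PhyloTree.from_newick(newick)
        D = _patristic_matrix(newick)
        est = nj_tree(D)
        assert est.bipartitions() == true_tree.bipartitions()
        back = _patristic_matrix(est.to_newick())
        assert np.allclose(back.matrix, D.matrix, atol=1e-4)


class TestRooting:
    def test_single_outgroup(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,O:4):1);")
        rooted = root_on_outgroup(t, {"O"})
        assert rooted.rooted
        kids = rooted._dtree.seed_node.child_nodes()
        assert len(kids) == 2
        sides = {frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids}
        assert frozenset({"O"}) in sides
        # midpoint rooting of the stem edge (length 4)
        o_leaf = next(l for l in rooted._dtree.leaf_node_iter() if l.taxon.label == "O")
        assert o_leaf.edge.length == pytest.approx(2.0)

    def test_monophyletic_pair(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,((O1:1,O2:1):2,C:1):1);")
        rooted = root_on_outgroup(t, {"O1", "O2"})
        kids = rooted._dtree.seed_node.child_nodes()
        sides = {frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids}
        assert frozenset({"O1", "O2"}) in sides

    def test_missing_label_rejected(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="not in tree"):
            root_on_outgroup(t, {"Z"})

    def test_non_monophyletic_outgroup_rejected(self):
        t = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.raises(ValueError, match="monophyletic"):
            root_on_outgroup(t, {"A", "B"})


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        a = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = PhyloTree.from_newick("((B:2,A:2):1,(D:2,C:2):1);")
        assert rf_distance(a, b) == 0

    def test_conflicting_quartets(self):
        a = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(a, b) == 2

    def test_leaf_set_mismatch_rejected(self):
        a = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        b = PhyloTree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="leaf sets differ"):
            rf_distance(a, b)

    @given(st.integers(0, 10_000))
    def test_matches_dendropy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        nwk_a = random_tree_newick(rng, n)
        nwk_b = random_tree_newick(rng, n)
        mine = rf_distance(PhyloTree.from_newick(nwk_a), PhyloTree.from_newick(nwk_b))
        tns = dendropy.TaxonNamespace()
        da = dendropy.Tree.get(data=nwk_a, schema="newick", taxon_namespace=tns)
        db = dendropy.Tree.get(data=nwk_b, schema="newick", taxon_namespace=tns)
        da.is_rooted = db.is_rooted = False
        da.encode_bipartitions()
        db.encode_bipartitions()
        assert mine == treecompare.symmetric_difference(da, db)


class TestMonophyly:
    def test_examples(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert t.is_monophyletic({"A", "B"})
        assert not t.is_monophyletic({"A", "C"})
        assert t.is_monophyletic({"A", "B", "C", "D"})
        with pytest.raises(ValueError, match="unknown"):
            t.is_monophyletic({"A", "Z"})
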