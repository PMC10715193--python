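import dendropy
import numpy as np
import pytest
from scipy import stats

from cogscale import (
    DistanceMatrix,
    distance_divergence_association,
    exponent_divergence,
    patristic_phylum_matrix,
    simulate_tree,
)
from cogscale.errors import InsufficientDataError, ValidationError


def brute_force_patristic(tree):
    """Path-walking oracle: tip-to-tip distance via shared ancestors."""
    dists = {}
    for taxon in tree.taxon_namespace:
        node = tree.find_node_with_taxon_label(taxon.label)
        acc, d = {}, 0.0
        while node is not None:
            acc[id(node)] = d
            d += node.edge.length or 0.0
            node = node.parent_node
        dists[taxon.label] = acc
    out = {}
    labels = [t.label for t in tree.taxon_namespace]
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            shared = [
                dists[a][k] + dists[b][k] for k in dists[a] if k in dists[b]
            ]
            out[(a, b)] = min(shared)
    return out


class TestPatristic:
    def test_two_singleton_phyla(self):
        tree = dendropy.Tree.get(data="(A:1.5,B:2.5);", schema="newick")
        dm = patristic_phylum_matrix(tree, {"A": "P1", "B": "P2"})
        assert dm.d[0, 1] == pytest.approx(4.0)

    def test_star_tree_unit_branches(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        dm = patristic_phylum_matrix(tree, {l: l for l in "ABCD"})
        off_diag = dm.d[~np.eye(4, dtype=bool)]
        assert np.allclose(off_diag, 2.0)

    def test_phylum_averaging(self):
        tree = dendropy.Tree.get(
            data="((A:1,B:1):1,(C:1,D:3):1);", schema="newick"
        )
        dm = patristic_phylum_matrix(tree, {"A": "P", "B": "P", "C": "Q", "D": "Q"})
        # pairs: A-C=4, A-D=6, B-C=4, B-D=6 -> mean 5
        i, j = dm.labels.index("P"), dm.labels.index("Q")
        assert dm.d[i, j] == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        newick, _ = simulate_tree([f"P{i}" for i in range(12)], 0.5, seed=4)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        oracle = brute_force_patristic(tree)
        dm = patristic_phylum_matrix(tree, {f"P{i}": f"P{i}" for i in range(12)})
        for (a, b), expected in oracle.items():
            i, j = dm.labels.index(a), dm.labels.index(b)
            assert dm.d[i, j] == pytest.approx(expected, abs=1e-9)

    def test_matrix_invariants(self):
        newick, _ = simulate_tree([f"P{i}" for i in range(8)], 0.0, seed=9)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        dm = patristic_phylum_matrix(tree, {f"P{i}": f"P{i}" for i in range(8)})
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        off = dm.d[~np.eye(8, dtype=bool)]
        assert (off > 0).all()

    def test_missing_branch_lengths(self):
        tree = dendropy.Tree.get(data="(A,B,C);", schema="newick")
        with pytest.raises(ValidationError):
            patristic_phylum_matrix(tree, {"A": "P", "B": "Q", "C": "R"})


class TestDivergence:
    def test_abs_diff_and_quotient(self):
        vm = exponent_divergence({"P": 1.5, "Q": 1.2}, mode="abs_diff")
        assert vm.v[0, 1] == pytest.approx(0.3)
        vq = exponent_divergence({"P": 1.5, "Q": 1.2}, mode="quotient")
        assert vq.v[0, 1] == pytest.approx(1.25)
        assert vq.v[0, 0] == 1.0

    def test_equal_slopes(self):
        vm = exponent_divergence({"P": 1.0, "Q": 1.0}, mode="abs_diff")
        assert vm.v[0, 1] == 0.0
        vq = exponent_divergence({"P": 1.0, "Q": 1.0}, mode="quotient")
        assert vq.v[0, 1] == 1.0

    def test_sign_change_quotient_na(self):
        vq = exponent_divergence({"P": 0.5, "Q": -0.1}, mode="quotient")
        assert np.isnan(vq.v[0, 1])


class TestAssociation:
    def _setup(self, coupling, seed, n=20):
        phyla = [f"P{i}" for i in range(n)]
        newick, offsets = simulate_tree(phyla, coupling, seed=seed)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        dm = patristic_phylum_matrix(tree, {p: p for p in phyla})
        vm = exponent_divergence(offsets, mode="abs_diff")
        return dm, vm

    def test_coupled_tree_gives_strong_spearman(self):
        dm, vm = self._setup(1.0, seed=3)
        stat, n_pairs = distance_divergence_association(dm, vm, "spearman")
        assert stat > 0.5
        assert n_pairs == 190

    def test_decoupled_tree_gives_weak_pearson(self):
        hits = 0
        for seed in range(25):
            dm, vm = self._setup(0.0, seed=seed)
            stat, _ = distance_divergence_association(dm, vm, "pearson")
            hits += abs(stat) < 0.2
        assert hits >= 22

    def test_relabeling_invariance(self, rng):
        dm, vm = self._setup(1.0, seed=6, n=10)
        stat, _ = distance_divergence_association(dm, vm, "spearman")
        perm = list(rng.permutation(list(dm.labels)))
        dm2 = dm.reorder(perm)
        idx = [vm.labels.index(l) for l in perm]
        from cogscale.phylo import DivergenceMatrix

        vm2 = DivergenceMatrix(tuple(perm), vm.mode, vm.v[np.ix_(idx, idx)])
        stat2, _ = distance_divergence_association(dm2, vm2, "spearman")
        assert stat2 == pytest.approx(stat)

    def test_two_phyla_insufficient(self):
        d = DistanceMatrix(("P", "Q"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        vm = exponent_divergence({"P": 1.0, "Q": 1.2})
        with pytest.raises(InsufficientDataError):
            distance_divergence_association(d, vm)

    def test_mantel_permutation_p_value(self):
        dm, vm = self._setup(1.0, seed=3)
        stat, n_pairs, p = distance_divergence_association(
            dm, vm, "spearman", mantel_permutations=99, seed=0
        )
        assert p < 0.05
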