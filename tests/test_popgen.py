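"""Shared-allele distances, neighbor joining and bootstrap support."""

import numpy as np
import pytest

from nirvspipe.core import NirvsLocus
from nirvspipe.popgen import (
    AlleleTable,
    bipartitions,
    bootstrap_tree,
    das_distance,
    das_matrix,
    neighbor_joining,
    patristic_distances,
    subset_tree,
)
from nirvspipe.simulate import simulate_population_alleles


class TestDas:
    def test_identical_profiles(self):
        prof = {"l1": frozenset({"a"}), "l2": frozenset({"b", "c"})}
        assert das_distance(prof, prof) == 0.0

    def test_disjoint_profiles(self):
        a = {"l1": frozenset({"a"}), "l2": frozenset({"b"})}
        b = {"l1": frozenset({"x"}), "l2": frozenset({"y"})}
        assert das_distance(a, b) == 1.0

    def test_half_shared(self):
        a = {"l1": frozenset({"s"}), "l2": frozenset({"p"})}
        b = {"l1": frozenset({"s"}), "l2": frozenset({"q"})}
        assert das_distance(a, b) == pytest.approx(0.5)

    def test_semimetric_properties(self, rng):
        """Symmetry, zero diagonal and [0, 1] range on random profiles."""
        pool = [f"a{i}" for i in range(6)]
        for _ in range(30):
            a = {f"l{j}": frozenset(rng.choice(pool, size=int(rng.integers(1, 4)), replace=False))
                 for j in range(5)}
            b = {f"l{j}": frozenset(rng.choice(pool, size=int(rng.integers(1, 4)), replace=False))
                 for j in range(5)}
            d_ab = das_distance(a, b)
            assert das_distance(b, a) == pytest.approx(d_ab)
            assert das_distance(a, a) == 0.0
            assert 0.0 <= d_ab <= 1.0

    def test_null_allele_shared_absence_counts(self):
        a = {"l1": frozenset({"null"})}
        b = {"l1": frozenset({"null"})}
        assert das_distance(a, b) == 0.0


class TestAlleleTable:
    def test_csv_round_trip(self, tmp_path):
        table, _ = simulate_population_alleles(seed=3)
        path = tmp_path / "alleles.csv"
        table.to_csv(path)
        back = AlleleTable.from_csv(path)
        assert back.populations == table.populations
        assert back.loci == table.loci
        for pop in table.populations:
            for locus in table.loci:
                assert back.alleles(pop, locus) == table.alleles(pop, locus)

    def test_incomplete_population_rejected(self):
        with pytest.raises(ValueError):
            AlleleTable({"p1": {"l1": {"a"}}, "p2": {"l2": {"a"}}})

    def test_empty_allele_set_rejected(self):
        with pytest.raises(ValueError):
            AlleleTable({"p1": {"l1": set()}})


def random_additive_tree(n_taxa, rng):
    """Random topology with branch lengths; returns (distance matrix, labels)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # build a random unrooted tree by sequential taxon attachment, tracked
    # as an explicit edge-weighted graph
    import networkx as nx

    g = nx.Graph()
    g.add_edge(labels[0], labels[1], weight=float(rng.uniform(0.2, 1.0)))
    internal = 0
    for leaf in labels[2:]:
        u, v = list(g.edges())[int(rng.integers(0, g.number_of_edges()))]
        w = g[u][v]["weight"]
        split = float(rng.uniform(0.25, 0.75)) * w
        hub = f"x{internal}"
        internal += 1
        g.remove_edge(u, v)
        g.add_edge(u, hub, weight=split)
        g.add_edge(hub, v, weight=w - split)
        g.add_edge(hub, leaf, weight=float(rng.uniform(0.2, 1.0)))
    dist = np.zeros((n_taxa, n_taxa))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            dist[i, j] = dist[j, i] = lengths[labels[i]][labels[j]]
    return dist, labels


class TestNeighborJoining:
    def test_worked_four_taxon_matrix(self):
        # additive matrix of ((A:1,B:2):1,(C:3,D:4)); AB|CD with internal 1
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(d, labels)
        mat, names = patristic_distances(tree)
        order = [names.index(l) for l in labels]
        assert np.allclose(mat[np.ix_(order, order)], d)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxon_star(self):
        # ultrametric 3-taxon: every leaf 1.5 from the center
        d = np.array([[0, 3, 3], [3, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C"])
        assert sorted(leaf.length for leaf in tree.leaves()) == [1.5, 1.5, 1.5]

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["A", "B"])

    def test_label_permutation_only_permutes_output(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        perm = [2, 0, 3, 1]
        tree = neighbor_joining(d[np.ix_(perm, perm)], [["A", "B", "C", "D"][i] for i in perm])
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_recovers_random_additive_trees(self, rng):
        """Patristic distances of the NJ tree reproduce any additive input."""
        for _ in range(50):
            n = int(rng.integers(4, 9))
            d, labels = random_additive_tree(n, rng)
            tree = neighbor_joining(d, labels)
            mat, names = patristic_distances(tree)
            order = [names.index(l) for l in labels]
            assert np.allclose(mat[np.ix_(order, order)], d, atol=1e-9)

    def test_matches_scikit_bio_on_additive_matrix(self, rng):
        """Independent cross-check against scikit-bio's NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj

        d, labels = random_additive_tree(6, rng)
        ours = neighbor_joining(d, labels)
        theirs = nj(DistanceMatrix(d, labels))
        mat, names = patristic_distances(ours)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    assert mat[i, j] == pytest.approx(
                        theirs.find(a).distance(theirs.find(b)), abs=1e-6
                    )


class TestBootstrap:
    def test_single_locus_all_supports_one(self):
        table = AlleleTable(
            {
                "p1": {"l1": {"a"}},
                "p2": {"l1": {"a", "b"}},
                "p3": {"l1": {"c"}},
                "p4": {"l1": {"c", "d"}},
            }
        )
        tree = bootstrap_tree(table, n_reps=20, seed=0)
        supports = [n.support for n in _internal_nodes(tree)]
        assert supports and all(s == 1.0 for s in supports)

    def test_seeded_run_is_reproducible(self):
        table, _ = simulate_population_alleles(seed=5)
        a = bootstrap_tree(table, n_reps=30, seed=42).newick()
        b = bootstrap_tree(table, n_reps=30, seed=42).newick()
        assert a == b

    def test_two_cluster_design_recovers_split(self):
        table, clusters = simulate_population_alleles(
            cluster_drift=0.95, pop_drift=0.05, null_prob=0.0, seed=11
        )
        tree = bootstrap_tree(table, n_reps=200, seed=7)
        small = min(clusters, key=len)
        support = _support_for(tree, set(small))
        assert support is not None and support >= 0.95

    def test_supports_in_unit_interval(self):
        table, _ = simulate_population_alleles(seed=9)
        tree = bootstrap_tree(table, n_reps=50, seed=1)
        for node in _internal_nodes(tree):
            assert 0.0 <= node.support <= 1.0


def _internal_nodes(tree):
    out = []

    def walk(node, is_root):
        if not node.is_leaf and not is_root and node.support is not None:
            out.append(node)
        for child in node.children:
            walk(child, False)

    walk(tree, True)
    return out


def _support_for(tree, side):
    names = set(tree.leaf_names())
    for node in _internal_nodes(tree):
        below = set(node.leaf_names())
        if below == side or below == names - side:
            return node.support
    return None


class TestSubsetTree:
    def _meta(self, loci_ids):
        out = []
        for i, lid in enumerate(loci_ids):
            family = "Flavivirus" if i % 2 == 0 else "Rhabdovirus"
            out.append(NirvsLocus(lid, "c", i * 100, i * 100 + 50, viral_family=family))
        return out

    def test_filter_matching_all_equals_full_tree(self):
        table, _ = simulate_population_alleles(seed=13)
        meta = self._meta(table.loci)
        full = bootstrap_tree(table, n_reps=25, seed=3).newick()
        same = subset_tree(table, meta, lambda l: True, n_reps=25, seed=3).newick()
        assert full == same

    def test_family_filter_uses_family_loci_only(self):
        table, _ = simulate_population_alleles(seed=13)
        meta = self._meta(table.loci)
        tree = subset_tree(table, meta, lambda l: l.viral_family == "Flavivirus",
                           n_reps=10, seed=3)
        assert set(tree.leaf_names()) == set(table.populations)

    def test_empty_filter_errors(self):
        table, _ = simulate_population_alleles(seed=13)
        meta = self._meta(table.loci)
        with pytest.raises(ValueError):
            subset_tree(table, meta, lambda l: False)

    def test_complementary_filters_partition_loci(self):
        table, _ = simulate_population_alleles(seed=13)
        meta = self._meta(table.loci)
        flavi = [l.locus_id for l in meta if l.viral_family == "Flavivirus"]
        rha = [l.locus_id for l in meta if l.viral_family == "Rhabdovirus"]
        assert sorted(flavi + rha) == sorted(table.loci)
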