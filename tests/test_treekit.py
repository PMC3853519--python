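import itertools
import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from orthomatrix.errors import InvalidInputError
from orthomatrix.treekit import (
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    nj_tree,
    p_distance_matrix,
    read_newick,
    rf_distance,
    tree_splits,
)


def random_additive_tree(n: int, seed: int):
    """Random binary topology with positive lengths and its distance matrix."""
    rng = random.Random(seed)
    labels = [f"L{i:02d}" for i in range(n)]
    newick = _random_topology(labels, rng)
    tree = read_newick(newick)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = rng.uniform(0.05, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    vals = np.array(
        [[0.0 if a == b else pdm.patristic_distance(tax[a], tax[b]) for b in labels] for a in labels]
    )
    return tree, DistanceMatrix(labels, vals)


def _random_topology(labels, rng):
    groups = [lab for lab in labels]
    while len(groups) > 3:
        i, j = sorted(rng.sample(range(len(groups)), 2))
        b = groups.pop(j)
        a = groups.pop(i)
        groups.append(f"({a},{b})")
    return "(" + ",".join(groups) + ");"


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InvalidInputError):
            DistanceMatrix(["a", "b"], v)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(InvalidInputError):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestNeighborJoining:
    def test_three_labels_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        tree = neighbor_joining(d)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 4.0}

    def test_additive_six_leaf_recovery(self):
        true, d = random_additive_tree(6, seed=3)
        assert rf_distance(neighbor_joining(d), true) == 0

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_consistency_on_additive_matrices(self, n, seed):
        true, d = random_additive_tree(n, seed=seed * 31 + n)
        assert rf_distance(neighbor_joining(d), true) == 0

    def test_equal_distances_deterministic(self):
        v = np.full((5, 5), 1.0) - np.eye(5)
        d = DistanceMatrix(list("abcde"), v)
        t1 = neighbor_joining(d).as_string(schema="newick")
        t2 = neighbor_joining(d).as_string(schema="newick")
        assert t1 == t2

    def test_agrees_with_scikit_bio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        true, d = random_additive_tree(8, seed=17)
        sk_dm = skbio.DistanceMatrix(d.values, ids=d.labels)
        sk_newick = str(skbio.tree.nj(sk_dm))
        sk_tree = read_newick(sk_newick)
        assert rf_distance(neighbor_joining(d), sk_tree) == 0

    def test_too_few_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestPDistance:
    def test_pairwise_deletion_excludes_ambiguity_and_gaps(self):
        d = p_distance_matrix({"a": "ACGTAC", "b": "ACGTNC", "c": "TCG-AC"})
        la = d.labels.index("a")
        lb = d.labels.index("b")
        lc = d.labels.index("c")
        assert d.values[la, lb] == 0.0  # N site excluded
        assert d.values[la, lc] == pytest.approx(1 / 5)

    def test_disjoint_fragments_get_triangle_bound(self):
        rows = {
            "f1": "ACGT----",
            "f2": "----ACGT",
            "k": "ACGTACGT",
        }
        d = p_distance_matrix(rows)
        i, j = d.labels.index("f1"), d.labels.index("f2")
        assert d.values[i, j] == 0.0  # both identical to the bridging row


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = read_newick("((a,b),(c,d));")
        assert rf_distance(t, read_newick("((a,b),(c,d));")) == 0

    def test_conflicting_quartets(self):
        # both resolved 4-leaf topologies each have one unique split
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    @pytest.mark.parametrize("n", [5, 8])
    def test_star_vs_binary(self, n):
        labels = [f"x{i}" for i in range(n)]
        star = read_newick("(" + ",".join(labels) + ");")
        rng = random.Random(n)
        binary = read_newick(_random_topology(labels, rng))
        assert rf_distance(star, binary) == n - 3

    def test_metric_properties_on_random_triples(self):
        labels = [f"x{i}" for i in range(6)]
        rng = random.Random(5)
        trees = [read_newick(_random_topology(labels, rng)) for _ in range(6)]
        for a, b, c in itertools.combinations(trees, 3):
            dab, dbc, dac = rf_distance(a, b), rf_distance(b, c), rf_distance(a, c)
            assert dab == rf_distance(b, a)
            assert dac <= dab + dbc

    def test_matches_dendropy_oracle(self):
        labels = [f"x{i}" for i in range(8)]
        rng = random.Random(9)
        for _ in range(10):
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=_random_topology(labels, rng), schema="newick",
                                   taxon_namespace=tns)
            t2 = dendropy.Tree.get(data=_random_topology(labels, rng), schema="newick",
                                   taxon_namespace=tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            expected = treecompare.symmetric_difference(t1, t2)
            assert rf_distance(t1, t2) == expected

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            rf_distance(read_newick("((a,b),(c,d));"), read_newick("((a,b),(c,e));"))


class TestBootstrap:
    def test_unanimous_signal_gives_full_support(self):
        # every site splits the leaves as ab|cd
        rows = {
            "a": "A" * 25 + "C" * 25,
            "b": "A" * 25 + "C" * 25,
            "c": "T" * 25 + "G" * 25,
            "d": "T" * 25 + "G" * 25,
        }
        tree = bootstrap_support(rows, replicates=50, seed=5)
        supports = [float(nd.label) for nd in tree.preorder_node_iter()
                    if nd.label is not None and not nd.is_leaf() and nd.parent_node is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_seeded_determinism(self):
        rows = {"a": "ACGTAC" * 20, "b": "ACGTTC" * 20, "c": "GCGTAC" * 20, "d": "GCATAC" * 20}
        t1 = bootstrap_support(rows, 40, seed=3).as_string(schema="newick")
        t2 = bootstrap_support(rows, 40, seed=3).as_string(schema="newick")
        assert t1 == t2

    def test_even_conflict_near_fifty_percent(self):
        # 50 sites support ab|cd, 50 sites support ac|bd
        rows = {
            "a": "A" * 50 + "G" * 50,
            "b": "A" * 50 + "T" * 50,
            "c": "C" * 50 + "G" * 50,
            "d": "C" * 50 + "T" * 50,
        }
        tree = bootstrap_support(rows, replicates=400, seed=11)
        supports = [float(nd.label) for nd in tree.preorder_node_iter()
                    if nd.label is not None and not nd.is_leaf() and nd.parent_node is not None]
        assert len(supports) == 1
        # binomial oracle: 3 sd of a fair coin at 400 replicates is 7.5 points
        assert abs(supports[0] - 50.0) <= 3 * 100 * (0.25 / 400) ** 0.5 + 4.0

    def test_monte_carlo_error_shrinks_with_replicates(self):
        rows = {
            "a": "A" * 50 + "G" * 50,
            "b": "A" * 50 + "T" * 50,
            "c": "C" * 50 + "G" * 50,
            "d": "C" * 50 + "T" * 50,
        }

        def spread(reps):
            vals = []
            for seed in range(6):
                t = bootstrap_support(rows, reps, seed=seed)
                vals.extend(float(nd.label) for nd in t.preorder_node_iter()
                            if nd.label is not None and not nd.is_leaf()
                            and nd.parent_node is not None)
            return np.std(vals)

        assert spread(256) < spread(16)

    def test_zero_length_alignment_rejected(self):
        with pytest.raises(InvalidInputError):
            bootstrap_support({"a": "", "b": ""}, 10, seed=0)


def test_nj_tree_and_splits_round_trip():
    rows = {"a": "AAAACC", "b": "AAAAGG", "c": "TTTTCC", "d": "TTTTGG"}
    tree = nj_tree(rows)
    assert len(tree_splits(tree)) == 1
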