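import itertools

import numpy as np
import pytest

from genefam.phylo import (MultipleAlignment, Node, PhyloTree,
                           bootstrap_support, complete_deletion,
                           distance_matrix, jtt_distance, jtt_frequencies,
                           jtt_transition, majority_rule_consensus,
                           ml_search, neighbor_joining, nj_tree, tree_loglik)
from genefam.seqio import SequenceRecord
from genefam.simulate import evolve_on_tree

AA = "ARNDCQEGHILKMFPSTWYV"


def four_taxon_tree(internal=0.4, pendant=0.15):
    root = Node()
    v = Node(length=internal)
    root.add(v)
    v.add(Node("A", pendant))
    v.add(Node("B", pendant))
    root.add(Node("C", pendant))
    root.add(Node("D", pendant))
    return PhyloTree(root)


def random_protein(n, seed):
    rng = np.random.default_rng(seed)
    return SequenceRecord("root", "".join(rng.choice(list(AA), n)), "protein")


def brute_force_loglik(tree: PhyloTree, aln: MultipleAlignment) -> float:
    """Independent oracle: sum the joint probability over every internal
    state assignment, site by site."""
    freqs = jtt_frequencies()
    idx = {a: i for i, a in enumerate(AA)}
    seqs = dict(aln.rows)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    for site in range(aln.n_sites):
        site_prob = 0.0
        for states in itertools.product(range(20), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, states)}
            p = freqs[assign[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                s = (idx[seqs[n.name][site]] if n.is_leaf() else assign[id(n)])
                p *= jtt_transition(n.length)[assign[id(n.parent)], s]
            site_prob += p
        total += np.log(site_prob)
    return total


class TestJttModel:
    def test_transition_rows_sum_to_one(self):
        for t in (0.0, 0.1, 1.0, 5.0):
            assert np.allclose(jtt_transition(t).sum(axis=1), 1.0)

    def test_zero_time_is_identity(self):
        assert np.allclose(jtt_transition(0.0), np.eye(20), atol=1e-10)

    def test_detailed_balance(self):
        pi = jtt_frequencies()
        F = pi[:, None] * jtt_transition(0.7)
        assert np.allclose(F, F.T, atol=1e-12)

    def test_unit_rate_normalization(self):
        # expected fraction changed ~ t for small t
        pi = jtt_frequencies()
        t = 1e-4
        p_change = 1.0 - (pi * np.diag(jtt_transition(t))).sum()
        assert p_change == pytest.approx(t, rel=1e-3)


class TestCompleteDeletion:
    def test_gap_column_removed(self):
        aln = MultipleAlignment([("a", "A-C"), ("b", "AGC")])
        assert complete_deletion(aln).rows == [("a", "AC"), ("b", "AC")]

    def test_gap_free_unchanged(self):
        aln = MultipleAlignment([("a", "ARN"), ("b", "DCQ")])
        assert complete_deletion(aln).rows == aln.rows

    def test_all_columns_gapped_is_error(self):
        aln = MultipleAlignment([("a", "-A"), ("b", "A-")])
        with pytest.raises(ValueError, match="pairwise"):
            complete_deletion(aln)

    def test_missing_data_column_removed(self):
        aln = MultipleAlignment([("a", "AXC"), ("b", "AGC")])
        assert complete_deletion(aln).rows == [("a", "AC"), ("b", "AC")]


class TestJttDistance:
    def test_identical_is_zero(self):
        assert jtt_distance("ACDEF", "ACDEF") == 0.0

    def test_symmetric(self):
        a, b = "ACDEFGHIKL" * 5, "ACDEYGHIKV" * 5
        assert jtt_distance(a, b) == pytest.approx(jtt_distance(b, a), abs=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            jtt_distance("ACD", "ACDE")

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(17)
        root = random_protein(50, 23)
        tree = PhyloTree(Node())
        tree.root.add(Node("x", 0.25))
        tree.root.add(Node("y", 0.25))
        aln = evolve_on_tree(tree, root, seed=3)
        a, b = aln.rows[0][1], aln.rows[1][1]
        t_hat = jtt_distance(a, b)

        # independent dense-grid scan of the same likelihood
        from genefam.phylo import encode_protein
        ia, ib = encode_protein(a), encode_protein(b)
        counts = np.zeros((20, 20))
        np.add.at(counts, (ia, ib), 1.0)
        logpi = np.log(jtt_frequencies())
        grid = np.arange(1e-4, 3.0, 1e-4)
        lls = [
            (counts * (logpi[:, None] + np.log(jtt_transition(t)))).sum()
            for t in grid
        ]
        t_grid = grid[int(np.argmax(lls))]
        assert abs(t_hat - t_grid) < 1e-3

    def test_increases_with_divergence(self):
        root = random_protein(120, 5)
        medians = []
        for scale in (0.05, 0.2, 0.6):
            ds = []
            for seed in range(8):
                tree = PhyloTree(Node())
                tree.root.add(Node("x", scale))
                tree.root.add(Node("y", scale))
                aln = evolve_on_tree(tree, root, seed=seed)
                ds.append(jtt_distance(aln.rows[0][1], aln.rows[1][1]))
            medians.append(np.median(ds))
        assert medians[0] < medians[1] < medians[2]


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = neighbor_joining(D, ["A", "B", "C"])
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_matrix_recovers_topology_and_paths(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            tree = four_taxon_tree(internal=rng.uniform(0.2, 1.0),
                                   pendant=rng.uniform(0.05, 0.5))
            D, labels = _path_distances(tree)
            nj = neighbor_joining(D, labels)
            assert nj.splits() == tree.splits()
            D2, labels2 = _path_distances(nj)
            order = [labels2.index(l) for l in labels]
            assert np.allclose(D, D2[np.ix_(order, order)], atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(D, list("ABC"))

    def test_agrees_with_skbio_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 6
            X = rng.uniform(0.1, 1.0, size=(n, 3))
            D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(D, 0.0)
            labels = [f"t{k}" for k in range(n)]
            ours = neighbor_joining(D, labels).splits()
            ref = skbio_nj(DistanceMatrix(D, labels))
            theirs = set()
            names = frozenset(labels)
            refname = min(names)
            for node in ref.non_tips():
                s = frozenset(t.name for t in node.tips())
                if 2 <= len(s) <= n - 2:
                    theirs.add(s if refname not in s else names - s)
            assert ours == theirs


def _path_distances(tree: PhyloTree):
    leaves = tree.leaves()
    labels = [l.name for l in leaves]
    def path_to_root(n):
        out = []
        while n.parent is not None:
            out.append(n)
            n = n.parent
        return out
    D = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i >= j:
                continue
            pa, pb = path_to_root(a), path_to_root(b)
            sa, sb = set(map(id, pa)), set(map(id, pb))
            d = sum(n.length for n in pa if id(n) not in sb)
            d += sum(n.length for n in pb if id(n) not in sa)
            D[i, j] = D[j, i] = d
    return D, labels


class TestTreeLoglik:
    def test_two_taxa_one_site_equals_state_sum(self):
        tree = PhyloTree(Node())
        tree.root.add(Node("x", 0.3))
        tree.root.add(Node("y", 0.8))
        aln = MultipleAlignment([("x", "W"), ("y", "C")])
        freqs = jtt_frequencies()
        iW, iC = AA.index("W"), AA.index("C")
        direct = sum(
            freqs[s] * jtt_transition(0.3)[s, iW] * jtt_transition(0.8)[s, iC]
            for s in range(20))
        assert tree_loglik(tree, aln) == pytest.approx(np.log(direct))

    def test_matches_brute_force_on_small_trees(self):
        root = random_protein(3, 31)
        tree = four_taxon_tree()
        aln = evolve_on_tree(tree, root, seed=6)
        assert tree_loglik(tree, aln) == \
               pytest.approx(brute_force_loglik(tree, aln), abs=1e-8)

    def test_invariant_to_rerooting(self):
        root = random_protein(40, 13)
        aln = evolve_on_tree(four_taxon_tree(), root, seed=2)
        # same unrooted tree, three rooted representations
        t1 = four_taxon_tree()
        t2 = PhyloTree(Node())
        v = Node(length=0.4)
        v.add(Node("C", 0.15)); v.add(Node("D", 0.15))
        t2.root.add(v); t2.root.add(Node("A", 0.15)); t2.root.add(Node("B", 0.15))
        t3 = PhyloTree(Node())
        left, right = Node(length=0.1), Node(length=0.3)
        left.add(Node("A", 0.15)); left.add(Node("B", 0.15))
        right.add(Node("C", 0.15)); right.add(Node("D", 0.15))
        t3.root.add(left); t3.root.add(right)
        lls = [tree_loglik(t, aln) for t in (t1, t2, t3)]
        assert lls[0] == pytest.approx(lls[1], abs=1e-8)
        assert lls[0] == pytest.approx(lls[2], abs=1e-8)

    def test_zero_branch_lengths_identical_sequences(self):
        tree = four_taxon_tree(internal=0.0, pendant=0.0)
        seq = "ARNDW"
        aln = MultipleAlignment([(n, seq) for n in "ABCD"])
        freqs = jtt_frequencies()
        expected = sum(np.log(freqs[AA.index(a)]) for a in seq)
        assert tree_loglik(tree, aln) == pytest.approx(expected, abs=1e-8)

    def test_leaf_mismatch_rejected(self):
        tree = four_taxon_tree()
        aln = MultipleAlignment([("A", "W"), ("B", "W"), ("C", "W"),
                                 ("E", "W")])
        with pytest.raises(ValueError, match="leaves"):
            tree_loglik(tree, aln)


class TestMlSearch:
    def test_never_worse_than_start(self):
        root = random_protein(60, 3)
        aln = evolve_on_tree(four_taxon_tree(), root, seed=9)
        start = nj_tree(aln)
        start_ll = tree_loglik(start, aln)
        out = ml_search(aln, start)
        assert out.loglik >= start_ll - 1e-9

    def test_agrees_with_exhaustive_topology_search(self):
        # all 3 unrooted 4-taxon topologies, each with optimized lengths
        for seed in range(5):
            root = random_protein(80, 100 + seed)
            aln = evolve_on_tree(four_taxon_tree(), root, seed=seed)
            result = ml_search(aln, nj_tree(aln))
            from genefam.phylo import optimize_branch_lengths
            best = None
            for pair in (("A", "B"), ("A", "C"), ("A", "D")):
                t = PhyloTree(Node())
                v = Node(length=0.2)
                rest = [n for n in "ABCD" if n not in pair]
                for nm in pair:
                    v.add(Node(nm, 0.2))
                t.root.add(v)
                for nm in rest:
                    t.root.add(Node(nm, 0.2))
                opt = optimize_branch_lengths(t, aln, max_rounds=4)
                if best is None or opt.loglik > best.loglik:
                    best = opt
            assert result.splits() == best.splits()
            assert result.loglik == pytest.approx(best.loglik, abs=1e-3)


class TestBootstrap:
    def _alignment(self, seed=0):
        root = random_protein(100, 77)
        return evolve_on_tree(four_taxon_tree(internal=0.5), root, seed=seed)

    def test_deterministic_given_seed(self):
        aln = self._alignment()
        a = bootstrap_support(aln, n_reps=30, seed=4)
        b = bootstrap_support(aln, n_reps=30, seed=4)
        assert [n.support for n in a.internal_edges()] == \
               [n.support for n in b.internal_edges()]

    def test_supports_within_bounds(self):
        aln = self._alignment(seed=1)
        tree = bootstrap_support(aln, n_reps=25, seed=2)
        supports = [n.support for n in tree.internal_edges()]
        assert supports and all(0.0 <= s <= 100.0 for s in supports)

    def test_strong_signal_high_support(self):
        aln = self._alignment(seed=2)
        tree = bootstrap_support(aln, n_reps=50, seed=3)
        for node in tree.internal_edges():
            assert node.support >= 95.0

    def test_majority_rule_consensus(self):
        aln = self._alignment(seed=3)
        tree = bootstrap_support(aln, n_reps=40, seed=5)
        cons = majority_rule_consensus(tree._replicate_splits,
                                       tree.leaf_names())
        assert set(cons.leaf_names()) == set("ABCD")
        assert cons.splits() <= {frozenset("CD"), frozenset("AB")}


class TestNewick:
    def test_roundtrip(self):
        tree = four_taxon_tree()
        tree.internal_edges()[0].support = 97.0
        text = tree.newick()
        back = PhyloTree.from_newick(text)
        assert set(back.leaf_names()) == set("ABCD")
        assert back.splits() == tree.splits()
        (internal,) = back.internal_edges()
        assert internal.support == 97.0
        assert internal.length == pytest.approx(0.4)


class TestDistanceMatrixHelper:
    def test_complete_deletion_applied(self):
        aln = MultipleAlignment(
            [("a", "ARN-W"), ("b", "ARNDW"), ("c", "ARNDW")])
        D, labels = distance_matrix(aln)
        assert labels == ["a", "b", "c"]
        assert D[0, 1] == pytest.approx(0.0, abs=1e-6)
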