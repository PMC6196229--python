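"""Distance matrices, neighbor joining, rooting and bootstrap supports."""

import random

import dendropy
import numpy as np
import pytest

from syntrace import (
    DistanceMatrix,
    SimilarityNetwork,
    bootstrap_support,
    distances_from_hits,
    nj_tree,
    path_length_matrix,
    root_by_most_divergent,
)
from syntrace.phylo import read_newick, write_newick

from conftest import make_hit


def random_additive_dm(n: int, seed: int) -> tuple[DistanceMatrix, str]:
    """Patristic distances of a random binary tree with positive lengths."""
    rnd = random.Random(seed)
    ids = [f"t{i}" for i in range(n)]
    parts = [f"{t}:{rnd.uniform(0.05, 1.0):.6f}" for t in ids]
    while len(parts) > 2:
        i = rnd.randrange(len(parts))
        a = parts.pop(i)
        j = rnd.randrange(len(parts))
        b = parts.pop(j)
        parts.append(f"({a},{b}):{rnd.uniform(0.05, 1.0):.6f}")
    newick = f"({parts[0]},{parts[1]});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    d = path_length_matrix(tree, ids)
    return DistanceMatrix(ids=ids, d=d), newick


class TestDistances:
    def test_identical_pair_distance_zero(self):
        net = SimilarityNetwork.from_hits(
            [make_hit("a", "b", 1e-180, ident=100.0),
             make_hit("a", "c", 1e-60, ident=70.0),
             make_hit("b", "c", 1e-60, ident=70.0)]
        )
        dm = distances_from_hits(net, {"a", "b", "c"})
        assert dm.d[dm.index("a"), dm.index("b")] == 0.0

    def test_identity_transform(self):
        """74.5% identity maps to a 0.255 uncorrected distance."""
        net = SimilarityNetwork.from_hits([make_hit("a", "b", 1e-80, ident=74.5)])
        dm = distances_from_hits(net, {"a", "b"})
        assert dm.d[0, 1] == pytest.approx(0.255, abs=1e-9)

    def test_matrix_matches_brute_force_recomputation(self):
        rnd = random.Random(3)
        ids = [f"g{i}" for i in range(6)]
        idents = {}
        hits = []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ident = rnd.uniform(40, 99)
                idents[(a, b)] = ident
                hits.append(make_hit(a, b, 1e-50, ident=ident))
        net = SimilarityNetwork.from_hits(hits)
        dm = distances_from_hits(net, ids)
        for (a, b), ident in idents.items():
            assert dm.d[dm.index(a), dm.index(b)] == pytest.approx(
                1 - ident / 100.0
            )

    def test_missing_pair_gets_max_plus_epsilon(self):
        net = SimilarityNetwork.from_hits(
            [make_hit("a", "b", 1e-50, ident=60.0)]
        )
        net.graph.add_node("c")
        dm = distances_from_hits(net, {"a", "b", "c"})
        assert dm.d[dm.index("a"), dm.index("c")] > 0.4


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        """Tree ((A:1,B:2):1,(C:3,D:1)) is recovered exactly."""
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(ids=ids, d=d))
        assert np.allclose(path_length_matrix(tree, ids), d, atol=1e-12)
        # cherry structure: A+B are sisters (so are C+D)
        pdm = path_length_matrix(tree, ids)
        assert pdm[0, 1] == pytest.approx(3.0)
        assert pdm[2, 3] == pytest.approx(4.0)

    def test_all_zero_matrix_gives_zero_lengths(self):
        ids = ["a", "b", "c", "d"]
        tree = nj_tree(DistanceMatrix(ids=ids, d=np.zeros((4, 4))))
        assert all(
            (e.length or 0.0) == 0.0 for e in tree.preorder_edge_iter()
        )

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_random_additive_matrices_recovered(self, n):
        for seed in range(5):
            dm, _ = random_additive_dm(n, seed=100 * n + seed)
            tree = nj_tree(dm)
            assert np.allclose(
                path_length_matrix(tree, dm.ids), dm.d, atol=1e-9
            )

    def test_under_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=["a", "b"], d=np.zeros((2, 2))))

    def test_topology_agrees_with_skbio(self):
        """Independent cross-check against scikit-bio's NJ."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        dm, _ = random_additive_dm(7, seed=11)
        ours = path_length_matrix(nj_tree(dm), dm.ids)
        sk_tree = sknj(SkDM(dm.d, ids=dm.ids))
        sk = np.array(
            [[sk_tree.find(a).distance(sk_tree.find(b)) for b in dm.ids]
             for a in dm.ids]
        )
        assert np.allclose(ours, sk, atol=1e-6)


class TestRooting:
    def test_divergent_leaf_becomes_outgroup(self):
        ids = ["a", "b", "c", "d"]
        d = np.array([
            [0.0, 0.1, 0.1, 0.9],
            [0.1, 0.0, 0.1, 0.9],
            [0.1, 0.1, 0.0, 0.9],
            [0.9, 0.9, 0.9, 0.0],
        ])
        dm = DistanceMatrix(ids=ids, d=d)
        rooted = root_by_most_divergent(nj_tree(dm), dm)
        root_children = rooted.seed_node.child_nodes()
        outgroups = [
            c.taxon.label for c in root_children if c.is_leaf() and c.taxon
        ]
        assert "d" in outgroups

    def test_tie_breaks_lexicographically(self):
        ids = ["c", "a", "b", "d"]
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(ids=ids, d=d)
        rooted = root_by_most_divergent(nj_tree(dm), dm)
        outgroups = [
            c.taxon.label for c in rooted.seed_node.child_nodes()
            if c.is_leaf() and c.taxon
        ]
        assert outgroups == ["a"]

    def test_rooting_preserves_leaf_to_leaf_paths(self):
        dm, _ = random_additive_dm(6, seed=5)
        tree = nj_tree(dm)
        before = path_length_matrix(tree, dm.ids)
        after = path_length_matrix(root_by_most_divergent(tree, dm), dm.ids)
        assert np.allclose(before, after, atol=1e-9)

    def test_newick_round_trip(self, tmp_path):
        dm, _ = random_additive_dm(5, seed=8)
        tree = nj_tree(dm)
        path = write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(path)
        assert np.allclose(
            path_length_matrix(back, dm.ids),
            path_length_matrix(tree, dm.ids),
            atol=1e-6,
        )


def two_clade_alignment(n_per_clade=4, ncols=200, seed=0):
    rnd = random.Random(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    base1 = "".join(rnd.choice(aa) for _ in range(ncols))
    base2 = "".join(rnd.choice(aa) for _ in range(ncols))
    aln = {}
    for clade, base in (("x", base1), ("y", base2)):
        for i in range(n_per_clade):
            row = list(base)
            for _ in range(5):  # light within-clade noise
                p = rnd.randrange(ncols)
                row[p] = rnd.choice(aa)
            aln[f"{clade}{i}"] = "".join(row)
    return aln


class TestBootstrap:
    def test_strong_clade_signal_high_support(self):
        aln = two_clade_alignment()
        tree = bootstrap_support(list(aln), aln, B=100, seed=1)
        clade = frozenset(f"x{i}" for i in range(4))
        supports = {}
        for node in tree.preorder_internal_node_iter():
            if node is tree.seed_node:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            supports[below] = node.support
        matching = [
            s for bp, s in supports.items() if bp in (clade, frozenset(aln) - clade)
        ]
        assert matching and max(matching) >= 0.95

    def test_single_replicate_supports_are_binary(self):
        aln = two_clade_alignment(seed=3)
        tree = bootstrap_support(list(aln), aln, B=1, seed=2)
        for node in tree.preorder_internal_node_iter():
            if node is not tree.seed_node:
                assert node.support in (0.0, 1.0)

    def test_same_seed_reproduces_supports(self):
        aln = two_clade_alignment(seed=4)
        t1 = bootstrap_support(list(aln), aln, B=25, seed=9)
        t2 = bootstrap_support(list(aln), aln, B=25, seed=9)
        s1 = sorted(n.support for n in t1.preorder_internal_node_iter()
                    if n is not t1.seed_node)
        s2 = sorted(n.support for n in t2.preorder_internal_node_iter()
                    if n is not t2.seed_node)
        assert s1 == s2

    def test_leaf_order_permutation_invariant(self):
        aln = two_clade_alignment(seed=6)
        members = list(aln)
        shuffled = list(reversed(members))
        t1 = bootstrap_support(members, aln, B=20, seed=4)
        t2 = bootstrap_support(shuffled, aln, B=20, seed=4)
        s1 = sorted(n.support for n in t1.preorder_internal_node_iter()
                    if n is not t1.seed_node)
        s2 = sorted(n.support for n in t2.preorder_internal_node_iter()
                    if n is not t2.seed_node)
        assert s1 == s2

    def test_requires_alignment_not_hits(self):
        with pytest.raises(ValueError):
            bootstrap_support(["a", "b", "c"], {"a": "MK", "b": "MK"}, B=5, seed=0)
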