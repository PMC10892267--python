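"""p-distances, neighbor joining, bootstrap supports and Newick output."""
import numpy as np
import pytest

from cubkit import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    p_distance,
    write_newick,
)
from cubkit.errors import UndefinedMetricError, ValidationError

from _oracles import random_additive_matrix


def tree_leaf_distances(tree):
    """Leaf-to-leaf path lengths of a PhyloTree, by traversal."""
    import collections
    adj = collections.defaultdict(list)

    def build(node):
        for child, ln in node.children:
            adj[id(node)].append((id(child), ln))
            adj[id(child)].append((id(node), ln))
            build(child)

    build(tree.root)
    leaves = {}

    def collect(node):
        if node.is_leaf:
            leaves[node.label] = id(node)
        for child, _ in node.children:
            collect(child)

    collect(tree.root)

    def dist(u, v):
        seen = {u: 0.0}
        stack = [u]
        while stack:
            x = stack.pop()
            for y, ln in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + ln
                    stack.append(y)
        return seen[v]

    out = {}
    names = sorted(leaves)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = dist(leaves[a], leaves[b])
    return out


class TestAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValidationError):
            Alignment(ids=["a", "b"], rows=["ACGT", "ACG"])

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            Alignment(ids=["a"], rows=["ACGT"])


class TestPDistance:
    def test_identical_sequences_zero(self):
        aln = Alignment(ids=["a", "b"], rows=["ACGTACGT", "ACGTACGT"])
        assert p_distance(aln).matrix[0, 1] == 0.0

    def test_one_site_in_four(self):
        aln = Alignment(ids=["a", "b"], rows=["ACGT", "ACGA"])
        assert p_distance(aln).matrix[0, 1] == pytest.approx(0.25)

    def test_complete_deletion_removes_gapped_columns(self):
        aln = Alignment(ids=["a", "b", "c"],
                        rows=["AC-TA", "ACGTA", "TCGTA"])
        d = p_distance(aln, gap_mode="complete_deletion")
        # column 2 dropped for everyone: 4 usable columns
        assert d.matrix[0, 2] == pytest.approx(1 / 4)

    def test_pairwise_deletion_hand_tally(self):
        aln = Alignment(ids=["a", "b", "c"],
                        rows=["AC-TA", "ACGTA", "TCGTA"])
        d = p_distance(aln, gap_mode="pairwise_deletion")
        # a vs b compares 4 columns, 0 differ; a vs c compares 4, 1 differs
        assert d.matrix[0, 1] == 0.0
        assert d.matrix[0, 2] == pytest.approx(1 / 4)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT-"), 50)) for _ in range(6)]
        d = p_distance(Alignment(ids=[f"s{i}" for i in range(6)], rows=rows),
                       gap_mode="pairwise_deletion")
        assert np.all(d.matrix >= 0) and np.all(d.matrix <= 1)

    def test_all_gapped_columns_error(self):
        aln = Alignment(ids=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(UndefinedMetricError):
            p_distance(aln, gap_mode="complete_deletion")


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # distances generated by ((A:1,B:2):1,(C:3,D:4))
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        dists = tree_leaf_distances(tree)
        for (a, b), d in dists.items():
            i, j = "ABCD".index(a), "ABCD".index(b)
            assert d == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("XYZ"), D))
        lengths = {ch.label: ln for ch, ln in tree.root.children}
        assert lengths == pytest.approx({"X": 1.0, "Y": 2.0, "Z": 4.0})

    def test_random_additive_trees_recovered_exactly(self):
        rng = np.random.default_rng(17)
        for n in (5, 6, 8, 10, 12):
            for _ in range(4):
                D, true_splits = random_additive_matrix(rng, n)
                ids = [f"t{i}" for i in range(n)]
                tree = neighbor_joining(DistanceMatrix(ids, D))
                got = {frozenset(int(x[1:]) for x in s) for s in tree.bipartitions()}
                assert got == true_splits
                dists = tree_leaf_distances(tree)
                for (a, b), d in dists.items():
                    assert d == pytest.approx(D[int(a[1:]), int(b[1:])], abs=1e-9)

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(23)
        for _ in range(5):
            D, _ = random_additive_matrix(rng, 7)
            D += rng.uniform(0, 0.05, D.shape)        # perturb off additivity
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            ids = [f"t{i}" for i in range(7)]
            ours = neighbor_joining(DistanceMatrix(ids, D))
            ref = skbio_nj(SkbioDM(D, ids))
            ref_splits = set()
            for node in ref.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= 5:
                    canon = side if "t0" not in side else frozenset(ids) - side
                    ref_splits.add(canon)
            assert ours.bipartitions() == ref_splits

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(list("AB"), np.array([[0, 1], [2, 0]], float))


@pytest.fixture(scope="module")
def two_group_alignment():
    rng = np.random.default_rng(0)
    a = "".join(rng.choice(list("ACGT"), 80))
    b = "".join(rng.choice(list("ACGT"), 80))
    return Alignment(ids=["a1", "a2", "b1", "b2"], rows=[a, a, b, b])


class TestBootstrap:
    def test_perfect_signal_full_support(self, two_group_alignment):
        tree = bootstrap_support(two_group_alignment, replicates=25, seed=9)
        supports = []

        def collect(node):
            for child, _ in node.children:
                if child.support is not None:
                    supports.append(child.support)
                collect(child)

        collect(tree.root)
        assert supports == [100.0]

    def test_taxon_order_invariance(self, two_group_alignment):
        reordered = Alignment(
            ids=list(reversed(two_group_alignment.ids)),
            rows=list(reversed(two_group_alignment.rows)))
        t1 = bootstrap_support(two_group_alignment, replicates=10, seed=3)
        t2 = bootstrap_support(reordered, replicates=10, seed=3)
        assert t1.newick() == t2.newick()

    def test_deterministic_across_reruns(self, two_group_alignment):
        t1 = bootstrap_support(two_group_alignment, replicates=10, seed=5)
        t2 = bootstrap_support(two_group_alignment, replicates=10, seed=5)
        assert t1.newick() == t2.newick()

    def test_seed_required(self, two_group_alignment):
        with pytest.raises(ValueError):
            bootstrap_support(two_group_alignment, replicates=5, seed=None)


class TestNewick:
    def test_single_line_terminated(self, tmp_path):
        D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("XYZ"), D))
        out = tmp_path / "t.nwk"
        write_newick(tree, out)
        text = out.read_text().strip()
        assert text.endswith(";") and "\n" not in text

    def test_roundtrip_preserves_taxa_and_supports(self, tmp_path, two_group_alignment):
        import dendropy
        tree = bootstrap_support(two_group_alignment, replicates=10, seed=7)
        out = tmp_path / "t.nwk"
        write_newick(tree, out)
        parsed = dendropy.Tree.get(path=str(out), schema="newick")
        taxa = {l.taxon.label for l in parsed.leaf_node_iter()}
        assert taxa == set(two_group_alignment.ids)
        internal_labels = [n.label for n in parsed.preorder_internal_node_iter()
                           if n.label]
        assert internal_labels == ["100"]

    def test_write_read_write_idempotent(self, tmp_path):
        import dendropy
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        p1 = tmp_path / "a.nwk"
        write_newick(tree, p1)
        t1 = dendropy.Tree.get(path=str(p1), schema="newick")
        s1 = t1.as_string(schema="newick")
        t2 = dendropy.Tree.get(data=s1, schema="newick")
        assert t2.as_string(schema="newick") == s1
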