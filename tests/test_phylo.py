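"""NJ correctness against enumeration oracles, support values, set rules."""

import io
import itertools

import numpy as np
import pytest
from skbio import TreeNode

from trdkit import (
    assign_trdv1_set,
    branch_support,
    neighbor_joining,
    p_distance_matrix,
)
from trdkit.numbering import VFeatureSet
from trdkit.phylo import DistanceMatrix


# ---------------------------------------------------------------------------
# oracle: exhaustive unrooted-topology enumeration + least-squares fit
# ---------------------------------------------------------------------------

def _enumerate_topologies(labels):
    """All unrooted binary topologies as edge lists (taxa str, internal int)."""
    first = [("I0", labels[0]), ("I0", labels[1]), ("I0", labels[2])]
    trees = [first]
    for k, taxon in enumerate(labels[3:], start=1):
        new_trees = []
        for edges in trees:
            for idx in range(len(edges)):
                u, v = edges[idx]
                w = f"I{k}x{idx}"
                new = edges[:idx] + edges[idx + 1 :]
                new += [(u, w), (w, v), (w, taxon)]
                new_trees.append(new)
        trees = new_trees
    return trees


def _paths(edges, labels):
    adj = {}
    for i, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, i))
        adj.setdefault(v, []).append((u, i))
    paths = {}
    for a in labels:
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, used = stack.pop()
            if isinstance(node, str) and node in labels and node != a:
                paths[frozenset((a, node))] = used
            for nb, ei in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, node, used + [ei]))
    return paths


def _bipartition_lengths(edges, lengths, labels):
    """Map each edge to (canonical tip-set, length)."""
    out = {}
    lab_set = frozenset(labels)
    ref = min(labels)
    for i, (u, v) in enumerate(edges):
        # tips on v's side when edge removed
        adj = {}
        for j, (a, b) in enumerate(edges):
            if j == i:
                continue
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        side = set()
        stack, seen = [v], {v}
        while stack:
            node = stack.pop()
            if node in labels:
                side.add(node)
            for nb in adj.get(node, []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(side)
        if ref in side:
            side = lab_set - side
        out[side] = lengths[i]
    return out


def _ls_fit(edges, dm: DistanceMatrix):
    labels = dm.labels
    pairs = list(itertools.combinations(labels, 2))
    paths = _paths(edges, set(labels))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        for ei in paths[frozenset((a, b))]:
            A[r, ei] = 1.0
        y[r] = dm.d[labels.index(a), labels.index(b)]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.sum((A @ x - y) ** 2))
    return x, resid


def _skbio_bipartition_lengths(tree: TreeNode, labels):
    out = {}
    lab_set = frozenset(labels)
    ref = min(labels)
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        if ref in side:
            side = lab_set - side
        out[side] = out.get(side, 0.0) + node.length
    return out


def _random_additive(rng, n):
    labels = [f"t{i}" for i in range(n)]
    topos = _enumerate_topologies(labels)
    edges = topos[rng.integers(len(topos))]
    lengths = rng.uniform(0.05, 0.5, size=len(edges))
    paths = _paths(edges, set(labels))
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        path = paths[frozenset((labels[i], labels[j]))]
        d[i, j] = d[j, i] = sum(lengths[e] for e in path)
    return DistanceMatrix(labels=labels, d=d), edges, lengths


class TestPDistance:
    def test_identical_sequences(self):
        dm = p_distance_matrix([("a", "ACGTACGTAC"), ("b", "ACGTACGTAC")])
        assert dm.d[0, 1] == 0.0

    def test_one_difference_in_ten(self):
        dm = p_distance_matrix([("a", "ACGTACGTAC"), ("b", "ACGTACGTAA")])
        assert dm.d[0, 1] == pytest.approx(0.1)

    def test_complete_deletion_column_count(self):
        aln = [
            ("a", "ACGTACGTACGT"),
            ("b", "AC-TACGTACGA"),
            ("c", "ACGTAC-TACGA"),
        ]
        dm = p_distance_matrix(aln, complete_deletion=True)
        assert dm.positions_used == 10
        assert dm.d[0, 1] == pytest.approx(1 / 10)

    def test_all_columns_deleted_errors(self):
        with pytest.raises(ValueError, match="every column"):
            p_distance_matrix([("a", "---"), ("b", "AC-")])

    def test_range_and_symmetry(self, rng):
        seqs = [
            ("s%d" % i, "".join(rng.choice(list("ACGT"), size=60)))
            for i in range(6)
        ]
        dm = p_distance_matrix(seqs)
        assert np.all(dm.d >= 0) and np.all(dm.d <= 1)
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)


class TestNeighborJoining:
    def test_three_point_closed_form(self):
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            d=np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
        )
        tree = neighbor_joining(dm).tree
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == pytest.approx({"A": 0.1, "B": 0.1, "C": 0.3})

    @pytest.mark.parametrize("seed", range(10))
    def test_random_three_taxon_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.uniform(0.05, 0.5, size=3)
        d = np.array([[0, a + b, a + c], [a + b, 0, b + c], [a + c, b + c, 0]])
        tree = neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], d=d)).tree
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == pytest.approx({"A": a, "B": b, "C": c})

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_recovery_vs_enumeration_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            dm, true_edges, true_lengths = _random_additive(rng, n)
            # oracle: least-squares over every unrooted topology
            best = None
            for edges in _enumerate_topologies(dm.labels):
                x, resid = _ls_fit(edges, dm)
                if best is None or resid < best[2]:
                    best = (edges, x, resid)
            oracle_map = _bipartition_lengths(
                best[0], dict(enumerate(best[1])), dm.labels
            )
            assert best[2] < 1e-18
            nj_map = _skbio_bipartition_lengths(
                neighbor_joining(dm).tree, dm.labels
            )
            assert set(nj_map) == set(oracle_map)
            for part, length in oracle_map.items():
                assert nj_map[part] == pytest.approx(length, abs=1e-9)

    def test_all_zero_matrix_star(self):
        dm = DistanceMatrix(labels=list("ABCD"), d=np.zeros((4, 4)))
        tree = neighbor_joining(dm).tree
        assert all(
            n.length == pytest.approx(0.0)
            for n in tree.traverse(include_self=False)
        )

    def test_non_symmetric_rejected(self):
        d = np.array([[0, 1.0, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=list("ABC"), d=d)

    def test_matches_skbio_topology(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        seqs = [
            (f"s{i}", "".join(rng.choice(list("ACGT"), size=120)))
            for i in range(7)
        ]
        dm = p_distance_matrix(seqs)
        ours = neighbor_joining(dm).tree
        theirs = skbio_nj(SkbioDM(dm.d, ids=dm.labels))
        labels = frozenset(dm.labels)

        def parts(tree):
            ref = min(labels)
            out = set()
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(labels) - 1:
                    out.add(side if ref not in side else labels - side)
            return out

        assert parts(ours) == parts(theirs)


class TestBranchSupport:
    def _two_clade_alignment(self):
        rng = np.random.default_rng(5)
        block_a = "".join(rng.choice(list("ACGT"), size=200))
        # clade B differs at every site
        shift = {"A": "C", "C": "G", "G": "T", "T": "A"}
        block_b = "".join(shift[c] for c in block_a)
        aln = [(f"a{i}", block_a) for i in range(5)]
        aln += [(f"b{i}", block_b) for i in range(5)]
        return aln

    def test_central_split_full_support(self):
        aln = self._two_clade_alignment()
        ptree = branch_support(aln, replicates=100, seed=1)
        central = frozenset(f"b{i}" for i in range(5))
        assert ptree.supports[central] == pytest.approx(100.0)

    def test_determinism(self):
        aln = self._two_clade_alignment()
        s1 = branch_support(aln, replicates=50, seed=9).supports
        s2 = branch_support(aln, replicates=50, seed=9).supports
        assert s1 == s2

    def test_input_order_invariance(self):
        aln = self._two_clade_alignment()
        s1 = branch_support(aln, replicates=50, seed=9).supports
        s2 = branch_support(aln[::-1], replicates=50, seed=9).supports
        assert s1 == s2

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            branch_support(self._two_clade_alignment(), replicates=0, seed=1)


def _features(cdr1, res57, trp107, cdr2_deleted=False):
    return VFeatureSet(
        cdr1_length=cdr1,
        residue_57=res57,
        trp_107=trp107,
        qxs_motif=True,
        yfc_motif=True,
        cdr2_deleted=cdr2_deleted,
        post104_extension=4,
    )


class TestSetAssignment:
    @pytest.mark.parametrize(
        "cdr1,res57,trp107,expected",
        [
            (7, "G", "absent", 1),
            (7, "Y", "present", 2),
            (7, "Y", "absent", 2),
            (9, "E", "absent", 3),
            (9, "N", "absent", 6),
            (5, "A", "present", 7),
            (10, "V", "present", 7),
            (7, "N", "present", 10),
            (7, "V", "present", 11),
        ],
    )
    def test_unambiguous_tuples(self, cdr1, res57, trp107, expected):
        sa = assign_trdv1_set(_features(cdr1, res57, trp107))
        assert sa.set_id == expected
        assert sa.evidence == "features-only"

    def test_lacks_cdr2_is_set_nine(self):
        sa = assign_trdv1_set(_features(7, None, "present", cdr2_deleted=True))
        assert sa.set_id == 9

    def test_sets_5_and_8_ambiguous_without_tree(self):
        sa = assign_trdv1_set(_features(9, "Y", "present"))
        assert sa.set_id is None
        assert sa.evidence == "ambiguous"
        assert sa.candidate_sets == [5, 8]

    def test_sets_4_and_6_ambiguous_without_tree(self):
        sa = assign_trdv1_set(_features(9, "Y", "absent"))
        assert sa.evidence == "ambiguous"
        assert sa.candidate_sets == [4, 6]

    def test_tree_resolves_five_vs_eight(self):
        tree = TreeNode.read(
            io.StringIO("((query:1,TRDV1aj:1):1,(TRDV1ad:1,TRDV1x:1):1,out:1);")
        )
        members = {5: ["TRDV1aj"], 8: ["TRDV1ad", "TRDV1x"]}
        sa = assign_trdv1_set(
            _features(9, "Y", "present"), tree=tree,
            gene_name="query", set_members=members,
        )
        assert sa.set_id == 5
        assert sa.evidence == "tree-resolved"

    def test_exception_genes(self):
        sa = assign_trdv1_set(_features(8, "Y", "present"), gene_name="TRDV1t")
        assert sa.set_id == 2
        sa = assign_trdv1_set(_features(18, None, "present", cdr2_deleted=True),
                              gene_name="TRDV1o")
        assert sa.set_id == 9
        sa = assign_trdv1_set(_features(9, "Y", "absent"), gene_name="TRDV1d")
        assert sa.set_id == 5

    def test_pure_function(self):
        f = _features(9, "Y", "present")
        assert assign_trdv1_set(f) == assign_trdv1_set(f)
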