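"""Neighbor-joining phylogeny on p-distances and TRDV1 set classification.

Trees are built with the classic neighbor-joining agglomeration on
p-distance matrices (proportion of differing sites, complete deletion of
gapped columns).  The implementation is deterministic: when two pairs tie on
the Q criterion, the lexicographically smallest label pair (each cluster
labelled by its smallest leaf name) is joined.  Branch support is estimated
by resampling alignment columns with replacement, rebuilding the tree and
scoring each original internal bipartition by the percentage of replicates
that contain it — a site-bootstrap partition frequency that serves for both
the bootstrap and the interior-branch style of support reporting.

TRDV1 genes fall into eleven sets defined by CDR features (CDR1 length, the
residue at IMGT position 57, presence of Trp at IMGT 107); two feature
tuples are shared between sets (5/8 and 4/6) and are resolved, when a tree
is available, by the smallest clade joining the query to a reference member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from trdkit.numbering import VFeatureSet

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "SetAssignment",
    "p_distance_matrix",
    "neighbor_joining",
    "branch_support",
    "assign_trdv1_set",
    "SET_RULES",
    "SET_EXCEPTIONS",
]

GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels."""

    labels: list[str]
    d: np.ndarray
    positions_used: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class PhyloTree:
    """An unrooted NJ tree with optional per-bipartition support values."""

    tree: TreeNode
    supports: dict[frozenset, float] | None = None
    replicates: int = 0

    def to_newick(self) -> str:
        return str(self.tree)


def _aligned_items(alignment) -> tuple[list[str], list[str]]:
    if isinstance(alignment, Mapping):
        labels, seqs = list(alignment.keys()), [alignment[k] for k in alignment]
    else:
        labels, seqs = [x[0] for x in alignment], [x[1] for x in alignment]
    if len(set(len(s) for s in seqs)) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return labels, [s.upper() for s in seqs]


def p_distance_matrix(alignment, complete_deletion: bool = True) -> DistanceMatrix:
    """Pairwise p-distances (proportion of differing sites) for an alignment.

    With ``complete_deletion`` every column containing a gap in *any*
    sequence is removed before distances are computed.  ``alignment`` is a
    mapping name → sequence or a list of (name, sequence) pairs.
    """
    labels, seqs = _aligned_items(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    arr = np.array([list(s) for s in seqs])
    if complete_deletion:
        keep = ~np.isin(arr, list(GAP_CHARS)).any(axis=0)
        arr = arr[:, keep]
    if arr.shape[1] == 0:
        raise ValueError("complete deletion removed every column")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    return DistanceMatrix(labels=labels, d=d, positions_used=arr.shape[1])


def neighbor_joining(matrix: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Classic neighbor-joining agglomeration.

    Deterministic given the matrix: Q ties are broken by the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by its smallest leaf name).  Negative branch lengths are retained unless
    ``clamp_negative`` is set, in which case they are clamped at 0.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = matrix.d.copy()
    nodes = [TreeNode(name=lab) for lab in matrix.labels]
    minlab = list(matrix.labels)
    active = list(range(n))

    def _clamp(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((minlab[i], minlab[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        vi = D[i, j] / 2 + (r[i] - r[j]) / (2 * (len(active) - 2))
        vj = D[i, j] - vi
        parent = TreeNode()
        nodes[i].length = _clamp(vi)
        nodes[j].length = _clamp(vj)
        parent.extend([nodes[i], nodes[j]])
        # distances to the new cluster
        new_idx = len(nodes)
        nodes.append(parent)
        minlab.append(min(minlab[i], minlab[j]))
        Dn = np.zeros((new_idx + 1, new_idx + 1))
        Dn[: D.shape[0], : D.shape[1]] = D
        for k in active:
            if k in (i, j):
                continue
            dk = (D[i, k] + D[j, k] - D[i, j]) / 2
            Dn[new_idx, k] = Dn[k, new_idx] = dk
        D = Dn
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # terminal three-point configuration
    a, b, c = active
    root = TreeNode()
    nodes[a].length = _clamp((D[a, b] + D[a, c] - D[b, c]) / 2)
    nodes[b].length = _clamp((D[a, b] + D[b, c] - D[a, c]) / 2)
    nodes[c].length = _clamp((D[a, c] + D[b, c] - D[a, b]) / 2)
    root.extend([nodes[a], nodes[b], nodes[c]])
    return PhyloTree(tree=root)


def _bipartitions(tree: TreeNode, all_tips: frozenset) -> set[frozenset]:
    """Internal bipartitions as canonical tip subsets.

    Each internal edge splits the tips in two; the side not containing the
    alphabetically first tip is kept as the canonical representation.
    Trivial splits (single tip / all tips) are excluded.
    """
    ref = min(all_tips)
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(all_tips) - 1:
            continue
        if ref in side:
            side = all_tips - side
        parts.add(side)
    return parts


def branch_support(
    alignment,
    replicates: int,
    seed: int,
    method: str = "interior-branch",
    complete_deletion: bool = True,
) -> PhyloTree:
    """NJ tree with per-bipartition support from site resampling.

    Columns retained after complete deletion are resampled with replacement
    ``replicates`` times; each replicate tree votes for the original internal
    bipartitions it contains.  Taxon order is canonicalized (sorted labels)
    before resampling so support values do not depend on input order.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if method not in {"interior-branch", "bootstrap"}:
        raise ValueError(f"unknown support method {method!r}")
    labels, seqs = _aligned_items(alignment)
    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    seqs = [seqs[i] for i in order]
    arr = np.array([list(s) for s in seqs])
    if complete_deletion:
        keep = ~np.isin(arr, list(GAP_CHARS)).any(axis=0)
        arr = arr[:, keep]
    if arr.shape[1] == 0:
        raise ValueError("complete deletion removed every column")
    n_cols = arr.shape[1]

    def _dm(cols: np.ndarray) -> DistanceMatrix:
        sub = arr[:, cols]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = np.mean(sub[i] != sub[j])
        return DistanceMatrix(labels=labels, d=d, positions_used=len(cols))

    base = neighbor_joining(_dm(np.arange(n_cols)))
    all_tips = frozenset(labels)
    original = _bipartitions(base.tree, all_tips)
    counts = {p: 0 for p in original}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = neighbor_joining(_dm(cols))
        rep_parts = _bipartitions(rep.tree, all_tips)
        for p in original:
            if p in rep_parts:
                counts[p] += 1
    supports = {p: 100.0 * c / replicates for p, c in counts.items()}
    # annotate internal nodes for newick export
    for node in base.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if min(all_tips) not in side else all_tips - side
        if canon in supports:
            node.name = f"{supports[canon]:g}"
    return PhyloTree(tree=base.tree, supports=supports, replicates=replicates)


# ---------------------------------------------------------------------------
# TRDV1 set classification
# ---------------------------------------------------------------------------

@dataclass
class SetAssignment:
    """Assignment of a TRDV1 gene to one of the eleven phylogenetic sets."""

    gene: str
    set_id: int | None
    evidence: str  # "features-only" | "tree-resolved" | "ambiguous"
    candidate_sets: list[int] = field(default_factory=list)


def _rule(set_id, cdr1, res57, w107, cdr2_deleted=False):
    return {
        "set_id": set_id,
        "cdr1": cdr1,
        "res57": res57,
        "w107": w107,  # True = present required, False = absent required, None = either
        "cdr2_deleted": cdr2_deleted,
    }


#: Feature rules per set: CDR1 length(s), residue at IMGT 57, Trp-107 requirement.
SET_RULES = [
    _rule(1, {7}, {"G"}, False),
    _rule(2, {7}, {"Y"}, None),
    _rule(3, {9}, {"E"}, None),
    _rule(4, {9}, {"Y"}, False),
    _rule(5, {9}, {"Y"}, True),
    _rule(6, {9}, {"Y", "N"}, False),
    _rule(7, {5, 10}, {"A", "V"}, True),
    _rule(8, {9}, {"Y"}, True),
    _rule(9, {7}, None, None, cdr2_deleted=True),
    _rule(10, {7}, {"N", "G"}, True),
    _rule(11, {7}, {"G", "V"}, True),
]

#: Per-gene exceptions honored instead of widening the rules.
SET_EXCEPTIONS = {
    "TRDV1t": 2,  # CDR1 length of 8
    "TRDV1o": 9,  # CDR1 length of 18
    "TRDV1d": 5,  # Q instead of W at IMGT 107
}


def _matches(rule: dict, f: VFeatureSet) -> bool:
    if rule["cdr2_deleted"]:
        if not f.cdr2_deleted:
            return False
    elif f.cdr2_deleted:
        return False
    if f.cdr1_length not in rule["cdr1"]:
        return False
    if rule["res57"] is not None:
        if f.residue_57 is None or f.residue_57 not in rule["res57"]:
            return False
    if rule["w107"] is not None:
        present = f.trp_107 == "present"
        if rule["w107"] != present:
            return False
    return True


def assign_trdv1_set(
    features: VFeatureSet,
    tree: PhyloTree | TreeNode | None = None,
    gene_name: str = "",
    set_members: Mapping[int, Sequence[str]] | None = None,
) -> SetAssignment:
    """Assign a TRDV1 gene to a phylogenetic set from its CDR features.

    When several sets match the feature tuple (sets 5/8 and 4/6 share
    features), the ambiguity is resolved by the smallest tree clade joining
    the gene to a reference member of a candidate set; without a tree (or
    reference members) the assignment is flagged ambiguous.
    """
    if gene_name in SET_EXCEPTIONS:
        return SetAssignment(
            gene=gene_name,
            set_id=SET_EXCEPTIONS[gene_name],
            evidence="features-only",
            candidate_sets=[SET_EXCEPTIONS[gene_name]],
        )
    candidates = [r["set_id"] for r in SET_RULES if _matches(r, features)]
    if len(candidates) == 1:
        return SetAssignment(
            gene=gene_name, set_id=candidates[0],
            evidence="features-only", candidate_sets=candidates,
        )
    if not candidates:
        return SetAssignment(
            gene=gene_name, set_id=None, evidence="features-only", candidate_sets=[]
        )
    # multiple candidates: try tree resolution
    tnode = tree.tree if isinstance(tree, PhyloTree) else tree
    if tnode is not None and set_members and gene_name:
        tips = {t.name: t for t in tnode.tips()}
        if gene_name in tips:
            best: tuple[int, int] | None = None  # (clade size, set_id)
            for sid in candidates:
                for member in set_members.get(sid, []):
                    if member not in tips or member == gene_name:
                        continue
                    lca = tnode.lca([tips[gene_name], tips[member]])
                    size = sum(1 for _ in lca.tips())
                    if best is None or (size, sid) < best:
                        best = (size, sid)
            if best is not None:
                sizes = set()
                for sid in candidates:
                    for member in set_members.get(sid, []):
                        if member in tips and member != gene_name:
                            lca = tnode.lca([tips[gene_name], tips[member]])
                            sizes.add((sum(1 for _ in lca.tips()), sid))
                min_size = min(s for s, _ in sizes)
                winners = sorted({sid for s, sid in sizes if s == min_size})
                if len(winners) == 1:
                    return SetAssignment(
                        gene=gene_name, set_id=winners[0],
                        evidence="tree-resolved", candidate_sets=sorted(candidates),
                    )
    return SetAssignment(
        gene=gene_name, set_id=None, evidence="ambiguous",
        candidate_sets=sorted(candidates),
    )
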