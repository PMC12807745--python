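"""Tree and alignment preparation ahead of event inference.

The pipeline order is: root the tree at the minimum-variance point, then
remove leaves on excessively long branches (>= 50x the mean branch length
of the input tree by default).  Alignment-column trimming (drop columns
with gap content strictly above 90%) is provided for upstream family
reconstruction workflows.

MinVar rooting places the root anywhere along any edge (not only at
nodes): on each edge the variance of root-to-tip path lengths is an exact
quadratic in the root offset, minimized in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AllLeavesRemovedError, DegenerateTreeError, EmptyAlignmentError
from .tree import GeneTree, LeafLabel, TreeNode

__all__ = [
    "PruneReport",
    "Msa",
    "read_msa",
    "write_msa",
    "minvar_root",
    "prune_long_branches",
    "trim_alignment",
]

GAP_CHARS = frozenset("-.")


# -- MinVar rooting ------------------------------------------------------------


def _unrooted_edges(tree: GeneTree):
    """View the tree as an undirected graph; a degree-2 root is dissolved.

    Returns (adjacency, edges) where adjacency maps id(node) -> list of
    (neighbor, length) and edges is a list of (u, v, length) with v the
    original child.
    """
    edges: list[tuple[TreeNode, TreeNode, float]] = []
    for node in tree.postorder():
        if node.parent is not None:
            edges.append((node.parent, node, node.length))
    root = tree.root
    if len(root.children) == 2:
        a, b = root.children
        edges = [e for e in edges if e[0] is not root]
        edges.append((a, b, a.length + b.length))
    adjacency: dict[int, list[tuple[TreeNode, float]]] = {}
    for u, v, L in edges:
        adjacency.setdefault(id(u), []).append((v, L))
        adjacency.setdefault(id(v), []).append((u, L))
    return adjacency, edges


def _side_leaf_distances(
    start: TreeNode, banned: TreeNode, adjacency
) -> list[tuple[TreeNode, float]]:
    """Distances from `start` to every leaf reachable without crossing to `banned`."""
    out: list[tuple[TreeNode, float]] = []
    stack = [(start, banned, 0.0)]
    while stack:
        node, came_from, dist = stack.pop()
        if node.is_leaf:
            out.append((node, dist))
        for nbr, L in adjacency.get(id(node), ()):
            if nbr is not came_from:
                stack.append((nbr, node, dist + L))
    return out


def _leaf_name(node: TreeNode) -> str:
    return str(node.label) if node.label is not None else node.name


def _build_subtree(vertex: TreeNode, banned: TreeNode, adjacency, length: float) -> TreeNode:
    node = TreeNode(length=length, label=vertex.label, name=vertex.name)
    for nbr, L in adjacency.get(id(vertex), ()):
        if nbr is not banned:
            node.add_child(_build_subtree(nbr, vertex, adjacency, L))
    return node


def minvar_root(tree: GeneTree) -> GeneTree:
    """Root the tree at the point minimizing the variance of root-to-tip paths.

    The input rooting is ignored (a bifurcating root is dissolved first).
    Every edge admits a closed-form optimum: with ``n1`` leaves at summed
    distance ``s1`` (squares ``q1``) on one side and ``n2, s2, q2`` on the
    other, the tip-distance variance at offset ``x`` is a strictly convex
    quadratic.  Ties (within 1e-12) are broken by the lexicographically
    smallest side leaf-name set, then the smaller offset.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise DegenerateTreeError("MinVar rooting requires at least 2 leaves")
    adjacency, edges = _unrooted_edges(tree)
    n = len(leaves)

    best: Optional[tuple[float, tuple, TreeNode, TreeNode, float, float]] = None
    for u, v, L in edges:
        v_side = _side_leaf_distances(v, u, adjacency)
        u_side = _side_leaf_distances(u, v, adjacency)
        n1 = len(v_side)
        n2 = len(u_side)
        s1 = sum(d for _, d in v_side)
        s2 = sum(d for _, d in u_side)
        q1 = sum(d * d for _, d in v_side)
        q2 = sum(d * d for _, d in u_side)
        # sum of tip distances T(x) and of squares Q(x), x measured from v
        # T = (n1 - n2) x + (s1 + s2 + n2 L)
        # Q = (n1 + n2) x^2 + (2 s1 - 2 s2 - 2 n2 L) x + (q1 + q2 + 2 L s2 + n2 L^2)
        t1 = n1 - n2
        t0 = s1 + s2 + n2 * L
        Q2 = n1 + n2
        Q1 = 2.0 * s1 - 2.0 * s2 - 2.0 * n2 * L
        Q0 = q1 + q2 + 2.0 * L * s2 + n2 * L * L
        A = Q2 / n - (t1 * t1) / (n * n)
        B = Q1 / n - 2.0 * t1 * t0 / (n * n)
        C = Q0 / n - (t0 * t0) / (n * n)
        if A > 0:
            x = min(max(-B / (2.0 * A), 0.0), L)
        else:  # flat or concave (degenerate lengths): compare endpoints
            x = 0.0 if C <= A * L * L + B * L + C else L
        var = A * x * x + B * x + C
        names = tuple(sorted(_leaf_name(leaf) for leaf, _ in v_side))
        alt = tuple(sorted(_leaf_name(leaf) for leaf, _ in u_side))
        key = (min(names, alt), x)
        if (
            best is None
            or var < best[0] - 1e-12
            or (var <= best[0] + 1e-12 and key < best[1])
        ):
            best = (var, key, u, v, L, x)

    assert best is not None
    _, _, u, v, L, x = best
    root = TreeNode()
    root.add_child(_build_subtree(v, u, adjacency, x))
    root.add_child(_build_subtree(u, v, adjacency, L - x))
    return GeneTree(root)


def root_to_tip_variance(tree: GeneTree) -> float:
    """Variance (population) of root-to-leaf path lengths."""
    dists = []

    def walk(node: TreeNode, acc: float) -> None:
        if node.is_leaf:
            dists.append(acc)
        for child in node.children:
            walk(child, acc + child.length)

    walk(tree.root, 0.0)
    return float(np.var(dists))


# -- long-branch pruning -------------------------------------------------------


@dataclass
class PruneReport:
    """What long-branch pruning removed and the threshold it used."""

    removed: list[tuple[LeafLabel, float]] = field(default_factory=list)
    mean_branch_length: float = 0.0
    threshold_factor: float = 50.0


def prune_long_branches(
    tree: GeneTree, factor: float = 50.0, iterative: bool = False
) -> tuple[GeneTree, PruneReport]:
    """Drop leaves whose pendant branch is >= ``factor`` x mean branch length.

    The mean is taken over ALL branches of the input tree (pendant and
    internal) in a single pass; with ``iterative=True`` the mean is
    recomputed and pruning repeated until stable.  Unary nodes created by
    removal are suppressed with branch lengths summed.  The input tree is
    not modified.
    """
    work = tree.copy()
    report = PruneReport(threshold_factor=factor)
    first_pass = True
    while True:
        branches = [n.length for n in work.postorder() if n.parent is not None]
        mean = sum(branches) / len(branches) if branches else 0.0
        if first_pass:
            report.mean_branch_length = mean
            first_pass = False
        threshold = factor * mean
        victims = [
            leaf for leaf in work.leaves() if mean > 0 and leaf.length >= threshold
        ]
        if len(victims) >= work.n_leaves:
            raise AllLeavesRemovedError(
                "long-branch pruning would remove every leaf; check branch lengths"
            )
        for leaf in victims:
            report.removed.append((leaf.label, leaf.length))
            leaf.detach()
        work.suppress_unary()
        if not victims or not iterative:
            break
    return work, report


# -- alignment trimming --------------------------------------------------------


@dataclass
class Msa:
    """An aligned set of amino-acid sequences (gap characters ``-`` and ``.``)."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.records:
            lengths = {len(seq) for _, seq in self.records}
            if len(lengths) > 1:
                raise EmptyAlignmentError("sequences have unequal aligned lengths")
            ids = [rid for rid, _ in self.records]
            if len(set(ids)) != len(ids):
                raise EmptyAlignmentError("duplicate sequence ids in alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0


def read_msa(path: str | Path) -> Msa:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return Msa(records)


def write_msa(msa: Msa, path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in msa.records),
        str(path),
        "fasta",
    )


def trim_alignment(
    msa: Msa, max_gap_fraction: float = 0.9
) -> tuple[Msa, list[int]]:
    """Remove columns whose gap fraction is strictly greater than the cutoff.

    A column with gap content exactly at the cutoff (e.g. 9 gaps in 10
    sequences at 0.9) is kept.  Returns the trimmed alignment and the
    0-based indices of removed columns; idempotent.
    """
    if not msa.records or msa.n_columns == 0:
        raise EmptyAlignmentError("cannot trim an empty alignment")
    arr = np.array([list(seq) for _, seq in msa.records])
    is_gap = np.isin(arr, list(GAP_CHARS))
    gap_frac = is_gap.mean(axis=0)
    removed = np.nonzero(gap_frac > max_gap_fraction)[0]
    keep = np.nonzero(gap_frac <= max_gap_fraction)[0]
    trimmed = Msa(
        [(rid, "".join(arr[i, keep])) for i, (rid, _) in enumerate(msa.records)]
    )
    return trimmed, [int(i) for i in removed]
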