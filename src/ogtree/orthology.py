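"""Speciation/duplication calling with taxonomic-outlier-tolerant scoring.

Every internal node of a rooted, LCA-annotated gene tree is scored with
the species-overlap (SO) statistic: the species shared between two child
clades divided by their species union.  A node is called a duplication
when SO >= 10% (all threshold comparisons here are inclusive).

Before scoring, a two-step outlier exclusion makes the call tolerant to
misplaced sequences (long-branch attraction, horizontal transfer):

1. the *reference LCA* of the node is the deepest taxon whose lineage
   covers >= 90% of the node's sequences;
2. each sequence outside that reference lineage is a candidate outlier;
   it is excluded (for this node's score only) if any taxon on its species
   lineage — the taxonomy root excepted — is overwhelmingly represented
   outside the node (>= 95% of that taxon's sequences in the whole tree
   are external).

Exclusion is temporary: outliers remain members of any orthologous group
the node seeds; only the event call at the node being scored is affected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import DegenerateNodeError
from .taxonomy import TaxonomyTable
from .tree import GeneTree, LeafLabel, TreeNode

__all__ = [
    "ThresholdConfig",
    "NodeAnnotation",
    "SPECIATION",
    "DUPLICATION",
    "LEAF",
    "species_overlap",
    "reference_lca",
    "detect_outliers",
    "annotate_events",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"
LEAF = "leaf"


@dataclass(frozen=True)
class ThresholdConfig:
    """All tunable thresholds of the delineation algorithm.

    Defaults are the published operating point: SO >= 0.10 calls a
    duplication, the reference lineage must cover >= 90% of a node's
    sequences, an outlier's lineage must be >= 95% external, duplication
    nodes must hold >= 70% of their reference-lineage sequences to be
    retained, and pendant branches >= 50x the mean are pruned.
    """

    so_duplication_threshold: float = 0.10
    reference_lca_coverage: float = 0.90
    outlier_external_fraction: float = 0.95
    duplication_retention_fraction: float = 0.70
    long_branch_factor: float = 50.0
    # behavioral switches (defaults follow the single-pass reading)
    multifurcation_mode: str = "max"  # or "mean": aggregate of pairwise scores
    outlier_lineage_includes_species: bool = True
    outlier_detection: bool = True

    def __post_init__(self) -> None:
        for name in (
            "so_duplication_threshold",
            "reference_lca_coverage",
            "outlier_external_fraction",
            "duplication_retention_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.long_branch_factor <= 0:
            raise ValueError("long_branch_factor must be > 0")
        if self.multifurcation_mode not in ("max", "mean"):
            raise ValueError("multifurcation_mode must be 'max' or 'mean'")


@dataclass
class NodeAnnotation:
    """Event call and scoring context for one tree node."""

    event: str
    so_score: float = 0.0
    reference_lca: str = ""
    outliers: frozenset[LeafLabel] = field(default_factory=frozenset)


def _child_species_sets(
    node: TreeNode, excluded: frozenset[LeafLabel]
) -> list[set[str]]:
    sets = []
    for child in node.children:
        species = {
            leaf.label.species
            for leaf in child.leaves()
            if leaf.label not in excluded
        }
        sets.append(species)
    return sets


def species_overlap(
    node: TreeNode,
    excluded: frozenset[LeafLabel] = frozenset(),
    multifurcation_mode: str = "max",
) -> float:
    """Species-overlap score of an internal node after outlier exclusion.

    For a bifurcation: |S_a & S_b| / |S_a | S_b| over the child species
    sets.  Multifurcations take the maximum (default) or mean pairwise
    score.  Raises :class:`DegenerateNodeError` when any child loses all
    its leaves to exclusion; callers treat such nodes as speciations.
    """
    if node.is_leaf or len(node.children) < 2:
        raise DegenerateNodeError("species overlap requires >=2 child clades")
    sets = _child_species_sets(node, excluded)
    if any(not s for s in sets):
        raise DegenerateNodeError(
            "a child clade retains no leaves after outlier exclusion"
        )
    scores = [
        len(a & b) / len(a | b) for a, b in itertools.combinations(sets, 2)
    ]
    if multifurcation_mode == "mean":
        return sum(scores) / len(scores)
    return max(scores)


def reference_lca(
    node: TreeNode, table: TaxonomyTable, coverage: float = 0.90
) -> str:
    """Deepest taxon whose lineage covers >= ``coverage`` of the node's leaves.

    Counted over sequences (leaves), not distinct species.  The taxonomy
    root always qualifies, so the result is defined for every node.  Ties
    at equal depth are broken by higher coverage, then taxon id.
    """
    leaves = node.leaves()
    n = len(leaves)
    counts: dict[str, int] = {}
    for leaf in leaves:
        for t in table.lineage(leaf.label.species):
            counts[t] = counts.get(t, 0) + 1
    best = table.root_id
    best_key = (1, n, "")
    for t, c in counts.items():
        if c / n >= coverage:
            key = (table.depth(t), c, t)
            if key > best_key:
                best = t
                best_key = key
    return best


def _tree_taxon_counts(tree: GeneTree, table: TaxonomyTable) -> dict[str, int]:
    """For every taxon, how many tree leaves carry it on their species lineage."""
    counts: dict[str, int] = {}
    for leaf in tree.leaves():
        for t in table.lineage(leaf.label.species):
            counts[t] = counts.get(t, 0) + 1
    return counts


def detect_outliers(
    node: TreeNode,
    tree: GeneTree,
    table: TaxonomyTable,
    config: ThresholdConfig = ThresholdConfig(),
    node_reference_lca: str | None = None,
    tree_counts: dict[str, int] | None = None,
) -> frozenset[LeafLabel]:
    """Leaves to exclude (temporarily) from this node's SO score.

    Candidates are the node's leaves whose species lineage does not contain
    the node's reference LCA.  A candidate is an outlier iff some taxon on
    its species lineage (taxonomy root excluded; the species itself
    included by default) has >= ``outlier_external_fraction`` of its
    tree-wide sequences OUTSIDE the node.  Candidates are judged
    independently, in one pass.
    """
    ref = (
        node_reference_lca
        if node_reference_lca is not None
        else reference_lca(node, table, config.reference_lca_coverage)
    )
    totals = tree_counts if tree_counts is not None else _tree_taxon_counts(tree, table)

    node_leaves = node.leaves()
    inside: dict[str, int] = {}
    for leaf in node_leaves:
        for t in table.lineage(leaf.label.species):
            inside[t] = inside.get(t, 0) + 1

    outliers: set[LeafLabel] = set()
    for leaf in node_leaves:
        lineage = table.lineage(leaf.label.species)
        if ref in lineage:
            continue
        candidate_taxa = lineage[1:]  # skip the taxonomy root
        if not config.outlier_lineage_includes_species:
            candidate_taxa = candidate_taxa[:-1]
        for t in candidate_taxa:
            total = totals[t]
            external = total - inside.get(t, 0)
            if total > 0 and external / total >= config.outlier_external_fraction:
                outliers.add(leaf.label)
                break
    return frozenset(outliers)


def annotate_events(
    tree: GeneTree, table: TaxonomyTable, config: ThresholdConfig = ThresholdConfig()
) -> GeneTree:
    """Call speciation/duplication on every internal node, in post-order.

    Requires a rooted tree with node LCAs annotated
    (:func:`ogtree.tree.annotate_node_lcas`).  Each internal node gets a
    :class:`NodeAnnotation` with its event, SO score, reference LCA and the
    outliers excluded from its score.  Unscorable nodes (a child emptied by
    exclusion) default to speciation with score 0: duplication calls
    require positive evidence.  Modifies the tree in place and returns it.
    """
    tree_counts = _tree_taxon_counts(tree, table)
    for node in tree.postorder():
        if node.is_leaf:
            node.annotation = NodeAnnotation(
                event=LEAF, reference_lca=node.label.species
            )
            continue
        ref = reference_lca(node, table, config.reference_lca_coverage)
        if config.outlier_detection:
            outliers = detect_outliers(
                node,
                tree,
                table,
                config,
                node_reference_lca=ref,
                tree_counts=tree_counts,
            )
        else:
            outliers = frozenset()
        try:
            score = species_overlap(node, outliers, config.multifurcation_mode)
            event = (
                DUPLICATION
                if score >= config.so_duplication_threshold
                else SPECIATION
            )
        except DegenerateNodeError:
            score = 0.0
            event = SPECIATION
        node.annotation = NodeAnnotation(
            event=event, so_score=score, reference_lca=ref, outliers=outliers
        )
    return tree
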