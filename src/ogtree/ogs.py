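"""Orthologous-group delineation from an event-annotated gene tree.

Because every OG of a family is cut out of the same tree, the resulting
set is hierarchically consistent by construction: any two OGs are either
disjoint or nested.  OG seeds are the tree root plus the children of
every *retained* duplication node — a duplication is retained only if it
holds >= 70% of all tree sequences belonging to its reference lineage,
which suppresses spurious splits driven by a handful of misplaced
sequences.  Each OG is dated with the species LCA of its members, giving
the taxonomic level at which the group originated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import UnknownLeafError
from .orthology import DUPLICATION, SPECIATION, ThresholdConfig
from .taxonomy import TaxonomyTable
from .tree import GeneTree, LeafLabel, TreeNode

__all__ = [
    "OrthologousGroup",
    "OgSet",
    "retained_duplications",
    "extract_ogs",
    "basal_ogs",
    "pairwise_orthologs",
]


@dataclass
class OrthologousGroup:
    """One OG: members, taxonomic dating, and its place in the hierarchy."""

    og_id: str
    members: frozenset[LeafLabel]
    level: str  # taxon-id of the evolutionary origin
    source_node: Optional[TreeNode] = None
    parent_og: Optional[str] = None
    family_id: str = "fam"

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class OgSet:
    """All OGs delineated from one family tree."""

    ogs: list[OrthologousGroup] = field(default_factory=list)
    basal_ids: frozenset[str] = frozenset()
    family_id: str = "fam"

    def __iter__(self):
        return iter(self.ogs)

    def __len__(self) -> int:
        return len(self.ogs)

    def by_id(self, og_id: str) -> OrthologousGroup:
        for og in self.ogs:
            if og.og_id == og_id:
                return og
        raise KeyError(og_id)

    def basal(self) -> list[OrthologousGroup]:
        return [og for og in self.ogs if og.og_id in self.basal_ids]

    def finest_partition(self) -> list[frozenset[LeafLabel]]:
        """Partition of leaves into their smallest containing OGs.

        Each leaf is assigned to the smallest OG containing it; the
        resulting blocks partition the family's leaf set and represent the
        finest orthology resolution of the hierarchy.
        """
        ordered = sorted(self.ogs, key=lambda og: og.size)
        assigned: dict[LeafLabel, str] = {}
        for og in ordered:
            for member in og.members:
                assigned.setdefault(member, og.og_id)
        blocks: dict[str, set[LeafLabel]] = {}
        for member, og_id in assigned.items():
            blocks.setdefault(og_id, set()).add(member)
        return [frozenset(b) for b in blocks.values()]

    def membership(self, basal_only: bool = False) -> dict[str, str]:
        """protein -> og_id map (smallest containing OG; or basal OG only)."""
        mapping: dict[str, str] = {}
        source = self.basal() if basal_only else sorted(self.ogs, key=lambda og: og.size)
        for og in source:
            for member in og.members:
                mapping.setdefault(str(member), og.og_id)
        return mapping

    def to_frame(self, table: Optional[TaxonomyTable] = None) -> pd.DataFrame:
        rows = []
        for og in self.ogs:
            rows.append(
                {
                    "og_id": og.og_id,
                    "family_id": og.family_id,
                    "level_taxid": og.level,
                    "level_name": table.name(og.level) if table else og.level,
                    "parent_og": og.parent_og or "",
                    "is_basal": og.og_id in self.basal_ids,
                    "n_members": og.size,
                    "members": ",".join(sorted(str(m) for m in og.members)),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "og_id",
                "family_id",
                "level_taxid",
                "level_name",
                "parent_og",
                "is_basal",
                "n_members",
                "members",
            ],
        )


def retained_duplications(
    tree: GeneTree,
    table: TaxonomyTable,
    config: ThresholdConfig = ThresholdConfig(),
) -> set[int]:
    """Duplication nodes that hold enough of their reference lineage.

    A duplication node with reference LCA ``r`` is retained iff the leaves
    under it whose species lineage contains ``r`` make up at least
    ``duplication_retention_fraction`` of ALL such leaves in the whole
    tree.  Returns ``id()`` keys of the retained nodes.  Requires the tree
    to be annotated by :func:`ogtree.orthology.annotate_events`.
    """
    retained: set[int] = set()
    all_leaves = tree.leaves()

    for node in tree.postorder():
        ann = node.annotation
        if ann is None or ann.event != DUPLICATION:
            continue
        r = ann.reference_lca
        under = sum(
            1 for leaf in node.leaves() if r in table.lineage_set(leaf.label.species)
        )
        total = sum(
            1 for leaf in all_leaves if r in table.lineage_set(leaf.label.species)
        )
        if total > 0 and under / total >= config.duplication_retention_fraction:
            retained.add(id(node))
    return retained


def extract_ogs(
    tree: GeneTree,
    table: TaxonomyTable,
    config: ThresholdConfig = ThresholdConfig(),
    family_id: str = "fam",
) -> OgSet:
    """Delineate the hierarchically consistent OG set of one family tree.

    Seeds are (a) the root — a family always has a root OG, even when the
    root itself is a retained duplication — and (b) every child of every
    retained duplication node.  An OG's members are ALL leaves under its
    seed; nesting is expressed through ``parent_og`` links, not by member
    exclusion, so outlier leaves stay members of every OG that spans them.
    Levels are the species LCA of the members.  Non-retained duplications
    create no OG boundary.  og_ids are ``<family>@<level>@<ordinal>`` with
    ordinals assigned in pre-order, hence deterministic.
    """
    retained = retained_duplications(tree, table, config)

    ogs: list[OrthologousGroup] = []
    counter = 0

    def make_og(node: TreeNode, parent_id: Optional[str]) -> OrthologousGroup:
        nonlocal counter
        members = frozenset(leaf.label for leaf in node.leaves())
        level = table.lca({m.species for m in members})
        og = OrthologousGroup(
            og_id=f"{family_id}@{level}@{counter}",
            members=members,
            level=level,
            source_node=node,
            parent_og=parent_id,
            family_id=family_id,
        )
        counter += 1
        ogs.append(og)
        return og

    def walk(node: TreeNode, enclosing_id: str) -> None:
        # pre-order: a retained duplication seeds one OG per child
        if id(node) in retained:
            for child in node.children:
                child_og = make_og(child, enclosing_id)
                walk(child, child_og.og_id)
        else:
            for child in node.children:
                walk(child, enclosing_id)

    root_og = make_og(tree.root, None)
    walk(tree.root, root_og.og_id)

    basal = frozenset(og.og_id for og in ogs if og.parent_og is None)
    return OgSet(ogs=ogs, basal_ids=basal, family_id=family_id)


def basal_ogs(ogset: OgSet) -> list[OrthologousGroup]:
    """OGs contained in no other OG of the same family (no parent link)."""
    return [og for og in ogset.ogs if og.parent_og is None]


def pairwise_orthologs(
    tree: GeneTree, query: LeafLabel
) -> list[tuple[LeafLabel, str, str]]:
    """Orthology relation of a query leaf to every other leaf of its tree.

    The relation is decided by the event at the tree-LCA of the pair:
    speciation -> ortholog, duplication -> in-paralog.  The third element
    is the species LCA of the mediating node (the taxonomic scope of the
    relation).  The tree must be event-annotated and LCA-annotated.
    """
    query_node = tree.find_leaf(query)
    if query_node is None:
        raise UnknownLeafError(f"leaf {query} not found in tree")
    out: list[tuple[LeafLabel, str, str]] = []
    for leaf in tree.leaves():
        if leaf is query_node:
            continue
        mediator = tree.lca_node(query_node, leaf)
        ann = mediator.annotation
        event = ann.event if ann is not None else SPECIATION
        relation = "in-paralog" if event == DUPLICATION else "ortholog"
        out.append((leaf.label, relation, mediator.lca or ""))
    return out
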