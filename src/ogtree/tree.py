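"""Gene-tree container: parsing, annotation and Newick serialization.

Leaves follow the ``<species-taxid><sep><protein-id>`` naming convention
common to orthology databases (``9606.ENSP...``); the label is split at the FIRST
separator occurrence so protein identifiers may themselves contain the
separator.  Multifurcations are preserved.  Newick parsing is delegated to
dendropy; serialization is done here so event calls, per-node species LCAs
and species-overlap scores can be emitted as NHX comment tags
(``[&&NHX:Ev=D:LCA=<taxid>:SO=<float>]``).
"""

from __future__ import annotations

import itertools
from typing import Any, Iterator, NamedTuple, Optional

import dendropy

from .errors import LeafLabelError, NewickParseError, UnknownSpeciesError
from .taxonomy import TaxonomyTable

__all__ = [
    "LeafLabel",
    "TreeNode",
    "GeneTree",
    "parse_newick",
    "write_newick",
    "annotate_node_lcas",
]


class LeafLabel(NamedTuple):
    """Species taxon-id plus protein identifier of one gene-tree leaf."""

    species: str
    protein: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.species}.{self.protein}"


class TreeNode:
    """One node of a gene tree.

    ``length`` is the branch length to the parent (0 at the root and for
    missing lengths).  Leaves carry a :class:`LeafLabel`; internal nodes may
    carry a name/support string.  ``species_set``/``lca`` are filled by
    :func:`annotate_node_lcas`, ``annotation`` by event annotation.
    """

    __slots__ = (
        "children",
        "parent",
        "length",
        "name",
        "label",
        "species_set",
        "lca",
        "annotation",
    )

    def __init__(
        self,
        length: float = 0.0,
        label: Optional[LeafLabel] = None,
        name: str = "",
    ):
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None
        self.length: float = length
        self.name: str = name
        self.label = label
        self.species_set: Optional[frozenset[str]] = None
        self.lca: Optional[str] = None
        self.annotation: Any = None

    # -- structure ------------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "TreeNode":
        """Remove this node (and its subtree) from its parent."""
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def ancestors(self) -> Iterator["TreeNode"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def copy(self) -> "TreeNode":
        """Deep structural copy; annotations are carried over by reference."""
        dup = TreeNode(length=self.length, label=self.label, name=self.name)
        dup.species_set = self.species_set
        dup.lca = self.lca
        dup.annotation = self.annotation
        for child in self.children:
            dup.add_child(child.copy())
        return dup


class GeneTree:
    """A rooted gene tree (binary or multifurcating) with species-tagged leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.root.parent = None
        self.root.length = self.root.length or 0.0

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_labels(self) -> list[LeafLabel]:
        return [n.label for n in self.leaves()]

    def species(self) -> set[str]:
        return {n.label.species for n in self.leaves()}

    def find_leaf(self, label: LeafLabel) -> Optional[TreeNode]:
        for n in self.leaves():
            if n.label == label:
                return n
        return None

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy())

    def lca_node(self, a: TreeNode, b: TreeNode) -> TreeNode:
        """Lowest common ancestor of two nodes of this tree."""
        seen = {id(a)}
        seen.update(id(x) for x in a.ancestors())
        if id(b) in seen:
            return b
        for node in b.ancestors():
            if id(node) in seen:
                return node
        raise ValueError("nodes do not share a root")

    def suppress_unary(self) -> None:
        """Collapse single-child internal nodes, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                child.length += node.length
                if node.parent is None:
                    child.parent = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                changed = True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneTree({self.n_leaves} leaves)"


# -- Newick I/O ----------------------------------------------------------------


def parse_newick(text: str, label_separator: str = ".") -> GeneTree:
    """Parse a Newick string into a :class:`GeneTree`.

    Leaf names are split into (species, protein) at the first occurrence of
    ``label_separator``.  Missing branch lengths become 0; internal node
    labels/supports are stored but unused downstream.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"invalid Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> TreeNode:
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if dnode.is_leaf():
            raw = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
            if label_separator not in raw:
                raise LeafLabelError(
                    f"leaf {raw!r} lacks the label separator {label_separator!r}"
                )
            species, protein = raw.split(label_separator, 1)
            if not species or not protein:
                raise LeafLabelError(f"leaf {raw!r} has an empty species or protein part")
            return TreeNode(length=length, label=LeafLabel(species, protein))
        node = TreeNode(length=length, name=str(dnode.label) if dnode.label else "")
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    tree = GeneTree(root)
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        dupes = [str(l) for l, c in itertools.groupby(sorted(labels)) if len(list(c)) > 1]
        raise LeafLabelError(f"duplicate leaf labels: {dupes[:5]}")
    return tree


def _fmt_length(x: float) -> str:
    return f"{x:.10g}"


def _nhx_tag(node: TreeNode) -> str:
    ann = node.annotation
    if ann is None:
        return ""
    parts = []
    event = getattr(ann, "event", None)
    if event in ("duplication", "speciation"):
        parts.append(f"Ev={'D' if event == 'duplication' else 'S'}")
    if getattr(ann, "reference_lca", None):
        parts.append(f"LCA={ann.reference_lca}")
    so = getattr(ann, "so_score", None)
    if so is not None and event in ("duplication", "speciation"):
        parts.append(f"SO={so:.6g}")
    return f"[&&NHX:{':'.join(parts)}]" if parts else ""


def write_newick(
    tree: GeneTree, with_annotations: bool = False, label_separator: str = "."
) -> str:
    """Serialize to Newick; round-trips through :func:`parse_newick`.

    With ``with_annotations`` each annotated internal node carries an NHX
    comment tag with its event call (``Ev=D``/``Ev=S``), reference LCA and
    species-overlap score.
    """

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            name = f"{node.label.species}{label_separator}{node.label.protein}"
            s = f"{name}:{_fmt_length(node.length)}"
        else:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner}){node.name}"
            if node.parent is not None:
                s += f":{_fmt_length(node.length)}"
        if with_annotations:
            s += _nhx_tag(node)
        return s

    return fmt(tree.root) + ";"


# -- taxonomic annotation ------------------------------------------------------


def annotate_node_lcas(tree: GeneTree, table: TaxonomyTable) -> GeneTree:
    """Store on every node the species set and species-LCA of its leaves.

    Modifies the tree in place and returns it.  Raises
    :class:`UnknownSpeciesError` listing every leaf whose species taxon is
    absent from the table.
    """
    unknown = sorted(
        {str(n.label) for n in tree.leaves() if n.label.species not in table}
    )
    if unknown:
        raise UnknownSpeciesError(f"leaf species not in taxonomy: {unknown[:10]}")
    for node in tree.postorder():
        if node.is_leaf:
            node.species_set = frozenset((node.label.species,))
        else:
            acc: set[str] = set()
            for child in node.children:
                acc.update(child.species_set)
            node.species_set = frozenset(acc)
        node.lca = table.lca(node.species_set)
    return tree
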