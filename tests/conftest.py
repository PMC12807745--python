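"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import ogtree as og


@pytest.fixture
def flat_tax() -> og.TaxonomyTable:
    """Flat taxonomy: species s1..s10 directly under root r."""
    parents = {"r": "r"}
    parents.update({f"s{i}": "r" for i in range(1, 11)})
    return og.TaxonomyTable.from_parent_map(parents)


@pytest.fixture
def textbook_tree(flat_tax) -> og.GeneTree:
    """((s1.a,s2.a),(s1.b,s2.b)) — root duplication, two speciation children."""
    tree = og.parse_newick("((s1.a:1,s2.a:1):1,(s1.b:1,s2.b:1):1);")
    og.annotate_node_lcas(tree, flat_tax)
    og.annotate_events(tree, flat_tax)
    return tree


def random_taxonomy(rng: np.random.Generator, n_taxa: int) -> og.TaxonomyTable:
    """Random parent-pointer tree: taxon t{i} attaches under a lower-index taxon."""
    parents = {"t0": "t0"}
    for i in range(1, n_taxa):
        parents[f"t{i}"] = f"t{int(rng.integers(i))}"
    return og.TaxonomyTable.from_parent_map(parents)


def brute_force_lca(table: og.TaxonomyTable, taxids) -> str:
    """Independent LCA oracle: deepest member of the lineage-set intersection."""
    common = None
    for t in taxids:
        s = set(table.lineage(t))
        common = s if common is None else common & s
    return max(common, key=lambda t: len(table.lineage(t)))


def topology_signature(node: og.TreeNode, with_lengths: bool = True):
    """Canonical, rotation-invariant signature for isomorphism checks."""
    if node.is_leaf:
        base = ("leaf", str(node.label))
    else:
        base = ("node", tuple(
            sorted(topology_signature(c, with_lengths) for c in node.children)
        ))
    # serialization carries 10 significant digits; compare well inside that
    return (base, round(node.length, 6)) if with_lengths else base


def duplication_signatures(tree: og.GeneTree) -> set[frozenset]:
    """Leaf-set signatures of nodes called duplications."""
    return {
        frozenset(leaf.label for leaf in n.leaves())
        for n in tree.internal_nodes()
        if n.annotation is not None and n.annotation.event == og.DUPLICATION
    }


def annotated_copy(
    gene_tree: og.GeneTree,
    taxonomy: og.TaxonomyTable,
    config: og.ThresholdConfig = og.ThresholdConfig(),
) -> og.GeneTree:
    """Annotate a working copy (LCAs + events) without touching the input."""
    work = gene_tree.copy()
    og.annotate_node_lcas(work, taxonomy)
    og.annotate_events(work, taxonomy, config)
    return work
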