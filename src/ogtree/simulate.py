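"""Gene-family simulator with ground-truth event labels.

The generator produces the three inputs the delineation pipeline needs —
a species tree, a taxonomy mirroring it, and gene trees — plus the truth
against which inference is judged:

* species tree: pure-birth (Yule) process run to ``n_species`` tips; the
  taxonomy lists every tree node as a taxon (internal nodes are ancestral
  taxa), so species lineages are perfectly consistent with the tree;
* gene tree: a birth-death (duplication/loss) walk down the species
  tree.  Duplications fork a gene lineage in place, losses terminate it;
  both are Poisson processes per lineage per unit branch length.  Every
  duplication whose two daughter lineages survive to the tips is an
  internal node of the emitted tree and is recorded as ground truth;
* noise: leaf transplants (detach a leaf, re-attach it inside a foreign
  speciation clade — emulating horizontal transfer or long-branch
  attraction artifacts) and pendant-branch inflation (emulating rate
  artifacts caught by long-branch pruning).

All randomness derives from ``SimulationConfig.seed``; a fixed config
yields byte-identical Newick output.  True duplication nodes carry the
internal node name ``"D"`` so ground truth survives serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import AllLineagesLostError, ConfigError
from .taxonomy import TaxonEntry, TaxonomyTable
from .tree import GeneTree, LeafLabel, TreeNode

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_species_tree",
    "simulate_gene_tree",
    "inject_noise",
    "simulate_family",
]

TRUE_DUP_MARK = "D"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated gene family.

    Rates are events per lineage per unit time; species-tree branch
    lengths are in the same time units.  ``branch_inflation`` is
    (fraction of leaves, multiplier) applied to pendant branches.
    """

    n_species: int = 20
    species_birth_rate: float = 1.0
    duplication_rate: float = 0.1
    loss_rate: float = 0.0
    n_noise_transplants: int = 0
    branch_inflation: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if self.species_birth_rate <= 0:
            raise ConfigError("species_birth_rate must be > 0")
        for name in ("duplication_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_noise_transplants < 0:
            raise ConfigError("n_noise_transplants must be >= 0")
        frac, mult = self.branch_inflation
        if not 0.0 <= frac <= 1.0 or mult < 0:
            raise ConfigError("branch_inflation must be (fraction in [0,1], multiplier >= 0)")


@dataclass
class GroundTruth:
    """What the simulator actually did, for judging inference."""

    duplication_nodes: set[TreeNode] = field(default_factory=set)
    transplanted_leaves: set[LeafLabel] = field(default_factory=set)
    true_og_partition: list[frozenset[LeafLabel]] = field(default_factory=list)

    def duplication_signatures(self) -> set[frozenset[LeafLabel]]:
        """Leaf-set signatures of the true duplication nodes.

        Signatures are evaluated lazily so they stay valid after noise
        operators rearrange the tree.
        """
        return {
            frozenset(leaf.label for leaf in node.leaves())
            for node in self.duplication_nodes
        }


def simulate_species_tree(config: SimulationConfig) -> tuple[GeneTree, TaxonomyTable]:
    """Yule species tree plus a taxonomy mirroring every tree node.

    Species taxa are ``S1..Sn`` (assigned in left-to-right leaf order),
    ancestral taxa ``T1..`` in pre-order, the root taxon is ``root``.
    """
    rng = np.random.default_rng([config.seed, 0])
    root = TreeNode()
    tips: list[TreeNode] = [root]
    while len(tips) < config.n_species:
        k = len(tips)
        wait = rng.exponential(1.0 / (k * config.species_birth_rate))
        for tip in tips:
            tip.length += wait
        idx = int(rng.integers(k))
        splitting = tips.pop(idx)
        left, right = TreeNode(), TreeNode()
        splitting.add_child(left)
        splitting.add_child(right)
        tips.extend([left, right])
    final = rng.exponential(1.0 / (len(tips) * config.species_birth_rate))
    for tip in tips:
        tip.length += final
    root.length = 0.0
    tree = GeneTree(root)

    entries: dict[str, TaxonEntry] = {}
    n_internal = 0
    n_leaf = 0

    def assign(node: TreeNode, parent_taxon: str) -> None:
        nonlocal n_internal, n_leaf
        if node.is_leaf:
            n_leaf += 1
            taxon = f"S{n_leaf}"
            node.label = LeafLabel(species=taxon, protein="sp")
            rank = "species"
        elif node.parent is None:
            taxon = "root"
            rank = "root"
        else:
            n_internal += 1
            taxon = f"T{n_internal}"
            rank = "clade"
        node.name = taxon
        entries[taxon] = TaxonEntry(parent=parent_taxon or taxon, rank=rank, name=taxon)
        for child in node.children:
            assign(child, taxon)

    assign(root, "")
    return tree, TaxonomyTable(entries)


def simulate_gene_tree(
    species_tree: GeneTree,
    taxonomy: TaxonomyTable,
    config: SimulationConfig,
) -> tuple[GeneTree, GroundTruth]:
    """Evolve one gene family down the species tree.

    Returns the surviving gene tree (leaves ``<taxid>.g<k>``) and the
    ground truth: duplication nodes with both daughters surviving, and
    the leaf partition obtained by cutting the tree at those nodes.
    Raises :class:`AllLineagesLostError` when loss kills every lineage.
    """
    rng = np.random.default_rng([config.seed, 1])
    d = config.duplication_rate
    mu = config.loss_rate
    gene_counters: dict[str, int] = {}
    dup_nodes: set[TreeNode] = set()

    def evolve(sp_node: TreeNode, remaining: float) -> Optional[TreeNode]:
        t_dup = rng.exponential(1.0 / d) if d > 0 else math.inf
        t_loss = rng.exponential(1.0 / mu) if mu > 0 else math.inf
        t = min(t_dup, t_loss)
        if t < remaining:
            if t_loss <= t_dup:
                return None
            left = evolve(sp_node, remaining - t)
            right = evolve(sp_node, remaining - t)
            if left is None and right is None:
                return None
            if left is None or right is None:
                survivor = left if left is not None else right
                survivor.length += t
                return survivor
            node = TreeNode(length=t, name=TRUE_DUP_MARK)
            node.add_child(left)
            node.add_child(right)
            dup_nodes.add(node)
            return node
        # the lineage reaches sp_node intact
        if sp_node.is_leaf:
            taxon = sp_node.label.species
            gene_counters[taxon] = gene_counters.get(taxon, 0) + 1
            return TreeNode(
                length=remaining,
                label=LeafLabel(species=taxon, protein=f"g{gene_counters[taxon]}"),
            )
        kids = [evolve(child, child.length) for child in sp_node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += remaining
            return kids[0]
        node = TreeNode(length=remaining)
        for k in kids:
            node.add_child(k)
        return node

    gene_root = evolve(species_tree.root, 0.0)
    if gene_root is None:
        raise AllLineagesLostError("all gene lineages were lost; retry with a new seed")
    gene_root.length = 0.0
    tree = GeneTree(gene_root)
    truth = GroundTruth(duplication_nodes=dup_nodes)
    truth.true_og_partition = _partition_at(tree, dup_nodes)
    return tree, truth


def _partition_at(
    tree: GeneTree, cut_nodes: set[TreeNode]
) -> list[frozenset[LeafLabel]]:
    """Leaf blocks obtained by cutting the tree below each cut node."""
    cut_ids = {id(n) for n in cut_nodes}
    blocks: list[set[LeafLabel]] = []

    def walk(node: TreeNode, current: set[LeafLabel]) -> None:
        if node.is_leaf:
            current.add(node.label)
            return
        if id(node) in cut_ids:
            for child in node.children:
                fresh: set[LeafLabel] = set()
                blocks.append(fresh)
                walk(child, fresh)
        else:
            for child in node.children:
                walk(child, current)

    first: set[LeafLabel] = set()
    blocks.append(first)
    walk(tree.root, first)
    return [frozenset(b) for b in blocks if b]


def inject_noise(
    tree: GeneTree, truth: GroundTruth, config: SimulationConfig
) -> tuple[GeneTree, GroundTruth]:
    """Apply leaf transplants and pendant-branch inflation in place.

    Each transplant detaches a uniformly chosen leaf and re-attaches it at
    the midpoint of the branch above a uniformly chosen foreign speciation
    clade (an internal non-duplication node that is neither the root nor
    an ancestor of the leaf).  The leaf multiset is conserved.  True
    duplication nodes dissolved by the detachment (their other daughter
    was the transplanted leaf) are dropped from the ground truth.
    """
    rng = np.random.default_rng([config.seed, 2])
    for _ in range(config.n_noise_transplants):
        leaves = tree.leaves()
        if len(leaves) < 3:
            break
        leaf = leaves[int(rng.integers(len(leaves)))]
        parent = leaf.parent
        leaf.detach()
        _suppress_upwards(tree, parent, truth)
        # the leaf is now outside the tree, so every remaining speciation
        # clade is foreign to it
        targets = [
            n
            for n in tree.postorder()
            if not n.is_leaf
            and n is not tree.root
            and n not in truth.duplication_nodes
        ]
        if not targets:
            # re-attach at the root to conserve the leaf multiset
            tree.root.add_child(leaf)
            continue
        target = targets[int(rng.integers(len(targets)))]
        # split the branch above the target at its midpoint
        grand = target.parent
        joint = TreeNode(length=target.length / 2.0)
        target.length = target.length / 2.0
        idx = grand.children.index(target)
        grand.children[idx] = joint
        joint.parent = grand
        joint.add_child(target)
        joint.add_child(leaf)
        truth.transplanted_leaves.add(leaf.label)

    frac, mult = config.branch_inflation
    if frac > 0 and mult != 1.0:
        leaves = tree.leaves()
        k = int(round(frac * len(leaves)))
        if k > 0:
            chosen = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False)
            for i in sorted(int(c) for c in chosen):
                leaves[i].length *= mult
    return tree, truth


def _suppress_upwards(tree: GeneTree, node: Optional[TreeNode], truth: GroundTruth) -> None:
    """Collapse a node left unary by a detachment; update ground truth."""
    while node is not None and len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        truth.duplication_nodes.discard(node)
        if node.parent is None:
            child.parent = None
            child.length = 0.0
            tree.root = child
            node = None
        else:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
            node = parent


def simulate_family(
    config: SimulationConfig,
) -> tuple[GeneTree, TaxonomyTable, GeneTree, GroundTruth]:
    """Convenience wrapper: species tree, taxonomy, noisy gene tree, truth.

    Gene-family simulation retries with derived seeds if every lineage is
    lost (only possible with a positive loss rate).
    """
    species_tree, taxonomy = simulate_species_tree(config)
    attempt = config
    for retry in range(50):
        try:
            gene_tree, truth = simulate_gene_tree(species_tree, taxonomy, attempt)
            break
        except AllLineagesLostError:
            attempt = replace(attempt, seed=attempt.seed + 1_000_003 * (retry + 1))
    else:
        raise AllLineagesLostError(
            "all lineages lost in 50 consecutive attempts; lower loss_rate"
        )
    gene_tree, truth = inject_noise(gene_tree, truth, attempt)
    return species_tree, taxonomy, gene_tree, truth
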