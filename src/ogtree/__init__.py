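"""ogtree: noise-tolerant orthologous-group delineation from gene trees.

The pipeline: MinVar-root a gene tree, prune long-branch leaves, annotate
per-node species LCAs against a taxonomy, call speciation/duplication
events with the outlier-tolerant species-overlap score, and cut the tree
into hierarchically consistent, taxonomically dated orthologous groups.
A built-in duplication-loss simulator provides ground-truth test data.
"""

from .errors import (
    AllLeavesRemovedError,
    AllLineagesLostError,
    ConfigError,
    CycleError,
    DegenerateNodeError,
    DegenerateTreeError,
    EmptyAlignmentError,
    LeafLabelError,
    MissingTreeError,
    NewickParseError,
    OgtreeError,
    TaxonomyError,
    TaxonomyParseError,
    UnknownLeafError,
    UnknownSpeciesError,
    UnknownTaxonError,
)
from .metrics import (
    BenchmarkResult,
    DupRateReport,
    GroupScore,
    SizeDistribution,
    duplication_rate,
    fscore_benchmark,
    size_distribution,
)
from .ogs import (
    OgSet,
    OrthologousGroup,
    basal_ogs,
    extract_ogs,
    pairwise_orthologs,
    retained_duplications,
)
from .orthology import (
    DUPLICATION,
    LEAF,
    SPECIATION,
    NodeAnnotation,
    ThresholdConfig,
    annotate_events,
    detect_outliers,
    reference_lca,
    species_overlap,
)
from .preprocessing import (
    Msa,
    PruneReport,
    minvar_root,
    prune_long_branches,
    read_msa,
    root_to_tip_variance,
    trim_alignment,
    write_msa,
)
from .simulate import (
    GroundTruth,
    SimulationConfig,
    inject_noise,
    simulate_family,
    simulate_gene_tree,
    simulate_species_tree,
)
from .taxonomy import TaxonEntry, TaxonomyTable, load_taxonomy
from .tree import (
    GeneTree,
    LeafLabel,
    TreeNode,
    annotate_node_lcas,
    parse_newick,
    write_newick,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def delineate(
    tree: GeneTree,
    table: TaxonomyTable,
    config: ThresholdConfig = ThresholdConfig(),
    family_id: str = "fam",
    root: bool = True,
    prune: bool = True,
) -> tuple[GeneTree, OgSet, PruneReport]:
    """Run the full delineation pipeline on one gene tree.

    Rooting (MinVar), long-branch pruning, LCA annotation, event calling
    and OG extraction, in that order.  Returns the annotated working tree,
    the OG set and the pruning report.  The input tree is left untouched.
    """
    work = tree.copy()
    if root and work.n_leaves >= 2:
        work = minvar_root(work)
    if prune:
        work, report = prune_long_branches(work, factor=config.long_branch_factor)
    else:
        report = PruneReport(threshold_factor=config.long_branch_factor)
    annotate_node_lcas(work, table)
    annotate_events(work, table, config)
    ogset = extract_ogs(work, table, config, family_id=family_id)
    return work, ogset, report
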