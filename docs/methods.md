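# Methods

## Problem setting

A gene-family tree mixes two kinds of internal nodes: speciations
(descendants diverged with their host genomes) and duplications
(descendants are paralogs within genomes). Orthologous groups are
obtained by cutting the tree below duplication events; every error in
event calling therefore propagates into group membership. On automated,
database-scale input — trees inferred from automatic alignments of
families with thousands of sequences — misplaced leaves are common, and
a single stray sequence can make two clades "share" a species and turn
a speciation into a spurious duplication. The pipeline implemented here
is designed around that failure mode.

## Event calling

Let the species sets of a node's two child clades be S_a and S_b. The
species-overlap score SO = |S_a ∩ S_b| / |S_a ∪ S_b| is 0 for a perfect
speciation and 1 for a full duplication; a node is called a duplication
when SO ≥ `so_duplication_threshold` (default 0.10). Multifurcating
nodes are scored as the maximum pairwise child score by default
(`multifurcation_mode="mean"` averages instead); the maximum is the
conservative choice for detecting duplications, since any overlapping
child pair is evidence of paralogy.

Outlier exclusion runs per node, before scoring:

1. *Reference LCA*: the deepest taxon whose lineage covers at least
   `reference_lca_coverage` (0.90) of the node's sequences, counted per
   sequence, not per species. The taxonomy root always qualifies, so the
   reference is always defined; ties (possible only when coverage ≤ 0.5)
   break toward higher coverage, then taxon id.
2. *Candidates* are the node's sequences whose species lineage does not
   contain the reference LCA. A candidate is excluded iff some taxon on
   its species lineage — the taxonomy root excepted, the species itself
   included (`outlier_lineage_includes_species`) — has at least
   `outlier_external_fraction` (0.95) of its tree-wide sequences outside
   the node. The root exception matters: every sequence carries the root
   on its lineage, and for any small node most root-lineage sequences
   are external, so without the exception every candidate would be an
   outlier whenever a node holds under 5% of the tree.

Candidates are judged independently in one pass; the reference LCA is
not recomputed after exclusions. Exclusion is temporary: it affects the
scored node's SO only. A node whose child loses all leaves to exclusion
is unscorable and defaults to speciation with score 0 — duplication
calls require positive evidence. All threshold comparisons are
inclusive (≥), which the boundary tests pin exactly (SO = 1/10,
coverage = 9/10, external = 20/21, retention = 7/10).

## Tree preparation

Trees are rooted by minimum variance: on each edge, root-to-tip
distances are linear in the root offset, so the variance is an exact
convex quadratic minimized in closed form; the global optimum over all
edges is taken, with ties (within 1e-12) broken by the lexicographically
smallest side leaf-name set, then the smaller offset, for determinism.
Rooting precedes long-branch pruning and the tree is not re-rooted
afterwards. Pruning removes leaves whose pendant branch is at least
`long_branch_factor` (50) times the mean over all branches — pendant and
internal — of the input tree, in a single pass (`iterative=True`
recomputes the mean after each round). The factor-50 rule is deliberately
lax: a single 1000-length branch among twenty unit branches survives,
because the outlier itself inflates the mean (1000 < 50 × 50.95).
Alignment-column trimming removes columns whose gap fraction (`-` and
`.`, case-insensitive residues) is strictly greater than 0.9 — a column
with exactly 90% gaps is kept.

## OG extraction and dating

A duplication node with reference LCA r is *retained* iff the sequences
under it whose lineage contains r are at least
`duplication_retention_fraction` (0.70) of all such sequences in the
whole tree (tree-wide denominator; a parent-scoped variant would be a
one-line change but the tree-wide reading matches "all sequences").
Retention suppresses splits driven by small paralogous fragments. OG
seeds are the root — a family always has a root OG, even when the root
itself is a retained duplication — plus every child of every retained
duplication. An OG's members are all leaves under its seed; nesting is
expressed through parent links rather than member exclusion, so outlier
leaves remain members of every OG spanning them. Levels are the species
LCA of the members; ids are `<family>@<level>@<ordinal>` with pre-order
ordinals, hence deterministic. Under these rules any two OGs are nested
or disjoint, and the basal (parentless) OGs partition the family — with
a root OG always present, each family has exactly one basal OG, and
the finest partition (each leaf's smallest containing OG) is the
family's maximal orthology resolution.

Pairwise relations follow from the event at the tree-LCA of a pair:
speciation → ortholog, duplication → in-paralog, reported with the
mediating node's species LCA as the taxonomic scope.

## Metrics

*Duplication rate*: per basal OG, the number of duplication nodes in
its subtree spanning more than one species; single-species duplications
are ignored because they never split orthology across genomes. The mean
over basal OGs is a proxy for in-paralog load.

*Reference-group benchmark*: for reference group K and any OG O sharing
a protein with K, TP = |K ∩ O|, FN = members of K assigned to another
OG, FP = members of O outside K that carry some reference annotation —
unannotated proteins are neither TP nor FP, since a false positive must
come "from a different group". Proteins mapping to several reference
groups are counted independently per group. The best OG per group
maximizes F (ties: larger TP, then lexicographic id); the headline
number is the mean best-F over groups. Comparisons default to basal OGs.

## The simulator

`simulate_species_tree` draws a pure-birth (Yule) species tree
(`species_birth_rate` 1.0/lineage/unit time) to `n_species` tips and
mirrors every tree node into the taxonomy, so species lineages are
perfectly consistent with the tree — taxonomy error is deliberately not
modeled, isolating algorithm behavior. `simulate_gene_tree` runs a
duplication–loss (Gillespie) walk down the species tree: exponential
waiting times at `duplication_rate` and `loss_rate` per lineage per
unit branch length, no rate heterogeneity. Only duplications whose two
daughter lineages both survive become tree nodes; exactly those are
recorded as ground truth, together with the leaf partition obtained by
cutting the tree at them. `inject_noise` detaches uniformly chosen
leaves and re-attaches them at the midpoint of the branch above a
uniformly chosen foreign speciation clade (horizontal-transfer /
long-branch-attraction emulation), and can inflate pendant branches of
a leaf fraction by a multiplier. All randomness derives from one seed
(separate streams per stage), so identical configs give byte-identical
Newick output.

What the simulator does *not* emulate: sequence-level error (trees are
topologically correct except for the injected noise), clade-biased gene
content (rates are homogeneous, so families are taxonomically balanced),
and incomplete species sampling. Passing tests therefore demonstrate
correctness of the algorithm under its stated assumptions, not
robustness to every artifact of real tree inference.

## Study conditions used by the tests and acceptance script

* *Clean recovery*: 100 families, 20 species, duplication rate 0.1, no
  loss, no noise. In this regime detection is exact by construction
  (disjoint children at speciations, full overlap at duplications), so
  precision and recall are asserted at exactly 1.0, and the OG hierarchy
  cut at every duplication (retention disabled) must equal the true
  partition.
* *Noise tolerance*: 100 families of 400–3000 sequences (8 species,
  duplication rate 2.0, loss rate 0.5 — the paralog-rich, prokaryote-like
  regime where species-overlap artifacts actually arise), each with 1–3
  transplanted leaves. False duplication calls are compared with outlier
  exclusion on versus off. The size floor reflects the scale of real
  database families; in small families the exclusion rule simply never
  fires, because no lineage reaches 95% externality.
* *Oracles*: 200 families (≤ 50 leaves) for the SO score against
  brute-force set arithmetic; 50 trees (≤ 30 leaves) for MinVar rooting
  against an exhaustive per-edge scan at 1e-9.

A structural note on noise tolerance: the exclusion rule is
lineage-based, not topology-based. A transplanted leaf whose species is
covered by the meeting node's reference LCA produces no candidate and
its false duplication cannot be rescued; under uniform transplants this
is the majority of cases, so exclusion removes a modest fraction of
false calls (and, by design, never needs to add any in aggregate). The
rescuable scenario — a ≥ 90%-coherent clade invaded by a sequence whose
lineage is ≥ 95% external — requires large families with repeated,
scattered paralogy, which is why the noise study runs in that regime.

## Numerical and degenerate-input choices

Branch lengths are non-negative; missing lengths parse to 0. Newick
serialization uses 10 significant digits and round-trips to isomorphic
trees. Leaf labels split at the first separator occurrence (protein ids
may contain dots). A single-sequence family yields one single-member
basal OG. Empty taxon sets, unknown taxa/leaves, cyclic taxonomies,
all-gap alignments and prunings that would remove every leaf raise
typed errors (`ogtree.errors`). The MinVar quadratic is strictly convex
whenever both edge sides hold a leaf; flat degenerate cases fall back to
endpoint comparison.

## Known limitations

The pipeline consumes precomputed gene trees; alignment, tree inference
and family clustering are out of scope. The outlier rule shares the
blind spot discussed above for misplacements within their own taxonomic
scope. NCBI merged/deleted-taxid resolution is not implemented; the
taxonomy is taken as given.
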