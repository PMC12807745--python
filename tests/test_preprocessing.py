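"""MinVar rooting, long-branch pruning and alignment trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ogtree as og
from ogtree.errors import (
    AllLeavesRemovedError,
    DegenerateTreeError,
    EmptyAlignmentError,
)
from ogtree.preprocessing import root_to_tip_variance


# -- independent MinVar oracle -------------------------------------------------


def _leaf_distances_from(tree, start_node):
    """Path lengths from a node to every leaf, via undirected traversal."""
    # adjacency over the rooted tree viewed as an undirected graph
    adj = {}
    for n in tree.postorder():
        if n.parent is not None:
            adj.setdefault(id(n), []).append((n.parent, n.length))
            adj.setdefault(id(n.parent), []).append((n, n.length))
    out = {}
    stack = [(start_node, None, 0.0)]
    while stack:
        node, prev, dist = stack.pop()
        if node.is_leaf:
            out[id(node)] = dist
        for nbr, L in adj.get(id(node), ()):
            if nbr is not prev:
                stack.append((nbr, node, dist + L))
    return out


def minvar_oracle_variance(tree):
    """Exhaustive per-edge scan: fit the exact variance quadratic from three
    sampled root positions per edge and minimize it in closed form."""
    best = np.inf
    leaves = tree.leaves()
    for child in tree.postorder():
        if child.parent is None:
            continue
        L = child.length
        d_child = _leaf_distances_from(tree, child)
        below = {id(l) for l in child.leaves()}

        # root at offset x from the child end of this edge: below-side
        # leaves are reached directly (d + x), above-side leaves through
        # the parent end (d - L + (L - x))
        def variance(x):
            vals = []
            for leaf in leaves:
                d = d_child[id(leaf)]
                if id(leaf) in below:
                    vals.append(d + x)
                else:
                    # d includes the full edge L; root sits x from child
                    vals.append(d - L + (L - x))
            return float(np.var(vals))

        if L == 0:
            best = min(best, variance(0.0))
            continue
        xs = np.array([0.0, L / 2, L])
        ys = np.array([variance(x) for x in xs])
        a, b, c = np.polyfit(xs, ys, 2)
        cands = [0.0, L]
        if a > 0:
            cands.append(float(np.clip(-b / (2 * a), 0.0, L)))
        best = min(best, min(variance(x) for x in cands))
    return best


class TestMinvarRoot:
    def test_two_leaf_midpoint(self):
        tree = og.parse_newick("(1.A:1,2.B:3);")
        rooted = og.minvar_root(tree)
        lengths = sorted(c.length for c in rooted.root.children)
        assert lengths == pytest.approx([2.0, 2.0])
        assert root_to_tip_variance(rooted) == pytest.approx(0.0, abs=1e-12)

    def test_ultrametric_tree_recovers_zero_variance(self):
        # ultrametric when rooted correctly; feed it mis-rooted
        tree = og.parse_newick("(1.a:1,(2.b:2,(3.c:1,4.d:1):1):3);")
        rooted = og.minvar_root(tree)
        assert root_to_tip_variance(rooted) <= minvar_oracle_variance(tree) + 1e-12

    def test_quartet_matches_exhaustive_scan(self):
        tree = og.parse_newick("((1.A:1,2.B:1):1,(3.C:1,4.D:5):1);")
        rooted = og.minvar_root(tree)
        assert root_to_tip_variance(rooted) == pytest.approx(
            minvar_oracle_variance(tree), abs=1e-9
        )

    def test_matches_oracle_on_random_trees(self):
        for seed in range(20):
            cfg = og.SimulationConfig(
                n_species=int(5 + seed % 10), duplication_rate=0.3, seed=seed
            )
            _, _, gene, _ = og.simulate_family(cfg)
            if gene.n_leaves < 3 or gene.n_leaves > 30:
                continue
            rooted = og.minvar_root(gene)
            assert root_to_tip_variance(rooted) == pytest.approx(
                minvar_oracle_variance(gene), abs=1e-9
            )

    def test_degenerate_tree_rejected(self):
        with pytest.raises(DegenerateTreeError):
            og.minvar_root(og.parse_newick("(1.a:1);"))

    def test_leaf_set_preserved(self):
        tree = og.parse_newick("((1.a:1,2.b:4):2,(3.c:1,4.d:1):0.5);")
        rooted = og.minvar_root(tree)
        assert sorted(map(str, rooted.leaf_labels())) == sorted(
            map(str, tree.leaf_labels())
        )


class TestPruneLongBranches:
    def test_equal_lengths_nothing_removed(self):
        tree = og.parse_newick("((1.a:1,2.b:1):1,(3.c:1,4.d:1):1);")
        pruned, report = og.prune_long_branches(tree)
        assert report.removed == []
        assert pruned.n_leaves == 4

    def test_threshold_strictness_keeps_single_huge_branch(self):
        # caterpillar with 20 branches: 19 of length 1 plus one pendant of
        # 1000. mean = 1019/20 = 50.95, 50x mean = 2547.5 > 1000, so even
        # the huge branch survives — the factor-50 rule is deliberately lax
        nwk = "(s1.p:1,s2.p:1)"
        for i in range(3, 11):
            nwk = f"({nwk}:1,s{i}.p:1)"
        tree = og.parse_newick(f"({nwk}:1,long.leaf:1000);")
        n_branches = sum(1 for n in tree.postorder() if n.parent is not None)
        assert n_branches == 20
        pruned, report = og.prune_long_branches(tree, factor=50)
        assert report.removed == []
        assert report.mean_branch_length == pytest.approx(1019 / 20)

    def test_factor_override_removes_outlier(self):
        # branches {0.01 x5, 10}: mean 1.675; 50x = 83.75 keeps the 10;
        # factor 5 gives 8.375 <= 10 and removes exactly one leaf
        nwk = "((1.a:0.01,2.b:0.01):0.01,(3.c:0.01,4.d:10):0.01);"
        tree = og.parse_newick(nwk)
        kept, report = og.prune_long_branches(tree, factor=50)
        assert report.removed == []
        pruned, report5 = og.prune_long_branches(tree, factor=5)
        assert [str(lbl) for lbl, _ in report5.removed] == ["4.d"]
        assert pruned.n_leaves == 3

    def test_unary_suppression_sums_lengths(self):
        tree = og.parse_newick("((1.a:0.1,2.b:30):0.2,3.c:0.1);")
        pruned, report = og.prune_long_branches(tree, factor=3)
        assert [str(lbl) for lbl, _ in report.removed] == ["2.b"]
        # 1.a's branch now includes the suppressed parent edge
        leaf_a = pruned.find_leaf(og.LeafLabel("1", "a"))
        assert leaf_a.length == pytest.approx(0.1 + 0.2)

    def test_huge_factor_is_identity(self):
        cfg = og.SimulationConfig(n_species=10, duplication_rate=0.5, seed=5)
        _, _, gene, _ = og.simulate_family(cfg)
        pruned, report = og.prune_long_branches(gene, factor=1e12)
        assert report.removed == []
        assert pruned.n_leaves == gene.n_leaves

    def test_removing_every_leaf_is_an_error(self):
        tree = og.parse_newick("(1.a:1,2.b:1);")
        with pytest.raises(AllLeavesRemovedError):
            og.prune_long_branches(tree, factor=1)


class TestTrimAlignment:
    def test_all_gap_column_removed(self):
        records = [(f"s{i}", "A-C") for i in range(10)]
        msa = og.Msa(records)
        trimmed, removed = og.trim_alignment(msa)
        assert removed == [1]
        assert trimmed.records[0][1] == "AC"

    def test_exactly_ninety_percent_gaps_kept(self):
        # 9 gaps in 10 sequences = 0.90 exactly; the rule is strict `>`
        records = [("s0", "AAC")] + [(f"s{i}", "A-C") for i in range(1, 10)]
        msa = og.Msa(records)
        trimmed, removed = og.trim_alignment(msa, max_gap_fraction=0.9)
        assert removed == []
        assert trimmed.n_columns == 3

    def test_planted_columns_match_brute_force(self):
        rng = np.random.default_rng(17)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        arr = alphabet[rng.integers(0, 20, size=(20, 50))]  # no gaps yet
        planted = sorted(rng.choice(50, size=8, replace=False).tolist())
        for col in planted:
            gap_rows = rng.choice(20, size=19, replace=False)
            arr[gap_rows, col] = "-"
        msa = og.Msa([(f"s{i}", "".join(row)) for i, row in enumerate(arr)])
        _, removed = og.trim_alignment(msa, max_gap_fraction=0.9)
        brute = [
            c for c in range(50)
            if sum(arr[r, c] in "-." for r in range(20)) / 20 > 0.9
        ]
        assert removed == brute
        assert set(removed) <= set(planted)

    def test_idempotent(self):
        records = [(f"s{i}", "A--C" if i else "AA-C") for i in range(10)]
        msa = og.Msa(records)
        once, _ = og.trim_alignment(msa)
        twice, removed_again = og.trim_alignment(once)
        assert removed_again == []
        assert [s for _, s in twice.records] == [s for _, s in once.records]

    @settings(derandomize=True, max_examples=40)
    @given(
        rows=st.lists(
            st.text(alphabet="ACDEF-.", min_size=6, max_size=6),
            min_size=2, max_size=12,
        ),
        cutoff=st.sampled_from([0.5, 0.75, 0.9]),
    )
    def test_trimming_is_idempotent_and_keeps_column_order(self, rows, cutoff):
        msa = og.Msa([(f"s{i}", seq) for i, seq in enumerate(rows)])
        trimmed, removed = og.trim_alignment(msa, max_gap_fraction=cutoff)
        if trimmed.n_columns == 0:
            return
        again, removed_again = og.trim_alignment(trimmed, max_gap_fraction=cutoff)
        assert removed_again == []
        # surviving columns appear in their original relative order
        kept = [c for c in range(6) if c not in removed]
        for (_, orig), (_, out) in zip(msa.records, trimmed.records):
            assert out == "".join(orig[c] for c in kept)

    def test_empty_alignment_rejected(self):
        with pytest.raises(EmptyAlignmentError):
            og.trim_alignment(og.Msa([]))

    def test_fasta_round_trip(self, tmp_path):
        msa = og.Msa([("a", "AC-D"), ("b", "A--D")])
        og.write_msa(msa, tmp_path / "m.fa")
        back = og.read_msa(tmp_path / "m.fa")
        assert back.records == msa.records
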