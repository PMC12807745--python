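"""Evaluation statistics for delineated orthologous groups.

Three views:

* duplication rate — mean number of non-species-specific duplication
  events per basal-OG phylogeny; a proxy for the in-paralog load of the
  groups (species-specific duplications are ignored because they never
  split orthology);
* reference-group benchmark — precision/recall/F-score of OGs against a
  curated functional grouping (KEGG-Orthology-style), pairing each
  reference group with its best-F OG;
* size distribution — histogram of basal OG sizes with singleton and
  oversize counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MissingTreeError
from .ogs import OgSet, OrthologousGroup
from .orthology import DUPLICATION

__all__ = [
    "GroupScore",
    "BenchmarkResult",
    "DupRateReport",
    "SizeDistribution",
    "duplication_rate",
    "fscore_benchmark",
    "size_distribution",
]


@dataclass(frozen=True)
class GroupScore:
    """Best-OG match statistics for one reference group."""

    best_og_id: str | None
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


@dataclass
class BenchmarkResult:
    per_group: dict[str, GroupScore]
    mean_f: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group_id": gid,
                "best_og_id": s.best_og_id or "",
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
                "precision": s.precision,
                "recall": s.recall,
                "f_score": s.f_score,
            }
            for gid, s in sorted(self.per_group.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "group_id", "best_og_id", "tp", "fp", "fn",
                "precision", "recall", "f_score",
            ],
        )


@dataclass
class DupRateReport:
    """Non-species-specific duplication counts per basal OG."""

    per_og: dict[str, int] = field(default_factory=dict)
    mean_rate: float = 0.0


@dataclass
class SizeDistribution:
    table: pd.DataFrame  # columns: size, count
    n_singletons: int
    n_over_threshold: int
    threshold: int


def duplication_rate(basal: Sequence[OrthologousGroup]) -> DupRateReport:
    """Mean duplication count over basal-OG subtrees.

    For each basal OG, counts duplication nodes in its source subtree
    whose leaves span more than one species; duplications confined to a
    single species are ignored.  The subtree must be event-annotated and
    species-set-annotated.
    """
    per_og: dict[str, int] = {}
    for og in basal:
        node = og.source_node
        if node is None:
            raise MissingTreeError(f"basal OG {og.og_id} has no source subtree")
        count = 0
        for n in node.postorder():
            if n.is_leaf:
                continue
            ann = n.annotation
            if ann is None:
                raise MissingTreeError(
                    f"subtree of OG {og.og_id} is not event-annotated"
                )
            species = n.species_set or frozenset(
                leaf.label.species for leaf in n.leaves()
            )
            if ann.event == DUPLICATION and len(species) > 1:
                count += 1
        per_og[og.og_id] = count
    mean = sum(per_og.values()) / len(per_og) if per_og else 0.0
    return DupRateReport(per_og=per_og, mean_rate=mean)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def fscore_benchmark(
    og_membership: Mapping[str, str],
    ref_membership: Mapping[str, str] | Iterable[tuple[str, str]],
) -> BenchmarkResult:
    """Score OGs against reference functional groups, best OG per group.

    ``og_membership`` maps protein -> og_id (each protein in one OG, e.g.
    its basal OG).  ``ref_membership`` maps protein -> reference-group id,
    or is an iterable of (protein, group) pairs when proteins belong to
    several groups; each (protein, group) pair is counted independently
    within its group.

    For a group K and candidate OG O (any OG sharing a protein with K):
    TP = |K & O|; FN = members of K assigned to a different OG; FP =
    members of O outside K that carry some reference annotation
    (unannotated proteins are neither TP nor FP).  The best OG per group
    maximizes F, ties broken by larger TP then lexicographic og_id;
    ``mean_f`` averages the best F over all reference groups.
    """
    if isinstance(ref_membership, Mapping):
        pairs = list(ref_membership.items())
    else:
        pairs = list(ref_membership)

    groups: dict[str, set[str]] = {}
    annotated: set[str] = set()
    for protein, gid in pairs:
        groups.setdefault(gid, set()).add(protein)
        annotated.add(protein)

    og_members: dict[str, set[str]] = {}
    for protein, og_id in og_membership.items():
        og_members.setdefault(og_id, set()).add(protein)

    per_group: dict[str, GroupScore] = {}
    for gid, members in groups.items():
        placed = {p for p in members if p in og_membership}
        candidates = sorted({og_membership[p] for p in placed})
        best: GroupScore | None = None
        for og_id in candidates:
            O = og_members[og_id]
            tp = len(members & O)
            fn = len(placed - O)
            fp = len((O - members) & annotated)
            p, r, f = _prf(tp, fp, fn)
            score = GroupScore(og_id, tp, fp, fn, p, r, f)
            if (
                best is None
                or f > best.f_score
                or (f == best.f_score and tp > best.tp)
                or (f == best.f_score and tp == best.tp and og_id < best.best_og_id)
            ):
                best = score
        if best is None:
            best = GroupScore(None, 0, 0, 0, 0.0, 0.0, 0.0)
        per_group[gid] = best

    mean_f = (
        sum(s.f_score for s in per_group.values()) / len(per_group)
        if per_group
        else 0.0
    )
    return BenchmarkResult(per_group=per_group, mean_f=mean_f)


def size_distribution(
    ogsets: Iterable[OgSet], large_threshold: int = 100_000
) -> SizeDistribution:
    """Histogram of basal OG sizes plus singleton / oversize counts."""
    sizes = [og.size for ogset in ogsets for og in ogset.basal()]
    if sizes:
        counts = pd.Series(sizes).value_counts().sort_index()
        table = pd.DataFrame({"size": counts.index, "count": counts.values})
    else:
        table = pd.DataFrame(columns=["size", "count"])
    return SizeDistribution(
        table=table,
        n_singletons=sum(1 for s in sizes if s == 1),
        n_over_threshold=sum(1 for s in sizes if s > large_threshold),
        threshold=large_threshold,
    )
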