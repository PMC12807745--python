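"""Taxonomic hierarchy with lineage and last-common-ancestor queries.

The taxonomy is a parent-pointer table: each taxon points at its parent,
the root points at itself.  Taxon identifiers are opaque strings so that
NCBI numeric taxids and synthetic labels from the simulator share one code
path.  Rank labels are carried for reporting but never interpreted by the
orthology algorithm, which is purely lineage-set based.

Two on-disk dialects are supported:

* a four-column TSV with header ``taxid  parent  rank  name`` (the default);
* the NCBI taxdump ``nodes.dmp``/``names.dmp`` pipe-delimited convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CycleError, TaxonomyParseError, UnknownTaxonError

__all__ = ["TaxonEntry", "TaxonomyTable", "load_taxonomy", "write_taxonomy"]


@dataclass(frozen=True)
class TaxonEntry:
    """One taxonomy row: parent pointer plus descriptive labels."""

    parent: str
    rank: str = ""
    name: str = ""


class TaxonomyTable:
    """Validated parent-pointer taxonomy supporting lineage/LCA queries.

    Parameters
    ----------
    entries
        Mapping taxon-id -> :class:`TaxonEntry`.  Exactly one taxon must be
        its own parent (the root).  Every parent chain must terminate at the
        root without cycles; orphaned parents are rejected.
    """

    def __init__(self, entries: Mapping[str, TaxonEntry]):
        self._entries: dict[str, TaxonEntry] = dict(entries)
        if not self._entries:
            raise TaxonomyParseError("taxonomy table is empty")
        roots = [t for t, e in self._entries.items() if e.parent == t]
        if len(roots) > 1:
            raise TaxonomyParseError(
                f"expected exactly one root taxon, found {len(roots)}: {sorted(roots)[:5]}"
            )
        # With zero self-parented taxa every chain must cycle or orphan;
        # _validate raises the specific error.
        self.root_id: str = roots[0] if roots else ""
        self._lineages: dict[str, tuple[str, ...]] = {}
        self._validate()
        self._lineage_sets: dict[str, frozenset[str]] = {
            t: frozenset(lin) for t, lin in self._lineages.items()
        }

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_parent_map(cls, parents: Mapping[str, str]) -> "TaxonomyTable":
        """Build a table from a bare taxon -> parent mapping."""
        return cls({t: TaxonEntry(parent=p) for t, p in parents.items()})

    def _validate(self) -> None:
        """Resolve every lineage once; detect cycles and orphans."""
        if self.root_id:
            self._lineages[self.root_id] = (self.root_id,)
        for taxid in self._entries:
            chain: list[str] = []
            on_path: set[str] = set()
            cur = taxid
            while cur not in self._lineages:
                if cur in on_path:
                    raise CycleError(f"taxonomy cycle detected at taxon {cur!r}")
                if cur not in self._entries:
                    raise TaxonomyParseError(
                        f"taxon {chain[-1]!r} points at unknown parent {cur!r}"
                    )
                chain.append(cur)
                on_path.add(cur)
                cur = self._entries[cur].parent
            base = self._lineages[cur]
            for node in reversed(chain):
                base = base + (node,)
                self._lineages[node] = base

    # -- basic container protocol --------------------------------------------

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def parent(self, taxid: str) -> str:
        self._check(taxid)
        return self._entries[taxid].parent

    def rank(self, taxid: str) -> str:
        self._check(taxid)
        return self._entries[taxid].rank

    def name(self, taxid: str) -> str:
        self._check(taxid)
        return self._entries[taxid].name or taxid

    def _check(self, taxid: str) -> None:
        if taxid not in self._entries:
            raise UnknownTaxonError(f"unknown taxon {taxid!r}")

    # -- queries ---------------------------------------------------------------

    def lineage(self, taxid: str) -> tuple[str, ...]:
        """Root-to-taxon ordered lineage, both endpoints included."""
        self._check(taxid)
        return self._lineages[taxid]

    def lineage_set(self, taxid: str) -> frozenset[str]:
        """The lineage as a set, for containment tests."""
        self._check(taxid)
        return self._lineage_sets[taxid]

    def depth(self, taxid: str) -> int:
        """Number of taxa on the lineage (root has depth 1)."""
        return len(self.lineage(taxid))

    def lca(self, taxids: Iterable[str]) -> str:
        """Last common ancestor: the deepest taxon on every input lineage.

        Lineages are root-first paths in a tree, so the LCA is the last
        element of their common prefix.
        """
        ids = list(taxids)
        if not ids:
            raise UnknownTaxonError("lca of an empty taxon set is undefined")
        ref = self.lineage(ids[0])
        common = len(ref)
        for t in ids[1:]:
            lin = self.lineage(t)
            k = 0
            upper = min(common, len(lin))
            while k < upper and lin[k] == ref[k]:
                k += 1
            common = k
            if common == 1:
                break
        return ref[common - 1]

    def is_ancestor(self, ancestor: str, taxid: str) -> bool:
        """True if `ancestor` lies on `taxid`'s lineage (inclusive)."""
        return ancestor in self.lineage_set(taxid)


def _load_tsv(path: Path) -> TaxonomyTable:
    entries: dict[str, TaxonEntry] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:2]] != ["taxid", "parent"]:
            raise TaxonomyParseError(
                f"{path}: line 1: expected header 'taxid\\tparent\\trank\\tname'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise TaxonomyParseError(f"{path}: line {lineno}: expected >=2 columns")
            taxid, parent = row[0].strip(), row[1].strip()
            if not taxid:
                raise TaxonomyParseError(f"{path}: line {lineno}: empty taxid")
            if taxid in entries:
                raise TaxonomyParseError(f"{path}: line {lineno}: duplicate taxid {taxid!r}")
            rank = row[2].strip() if len(row) > 2 else ""
            name = row[3].strip() if len(row) > 3 else ""
            entries[taxid] = TaxonEntry(parent=parent or taxid, rank=rank, name=name)
    return TaxonomyTable(entries)


def _split_dmp(line: str) -> list[str]:
    # nodes.dmp rows are '<f1>\t|\t<f2>\t|\t...\t|'
    return [f.strip() for f in line.rstrip("\n").rstrip("\t|").split("\t|\t")]


def _load_ncbi_dump(path: Path) -> TaxonomyTable:
    nodes = path / "nodes.dmp" if path.is_dir() else path
    if not nodes.exists():
        raise TaxonomyParseError(f"nodes.dmp not found at {nodes}")
    entries: dict[str, TaxonEntry] = {}
    with open(nodes, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise TaxonomyParseError(f"{nodes}: line {lineno}: expected >=3 fields")
            taxid, parent, rank = fields[0], fields[1], fields[2]
            entries[taxid] = TaxonEntry(parent=parent, rank=rank)
    names_path = nodes.parent / "names.dmp"
    if names_path.exists():
        names: dict[str, str] = {}
        with open(names_path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _split_dmp(line)
                if len(fields) >= 4 and fields[3] == "scientific name":
                    names[fields[0]] = fields[1]
        entries = {
            t: TaxonEntry(parent=e.parent, rank=e.rank, name=names.get(t, ""))
            for t, e in entries.items()
        }
    return TaxonomyTable(entries)


def load_taxonomy(path: str | Path, dialect: str = "tsv") -> TaxonomyTable:
    """Load a taxonomy table from disk.

    Parameters
    ----------
    path
        TSV file for the default dialect; for ``ncbi-dump`` either the
        ``nodes.dmp`` file or the directory containing it (``names.dmp``,
        if present alongside, supplies scientific names).
    dialect
        ``"tsv"`` (4-column, tab-separated, header row) or ``"ncbi-dump"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _load_tsv(path)
    if dialect == "ncbi-dump":
        return _load_ncbi_dump(path)
    raise ValueError(f"unknown taxonomy dialect {dialect!r}")


def write_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    """Write the default 4-column TSV dialect (taxid, parent, rank, name)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxid", "parent", "rank", "name"])
        for taxid in sorted(table):
            writer.writerow(
                [taxid, table.parent(taxid), table.rank(taxid), table.name(taxid)]
            )
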