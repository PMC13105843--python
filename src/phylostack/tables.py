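"""Tabular inputs: taxonomy rank tables and sample × taxon abundance matrices.

Hierarchical information frequently arrives not as a tree but as a rank table
(one row per taxon, ordered columns from coarse to fine, e.g. Kingdom →
Phylum → … → OTU).  :func:`taxonomy_to_tree` converts such a table into a
:class:`~phylostack.tree.Hierarchy`.  Missing cells are skipped — a row's
path is its non-missing cells in rank order, so no placeholder
"unclassified" nodes are invented.  The same name appearing under different
parents yields distinct nodes (taxonomic homonyms are real), disambiguated
internally by their full path.

:class:`AbundanceTable` wraps a pandas DataFrame of non-negative values with
samples in rows and taxa in columns.  Rows need not sum to one: raw counts,
CPMs or relative abundances are all acceptable, and downstream layout offers
both normalized and raw bar modes.  :func:`validate` checks the tree/matrix
contract — the set of leaf labels must equal the set of column names — and
on success returns the matrix with columns reindexed to leaf order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import DuplicateLeafError, Hierarchy, HierarchyError, TaxonNode

__all__ = [
    "TaxonomyTable",
    "AbundanceTable",
    "ValidationReport",
    "taxonomy_to_tree",
    "validate",
]


def _clean_cell(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    return s if s else None


@dataclass
class TaxonomyTable:
    """One row per taxon; columns are rank names ordered coarse → fine.

    Cells may be missing (None / NaN / empty string); the finest non-missing
    cell of each row is that row's leaf identifier and must be unique.
    """

    ranks: list[str]
    rows: list[list[str | None]]

    def __post_init__(self) -> None:
        width = len(self.ranks)
        self.rows = [[_clean_cell(c) for c in row] for row in self.rows]
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise HierarchyError(f"taxonomy row {i} has {len(row)} cells, expected {width}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TaxonomyTable":
        return cls(ranks=[str(c) for c in df.columns], rows=df.values.tolist())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.ranks)

    def paths(self) -> list[list[tuple[str, str]]]:
        """Per row, the (cell, rank) pairs of non-missing cells in rank order."""
        out = []
        for row in self.rows:
            out.append([(c, r) for c, r in zip(row, self.ranks) if c is not None])
        return out


@dataclass
class AbundanceTable:
    """Samples × taxa matrix of non-negative real values.

    Backed by a pandas DataFrame: the index holds sample ids, the columns
    taxon ids.  Values are coerced to float.  Negative entries are permitted
    at construction so that :func:`validate` can report them with addresses.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise HierarchyError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise HierarchyError(f"duplicate taxon ids: {dups}")
        self.data = df.astype(float)
        self.data.index = self.data.index.map(str)
        self.data.columns = self.data.columns.map(str)

    @classmethod
    def from_arrays(cls, sample_ids, taxon_ids, values) -> "AbundanceTable":
        return cls(pd.DataFrame(np.asarray(values, dtype=float), index=list(sample_ids), columns=list(taxon_ids)))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.data.index)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)])

    def reindex_columns(self, taxon_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[:, list(taxon_ids)])

    def row(self, sample_id: str) -> np.ndarray:
        return self.data.loc[sample_id].to_numpy()


# ---------------------------------------------------------------------------
# taxonomy table -> tree
# ---------------------------------------------------------------------------

def taxonomy_to_tree(table: TaxonomyTable) -> Hierarchy:
    """Build a hierarchy from a rank table.

    Every distinct rank-path prefix becomes one internal node labeled by its
    cell value (column name recorded as the node's rank); each row's finest
    non-missing entry becomes a leaf.  Children appear in first-appearance
    order.  A synthetic root is added only when the table has more than one
    top-level name.
    """
    paths = table.paths()
    if not paths:
        raise HierarchyError("empty taxonomy table")
    for i, p in enumerate(paths):
        if not p:
            raise HierarchyError(f"taxonomy row {i} has no non-missing cells")

    leaf_labels = [p[-1][0] for p in paths]
    dups = sorted({l for l in leaf_labels if leaf_labels.count(l) > 1})
    if dups:
        raise DuplicateLeafError(dups)

    full_paths = {tuple(c for c, _ in p) for p in paths}
    for p in full_paths:
        for k in range(1, len(p)):
            if p[:k] in full_paths:
                raise HierarchyError(
                    f"row path {'/'.join(p[:k])} is both a leaf and an ancestor of {'/'.join(p)}"
                )

    root_id = "__root__"
    nodes: dict[str, TaxonNode] = {root_id: TaxonNode(root_id, "", None)}
    path_to_id: dict[tuple[str, ...], str] = {(): root_id}
    used_ids = {root_id}

    def make_id(label: str, path: tuple[str, ...]) -> str:
        if label not in used_ids:
            return label
        return "/".join(path)

    for p in paths:
        cells = tuple(c for c, _ in p)
        for k in range(1, len(cells) + 1):
            prefix = cells[:k]
            if prefix in path_to_id:
                continue
            label, rank = p[k - 1]
            nid = make_id(label, prefix)
            if nid in used_ids:
                raise HierarchyError(f"cannot assign unique id for node at path {'/'.join(prefix)}")
            used_ids.add(nid)
            parent_id = path_to_id[cells[: k - 1]]
            nodes[nid] = TaxonNode(nid, label, parent_id, rank=rank)
            nodes[parent_id].children.append(nid)
            path_to_id[prefix] = nid

    root_children = nodes[root_id].children
    if len(root_children) == 1:
        # single top-level name: promote it, drop the synthetic root
        new_root = root_children[0]
        nodes[new_root].parent = None
        del nodes[root_id]
        return Hierarchy(nodes, new_root)
    nodes[root_id].label = "root"
    return Hierarchy(nodes, root_id)


# ---------------------------------------------------------------------------
# tree / matrix contract
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of checking an abundance matrix against a hierarchy.

    ``ok`` iff no leaves are missing from the columns, no columns are unknown
    to the tree, and no value is negative.  When ok, ``aligned`` holds the
    abundance table with columns reindexed to the hierarchy's leaf order.
    """

    missing_columns: list[str] = field(default_factory=list)
    unknown_columns: list[str] = field(default_factory=list)
    negative_cells: list[tuple[str, str, float]] = field(default_factory=list)
    aligned: AbundanceTable | None = None

    @property
    def ok(self) -> bool:
        return not (self.missing_columns or self.unknown_columns or self.negative_cells)

    def summary(self) -> str:
        if self.ok:
            return "ok"
        parts = []
        if self.missing_columns:
            parts.append(f"leaves missing from abundance columns: {self.missing_columns}")
        if self.unknown_columns:
            parts.append(f"abundance columns not in tree leaves: {self.unknown_columns}")
        if self.negative_cells:
            addr = [f"({s},{t})={v:g}" for s, t, v in self.negative_cells[:5]]
            more = "" if len(self.negative_cells) <= 5 else f" (+{len(self.negative_cells) - 5} more)"
            parts.append(f"negative values at {addr}{more}")
        return "; ".join(parts)


def validate(h: Hierarchy, a: AbundanceTable) -> ValidationReport:
    """Check the leaf/column contract and non-negativity.

    The join key is leaf *labels* (unique by tree invariant) against column
    names.  Order mismatches are not an error: on success the aligned table
    is reindexed to leaf order.
    """
    leaf_labels = h.leaf_labels
    cols = set(a.taxon_ids)
    leaf_set = set(leaf_labels)
    report = ValidationReport(
        missing_columns=[l for l in leaf_labels if l not in cols],
        unknown_columns=[c for c in a.taxon_ids if c not in leaf_set],
    )
    vals = a.values
    if np.any(vals < 0):
        rows, colidx = np.nonzero(vals < 0)
        sids, tids = a.sample_ids, a.taxon_ids
        report.negative_cells = [
            (sids[i], tids[j], float(vals[i, j])) for i, j in zip(rows, colidx)
        ]
    if report.ok:
        report.aligned = a.reindex_columns(leaf_labels)
    return report
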