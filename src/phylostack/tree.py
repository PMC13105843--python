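"""Rooted, labeled, not-necessarily-binary trees over taxa.

A :class:`Hierarchy` is the tree side of a linked tree/barplot view: a rooted
tree whose leaves carry the taxon identifiers that join to the columns of an
abundance matrix.  Internal nodes represent coarser taxonomic (or cell-type)
groupings.  Child order is meaningful — it determines ``leaf_order`` and hence
the vertical order of both the drawn tree and the stacked-bar segments — and
is never re-sorted.

Newick input is parsed with :mod:`dendropy`; output is written by a small
deterministic writer so that round-trips preserve topology, labels and leaf
order byte-for-byte.  Branch lengths are parsed and stored but the layout is
cladogram-style (depth-based), so they are never used downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "TaxonNode",
    "Hierarchy",
    "HierarchyError",
    "NewickParseError",
    "DuplicateLeafError",
    "UnknownNodeError",
    "parse_newick",
    "write_newick",
]


class HierarchyError(ValueError):
    """Invalid tree structure or tree-building input."""


class NewickParseError(HierarchyError):
    """Malformed Newick text."""


class DuplicateLeafError(HierarchyError):
    """Two leaves share a label; leaf labels are the join key to abundance columns."""

    def __init__(self, duplicates: list[str]):
        self.duplicates = list(duplicates)
        super().__init__(f"duplicate leaf labels: {', '.join(sorted(self.duplicates))}")


class UnknownNodeError(KeyError):
    """A node id that does not exist in the hierarchy."""

    def __init__(self, node_id: str):
        self.node_id = node_id
        super().__init__(f"unknown node id: {node_id!r}")


@dataclass
class TaxonNode:
    """One node of a :class:`Hierarchy`.

    ``label`` is the display string (may be empty for unlabeled internal
    nodes); ``node_id`` is unique within the tree.  ``rank`` records the
    taxonomy-table column a node came from, when applicable.
    """

    node_id: str
    label: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    rank: str | None = None
    branch_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Hierarchy:
    """A rooted tree with unique node ids and unique leaf labels.

    Invariants checked at construction:

    * node ids are unique (enforced by the dict) and parent/children links are
      mutually consistent;
    * exactly one node (the root) has no parent, and every node is reachable
      from it;
    * leaf labels are unique across the tree.

    ``leaf_order`` is the depth-first, left-to-right leaf sequence implied by
    the stored child order; it is recomputed, never stored independently.
    """

    def __init__(self, nodes: dict[str, TaxonNode], root: str):
        self._nodes = dict(nodes)
        self.root = root
        self._check()
        self._preorder = self._compute_preorder()
        self._leaf_order = [n for n in self._preorder if self._nodes[n].is_leaf]

    # -- construction-time validation ------------------------------------
    def _check(self) -> None:
        if self.root not in self._nodes:
            raise HierarchyError(f"root {self.root!r} not among nodes")
        if self._nodes[self.root].parent is not None:
            raise HierarchyError("root must have no parent")
        roots = [n for n, nd in self._nodes.items() if nd.parent is None]
        if len(roots) != 1:
            raise HierarchyError(f"expected exactly one parentless node, found {roots}")
        for nid, nd in self._nodes.items():
            if nd.node_id != nid:
                raise HierarchyError(f"node keyed {nid!r} carries id {nd.node_id!r}")
            for c in nd.children:
                if c not in self._nodes:
                    raise HierarchyError(f"child {c!r} of {nid!r} does not exist")
                if self._nodes[c].parent != nid:
                    raise HierarchyError(f"parent link of {c!r} disagrees with child list of {nid!r}")

    def _compute_preorder(self) -> list[str]:
        order: list[str] = []
        stack = [self.root]
        seen: set[str] = set()
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise HierarchyError(f"cycle detected at {nid!r}")
            seen.add(nid)
            order.append(nid)
            stack.extend(reversed(self._nodes[nid].children))
        if len(seen) != len(self._nodes):
            unreachable = sorted(set(self._nodes) - seen)
            raise HierarchyError(f"nodes unreachable from root: {unreachable}")
        labels = [self._nodes[n].label for n in order if self._nodes[n].is_leaf]
        dups = sorted({l for l in labels if labels.count(l) > 1})
        if dups:
            raise DuplicateLeafError(dups)
        return order

    # -- basic accessors --------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, node_id: str) -> TaxonNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownNodeError(node_id) from None

    def label(self, node_id: str) -> str:
        return self.node(node_id).label

    def display_label(self, node_id: str) -> str:
        """Label for UI/legend purposes; falls back to the id when empty."""
        lab = self.node(node_id).label
        return lab if lab else node_id

    def parent(self, node_id: str) -> str | None:
        return self.node(node_id).parent

    def children(self, node_id: str) -> list[str]:
        return list(self.node(node_id).children)

    def is_leaf(self, node_id: str) -> bool:
        return self.node(node_id).is_leaf

    def preorder(self) -> list[str]:
        """All node ids, depth-first pre-order, child order as stored."""
        return list(self._preorder)

    @property
    def leaf_order(self) -> list[str]:
        return list(self._leaf_order)

    @property
    def leaf_labels(self) -> list[str]:
        return [self._nodes[n].label for n in self._leaf_order]

    def ancestors(self, node_id: str) -> list[str]:
        """Proper ancestors of ``node_id``, nearest first, ending at the root."""
        out: list[str] = []
        p = self.node(node_id).parent
        while p is not None:
            out.append(p)
            p = self._nodes[p].parent
        return out

    def depth(self, node_id: str) -> int:
        return len(self.ancestors(node_id))

    # -- queries -----------------------------------------------------------
    def leaves_under(self, node_id: str) -> list[str]:
        """Leaves of ``node_id``'s subtree in leaf_order; a leaf yields itself."""
        nd = self.node(node_id)
        if nd.is_leaf:
            return [node_id]
        out: list[str] = []
        stack = list(reversed(nd.children))
        while stack:
            cur = stack.pop()
            cnd = self._nodes[cur]
            if cnd.is_leaf:
                out.append(cur)
            else:
                stack.extend(reversed(cnd.children))
        return out

    def search_labels(self, query: str) -> list[str]:
        """Nodes (internal and leaf) whose label contains ``query``, case-insensitively.

        Results come back in pre-order.  An empty query matches nothing.
        """
        if not query:
            return []
        q = query.lower()
        return [n for n in self._preorder if q in self._nodes[n].label.lower()]

    def find_by_label(self, label: str) -> list[str]:
        """Nodes whose label equals ``label`` exactly, in pre-order."""
        return [n for n in self._preorder if self._nodes[n].label == label]

    def resolve(self, token: str) -> str:
        """Resolve a user-supplied token to a node id.

        Exact node ids win; otherwise a unique exact label match is accepted.
        Ambiguous or unknown tokens raise.
        """
        if token in self._nodes:
            return token
        hits = self.find_by_label(token)
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise UnknownNodeError(token)
        raise HierarchyError(f"label {token!r} is ambiguous: matches nodes {hits}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Hierarchy {len(self._nodes)} nodes, {len(self._leaf_order)} leaves, root={self.root!r}>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _prescan_newick(text: str) -> None:
    """Cheap structural scan giving character offsets for common errors.

    Quoted labels may legally contain parentheses, so the scan tracks quote
    state.  Finer-grained syntax errors are left to the real parser.
    """
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError(f"unbalanced ')' at character {i}")
    if in_quote:
        raise NewickParseError("unterminated quoted label")
    if depth > 0:
        raise NewickParseError(f"{depth} unclosed '(' at end of input")
    if ";" not in text:
        raise NewickParseError(f"missing terminating ';' (scanned {len(text)} characters)")


def parse_newick(text: str) -> Hierarchy:
    """Parse Newick text into a :class:`Hierarchy`.

    Unlabeled internal nodes receive generated ids ``node_0001``, numbered in
    pre-order.  Branch lengths are stored but unused downstream.  Duplicate
    leaf labels raise :class:`DuplicateLeafError`; structural errors raise
    :class:`NewickParseError` with a character offset where one can be given.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    _prescan_newick(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failed: {exc}") from exc

    nodes: dict[str, TaxonNode] = {}
    counter = 0
    used: set[str] = set()

    def visit(dnode, parent_id: str | None) -> str:
        nonlocal counter
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
            if not label:
                raise NewickParseError("leaf without a label")
        else:
            label = dnode.label or ""
        if label and label not in used:
            nid = label
        else:
            counter += 1
            nid = f"node_{counter:04d}"
            while nid in used:  # guard against user labels shaped like generated ids
                counter += 1
                nid = f"node_{counter:04d}"
        used.add(nid)
        nodes[nid] = TaxonNode(
            node_id=nid,
            label=label,
            parent=parent_id,
            rank=None,
            branch_length=dnode.edge.length if dnode.edge is not None else None,
        )
        for child in dnode.child_nodes():
            cid = visit(child, nid)
            nodes[nid].children.append(cid)
        return nid

    root_id = visit(dtree.seed_node, None)
    return Hierarchy(nodes, root_id)


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,='\"]")


def _quote_label(label: str) -> str:
    if not label:
        return ""
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(h: Hierarchy, include_branch_lengths: bool = True) -> str:
    """Serialize a hierarchy to Newick; ``parse_newick`` round-trips it.

    Generated ids of unlabeled internal nodes are not written (their label is
    empty), so a parse→write→parse cycle preserves topology, labels and
    leaf_order exactly.
    """

    def fmt(node_id: str) -> str:
        nd = h.node(node_id)
        if nd.is_leaf:
            s = _quote_label(nd.label)
        else:
            s = "(" + ",".join(fmt(c) for c in nd.children) + ")" + _quote_label(nd.label)
        if include_branch_lengths and nd.branch_length is not None:
            s += f":{nd.branch_length:g}"
        return s

    return fmt(h.root) + ";"
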