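"""Explicit, replayable view state: collapse/expand, subtree painting, palettes.

In the interactive tool these are hover, click and key events; here they are
pure functions on an immutable :class:`ViewState`, so a whole interaction
session is a list of operations that can be replayed deterministically (see
:func:`replay`) and serialized to JSON.

Semantics
---------
* Collapsing an internal node hides its interior; its leaves' abundances are
  merged into a single column/rectangle for the whole subtree.  Collapse
  states nest: a collapsed descendant of a collapsed node keeps its own state,
  so expanding the outer node restores the previous view exactly.
* Paints are recorded as an insertion-ordered log of (node, color-index)
  assignments.  A paint whose node is hidden inside a collapsed subtree is
  *suspended*, not deleted; expanding restores it with its original color.
  A color used only by suspended paints returns to the palette's free pool.
* Color resolution is nearest-painted-visible-ancestor: painting a node colors
  its whole visible subtree, and a deeper paint overrides a shallower one on
  the leaves it covers.
* ``frozen`` mirrors the freeze-for-export toggle; it is advisory metadata
  carried through serialization and does not gate any operation here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .tables import AbundanceTable, validate
from .tree import Hierarchy, UnknownNodeError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PALETTE",
    "Palette",
    "ViewState",
    "EffectiveComposition",
    "ViewError",
    "HiddenNodeError",
    "collapse",
    "expand",
    "paint",
    "next_color",
    "effective_leaves",
    "aggregate",
    "legend",
    "LegendEntry",
    "resolve_color",
    "replay",
    "state_to_dict",
    "state_from_dict",
]

#: Default six-color palette (Okabe–Ito subset; colorblind-safe).
DEFAULT_PALETTE: tuple[str, ...] = (
    "#0072b2",  # blue
    "#d55e00",  # vermillion
    "#009e73",  # bluish green
    "#cc79a7",  # reddish purple
    "#e69f00",  # orange
    "#56b4e9",  # sky blue
)


class ViewError(ValueError):
    """Invalid view-state operation."""


class HiddenNodeError(ViewError):
    """Operation on a node hidden inside a collapsed subtree."""

    def __init__(self, node_id: str, collapsed_ancestor: str):
        self.node_id = node_id
        self.collapsed_ancestor = collapsed_ancestor
        super().__init__(
            f"node {node_id!r} is hidden inside collapsed subtree {collapsed_ancestor!r}"
        )


@dataclass(frozen=True)
class Palette:
    """An ordered color list plus the cursor of the next color to issue."""

    colors: tuple[str, ...] = DEFAULT_PALETTE
    cursor: int = 0

    def __post_init__(self):
        if len(self.colors) < 1:
            raise ViewError("palette must have at least one color")
        if not (0 <= self.cursor < len(self.colors)):
            raise ViewError(f"palette cursor {self.cursor} out of range [0, {len(self.colors)})")

    def __len__(self) -> int:
        return len(self.colors)


@dataclass(frozen=True)
class ViewState:
    """Immutable interaction state bound (by convention) to one hierarchy.

    ``paint_log`` holds every current paint assignment in insertion order;
    whether a paint is active or suspended is *derived* from ``collapsed``
    and the tree, which makes collapse→expand round-trips exact by
    construction.
    """

    collapsed: frozenset[str] = frozenset()
    paint_log: tuple[tuple[str, int], ...] = ()
    palette: Palette = field(default_factory=Palette)
    frozen: bool = False


# ---------------------------------------------------------------------------
# visibility helpers
# ---------------------------------------------------------------------------

def hidden_by(h: Hierarchy, s: ViewState, node_id: str) -> str | None:
    """The outermost collapsed proper ancestor hiding ``node_id``, or None."""
    hit = None
    for anc in h.ancestors(node_id):
        if anc in s.collapsed:
            hit = anc
    return hit


def is_visible(h: Hierarchy, s: ViewState, node_id: str) -> bool:
    """Visible = no collapsed proper ancestor (a collapsed node is itself visible)."""
    return all(anc not in s.collapsed for anc in h.ancestors(node_id))


def active_paints(h: Hierarchy, s: ViewState) -> list[tuple[str, int]]:
    return [(n, c) for n, c in s.paint_log if is_visible(h, s, n)]


def suspended_paints(h: Hierarchy, s: ViewState) -> list[tuple[str, int]]:
    return [(n, c) for n, c in s.paint_log if not is_visible(h, s, n)]


def released_colors(h: Hierarchy, s: ViewState) -> list[int]:
    """Colors held only by suspended paints, free for re-issue.

    Ordered by first appearance in the paint log (deterministic).
    """
    active = {c for _, c in active_paints(h, s)}
    out: list[int] = []
    for n, c in s.paint_log:
        if c not in active and c not in out and not is_visible(h, s, n):
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def collapse(h: Hierarchy, s: ViewState, node_id: str) -> ViewState:
    """Collapse ``node_id``'s subtree; idempotent; a leaf is a no-op.

    Paints strictly inside the subtree become suspended (derived), and any
    color used only by suspended paints returns to the free pool.
    """
    if h.is_leaf(node_id):
        return s
    if node_id in s.collapsed:
        return s
    return replace(s, collapsed=s.collapsed | {node_id})


def expand(h: Hierarchy, s: ViewState, node_id: str) -> ViewState:
    """Expand a collapsed node, restoring its previous interior state.

    Suspended paints whose node becomes visible again are restored with
    their original colors; collapsed descendants stay collapsed.  Expanding
    a non-collapsed node is a logged no-op.
    """
    if node_id not in h:
        raise UnknownNodeError(node_id)
    if node_id not in s.collapsed:
        logger.warning("expand: node %r is not collapsed; no-op", node_id)
        return s
    return replace(s, collapsed=s.collapsed - {node_id})


def next_color(h: Hierarchy, s: ViewState) -> tuple[ViewState, int]:
    """Issue the next color index: freed colors first, else the cursor.

    With no freed colors the sequence is 0, 1, …, L−1, 0, … (modular cycling
    over the palette length L).  A freed color is offered until a paint
    actually consumes it; the cursor does not advance when a freed color is
    issued.
    """
    freed = released_colors(h, s)
    if freed:
        return s, freed[0]
    idx = s.palette.cursor
    pal = replace(s.palette, cursor=(idx + 1) % len(s.palette))
    return replace(s, palette=pal), idx


def paint(h: Hierarchy, s: ViewState, node_id: str, color_index: int | None = None) -> ViewState:
    """Paint ``node_id``'s visible subtree with a palette color.

    With ``color_index`` None the next palette color is issued (hover/Control
    semantics); an explicit index models the number keys.  Repainting a
    painted node replaces its color in place (legend position is kept).
    """
    if node_id not in h:
        raise UnknownNodeError(node_id)
    anc = hidden_by(h, s, node_id)
    if anc is not None:
        raise HiddenNodeError(node_id, anc)
    if color_index is None:
        s, color_index = next_color(h, s)
    elif not (0 <= color_index < len(s.palette)):
        raise ViewError(
            f"color index {color_index} out of range for a {len(s.palette)}-color palette"
        )
    log = list(s.paint_log)
    for i, (n, _) in enumerate(log):
        if n == node_id:
            log[i] = (node_id, color_index)
            break
    else:
        log.append((node_id, color_index))
    return replace(s, paint_log=tuple(log))


def unpaint(h: Hierarchy, s: ViewState, node_id: str) -> ViewState:
    """Remove a node's paint assignment entirely (no-op if unpainted)."""
    return replace(s, paint_log=tuple((n, c) for n, c in s.paint_log if n != node_id))


def freeze(s: ViewState, frozen: bool = True) -> ViewState:
    return replace(s, frozen=frozen)


def effective_leaves(h: Hierarchy, s: ViewState) -> list[str]:
    """The visible frontier: depth-first traversal not descending into collapsed nodes.

    Yields uncollapsed leaves plus maximal collapsed internal nodes, in the
    order induced by leaf_order.
    """
    out: list[str] = []
    stack = [h.root]
    while stack:
        nid = stack.pop()
        if nid in s.collapsed or h.is_leaf(nid):
            out.append(nid)
        else:
            stack.extend(reversed(h.children(nid)))
    return out


def resolve_color(h: Hierarchy, s: ViewState, node_id: str) -> int | None:
    """Color of a visible node: nearest painted visible ancestor (or self) wins."""
    act = dict(active_paints(h, s))
    if node_id in act:
        return act[node_id]
    for anc in h.ancestors(node_id):
        if anc in act:
            return act[anc]
    return None


@dataclass
class EffectiveComposition:
    """The abundance matrix as seen through a view state.

    One column per effective leaf (visible frontier node); a collapsed node's
    column is the sum over its descendant leaves, so per-sample totals equal
    the raw per-sample totals exactly.
    """

    sample_ids: list[str]
    effective_leaf_ids: list[str]
    labels: list[str]
    values: np.ndarray
    color_of: dict[str, int | None]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)


def aggregate(a: AbundanceTable, h: Hierarchy, s: ViewState) -> EffectiveComposition:
    """Aggregate abundances onto the visible frontier.

    Requires ``validate(h, a)`` to pass; raises ``ViewError`` with the
    report's summary otherwise.
    """
    report = validate(h, a)
    if not report.ok:
        raise ViewError(f"abundance/hierarchy mismatch: {report.summary()}")
    aligned = report.aligned
    col_index = {lab: j for j, lab in enumerate(aligned.taxon_ids)}
    frontier = effective_leaves(h, s)
    vals = aligned.values
    out = np.empty((vals.shape[0], len(frontier)), dtype=float)
    for j, nid in enumerate(frontier):
        idx = [col_index[h.label(l)] for l in h.leaves_under(nid)]
        out[:, j] = vals[:, idx].sum(axis=1)
    colors = {nid: resolve_color(h, s, nid) for nid in frontier}
    return EffectiveComposition(
        sample_ids=aligned.sample_ids,
        effective_leaf_ids=frontier,
        labels=[h.display_label(n) for n in frontier],
        values=out,
        color_of=colors,
    )


@dataclass(frozen=True)
class LegendEntry:
    node_id: str
    label: str
    color_index: int


def legend(h: Hierarchy, s: ViewState) -> list[LegendEntry]:
    """One entry per *active* paint, labeled by the painted node, in insertion order.

    Suspended paints (inside collapsed subtrees) are excluded, matching the
    rule that their colors leave the palette while hidden.
    """
    return [
        LegendEntry(n, h.display_label(n), c) for n, c in active_paints(h, s)
    ]


# ---------------------------------------------------------------------------
# replay + serialization
# ---------------------------------------------------------------------------

def replay(h: Hierarchy, events: list[dict], state: ViewState | None = None) -> ViewState:
    """Apply a JSON-able event log to a state; the scripted stand-in for a session.

    Supported events: ``{"op": "collapse"|"expand"|"paint"|"unpaint",
    "node": id, ["color": int]}``, ``{"op": "freeze", ["value": bool]}``.
    """
    s = state if state is not None else ViewState()
    for ev in events:
        op = ev.get("op")
        if op == "collapse":
            s = collapse(h, s, ev["node"])
        elif op == "expand":
            s = expand(h, s, ev["node"])
        elif op == "paint":
            s = paint(h, s, ev["node"], ev.get("color"))
        elif op == "unpaint":
            s = unpaint(h, s, ev["node"])
        elif op == "freeze":
            s = freeze(s, ev.get("value", True))
        else:
            raise ViewError(f"unknown event op: {op!r}")
    return s


def state_to_dict(s: ViewState) -> dict:
    return {
        "collapsed": sorted(s.collapsed),
        "paints": [{"node": n, "color": c} for n, c in s.paint_log],
        "palette": {"colors": list(s.palette.colors), "cursor": s.palette.cursor},
        "frozen": s.frozen,
    }


def state_from_dict(d: dict) -> ViewState:
    pal = d.get("palette", {})
    palette = Palette(
        colors=tuple(pal.get("colors", DEFAULT_PALETTE)),
        cursor=int(pal.get("cursor", 0)),
    )
    return ViewState(
        collapsed=frozenset(d.get("collapsed", [])),
        paint_log=tuple((p["node"], int(p["color"])) for p in d.get("paints", [])),
        palette=palette,
        frozen=bool(d.get("frozen", False)),
    )


def check_bound(h: Hierarchy, s: ViewState) -> None:
    """Raise if the state references nodes absent from ``h``."""
    for nid in s.collapsed:
        if nid not in h:
            raise UnknownNodeError(nid)
    for nid, c in s.paint_log:
        if nid not in h:
            raise UnknownNodeError(nid)
        if not (0 <= c < len(s.palette)):
            raise ViewError(f"paint color {c} out of palette range")
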