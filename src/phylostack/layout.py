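"""Pure geometry for the linked tree/barplot view.

The canvas is split into a left tree panel and a right bar panel sharing a
vertical axis: the i-th effective leaf's node and the i-th segment of every
bar sit at the same rank top-to-bottom, which is what visually links the two
panels.  Coordinates use an abstract unit square-ish canvas with the origin
top-left and y increasing downward (SVG convention).

Tree layout is cladogram-style: x proportional to topological depth among
*visible* nodes (branch lengths ignored), leaves evenly spaced vertically
(band centers), internal nodes at the mean y of their children.  Only the
visible frontier and its ancestors are laid out — collapsing redraws the
tree into the freed space.

Bar layout stacks segments top-to-bottom in effective-leaf order.  In
normalized mode each bar's segments partition the full bar height; in raw
mode heights share one global scale (tallest total = full height), so bar
totals may differ — abundances need not sum to one.

Hover targeting is a nearest-site partition over the laid-out node
positions (the Voronoi dual of the Delaunay triangulation kept on the
map); a point query returns the nearest node, ties going to the smaller
pre-order index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .arrange import Arrangement
from .tree import Hierarchy
from .view import EffectiveComposition, ViewState, effective_leaves

__all__ = [
    "CanvasSpec",
    "NodePlacement",
    "TreeLayout",
    "BarRect",
    "BarLayout",
    "HoverRegionMap",
    "LayoutError",
    "layout_tree",
    "layout_bars",
    "hover_map",
    "layout_to_dict",
]


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class CanvasSpec:
    """Canvas geometry in abstract units; origin top-left, y downward.

    ``tree_fraction`` and ``bar_fraction`` split the inner width (after
    margins) between the two panels; any remainder is the inter-panel
    spacer.  ``bar_gap`` is the fraction of each sample band left empty
    between neighboring bars.
    """

    width: float = 960.0
    height: float = 600.0
    tree_fraction: float = 0.42
    bar_fraction: float = 0.50
    margin: float = 16.0
    bar_gap: float = 0.15

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise LayoutError("canvas dimensions must be positive")
        for name in ("tree_fraction", "bar_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise LayoutError(f"{name} must lie in (0,1), got {v}")
        if self.tree_fraction + self.bar_fraction > 1:
            raise LayoutError("tree_fraction + bar_fraction must be <= 1")
        if not (0 <= self.bar_gap < 1):
            raise LayoutError("bar_gap must lie in [0,1)")
        if self.margin < 0 or 2 * self.margin >= min(self.width, self.height):
            raise LayoutError("margin too large for canvas")

    @property
    def inner_width(self) -> float:
        return self.width - 2 * self.margin

    @property
    def panel_height(self) -> float:
        return self.height - 2 * self.margin

    @property
    def panel_y0(self) -> float:
        return self.margin

    @property
    def tree_x0(self) -> float:
        return self.margin

    @property
    def tree_width(self) -> float:
        return self.inner_width * self.tree_fraction

    @property
    def bar_x0(self) -> float:
        spacer = self.inner_width * (1 - self.tree_fraction - self.bar_fraction)
        return self.margin + self.tree_width + spacer

    @property
    def bar_width(self) -> float:
        return self.inner_width * self.bar_fraction


@dataclass
class NodePlacement:
    node_id: str
    label: str
    x: float
    y: float
    depth: int
    is_collapsed: bool
    is_terminal: bool  # on the visible frontier (leaf or maximal collapsed node)


@dataclass
class TreeLayout:
    """Positions for visible nodes and edges; ``order`` is visible pre-order."""

    nodes: dict[str, NodePlacement]
    order: list[str]
    edges: list[tuple[str, str]]
    frontier: list[str]

    def positions(self) -> np.ndarray:
        return np.array([[self.nodes[n].x, self.nodes[n].y] for n in self.order], dtype=float)


def layout_tree(h: Hierarchy, s: ViewState, c: CanvasSpec) -> TreeLayout:
    """Lay out the visible tree: even leaf bands, parents at child-mean y.

    Deterministic; the root is always visible, so the layout is never empty.
    A single-node frontier sits at the vertical center of the panel.
    """
    frontier = effective_leaves(h, s)
    n = len(frontier)
    band = c.panel_height / n
    y_of: dict[str, float] = {
        nid: c.panel_y0 + (i + 0.5) * band for i, nid in enumerate(frontier)
    }
    frontier_set = set(frontier)

    order: list[str] = []
    edges: list[tuple[str, str]] = []
    depth_of: dict[str, int] = {h.root: 0}
    stack = [h.root]
    while stack:
        nid = stack.pop()
        order.append(nid)
        if nid in frontier_set:
            continue
        children = h.children(nid)
        for child in children:
            depth_of[child] = depth_of[nid] + 1
            edges.append((nid, child))
        stack.extend(reversed(children))

    # post-order pass for internal y
    def compute_y(nid: str) -> float:
        if nid in y_of:
            return y_of[nid]
        ys = [compute_y(ch) for ch in h.children(nid)]
        y_of[nid] = float(np.mean(ys))
        return y_of[nid]

    compute_y(h.root)

    max_depth = max(depth_of.values())
    xstep = c.tree_width / max_depth if max_depth > 0 else 0.0
    nodes = {
        nid: NodePlacement(
            node_id=nid,
            label=h.display_label(nid),
            x=c.tree_x0 + depth_of[nid] * xstep if max_depth > 0 else c.tree_x0 + c.tree_width / 2,
            y=y_of[nid],
            depth=depth_of[nid],
            is_collapsed=nid in s.collapsed,
            is_terminal=nid in frontier_set,
        )
        for nid in order
    }
    return TreeLayout(nodes=nodes, order=order, edges=edges, frontier=frontier)


@dataclass
class BarRect:
    sample_id: str
    leaf_id: str
    x: float
    y: float
    width: float
    height: float
    color_index: int | None
    value: float


@dataclass
class BarLayout:
    """Stacked rectangles per (sample, effective leaf), top-to-bottom.

    Zero-valued segments are kept with zero height so (sample × leaf)
    addressing is stable; renderers drop them.
    """

    rects: list[BarRect]
    bars: dict[str, tuple[float, float]]  # sample -> (x, width)
    sample_order: list[str]
    leaf_order: list[str]
    normalized: bool
    bar_height: float


def layout_bars(
    e: EffectiveComposition,
    arr: Arrangement,
    c: CanvasSpec,
    normalize: bool = True,
) -> BarLayout:
    """Stack the effective composition into bar rectangles.

    Normalized mode: each bar's segment heights sum to the full bar height
    (an all-zero sample yields zero-height segments).  Raw mode: one global
    scale set by the largest arranged sample total, so bars keep their
    relative totals.
    """
    samples = arr.ordered_samples
    index = {sid: i for i, sid in enumerate(e.sample_ids)}
    unknown = [sid for sid in samples if sid not in index]
    if unknown:
        raise LayoutError(f"arranged samples absent from composition: {unknown}")
    nbars = len(samples)
    if nbars == 0:
        raise LayoutError("empty arrangement")
    band = c.bar_width / nbars
    width = band * (1 - c.bar_gap)
    H = c.panel_height

    if not normalize:
        arranged = e.values[[index[sid] for sid in samples], :]
        max_total = float(arranged.sum(axis=1).max())
        scale = H / max_total if max_total > 0 else 0.0

    rects: list[BarRect] = []
    bars: dict[str, tuple[float, float]] = {}
    for bi, sid in enumerate(samples):
        row = e.values[index[sid], :]
        total = float(row.sum())
        if normalize:
            sc = H / total if total > 0 else 0.0
        else:
            sc = scale
        x = c.bar_x0 + bi * band + (band - width) / 2.0
        bars[sid] = (x, width)
        y = c.panel_y0
        for j, lid in enumerate(e.effective_leaf_ids):
            hgt = float(row[j]) * sc
            rects.append(
                BarRect(
                    sample_id=sid,
                    leaf_id=lid,
                    x=x,
                    y=y,
                    width=width,
                    height=hgt,
                    color_index=e.color_of[lid],
                    value=float(row[j]),
                )
            )
            y += hgt
    return BarLayout(
        rects=rects,
        bars=bars,
        sample_order=list(samples),
        leaf_order=list(e.effective_leaf_ids),
        normalized=normalize,
        bar_height=H,
    )


@dataclass
class HoverRegionMap:
    """Nearest-node partition of the tree panel over laid-out node sites.

    ``triangulation`` holds the Delaunay triangulation of the sites when one
    exists (≥3 affinely independent points); the point query itself is the
    dual nearest-site (Voronoi) lookup, with exact ties going to the smaller
    pre-order index.
    """

    ids: list[str]
    sites: np.ndarray
    triangulation: Delaunay | None = field(repr=False, default=None)

    def query(self, points) -> list[str]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.sites[None, :, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)  # first minimum = smallest pre-order index
        return [self.ids[i] for i in idx]

    def query_one(self, x: float, y: float) -> str:
        return self.query([[x, y]])[0]


def hover_map(t: TreeLayout) -> HoverRegionMap:
    """Build the hover partition from a tree layout (sites in pre-order)."""
    sites = t.positions()
    if sites.shape[0] == 0:
        raise LayoutError("no visible nodes to build a hover map from")
    tri = None
    if sites.shape[0] >= 3:
        try:
            tri = Delaunay(sites)
        except QhullError:
            tri = None  # degenerate (e.g. collinear) sites; query still exact
    return HoverRegionMap(ids=list(t.order), sites=sites, triangulation=tri)


def layout_to_dict(t: TreeLayout, b: BarLayout, legend_entries=None) -> dict:
    """JSON-able layout description for external renderers."""
    return {
        "tree": {
            "nodes": [
                {
                    "id": p.node_id,
                    "label": p.label,
                    "x": p.x,
                    "y": p.y,
                    "depth": p.depth,
                    "collapsed": p.is_collapsed,
                    "terminal": p.is_terminal,
                }
                for p in (t.nodes[n] for n in t.order)
            ],
            "edges": [{"parent": a, "child": bb} for a, bb in t.edges],
            "frontier": list(t.frontier),
        },
        "bars": {
            "sample_order": b.sample_order,
            "leaf_order": b.leaf_order,
            "normalized": b.normalized,
            "rects": [
                {
                    "sample": r.sample_id,
                    "leaf": r.leaf_id,
                    "x": r.x,
                    "y": r.y,
                    "width": r.width,
                    "height": r.height,
                    "color": r.color_index,
                    "value": r.value,
                }
                for r in b.rects
            ],
        },
        "legend": [
            {"node": le.node_id, "label": le.label, "color": le.color_index}
            for le in (legend_entries or [])
        ],
    }
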