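"""Deterministic SVG export of a laid-out view.

The export is the static equivalent of freezing the interactive view: tree
panel, stacked bars, legend and labels, written as a small SVG 1.1 subset
(``rect``, ``line``, ``circle``, ``text``, ``g`` — no CSS, no script).
Output is byte-stable: attribute order is fixed, coordinates are printed
with two decimals, fonts are referenced by family name only, and element
ids are derived from node/sample ids (``tree-node-<id>``,
``bar-<sample>-<leaf>``, ``legend-<i>``), so identical inputs give
identical bytes — the basis for snapshot testing.

Zero-height bar segments are dropped at this stage (the layout keeps them
for stable addressing).  Collapsed nodes are drawn with a thicker border.
Unpainted segments render in a neutral gray with thin separators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .arrange import Arrangement
from .layout import BarLayout, CanvasSpec, TreeLayout, layout_bars, layout_tree
from .tables import AbundanceTable
from .tree import Hierarchy
from .view import (
    DEFAULT_PALETTE,
    LegendEntry,
    ViewState,
    aggregate,
    legend as view_legend,
)

__all__ = ["StyleConfig", "SvgDocument", "RenderError", "render", "render_view"]

NEUTRAL_GRAY = "#cccccc"


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class StyleConfig:
    """Customizable appearance: palette, font sizes, strokes, dimensions."""

    palette: tuple[str, ...] = DEFAULT_PALETTE
    neutral_color: str = NEUTRAL_GRAY
    node_label_size: float = 10.0
    sample_label_size: float = 9.0
    legend_size: float = 11.0
    edge_stroke_width: float = 1.2
    node_radius: float = 3.0
    collapsed_border_multiplier: float = 2.5
    separator_width: float = 0.4
    label_mode: str = "legend"  # "legend" | "on-subtree"
    hide_sample_labels: bool = False
    width: float = 960.0
    height: float = 600.0
    font_family: str = "sans-serif"

    def __post_init__(self):
        if not self.palette:
            raise RenderError("palette must be non-empty")
        for name in ("node_label_size", "sample_label_size", "legend_size",
                     "edge_stroke_width", "node_radius", "collapsed_border_multiplier"):
            if getattr(self, name) <= 0:
                raise RenderError(f"{name} must be positive")
        if self.label_mode not in ("legend", "on-subtree"):
            raise RenderError(f"label_mode must be 'legend' or 'on-subtree', got {self.label_mode!r}")

    def canvas(self, **overrides) -> CanvasSpec:
        kw = {"width": self.width, "height": self.height}
        kw.update(overrides)
        return CanvasSpec(**kw)

    def color(self, index: int | None) -> str:
        if index is None:
            return self.neutral_color
        return self.palette[index % len(self.palette)]


@dataclass
class SvgDocument:
    """Rendered SVG text plus element counts for introspection/tests."""

    text: str
    counts: dict[str, int] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.text)

    def __str__(self) -> str:
        return self.text


_ID_SAFE = re.compile(r"[^A-Za-z0-9_.:-]")


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")
    )


def _sid(raw: str) -> str:
    return _ID_SAFE.sub("_", raw)


def _f(v: float) -> str:
    return f"{v:.2f}"


def render(
    t: TreeLayout,
    b: BarLayout,
    legend_entries: list[LegendEntry],
    sc: StyleConfig,
) -> SvgDocument:
    """Render tree + bars + legend to a byte-stable SVG document.

    The two layouts must come from the same view state (same frontier);
    a mismatch raises :class:`RenderError`.
    """
    if list(t.frontier) != list(b.leaf_order):
        raise RenderError(
            "tree and bar layouts disagree on the visible frontier: "
            f"{t.frontier} vs {b.leaf_order}"
        )
    W, H = sc.width, sc.height
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(W)}" height="{_f(H)}" '
        f'viewBox="0 0 {_f(W)} {_f(H)}" font-family="{_esc(sc.font_family)}">'
    )
    counts = {"nodes": 0, "edges": 0, "rects": 0, "legend": 0, "labels": 0}

    # tree edges (right-angle elbows look best in cladograms; straight lines
    # keep the geometry trivially checkable, so straight lines it is)
    out.append('<g id="edges">')
    for parent, child in t.edges:
        p, q = t.nodes[parent], t.nodes[child]
        out.append(
            f'<line x1="{_f(p.x)}" y1="{_f(p.y)}" x2="{_f(q.x)}" y2="{_f(q.y)}" '
            f'stroke="#555555" stroke-width="{_f(sc.edge_stroke_width)}"/>'
        )
        counts["edges"] += 1
    out.append("</g>")

    # tree nodes
    out.append('<g id="nodes">')
    for nid in t.order:
        p = t.nodes[nid]
        sw = sc.edge_stroke_width * (sc.collapsed_border_multiplier if p.is_collapsed else 1.0)
        out.append(
            f'<circle id="tree-node-{_sid(nid)}" cx="{_f(p.x)}" cy="{_f(p.y)}" '
            f'r="{_f(sc.node_radius)}" fill="#ffffff" stroke="#333333" stroke-width="{_f(sw)}"/>'
        )
        counts["nodes"] += 1
    out.append("</g>")

    # frontier node labels
    out.append('<g id="node-labels">')
    for nid in t.frontier:
        p = t.nodes[nid]
        out.append(
            f'<text x="{_f(p.x + sc.node_radius + 3)}" y="{_f(p.y)}" dy="0.32em" '
            f'font-size="{_f(sc.node_label_size)}" fill="#333333">{_esc(p.label)}</text>'
        )
        counts["labels"] += 1
    out.append("</g>")

    # bars: nonzero segments only
    out.append('<g id="bars">')
    for r in b.rects:
        if r.height <= 0:
            continue
        fill = sc.color(r.color_index)
        out.append(
            f'<rect id="bar-{_sid(r.sample_id)}-{_sid(r.leaf_id)}" x="{_f(r.x)}" y="{_f(r.y)}" '
            f'width="{_f(r.width)}" height="{_f(r.height)}" fill="{fill}" '
            f'stroke="#ffffff" stroke-width="{_f(sc.separator_width)}"/>'
        )
        counts["rects"] += 1
    out.append("</g>")

    # sample labels under the bars
    if not sc.hide_sample_labels:
        out.append('<g id="sample-labels">')
        for sid_ in b.sample_order:
            x, w = b.bars[sid_]
            out.append(
                f'<text x="{_f(x + w / 2)}" y="{_f(H - 3)}" text-anchor="middle" '
                f'font-size="{_f(sc.sample_label_size)}" fill="#333333">{_esc(sid_)}</text>'
            )
            counts["labels"] += 1
        out.append("</g>")

    # legend: separate block, or labels placed at the painted subtree roots
    out.append('<g id="legend">')
    if sc.label_mode == "on-subtree":
        for i, le in enumerate(legend_entries):
            if le.node_id not in t.nodes:
                raise RenderError(f"painted node {le.node_id!r} absent from tree layout")
            p = t.nodes[le.node_id]
            out.append(
                f'<g id="legend-{i}">'
                f'<text x="{_f(p.x)}" y="{_f(p.y - 6)}" text-anchor="middle" '
                f'font-size="{_f(sc.legend_size)}" fill="{sc.color(le.color_index)}">'
                f"{_esc(le.label)}</text></g>"
            )
            counts["legend"] += 1
            counts["labels"] += 1
    else:
        lx = W - 150.0
        for i, le in enumerate(legend_entries):
            ly = 14.0 + i * (sc.legend_size + 5)
            out.append(
                f'<g id="legend-{i}">'
                f'<rect x="{_f(lx)}" y="{_f(ly)}" width="{_f(sc.legend_size)}" '
                f'height="{_f(sc.legend_size)}" fill="{sc.color(le.color_index)}"/>'
                f'<text x="{_f(lx + sc.legend_size + 4)}" y="{_f(ly + sc.legend_size - 2)}" '
                f'font-size="{_f(sc.legend_size)}" fill="#333333">{_esc(le.label)}</text></g>'
            )
            counts["legend"] += 1
            counts["labels"] += 1
    out.append("</g>")
    out.append("</svg>")
    return SvgDocument(text="\n".join(out) + "\n", counts=counts)


def render_view(
    h: Hierarchy,
    a: AbundanceTable,
    s: ViewState,
    arr: Arrangement,
    sc: StyleConfig | None = None,
    normalize: bool = True,
    canvas: CanvasSpec | None = None,
) -> SvgDocument:
    """One-call pipeline: aggregate → layouts → legend → render."""
    sc = sc or StyleConfig()
    c = canvas or sc.canvas()
    e = aggregate(a, h, s)
    t = layout_tree(h, s, c)
    b = layout_bars(e, arr, c, normalize=normalize)
    entries = view_legend(h, s)
    return render(t, b, entries, sc)
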