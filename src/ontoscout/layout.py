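"""Visualization-ready layout geometry for the exploration graph.

Two layouts are computed as plain data, renderer-agnostic:

* a squarified treemap of the pruned hierarchy — sibling rectangle areas
  proportional to term size *relative to the siblings* (not to the root,
  which is inherently ambiguous in a polyhierarchy), colour emitted as the
  integer subtree depth;
* a layered node-link layout — terms in columns indexed by their
  distance to the root in the pruned graph, each column independently
  sortable (precision by default), with hidden-link counts for edges whose
  partner falls outside a visible window.

Coordinates live in the unit square, origin top-left, y growing downward;
rectangles are half-open [x, x+w) × [y, y+h).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import LayoutError, UnknownTermError
from .metrics import TermStat
from .pruning import ExplorationGraph

SortKey = Literal["precision", "recall", "name", "size"]
SORT_KEYS: tuple[str, ...] = ("precision", "recall", "name", "size")


# ---------------------------------------------------------------------------
# treemap

@dataclass
class TreemapNode:
    term: str
    rect: tuple[float, float, float, float]  # x, y, w, h
    area_fraction: float  # of the parent rectangle
    color_level: int  # subtree depth of the term in the pruned graph
    children: list["TreemapNode"] = field(default_factory=list)


@dataclass
class TreemapLayout:
    root_term: str
    visible_depth: int
    breadcrumb: list[str]  # absolute root ... root_term, provenance-expanded
    nodes: TreemapNode


def _worst_aspect(row: Sequence[float], side: float) -> float:
    """Worst aspect ratio of a row of areas laid along a side of length `side`."""
    total = sum(row)
    if total <= 0 or side <= 0:
        return float("inf")
    thickness = total / side
    worst = 1.0
    for area in row:
        length = area / thickness
        worst = max(worst, length / thickness, thickness / length)
    return worst


def _squarify(areas: list[float], x: float, y: float, w: float,
              h: float) -> list[tuple[float, float, float, float]]:
    """Squarified tiling of `areas` (summing to w*h) into the rectangle.

    Classic greedy algorithm: grow a row along the shorter side while the
    worst aspect ratio improves, then fix the row and recurse into the rest.
    """
    rects: list[tuple[float, float, float, float]] = []
    i = 0
    while i < len(areas):
        side = min(w, h)
        row = [areas[i]]
        j = i + 1
        while j < len(areas):
            if _worst_aspect(row + [areas[j]], side) <= _worst_aspect(row, side):
                row.append(areas[j])
                j += 1
            else:
                break
        total = sum(row)
        if w >= h:  # lay the row vertically along the left edge
            thickness = total / h if h > 0 else 0.0
            yy = y
            for area in row:
                hh = area / thickness if thickness > 0 else 0.0
                rects.append((x, yy, thickness, hh))
                yy += hh
            x += thickness
            w -= thickness
        else:  # horizontally along the top edge
            thickness = total / w if w > 0 else 0.0
            xx = x
            for area in row:
                ww = area / thickness if thickness > 0 else 0.0
                rects.append((xx, y, ww, thickness))
                xx += ww
            y += thickness
            h -= thickness
        i = j
    return rects


def _treemap_children(eg: ExplorationGraph, term: str,
                      rect: tuple[float, float, float, float],
                      levels_left: int) -> list[TreemapNode]:
    if levels_left <= 0:
        return []
    kids = [c for c in eg.graph.children_of(term) if eg.size_of(c) > 0]
    if not kids:
        return []
    # deterministic input order: size descending, tie by label then id
    kids.sort(key=lambda c: (-eg.size_of(c),
                             eg.graph.terms[c].display_label(), c))
    total = sum(eg.size_of(c) for c in kids)
    x, y, w, h = rect
    parent_area = w * h
    areas = [eg.size_of(c) / total * parent_area for c in kids]
    rects = _squarify(areas, x, y, w, h)
    nodes = []
    for c, r in zip(kids, rects):
        node = TreemapNode(
            term=c, rect=r, area_fraction=eg.size_of(c) / total,
            color_level=eg.measures.subtree_depth.get(c, 0),
            children=_treemap_children(eg, c, r, levels_left - 1))
        nodes.append(node)
    return nodes


def treemap_layout(eg: ExplorationGraph, root: str | None = None,
                   depth: int = 1) -> TreemapLayout:
    """Squarified treemap of `depth` nested levels below `root`.

    Terminal terms (no retained subclasses) carry no children and are the
    borderless rectangles of the rendering.  Sibling areas are normalised to
    the sibling size sum, so with overlapping polyhierarchy siblings areas
    remain a *relative*, not absolute, encoding.
    """
    root = root if root is not None else eg.root
    if root not in eg.graph.terms:
        raise UnknownTermError(root)
    if depth < 1:
        raise LayoutError("treemap depth must be >= 1")
    if root != eg.root and eg.size_of(root) == 0:
        raise LayoutError(f"cannot build a treemap on size-zero term {root}")
    unit = (0.0, 0.0, 1.0, 1.0)
    top = TreemapNode(
        term=root, rect=unit, area_fraction=1.0,
        color_level=eg.measures.subtree_depth.get(root, 0),
        children=_treemap_children(eg, root, unit, depth))
    return TreemapLayout(root_term=root, visible_depth=depth,
                         breadcrumb=breadcrumb_path(root, eg), nodes=top)


# ---------------------------------------------------------------------------
# node-link

@dataclass
class HiddenLinks:
    incoming: int = 0  # edges from parents outside the visible window
    outgoing: int = 0  # edges to children outside the visible window


@dataclass
class NodeLinkLayout:
    columns: list[list[str]]  # index = distance to root in the pruned graph
    sort_key: str
    bars: dict[str, tuple[float | None, float | None]]  # term -> (precision, recall)
    hidden_links: dict[str, HiddenLinks]
    window: tuple[int, int, int] | None  # (first_column, n_columns, rows_per_column)


def _column_sort_key(eg: ExplorationGraph, stats: dict[str, TermStat],
                     sort_key: str):
    def label(t: str) -> str:
        return eg.graph.terms[t].display_label()

    if sort_key == "name":
        return lambda t: (label(t).lower(), t)
    if sort_key == "size":
        return lambda t: (-eg.size_of(t), label(t), t)

    def numeric(t: str) -> tuple:
        s = stats.get(t)
        v = getattr(s, sort_key, None) if s is not None else None
        # undefined values sort after every defined one
        return ((0, -v) if v is not None else (1, 0.0), label(t), t)

    return numeric


def nodelink_layout(eg: ExplorationGraph, stats: dict[str, TermStat],
                    sort_key: str = "precision",
                    window: tuple[int, int, int] | None = None) -> NodeLinkLayout:
    """Columns by pruned-graph distance, sorted within each column.

    Numeric sort keys are descending; ties break by label then id.  When a
    window ``(first_column, n_columns, rows_per_column)`` is given, each
    visible term counts its edges to non-visible partners: parent links as
    incoming, child links as outgoing.
    """
    if sort_key not in SORT_KEYS:
        raise LayoutError(f"unknown sort key {sort_key!r}; expected one of {SORT_KEYS}")
    dist = eg.measures.distance
    terms = eg.retained_non_root()
    n_cols = (max((dist[t] for t in terms), default=0)) + 1
    columns: list[list[str]] = [[] for _ in range(n_cols)]
    for t in terms:
        columns[dist[t]].append(t)
    key = _column_sort_key(eg, stats, sort_key)
    for col in columns:
        col.sort(key=key)

    visible: set[str] = set(terms)
    if window is not None:
        first, width, rows = window
        visible = {
            t
            for ci in range(first, min(first + width, n_cols))
            for t in columns[ci][:rows]
        }

    hidden: dict[str, HiddenLinks] = {}
    for t in sorted(visible):
        hl = HiddenLinks()
        for p in eg.graph.parents_of(t):
            if p != eg.root and p not in visible:
                hl.incoming += 1
        for c in eg.graph.children_of(t):
            if c not in visible:
                hl.outgoing += 1
        hidden[t] = hl

    bars = {
        t: ((stats[t].precision, stats[t].recall) if t in stats else (None, None))
        for t in terms
    }
    return NodeLinkLayout(columns=columns, sort_key=sort_key, bars=bars,
                          hidden_links=hidden, window=window)


# ---------------------------------------------------------------------------
# breadcrumbs

def breadcrumb_path(term: str, eg: ExplorationGraph,
                    expand_provenance: bool = True) -> list[str]:
    """Shortest retained path from the absolute root down to ``term``.

    Among equally short paths the lexicographically smallest parent id wins
    at every step.  With ``expand_provenance`` the ancestors absorbed during
    pruning are interleaved (most general first) as display-only entries,
    restoring the full ontological lineage.
    """
    if term not in eg.graph.terms:
        raise UnknownTermError(term)
    dist = eg.measures.distance
    path = [term]
    cur = term
    while cur != eg.root:
        parents = sorted(eg.graph.parents_of(cur),
                         key=lambda p: (dist.get(p, 0), p))
        best = min(dist.get(p, 0) for p in parents)
        cur = next(p for p in parents if dist.get(p, 0) == best)
        path.append(cur)
    path.reverse()
    if not expand_provenance:
        return path
    expanded: list[str] = []
    for entry in path:
        # provenance is stored most-specific-first; display top-down
        expanded.extend(reversed(eg.provenance.get(entry, [])))
        expanded.append(entry)
    return expanded


# ---------------------------------------------------------------------------
# JSON export (stable key order)

def treemap_to_json(layout: TreemapLayout) -> str:
    def node_doc(n: TreemapNode) -> dict:
        return {
            "term": n.term,
            "rect": [round(v, 12) for v in n.rect],
            "area_fraction": round(n.area_fraction, 12),
            "color_level": n.color_level,
            "children": [node_doc(c) for c in n.children],
        }

    doc = {
        "kind": "treemap",
        "root_term": layout.root_term,
        "visible_depth": layout.visible_depth,
        "breadcrumb": layout.breadcrumb,
        "nodes": node_doc(layout.nodes),
    }
    return json.dumps(doc, indent=1)


def nodelink_to_json(layout: NodeLinkLayout) -> str:
    doc = {
        "kind": "nodelink",
        "sort_key": layout.sort_key,
        "window": list(layout.window) if layout.window else None,
        "columns": layout.columns,
        "bars": {
            t: [None if v is None else round(v, 12) for v in pr]
            for t, pr in sorted(layout.bars.items())
        },
        "hidden_links": {
            t: {"incoming": hl.incoming, "outgoing": hl.outgoing}
            for t, hl in sorted(layout.hidden_links.items())
        },
    }
    return json.dumps(doc, indent=1)
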