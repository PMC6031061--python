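import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoscout import (LayoutError, ROOT_ID, ResultSet, UnknownTermError,
                       breadcrumb_path, build_exploration_graph,
                       compute_all_stats, nodelink_layout, treemap_layout)
from ontoscout.layout import _squarify, _worst_aspect
from ontoscout.repository import AttributeValue, Dataset, Repository

from conftest import random_bundle
from test_ontology import make_graph

TOL = 1e-9


def bundle_from(edges, annotations):
    """Exploration bundle from explicit (child,parent) edges and
    dataset -> [terms] annotations."""
    g = make_graph(edges)
    repo = Repository()
    for did, terms in annotations.items():
        repo.add(Dataset(id=did, title=did, attributes=tuple(
            AttributeValue(f"a{i}", "x", t) for i, t in enumerate(terms))))
    eg = build_exploration_graph(g, repo)
    return g, repo, eg


# ---------------------------------------------------------------------------
# treemap

def sibling_fixture():
    return bundle_from(
        [("X:A", "X:P"), ("X:B", "X:P"), ("X:C", "X:P"), ("X:P", ROOT_ID)],
        {"d1": ["X:A"], "d2": ["X:A"], "d3": ["X:B"], "d4": ["X:C"]})


def test_sibling_areas_proportional_to_sizes():
    _, _, eg = sibling_fixture()
    tm = treemap_layout(eg, root="X:P", depth=1)
    fractions = {n.term: n.area_fraction for n in tm.nodes.children}
    assert fractions == {"X:A": 0.5, "X:B": 0.25, "X:C": 0.25}


def test_single_child_tiles_full_parent(mammalia):
    tm = treemap_layout(mammalia.eg, depth=1)
    (child,) = tm.nodes.children
    assert child.term == "NCBITaxon:9606"
    assert child.area_fraction == 1.0
    assert child.rect == (0.0, 0.0, 1.0, 1.0)


def test_depth_two_emits_exactly_two_levels(leukocyte):
    tm = treemap_layout(leukocyte.eg, depth=2)
    assert tm.visible_depth == 2
    for first in tm.nodes.children:
        for second in first.children:
            assert second.children == []  # recursion stops at the set depth


def test_terminal_terms_carry_no_children(leukocyte):
    tm = treemap_layout(leukocyte.eg, depth=4)
    leaves = [n for n in iter_nodes(tm.nodes)
              if not leukocyte.eg.graph.children_of(n.term)]
    assert leaves and all(n.children == [] for n in leaves)


def iter_nodes(node):
    yield node
    for c in node.children:
        yield from iter_nodes(c)


def assert_tiles(parent, children):
    px, py, pw, ph = parent
    area = sum(r[2] * r[3] for r in children)
    assert area == pytest.approx(pw * ph, abs=TOL)
    for (x, y, w, h) in children:
        assert x >= px - TOL and y >= py - TOL
        assert x + w <= px + pw + TOL and y + h <= py + ph + TOL
    # pairwise disjoint (half-open rectangles)
    for i, a in enumerate(children):
        for b in children[i + 1:]:
            ox = max(0.0, min(a[0] + a[2], b[0] + b[2]) - max(a[0], b[0]))
            oy = max(0.0, min(a[1] + a[3], b[1] + b[3]) - max(a[1], b[1]))
            assert ox * oy == pytest.approx(0.0, abs=TOL)


def test_children_tile_parent_exactly(taxonomy):
    """Disjoint-sibling case: child rectangles cover the parent with no
    overlap and no gap (area conserved to 1e-9 at every level)."""
    tm = treemap_layout(taxonomy.eg, depth=3)
    for node in iter_nodes(tm.nodes):
        if node.children:
            assert_tiles(node.rect, [c.rect for c in node.children])


def test_color_level_is_subtree_depth(leukocyte):
    tm = treemap_layout(leukocyte.eg, depth=2)
    for node in iter_nodes(tm.nodes):
        assert node.color_level == \
            leukocyte.eg.measures.subtree_depth[node.term]


def test_treemap_on_zero_size_root_is_error(leukocyte):
    with pytest.raises((LayoutError, UnknownTermError)):
        treemap_layout(leukocyte.eg, root="CL:9999999", depth=1)
    with pytest.raises(LayoutError):
        treemap_layout(leukocyte.eg, depth=0)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=50), min_size=1,
                max_size=9))
def test_squarify_rows_satisfy_greedy_stopping_rule(sizes):
    """Reconstruct the rows of the squarified tiling and check local
    optimality: when a row was closed, admitting the next sibling would not
    have improved (lowered) the row's worst aspect ratio."""
    sizes = sorted(sizes, reverse=True)
    total = sum(sizes)
    areas = [s / total for s in sizes]
    rects = _squarify(areas, 0.0, 0.0, 1.0, 1.0)
    assert sum(w * h for _, _, w, h in rects) == pytest.approx(1.0, abs=TOL)

    # peel strips off the free rectangle in emission order
    x = y = 0.0
    w = h = 1.0
    i = 0
    while i < len(rects):
        side = min(w, h)
        vertical = w >= h
        strip = [rects[i]]
        j = i + 1
        while j < len(rects) and (
                rects[j][0] == rects[i][0] if vertical
                else rects[j][1] == rects[i][1]):
            strip.append(rects[j])
            j += 1
        row_areas = [r[2] * r[3] for r in strip]
        if j < len(rects):
            # stopping rule: admitting the next sibling into this row would
            # not have improved the row's worst aspect ratio
            nxt = rects[j][2] * rects[j][3]
            assert _worst_aspect(row_areas + [nxt], side) >= \
                _worst_aspect(row_areas, side) - TOL
        # extension rule: every element after the first joined the row only
        # because it did not worsen the worst aspect ratio at that point
        for k in range(1, len(row_areas)):
            assert _worst_aspect(row_areas[:k + 1], side) <= \
                _worst_aspect(row_areas[:k], side) + TOL
        thickness = sum(row_areas) / side
        if vertical:
            x += thickness
            w -= thickness
        else:
            y += thickness
            h -= thickness
        i = j


def test_breadcrumb_in_layout_reaches_absolute_root(leukocyte):
    tm = treemap_layout(leukocyte.eg, root="CL:0000738", depth=1)
    assert tm.breadcrumb[0] == ROOT_ID
    assert tm.breadcrumb[-1] == "CL:0000738"


# ---------------------------------------------------------------------------
# node-link

def test_columns_partition_terms_by_distance(leukocyte):
    stats = compute_all_stats(ResultSet.of(leukocyte.repo.ids()), leukocyte.eg)
    nl = nodelink_layout(leukocyte.eg, stats)
    for ci, col in enumerate(nl.columns):
        for t in col:
            assert leukocyte.eg.measures.distance[t] == ci
    placed = [t for col in nl.columns for t in col]
    assert sorted(placed) == leukocyte.eg.retained_non_root()


def test_default_sort_is_precision_descending(leukocyte):
    result = ResultSet.of(["lk01", "lk02", "lk03", "lk04", "lk05"])
    stats = compute_all_stats(result, leukocyte.eg)
    nl = nodelink_layout(leukocyte.eg, stats)
    assert nl.sort_key == "precision"
    for col in nl.columns:
        values = [stats[t].precision for t in col if t in stats]
        assert values == sorted(values, reverse=True)


def test_unknown_sort_key_is_error(leukocyte):
    stats = compute_all_stats(ResultSet.of(leukocyte.repo.ids()), leukocyte.eg)
    with pytest.raises(LayoutError):
        nodelink_layout(leukocyte.eg, stats, sort_key="magic")


def test_full_window_has_no_hidden_links(leukocyte):
    stats = compute_all_stats(ResultSet.of(leukocyte.repo.ids()), leukocyte.eg)
    nl = nodelink_layout(leukocyte.eg, stats,
                         window=(0, len(nl_cols(leukocyte)), 10_000))
    assert all(hl.incoming == 0 and hl.outgoing == 0
               for hl in nl.hidden_links.values())


def nl_cols(bundle):
    stats = compute_all_stats(ResultSet.of(bundle.repo.ids()), bundle.eg)
    return nodelink_layout(bundle.eg, stats).columns


def test_hidden_links_match_edge_enumeration(leukocyte):
    """Hiding one column: every edge crossing into it is counted once on its
    visible endpoint; totals equal a brute-force edge scan."""
    eg = leukocyte.eg
    stats = compute_all_stats(ResultSet.of(leukocyte.repo.ids()), eg)
    n_cols = len(nl_cols(leukocyte))
    nl = nodelink_layout(eg, stats, window=(0, n_cols - 1, 10_000))
    hidden_terms = set(nl_cols(leukocyte)[n_cols - 1])
    visible = set(nl.hidden_links)
    assert visible.isdisjoint(hidden_terms)
    for t in visible:
        incoming = sum(1 for p in eg.graph.parents_of(t)
                       if p != ROOT_ID and p in hidden_terms)
        outgoing = sum(1 for c in eg.graph.children_of(t)
                       if c in hidden_terms)
        assert nl.hidden_links[t].incoming == incoming
        assert nl.hidden_links[t].outgoing == outgoing


def test_rows_per_column_limit_hides_overflow(leukocyte):
    stats = compute_all_stats(ResultSet.of(leukocyte.repo.ids()), leukocyte.eg)
    nl = nodelink_layout(leukocyte.eg, stats, window=(0, 10, 1))
    visible = set(nl.hidden_links)
    assert visible == {col[0] for col in nl.columns if col}


# ---------------------------------------------------------------------------
# breadcrumbs

def test_breadcrumb_distance_one_term():
    _, _, eg = sibling_fixture()
    assert breadcrumb_path("X:P", eg) == [ROOT_ID, "X:P"]


def test_breadcrumb_expands_absorbed_lineage(mammalia):
    """The collapsed taxon chain reappears as display-only lineage between
    the root and human, in top-down order."""
    assert breadcrumb_path("NCBITaxon:9606", mammalia.eg) == [
        ROOT_ID, "NCBITaxon:33208", "NCBITaxon:7742", "NCBITaxon:40674",
        "NCBITaxon:9443", "NCBITaxon:9605", "NCBITaxon:9606"]
    assert breadcrumb_path("NCBITaxon:9606", mammalia.eg,
                           expand_provenance=False) == \
        [ROOT_ID, "NCBITaxon:9606"]


def test_breadcrumb_diamond_takes_shortest_path_tie_lexicographic():
    _, _, eg = bundle_from(
        [("X:B", ROOT_ID), ("X:C", ROOT_ID), ("X:D", "X:B"), ("X:D", "X:C")],
        {"d1": ["X:D"], "d2": ["X:B"], "d3": ["X:C"]})
    # all-paths check: both [root,B,D] and [root,C,D] are shortest
    assert breadcrumb_path("X:D", eg) == [ROOT_ID, "X:B", "X:D"]


def test_breadcrumb_unknown_term_is_error(leukocyte):
    with pytest.raises(UnknownTermError):
        breadcrumb_path("XX:404", leukocyte.eg)
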