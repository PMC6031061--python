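import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoscout import (CartError, DataCart, QueryParseError, TermQuery,
                       TextQuery, UnknownTermError, cart_add, cart_list,
                       cart_remove, evaluate, evaluate_term_query,
                       highlight_terms, kwic_snippet, parse_query, root_at,
                       text_search, toggle_query_state)
from ontoscout.query import QueryExpression, tokenize

from _oracles import closure_by_dataset, term_query_oracle
from conftest import random_bundle

NATIVE = "CL:0000003"
PRECURSOR = "CL:0011115"
LEUKOCYTE = "CL:0000738"


# ---------------------------------------------------------------------------
# text search

def test_synonym_expansion_retrieves_mice_for_mouse(leukocyte):
    """'mouse' matches a dataset whose text only says 'mice', through the
    ontology synonym list of the mouse term."""
    result = text_search(TextQuery("mouse"), leukocyte.repo, leukocyte.graph)
    assert "lk02" in result.retrieved  # lk02 mentions only "mice"
    without = text_search(TextQuery("mouse", expand_synonyms=False),
                          leukocyte.repo, leukocyte.graph)
    assert "lk02" not in without.retrieved


def test_leukocyte_text_search_retrieves_nothing(leukocyte):
    """No free text mentions 'leukocyte' even though 12 datasets carry
    leukocyte subtype annotations — the scenario motivating semantic search."""
    assert len(text_search(TextQuery("leukocyte"), leukocyte.repo,
                           leukocyte.graph)) == 0


def test_empty_query_returns_whole_repository(leukocyte):
    result = text_search(TextQuery(""), leukocyte.repo, leukocyte.graph)
    assert list(result.retrieved) == leukocyte.repo.ids()


def test_multi_token_search_is_conjunctive(fig5):
    result = text_search(TextQuery("human hepatocyte p53"), fig5.repo,
                         fig5.graph)
    assert list(result.retrieved) == ["ds1"]


def test_ranking_prefers_title_matches_and_breaks_ties_by_id(leukocyte):
    result = text_search(TextQuery("monocyte"), leukocyte.repo, leukocyte.graph)
    assert result.retrieved[0] == "lk05"  # 'monocyte' in the title
    repeated = text_search(TextQuery("monocyte"), leukocyte.repo,
                           leukocyte.graph)
    assert result.retrieved == repeated.retrieved


# ---------------------------------------------------------------------------
# KWIC snippets

def test_kwic_marks_match_with_context(leukocyte):
    snippet = kwic_snippet(leukocyte.repo["lk01"], TextQuery("spleen"),
                           window=10, graph=leukocyte.graph)
    assert "[spleen]" in snippet
    assert snippet.startswith("…")


def test_kwic_at_field_start_has_no_leading_ellipsis(leukocyte):
    snippet = kwic_snippet(leukocyte.repo["lk05"], TextQuery("mouse"),
                           window=15, graph=leukocyte.graph)
    assert snippet.startswith("[Mouse]")


def test_kwic_centers_matched_synonym_not_query_token(leukocyte):
    """Searching 'mouse' against text that says 'mice' marks the synonym
    occurrence; offsets agree with a naive substring scan."""
    d = leukocyte.repo["lk02"]
    snippet = kwic_snippet(d, TextQuery("mouse"), window=8,
                           graph=leukocyte.graph)
    assert "[mice]" in snippet
    naive = d.title.lower().find("mice")
    assert d.title[naive:naive + 4] == "mice"


def test_kwic_no_match_is_empty(leukocyte):
    assert kwic_snippet(leukocyte.repo["lk01"], TextQuery("zebrafish"),
                        graph=leukocyte.graph) == ""


# ---------------------------------------------------------------------------
# term queries

def test_native_cell_minus_precursor_retrieves_five(leukocyte):
    tq = TermQuery(and_terms=frozenset({NATIVE}),
                   not_terms=frozenset({PRECURSOR}))
    result = evaluate_term_query(tq, leukocyte.index)
    assert sorted(result.retrieved) == ["lk01", "lk02", "lk03", "lk04", "lk05"]


def test_empty_term_query_returns_universe(leukocyte):
    assert evaluate_term_query(TermQuery(), leukocyte.index).as_set() == \
        leukocyte.index.universe


def test_unknown_term_raises_with_name(leukocyte):
    with pytest.raises(UnknownTermError, match="XX:404"):
        evaluate_term_query(TermQuery(and_terms=frozenset({"XX:404"})),
                            leukocyte.index)


def test_not_only_query_is_universe_minus_union(leukocyte):
    tq = TermQuery(not_terms=frozenset({PRECURSOR, "NCBITaxon:9606"}))
    result = evaluate_term_query(tq, leukocyte.index)
    expected = (leukocyte.index.universe
                - leukocyte.index.transitive_of(PRECURSOR)
                - leukocyte.index.transitive_of("NCBITaxon:9606"))
    assert result.as_set() == expected


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.data())
def test_term_query_matches_per_dataset_predicate_oracle(seed, data):
    b = random_bundle(seed, n_terms=50, n_datasets=40)
    used = sorted(b.index.transitive)
    closure = closure_by_dataset(b.graph, b.repo)
    chosen = data.draw(st.lists(st.sampled_from(used), min_size=0, max_size=6,
                                unique=True))
    roles = data.draw(st.lists(st.sampled_from(["and", "or", "not"]),
                               min_size=len(chosen), max_size=len(chosen)))
    groups = {"and": set(), "or": set(), "not": set()}
    for t, role in zip(chosen, roles):
        groups[role].add(t)
    tq = TermQuery(and_terms=frozenset(groups["and"]),
                   or_terms=frozenset(groups["or"]),
                   not_terms=frozenset(groups["not"]))
    result = evaluate_term_query(tq, b.index)
    assert result.as_set() == term_query_oracle(
        b.repo, closure, groups["and"], groups["or"], groups["not"])


# ---------------------------------------------------------------------------
# query-state toggling

def test_toggle_cycles_through_four_states(leukocyte):
    tq = TermQuery()
    states = []
    for _ in range(4):
        tq = toggle_query_state(tq, NATIVE)
        states.append(tq.state_of(NATIVE))
    assert states == ["or", "and", "not", "none"]
    assert tq == TermQuery()  # cycle of length four restores the query


def test_toggle_moves_term_between_sets():
    tq = TermQuery(and_terms=frozenset({NATIVE}))
    tq = toggle_query_state(tq, NATIVE)
    assert NATIVE in tq.not_terms and NATIVE not in tq.and_terms


def test_term_cannot_be_in_two_sets():
    with pytest.raises(ValueError):
        TermQuery(and_terms=frozenset({NATIVE}), or_terms=frozenset({NATIVE}))


# ---------------------------------------------------------------------------
# rooting

def test_root_at_native_cell_restricts_view_and_results(leukocyte):
    view, tq = root_at(NATIVE, leukocyte.eg, TermQuery())
    assert tq.root_term == NATIVE
    assert view.visible_terms == {NATIVE} | leukocyte.eg.graph.descendants(NATIVE)
    result = evaluate_term_query(tq, leukocyte.index)
    assert result.as_set() <= leukocyte.index.transitive_of(NATIVE)


def test_root_at_leaf_is_single_node_view(leukocyte):
    view, _ = root_at("CL:0000084", leukocyte.eg, TermQuery())
    assert view.visible_terms == {"CL:0000084"}


def test_unroot_restores_original_view_and_results(leukocyte):
    _, rooted = root_at(NATIVE, leukocyte.eg, TermQuery())
    restored_view, restored = root_at(None, leukocyte.eg, rooted)
    assert restored_view is leukocyte.eg
    assert restored == TermQuery()
    assert evaluate_term_query(restored, leukocyte.index).as_set() == \
        leukocyte.index.universe


def test_rooting_commutes_with_querying(leukocyte):
    tq = TermQuery(not_terms=frozenset({PRECURSOR}))
    _, rooted = root_at(NATIVE, leukocyte.eg, tq)
    via_root = evaluate_term_query(rooted, leukocyte.index)
    direct = evaluate_term_query(
        TermQuery(not_terms=frozenset({PRECURSOR}), root_term=NATIVE),
        leukocyte.index)
    assert via_root.as_set() == direct.as_set()


def test_root_at_pruned_term_is_error(leukocyte):
    with pytest.raises(UnknownTermError):
        root_at("CL:0000000", leukocyte.eg, TermQuery())  # collapsed term


# ---------------------------------------------------------------------------
# combined evaluation

def test_combined_mouse_native_not_precursor_scenario(leukocyte):
    """Free text 'mouse' + annotated native cell + no precursor annotations."""
    q = QueryExpression(
        text=TextQuery("mouse"),
        terms=TermQuery(and_terms=frozenset({NATIVE}),
                        not_terms=frozenset({PRECURSOR})))
    result = evaluate(q, leukocyte.repo, leukocyte.eg, leukocyte.index,
                      leukocyte.graph)
    assert sorted(result.retrieved) == ["lk01", "lk02", "lk03", "lk04", "lk05"]


def test_empty_combined_query_returns_everything(leukocyte):
    q = QueryExpression()
    result = evaluate(q, leukocyte.repo, leukocyte.eg, leukocyte.index,
                      leukocyte.graph)
    assert result.as_set() == leukocyte.index.universe


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.data())
def test_combined_result_is_intersection_of_components(seed, data):
    b = random_bundle(seed, n_terms=40, n_datasets=30)
    used = sorted(b.index.transitive)
    term = data.draw(st.sampled_from(used))
    word = data.draw(st.sampled_from(["study", "profile", "assay", "cohort",
                                      "series", "screen", "term"]))
    q = QueryExpression(text=TextQuery(word),
                        terms=TermQuery(and_terms=frozenset({term})))
    combined = evaluate(q, b.repo, b.eg, b.index, b.graph).as_set()
    text_only = text_search(q.text, b.repo, b.graph).as_set()
    terms_only = evaluate_term_query(q.terms, b.index).as_set()
    assert combined == text_only & terms_only


# ---------------------------------------------------------------------------
# canonical query strings

def test_parse_canonical_query_round_trip():
    q = parse_query('"mouse liver" +term:CL:0000003 -term:CL:0011115 '
                    '~term:CL:0000738 root:CL:0000003')
    assert q.text.raw == "mouse liver"
    assert q.terms.and_terms == {"CL:0000003"}
    assert q.terms.not_terms == {"CL:0011115"}
    assert q.terms.or_terms == {"CL:0000738"}
    assert q.terms.root_term == "CL:0000003"
    assert parse_query(q.canonical()) == q


@pytest.mark.parametrize("bad", ["+term:", "root:a root:b",
                                 "+term:X:1 -term:X:1"])
def test_malformed_query_strings_raise(bad):
    with pytest.raises(QueryParseError):
        parse_query(bad)


# ---------------------------------------------------------------------------
# data cart

def test_cart_deduplicates_and_preserves_order(leukocyte):
    cart = DataCart()
    cart_add(cart, ["lk03", "lk01", "lk03"], leukocyte.repo)
    assert cart_list(cart) == ["lk03", "lk01"]
    cart_add(cart, ["lk01", "lk02"], leukocyte.repo)
    assert cart_list(cart) == ["lk03", "lk01", "lk02"]


def test_cart_saved_collections_overlap_deduplicated(leukocyte):
    """Saving one collection and later a larger overlapping one keeps each
    dataset once, in first-seen order."""
    cart = DataCart()
    cart_add(cart, ["lk01", "lk02", "lk03"], leukocyte.repo)
    cart_add(cart, ["lk02", "lk03", "lk04", "lk05"], leukocyte.repo)
    assert cart_list(cart) == ["lk01", "lk02", "lk03", "lk04", "lk05"]


def test_cart_unknown_ids_are_errors(leukocyte):
    cart = DataCart()
    with pytest.raises(CartError):
        cart_add(cart, ["nope"], leukocyte.repo)
    with pytest.raises(CartError):
        cart_remove(cart, ["lk01"])


# ---------------------------------------------------------------------------
# highlighting

def test_highlight_direct_vs_indirect_terms(mammalia):
    """A dataset annotated only 'human' highlights human directly; its
    retained ancestors (none here besides the root) come back outlined."""
    direct, indirect = highlight_terms(mammalia.repo["hs01"], mammalia.eg)
    assert direct == {"NCBITaxon:9606"}
    assert indirect == frozenset()


def test_highlight_two_terms_share_ancestor_once(leukocyte):
    d = leukocyte.repo["lk06"]  # T cell + HSC + mouse
    direct, indirect = highlight_terms(d, leukocyte.eg)
    assert {"CL:0000084", "CL:0000037", "NCBITaxon:10090"} == direct
    assert NATIVE in indirect  # shared ancestor listed once
    assert not (direct & indirect)


def test_highlight_unannotated_dataset_is_empty(fig5):
    from ontoscout.repository import Dataset

    plain = Dataset(id="zz", title="no annotations")
    assert highlight_terms(plain, fig5.eg) == (frozenset(), frozenset())


def test_tokenize_is_deterministic_lowercase():
    assert tokenize("RNA-Seq of Mouse/human!") == ["rna", "seq", "of",
                                                   "mouse", "human"]
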