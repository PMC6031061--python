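"""Free-text search, Boolean term queries, rooting, and the data cart.

Text search is conjunctive token matching (every query token, or one of its
synonym expansions, must occur in the dataset's title, description or an
attribute text value), ranked by a BM25-style weighted relevance score.
Term queries are pure set algebra over the transitive annotation sets:

    base   = (∩ over AND-terms) ∩ (∪ over OR-terms, or universe if none)
    result = base − (∪ over NOT-terms)            [∩ S_root_term if rooted]

AND is intersected first and NOT subtracted last, so NOT is an absolute
exclusion.  A combined query is the intersection of the text result and the
term result, in text-relevance order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

from .errors import CartError, QueryParseError, UnknownTermError
from .metrics import ResultSet
from .ontology import OntologyGraph
from .pruning import ExplorationGraph
from .repository import AnnotationIndex, Dataset, Repository

QueryState = Literal["none", "or", "and", "not"]
_STATE_CYCLE: tuple[QueryState, ...] = ("none", "or", "and", "not")

_TOKEN = re.compile(r"[a-z0-9]+")

#: Field weights of the relevance score (title is boosted).
FIELD_WEIGHTS = {"title": 3.0, "description": 1.0, "attribute": 1.0}


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, no stemming."""
    return _TOKEN.findall(text.lower())


# ---------------------------------------------------------------------------
# query expressions

@dataclass(frozen=True)
class TextQuery:
    raw: str = ""
    expand_synonyms: bool = True

    def tokens(self) -> list[str]:
        return tokenize(self.raw)


@dataclass(frozen=True)
class TermQuery:
    """Boolean annotation-term query with four per-term states.

    Every term is in at most one of the or/and/not sets; ``root_term``
    restricts both the visible subtree and the retrieved datasets.
    """

    or_terms: frozenset[str] = frozenset()
    and_terms: frozenset[str] = frozenset()
    not_terms: frozenset[str] = frozenset()
    root_term: str | None = None

    def __post_init__(self):
        sets = (self.or_terms, self.and_terms, self.not_terms)
        total = sum(len(s) for s in sets)
        if len(self.or_terms | self.and_terms | self.not_terms) != total:
            raise ValueError("a term may appear in at most one of or/and/not")

    def state_of(self, term: str) -> QueryState:
        if term in self.or_terms:
            return "or"
        if term in self.and_terms:
            return "and"
        if term in self.not_terms:
            return "not"
        return "none"

    def is_empty(self) -> bool:
        return not (self.or_terms or self.and_terms or self.not_terms
                    or self.root_term)


@dataclass(frozen=True)
class QueryExpression:
    text: TextQuery = TextQuery()
    terms: TermQuery = TermQuery()

    def canonical(self) -> str:
        """Canonical string form shown in the query term bar / accepted by
        the CLI: free text plus `+term:` (and), `~term:` (or), `-term:` (not)
        and `root:` clauses."""
        parts: list[str] = []
        if self.text.raw:
            parts.append(f'"{self.text.raw}"')
        parts += [f"+term:{t}" for t in sorted(self.terms.and_terms)]
        parts += [f"~term:{t}" for t in sorted(self.terms.or_terms)]
        parts += [f"-term:{t}" for t in sorted(self.terms.not_terms)]
        if self.terms.root_term:
            parts.append(f"root:{self.terms.root_term}")
        return " ".join(parts)


def parse_query(raw: str, expand_synonyms: bool = True) -> QueryExpression:
    """Parse the canonical query-string syntax.

    Free text may be quoted or bare; clauses are whitespace-separated.
    """
    text_parts: list[str] = []
    and_t, or_t, not_t = set(), set(), set()
    root: str | None = None
    tokens = re.findall(r'"[^"]*"|\S+', raw)
    for i, tok in enumerate(tokens):
        if tok.startswith("+term:"):
            val = tok[len("+term:"):]
        elif tok.startswith("~term:"):
            val = tok[len("~term:"):]
        elif tok.startswith("-term:"):
            val = tok[len("-term:"):]
        elif tok.startswith("root:"):
            val = tok[len("root:"):]
        else:
            text_parts.append(tok.strip('"'))
            continue
        if not val:
            raise QueryParseError(f"clause {tok!r} has an empty term id", i)
        if tok.startswith("+term:"):
            and_t.add(val)
        elif tok.startswith("~term:"):
            or_t.add(val)
        elif tok.startswith("-term:"):
            not_t.add(val)
        else:
            if root is not None:
                raise QueryParseError("multiple root: clauses", i)
            root = val
    try:
        tq = TermQuery(or_terms=frozenset(or_t), and_terms=frozenset(and_t),
                       not_terms=frozenset(not_t), root_term=root)
    except ValueError as exc:
        raise QueryParseError(str(exc)) from exc
    return QueryExpression(text=TextQuery(raw=" ".join(text_parts),
                                          expand_synonyms=expand_synonyms),
                           terms=tq)


def toggle_query_state(tq: TermQuery, term: str) -> TermQuery:
    """Cycle a term through none -> or -> and -> not -> none."""
    state = tq.state_of(term)
    nxt = _STATE_CYCLE[(_STATE_CYCLE.index(state) + 1) % 4]
    or_t = set(tq.or_terms) - {term}
    and_t = set(tq.and_terms) - {term}
    not_t = set(tq.not_terms) - {term}
    if nxt == "or":
        or_t.add(term)
    elif nxt == "and":
        and_t.add(term)
    elif nxt == "not":
        not_t.add(term)
    return TermQuery(or_terms=frozenset(or_t), and_terms=frozenset(and_t),
                     not_terms=frozenset(not_t), root_term=tq.root_term)


# ---------------------------------------------------------------------------
# text search

def _synonym_groups(graph: OntologyGraph) -> dict[str, frozenset[str]]:
    """token -> expansion token set, derived from ontology labels/synonyms.

    A query token that equals a term's single-word label or synonym is
    expanded with that term's other single-word names; e.g. 'mouse' ->
    {'mouse', 'mice'}.  Multi-word synonyms do not participate (token
    matching has no phrase semantics, and expanding 'leukocyte' with the
    individual words of 'white blood cell' would match unrelated text).
    """
    groups: dict[str, set[str]] = {}
    for term in graph.terms.values():
        names = [term.label, *term.synonyms]
        single = {n.lower().strip() for n in names
                  if n.strip() and " " not in n.strip()}
        for key in single:
            groups.setdefault(key, set()).update(single)
    return {k: frozenset(v) for k, v in groups.items()}


def _dataset_fields(dataset: Dataset) -> list[tuple[str, str]]:
    fields = [("title", dataset.title), ("description", dataset.description)]
    fields += [("attribute", a.text_value) for a in dataset.attributes
               if a.text_value]
    return fields


def text_search(q: TextQuery, repo: Repository,
                graph: OntologyGraph | None = None) -> ResultSet:
    """Conjunctive token search over title, description and attribute text.

    With synonym expansion on, each query token may be satisfied by any
    token of its ontology-derived expansion group.  Results are ranked by a
    BM25-style score (field-weighted term frequency, inverse document
    frequency, length normalisation), ties broken by dataset id.  An empty
    query returns the whole repository in id order.
    """
    tokens = q.tokens()
    if not tokens:
        return ResultSet.of(repo.ids(), query=q)

    groups: list[frozenset[str]] = []
    syn = _synonym_groups(graph) if (q.expand_synonyms and graph is not None) else {}
    for tok in tokens:
        groups.append(syn.get(tok, frozenset()) | {tok})

    # token statistics per dataset
    field_tf: dict[str, dict[str, dict[str, int]]] = {}
    doc_len: dict[str, int] = {}
    for d in repo.datasets.values():
        tf: dict[str, dict[str, int]] = {}
        n = 0
        for fname, text in _dataset_fields(d):
            for tok in tokenize(text):
                tf.setdefault(fname, {}).setdefault(tok, 0)
                tf[fname][tok] += 1
                n += 1
        field_tf[d.id] = tf
        doc_len[d.id] = n

    def group_tf(did: str, group: frozenset[str]) -> dict[str, int]:
        return {f: sum(tfs.get(tok, 0) for tok in group)
                for f, tfs in field_tf[did].items()}

    n_docs = len(repo)
    avg_len = (sum(doc_len.values()) / n_docs) if n_docs else 1.0
    k1, b = 1.5, 0.75
    scored: list[tuple[float, str]] = []
    for did in repo.ids():
        score = 0.0
        matched_all = True
        for group in groups:
            per_field = group_tf(did, group)
            weighted_tf = sum(FIELD_WEIGHTS[f] * c for f, c in per_field.items())
            if weighted_tf == 0:
                matched_all = False
                break
            df = sum(
                1 for other in repo.ids()
                if any(sum(tfs.get(tok, 0) for tok in group) > 0
                       for tfs in field_tf[other].values()))
            idf = math.log(1.0 + (n_docs - df + 0.5) / (df + 0.5))
            norm = k1 * (1.0 - b + b * doc_len[did] / (avg_len or 1.0))
            score += idf * weighted_tf * (k1 + 1.0) / (weighted_tf + norm)
        if matched_all:
            scored.append((score, did))
    scored.sort(key=lambda sd: (-sd[0], sd[1]))
    return ResultSet.of((did for _, did in scored), query=q)


def kwic_snippet(dataset: Dataset, q: TextQuery, window: int = 30,
                 graph: OntologyGraph | None = None) -> str:
    """Keyword-in-context snippet for the first matched token.

    The matched token (which may be a synonym of the query token) is wrapped
    in square brackets, with up to ``window`` characters of context on each
    side; an ellipsis marks truncation.  Empty string when nothing matches.
    """
    tokens = q.tokens()
    if not tokens:
        return ""
    syn = _synonym_groups(graph) if (q.expand_synonyms and graph is not None) else {}
    accepted = set()
    for tok in tokens:
        accepted |= syn.get(tok, frozenset()) | {tok}
    for _, text in _dataset_fields(dataset):
        low = text.lower()
        best: tuple[int, int] | None = None
        for m in _TOKEN.finditer(low):
            if m.group(0) in accepted and (best is None or m.start() < best[0]):
                best = (m.start(), m.end())
        if best is None:
            continue
        start, end = best
        lo = max(0, start - window)
        hi = min(len(text), end + window)
        prefix = "…" if lo > 0 else ""
        suffix = "…" if hi < len(text) else ""
        return (f"{prefix}{text[lo:start]}[{text[start:end]}]"
                f"{text[end:hi]}{suffix}")
    return ""


# ---------------------------------------------------------------------------
# term queries

def _resolve(term: str, source: AnnotationIndex | ExplorationGraph) -> frozenset[str]:
    s = source.transitive_of(term)
    if not s:
        if isinstance(source, ExplorationGraph) and term not in source.graph.terms:
            raise UnknownTermError(term, "not retained in the exploration graph")
        if isinstance(source, AnnotationIndex) and term not in source.transitive:
            raise UnknownTermError(term, "no annotated dataset")
    return s


def evaluate_term_query(tq: TermQuery,
                        index: AnnotationIndex | ExplorationGraph) -> ResultSet:
    """Pure set algebra over transitive annotation sets (see module docs)."""
    universe = index.universe if isinstance(index, AnnotationIndex) else index.universe
    if tq.and_terms or tq.or_terms:
        base: frozenset[str] | None = None
        for t in sorted(tq.and_terms):
            s = _resolve(t, index)
            base = s if base is None else (base & s)
        if tq.or_terms:
            union: frozenset[str] = frozenset()
            for t in sorted(tq.or_terms):
                union |= _resolve(t, index)
            base = union if base is None else (base & union)
        assert base is not None
    else:
        base = universe
    for t in sorted(tq.not_terms):
        base -= _resolve(t, index)
    if tq.root_term is not None:
        base &= _resolve(tq.root_term, index)
    return ResultSet.of(sorted(base), query=tq)


@dataclass(frozen=True)
class RootedView:
    """Exploration graph restricted to a subtree root and its descendants."""

    eg: ExplorationGraph
    root_term: str
    visible_terms: frozenset[str]

    def breadcrumb(self) -> list[str]:
        from .layout import breadcrumb_path

        return breadcrumb_path(self.root_term, self.eg)


def root_at(term: str | None, eg: ExplorationGraph,
            tq: TermQuery) -> tuple[RootedView | ExplorationGraph, TermQuery]:
    """Zoom into a subtree and simultaneously restrict the retrieved datasets.

    Passing ``None`` un-roots: the full graph and a query without
    ``root_term`` are restored.
    """
    if term is None:
        return eg, replace(tq, root_term=None)
    if term not in eg.graph.terms:
        raise UnknownTermError(term, "cannot root at a pruned or unknown term")
    visible = frozenset({term} | eg.graph.descendants(term))
    view = RootedView(eg=eg, root_term=term, visible_terms=visible)
    return view, replace(tq, root_term=term)


def evaluate(q: QueryExpression, repo: Repository, eg: ExplorationGraph,
             index: AnnotationIndex,
             graph: OntologyGraph | None = None) -> ResultSet:
    """Combined query: text result ∩ term result, in text-relevance order."""
    text_result = text_search(q.text, repo, graph if graph is not None else eg.graph)
    term_result = evaluate_term_query(q.terms, index).as_set()
    return ResultSet.of((d for d in text_result.retrieved if d in term_result),
                        query=q)


# ---------------------------------------------------------------------------
# data cart

@dataclass
class DataCart:
    """Session-scoped, insertion-ordered, duplicate-free dataset collection."""

    saved: dict[str, None] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.saved)


def cart_add(cart: DataCart, ids: Iterable[str], repo: Repository) -> DataCart:
    for did in ids:
        if did not in repo:
            raise CartError(f"unknown dataset id: {did}")
        cart.saved.setdefault(did, None)
    return cart


def cart_remove(cart: DataCart, ids: Iterable[str]) -> DataCart:
    for did in ids:
        if did not in cart.saved:
            raise CartError(f"dataset not in cart: {did}")
        del cart.saved[did]
    return cart


def cart_list(cart: DataCart) -> list[str]:
    return list(cart.saved)


# ---------------------------------------------------------------------------
# highlighting

def highlight_terms(dataset: Dataset,
                    eg: ExplorationGraph) -> tuple[frozenset[str], frozenset[str]]:
    """Direct vs indirect retained annotation terms of one dataset.

    Direct terms are the dataset's asserted annotations mapped to their
    retained representatives (a collapsed term is represented by the child
    that absorbed it); indirect terms are the retained strict ancestors of
    the direct set, the virtual root excluded.
    """
    direct: set[str] = set()
    for t in dataset.annotation_terms():
        rep = eg.representative_of(t)
        if rep is not None and rep != eg.root:
            direct.add(rep)
    indirect: set[str] = set()
    for t in direct:
        indirect |= eg.graph.ancestors(t)
    indirect -= direct
    indirect.discard(eg.root)
    return frozenset(direct), frozenset(indirect)
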