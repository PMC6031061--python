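"""Reduction of the merged ontology graph to the exploration graph.

Biomedical ontologies describe whole domains, but a repository typically
uses only a tiny fraction of their terms for annotation.  Two reductions
make the annotation hierarchy explorable:

1. *Hide unused terms*: only terms whose transitive dataset set is
   non-empty are retained (plus the virtual root); retained children whose
   retained ancestors were only reachable through removed terms are
   re-linked to their nearest retained ancestors.

2. *Collapse redundant parents*: a parent describing exactly the same
   dataset set as one of its children adds no information (zero mutual
   information with any other attribute), so such parents are absorbed into
   that child until every remaining edge (c, p) satisfies strict containment
   S_c ⊊ S_p (or p is the virtual root).  When a whole ancestor chain has
   equal sets, the most specific (deepest) term is the one kept.

Absorbed ancestors are recorded per retained term (*provenance*) so that
breadcrumb paths can still display the full ontological lineage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .ontology import (GraphMeasures, OntologyGraph, Term, compute_measures,
                       graph_from_json, graph_to_json)
from .repository import AnnotationIndex, Repository, build_annotation_index


@dataclass
class ExplorationGraph:
    """The pruned, annotation-restricted graph with per-term statistics.

    Invariants: every retained non-root term has size >= 1; every retained
    edge (c, p) with p != root satisfies transitive(c) ⊊ transitive(p); the
    graph is a DAG under the single virtual root.  ``provenance[t]`` lists
    the collapsed ancestors absorbed into t's incoming edges, ordered from
    most to least specific.
    """

    graph: OntologyGraph
    sizes: dict[str, int]
    measures: GraphMeasures
    provenance: dict[str, list[str]] = field(default_factory=dict)
    transitive: dict[str, frozenset[str]] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()
    #: labels/terms of ancestors removed by either pruning stage, for display
    removed_terms: dict[str, Term] = field(default_factory=dict)

    @property
    def root(self) -> str:
        return self.graph.root

    def retained(self) -> list[str]:
        """Retained term ids, root included, in deterministic order."""
        return sorted(self.graph.terms)

    def retained_non_root(self) -> list[str]:
        return sorted(t for t in self.graph.terms if t != self.root)

    def size_of(self, term: str) -> int:
        return self.sizes.get(term, 0)

    def transitive_of(self, term: str) -> frozenset[str]:
        return self.transitive.get(term, frozenset())

    def representative_of(self, term: str) -> str | None:
        """Retained term standing in for ``term`` (itself if retained)."""
        if term in self.graph.terms:
            return term
        for kept, absorbed in self.provenance.items():
            if term in absorbed:
                return kept
        return None

    def term(self, term_id: str) -> Term:
        if term_id in self.graph.terms:
            return self.graph.terms[term_id]
        return self.removed_terms[term_id]


def restrict_to_used(graph: OntologyGraph, index: AnnotationIndex) -> OntologyGraph:
    """Drop every term with transitive size 0 (keeping the root).

    Terminal and inner zero-size terms disappear alike; a retained child
    whose retained ancestors were only reachable through removed inner
    terms is re-linked to its nearest retained ancestor(s).
    """
    keep = {t for t in graph.terms if index.size(t) > 0}
    keep.add(graph.root)

    # nearest retained ancestors of every removed term, memoised top-down
    nearest: dict[str, frozenset[str]] = {}
    for t in graph.topological_order():  # parents first
        if t in keep:
            continue
        acc: set[str] = set()
        for p in graph.parents_of(t):
            if p in keep:
                acc.add(p)
            else:
                acc |= nearest[p]
        nearest[t] = frozenset(acc)

    pruned = OntologyGraph(validate=False)
    for t in keep:
        if t != graph.root:
            pruned.add_term(graph.terms[t])
    for t in keep:
        for p in graph.parents_of(t):
            targets = (p,) if p in keep else tuple(nearest[p])
            for q in targets:
                if q != t:
                    pruned.add_edge(t, q)
    pruned.attach_orphans_to_root()
    pruned.validate()
    return pruned


def collapse_redundant_parents(graph: OntologyGraph,
                               index: AnnotationIndex) -> ExplorationGraph:
    """Absorb parents whose dataset set equals one of their children's.

    Repeatedly removes any non-root term p having a child c with
    transitive(p) == transitive(c): c (and any other children of p) are
    re-linked to p's parents, and p — plus whatever p had absorbed before —
    is appended to c's provenance.  Iteration runs to a fixpoint, processing
    candidates in decreasing distance-to-root order, so the output is
    deterministic and the deepest (most specific) term of an equal-set chain
    is the one kept.  At the fixpoint every edge (c, p) with p != root
    satisfies transitive(c) ⊊ transitive(p): an equal-set pair would make p
    a candidate again.

    A parent whose set equals the *union* of two or more proper-subset
    children is retained (no single child matches it); removing it would
    disconnect the siblings, and the strict-containment contract concerns
    parent–child pairs.
    """
    work = graph.copy()
    provenance: dict[str, list[str]] = {}
    removed_terms: dict[str, Term] = {}

    changed = True
    while changed:
        changed = False
        distance = compute_measures(work).distance
        candidates = sorted(
            (t for t in work.terms if t != work.root),
            key=lambda t: (-distance.get(t, 0), t))
        for p in candidates:
            if p not in work.terms:
                continue
            equal_kids = sorted(
                (c for c in work.children_of(p)
                 if index.transitive_of(c) == index.transitive_of(p)),
                key=lambda c: (-distance.get(c, 0), c))
            if not equal_kids:
                continue
            c = equal_kids[0]  # the absorbing child: deepest, tie by id
            for child in work.children_of(p):
                for q in work.parents_of(p):
                    if q != child:
                        work.add_edge(child, q)
            remove_term(work, p)
            prov_c = provenance.setdefault(c, [])
            prov_c.append(p)
            prov_c.extend(provenance.pop(p, ()))
            removed_terms[p] = graph.terms[p]
            changed = True

    work.validate()
    measures = compute_measures(work)
    sizes = {t: index.size(t) for t in work.terms if index.size(t) > 0}
    transitive = {t: index.transitive_of(t) for t in work.terms
                  if index.size(t) > 0}
    return ExplorationGraph(graph=work, sizes=sizes, measures=measures,
                            provenance=provenance, transitive=transitive,
                            universe=index.universe, removed_terms=removed_terms)


def remove_term(graph: OntologyGraph, term: str) -> None:
    """Remove a term and its incident edges in place."""
    for p in graph.parents_of(term):
        graph.edges.discard((term, p))
        graph._children[p].discard(term)  # noqa: SLF001 - module-internal surgery
    for c in graph.children_of(term):
        graph.edges.discard((c, term))
        graph._parents[c].discard(term)
    del graph.terms[term]
    del graph._parents[term]
    del graph._children[term]


def build_exploration_graph(graph: OntologyGraph, repo: Repository,
                            index: AnnotationIndex | None = None) -> ExplorationGraph:
    """Full pipeline: closure -> hide unused -> collapse -> measures."""
    if index is None:
        index = build_annotation_index(repo, graph)
    restricted = restrict_to_used(graph, index)
    eg = collapse_redundant_parents(restricted, index)
    # carry labels of terms dropped by the restriction stage too, for reports
    for t in graph.terms:
        if t not in eg.graph.terms and t not in eg.removed_terms:
            eg.removed_terms[t] = graph.terms[t]
    return eg


# ---------------------------------------------------------------------------
# persistence (consumed by the layout and query modules / CLI)

def exploration_to_json(eg: ExplorationGraph) -> str:
    doc = {
        "graph": json.loads(graph_to_json(eg.graph)),
        "sizes": {t: eg.sizes[t] for t in sorted(eg.sizes)},
        "distance": {t: eg.measures.distance[t]
                     for t in sorted(eg.measures.distance)},
        "subtree_depth": {t: eg.measures.subtree_depth[t]
                          for t in sorted(eg.measures.subtree_depth)},
        "provenance": {t: eg.provenance[t] for t in sorted(eg.provenance)},
        "transitive": {t: sorted(eg.transitive[t]) for t in sorted(eg.transitive)},
        "universe": sorted(eg.universe),
        "removed_terms": {
            t: {"label": term.label, "ontology_tags": sorted(term.ontology_tags)}
            for t, term in sorted(eg.removed_terms.items())
        },
    }
    return json.dumps(doc, indent=1)


def exploration_from_json(text: str) -> ExplorationGraph:
    doc = json.loads(text)
    graph = graph_from_json(json.dumps(doc["graph"]))
    measures = GraphMeasures(distance=dict(doc["distance"]),
                             subtree_depth=dict(doc["subtree_depth"]))
    removed = {
        t: Term(id=t, label=entry["label"],
                ontology_tags=frozenset(entry["ontology_tags"]))
        for t, entry in doc.get("removed_terms", {}).items()
    }
    return ExplorationGraph(
        graph=graph,
        sizes={t: int(v) for t, v in doc["sizes"].items()},
        measures=measures,
        provenance={t: list(v) for t, v in doc["provenance"].items()},
        transitive={t: frozenset(v) for t, v in doc["transitive"].items()},
        universe=frozenset(doc["universe"]),
        removed_terms=removed,
    )


def save_exploration(eg: ExplorationGraph, path: str | Path) -> None:
    Path(path).write_text(exploration_to_json(eg), encoding="utf-8")


def load_exploration(path: str | Path) -> ExplorationGraph:
    return exploration_from_json(Path(path).read_text(encoding="utf-8"))
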