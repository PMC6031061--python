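"""Ontology subclass graphs: parsing, merging, graph measures and export.

Ontologies are reduced to a simplified property graph: one node per named
class (id, label, synonyms, source-ontology tags) and one directed edge per
asserted named-class subsumption (child -> parent).  All graphs share a
single virtual root term with the reserved id ``OWL:Thing``; classes that
have no asserted parent are attached to it, so that every term has a path
to the root and the whole collection of ontologies can be traversed as one
DAG.

Equivalence axioms and existential restrictions are deliberately not
materialised as edges; only asserted subclass relations between named
classes are kept (see :data:`EDGE_FILTERS` for the extension hook).
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx

from .errors import CycleError, OntologyFormatError

ROOT_ID = "OWL:Thing"
ROOT_LABEL = "Thing"

#: Namespace -> CURIE prefix map used by :func:`normalize_term_id`.
#: Extendable via the ``prefix_map`` argument / CLI config.
DEFAULT_PREFIX_MAP: dict[str, str] = {
    "http://purl.obolibrary.org/obo/": "",  # OBO PURLs: obo/CL_0000000 -> CL:0000000
    "http://www.ebi.ac.uk/efo/": "EFO",
    "http://purl.org/obo/owl/": "",
    "http://www.w3.org/2002/07/owl#": "OWL",
}

#: Hook for incorporating additional relationship types (e.g. existential
#: quantification properties) when parsing.  Maps a relation keyword to a
#: predicate deciding whether the relation becomes a subclass-like edge.
#: Only ``is_a`` / rdfs:subClassOf are enabled by default.
EDGE_FILTERS: dict[str, Callable[[str], bool]] = {"is_a": lambda _: True}

_OBO_PURL = re.compile(r"^http://purl\.obolibrary\.org/obo/([A-Za-z][\w]*?)_(\S+)$")


def normalize_term_id(value: str, prefix_map: Mapping[str, str] | None = None) -> str:
    """Normalize a term identifier to CURIE form ``PREFIX:LOCALID``.

    Full IRIs are mapped through the prefix map; OBO PURLs become standard
    OBO CURIEs.  Identifiers that are already CURIEs, and IRIs with unknown
    prefixes, are returned unchanged (the full IRI then serves as the id).
    Normalization is idempotent.
    """
    value = value.strip()
    if not value:
        raise ValueError("empty term identifier")
    m = _OBO_PURL.match(value)
    if m:
        return f"{m.group(1)}:{m.group(2)}"
    if value.startswith(("http://", "https://")):
        pmap = dict(DEFAULT_PREFIX_MAP)
        if prefix_map:
            pmap.update(prefix_map)
        for ns, prefix in sorted(pmap.items(), key=lambda kv: -len(kv[0])):
            if value.startswith(ns):
                local = value[len(ns):].lstrip("#/")
                if not local:
                    break
                return f"{prefix}:{local}" if prefix else local.replace("_", ":", 1)
    return value


@dataclass(frozen=True)
class Term:
    """A named ontology class.

    ``ontology_tags`` records every source ontology (by its short uppercase
    abbreviation, e.g. ``EFO``) that asserted this class, so a class parsed
    from several ontologies stays a single node whose occurrences remain
    traceable.
    """

    id: str
    label: str = ""
    synonyms: tuple[str, ...] = ()
    ontology_tags: frozenset[str] = frozenset()

    def display_label(self) -> str:
        return self.label or self.id


@dataclass(frozen=True)
class GraphMeasures:
    """Distance-to-root and subtree depth for every term.

    distance(t): length of the shortest path from t up to the root.
    subtree_depth(t): longest downward path from t to any descendant
    (0 for leaves); this drives the treemap colour encoding.
    """

    distance: dict[str, int]
    subtree_depth: dict[str, int]


class OntologyGraph:
    """Merged subclass DAG with a single virtual root.

    Vertices are :class:`Term` objects keyed by normalized id; edges are
    (child, parent) pairs.  The graph is validated to be acyclic, free of
    self-edges and rooted: every non-root term reaches ``OWL:Thing``.
    """

    def __init__(self, terms: Mapping[str, Term] | None = None,
                 edges: Iterable[tuple[str, str]] = (), *, validate: bool = True):
        self.terms: dict[str, Term] = dict(terms or {})
        if ROOT_ID not in self.terms:
            self.terms[ROOT_ID] = Term(id=ROOT_ID, label=ROOT_LABEL)
        self.edges: set[tuple[str, str]] = set()
        self._parents: dict[str, set[str]] = {t: set() for t in self.terms}
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, parent in edges:
            self.add_edge(child, parent)
        if validate:
            self.validate()

    # -- construction ----------------------------------------------------
    def add_term(self, term: Term) -> None:
        existing = self.terms.get(term.id)
        if existing is not None:
            merged = Term(
                id=term.id,
                label=existing.label or term.label,
                synonyms=tuple(dict.fromkeys(existing.synonyms + term.synonyms)),
                ontology_tags=existing.ontology_tags | term.ontology_tags,
            )
            self.terms[term.id] = merged
        else:
            self.terms[term.id] = term
            self._parents.setdefault(term.id, set())
            self._children.setdefault(term.id, set())

    def add_edge(self, child: str, parent: str) -> None:
        if child == parent:
            return  # self-edges carry no subsumption information
        for t in (child, parent):
            if t not in self.terms:
                raise KeyError(f"edge endpoint not in graph: {t}")
        self.edges.add((child, parent))
        self._parents[child].add(parent)
        self._children[parent].add(child)

    def attach_orphans_to_root(self) -> None:
        """Give every parentless non-root term an edge to the virtual root."""
        for t in list(self.terms):
            if t != ROOT_ID and not self._parents[t]:
                self.add_edge(t, ROOT_ID)

    # -- queries ---------------------------------------------------------
    @property
    def root(self) -> str:
        return ROOT_ID

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parents_of(self, term_id: str) -> frozenset[str]:
        return frozenset(self._parents[term_id])

    def children_of(self, term_id: str) -> frozenset[str]:
        return frozenset(self._children[term_id])

    def ancestors(self, term_id: str) -> set[str]:
        """All strict ancestors of a term (including the root)."""
        seen: set[str] = set()
        stack = list(self._parents[term_id])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self._parents[t])
        return seen

    def descendants(self, term_id: str) -> set[str]:
        seen: set[str] = set()
        stack = list(self._children[term_id])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self._children[t])
        return seen

    def topological_order(self) -> list[str]:
        """Parents-before-children order (root first); deterministic."""
        indeg = {t: len(self._parents[t]) for t in self.terms}
        ready = sorted(t for t, d in indeg.items() if d == 0)
        order: list[str] = []
        queue = deque(ready)
        while queue:
            t = queue.popleft()
            order.append(t)
            newly = []
            for c in self._children[t]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    newly.append(c)
            for c in sorted(newly):
                queue.append(c)
        if len(order) != len(self.terms):
            raise CycleError(self._find_cycle())
        return order

    def _find_cycle(self) -> list[str]:
        g = self.to_networkx()
        cyc = nx.find_cycle(g)
        return [u for u, _ in cyc] + [cyc[-1][1]]

    def validate(self) -> None:
        """Enforce the graph invariants; raises CycleError on cycles."""
        self.topological_order()  # raises on cycles
        for t in self.terms:
            if t == ROOT_ID:
                continue
            if not self._parents[t]:
                raise OntologyFormatError(
                    f"term {t} has no path to the root; call attach_orphans_to_root()")
            if not self.terms[t].ontology_tags:
                raise OntologyFormatError(f"non-virtual term {t} has no ontology tag")

    # -- interop ---------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for t, term in self.terms.items():
            g.add_node(t, label=term.label,
                       ontology_tags="|".join(sorted(term.ontology_tags)),
                       synonyms="|".join(term.synonyms))
        for child, parent in self.edges:
            g.add_edge(child, parent, type="subclass_of")
        return g

    def copy(self) -> "OntologyGraph":
        return OntologyGraph(dict(self.terms), set(self.edges), validate=False)

    def equal_structure(self, other: "OntologyGraph") -> bool:
        return (set(self.terms) == set(other.terms)
                and self.edges == other.edges
                and all(self.terms[t].ontology_tags == other.terms[t].ontology_tags
                        for t in self.terms))


# ---------------------------------------------------------------------------
# parsing

def _parse_obo_synonym(raw: str) -> str:
    # OBO synonym tag value: "mice" EXACT [] -> mice
    m = re.match(r'\s*"((?:[^"\\]|\\.)*)"', raw)
    return m.group(1).replace('\\"', '"') if m else raw.strip()


def load_obo(path: str | Path, tag: str,
             prefix_map: Mapping[str, str] | None = None) -> OntologyGraph:
    """Load an OBO 1.4 flat file into a subclass graph (``is_a`` edges only)."""
    import obonet

    try:
        raw = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:  # noqa: BLE001 - surface parse failures uniformly
        raise OntologyFormatError(f"cannot parse OBO file {path}: {exc}") from exc

    graph = OntologyGraph()
    tagset = frozenset({tag})
    norm = {n: normalize_term_id(n, prefix_map) for n in raw.nodes}
    for node, data in raw.nodes(data=True):
        synonyms = tuple(_parse_obo_synonym(s) for s in data.get("synonym", []))
        graph.add_term(Term(id=norm[node], label=data.get("name", ""),
                            synonyms=synonyms, ontology_tags=tagset))
    for child, parent, key in raw.edges(keys=True):
        if key in EDGE_FILTERS and EDGE_FILTERS[key](key):
            graph.add_edge(norm[child], norm[parent])
    graph.attach_orphans_to_root()
    graph.validate()
    return graph


_OWL_SYNONYM_PREDICATES = (
    "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym",
    "http://www.geneontology.org/formats/oboInOwl#hasRelatedSynonym",
    "http://www.geneontology.org/formats/oboInOwl#hasSynonym",
)


def load_owl(path: str | Path, tag: str,
             prefix_map: Mapping[str, str] | None = None) -> OntologyGraph:
    """Load an OWL RDF/XML file: named classes and asserted subClassOf edges.

    Anonymous classes (restrictions, intersections) are skipped: only
    subsumptions whose subject and object are both IRIs become edges.
    """
    from rdflib import Graph as RDFGraph
    from rdflib import RDF, RDFS, OWL, URIRef

    rdf = RDFGraph()
    try:
        rdf.parse(str(path))
    except Exception as exc:  # noqa: BLE001
        raise OntologyFormatError(f"cannot parse OWL file {path}: {exc}") from exc

    graph = OntologyGraph()
    tagset = frozenset({tag})
    classes = {c for c in rdf.subjects(RDF.type, OWL.Class) if isinstance(c, URIRef)}
    classes |= {c for c in rdf.subjects(RDF.type, RDFS.Class) if isinstance(c, URIRef)}
    # classes may also appear only as subClassOf endpoints
    for s, o in rdf.subject_objects(RDFS.subClassOf):
        if isinstance(s, URIRef):
            classes.add(s)
        if isinstance(o, URIRef):
            classes.add(o)
    classes.discard(OWL.Thing)

    def norm(iri: URIRef) -> str:
        return normalize_term_id(str(iri), prefix_map)

    for c in classes:
        label = next((str(v) for v in rdf.objects(c, RDFS.label)), "")
        synonyms = tuple(
            str(v) for pred in _OWL_SYNONYM_PREDICATES
            for v in rdf.objects(c, URIRef(pred)))
        graph.add_term(Term(id=norm(c), label=label, synonyms=synonyms,
                            ontology_tags=tagset))
    for s, o in rdf.subject_objects(RDFS.subClassOf):
        if isinstance(s, URIRef) and isinstance(o, URIRef) and s in classes:
            if o == OWL.Thing:
                graph.add_edge(norm(s), ROOT_ID)
            elif o in classes:
                graph.add_edge(norm(s), norm(o))
    graph.attach_orphans_to_root()
    graph.validate()
    return graph


def load_ontology(path: str | Path, tag: str,
                  prefix_map: Mapping[str, str] | None = None) -> OntologyGraph:
    """Dispatch on file extension: ``.obo`` vs OWL RDF/XML (anything else)."""
    if not tag:
        raise ValueError("ontology tag must be non-empty")
    suffix = Path(path).suffix.lower()
    if suffix == ".obo":
        return load_obo(path, tag, prefix_map)
    return load_owl(path, tag, prefix_map)


def merge_graphs(graphs: list[OntologyGraph]) -> OntologyGraph:
    """Union of vertices and edges under one shared virtual root.

    Terms with equal (normalized) ids collapse into a single node whose
    ``ontology_tags`` is the union of the sources, so the merged polyhierarchy
    can be traversed as one graph while each class's origin stays traceable.
    """
    if not graphs:
        raise ValueError("merge_graphs requires at least one graph")
    merged = OntologyGraph()
    for g in graphs:
        for term in g.terms.values():
            if term.id != ROOT_ID:
                merged.add_term(term)
        for child, parent in g.edges:
            merged.add_edge(child, parent)
    merged.attach_orphans_to_root()
    merged.validate()  # raises CycleError if the union became cyclic
    return merged


def compute_measures(graph: OntologyGraph) -> GraphMeasures:
    """BFS distances from the root plus longest-downward-path subtree depths."""
    distance: dict[str, int] = {graph.root: 0}
    queue = deque([graph.root])
    while queue:
        t = queue.popleft()
        for c in sorted(graph.children_of(t)):
            if c not in distance:
                distance[c] = distance[t] + 1
                queue.append(c)
    depth: dict[str, int] = {}
    for t in reversed(graph.topological_order()):
        kids = graph.children_of(t)
        depth[t] = 1 + max(depth[c] for c in kids) if kids else 0
    return GraphMeasures(distance=distance, subtree_depth=depth)


# ---------------------------------------------------------------------------
# export / import

def export_property_graph(graph: OntologyGraph, path: str | Path) -> None:
    """Write the simplified property graph: GraphML or JSON by extension.

    Each node record carries id, label and ontology tags; each edge is typed
    ``subclass_of``.  Re-importing the export reproduces an isomorphic graph.
    """
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        nx.write_graphml(graph.to_networkx(), str(path))
    else:
        path.write_text(graph_to_json(graph), encoding="utf-8")


def graph_to_json(graph: OntologyGraph) -> str:
    doc = {
        "root": graph.root,
        "nodes": [
            {
                "id": t.id,
                "label": t.label,
                "synonyms": list(t.synonyms),
                "ontology_tags": sorted(t.ontology_tags),
            }
            for t in (graph.terms[k] for k in sorted(graph.terms))
        ],
        "edges": [
            {"child": c, "parent": p, "type": "subclass_of"}
            for c, p in sorted(graph.edges)
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=False)


def graph_from_json(text: str) -> OntologyGraph:
    doc = json.loads(text)
    graph = OntologyGraph()
    for node in doc["nodes"]:
        graph.add_term(Term(id=node["id"], label=node.get("label", ""),
                            synonyms=tuple(node.get("synonyms", ())),
                            ontology_tags=frozenset(node.get("ontology_tags", ()))))
    for edge in doc["edges"]:
        graph.add_edge(edge["child"], edge["parent"])
    graph.validate()
    return graph


def import_property_graph(path: str | Path) -> OntologyGraph:
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(str(path))
        graph = OntologyGraph()
        for node, data in g.nodes(data=True):
            tags = frozenset(t for t in data.get("ontology_tags", "").split("|") if t)
            syns = tuple(s for s in data.get("synonyms", "").split("|") if s)
            graph.add_term(Term(id=node, label=data.get("label", ""),
                                synonyms=syns, ontology_tags=tags))
        for child, parent in g.edges():
            graph.add_edge(child, parent)
        graph.validate()
        return graph
    return graph_from_json(path.read_text(encoding="utf-8"))
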