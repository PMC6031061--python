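"""Brute-force reference implementations used to cross-check the package.

Each oracle recomputes a quantity by the most direct method available
(per-dataset ancestor enumeration, exhaustive path enumeration, per-dataset
predicate evaluation) and stays independent of the code paths it verifies.
"""

from __future__ import annotations

from ontoscout.ontology import OntologyGraph
from ontoscout.repository import Repository


def closure_by_dataset(graph: OntologyGraph, repo: Repository) -> dict[str, set[str]]:
    """Transitive term sets built per dataset: each dataset contributes
    itself to every ancestor of each of its direct annotation terms."""
    sets: dict[str, set[str]] = {}
    for d in repo.datasets.values():
        for t in d.annotation_terms():
            if t not in graph:
                continue
            for anc in {t} | graph.ancestors(t):
                sets.setdefault(anc, set()).add(d.id)
    return sets


def incidence_sizes(graph: OntologyGraph, repo: Repository) -> dict[str, int]:
    """Term sizes as column sums of the dataset x term incidence matrix."""
    closure = closure_by_dataset(graph, repo)
    return {t: len(s) for t, s in closure.items()}


def all_downward_paths(graph: OntologyGraph, start: str) -> list[list[str]]:
    paths: list[list[str]] = []

    def walk(node: str, acc: list[str]) -> None:
        paths.append(acc + [node])
        for c in graph.children_of(node):
            walk(c, acc + [node])

    walk(start, [])
    return paths


def brute_distance(graph: OntologyGraph) -> dict[str, int]:
    """Shortest root->term path length by exhaustive path enumeration."""
    dist: dict[str, int] = {}
    for path in all_downward_paths(graph, graph.root):
        t = path[-1]
        length = len(path) - 1
        if t not in dist or length < dist[t]:
            dist[t] = length
    return dist


def brute_subtree_depth(graph: OntologyGraph) -> dict[str, int]:
    """Longest downward path per term by exhaustive enumeration."""
    depth: dict[str, int] = {t: 0 for t in graph.terms}
    for t in graph.terms:
        for path in all_downward_paths(graph, t):
            depth[t] = max(depth[t], len(path) - 1)
    return depth


def has_cycle_dfs(nodes: list[str], edges: set[tuple[str, str]]) -> bool:
    """Brute-force DFS cycle detection on an arbitrary digraph."""
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        succ[a].append(b)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in nodes}

    def visit(n: str) -> bool:
        color[n] = GRAY
        for m in succ[n]:
            if color[m] == GRAY:
                return True
            if color[m] == WHITE and visit(m):
                return True
        color[n] = BLACK
        return False

    return any(color[n] == WHITE and visit(n) for n in nodes)


def term_query_oracle(repo: Repository, closure: dict[str, set[str]],
                      and_terms: set[str], or_terms: set[str],
                      not_terms: set[str], root_term: str | None = None) -> set[str]:
    """Per-dataset predicate evaluation of a Boolean term query."""
    result = set()
    for did in repo.datasets:
        member = lambda t: did in closure.get(t, set())  # noqa: E731
        ok = all(member(t) for t in and_terms)
        if or_terms:
            ok = ok and any(member(t) for t in or_terms)
        ok = ok and not any(member(t) for t in not_terms)
        if root_term is not None:
            ok = ok and member(root_term)
        if ok:
            result.add(did)
    return result
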