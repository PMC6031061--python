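"""Per-term precision and recall for a retrieved result set.

Given the currently retrieved datasets R and a term t with transitive
dataset set S_t:

    precision(t) = |R ∩ S_t| / |R|     — how frequently t annotates the
                                         retrieved collection;
    recall(t)    = |R ∩ S_t| / |S_t|   — how many of t's datasets were
                                         retrieved at all (the information
                                         scent of the term).

Both use the transitive set, so a term "counts" datasets annotated with any
of its descendants.  Undefined values (empty result set; unused term) raise
:class:`~ontoscout.errors.UndefinedMetricError` rather than returning 0.0,
because zero is a meaningful value in the displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import UndefinedMetricError
from .pruning import ExplorationGraph
from .repository import AnnotationIndex


@dataclass(frozen=True)
class ResultSet:
    """Ordered, duplicate-free list of retrieved dataset ids."""

    retrieved: tuple[str, ...]
    provenance_query: object | None = None

    def __post_init__(self):
        if len(set(self.retrieved)) != len(self.retrieved):
            raise ValueError("result set contains duplicate dataset ids")

    def __len__(self) -> int:
        return len(self.retrieved)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.retrieved)

    @classmethod
    def of(cls, ids: Iterable[str], query: object | None = None) -> "ResultSet":
        return cls(retrieved=tuple(dict.fromkeys(ids)), provenance_query=query)


@dataclass(frozen=True)
class TermStat:
    """Statistics of one term for one result set.

    The cross-consistency identity precision * |R| == recall * size ==
    |R ∩ S_t| holds exactly (the integer intersection is counted once and
    divided two ways).
    """

    term: str
    size: int
    hits: int  # |R ∩ S_t|
    precision: float | None  # None when undefined (|R| = 0)
    recall: float | None  # None when undefined (size = 0)


def precision(term: str, result: ResultSet, index: "AnnotationIndex | ExplorationGraph") -> float:
    """Fraction of the retrieved datasets that are annotated with the term."""
    if len(result) == 0:
        raise UndefinedMetricError("precision undefined for an empty result set")
    s_t = _transitive(index, term)
    return len(result.as_set() & s_t) / len(result)


def recall(term: str, result: ResultSet, index: "AnnotationIndex | ExplorationGraph") -> float:
    """Fraction of the term's datasets that were retrieved."""
    s_t = _transitive(index, term)
    if not s_t:
        raise UndefinedMetricError(f"recall undefined: term {term} annotates no dataset")
    return len(result.as_set() & s_t) / len(s_t)


def _transitive(index: "AnnotationIndex | ExplorationGraph", term: str) -> frozenset[str]:
    return index.transitive_of(term)


def compute_all_stats(result: ResultSet, eg: ExplorationGraph) -> dict[str, TermStat]:
    """Precision/recall of every retained term against one result set.

    The virtual root is excluded (it is not part of the statistics display).
    Terms whose recall would be undefined are emitted with ``recall=None``
    rather than silently dropped or zeroed.
    """
    if len(result) == 0:
        raise UndefinedMetricError("stats undefined for an empty result set")
    r = result.as_set()
    n = len(result)
    stats: dict[str, TermStat] = {}
    for t in eg.retained_non_root():
        s_t = eg.transitive_of(t)
        hits = len(r & s_t)
        stats[t] = TermStat(
            term=t, size=len(s_t), hits=hits, precision=hits / n,
            recall=(hits / len(s_t)) if s_t else None)
    return stats


def stats_table(stats: dict[str, TermStat], eg: ExplorationGraph) -> str:
    """Render the stats as a TSV table (term, label, size, precision, recall,
    distance, depth), sorted by term id; floats with 6 decimals."""
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6f}"

    lines = ["\t".join(("term_id", "label", "size", "precision", "recall",
                        "distance", "depth"))]
    for t in sorted(stats):
        s = stats[t]
        lines.append("\t".join((
            t, eg.graph.terms[t].display_label(), str(s.size),
            fmt(s.precision), fmt(s.recall),
            str(eg.measures.distance.get(t, "")),
            str(eg.measures.subtree_depth.get(t, "")))))
    return "\n".join(lines) + "\n"


def write_stats(stats: dict[str, TermStat], eg: ExplorationGraph,
                path: str | Path) -> None:
    Path(path).write_text(stats_table(stats, eg), encoding="utf-8", newline="\n")
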