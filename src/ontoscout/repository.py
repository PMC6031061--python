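"""Datasets, repository manifests and the transitive annotation index.

A dataset is an atomic unit with free-text attributes, some of which carry a
direct ontology-term annotation.  Through transitive subsumption every
superclass of a direct annotation term is also associated with the dataset
(its *indirect* annotation terms); the annotation index materialises both
levels as dataset-id sets per term.  The transitive set of a term t is its
set representation S_t, and |S_t| is the term's *size* — the central
statistic of the exploration view.

Manifest dialect: UTF-8 TSV (LF or CRLF), one row per attribute, header
``dataset_id  title  description  ownership  sharing  attribute_name
text_value  term_id``; an equivalent JSON form (list of dataset objects) is
accepted as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ManifestValidationError, SchemaError
from .ontology import OntologyGraph, normalize_term_id

MANIFEST_COLUMNS = [
    "dataset_id", "title", "description", "ownership", "sharing",
    "attribute_name", "text_value", "term_id",
]


@dataclass(frozen=True)
class AttributeValue:
    """One metadata attribute of a dataset (e.g. organism, technology, disease)."""

    attribute_name: str
    text_value: str = ""
    term: str | None = None

    def __post_init__(self):
        if not self.text_value and self.term is None:
            raise ManifestValidationError(
                f"attribute {self.attribute_name!r} has neither text nor term")


@dataclass(frozen=True)
class Dataset:
    id: str
    title: str
    description: str = ""
    ownership: str = ""
    sharing: str = ""
    attributes: tuple[AttributeValue, ...] = ()

    def __post_init__(self):
        if not self.title:
            raise ManifestValidationError(f"dataset {self.id!r} has an empty title")

    def annotation_terms(self) -> list[str]:
        """Direct annotation terms, deduplicated, in attribute order."""
        return list(dict.fromkeys(a.term for a in self.attributes if a.term))


@dataclass
class Repository:
    """Insertion-ordered collection of datasets keyed by id."""

    datasets: dict[str, Dataset] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.datasets)

    def __contains__(self, dataset_id: str) -> bool:
        return dataset_id in self.datasets

    def __getitem__(self, dataset_id: str) -> Dataset:
        return self.datasets[dataset_id]

    def ids(self) -> list[str]:
        return list(self.datasets)

    def add(self, dataset: Dataset) -> None:
        if dataset.id in self.datasets:
            raise ManifestValidationError(f"duplicate dataset id {dataset.id!r}")
        self.datasets[dataset.id] = dataset


@dataclass(frozen=True)
class UnresolvedAnnotation:
    """An annotation term that could not be found in the ontology graph."""

    dataset_id: str
    term_id: str
    attribute_name: str


@dataclass
class AnnotationIndex:
    """Direct and transitive per-term dataset sets over one repository.

    Invariants (checked by the test suite): direct(t) ⊆ transitive(t) ⊆
    universe for every t; transitive(child) ⊆ transitive(parent) along every
    subclass edge; transitive(root) covers every annotated dataset.
    """

    direct: dict[str, frozenset[str]]
    transitive: dict[str, frozenset[str]]
    universe: frozenset[str]
    unresolved: tuple[UnresolvedAnnotation, ...] = ()

    def direct_of(self, term: str) -> frozenset[str]:
        return self.direct.get(term, frozenset())

    def transitive_of(self, term: str) -> frozenset[str]:
        return self.transitive.get(term, frozenset())

    def size(self, term: str) -> int:
        return len(self.transitive.get(term, ()))


# ---------------------------------------------------------------------------
# manifest I/O

def _dataset_from_rows(dataset_id: str, rows: pd.DataFrame,
                       prefix_map: Mapping[str, str] | None) -> Dataset:
    heads = rows[["title", "description", "ownership", "sharing"]].drop_duplicates()
    if len(heads) > 1:
        raise ManifestValidationError(
            f"dataset {dataset_id!r} has conflicting title/description rows")
    head = heads.iloc[0]
    attrs = []
    for _, row in rows.iterrows():
        name = row["attribute_name"]
        if not name and not row["text_value"] and not row["term_id"]:
            continue  # dataset row without any attribute
        term = normalize_term_id(row["term_id"], prefix_map) if row["term_id"] else None
        attrs.append(AttributeValue(attribute_name=name,
                                    text_value=row["text_value"], term=term))
    return Dataset(id=dataset_id, title=head["title"],
                   description=head["description"], ownership=head["ownership"],
                   sharing=head["sharing"], attributes=tuple(attrs))


def load_repository(path: str | Path,
                    prefix_map: Mapping[str, str] | None = None) -> Repository:
    """Load a repository manifest (TSV or JSON, selected by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return repository_from_json(path.read_text(encoding="utf-8"), prefix_map)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                            encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"manifest {path} is empty (header required)") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"manifest {path} is missing columns: {', '.join(missing)}")
    repo = Repository()
    for dataset_id, rows in table.groupby("dataset_id", sort=False):
        repo.add(_dataset_from_rows(str(dataset_id), rows, prefix_map))
    return repo


def repository_from_json(text: str,
                         prefix_map: Mapping[str, str] | None = None) -> Repository:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"manifest JSON is malformed: {exc}") from exc
    if not isinstance(doc, list):
        doc = doc.get("datasets", None)
        if doc is None:
            raise SchemaError("manifest JSON must be a list or have a 'datasets' key")
    repo = Repository()
    for entry in doc:
        attrs = tuple(
            AttributeValue(
                attribute_name=a.get("attribute_name", ""),
                text_value=a.get("text_value", ""),
                term=(normalize_term_id(a["term_id"], prefix_map)
                      if a.get("term_id") else None))
            for a in entry.get("attributes", ()))
        repo.add(Dataset(id=entry["dataset_id"], title=entry.get("title", ""),
                         description=entry.get("description", ""),
                         ownership=entry.get("ownership", ""),
                         sharing=entry.get("sharing", ""), attributes=attrs))
    return repo


def repository_to_json(repo: Repository) -> str:
    doc = [
        {
            "dataset_id": d.id,
            "title": d.title,
            "description": d.description,
            "ownership": d.ownership,
            "sharing": d.sharing,
            "attributes": [
                {"attribute_name": a.attribute_name, "text_value": a.text_value,
                 "term_id": a.term or ""}
                for a in d.attributes
            ],
        }
        for d in repo.datasets.values()
    ]
    return json.dumps(doc, indent=1)


def write_manifest(repo: Repository, path: str | Path) -> None:
    """Write the TSV manifest form (one row per attribute, LF endings)."""
    rows = []
    for d in repo.datasets.values():
        if not d.attributes:
            rows.append((d.id, d.title, d.description, d.ownership, d.sharing,
                         "", "", ""))
        for a in d.attributes:
            rows.append((d.id, d.title, d.description, d.ownership, d.sharing,
                         a.attribute_name, a.text_value, a.term or ""))
    lines = ["\t".join(MANIFEST_COLUMNS)]
    lines += ["\t".join(r) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def write_unresolved_report(index: AnnotationIndex, path: str | Path) -> None:
    lines = ["\t".join(("dataset_id", "term_id", "attribute_name"))]
    for u in index.unresolved:
        lines.append("\t".join((u.dataset_id, u.term_id, u.attribute_name)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# annotation index

def build_annotation_index(repo: Repository, graph: OntologyGraph) -> AnnotationIndex:
    """Propagate direct annotations to every superclass (set semantics).

    A dataset annotated with two subclasses of t counts once in S_t.
    Annotation terms absent from the graph do not abort the build; they are
    collected in the unresolved-terms report and skipped.
    """
    direct: dict[str, set[str]] = {}
    unresolved: list[UnresolvedAnnotation] = []
    for d in repo.datasets.values():
        for a in d.attributes:
            if a.term is None:
                continue
            if a.term in graph:
                direct.setdefault(a.term, set()).add(d.id)
            else:
                unresolved.append(UnresolvedAnnotation(d.id, a.term, a.attribute_name))
    transitive: dict[str, set[str]] = {}
    for t in reversed(graph.topological_order()):  # children before parents
        acc = set(direct.get(t, ()))
        for c in graph.children_of(t):
            acc |= transitive.get(c, set())
        if acc:
            transitive[t] = acc
    return AnnotationIndex(
        direct={t: frozenset(s) for t, s in direct.items()},
        transitive={t: frozenset(s) for t, s in transitive.items()},
        universe=frozenset(repo.datasets),
        unresolved=tuple(unresolved),
    )


def term_size(index: AnnotationIndex) -> dict[str, int]:
    """size(t) = |S_t| for every term with a non-empty transitive set."""
    return {t: len(s) for t, s in index.transitive.items()}
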