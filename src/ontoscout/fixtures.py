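"""Synthetic ontologies and repositories for tests, demos and benchmarks.

The random generator emulates the regime seen in real annotated
repositories: deep, mildly polyhierarchical ontologies of which only a
small, ancestor-closed fraction of terms is ever reachable from dataset
annotations, with datasets annotated at varying depths.  Generation is
fully deterministic given the seed, and DAG-ness holds by construction
(parents are always sampled from strictly lower ranks).

Named fixtures reproduce small worked scenarios used throughout the test
suite: a taxonomy chain in which every dataset is annotated *human* (so all
ancestors up to *Mammalia* and beyond describe the same 10 datasets), a
cell-type branch with 12 leukocyte datasets of which 5 are native-cell but
not precursor-cell, a four-dataset repository realising the four
precision/recall quadrants, and a three-species taxonomy with prunable
equal-set inner chains.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .errors import FixtureSpecError
from .ontology import ROOT_ID, OntologyGraph, Term
from .repository import AttributeValue, Dataset, Repository

SYN_TAG = "SYN"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the random ontology + repository generator.

    ``used_term_fraction`` controls the size of the *ancestor-closed* used
    set: the generator picks direct annotation terms so that the set of all
    directly-or-indirectly used terms has exactly
    ``round(used_term_fraction * n_terms)`` members (virtual root excluded).
    """

    n_terms: int = 200
    max_depth: int = 8
    polyhierarchy_fraction: float = 0.15
    n_datasets: int = 40
    used_term_fraction: float = 0.2
    annotations_min: int = 1
    annotations_max: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_terms < 1 or self.n_datasets < 0 or self.max_depth < 1:
            raise FixtureSpecError("n_terms, max_depth must be >= 1; n_datasets >= 0")
        for frac in (self.polyhierarchy_fraction, self.used_term_fraction):
            if not 0.0 <= frac <= 1.0:
                raise FixtureSpecError("fractions must lie in [0, 1]")
        if not 0 <= self.annotations_min <= self.annotations_max:
            raise FixtureSpecError("need 0 <= annotations_min <= annotations_max")
        if round(self.used_term_fraction * self.n_terms) > self.n_terms:
            raise FixtureSpecError("used terms cannot exceed the term count")


def _term_id(i: int) -> str:
    return f"{SYN_TAG}:{i:06d}"


def generate(spec: FixtureSpec) -> tuple[OntologyGraph, Repository]:
    """Random rooted DAG plus an annotated repository (deterministic per seed)."""
    spec.validate()
    rng = random.Random(spec.seed)

    graph = OntologyGraph()
    ranks: dict[str, int] = {}
    by_rank: dict[int, list[str]] = {}
    tagset = frozenset({SYN_TAG})
    for i in range(1, spec.n_terms + 1):
        tid = _term_id(i)
        synonyms = (f"synonym {i}",) if i % 7 == 0 else ()
        graph.add_term(Term(id=tid, label=f"term {i}", synonyms=synonyms,
                            ontology_tags=tagset))
        rank = rng.randint(1, spec.max_depth)
        ranks[tid] = rank
        by_rank.setdefault(rank, []).append(tid)

    lower_pool: list[str] = []
    for rank in sorted(by_rank):
        for tid in by_rank[rank]:
            if lower_pool:
                graph.add_edge(tid, rng.choice(lower_pool))
                if (len(lower_pool) > 1
                        and rng.random() < spec.polyhierarchy_fraction):
                    second = rng.choice(lower_pool)
                    if (tid, second) not in graph.edges:
                        graph.add_edge(tid, second)
        lower_pool = lower_pool + by_rank[rank]
    graph.attach_orphans_to_root()
    graph.validate()

    used = _closed_used_set(graph, round(spec.used_term_fraction * spec.n_terms), rng)
    repo = _annotate(graph, used, spec, rng)
    return graph, repo


def _closed_used_set(graph: OntologyGraph, target: int,
                     rng: random.Random) -> list[str]:
    """Sample an ancestor-closed used set of exactly ``target`` terms.

    Grows the set by candidate terms whose full ancestor closure still fits,
    falling back to frontier terms (all parents already used) which always
    enlarge the set by exactly one, so the exact target is always reachable.
    """
    used: set[str] = set()
    all_terms = sorted(t for t in graph.terms if t != ROOT_ID)
    attempts = 0
    while len(used) < target:
        candidate = rng.choice(all_terms)
        closure = ({candidate} | graph.ancestors(candidate)) - {ROOT_ID} - used
        if closure and len(used) + len(closure) <= target:
            used |= closure
            attempts = 0
            continue
        attempts += 1
        if attempts > 50:  # fall back to the frontier: +1 growth guaranteed
            frontier = [t for t in all_terms if t not in used
                        and all(p in used or p == ROOT_ID
                                for p in graph.parents_of(t))]
            used.add(rng.choice(frontier))
            attempts = 0
    return sorted(used)


def _annotate(graph: OntologyGraph, used: list[str], spec: FixtureSpec,
              rng: random.Random) -> Repository:
    """Annotate datasets so that the transitive closure covers `used` exactly.

    Every minimal used term (one with no used child) must appear as a direct
    annotation somewhere, otherwise its branch would vanish from the
    exploration graph; minimal terms are dealt round-robin and the remaining
    annotation slots are filled uniformly from the used set.
    """
    used_set = set(used)
    minimal = [t for t in used
               if not (graph.children_of(t) & used_set)]
    if spec.n_datasets == 0 and minimal:
        raise FixtureSpecError("cannot cover used terms with zero datasets")
    if minimal and len(minimal) > spec.n_datasets * max(spec.annotations_max, 1):
        raise FixtureSpecError(
            f"{len(minimal)} minimal used terms cannot be covered by "
            f"{spec.n_datasets} datasets with <= {spec.annotations_max} "
            "annotations each")

    per_dataset: list[list[str]] = [[] for _ in range(spec.n_datasets)]
    for i, t in enumerate(minimal):
        per_dataset[i % spec.n_datasets].append(t)
    for i in range(spec.n_datasets):
        k = rng.randint(spec.annotations_min, spec.annotations_max)
        while len(per_dataset[i]) < k and used:
            t = rng.choice(used)
            if t not in per_dataset[i]:
                per_dataset[i].append(t)
            else:
                break  # tolerate short annotation lists on collision

    filler = ("study", "profile", "assay", "cohort", "series", "screen")
    repo = Repository()
    for i in range(spec.n_datasets):
        did = f"ds{i + 1:04d}"
        terms = per_dataset[i]
        labels = [graph.terms[t].label for t in terms]
        description = " ".join(
            [rng.choice(filler), "of"] + (labels or ["unannotated samples"]))
        attrs = tuple(
            AttributeValue(attribute_name=f"attr{j + 1}",
                           text_value=graph.terms[t].label, term=t)
            for j, t in enumerate(terms))
        repo.add(Dataset(id=did, title=f"Dataset {i + 1:04d}",
                         description=description,
                         ownership=f"lab{(i % 5) + 1}", sharing="public",
                         attributes=attrs))
    return repo


# ---------------------------------------------------------------------------
# named fixtures

NAMED_FIXTURES = ("mammalia_chain", "leukocyte_scenario", "fig5_quadrants",
                  "taxonomy_prune")

#: Captioned searches of the four precision/recall quadrant cases:
#: quadrant -> (free-text query, term whose precision/recall realises the case)
QUADRANT_SEARCHES: dict[str, tuple[str, str]] = {
    "A": ("human", "EFO:1002049"),        # low precision, low recall
    "B": ("human hepatocyte p53", "PR:000012421"),  # high precision, low recall
    "C": ("fibroblast", "EFO:1002049"),   # low precision, high recall
    "D": ("RNA-Seq", "PR:000012421"),     # high precision, high recall
}


def _graph(terms: list[tuple[str, str, str, tuple[str, ...]]],
           edges: list[tuple[str, str]]) -> OntologyGraph:
    g = OntologyGraph()
    for tid, label, tag, synonyms in terms:
        g.add_term(Term(id=tid, label=label, synonyms=synonyms,
                        ontology_tags=frozenset({tag})))
    for child, parent in edges:
        g.add_edge(child, parent)
    g.attach_orphans_to_root()
    g.validate()
    return g


def _dataset(did: str, title: str, description: str,
             annotations: list[tuple[str, str, str | None]],
             ownership: str = "demo-lab", sharing: str = "public") -> Dataset:
    attrs = tuple(AttributeValue(attribute_name=n, text_value=v, term=t)
                  for n, v, t in annotations)
    return Dataset(id=did, title=title, description=description,
                   ownership=ownership, sharing=sharing, attributes=attrs)


def _mammalia_chain() -> tuple[OntologyGraph, Repository]:
    """Ten datasets, all directly annotated *human*, under a deep taxon chain.

    Every ancestor of human (Homo, Primates, Mammalia, ...) describes the
    same 10 datasets, so after pruning only *human* survives below the root.
    """
    tax = "NCBITaxon"
    terms = [
        ("NCBITaxon:33208", "Metazoa", tax, ()),
        ("NCBITaxon:7742", "Vertebrata", tax, ()),
        ("NCBITaxon:40674", "Mammalia", tax, ()),
        ("NCBITaxon:9443", "Primates", tax, ()),
        ("NCBITaxon:9605", "Homo", tax, ()),
        ("NCBITaxon:9606", "human", tax, ("Homo sapiens",)),
    ]
    edges = [
        ("NCBITaxon:9606", "NCBITaxon:9605"),
        ("NCBITaxon:9605", "NCBITaxon:9443"),
        ("NCBITaxon:9443", "NCBITaxon:40674"),
        ("NCBITaxon:40674", "NCBITaxon:7742"),
        ("NCBITaxon:7742", "NCBITaxon:33208"),
    ]
    graph = _graph(terms, edges)
    repo = Repository()
    topics = ["hematopoiesis", "cardiomyocyte differentiation", "neural crest",
              "liver regeneration", "T cell activation", "iPSC reprogramming",
              "osteogenesis", "retinal organoids", "gut epithelium",
              "skin fibroblasts"]
    for i in range(10):
        repo.add(_dataset(
            f"hs{i + 1:02d}", f"Human {topics[i]} study",
            f"Profiling of {topics[i]} in human samples.",
            [("organism", "Homo sapiens", "NCBITaxon:9606")]))
    return graph, repo


def _leukocyte_scenario() -> tuple[OntologyGraph, Repository]:
    """Cell-type branch: 12 leukocyte datasets, 5 native-cell-not-precursor.

    No free text mentions "leukocyte" (datasets talk about subtypes), so a
    text search for it retrieves nothing even though 12 datasets carry
    leukocyte subtype annotations.
    """
    cl = "CL"
    terms = [
        ("CL:0000000", "cell", cl, ()),
        ("CL:0000003", "native cell", cl, ()),
        ("CL:0002371", "somatic cell", cl, ()),
        ("CL:0000548", "animal cell", cl, ()),
        ("CL:0011115", "precursor cell", cl, ()),
        ("CL:0000738", "leukocyte", cl, ("white blood cell",)),
        ("CL:0000084", "T cell", cl, ("T lymphocyte",)),
        ("CL:0000236", "B cell", cl, ("B lymphocyte",)),
        ("CL:0000576", "monocyte", cl, ()),
        ("CL:0000037", "hematopoietic stem cell", cl, ("HSC",)),
        ("CL:0011026", "progenitor cell", cl, ()),
        ("CL:0002319", "neural cell", cl, ()),
        ("CL:0000066", "epithelial cell", cl, ()),
        ("NCBITaxon:33208", "Metazoa", "NCBITaxon", ()),
        ("NCBITaxon:10090", "mouse", "NCBITaxon", ("mice", "Mus musculus")),
        ("NCBITaxon:9606", "human", "NCBITaxon", ("Homo sapiens",)),
    ]
    edges = [
        ("CL:0000003", "CL:0000000"),
        ("CL:0002371", "CL:0000003"),
        ("CL:0000548", "CL:0000003"),
        ("CL:0011115", "CL:0000003"),
        ("CL:0000738", "CL:0002371"),
        ("CL:0000738", "CL:0000548"),
        ("CL:0000084", "CL:0000738"),
        ("CL:0000236", "CL:0000738"),
        ("CL:0000576", "CL:0000738"),
        ("CL:0000037", "CL:0011115"),
        ("CL:0011026", "CL:0011115"),
        ("CL:0002319", "CL:0002371"),
        ("CL:0000066", "CL:0000548"),
        ("NCBITaxon:10090", "NCBITaxon:33208"),
        ("NCBITaxon:9606", "NCBITaxon:33208"),
    ]
    graph = _graph(terms, edges)

    mouse = ("organism", "Mus musculus", "NCBITaxon:10090")
    subtype = {
        "T": ("cell type", "T cells", "CL:0000084"),
        "B": ("cell type", "B cells", "CL:0000236"),
        "M": ("cell type", "monocytes", "CL:0000576"),
    }
    precursor = {
        "H": ("cell type", "hematopoietic stem cells", "CL:0000037"),
        "P": ("cell type", "progenitor cells", "CL:0011026"),
    }
    repo = Repository()
    # five native-cell datasets without precursor annotations
    clean = [
        ("lk01", "T", "RNA-seq of mouse T cells", "Transcriptomes of sorted "
         "T cells from mouse spleen."),
        ("lk02", "T", "Thymocyte maturation in mice", "Maturation time course "
         "of T cells isolated from mice thymi."),
        ("lk03", "B", "Mouse B cell receptor repertoire", "Receptor "
         "repertoires of B cells from mouse bone marrow."),
        ("lk04", "B", "Germinal center B cells in mouse", "Sorted germinal "
         "center B cells from immunized mouse lymph nodes."),
        ("lk05", "M", "Mouse monocyte chemotaxis", "Chemotaxis assays of "
         "blood monocytes from mouse."),
    ]
    for did, sub, title, desc in clean:
        repo.add(_dataset(did, title, desc, [subtype[sub], mouse]))
    # seven datasets whose samples also include precursor populations
    mixed = [
        ("lk06", "T", "H", "Mouse T cell development atlas", "T cells and "
         "hematopoietic stem cells across mouse development."),
        ("lk07", "T", "P", "Thymic progenitors in mouse", "T cells and their "
         "progenitors from mouse thymus."),
        ("lk08", "B", "H", "Mouse B lymphopoiesis", "B cells plus "
         "hematopoietic stem cells from mouse marrow."),
        ("lk09", "B", "P", "Pro-B differentiation in mice", "B cells and "
         "progenitor fractions sorted from mice."),
        ("lk10", "M", "H", "Mouse monopoiesis time course", "Monocytes and "
         "hematopoietic stem cells from mouse."),
        ("lk11", "M", "P", "Monocyte progenitor screen in mouse", "Monocytes "
         "and committed progenitors from mouse blood."),
        ("lk12", "T", "P", "Mouse memory T cell precursors", "Memory T cells "
         "and precursor populations from mouse."),
    ]
    for did, sub, pre, title, desc in mixed:
        repo.add(_dataset(did, title, desc, [subtype[sub], precursor[pre], mouse]))
    # precursor-only datasets; pc01/pc02 also sample niche cell types so that
    # the somatic-cell and animal-cell branches are not reducible to leukocyte
    extra = {
        1: ("niche cell type", "neural niche cells", "CL:0002319"),
        2: ("niche cell type", "epithelial niche cells", "CL:0000066"),
    }
    for i, (pre, title, desc) in enumerate([
        ("H", "Mouse HSC quiescence", "Quiescent hematopoietic stem cells "
         "and their neural niche from mouse bone marrow."),
        ("P", "Progenitor metabolome in mouse", "Metabolic profiling of "
         "progenitor and epithelial niche cells from mouse."),
        ("H", "Aged mouse HSC epigenome", "Epigenomic maps of hematopoietic "
         "stem cells from aged mice."),
    ], start=1):
        anns = [precursor[pre], mouse] + ([extra[i]] if i in extra else [])
        repo.add(_dataset(f"pc{i:02d}", title, desc, anns))
    # datasets outside the cell-type branch entirely
    repo.add(_dataset("hs01", "Human liver proteome",
                      "Proteomic survey of human liver biopsies.",
                      [("organism", "Homo sapiens", "NCBITaxon:9606")]))
    repo.add(_dataset("hs02", "Human plasma metabolites",
                      "Metabolite panels from human plasma donors.",
                      [("organism", "Homo sapiens", "NCBITaxon:9606")]))
    return graph, repo


def _fig5_quadrants() -> tuple[OntologyGraph, Repository]:
    """Four datasets realising the four precision/recall quadrant cases."""
    terms = [
        ("NCBITaxon:33208", "Metazoa", "NCBITaxon", ()),
        ("NCBITaxon:9606", "human", "NCBITaxon", ("Homo sapiens",)),
        ("NCBITaxon:10090", "mouse", "NCBITaxon", ("mice",)),
        ("CL:0000000", "cell", "CL", ()),
        ("CL:0000182", "hepatocyte", "CL", ()),
        ("CL:0000057", "fibroblast", "CL", ()),
        ("PR:000000001", "protein", "PR", ()),
        ("PR:000012421", "p53", "PR", ("TP53",)),
        ("EFO:0000408", "disease", "EFO", ()),
        ("EFO:1002049", "fibrosis", "EFO", ()),
        ("OBI:0000070", "assay", "OBI", ()),
        ("OBI:0001271", "RNA-Seq", "OBI", ("transcription profiling by high "
                                           "throughput sequencing",)),
        ("OBI:0400148", "microarray", "OBI", ()),
    ]
    edges = [
        ("NCBITaxon:9606", "NCBITaxon:33208"),
        ("NCBITaxon:10090", "NCBITaxon:33208"),
        ("CL:0000182", "CL:0000000"),
        ("CL:0000057", "CL:0000000"),
        ("PR:000012421", "PR:000000001"),
        ("EFO:1002049", "EFO:0000408"),
        ("OBI:0001271", "OBI:0000070"),
        ("OBI:0400148", "OBI:0000070"),
    ]
    graph = _graph(terms, edges)
    repo = Repository()
    repo.add(_dataset(
        "ds1", "Human hepatocyte p53 RNA-Seq",
        "RNA-Seq of p53 targets in primary human hepatocyte cultures.",
        [("organism", "human", "NCBITaxon:9606"),
         ("cell type", "hepatocyte", "CL:0000182"),
         ("gene", "p53", "PR:000012421"),
         ("technology", "RNA-Seq", "OBI:0001271")]))
    repo.add(_dataset(
        "ds2", "Human fibroblast p53 pathway RNA-Seq",
        "RNA-Seq screen of the p53 pathway in human fibroblast tumor lines.",
        [("organism", "human", "NCBITaxon:9606"),
         ("cell type", "fibroblast", "CL:0000057"),
         ("gene", "p53", "PR:000012421"),
         ("technology", "RNA-Seq", "OBI:0001271")]))
    repo.add(_dataset(
        "ds3", "Human fibroblast p53 RNA-Seq",
        "RNA-Seq of p53 activation in human fibroblast cultures.",
        [("organism", "human", "NCBITaxon:9606"),
         ("cell type", "fibroblast", "CL:0000057"),
         ("gene", "p53", "PR:000012421"),
         ("technology", "RNA-Seq", "OBI:0001271")]))
    repo.add(_dataset(
        "ds4", "Mouse fibroblast fibrosis microarray",
        "Microarray profiling of fibrosis markers in mouse fibroblast lines.",
        [("organism", "mouse", "NCBITaxon:10090"),
         ("cell type", "fibroblast", "CL:0000057"),
         ("disease", "fibrosis", "EFO:1002049"),
         ("technology", "microarray", "OBI:0400148")]))
    return graph, repo


def _taxonomy_prune() -> tuple[OntologyGraph, Repository]:
    """Three species chains below a common ancestor with prunable inner terms.

    Below *Euteleostomi*, the inner chain terms (Homo, Primates, Mus,
    Rodentia, Danio, Actinopterygii) each describe exactly the same datasets
    as their single species child, so pruning collapses all six of them.
    """
    tax = "NCBITaxon"
    terms = [
        ("NCBITaxon:117571", "Euteleostomi", tax, ()),
        ("NCBITaxon:40674", "Mammalia", tax, ()),
        ("NCBITaxon:9443", "Primates", tax, ()),
        ("NCBITaxon:9605", "Homo", tax, ()),
        ("NCBITaxon:9606", "human", tax, ("Homo sapiens",)),
        ("NCBITaxon:9989", "Rodentia", tax, ()),
        ("NCBITaxon:10088", "Mus", tax, ()),
        ("NCBITaxon:10090", "mouse", tax, ("mice",)),
        ("NCBITaxon:7898", "Actinopterygii", tax, ()),
        ("NCBITaxon:7954", "Danio", tax, ()),
        ("NCBITaxon:7955", "zebrafish", tax, ("Danio rerio",)),
    ]
    edges = [
        ("NCBITaxon:40674", "NCBITaxon:117571"),
        ("NCBITaxon:9443", "NCBITaxon:40674"),
        ("NCBITaxon:9605", "NCBITaxon:9443"),
        ("NCBITaxon:9606", "NCBITaxon:9605"),
        ("NCBITaxon:9989", "NCBITaxon:40674"),
        ("NCBITaxon:10088", "NCBITaxon:9989"),
        ("NCBITaxon:10090", "NCBITaxon:10088"),
        ("NCBITaxon:7898", "NCBITaxon:117571"),
        ("NCBITaxon:7954", "NCBITaxon:7898"),
        ("NCBITaxon:7955", "NCBITaxon:7954"),
    ]
    graph = _graph(terms, edges)
    repo = Repository()
    species = ([("human", "Homo sapiens", "NCBITaxon:9606")] * 4
               + [("mouse", "Mus musculus", "NCBITaxon:10090")] * 3
               + [("zebrafish", "Danio rerio", "NCBITaxon:7955")] * 3)
    for i, (name, text, term) in enumerate(species):
        repo.add(_dataset(f"tx{i + 1:02d}", f"{name.capitalize()} study {i + 1}",
                          f"Expression atlas of {text} tissues.",
                          [("organism", text, term)]))
    return graph, repo


def named_fixture(name: str) -> tuple[OntologyGraph, Repository]:
    builders = {
        "mammalia_chain": _mammalia_chain,
        "leukocyte_scenario": _leukocyte_scenario,
        "fig5_quadrants": _fig5_quadrants,
        "taxonomy_prune": _taxonomy_prune,
    }
    if name not in builders:
        raise FixtureSpecError(
            f"unknown fixture {name!r}; expected one of {sorted(builders)}")
    return builders[name]()


# ---------------------------------------------------------------------------
# OBO emission (fixtures are written in OBO so they exercise the loader path)

def write_obo(graph: OntologyGraph, path: str | Path,
              ontology_name: str = "synthetic-fixture") -> None:
    lines = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for tid in sorted(graph.terms):
        if tid == ROOT_ID:
            continue
        term = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        if term.label:
            lines.append(f"name: {term.label}")
        for syn in term.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for parent in sorted(graph.parents_of(tid)):
            if parent != ROOT_ID:
                plabel = graph.terms[parent].label
                suffix = f" ! {plabel}" if plabel else ""
                lines.append(f"is_a: {parent}{suffix}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8", newline="\n")
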