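# Methods

This note documents the models and procedures implemented by `ontoscout`,
the assumptions behind them, the numerical and design choices made where
the design was genuinely open, and what the synthetic fixtures do and do
not establish about real repositories.

## Ontology model

Ontologies enter as OBO 1.4 flat files or OWL RDF/XML and are reduced to
a simplified subclass property graph: one node per *named* class (id,
label, synonyms, source-ontology tags), one edge per asserted named-class
subsumption. Anonymous class expressions (existential restrictions,
intersections, equivalences) are not materialised; a configuration hook
(`ontology.EDGE_FILTERS`) exists for incorporating further relation types
but only `is_a`/`rdfs:subClassOf` is enabled. Inferred subsumption (OWL
reasoning) is a non-goal.

Identifiers are normalised to CURIEs through a configurable prefix map
(OBO PURLs handled natively); unknown IRIs keep their full form as id, so
normalisation is total and idempotent. Merging ontologies unions vertices
and edges; a class asserted by several ontologies becomes one node whose
tag set records each source. All graphs share a single virtual root with
the reserved id `OWL:Thing`; parentless classes are attached to it.

Cycles among named classes are a **hard error** carrying one offending
cycle, never silently broken: every downstream computation — topological
closure, pruning, layered layout — assumes a DAG, and subclass cycles in
curated ontologies indicate data corruption rather than intent.

Graph measures: `distance` is the shortest-path length to the root (BFS
over reversed edges); `subtree_depth` is the longest downward path
(dynamic program over a deterministic topological order). Both are
recomputed on the pruned graph, so displayed columns and colours are
self-consistent with displayed edges; the alternative (original-ontology
distances) would scatter terms of one pruned column across several.

## Repository and annotation closure

A dataset is the atomic unit: id, title, description, ownership/sharing
surrogate fields, and a list of attributes, each a free-text value
optionally carrying one ontology term. Annotations attach at dataset
level (not file level). The manifest dialect is UTF-8 TSV, header
required, one row per attribute (LF or CRLF); an equivalent JSON form is
accepted. Annotation terms absent from the loaded ontologies never abort
an index build — they are collected into an unresolved-terms report
(dataset id, term id, attribute name) for curators, and the build
proceeds over resolvable terms.

The annotation index propagates each direct annotation to every
superclass in one pass over the reverse topological order. Sets have
**set semantics**: a dataset annotated with two subclasses of *t* counts
once in *S_t*. "Size" everywhere downstream means transitive |S_t|;
direct-use sets are retained separately (they drive the filled-vs-outline
distinction when highlighting a dataset's terms).

## Pruning to a strict containment hierarchy

Stage 1, *restriction*: only terms with size ≥ 1 are retained (plus the
root). With ancestor-closed sets, every ancestor of a used term is itself
used, so removal only ever eliminates whole unused subtrees; the
implementation nevertheless re-links a retained child across removed
terms to its nearest retained ancestors, which matters when callers
restrict with a non-closed (e.g. direct-use) index.

Stage 2, *collapse*: a non-root parent whose transitive set equals that
of one of its children is absorbed into that child — it cannot
discriminate among the datasets below it, so its mutual information with
any other attribute is zero. Candidates are processed to a fixpoint in
decreasing distance order, which makes the output deterministic and keeps
the **deepest (most specific)** term of an equal-set chain. The absorbing
child is the deepest equal-set child (ties by id); other children of the
removed parent re-link to the parent's parents, preserving truthful
subsumption. At the fixpoint every retained edge (c, p) with p ≠ root
satisfies *S_c* ⊊ *S_p*: an equal-set pair would itself be a candidate.
A parent whose set equals the *union* of two or more proper-subset
children has no equal-set child and is retained — removing it would
disconnect the siblings, and the containment contract concerns
parent–child pairs. For the same reason a last-common-ancestor term whose
set spans the whole repository survives exactly when it keeps ≥ 2
retained children. Choosing *which* class of a pruned branch is kept more
cleverly than "the most specific" is out of scope.

Absorbed ancestors are appended to the keeping term's provenance list
(most specific first), so breadcrumb paths can interleave the full
ontological lineage as display-only entries, and queries naming a
collapsed term can be mapped to its retained representative. Pruning
never alters any retained term's transitive set, and the pipeline is
idempotent: pruning an already-pruned graph is the identity.

## Precision, recall, and undefined values

For result set R: precision(t) = |R ∩ S_t|/|R|, recall(t) = |R ∩ S_t|/|S_t|.
The integer intersection is counted once and divided two ways, so the
identity precision·|R| = recall·size holds exactly in floating point.
Intersections use transitive sets, so a term's bars account for datasets
annotated with any descendant. An empty result set or an unused term
makes the corresponding metric **undefined**, reported as an explicit
flag/exception (`None` in tables) rather than 0.0 — zero is a meaningful
display value. The virtual root is excluded from statistics displays.
Term-enrichment testing is a non-goal.

## Query engine

Tokenization is lowercase, split on non-alphanumerics, no stemming —
predictable and locale-independent. Text search is **conjunctive**: every
query token (or one of its expansions) must occur in the title,
description or an attribute text value. Synonym expansion is
term-mediated: a token equal to a term's single-word label or synonym is
expanded with that term's other single-word names (mouse → mice).
Multi-word synonyms do not expand token-wise — without phrase matching,
expanding *leukocyte* with the individual words of *white blood cell*
would match every description containing "blood". Matching ontology
labels of a dataset's annotations in text search is off by default
(free-text and semantic retrieval stay distinct signals); ranking is a
BM25 score (k1 = 1.5, b = 0.75) over field-weighted term frequencies with
title weighted 3× over description and attribute text, ties broken by
dataset id. Keyword-in-context snippets mark the first matched token —
which may be a synonym, not the query token — with bracketed offsets and
window-limited context.

Term queries follow fixed operator precedence (the source behaviour
leaves it open): the AND-set is intersected first, the OR-union is then
intersected with it (or with the universe), NOT is subtracted last so
exclusion is absolute, and a root term finally intersects with its
subtree's set. Each term carries one of four query states (none → or →
and → not), cycled by `toggle_query_state`. Rooting commutes with
querying: zooming into a subtree then querying equals querying with
`root_term` set. The data cart is an insertion-ordered, duplicate-free
id collection with membership-checked add/remove.

## Layouts

Both layouts are geometry only; pixel rendering, transitions and UI
mechanics are out of scope.

**Treemap.** Squarified tiling (the standard choice for legible aspect
ratios; no particular algorithm is mandated by the problem) of the unit
square, origin top-left, y down, half-open rectangles. Sibling input
order is size-descending with label/id tie-breaks. Sibling areas are
normalised to the *sibling size sum*: in a polyhierarchy sibling sets may
overlap, so areas are a relative (per-parent) encoding, never relative to
the root; with disjoint siblings children tile their parent exactly
(conserved to 1e-9, property-tested). A term with several retained
parents is tiled under each parent, the treemap convention. Colour is
emitted as the integer subtree depth; mapping levels to a palette is the
renderer's job. Recursion stops at the visible depth (default 1);
terminal terms carry no children. The breadcrumb runs from the absolute
root to the current root term, provenance-expanded.

**Node-link.** Terms occupy columns indexed by pruned-graph distance,
each column independently sortable by precision (default, descending —
when exploration starts at the whole repository every recall is 1, so
precision is the informative default), recall, name or size; undefined
metric values sort last, ties by label then id. Each term carries its
precision/recall bar values. Given a visible window (first column, column
count, rows per column), every visible term counts edges to non-visible
partners: parent links as incoming, child links as outgoing hidden-link
bars. Edges touching the virtual root are not counted.

Breadcrumb paths take the shortest retained root path, breaking ties by
lexicographically smallest parent id, and optionally interleave absorbed
ancestors top-down.

## Synthetic fixtures

The random generator emulates the regime of real annotated repositories:
deep, mildly polyhierarchical ontologies (ranked DAG construction —
parents sampled from strictly lower ranks — acyclic by construction,
default depth 8, 15% of terms get a second parent), sparse ancestor-closed
usage, and datasets annotated at varying depths (1–4 direct terms each by
default). The used set is grown to an exact target cardinality; every
minimal used term is guaranteed a direct annotation so the closure of the
annotations equals the used set exactly. Generation is deterministic per
seed, down to byte-identical OBO/TSV emission.

Named fixtures encode the worked scenarios exercised throughout the test
and acceptance suites: `mammalia_chain` (10 datasets all annotated
*human* below a six-level taxon chain — every ancestor collapses),
`leukocyte_scenario` (12 leukocyte datasets, 5 native-cell-not-precursor,
no free text containing "leukocyte"), `fig5_quadrants` (4 datasets
realising the four precision/recall cases under the captioned searches —
the low/high case uses the search "fibroblast", whose retrieved set
contains all fibrosis datasets plus two others), and `taxonomy_prune`
(human/mouse/zebrafish chains under one ancestor with six collapsible
equal-set inner terms).

What passing on fixtures does *not* show: real ontologies carry relation
types, equivalence axioms and scale (10⁶ terms) that the fixtures only
sample; real metadata has typos, multilingual text and inconsistent
curation depth that the generator does not emulate; and free-text/
annotation discrepancies in the wild are systematic, not random. The
scalability check runs the full pipeline at 1000 retained annotation
terms — the regime where the node-link view is the practical bottleneck —
on one CPU; problem sizes in the test suite (≤ 60 terms / ≤ 40 datasets
for the 200-seed property sweeps, 10 000 terms for the sparse-usage
restriction check, 4 000 for the scaling check) were chosen to exercise
every code path while keeping the default run fast.

## Numerical choices and degenerate inputs

Tiling tolerance 1e-9; floats in TSV tables printed with 6 decimals and
in layout JSON rounded to 12 significant decimals for byte-stable output.
Empty query text returns the whole repository in id order; an empty term
query returns the universe; a header-only manifest yields an empty
repository and a root-only exploration graph (indexing warns but exits
0). Self-edges in ontology input are dropped as information-free;
duplicate edges collapse into the edge set. All iteration orders that
could leak hash randomness (topological order, collapse candidates,
query-set resolution, layout orderings) are explicitly sorted, so every
artefact is reproducible byte for byte.
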