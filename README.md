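# ontoscout

Ontology-guided search and exploration of annotated biomedical dataset
repositories.

Public data repositories (expression archives, metabolomics collections,
stem-cell catalogues, ...) describe each dataset with free-text metadata
plus ontology-term annotations — an organism from a taxonomy, a cell type
from a cell ontology, a technology from an assay ontology. Text search
alone gives no overview of what a repository contains and fails whenever
the sought concept is only implied by annotations (a search for
*leukocyte* finds nothing if datasets are annotated with *T cell* and
*monocyte*). `ontoscout` implements the computational core of an
ontology-guided exploration engine for such repositories: it turns
ontologies plus a dataset manifest into a pruned containment hierarchy
with per-term statistics, answers combined text/semantic queries, and
emits visualization-ready treemap and node-link layouts. Rendering and UI
are deliberately out of scope — every layout is plain data.

## Model

Ontologies are reduced to a property graph: one node per named class, one
directed edge per asserted subclass relation, merged across ontologies
under a single virtual root (`OWL:Thing`). For a term *t* with dataset set
*S_t* (every dataset annotated with *t* **or any of its descendants** —
the transitive closure of annotation under subsumption):

- **size**(t) = |S_t|, the central statistic of the exploration view;
- **distance**(t) = shortest path from *t* to the root;
- **subtree depth**(t) = longest downward path from *t* (treemap colour).

Because whole ontologies are huge but annotation usage is sparse, the
graph is pruned to an *exploration graph*: terms with size 0 are hidden,
and any parent describing exactly the same dataset set as one of its
children is absorbed into that child (it carries zero information about
the repository). The result is a strict containment hierarchy — for every
remaining edge (c, p) below the root, *S_c* ⊊ *S_p* — with the absorbed
lineage preserved per term for breadcrumb display.

Given a retrieved result set *R*, every term gets

```
precision(t) = |R ∩ S_t| / |R|        recall(t) = |R ∩ S_t| / |S_t|
```

Recall is the "information scent" of a term: how much of what the
repository holds for this attribute the current search has actually
surfaced. Term queries are pure set algebra over the *S_t*
(AND-intersection, then OR-union, NOT subtracted last, optional subtree
rooting), and text search is conjunctive token matching with
ontology-synonym expansion, ranked by a BM25-style field-weighted score.

## Worked example

The bundled `leukocyte_scenario` fixture has 17 datasets: 12 annotated
with leukocyte subtypes (7 of which also sample precursor populations),
3 precursor-only and 2 unrelated human datasets. No free text mentions
"leukocyte".

```sh
ontoscout simulate --name leukocyte_scenario --out demo/fx
ontoscout index --ontology demo/fx/fixture.obo CL \
                --manifest demo/fx/manifest.tsv --out demo/idx
ontoscout query '"mouse" +term:CL:0000003 -term:CL:0011115' --index demo/idx
```

The query asks for datasets whose text matches *mouse* (or a synonym such
as *mice*), annotated with *native cell* (`CL:0000003`) and free of
*precursor cell* (`CL:0011115`) annotations. Output (abridged):

```json
{
 "query": "\"mouse\" +term:CL:0000003 -term:CL:0011115",
 "n_retrieved": 5,
 "ids": ["lk05", "lk01", "lk02", "lk03", "lk04"],
 "stats": {
   "CL:0000738": {"size": 12, "precision": 1.0, "recall": 0.4166666666666667}
 }
}
```

Five datasets are retrieved; each of them carries a leukocyte subtype
annotation (precision 1.0), but only 5 of the 12 leukocyte datasets in
the repository were found (recall 5/12 ≈ 0.42) — the low recall signals
that relaxing the query would surface seven more relevant datasets.
Dropping the term clauses and querying `+term:CL:0000738` directly
retrieves all 12, even though a plain text search for "leukocyte"
retrieves none.

`ontoscout layout --index demo/idx --kind treemap --depth 2` and
`... --kind nodelink` emit the two layout geometries as JSON.

As a library, the same pipeline is four calls:

```python
from ontoscout import (named_fixture, build_annotation_index,
                       build_exploration_graph, compute_all_stats, ResultSet)

graph, repo = named_fixture("leukocyte_scenario")
index = build_annotation_index(repo, graph)
eg = build_exploration_graph(graph, repo, index)
stats = compute_all_stats(ResultSet.of(repo.ids()), eg)
```

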