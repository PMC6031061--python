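import pytest

from ontoscout import (FixtureSpec, build_annotation_index,
                       build_exploration_graph, generate, named_fixture)


class Bundle:
    """A fixture graph/repository with its derived index and pruned graph."""

    def __init__(self, graph, repo):
        self.graph = graph
        self.repo = repo
        self.index = build_annotation_index(repo, graph)
        self.eg = build_exploration_graph(graph, repo, self.index)


@pytest.fixture(scope="session")
def mammalia():
    return Bundle(*named_fixture("mammalia_chain"))


@pytest.fixture(scope="session")
def leukocyte():
    return Bundle(*named_fixture("leukocyte_scenario"))


@pytest.fixture(scope="session")
def fig5():
    return Bundle(*named_fixture("fig5_quadrants"))


@pytest.fixture(scope="session")
def taxonomy():
    return Bundle(*named_fixture("taxonomy_prune"))


def random_bundle(seed, n_terms=50, n_datasets=30, used_term_fraction=0.4,
                  max_depth=6, polyhierarchy_fraction=0.25,
                  annotations_max=4) -> Bundle:
    spec = FixtureSpec(n_terms=n_terms, max_depth=max_depth,
                       polyhierarchy_fraction=polyhierarchy_fraction,
                       n_datasets=n_datasets,
                       used_term_fraction=used_term_fraction,
                       annotations_max=annotations_max, seed=seed)
    return Bundle(*generate(spec))
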