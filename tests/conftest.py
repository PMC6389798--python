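import networkx as nx
import pytest

import hallmarknet as hn


@pytest.fixture(scope="session")
def default_dataset():
    """Three-cohort synthetic dataset with two shared and one cohort-specific module."""
    return hn.generate_cohorts(hn.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def annotation_fixtures(default_dataset):
    return hn.generate_annotation_fixtures(default_dataset)


@pytest.fixture(scope="session")
def fitted_results(default_dataset, annotation_fixtures):
    genesets, drugs = annotation_fixtures
    miner = hn.HallmarkMiner(
        default_dataset.cohorts, seed_cohort="cohort0",
        hallmark_min_cohorts=2, genesets=genesets, drugs=drugs,
    )
    return miner.fit(seed=11)


@pytest.fixture
def bridged_cliques():
    """Two 4-cliques joined through one bridge vertex of degree 2."""
    g = nx.Graph()
    for block in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(block[i], block[j])
    g.add_edge("a1", "x")
    g.add_edge("b1", "x")
    return g
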