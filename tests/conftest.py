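import numpy as np
import pytest

from pesuscept import (
    ExprSimConfig,
    GeneSet,
    extract_pathway,
    generate_expression_dataset,
    generate_ppi_graph,
    induce_pathway_subgraph,
)
from pesuscept.graph import PPIGraph


def random_graph(rng: np.random.Generator, n: int, p: float = 0.3) -> PPIGraph:
    """Erdos-Renyi-style helper used by graph/filter property tests."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return PPIGraph(list(range(n)), A)


@pytest.fixture(scope="session")
def ba_graph():
    """A 400-gene scale-free universe graph shared across tests."""
    return generate_ppi_graph(400, 2, seed=1)


@pytest.fixture(scope="session")
def pathway_geneset(ba_graph):
    return GeneSet("il4_il13_pathway", ba_graph.node_ids[:111])


@pytest.fixture(scope="session")
def pathway_graph(ba_graph, pathway_geneset):
    return induce_pathway_subgraph(ba_graph, pathway_geneset)


@pytest.fixture(scope="session")
def strong_dataset(ba_graph, pathway_geneset):
    """Pathway matrix with a strong graph-smooth class effect (norm 3*sqrt(111))."""
    cfg = ExprSimConfig(effect_size=3.0 * np.sqrt(111), seed=7)
    ds = generate_expression_dataset(cfg, ba_graph)
    sub, _ = extract_pathway(ds, pathway_geneset)
    return sub
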