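import numpy as np
import pandas as pd
import pytest

from possel.ontology import GeneSetCollection, OntologyGraph
import networkx as nx


@pytest.fixture(scope="session")
def toy_background() -> pd.Series:
    """The 4-score background used by the exhaustive enumeration oracle."""
    return pd.Series([0.0, 1.0, 2.0, 3.0], index=["g0", "g1", "g2", "g3"])


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """root <- mid <- leaf (child -> parent edges)."""
    g = nx.DiGraph()
    for t in ("leaf", "mid", "root"):
        g.add_node(t, name=t, namespace="bp")
    g.add_edge("leaf", "mid", relation="is_a")
    g.add_edge("mid", "root", relation="is_a")
    return OntologyGraph(graph=g)


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """leaf with two paths to root: leaf -> (a, b) -> root."""
    g = nx.DiGraph()
    for t in ("leaf", "a", "b", "root"):
        g.add_node(t, name=t, namespace="bp")
    g.add_edge("leaf", "a")
    g.add_edge("leaf", "b")
    g.add_edge("a", "root")
    g.add_edge("b", "root")
    return OntologyGraph(graph=g)


def make_collection(sets: dict, background=None, min_size=1) -> GeneSetCollection:
    bg = background if background is not None else {g for s in sets.values() for g in s}
    return GeneSetCollection(
        sets={t: frozenset(s) for t, s in sets.items()},
        background=frozenset(bg),
        min_size=min_size,
    )


@pytest.fixture(scope="session")
def null_scores_5000() -> pd.Series:
    """A 5,000-family null background of transformed lineage scores."""
    from possel.synthetic_data import simulate_scores

    return simulate_scores(5000, seed=20240901)
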