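import networkx as nx
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from reporternet.model import MetabolicModel


@pytest.fixture
def toy_model():
    """Two genes feeding one metabolite inside one pathway, plus extras.

    g1,g2 -> m1 in pw1; g3 -> m2 in pw1; g4 -> m3 (orphan of any pathway);
    m_cur is a currency-style hub touched by g1..g4.
    """
    return MetabolicModel(
        genes=frozenset({"g1", "g2", "g3", "g4"}),
        metabolites=frozenset({"m1", "m2", "m3", "m_cur"}),
        pathways=frozenset({"pw1"}),
        gene_metabolite=frozenset(
            {("g1", "m1"), ("g2", "m1"), ("g3", "m2"), ("g4", "m3"),
             ("g1", "m_cur"), ("g2", "m_cur"), ("g3", "m_cur"), ("g4", "m_cur")}
        ),
        metabolite_pathway=frozenset({("m1", "pw1"), ("m2", "pw1"), ("m_cur", "pw1")}),
    )


@pytest.fixture
def reaction_model():
    """Reaction-layer model: r1 is catalysed by two isozymes g1/g2."""
    return MetabolicModel(
        genes=frozenset({"g1", "g2", "g3"}),
        metabolites=frozenset({"m1", "m2"}),
        pathways=frozenset({"pw1"}),
        reactions=frozenset({"r1", "r2"}),
        gene_reaction=frozenset({("g1", "r1"), ("g2", "r1"), ("g3", "r2")}),
        reaction_metabolite=frozenset({("r1", "m1"), ("r2", "m2")}),
        gene_metabolite=frozenset({("g1", "m1"), ("g2", "m1"), ("g3", "m2")}),
        metabolite_pathway=frozenset({("m1", "pw1"), ("m2", "pw1")}),
    )


@pytest.fixture
def two_cliques_bridged():
    """Two 5-cliques joined by a single bridge edge 0-5."""
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g.add_edge(0, 5)
    return g


@pytest.fixture
def probe_map():
    return pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "p3", "p4"],
            "gene_id": ["gA", "gA", "gB", "gC"],
            "rank": [1, 2, 1, 1],
        }
    )
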