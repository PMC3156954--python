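import networkx as nx
import pytest

from metnet.model import Compound, MetabolicNetwork, Pathway, Reaction


@pytest.fixture
def toy_network() -> MetabolicNetwork:
    """Three-reaction network with ATP/ADP currency garnish.

    R1: A + ATP -> B + ADP  (EC 9.9.1.1)
    R2: B -> C              (EC 9.9.1.2)
    R3: C <-> D             (EC 9.9.1.3, reversible)
    Pathway P1 = {R1, R2}, P2 = {R3}.
    """
    net = MetabolicNetwork(currency_list={"ATP", "ADP"})
    net.add_reaction(Reaction(id="R1", enzymes={"9.9.1.1"},
                              substrates={"A", "ATP"}, products={"B", "ADP"},
                              direction="forward", source="ref", pathways={"P1"}))
    net.add_reaction(Reaction(id="R2", enzymes={"9.9.1.2"},
                              substrates={"B"}, products={"C"},
                              direction="forward", source="ref", pathways={"P1"}))
    net.add_reaction(Reaction(id="R3", enzymes={"9.9.1.3"},
                              substrates={"C"}, products={"D"},
                              direction="reversible", source="ref", pathways={"P2"}))
    net.add_pathway(Pathway(id="P1", reactions={"R1", "R2"}))
    net.add_pathway(Pathway(id="P2", reactions={"R3"}))
    return net


@pytest.fixture
def two_triangle_graph() -> nx.Graph:
    """Two triangles joined by a single bridge edge (7 edges total)."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"),
                      ("c", "d")])
    return g


@pytest.fixture
def clique_pair_graph() -> nx.Graph:
    """Two 4-cliques joined by one edge; the natural community structure."""
    g = nx.Graph()
    left = [f"L{i}" for i in range(4)]
    right = [f"R{i}" for i in range(4)]
    for grp in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(grp[i], grp[j])
    g.add_edge("L3", "R0")
    return g
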