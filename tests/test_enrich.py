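import itertools
from fractions import Fraction

import numpy as np
import pytest

from metnet.enrich import (
    EnrichmentInput,
    EnrichmentResult,
    analyze,
    enrichment_report,
    export_gmt,
    fisher_pathway_test,
    map_genes_to_enzymes,
)
from metnet.model import MetabolicNetwork, Pathway, Reaction
from metnet.simulate import make_enrichment_case


def enumerate_upper_tail(N, K, n, k):
    """Exact P(X >= k) by enumerating all C(N, n) selections."""
    population = range(N)
    members = set(range(K))
    total = hits = 0
    for sel in itertools.combinations(population, n):
        total += 1
        if len(members.intersection(sel)) >= k:
            hits += 1
    return Fraction(hits, total) if total else Fraction(1)


class TestMapGenes:
    def _input(self, selected, universe, gene_to_ec):
        return EnrichmentInput(selected_genes=set(selected),
                               universe_genes=set(universe),
                               gene_to_ec=gene_to_ec)

    def test_genes_sharing_an_ec_collapse(self):
        inp = self._input(
            ["g1", "g2", "g3"], ["g1", "g2", "g3"],
            {g: {"9.9.1.1"} for g in ["g1", "g2", "g3"]},
        )
        selected, background = map_genes_to_enzymes(inp)
        assert selected == background == {"9.9.1.1"}

    def test_multi_ec_gene_counts_each_enzyme(self):
        inp = self._input(["g"], ["g"], {"g": {"9.9.1.1", "9.9.1.2"}})
        selected, _ = map_genes_to_enzymes(inp)
        assert selected == {"9.9.1.1", "9.9.1.2"}

    def test_unmappable_selection_yields_empty_set(self):
        inp = self._input(["g1"], ["g1", "g2"], {"g2": {"9.9.1.1"}})
        selected, background = map_genes_to_enzymes(inp)
        assert selected == set() and background == {"9.9.1.1"}

    def test_empty_background_raises(self):
        inp = self._input([], ["g1"], {})
        with pytest.raises(ValueError, match="universe"):
            map_genes_to_enzymes(inp)

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            self._input(["x"], [], {})


class TestFisherPathwayTest:
    def test_reported_example_66_over_252(self):
        background = {f"9.9.1.{i}" for i in range(1, 11)}   # N=10
        pathway = {f"9.9.1.{i}" for i in range(1, 5)}       # K=4
        selected = {"9.9.1.1", "9.9.1.2", "9.9.1.3", "9.9.1.5", "9.9.1.6"}  # n=5, k=3
        res = fisher_pathway_test(selected, background, "toy", pathway)
        assert res.k == 3 and res.K == 4 and res.n == 5 and res.N == 10
        assert res.p == pytest.approx(66 / 252, rel=1e-12)

    def test_full_selection_gives_p_one(self):
        background = {f"9.9.1.{i}" for i in range(1, 8)}
        for K in (1, 3, 7):
            pathway = set(list(background)[:K])
            res = fisher_pathway_test(background, background, "p", pathway)
            assert res.p == pytest.approx(1.0)

    def test_untestable_pathway_returns_none(self):
        assert fisher_pathway_test(set(), {"9.9.1.1"}, "p", {"8.8.8.8"}) is None

    def test_matches_enumeration_oracle_small_cases(self):
        for N in (4, 6, 8):
            background = {f"9.9.1.{i}" for i in range(N)}
            for K in range(1, N + 1):
                pathway = {f"9.9.1.{i}" for i in range(K)}
                for n in range(1, N + 1):
                    selected = {f"9.9.1.{i}" for i in range(N - n, N)}
                    k = len(selected & pathway)
                    res = fisher_pathway_test(selected, background, "p", pathway)
                    oracle = enumerate_upper_tail(N, K, n, k)
                    assert res.p == pytest.approx(float(oracle), rel=1e-9)

    def test_monotone_in_k_with_margins_fixed(self):
        from scipy.stats import hypergeom
        N, K, n = 40, 12, 15
        tails = [float(hypergeom.sf(k - 1, N, K, n)) for k in range(0, min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))


class TestEnrichmentReport:
    def _res(self, name, p):
        return EnrichmentResult(pathway=name, k=1, K=2, n=3, N=10, p=p)

    def test_filters_and_sorts_by_p_then_name(self):
        rep = enrichment_report(
            [self._res("b", 0.01), self._res("a", 0.01), self._res("c", 0.2)]
        )
        assert [r.pathway for r in rep.significant] == ["a", "b"]
        assert [r.pathway for r in rep.full] == ["a", "b", "c"]

    def test_no_hits_gives_empty_filtered_table(self):
        rep = enrichment_report([self._res("a", 0.9)])
        assert rep.significant == [] and len(rep.full) == 1

    def test_alpha_one_reports_everything(self):
        rep = enrichment_report([self._res("a", 0.5), self._res("b", 0.99)], alpha=1.0)
        assert len(rep.significant) == 2

    def test_bh_adjustment_present_and_ordered(self):
        rep = enrichment_report([self._res("a", 0.01), self._res("b", 0.04)])
        assert all(r.q is not None and r.q >= r.p for r in rep.full)


class TestPlantedEnrichment:
    def test_planted_pathways_occupy_top_ranks(self):
        inp, net, _ = make_enrichment_case(
            seed=42, planted=[("pathway_00", 0.6), ("pathway_01", 0.6)],
            base_rate=0.05,
        )
        rep = analyze(inp, net)
        top2 = {r.pathway for r in rep.full[:2]}
        assert top2 == {"pathway_00", "pathway_01"}

    def test_null_case_calibrated(self):
        """Without planted signal the p < 0.05 rate stays near 5%."""
        hits = trials = 0
        for seed in range(40):
            inp, net, _ = make_enrichment_case(seed=seed, n_pathways=10,
                                               base_rate=0.3)
            if not inp.selected_genes:
                continue
            rep = analyze(inp, net, alpha=1.0)
            trials += len(rep.full)
            hits += sum(1 for r in rep.full if r.p < 0.05)
        assert trials > 100
        # generous binomial envelope for a quick sanity check
        assert hits / trials < 0.12


class TestExportGmt:
    def _network(self):
        net = MetabolicNetwork(currency_list=set())
        net.add_reaction(Reaction(id="R1", enzymes={"9.9.1.1"},
                                  substrates={"A"}, products={"B"}, pathways={"pw"}))
        net.add_pathway(Pathway(id="pw", name="pw", reactions={"R1"}))
        net.enzymes["9.9.1.1"].genes["fish"] = {"g2", "g1"}
        return net

    def test_line_format(self):
        lines = export_gmt(self._network(), "fish")
        assert lines == ["pw\tfish gene set\tg1\tg2"]

    def test_pathway_without_genes_omitted(self):
        net = self._network()
        net.add_reaction(Reaction(id="R2", enzymes={"9.9.1.2"},
                                  substrates={"C"}, products={"D"}, pathways={"empty"}))
        net.add_pathway(Pathway(id="empty", reactions={"R2"}))
        lines = export_gmt(net, "fish")
        assert len(lines) == 1

    def test_unknown_species_raises(self):
        with pytest.raises(KeyError):
            export_gmt(self._network(), "unicorn")

    def test_fixture_line_count_matches_manifest(self):
        inp, net, manifest = make_enrichment_case(seed=2, n_pathways=6)
        lines = export_gmt(net, "sim")
        with_genes = sum(
            1 for pid in net.pathways
            if any(net.enzymes[ec].genes.get("sim")
                   for ec in net.pathway_ec_set(pid, include_partial=True))
        )
        assert len(lines) == with_genes == manifest.counts["pathways"]
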