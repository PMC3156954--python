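"""Synthetic toy-scale inputs with known ground truth.

Every pipeline stage is testable without external downloads: this module
generates coherent reference models with planted duplicate reactions,
planted-partition reaction graphs, enrichment cases with planted
over-represented pathways, and annotation-stage inputs (homology hit tables,
a small ontology, ortholog and gene→EC maps).  All generators are
deterministic functions of their seed, and each returns a manifest recording
the planted truth so that expected test values can be recomputed.

Identifiers are synthetic but format-valid: EC numbers use the reserved-
style ``9.9.x.y`` range, compounds ``CX####``, genes ``G####`` — no real
biology is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .enrich import EnrichmentInput
from .integrate import ReferenceModel
from .model import Compound, MetabolicNetwork, Pathway, Reaction

__all__ = [
    "FixtureManifest",
    "make_reference_models",
    "make_modular_graph",
    "make_enrichment_case",
    "make_annotation_inputs",
    "CURRENCY_FIXTURE",
]

#: currency namespace used by all fixtures (subset of compound namespace)
CURRENCY_FIXTURE = frozenset({"CXATP", "CXADP", "CXNAD", "CXNADH", "CXH2O", "CXPI"})


@dataclass
class FixtureManifest:
    seed: int
    counts: Dict[str, int] = field(default_factory=dict)
    planted: Dict[str, object] = field(default_factory=dict)


def _ec(i: int) -> str:
    return f"9.9.{i // 100 + 1}.{i % 100 + 1}"


def _cid(i: int) -> str:
    return f"CX{i:04d}"


def make_reference_models(
    seed: int,
    n_pathways: int = 5,
    rxns_per_pathway: int = 4,
    overlap_fraction: float = 0.4,
    currency_rate: float = 0.5,
) -> Tuple[ReferenceModel, ReferenceModel, FixtureManifest]:
    """Two reference models sharing a planted duplicate reaction set.

    Model A holds ``n_pathways × rxns_per_pathway`` reactions organised in
    pathways; model B duplicates a fraction ``overlap_fraction`` of A's
    reactions (same enzymes and major compounds — currency garnish and
    direction may differ) and fills the rest with fresh reactions from the
    same compound namespace.  Currency compounds are attached at
    ``currency_rate`` per reaction.  The manifest records the duplicate
    pairs and expected merged counts.
    """
    rng = np.random.default_rng(seed)
    currency = sorted(CURRENCY_FIXTURE)

    n_rxns = n_pathways * rxns_per_pathway
    compounds = [_cid(i) for i in range(4 * n_rxns + 2)]

    def new_reaction(idx: int, model_tag: str, ec_i: int) -> Reaction:
        subs = {compounds[2 * idx]}
        prods = {compounds[2 * idx + 1]}
        if rng.random() < currency_rate:
            subs = subs | {currency[int(rng.integers(len(currency)))]}
        direction = "forward" if rng.random() < 0.7 else "reversible"
        return Reaction(
            id=f"{model_tag}{idx:03d}",
            enzymes={_ec(ec_i)},
            substrates=subs,
            products=prods - subs,
            direction=direction,
            source=model_tag,
        )

    reactions_a = [new_reaction(i, "A", i) for i in range(n_rxns)]
    pathways_a = [
        Pathway(
            id=f"PWA{p}",
            name=f"pathway_{p}",
            reactions={r.id for r in reactions_a[p * rxns_per_pathway : (p + 1) * rxns_per_pathway]},
        )
        for p in range(n_pathways)
    ]

    n_dup = int(round(overlap_fraction * n_rxns))
    dup_indices = sorted(rng.choice(n_rxns, size=n_dup, replace=False).tolist())
    reactions_b: List[Reaction] = []
    dup_pairs: List[Tuple[str, str]] = []
    for j, i in enumerate(dup_indices):
        src = reactions_a[i]
        # same enzymes + major compounds; currency garnish may differ
        subs = set(c for c in src.substrates if c not in CURRENCY_FIXTURE)
        prods = set(c for c in src.products if c not in CURRENCY_FIXTURE)
        if rng.random() < currency_rate:
            subs = subs | {currency[int(rng.integers(len(currency)))]}
        rxn = Reaction(
            id=f"B{j:03d}",
            enzymes=set(src.enzymes),
            substrates=subs,
            products=prods - subs,
            direction="reversible" if rng.random() < 0.5 else src.direction,
            source="B",
        )
        reactions_b.append(rxn)
        dup_pairs.append((src.id, rxn.id))
    for j in range(n_dup, n_rxns):
        reactions_b.append(new_reaction(n_rxns + j - n_dup, "B", n_rxns + j))
    # renumber fresh B reactions after the duplicates
    for j, rxn in enumerate(reactions_b):
        rxn.id = f"B{j:03d}"
    dup_pairs = [(a, f"B{j:03d}") for j, (a, _) in enumerate(dup_pairs)]

    pathways_b = [
        Pathway(
            id=f"PWB{p}",
            name=f"pathway_{p}",
            reactions={r.id for r in reactions_b[p * rxns_per_pathway : (p + 1) * rxns_per_pathway]},
        )
        for p in range(n_pathways)
    ]
    for model_rxns, model_pws in ((reactions_a, pathways_a), (reactions_b, pathways_b)):
        for pw in model_pws:
            for rid in pw.reactions:
                next(r for r in model_rxns if r.id == rid).pathways.add(pw.id)

    model_a = ReferenceModel(name="refA", reactions=reactions_a, pathways=pathways_a)
    model_b = ReferenceModel(name="refB", reactions=reactions_b, pathways=pathways_b)
    manifest = FixtureManifest(
        seed=seed,
        counts={
            "reactions_a": len(reactions_a),
            "reactions_b": len(reactions_b),
            "duplicates": n_dup,
            "merged_expected": len(reactions_a) + len(reactions_b) - n_dup,
            "pathways_a": n_pathways,
            "pathways_b": n_pathways,
        },
        planted={"duplicate_pairs": dup_pairs},
    )
    return model_a, model_b, manifest


def make_modular_graph(
    seed: int,
    k_modules: int = 4,
    nodes_per_module: int = 12,
    p_in: float = 0.8,
    p_out: float = 0.02,
) -> Tuple[nx.Graph, Dict[str, int]]:
    """Planted-partition graph over synthetic reaction ids with truth labels."""
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    nodes = [f"R{m}_{i:02d}" for m in range(k_modules) for i in range(nodes_per_module)]
    truth = {n: int(n[1 : n.index("_")]) for n in nodes}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            p = p_in if truth[u] == truth[v] else p_out
            if rng.random() < p:
                g.add_edge(u, v)
    return g, truth


def make_enrichment_case(
    seed: int,
    n_pathways: int = 20,
    planted: Sequence[Tuple[str, float]] = (),
    base_rate: float = 0.05,
    ecs_per_pathway: int = 8,
    genes_per_ec: int = 2,
) -> Tuple[EnrichmentInput, MetabolicNetwork, FixtureManifest]:
    """An enrichment input with pathways selected at planted vs base rates.

    Each pathway owns ``ecs_per_pathway`` private enzymes, each carried by
    ``genes_per_ec`` genes; every gene of a pathway is selected
    independently at the pathway's planted rate (or the base rate).  The
    returned network holds one single-reaction pathway per enzyme group so
    that enrichment runs against realistic pathway EC sets.
    """
    rng = np.random.default_rng(seed)
    planted_map = dict(planted)
    gene_to_ec: Dict[str, Set[str]] = {}
    universe: Set[str] = set()
    selected: Set[str] = set()
    net = MetabolicNetwork(currency_list=CURRENCY_FIXTURE)

    gene_i = 0
    ec_i = 0
    comp_i = 0
    for p in range(n_pathways):
        pname = f"pathway_{p:02d}"
        rate = planted_map.get(pname, base_rate)
        rxn_ids: Set[str] = set()
        for _ in range(ecs_per_pathway):
            ec = _ec(ec_i)
            ec_i += 1
            rid = f"R{ec_i:04d}"
            rxn_ids.add(rid)
            net.add_reaction(
                Reaction(
                    id=rid,
                    enzymes={ec},
                    substrates={_cid(comp_i)},
                    products={_cid(comp_i + 1)},
                    direction="forward",
                    source="sim",
                    pathways={pname},
                )
            )
            comp_i += 2
            for _ in range(genes_per_ec):
                gene = f"G{gene_i:04d}"
                gene_i += 1
                gene_to_ec[gene] = {ec}
                universe.add(gene)
                net.enzymes[ec].genes.setdefault("sim", set()).add(gene)
                if rng.random() < rate:
                    selected.add(gene)
        net.add_pathway(Pathway(id=pname, name=pname, reactions=rxn_ids))

    inp = EnrichmentInput(
        selected_genes=selected, universe_genes=universe, gene_to_ec=gene_to_ec
    )
    manifest = FixtureManifest(
        seed=seed,
        counts={
            "pathways": n_pathways,
            "genes": len(universe),
            "selected": len(selected),
        },
        planted={"pathways": sorted(planted_map), "rates": planted_map,
                 "base_rate": base_rate},
    )
    return inp, net, manifest


def make_annotation_inputs(
    seed: int,
    n_genes: int = 30,
    n_metabolic: int = 18,
) -> Dict[str, object]:
    """Coherent annotation-stage inputs with known truth.

    Produces query genes, two subject databases of homology hits (only the
    first ``n_metabolic`` genes get retained-quality hits), a small
    metabolism-rooted ontology, subject GO annotations, an ortholog map and
    consensus gene→EC table.  Returned as a dict with a ``truth`` entry
    naming the genes that should survive the metabolic-gene gate.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    subjects = [f"S{i:04d}" for i in range(n_genes)]

    # ontology: root -> biological_process -> metabolism -> {met_a, met_b}
    terms = {
        "T:0001": "root",
        "T:0002": "biological_process",
        "T:0008": "metabolism",
        "T:0010": "metabolism_a",
        "T:0011": "metabolism_b",
        "T:0020": "transport",
    }
    parents = {
        "T:0002": {"T:0001"},
        "T:0008": {"T:0002"},
        "T:0010": {"T:0008"},
        "T:0011": {"T:0008"},
        "T:0020": {"T:0002"},
    }

    hits_db1 = []
    hits_db2 = []
    subject_go: Dict[str, Set[str]] = {}
    ortholog_map: Dict[str, str] = {}
    consensus_ec: Dict[str, Set[str]] = {}
    human_ec: Dict[str, Set[str]] = {}
    metabolic_truth: List[str] = []

    for i, (g, s) in enumerate(zip(genes, subjects)):
        metabolic = i < n_metabolic
        go = "T:0010" if i % 2 == 0 else "T:0011"
        subject_go[s] = {go if metabolic else "T:0020"}
        good = metabolic or i % 3 == 0  # some non-metabolic genes also hit
        evalue = 10 ** float(rng.uniform(-30, -6)) if good else 10 ** float(rng.uniform(-4, -1))
        identical = int(rng.integers(40, 120)) if good else int(rng.integers(5, 30))
        hit = dict(query=g, subject=s, evalue=evalue,
                   identical_bases=identical, alignment_length=150)
        (hits_db1 if i % 2 == 0 else hits_db2).append(hit)
        if metabolic:
            metabolic_truth.append(g)
            if i % 2 == 0:
                ortholog_map[g] = f"H{i:04d}"
                human_ec[f"H{i:04d}"] = {_ec(i)}
            else:
                consensus_ec[g] = {_ec(i)}

    return {
        "genes": genes,
        "hits_db1": hits_db1,
        "hits_db2": hits_db2,
        "subject_go": subject_go,
        "ontology_terms": terms,
        "ontology_parents": parents,
        "metabolism_root": "T:0008",
        "ortholog_map": ortholog_map,
        "consensus_ec": consensus_ec,
        "human_ec": human_ec,
        "truth": {"metabolic_genes": metabolic_truth},
    }
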