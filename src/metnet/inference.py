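"""Ab initio reaction inference from enzyme-compound associations.

Enzymes identified in a genome but absent from every reference reaction model
can still be placed in the network: their known compound associations (e.g.
from a ligand database) are turned into reactions of unknown direction, and
reactions are linked whenever one can produce a metabolite the other consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .model import Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeCompoundAssociation",
    "InferenceReport",
    "infer_reactions",
    "link_reactions",
]


@dataclass
class EnzymeCompoundAssociation:
    """Compounds known to interact with an enzyme, with roles when available."""

    ec: str
    substrates: Set[str] = field(default_factory=set)
    products: Set[str] = field(default_factory=set)
    undirected_compounds: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.substrates or self.products or self.undirected_compounds):
            raise ValueError(f"association for {self.ec}: all compound sets empty")


@dataclass
class InferenceReport:
    n_unmatched: int
    n_inferred: int
    ecs_without_association: List[str]


def infer_reactions(
    unmatched_ecs: Set[str],
    associations: Sequence[EnzymeCompoundAssociation],
    id_prefix: str = "INF",
) -> Tuple[List[Reaction], InferenceReport]:
    """Build one inferred reaction per unmatched enzyme with associations.

    The reaction direction is ``unknown``; when the association distinguishes
    substrates from products the roles are kept (they aid drawing), while
    role-less participants are stored on the substrate side, the sides being
    non-informative under unknown direction.  Enzymes with no association
    produce nothing and are listed in the report.
    """
    by_ec: Dict[str, List[EnzymeCompoundAssociation]] = {}
    for assoc in associations:
        by_ec.setdefault(assoc.ec, []).append(assoc)

    reactions: List[Reaction] = []
    missing: List[str] = []
    counter = 0
    for ec in sorted(unmatched_ecs):
        assocs = by_ec.get(ec)
        if not assocs:
            missing.append(ec)
            continue
        substrates: Set[str] = set()
        products: Set[str] = set()
        for assoc in assocs:
            substrates |= assoc.substrates | assoc.undirected_compounds
            products |= assoc.products
        products -= substrates
        if not substrates and not products:
            logger.warning("infer_reactions: EC %s association has no compounds; skipped", ec)
            missing.append(ec)
            continue
        counter += 1
        reactions.append(
            Reaction(
                id=f"{id_prefix}{counter:04d}",
                enzymes={ec},
                substrates=substrates,
                products=products,
                direction="unknown",
                source="inferred",
            )
        )
    report = InferenceReport(
        n_unmatched=len(unmatched_ecs),
        n_inferred=len(reactions),
        ecs_without_association=missing,
    )
    return reactions, report


def _flows(reaction: Reaction) -> Tuple[Set[str], Set[str]]:
    """(consumable, producible) compound sets given the reaction direction."""
    if reaction.direction == "forward":
        return set(reaction.substrates), set(reaction.products)
    # reversible or unknown: every participant can play either role
    return reaction.compounds, reaction.compounds


def link_reactions(
    reactions: Sequence[Reaction], currency_list: Iterable[str]
) -> nx.Graph:
    """Adjacency among reactions through shared non-currency metabolites.

    Two reactions are linked when one can produce a non-currency compound
    the other consumes; for reversible or unknown-direction reactions any
    shared non-currency compound suffices.  Currency metabolites never
    create links.  The result is a simple undirected graph over reaction
    ids (no self-edges), invariant under input permutation.
    """
    currency = set(currency_list)
    g = nx.Graph()
    rxns = sorted(reactions, key=lambda r: r.id)
    for r in rxns:
        g.add_node(r.id)
    for i, r1 in enumerate(rxns):
        in1, out1 = _flows(r1)
        for r2 in rxns[i + 1 :]:
            in2, out2 = _flows(r2)
            shared = ((out1 & in2) | (out2 & in1)) - currency
            if shared:
                g.add_edge(r1.id, r2.id, compounds=sorted(shared))
    return g
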