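"""Core domain types for bipartite enzyme-compound metabolic networks.

The central artifact is :class:`MetabolicNetwork`: a collection of compounds,
enzymes (EC numbers), reactions and pathways from which a bipartite graph is
derived.  Enzymes and compounds are the two node types; an edge records that a
compound participates in a reaction catalysed by an enzyme.  Ubiquitous
cofactors ("currency metabolites" such as ATP, NAD+, H2O) create an excessive
number of uninformative edges, so most connectivity computations omit them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "Enzyme",
    "Reaction",
    "Pathway",
    "MetabolicNetwork",
    "NetworkStats",
    "StructuralIntegrityError",
    "DEFAULT_CURRENCY",
    "is_valid_ec",
    "is_partial_ec",
    "build_bipartite_graph",
    "derive_currency_list",
    "network_stats",
]

#: Packaged default currency-metabolite list.  Holds both the common display
#: names and the corresponding KEGG compound identifiers so that models keyed
#: either way are covered.  Overridable via configuration / file.
DEFAULT_CURRENCY: frozenset = frozenset(
    {
        "ATP", "ADP", "AMP", "NAD+", "NADH", "NADP+", "NADPH", "H2O", "H+",
        "CO2", "O2", "Phosphate", "Diphosphate", "CoA",
        # KEGG ids for the same compounds
        "C00002", "C00008", "C00020", "C00003", "C00004", "C00006", "C00005",
        "C00001", "C00080", "C00011", "C00007", "C00009", "C00013", "C00010",
    }
)

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

DIRECTIONS = ("forward", "reversible", "unknown")


def is_valid_ec(ec: str) -> bool:
    """True for a four-component EC string, complete or partial (``1.1.1.-``)."""
    return bool(_EC_RE.match(ec))


def is_partial_ec(ec: str) -> bool:
    """True when any of the four EC components is the placeholder ``-``."""
    return is_valid_ec(ec) and "-" in ec


class StructuralIntegrityError(ValueError):
    """A reaction references a compound or enzyme absent from the model."""


@dataclass
class Compound:
    id: str
    name: str = ""
    is_currency: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be nonempty")
        if not self.name:
            self.name = self.id


@dataclass
class Enzyme:
    """A catalytic activity identified by EC number.

    ``genes`` maps a species tag to the set of gene identifiers carrying this
    activity in that species.  Isozymes are not distinguished: all genes with
    the same EC number collapse onto one enzyme node.
    """

    ec: str
    name: str = ""
    genes: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not is_valid_ec(self.ec):
            raise ValueError(f"malformed EC number: {self.ec!r}")
        if not self.name:
            self.name = self.ec

    @property
    def is_partial(self) -> bool:
        return is_partial_ec(self.ec)


@dataclass
class Reaction:
    """One enzymatic (or spontaneous) transformation.

    ``source`` records provenance: a reference-model name, or ``"inferred"``
    for ab initio reactions built from enzyme-compound associations.  Inferred
    reactions carry ``direction="unknown"`` because substrate/product roles
    cannot in general be established for them.
    """

    id: str
    enzymes: Set[str] = field(default_factory=set)
    substrates: Set[str] = field(default_factory=set)
    products: Set[str] = field(default_factory=set)
    direction: str = "forward"
    source: str = ""
    pathways: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.enzymes = set(self.enzymes)
        self.substrates = set(self.substrates)
        self.products = set(self.products)
        self.pathways = set(self.pathways)
        if not self.substrates and not self.products:
            raise ValueError(f"reaction {self.id}: substrates ∪ products is empty")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"reaction {self.id}: bad direction {self.direction!r}")
        overlap = self.substrates & self.products
        if overlap:
            # canonicalize: a compound cannot be on both sides
            raise ValueError(
                f"reaction {self.id}: compounds on both sides: {sorted(overlap)}"
            )
        for ec in self.enzymes:
            if not is_valid_ec(ec):
                raise ValueError(f"reaction {self.id}: malformed EC {ec!r}")

    @property
    def compounds(self) -> Set[str]:
        return self.substrates | self.products

    def major_compounds(self, currency: Iterable[str]) -> Set[str]:
        """Participants that are not currency metabolites."""
        return self.compounds - set(currency)


@dataclass
class Pathway:
    id: str
    name: str = ""
    reactions: Set[str] = field(default_factory=set)
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reactions = set(self.reactions)
        if not self.name:
            self.name = self.id
        if not self.provenance:
            self.provenance = [self.name]


@dataclass
class NetworkStats:
    n_enzymes: int
    n_reactions: int
    n_pathways: int
    n_compounds: int

    def as_tuple(self):
        return (self.n_enzymes, self.n_reactions, self.n_pathways, self.n_compounds)


class MetabolicNetwork:
    """Bipartite enzyme-compound network induced by a reaction set."""

    def __init__(
        self,
        compounds: Iterable[Compound] = (),
        enzymes: Iterable[Enzyme] = (),
        reactions: Iterable[Reaction] = (),
        pathways: Iterable[Pathway] = (),
        currency_list: Optional[Iterable[str]] = None,
    ) -> None:
        self.compounds: Dict[str, Compound] = {}
        self.enzymes: Dict[str, Enzyme] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.pathways: Dict[str, Pathway] = {}
        self.currency_list: Set[str] = (
            set(currency_list) if currency_list is not None else set(DEFAULT_CURRENCY)
        )
        for c in compounds:
            self.add_compound(c)
        for e in enzymes:
            self.add_enzyme(e)
        for r in reactions:
            self.add_reaction(r)
        for p in pathways:
            self.add_pathway(p)

    # -- construction -------------------------------------------------

    def add_compound(self, compound: Compound) -> Compound:
        existing = self.compounds.get(compound.id)
        if existing is not None:
            return existing
        compound.is_currency = compound.id in self.currency_list
        self.compounds[compound.id] = compound
        return compound

    def add_enzyme(self, enzyme: Enzyme) -> Enzyme:
        existing = self.enzymes.get(enzyme.ec)
        if existing is not None:
            for sp, genes in enzyme.genes.items():
                existing.genes.setdefault(sp, set()).update(genes)
            return existing
        self.enzymes[enzyme.ec] = enzyme
        return enzyme

    def add_reaction(self, reaction: Reaction, register: bool = True) -> Reaction:
        """Add a reaction; with ``register`` auto-create referenced nodes."""
        if register:
            for cid in sorted(reaction.compounds):
                if cid not in self.compounds:
                    self.add_compound(Compound(cid))
            for ec in sorted(reaction.enzymes):
                if ec not in self.enzymes:
                    self.add_enzyme(Enzyme(ec))
        self.reactions[reaction.id] = reaction
        return reaction

    def add_pathway(self, pathway: Pathway) -> Pathway:
        self.pathways[pathway.id] = pathway
        return pathway

    # -- integrity -----------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`StructuralIntegrityError` on dangling references."""
        for rxn in self.reactions.values():
            missing = rxn.compounds - self.compounds.keys()
            if missing:
                raise StructuralIntegrityError(
                    f"reaction {rxn.id} references unknown compounds: {sorted(missing)}"
                )
            missing_ec = rxn.enzymes - self.enzymes.keys()
            if missing_ec:
                raise StructuralIntegrityError(
                    f"reaction {rxn.id} references unknown enzymes: {sorted(missing_ec)}"
                )
        for pw in self.pathways.values():
            missing_r = pw.reactions - self.reactions.keys()
            if missing_r:
                raise StructuralIntegrityError(
                    f"pathway {pw.id} references unknown reactions: {sorted(missing_r)}"
                )

    # -- derived sets --------------------------------------------------

    def ec_set(self, include_partial: bool = False) -> Set[str]:
        """All EC numbers used by reactions (partials excluded by default)."""
        ecs: Set[str] = set()
        for rxn in self.reactions.values():
            ecs.update(rxn.enzymes)
        if not include_partial:
            ecs = {ec for ec in ecs if not is_partial_ec(ec)}
        return ecs

    def pathway_ec_set(self, pathway_id: str, include_partial: bool = False) -> Set[str]:
        pw = self.pathways[pathway_id]
        ecs: Set[str] = set()
        for rid in pw.reactions:
            ecs.update(self.reactions[rid].enzymes)
        if not include_partial:
            ecs = {ec for ec in ecs if not is_partial_ec(ec)}
        return ecs

    def pathway_compound_set(self, pathway_id: str, omit_currency: bool = True) -> Set[str]:
        pw = self.pathways[pathway_id]
        comps: Set[str] = set()
        for rid in pw.reactions:
            comps.update(self.reactions[rid].compounds)
        if omit_currency:
            comps -= self.currency_list
        return comps


def _edge_roles(reaction: Reaction):
    """(compound id, role) pairs for one reaction's enzyme-compound edges."""
    if reaction.direction == "unknown":
        for cid in reaction.compounds:
            yield cid, "unknown"
    else:
        for cid in reaction.substrates:
            yield cid, "substrate"
        for cid in reaction.products:
            yield cid, "product"


def build_bipartite_graph(network: MetabolicNetwork, omit_currency: bool = False) -> nx.Graph:
    """Project a network onto its bipartite enzyme-compound graph.

    Nodes carry ``kind`` ("enzyme" or "compound", also exposed through the
    conventional ``bipartite`` 0/1 attribute); each (EC, compound) incidence
    across all reactions yields one edge whose ``roles`` attribute collects
    the participation roles (substrate/product/unknown) observed for the
    pair and whose ``reactions`` attribute lists the supporting reactions.
    With ``omit_currency`` the currency compounds and their edges are absent.
    """
    network.validate()
    g = nx.Graph()
    currency = network.currency_list if omit_currency else set()
    for ec in sorted(network.enzymes):
        g.add_node(ec, kind="enzyme", bipartite=0)
    for cid in sorted(network.compounds):
        if cid in currency:
            continue
        g.add_node(cid, kind="compound", bipartite=1)
    for rid in sorted(network.reactions):
        rxn = network.reactions[rid]
        for cid, role in _edge_roles(rxn):
            if cid in currency:
                continue
            for ec in rxn.enzymes:
                if g.has_edge(ec, cid):
                    g.edges[ec, cid]["roles"].add(role)
                    g.edges[ec, cid]["reactions"].append(rid)
                else:
                    g.add_edge(ec, cid, roles={role}, reactions=[rid])
    return g


def derive_currency_list(network: MetabolicNetwork, k: int) -> Set[str]:
    """The ``k`` most connected compounds of the full bipartite graph.

    Ties are broken by lexicographic compound id.  Asking for more compounds
    than exist returns them all with a logged warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    g = build_bipartite_graph(network, omit_currency=False)
    degrees = sorted(
        ((cid, g.degree(cid)) for cid in network.compounds if g.has_node(cid)),
        key=lambda item: (-item[1], item[0]),
    )
    if k > len(degrees):
        logger.warning(
            "derive_currency_list: k=%d exceeds compound count %d; returning all",
            k,
            len(degrees),
        )
        k = len(degrees)
    return {cid for cid, _ in degrees[:k]}


def network_stats(network: MetabolicNetwork) -> NetworkStats:
    """Counts of unique enzymes, reactions, pathways and compounds."""
    return NetworkStats(
        n_enzymes=len(network.enzymes),
        n_reactions=len(network.reactions),
        n_pathways=len(network.pathways),
        n_compounds=len(network.compounds),
    )
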