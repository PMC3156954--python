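"""Readers and writers for all interchange formats.

Tabular formats are plain TSV with ``#`` comment lines; writers are
deterministic (reactions sorted by id, pathways by name) so that files
round-trip byte-identically.  The SBML subset (Level 2, single default
compartment, EC numbers and provenance carried in reaction notes) is read
and written through libsbml.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import libsbml
import obonet
import yaml

from .annotation import HomologyHit, OntologyGraph
from .inference import EnzymeCompoundAssociation
from .integrate import ReferenceModel
from .model import Compound, MetabolicNetwork, Pathway, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "read_reaction_tsv",
    "write_reaction_tsv",
    "read_sbml",
    "write_sbml",
    "read_hits",
    "read_gene_list",
    "write_gene_list",
    "read_obo",
    "read_two_column_map",
    "read_gene_go",
    "read_gene_ec",
    "read_associations",
    "write_gmt",
    "read_config",
    "model_to_network",
    "network_to_model",
]

PathLike = Union[str, Path]

_REACTION_COLUMNS = [
    "reaction_id", "source", "ec_list", "substrates", "products",
    "direction", "pathway_list",
]


class FormatError(ValueError):
    """Malformed input file; message carries the line number."""


def _data_lines(path: PathLike):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _split_set(cell: str) -> Set[str]:
    return {tok for tok in cell.split(";") if tok}


def _join_set(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


# -- reaction TSV ----------------------------------------------------------

def read_reaction_tsv(path: PathLike, name: Optional[str] = None) -> ReferenceModel:
    """Read the 7-column reaction table into a reference model.

    Pathway records are derived from the reactions' pathway memberships.
    """
    reactions: List[Reaction] = []
    pathways: Dict[str, Set[str]] = {}
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) != len(_REACTION_COLUMNS):
            raise FormatError(
                f"{path}:{lineno}: expected {len(_REACTION_COLUMNS)} columns, got {len(cells)}"
            )
        rid, source, ecs, subs, prods, direction, pws = cells
        try:
            rxn = Reaction(
                id=rid,
                source=source,
                enzymes=_split_set(ecs),
                substrates=_split_set(subs),
                products=_split_set(prods),
                direction=direction,
                pathways=_split_set(pws),
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        reactions.append(rxn)
        for pw in rxn.pathways:
            pathways.setdefault(pw, set()).add(rid)
    return ReferenceModel(
        name=name or Path(path).stem,
        reactions=reactions,
        pathways=[
            Pathway(id=pid, name=pid, reactions=rids)
            for pid, rids in sorted(pathways.items())
        ],
    )


def write_reaction_tsv(model: ReferenceModel, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_REACTION_COLUMNS) + "\n")
        for rxn in sorted(model.reactions, key=lambda r: r.id):
            fh.write(
                "\t".join(
                    [
                        rxn.id,
                        rxn.source,
                        _join_set(rxn.enzymes),
                        _join_set(rxn.substrates),
                        _join_set(rxn.products),
                        rxn.direction,
                        _join_set(rxn.pathways),
                    ]
                )
                + "\n"
            )


# -- SBML subset -----------------------------------------------------------

_SBML_LEVEL, _SBML_VERSION = 2, 4


def _notes_body(rxn: Reaction) -> str:
    lines = [
        f"<p>EC: {_join_set(rxn.enzymes)}</p>",
        f"<p>SOURCE: {rxn.source}</p>",
        f"<p>DIRECTION: {rxn.direction}</p>",
        f"<p>PATHWAYS: {_join_set(rxn.pathways)}</p>",
    ]
    body = "".join(lines)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _parse_notes(notes: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for chunk in notes.split("<p>")[1:]:
        text = chunk.split("</p>")[0].strip()
        if ":" in text:
            key, _, value = text.partition(":")
            out[key.strip()] = value.strip()
    return out


def write_sbml(model: ReferenceModel, path: PathLike) -> None:
    """Write the reference model as a single-compartment SBML L2 document."""
    document = libsbml.SBMLDocument(_SBML_LEVEL, _SBML_VERSION)
    sbml_model = document.createModel()
    sbml_model.setId(_sanitize_sid(model.name))
    sbml_model.setName(model.name)
    comp = sbml_model.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)

    species_ids: Dict[str, str] = {}
    compounds = sorted({c for r in model.reactions for c in r.compounds})
    for cid in compounds:
        sp = sbml_model.createSpecies()
        sid = _sanitize_sid(cid)
        species_ids[cid] = sid
        sp.setId(sid)
        sp.setName(cid)
        sp.setCompartment("cell")

    for rxn in sorted(model.reactions, key=lambda r: r.id):
        sr = sbml_model.createReaction()
        sr.setId(_sanitize_sid(rxn.id))
        sr.setName(rxn.id)
        sr.setReversible(rxn.direction in ("reversible", "unknown"))
        for cid in sorted(rxn.substrates):
            ref = sr.createReactant()
            ref.setSpecies(species_ids[cid])
        for cid in sorted(rxn.products):
            ref = sr.createProduct()
            ref.setSpecies(species_ids[cid])
        sr.setNotes(_notes_body(rxn))
    status = libsbml.writeSBMLToFile(document, str(path))
    if not status:
        raise IOError(f"failed to write SBML to {path}")


def read_sbml(path: PathLike, name: Optional[str] = None) -> ReferenceModel:
    """Read the SBML subset back into a reference model.

    Unsupported SBML constructs (kinetic laws, rules, events, extra
    compartments) are ignored with a logged inventory.
    """
    reader = libsbml.SBMLReader()
    document = reader.readSBML(str(path))
    if document.getNumErrors() > 0:
        for i in range(document.getNumErrors()):
            err = document.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise FormatError(
                    f"{path}:{err.getLine()}: {err.getMessage().strip()}"
                )
    sbml_model = document.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: no model element found")

    ignored = []
    if sbml_model.getNumRules():
        ignored.append(f"{sbml_model.getNumRules()} rules")
    if sbml_model.getNumEvents():
        ignored.append(f"{sbml_model.getNumEvents()} events")
    if ignored:
        logger.info("read_sbml: ignoring unsupported constructs: %s", ", ".join(ignored))

    species_names = {
        sbml_model.getSpecies(i).getId(): sbml_model.getSpecies(i).getName()
        or sbml_model.getSpecies(i).getId()
        for i in range(sbml_model.getNumSpecies())
    }
    reactions: List[Reaction] = []
    pathways: Dict[str, Set[str]] = {}
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        notes = _parse_notes(sr.getNotesString() or "")
        direction = notes.get("DIRECTION") or (
            "reversible" if sr.getReversible() else "forward"
        )
        rid = sr.getName() or sr.getId()
        rxn = Reaction(
            id=rid,
            source=notes.get("SOURCE", ""),
            enzymes=_split_set(notes.get("EC", "")),
            substrates={
                species_names[sr.getReactant(j).getSpecies()]
                for j in range(sr.getNumReactants())
            },
            products={
                species_names[sr.getProduct(j).getSpecies()]
                for j in range(sr.getNumProducts())
            },
            direction=direction,
            pathways=_split_set(notes.get("PATHWAYS", "")),
        )
        reactions.append(rxn)
        for pw in rxn.pathways:
            pathways.setdefault(pw, set()).add(rxn.id)
    return ReferenceModel(
        name=name or sbml_model.getName() or sbml_model.getId(),
        reactions=reactions,
        pathways=[
            Pathway(id=pid, name=pid, reactions=rids)
            for pid, rids in sorted(pathways.items())
        ],
    )


def _sanitize_sid(raw: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x_" + out
    return out


# -- homology hits ---------------------------------------------------------

def read_hits(path: PathLike) -> List[HomologyHit]:
    """Read 12-column tabular local-alignment hits.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  ``identical_bases`` is derived as
    ``floor(pident × length / 100 + 0.5)``.
    """
    hits: List[HomologyHit] = []
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) != 12:
            raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cells)}")
        try:
            pident = float(cells[2])
            length = int(cells[3])
            evalue = float(cells[10])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        identical = int(math.floor(pident * length / 100.0 + 0.5))
        try:
            hits.append(
                HomologyHit(
                    query=cells[0],
                    subject=cells[1],
                    evalue=evalue,
                    identical_bases=identical,
                    alignment_length=length,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


# -- simple lists and maps -------------------------------------------------

def read_gene_list(path: PathLike) -> Set[str]:
    """One gene id per line; ``#`` comments and blank lines skipped."""
    return {line.strip() for _, line in _data_lines(path)}


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_two_column_map(path: PathLike) -> Dict[str, str]:
    """Strict 2-column TSV into a one-to-one mapping (last value wins)."""
    out: Dict[str, str] = {}
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
        out[cells[0]] = cells[1]
    return out


def _read_multimap(path: PathLike) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
        out.setdefault(cells[0], set()).add(cells[1])
    return out


def read_gene_go(path: PathLike) -> Dict[str, Set[str]]:
    """2-column gene → GO term TSV (one pair per line)."""
    return _read_multimap(path)


def read_gene_ec(path: PathLike) -> Dict[str, Set[str]]:
    """2-column gene → EC TSV (one pair per line)."""
    return _read_multimap(path)


# -- ontology --------------------------------------------------------------

def read_obo(path: PathLike, metabolism_root: str) -> OntologyGraph:
    """Read an OBO-subset ontology (id/name/is_a stanzas) via obonet."""
    graph = obonet.read_obo(str(path))
    terms = set(graph.nodes)
    parents: Dict[str, Set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return OntologyGraph(terms=terms, parents=parents, metabolism_root=metabolism_root)


# -- enzyme-compound associations -----------------------------------------

def read_associations(path: PathLike) -> List[EnzymeCompoundAssociation]:
    """3-column TSV (ec, role, compound_id), grouped into one association
    per enzyme; role is one of substrate/product/unknown."""
    grouped: Dict[str, Dict[str, Set[str]]] = {}
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
        ec, role, cid = cells
        if role not in ("substrate", "product", "unknown"):
            raise FormatError(f"{path}:{lineno}: bad role {role!r}")
        grouped.setdefault(ec, {"substrate": set(), "product": set(), "unknown": set()})[
            role
        ].add(cid)
    return [
        EnzymeCompoundAssociation(
            ec=ec,
            substrates=roles["substrate"],
            products=roles["product"],
            undirected_compounds=roles["unknown"],
        )
        for ec, roles in sorted(grouped.items())
    ]


# -- GMT -------------------------------------------------------------------

def write_gmt(lines: Sequence[str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


# -- configuration ---------------------------------------------------------

def read_config(path: PathLike) -> Dict:
    """YAML key-value configuration (currency list path, thresholds, seeds)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data


# -- model/network conversion ---------------------------------------------

def model_to_network(
    model: ReferenceModel, currency_list: Optional[Iterable[str]] = None
) -> MetabolicNetwork:
    """Promote a reference model to a full bipartite network container."""
    net = MetabolicNetwork(currency_list=currency_list)
    for rxn in model.reactions:
        net.add_reaction(rxn)
    for pw in model.pathways:
        net.add_pathway(pw)
    return net


def network_to_model(network: MetabolicNetwork, name: str = "network") -> ReferenceModel:
    return ReferenceModel(
        name=name,
        reactions=sorted(network.reactions.values(), key=lambda r: r.id),
        pathways=sorted(network.pathways.values(), key=lambda p: p.name),
    )
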