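"""Integration of reference reaction models.

Several curated models (two human networks plus a species model) are merged
into one reference reaction set.  Two reactions are considered identical when
they have the same enzymes and the same major (non-currency) compounds —
direction is ignored for identity.  Pathways are reconciled afterwards: two
pathways sharing a significant fraction of reactions are merged, the larger
partner lending its name.  The merged reference is finally restricted to the
enzyme complement of a target species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .model import DEFAULT_CURRENCY, Pathway, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceModel",
    "MergeReport",
    "reactions_equal",
    "reaction_identity_key",
    "merge_models",
    "merge_pathways",
    "restrict_to_enzymes",
]


@dataclass
class ReferenceModel:
    name: str
    reactions: List[Reaction] = field(default_factory=list)
    pathways: List[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"model {self.name}: duplicate reaction ids {dup}")

    def reaction_index(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}


def reaction_identity_key(
    reaction: Reaction, currency_list: Iterable[str]
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Hashable identity: (enzyme set, major-compound set)."""
    currency = set(currency_list)
    return (
        frozenset(reaction.enzymes),
        frozenset(reaction.compounds - currency),
    )


def reactions_equal(
    r1: Reaction, r2: Reaction, currency_list: Iterable[str] = DEFAULT_CURRENCY
) -> bool:
    """True when two reactions have the same enzymes and major compounds.

    Currency metabolites and direction are ignored, so a variant listing an
    extra ATP/ADP pair still matches.  This relation is an equivalence
    (reflexive, symmetric, transitive) for a fixed currency list.
    """
    currency = set(currency_list)
    return reaction_identity_key(r1, currency) == reaction_identity_key(r2, currency)


@dataclass
class MergeReport:
    per_source_counts: Dict[str, int]
    duplicate_count: int
    merged_count: int
    direction_conflicts: List[str] = field(default_factory=list)


def _oriented_direction(rxn: Reaction, canon: Reaction, currency: Set[str]) -> str:
    """Direction of ``rxn`` expressed in the canonical record's orientation."""
    if rxn.direction != "forward":
        return rxn.direction
    if rxn.substrates - currency == canon.substrates - currency:
        return "forward"
    if rxn.substrates - currency == canon.products - currency:
        return "backward"
    return "forward"


def _merge_directions(directions: Sequence[str]) -> Tuple[str, bool]:
    known = set(directions) - {"unknown"}
    if not known:
        return "unknown", False
    if known == {"forward"}:
        return "forward", False
    if known == {"backward"}:
        return "forward", False  # all agree, just mirrored against the canon
    if "forward" in known and "backward" in known:
        return "reversible", True  # duplicates run in opposite directions
    return "reversible", False


def merge_models(
    models: Sequence[ReferenceModel],
    currency_list: Iterable[str] = DEFAULT_CURRENCY,
) -> Tuple[ReferenceModel, MergeReport]:
    """Merge reference models, collapsing duplicate reactions.

    Duplicates (same enzymes + major compounds) collapse to a single record
    whose provenance lists every contributing source and whose pathway
    memberships are the union over duplicates.  The canonical id is the
    first-seen reaction id.  Conflicting directions among duplicates resolve
    to ``reversible`` and are logged.  Pathways from all models are carried
    over, re-keyed to canonical reaction ids.
    """
    if not models:
        raise ValueError("merge_models requires at least one model")
    currency = set(currency_list)

    canonical: Dict[Tuple[FrozenSet[str], FrozenSet[str]], Reaction] = {}
    members: Dict[Tuple[FrozenSet[str], FrozenSet[str]], List[Reaction]] = {}
    id_map: Dict[Tuple[str, str], str] = {}  # (model name, reaction id) -> canonical id
    per_source = {m.name: len(m.reactions) for m in models}
    duplicates = 0

    for model in models:
        for rxn in model.reactions:
            key = reaction_identity_key(rxn, currency)
            if key in canonical:
                duplicates += 1
            else:
                canonical[key] = Reaction(
                    id=rxn.id,
                    enzymes=set(rxn.enzymes),
                    substrates=set(rxn.substrates),
                    products=set(rxn.products),
                    direction=rxn.direction,
                    source=rxn.source or model.name,
                    pathways=set(rxn.pathways),
                )
                members[key] = []
            members[key].append(rxn)
            id_map[(model.name, rxn.id)] = canonical[key].id

    conflicts: List[str] = []
    merged_reactions: List[Reaction] = []
    for key, canon in canonical.items():
        group = members[key]
        sources = []
        for rxn in group:
            for src in (rxn.source or "").split("+"):
                if src and src not in sources:
                    sources.append(src)
        canon.source = "+".join(sources) if sources else canon.source
        canon.pathways = set().union(*(r.pathways for r in group))
        direction, conflict = _merge_directions(
            [_oriented_direction(r, canon, currency) for r in group]
        )
        if conflict:
            conflicts.append(canon.id)
            logger.warning("merge_models: direction conflict for %s; kept reversible", canon.id)
        canon.direction = direction
        merged_reactions.append(canon)
    merged_reactions.sort(key=lambda r: r.id)

    # carry pathways over, re-keyed to canonical reaction ids
    merged_pathways: Dict[str, Pathway] = {}
    for model in models:
        for pw in model.pathways:
            new_rids = {
                id_map[(model.name, rid)]
                for rid in pw.reactions
                if (model.name, rid) in id_map
            }
            if pw.id in merged_pathways:
                existing = merged_pathways[pw.id]
                existing.reactions |= new_rids
                for src in pw.provenance:
                    if src not in existing.provenance:
                        existing.provenance.append(src)
            else:
                merged_pathways[pw.id] = Pathway(
                    id=pw.id,
                    name=pw.name,
                    reactions=new_rids,
                    provenance=list(pw.provenance),
                )

    merged = ReferenceModel(
        name="+".join(m.name for m in models),
        reactions=merged_reactions,
        pathways=sorted(merged_pathways.values(), key=lambda p: p.name),
    )
    report = MergeReport(
        per_source_counts=per_source,
        duplicate_count=duplicates,
        merged_count=len(merged_reactions),
        direction_conflicts=conflicts,
    )
    return merged, report


def merge_pathways(
    pathways: Sequence[Pathway], min_overlap_fraction: float = 0.5
) -> Tuple[List[Pathway], Dict[str, str]]:
    """Merge pathways that share a significant number of common reactions.

    Two pathways are merge-candidates when their shared reaction count is at
    least ``min_overlap_fraction`` of the smaller pathway's reaction set; the
    merge relation is closed transitively.  Each merged pathway keeps the
    largest partner's id and name and lists every constituent name in its
    provenance.  Returns the new pathway list plus a rename map
    old id → surviving id.
    """
    if not 0 < min_overlap_fraction <= 1:
        raise ValueError("min_overlap_fraction must be in (0, 1]")
    pws = list(pathways)
    parent = {pw.id: pw.id for pw in pws}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, p in enumerate(pws):
        for q in pws[i + 1 :]:
            smaller = min(len(p.reactions), len(q.reactions))
            if smaller == 0:
                continue
            shared = len(p.reactions & q.reactions)
            if shared >= min_overlap_fraction * smaller:
                union(p.id, q.id)

    groups: Dict[str, List[Pathway]] = {}
    for pw in pws:
        groups.setdefault(find(pw.id), []).append(pw)

    merged: List[Pathway] = []
    rename: Dict[str, str] = {}
    for group in groups.values():
        # the largest partner's name wins; ties broken lexicographically
        head = sorted(group, key=lambda p: (-len(p.reactions), p.name))[0]
        reactions = set().union(*(p.reactions for p in group))
        provenance: List[str] = []
        for p in sorted(group, key=lambda p: (-len(p.reactions), p.name)):
            for src in p.provenance:
                if src not in provenance:
                    provenance.append(src)
        merged.append(
            Pathway(id=head.id, name=head.name, reactions=reactions, provenance=provenance)
        )
        for p in group:
            rename[p.id] = head.id
    merged.sort(key=lambda p: p.name)
    return merged, rename


def restrict_to_enzymes(
    reference: ReferenceModel,
    ecs: Set[str],
    currency_list: Iterable[str] = DEFAULT_CURRENCY,
) -> ReferenceModel:
    """Restrict a reference model to a species' enzyme complement.

    Keeps reactions whose enzyme set intersects ``ecs``.  Non-enzymatic
    reactions (empty EC set) are kept only when they share a non-currency
    compound with a kept reaction of the same pathway.  Pathways are
    re-derived from the surviving reactions; emptied pathways drop out.
    """
    currency = set(currency_list)
    kept: Dict[str, Reaction] = {
        r.id: r for r in reference.reactions if r.enzymes & ecs
    }
    # pathway -> major compounds covered by kept enzymatic reactions
    covered: Dict[str, Set[str]] = {}
    for rxn in kept.values():
        for pw in rxn.pathways:
            covered.setdefault(pw, set()).update(rxn.compounds - currency)
    for rxn in reference.reactions:
        if rxn.enzymes or rxn.id in kept:
            continue
        major = rxn.compounds - currency
        if any(major & covered.get(pw, set()) for pw in rxn.pathways):
            kept[rxn.id] = rxn

    pathways: List[Pathway] = []
    for pw in reference.pathways:
        surviving = pw.reactions & kept.keys()
        if surviving:
            pathways.append(
                Pathway(id=pw.id, name=pw.name, reactions=surviving,
                        provenance=list(pw.provenance))
            )
    return ReferenceModel(
        name=reference.name,
        reactions=sorted(kept.values(), key=lambda r: r.id),
        pathways=sorted(pathways, key=lambda p: p.name),
    )
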