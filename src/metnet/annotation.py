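"""Metabolic-gene identification and EC-number inference.

Genes are declared metabolic when they carry a Gene Ontology term that sits
under the metabolism subtree; EC numbers are then inferred either by carrying
them over from orthologs in a well-annotated genome, or from consensus-
sequence annotation.  Homology evidence arrives as tabular local-alignment
hits and is filtered on E-value and the absolute number of identical bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "HomologyHit",
    "OntologyGraph",
    "GeneAnnotation",
    "filter_hits",
    "cascade_filter",
    "transfer_go",
    "is_under_metabolism",
    "select_metabolic_genes",
    "infer_ec",
    "DEFAULT_MAX_EVALUE",
    "DEFAULT_MIN_IDENTICAL",
]

#: Homology acceptance thresholds: E-value strictly below 1e-5 and at least
#: 33 identical bases in the local alignment.
DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTICAL = 33


@dataclass(frozen=True)
class HomologyHit:
    """Summary of one local-alignment hit between a query and subject gene."""

    query: str
    subject: str
    evalue: float
    identical_bases: int
    alignment_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query}->{self.subject}")
        if not 0 <= self.identical_bases <= self.alignment_length:
            raise ValueError(
                f"identical_bases out of range for {self.query}->{self.subject}"
            )


class OntologyGraph:
    """A DAG of ontology terms with ``is_a`` parent links.

    ``metabolism_root`` names the subtree of interest; membership queries ask
    whether the root is reachable from a term by walking parent links.
    """

    def __init__(
        self,
        terms: Iterable[str],
        parents: Mapping[str, Set[str]],
        metabolism_root: str,
    ) -> None:
        self.terms: Set[str] = set(terms)
        self.parents: Dict[str, Set[str]] = {
            t: set(ps) for t, ps in parents.items()
        }
        if metabolism_root not in self.terms:
            raise ValueError(f"metabolism root {metabolism_root!r} not among terms")
        self.metabolism_root = metabolism_root
        self._check_acyclic()
        self._under_cache: Dict[str, bool] = {}

    def _check_acyclic(self) -> None:
        state: Dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t: str, stack: Tuple[str, ...]) -> None:
            if state.get(t) == 1:
                return
            if state.get(t) == 0:
                raise ValueError(f"ontology cycle through {t}")
            state[t] = 0
            for p in self.parents.get(t, ()):
                visit(p, stack + (t,))
            state[t] = 1

        for t in self.terms:
            visit(t, ())


@dataclass
class GeneAnnotation:
    gene: str
    species: str = ""
    go_terms: Set[str] = field(default_factory=set)
    ecs: Set[str] = field(default_factory=set)
    ec_evidence: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = self.ecs - self.ec_evidence.keys()
        if missing:
            raise ValueError(
                f"gene {self.gene}: ECs without evidence tag: {sorted(missing)}"
            )


def filter_hits(
    hits: Sequence[HomologyHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identical: int = DEFAULT_MIN_IDENTICAL,
) -> List[HomologyHit]:
    """Keep hits with E-value strictly under ``max_evalue`` and at least
    ``min_identical`` identical bases, preserving input order."""
    if max_evalue <= 0 or min_identical <= 0:
        raise ValueError("thresholds must be positive")
    return [
        h
        for h in hits
        if h.evalue < max_evalue and h.identical_bases >= min_identical
    ]


def cascade_filter(
    hit_databases: Sequence[Sequence[HomologyHit]],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identical: int = DEFAULT_MIN_IDENTICAL,
) -> List[HomologyHit]:
    """Per-query cascade over an ordered list of subject databases.

    For each query the first database yielding at least one retained hit
    wins; later databases are consulted only for queries still unmatched.
    This mirrors a two-stage search against a well-annotated sister genome
    first, then against reference sequences.
    """
    retained: List[HomologyHit] = []
    matched: Set[str] = set()
    for db_hits in hit_databases:
        kept = filter_hits(db_hits, max_evalue, min_identical)
        stage = [h for h in kept if h.query not in matched]
        retained.extend(stage)
        matched.update(h.query for h in stage)
    return retained


def transfer_go(
    hits: Sequence[HomologyHit], subject_go: Mapping[str, Set[str]]
) -> Dict[str, Set[str]]:
    """Assign each query the union of its retained subjects' GO terms.

    Queries with no retained hit are absent from the result; subjects with no
    GO annotation are skipped with a warning.
    """
    result: Dict[str, Set[str]] = {}
    for hit in hits:
        terms = subject_go.get(hit.subject)
        if terms is None:
            logger.warning("transfer_go: subject %s has no GO annotation; skipped", hit.subject)
            continue
        result.setdefault(hit.query, set()).update(terms)
    return result


def is_under_metabolism(term: str, ontology: OntologyGraph) -> bool:
    """True iff the metabolism root is reachable from ``term`` via is_a links
    (reflexively: the root itself qualifies)."""
    if term not in ontology.terms:
        raise KeyError(f"unknown ontology term: {term}")
    cache = ontology._under_cache
    root = ontology.metabolism_root

    def walk(t: str) -> bool:
        if t == root:
            return True
        if t in cache:
            return cache[t]
        cache[t] = False  # DAG: safe placeholder
        result = any(walk(p) for p in sorted(ontology.parents.get(t, ())))
        cache[t] = result
        return result

    return walk(term)


def select_metabolic_genes(
    annotations: Sequence[GeneAnnotation], ontology: OntologyGraph
) -> Tuple[List[str], List[str]]:
    """Split annotated genes into the construction set and the GO-only set.

    Returns ``(construction_genes, metabolic_go_genes)``: the first lists
    genes with a metabolism-subtree GO term AND at least one EC (only these
    enter network construction); the second lists all genes with a
    metabolism-subtree GO term, the broader "metabolic genes" tally (it
    includes e.g. transport proteins that carry a metabolism GO term but map
    to no enzyme).  Genes with an EC but no metabolic GO term are excluded
    with a warning.
    """
    go_only: List[str] = []
    selected: List[str] = []
    for ann in annotations:
        metabolic = any(
            is_under_metabolism(t, ontology) for t in ann.go_terms if t in ontology.terms
        )
        if metabolic:
            go_only.append(ann.gene)
            if ann.ecs:
                selected.append(ann.gene)
        elif ann.ecs:
            logger.warning(
                "gene %s has EC assignment but no metabolism GO term; excluded",
                ann.gene,
            )
    return selected, go_only


def infer_ec(
    gene: str,
    ortholog_map: Mapping[str, str],
    human_ec: Mapping[str, Set[str]],
    consensus_ec: Mapping[str, Set[str]],
) -> Dict[str, str]:
    """Infer EC numbers for one gene, tagged by evidence route.

    The union of ortholog-derived ECs (via ``ortholog_map`` into the
    reference species' gene→EC table) and consensus-sequence ECs is
    returned as a mapping EC → evidence tag; when both routes yield the
    same EC the ortholog tag takes precedence.
    """
    evidence: Dict[str, str] = {}
    for ec in consensus_ec.get(gene, set()):
        evidence[ec] = "consensus"
    ortholog = ortholog_map.get(gene)
    if ortholog is not None:
        for ec in human_ec.get(ortholog, set()):
            evidence[ec] = "ortholog"
    return evidence
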