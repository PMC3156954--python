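"""Pathway-module discovery by spectral modularity maximisation.

Reactions that do not map to any curated pathway are projected onto a simple
graph (reactions as nodes, edges for shared non-currency metabolites) and
partitioned by the leading-eigenvector method: the graph is recursively
bisected along the sign pattern of the dominant eigenvector of the modularity
matrix ``B = A - k k^T / 2m``, stopping when no split increases modularity

    Q = sum_c (e_cc - a_c^2),

where ``e_cc`` is the fraction of edges inside community ``c`` and ``a_c``
the fraction of edge ends attached to ``c``.  Candidate modules are then
curated — accepted as new pathways, merged into existing ones, or rejected —
while isolated reactions are attached to pathways whose metabolites they
connect; the whole procedure iterates to a fixpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .model import Pathway, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "build_reaction_graph",
    "modularity_Q",
    "leading_eigenvector_split",
    "extract_modules",
    "attach_isolated",
    "curate_modules",
    "organize_pathways",
    "DEFAULT_MIN_MODULE_SIZE",
]

#: Modules with fewer reactions than this are dismantled to isolated
#: reactions during curation ("too few" reactions to justify a pathway).
DEFAULT_MIN_MODULE_SIZE = 3

_EIG_TOL = 1e-10
_EIG_MAX_ITER = 10_000


@dataclass
class Partition:
    """A node → community assignment with its modularity score."""

    assignment: Dict[str, int]
    Q: float
    isolated: Set[str] = field(default_factory=set)

    def communities(self) -> List[Set[str]]:
        out: Dict[int, Set[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


def build_reaction_graph(
    reactions: Sequence[Reaction], currency_list: Iterable[str]
) -> nx.Graph:
    """Simple graph over reactions; edge = shared non-currency compound."""
    currency = set(currency_list)
    g = nx.Graph()
    rxns = sorted(reactions, key=lambda r: r.id)
    for r in rxns:
        g.add_node(r.id)
    for i, r1 in enumerate(rxns):
        m1 = r1.compounds - currency
        for r2 in rxns[i + 1 :]:
            shared = m1 & (r2.compounds - currency)
            if shared:
                g.add_edge(r1.id, r2.id, compounds=sorted(shared))
    return g


def modularity_Q(graph: nx.Graph, assignment: Mapping[str, int]) -> float:
    """Newman modularity of a node partition.

    Requires an assignment covering every node and a graph with at least one
    edge (Q is undefined otherwise).
    """
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)[:5]}")
    e_cc: Dict[int, float] = {}
    a_c: Dict[int, float] = {}
    for u, v in graph.edges:
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            e_cc[cu] = e_cc.get(cu, 0.0) + 1.0 / m
        a_c[cu] = a_c.get(cu, 0.0) + 0.5 / m
        a_c[cv] = a_c.get(cv, 0.0) + 0.5 / m
    return sum(e_cc.get(c, 0.0) - a_c[c] ** 2 for c in a_c)


def _leading_eigenpair(matrix: np.ndarray) -> Tuple[float, np.ndarray]:
    """Algebraically largest eigenpair via shifted power iteration.

    The matrix is shifted by its Gershgorin bound so the target eigenvalue
    becomes dominant in magnitude; convergence tolerance 1e-10, at most
    10,000 iterations.  Raises ``ArithmeticError`` when iteration fails to
    converge (e.g. a degenerate, tied leading eigenvalue).
    """
    n = matrix.shape[0]
    shift = float(np.max(np.sum(np.abs(matrix), axis=1)))
    shifted = matrix + shift * np.eye(n)
    # deterministic, non-uniform start vector
    v = np.linspace(1.0, 2.0, n)
    v /= np.linalg.norm(v)
    eigval = 0.0
    for _ in range(_EIG_MAX_ITER):
        w = shifted @ v
        norm = np.linalg.norm(w)
        if norm < _EIG_TOL:
            return -shift, v  # v in the kernel of the shifted matrix
        w /= norm
        eigval = float(w @ (shifted @ w))
        if np.linalg.norm(w - v) < _EIG_TOL or np.linalg.norm(w + v) < _EIG_TOL:
            v = w
            break
        v = w
    else:
        raise ArithmeticError("power iteration did not converge (degenerate spectrum?)")
    # fix the sign: largest-magnitude entry positive
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    return eigval - shift, v


def _modularity_submatrix(
    graph: nx.Graph, nodes: Sequence[str], degrees: Mapping[str, int], two_m: float
) -> np.ndarray:
    """Generalised modularity matrix B^(g) for a node subset.

    ``B_ij = A_ij - k_i k_j / 2m`` restricted to the subset, with the
    diagonal corrected by the subset row sums so that bisection deltas of
    subgraphs remain contributions to the global Q.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in graph.subgraph(nodes).edges:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    k = np.array([degrees[n_] for n_ in nodes], dtype=float)
    b = a - np.outer(k, k) / two_m
    b -= np.diag(b.sum(axis=1))
    return b


def leading_eigenvector_split(
    graph: nx.Graph,
    nodes: Optional[Sequence[str]] = None,
    degrees: Optional[Mapping[str, int]] = None,
    two_m: Optional[float] = None,
) -> Optional[Tuple[Set[str], Set[str]]]:
    """Bisect a (sub)graph by the sign of the leading modularity eigenvector.

    Returns the two node sets, or ``None`` when the graph is indivisible
    (non-positive leading eigenvalue, all-same-sign eigenvector, or a split
    that does not increase modularity).  When called on a whole graph it
    must be connected with at least two nodes; the ``nodes``/``degrees``/
    ``two_m`` arguments are used internally for recursive subdivision
    against the global degree sequence.
    """
    if nodes is None:
        if graph.number_of_nodes() < 2:
            raise ValueError("need at least two nodes to split")
        if not nx.is_connected(graph):
            raise ValueError("split connected components before calling")
        nodes = sorted(graph.nodes)
        degrees = dict(graph.degree())
        two_m = 2.0 * graph.number_of_edges()
    assert degrees is not None and two_m is not None
    if two_m == 0:
        return None
    nodes = list(nodes)
    b = _modularity_submatrix(graph, nodes, degrees, two_m)
    try:
        eigval, vec = _leading_eigenpair(b)
    except ArithmeticError:
        logger.warning("degenerate leading eigenvalue; declaring indivisible")
        return None
    if eigval <= _EIG_TOL:
        return None
    s = np.where(vec >= 0.0, 1.0, -1.0)
    if np.all(s > 0) or np.all(s < 0):
        return None
    delta_q = float(s @ b @ s) / (2.0 * two_m)
    if delta_q <= _EIG_TOL:
        return None
    part1 = {n_ for n_, si in zip(nodes, s) if si > 0}
    part2 = {n_ for n_, si in zip(nodes, s) if si < 0}
    return part1, part2


def extract_modules(graph: nx.Graph) -> Partition:
    """Partition a reaction graph into modules by recursive bisection.

    Connected components are processed independently; each is split until
    every part is indivisible.  Degree-zero nodes become singleton
    communities and are flagged ``isolated``.  The final modularity Q is
    reported (0.0 for an edgeless graph, where Q is undefined).
    """
    assignment: Dict[str, int] = {}
    isolated: Set[str] = set()
    next_label = 0
    degrees = dict(graph.degree())
    two_m = 2.0 * graph.number_of_edges()

    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        comp = set(comp)
        if len(comp) == 1:
            node = next(iter(comp))
            if degrees[node] == 0:
                isolated.add(node)
            assignment[node] = next_label
            next_label += 1
            continue
        stack = [sorted(comp)]
        while stack:
            part = stack.pop()
            if len(part) < 2:
                split = None
            else:
                split = leading_eigenvector_split(graph, part, degrees, two_m)
            if split is None:
                for node in part:
                    assignment[node] = next_label
                next_label += 1
            else:
                p1, p2 = split
                stack.append(sorted(p2))
                stack.append(sorted(p1))

    # renumber communities 0..k-1 in first-seen order
    relabel: Dict[int, int] = {}
    for node in sorted(assignment):
        c = assignment[node]
        if c not in relabel:
            relabel[c] = len(relabel)
    assignment = {n_: relabel[c] for n_, c in assignment.items()}

    q = modularity_Q(graph, assignment) if graph.number_of_edges() else 0.0
    return Partition(assignment=assignment, Q=q, isolated=isolated)


def attach_isolated(
    reactions: Sequence[Reaction],
    pathways: Sequence[Pathway],
    reaction_index: Mapping[str, Reaction],
    currency_list: Iterable[str],
    min_shared: int = 2,
) -> Dict[str, List[str]]:
    """Attach isolated reactions to pathways whose metabolites they connect.

    A reaction qualifies for a pathway when at least ``min_shared`` of its
    non-currency compounds occur in the pathway's compound set (two by
    default: the reaction must *connect* metabolites of the pathway, not
    merely touch one).  With several qualifying pathways the one sharing the
    most compounds wins; ties attach to all tied pathways.  Returns a map
    reaction id → list of pathway ids (absent = remains isolated).
    """
    currency = set(currency_list)
    pw_compounds: Dict[str, Set[str]] = {}
    for pw in pathways:
        comps: Set[str] = set()
        for rid in pw.reactions:
            rxn = reaction_index.get(rid)
            if rxn is not None:
                comps.update(rxn.compounds)
        pw_compounds[pw.id] = comps - currency

    attachment: Dict[str, List[str]] = {}
    for rxn in reactions:
        major = rxn.compounds - currency
        scores = {
            pid: len(major & comps)
            for pid, comps in pw_compounds.items()
            if len(major & comps) >= min_shared
        }
        if not scores:
            continue
        best = max(scores.values())
        attachment[rxn.id] = sorted(p for p, s in scores.items() if s == best)
    return attachment


def curate_modules(
    partition: Partition,
    pathways: Sequence[Pathway],
    decisions: Optional[Mapping[int, Tuple[str, Optional[str]]]] = None,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    name_offset: int = 0,
) -> Tuple[List[Pathway], Set[str]]:
    """Apply curation decisions to candidate modules.

    ``decisions`` maps a module index to ``("accept", name)``,
    ``("merge", pathway_id)`` or ``("reject", None)``.  Modules without an
    explicit decision follow the default rule: at least ``min_size``
    reactions → a new pathway named ``module_N``; smaller → dismantled back
    to isolated reactions.  Returns the updated pathway list and the set of
    reaction ids left isolated.
    """
    decisions = dict(decisions or {})
    communities = partition.communities()
    unknown = set(decisions) - set(range(len(communities)))
    if unknown:
        raise KeyError(f"curation decision for unknown module(s): {sorted(unknown)}")

    updated = {pw.id: pw for pw in pathways}
    leftover: Set[str] = set()
    new_index = name_offset
    for idx, members in enumerate(communities):
        action, target = decisions.get(idx, (None, None))
        if action is None:
            action = "accept" if len(members) >= min_size else "reject"
        if action == "accept":
            new_index += 1
            name = target or f"module_{new_index}"
            updated[name] = Pathway(id=name, name=name, reactions=set(members),
                                    provenance=[name])
        elif action == "merge":
            if target not in updated:
                raise KeyError(f"merge target pathway {target!r} not found")
            updated[target].reactions |= set(members)
        elif action == "reject":
            leftover |= set(members)
        else:
            raise ValueError(f"unknown curation action {action!r}")
    return sorted(updated.values(), key=lambda p: p.name), leftover


def organize_pathways(
    leftover_reactions: Sequence[Reaction],
    pathways: Sequence[Pathway],
    reaction_index: Mapping[str, Reaction],
    currency_list: Iterable[str],
    decisions: Optional[Mapping[int, Tuple[str, Optional[str]]]] = None,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    max_rounds: int = 20,
) -> Tuple[List[Pathway], List[Reaction]]:
    """Iterate attach → module extraction → curation to a fixpoint.

    Each round first attaches reactions to existing pathways, then extracts
    modules from the remainder and curates them with the default (or given)
    rules.  The loop stops when a round changes nothing; each productive
    round strictly shrinks the isolated-reaction pool, so termination is
    guaranteed.  Curation decisions apply to the first round only (module
    numbering is not stable across rounds).
    """
    pathways = list(pathways)
    pool = {r.id: r for r in leftover_reactions}
    index = dict(reaction_index)
    index.update(pool)
    round_no = 0
    while pool and round_no < max_rounds:
        round_no += 1
        changed = False

        attach_map = attach_isolated(
            list(pool.values()), pathways, index, currency_list
        )
        if attach_map:
            changed = True
            by_id = {pw.id: pw for pw in pathways}
            for rid, pids in attach_map.items():
                for pid in pids:
                    by_id[pid].reactions.add(rid)
                pool.pop(rid)

        if pool:
            graph = build_reaction_graph(list(pool.values()), currency_list)
            partition = extract_modules(graph)
            n_existing = sum(1 for p in pathways if p.id.startswith("module_"))
            new_pathways, leftover = curate_modules(
                partition,
                pathways,
                decisions if round_no == 1 else None,
                min_size=min_size,
                name_offset=n_existing,
            )
            accepted = {r for p in new_pathways for r in p.reactions} & pool.keys()
            if accepted:
                changed = True
            pathways = new_pathways
            pool = {rid: pool[rid] for rid in leftover if rid in pool}

        if not changed:
            break
    return pathways, sorted(pool.values(), key=lambda r: r.id)
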