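"""Automatic pathway diagram generation in the Graphviz DOT language.

Pathways render as directed bipartite diagrams: box nodes for enzymes,
ellipses for compounds, with substrate compounds pointing into the enzyme
node and products out of it.  Reactions without a known enzyme connect their
compounds through a diamond node labelled with the reaction id.  Currency
metabolites can be omitted, parallel edges with the same role merged, long
labels wrapped at word boundaries, and pathways whose edge count exceeds a
budget are split ("zoomed") into sub-diagrams along a modularity partition.

Output is deterministic text; rendering to an image is delegated to an
external ``dot`` binary when available and is never required.
"""

from __future__ import annotations

import re
import textwrap
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .model import MetabolicNetwork, Pathway, StructuralIntegrityError
from .modularity import build_reaction_graph, extract_modules

__all__ = ["RenderOptions", "pathway_to_dot", "wrap_label", "parse_dot"]

#: node fill colors keyed by regulation state (up/down/unclear)
_STATE_COLORS = {"up": "red", "down": "green", "unclear": "yellow"}


@dataclass
class RenderOptions:
    label_mode: str = "ids"  # "ids" or "names"
    omit_currency: bool = True
    wrap_width: int = 16
    zoom_edge_budget: int = 400
    merge_similar_edges: bool = True
    ec_state: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label_mode not in ("ids", "names"):
            raise ValueError("label_mode must be 'ids' or 'names'")
        if self.wrap_width < 8:
            raise ValueError("wrap_width must be >= 8")
        if self.zoom_edge_budget < 1:
            raise ValueError("zoom_edge_budget must be >= 1")


def wrap_label(text: str, width: int) -> str:
    """Wrap a label at word boundaries; a single long token is left intact."""
    if width < 8:
        raise ValueError("width must be >= 8")
    lines = textwrap.wrap(
        text, width=width, break_long_words=False, break_on_hyphens=False
    )
    return "\n".join(lines) if lines else text


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n") + '"'


def _node_stmt(node_id: str, label: str, shape: str, color: Optional[str]) -> str:
    attrs = [f"label={_quote(label)}", f"shape={shape}"]
    if color:
        attrs += [f"style=filled", f"fillcolor={color}"]
    return f"  {_quote(node_id)} [{', '.join(attrs)}];"


def _edges_for_reactions(
    rxn_ids: Sequence[str],
    network: MetabolicNetwork,
    options: RenderOptions,
) -> Tuple[List[Tuple[str, str, str]], Set[str], Set[str], Set[str]]:
    """Collect (tail, head, role) edges plus node sets for a reaction subset."""
    currency = network.currency_list if options.omit_currency else set()
    edges: List[Tuple[str, str, str]] = []
    enzymes: Set[str] = set()
    compounds: Set[str] = set()
    rxn_nodes: Set[str] = set()
    for rid in sorted(rxn_ids):
        rxn = network.reactions[rid]
        if rxn.enzymes:
            hubs = sorted(rxn.enzymes)
            enzymes.update(hubs)
        else:
            hubs = [rid]
            rxn_nodes.add(rid)
        known_roles = rxn.direction != "unknown"
        for hub in hubs:
            for cid in sorted(rxn.substrates):
                if cid in currency:
                    continue
                compounds.add(cid)
                edges.append((cid, hub, "substrate" if known_roles else "unknown"))
            for cid in sorted(rxn.products):
                if cid in currency:
                    continue
                compounds.add(cid)
                edges.append((hub, cid, "product" if known_roles else "unknown"))
    return edges, enzymes, compounds, rxn_nodes


def _render_document(
    title: str,
    rxn_ids: Sequence[str],
    network: MetabolicNetwork,
    options: RenderOptions,
) -> str:
    edges, enzymes, compounds, rxn_nodes = _edges_for_reactions(
        rxn_ids, network, options
    )
    lines = [f"digraph {_quote(title)} {{"]
    lines.append('  graph [overlap=false, rankdir=TB];')
    for ec in sorted(enzymes):
        enzyme = network.enzymes[ec]
        label = ec if options.label_mode == "ids" else enzyme.name
        color = _STATE_COLORS.get(options.ec_state.get(ec, ""), None)
        lines.append(_node_stmt(ec, wrap_label(label, options.wrap_width), "box", color))
    for cid in sorted(compounds):
        compound = network.compounds[cid]
        label = cid if options.label_mode == "ids" else compound.name
        lines.append(_node_stmt(cid, wrap_label(label, options.wrap_width), "ellipse", None))
    for rid in sorted(rxn_nodes):
        lines.append(_node_stmt(rid, rid, "diamond", None))

    if options.merge_similar_edges:
        counts: Dict[Tuple[str, str, str], int] = {}
        for e in edges:
            counts[e] = counts.get(e, 0) + 1
        rendered = sorted(counts.items())
        for (tail, head, role), mult in rendered:
            attrs = []
            if role == "unknown":
                attrs.append("dir=none")
            if mult > 1:
                attrs.append(f"label={_quote('x' + str(mult))}")
            suffix = f" [{', '.join(attrs)}]" if attrs else ""
            lines.append(f"  {_quote(tail)} -> {_quote(head)}{suffix};")
    else:
        for tail, head, role in sorted(edges):
            suffix = " [dir=none]" if role == "unknown" else ""
            lines.append(f"  {_quote(tail)} -> {_quote(head)}{suffix};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def pathway_to_dot(
    pathway: Pathway,
    network: MetabolicNetwork,
    options: Optional[RenderOptions] = None,
) -> List[str]:
    """Render a pathway to one or more DOT documents.

    Normally a single document is returned.  When the (merged) edge count
    exceeds ``zoom_edge_budget`` the pathway's reaction graph is partitioned
    by modularity and each community becomes its own sub-document, reducing
    edge clutter; the union of sub-document edges covers the full diagram.
    """
    options = options or RenderOptions()
    if not pathway.reactions:
        raise ValueError(f"pathway {pathway.id} has no reactions")
    missing = pathway.reactions - network.reactions.keys()
    if missing:
        raise StructuralIntegrityError(
            f"pathway {pathway.id} references unknown reactions: {sorted(missing)}"
        )
    rxn_ids = sorted(pathway.reactions)
    edges, _, _, _ = _edges_for_reactions(rxn_ids, network, options)
    n_edges = len(set(edges)) if options.merge_similar_edges else len(edges)
    if n_edges <= options.zoom_edge_budget:
        return [_render_document(pathway.name, rxn_ids, network, options)]

    rxns = [network.reactions[r] for r in rxn_ids]
    graph = build_reaction_graph(rxns, network.currency_list)
    partition = extract_modules(graph)
    communities = [sorted(c) for c in partition.communities()]
    if len(communities) < 2:
        half = len(rxn_ids) // 2
        communities = [rxn_ids[:half], rxn_ids[half:]]
    docs = []
    for i, comm in enumerate(communities, start=1):
        docs.append(
            _render_document(f"{pathway.name} (zoom {i})", comm, network, options)
        )
    return docs


# -- minimal structural DOT parser (for validation and tests) -------------

_DOT_HEADER = re.compile(r'^(strict\s+)?(di)?graph\s+("(?:[^"\\]|\\.)*"|\w+)?\s*\{$')
_DOT_NODE = re.compile(r'^("(?:[^"\\]|\\.)*"|\w+)\s*(\[[^\]]*\])?;$')
_DOT_EDGE = re.compile(
    r'^("(?:[^"\\]|\\.)*"|\w+)\s*(->|--)\s*("(?:[^"\\]|\\.)*"|\w+)\s*(\[[^\]]*\])?;$'
)
_DOT_ATTR = re.compile(r'^(graph|node|edge)\s*\[[^\]]*\];$')


def _unquote(token: str) -> str:
    if token.startswith('"'):
        body = token[1:-1]
        return body.replace('\\"', '"').replace("\\n", "\n").replace("\\\\", "\\")
    return token


def parse_dot(text: str) -> Tuple[Set[str], List[Tuple[str, str]]]:
    """Check a DOT document structurally; return (node ids, edges).

    Understands the restricted dialect this module emits (one statement per
    line, quoted identifiers, attribute lists).  Raises ``ValueError`` with
    the offending line on malformed input.
    """
    lines = [ln.strip() for ln in text.strip().splitlines()]
    if not lines or not _DOT_HEADER.match(lines[0]):
        raise ValueError(f"bad DOT header: {lines[0] if lines else '<empty>'}")
    if lines[-1] != "}":
        raise ValueError("missing closing brace")
    nodes: Set[str] = set()
    edges: List[Tuple[str, str]] = []
    for ln in lines[1:-1]:
        if not ln:
            continue
        if _DOT_ATTR.match(ln):
            continue
        m = _DOT_EDGE.match(ln)
        if m:
            tail, head = _unquote(m.group(1)), _unquote(m.group(3))
            nodes.update((tail, head))
            edges.append((tail, head))
            continue
        m = _DOT_NODE.match(ln)
        if m:
            nodes.add(_unquote(m.group(1)))
            continue
        raise ValueError(f"unparseable DOT statement: {ln}")
    return nodes, edges
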