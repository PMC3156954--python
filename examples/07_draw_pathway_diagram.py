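"""Render a pathway to an automatic DOT diagram.

Enzymes draw as boxes and compounds as ellipses; currency metabolites are
omitted, parallel same-role edges merge with a multiplicity label, and a
regulation map colors enzymes (green = down, red = up).  The output is plain
DOT text: pipe it through ``dot -Tsvg`` to obtain an image.
"""

from metnet import io as mio
from metnet.simulate import CURRENCY_FIXTURE, make_reference_models
from metnet.viz import RenderOptions, parse_dot, pathway_to_dot

model, _, _ = make_reference_models(seed=1)
network = mio.model_to_network(model, currency_list=CURRENCY_FIXTURE)
pathway = network.pathways["PWA0"]

options = RenderOptions(label_mode="ids", omit_currency=True,
                        ec_state={"9.9.1.1": "down"})
doc = pathway_to_dot(pathway, network, options)[0]
nodes, edges = parse_dot(doc)  # structural sanity check
print(doc)
print(f"// {len(nodes)} nodes, {len(edges)} edges — deterministic output")
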