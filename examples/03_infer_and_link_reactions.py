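"""Create ab initio reactions for enzymes missing from the reference models.

A phosphatidylinositol-5-phosphate 4-kinase (EC 2.7.1.149) has no reference
reaction, but its compound associations are known; it becomes an inferred
reaction of unknown direction.  Because it can produce the substrate of the
phosphoinositide-3-kinase reaction (EC 2.7.1.153), the two reactions are
linked into the same neighbourhood of the network.
"""

from metnet.inference import EnzymeCompoundAssociation, infer_reactions, link_reactions
from metnet.model import Reaction

PIP5 = "1-Phosphatidyl-1D-myo-inositol 5-phosphate"
PIP2 = "1-Phosphatidyl-D-myo-inositol 4,5-bisphosphate"
PIP3 = "Phosphatidylinositol-3,4,5-trisphosphate"

association = EnzymeCompoundAssociation(
    ec="2.7.1.149", undirected_compounds={PIP5, PIP2}
)
inferred, report = infer_reactions({"2.7.1.149"}, [association])
kinase_b = inferred[0]
print(f"inferred reaction: {kinase_b.id}  EC={sorted(kinase_b.enzymes)[0]}  "
      f"direction={kinase_b.direction}")

kinase_a = Reaction(id="ref_pi3k", enzymes={"2.7.1.153"},
                    substrates={PIP2}, products={PIP3}, direction="forward",
                    source="reference")
links = link_reactions([kinase_a, kinase_b], currency_list=set())
print("linked pairs:", sorted(links.edges))
# the shared non-currency metabolite (PIP2) joins the two reactions
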