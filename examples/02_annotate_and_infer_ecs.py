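"""Identify metabolic genes from homology hits and infer their EC numbers.

Homology hits are filtered (E-value strictly under 1e-5, at least 33
identical bases) through a two-stage cascade of subject databases; GO terms
transfer from the retained subjects, genes under the metabolism subtree are
kept, and EC numbers come from orthologs or consensus-sequence annotation.
"""

from metnet.annotation import (
    GeneAnnotation,
    HomologyHit,
    OntologyGraph,
    cascade_filter,
    infer_ec,
    select_metabolic_genes,
    transfer_go,
)
from metnet.simulate import make_annotation_inputs

data = make_annotation_inputs(seed=4)
databases = [
    [HomologyHit(**h) for h in data["hits_db1"]],
    [HomologyHit(**h) for h in data["hits_db2"]],
]
retained = cascade_filter(databases)
go_map = transfer_go(retained, data["subject_go"])
print(f"queries with retained hits: {len(go_map)} / {len(data['genes'])}")

ontology = OntologyGraph(
    terms=set(data["ontology_terms"]),
    parents=data["ontology_parents"],
    metabolism_root=data["metabolism_root"],
)
annotations = []
for gene, terms in sorted(go_map.items()):
    ecs = infer_ec(gene, data["ortholog_map"], data["human_ec"], data["consensus_ec"])
    annotations.append(
        GeneAnnotation(gene=gene, go_terms=terms, ecs=set(ecs), ec_evidence=ecs)
    )
selected, metabolic = select_metabolic_genes(annotations, ontology)
print(f"metabolic genes (GO gate):  {len(metabolic)}")
print(f"enter construction (has EC): {len(selected)}")
print("expected from the generator:", len(data["truth"]["metabolic_genes"]))
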