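"""Cross-species comparison of enzyme complements and pathway conservation.

For each pathway shared between a reference model (species A, e.g. human) and
a second model (species B, e.g. fish) the conservation ratio is the number of
shared EC numbers divided by species A's EC count, truncated to two decimals
for reporting (full precision is kept internally).  Partial EC numbers are
excluded from all counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

from .model import MetabolicNetwork, Pathway, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationRow",
    "ConservationReport",
    "enzyme_overlap",
    "conservation_ratio",
    "conservation_table",
    "conservation_from_counts",
    "duplication_excess",
    "CONSERVATION_BENCHMARK",
]

#: Published human-vs-fish per-pathway enzyme counts
#: (pathway, human ECs, fish ECs, overlap) used as a regression benchmark:
#: the reported conservation ratios must be reproducible from these count
#: columns alone.
CONSERVATION_BENCHMARK = (
    ("1- and 2-Methylnaphthalene degradation", 2, 3, 2),
    ("Hyaluronan metabolism", 3, 3, 3),
    ("Sialic acid metabolism", 18, 18, 18),
    ("Hexose phosphorylation", 5, 5, 5),
    ("Electron transport chain", 4, 5, 4),
    ("Limonene and pinene degradation", 3, 4, 3),
    ("Proteoglycan biosynthesis", 16, 16, 16),
    ("Glycosphingolipid biosynthesis - ganglioseries", 18, 17, 17),
    ("N-Glycan degradation", 8, 7, 7),
    ("Di-unsaturated fatty acid beta-oxidation", 7, 6, 6),
    ("Vitamin B1 (thiamin) metabolism", 7, 6, 6),
    ("Glycosphingolipid metabolism", 28, 24, 24),
    ("Glutamate metabolism", 14, 12, 12),
    ("TCA cycle", 18, 15, 15),
    ("Vitamin B9 (folate) metabolism", 17, 14, 14),
    ("Linoleate metabolism", 11, 9, 9),
    ("Phytanic acid peroxisomal oxidation", 13, 5, 5),
    ("Glycosylphosphatidylinositol(GPI)-anchor biosynthesis", 3, 1, 1),
    ("Vitamin H (biotin) metabolism", 6, 2, 2),
    ("Vitamin B12 (cyanocobalamin) metabolism", 3, 2, 1),
    ("Glyoxylate and Dicarboxylate metabolism", 7, 2, 2),
    ("Pentose and Glucuronate interconversions", 9, 2, 2),
    ("Ascorbate (vitamin C) and aldarate metabolism", 8, 1, 1),
)


@dataclass
class ConservationRow:
    pathway: str
    n_a: int
    n_b: int
    overlap: int
    ratio: float        # truncated to 2 decimals, as reported
    ratio_exact: float  # full precision

    def __post_init__(self) -> None:
        if self.overlap > min(self.n_a, self.n_b):
            raise ValueError(f"{self.pathway}: overlap exceeds min(n_a, n_b)")


@dataclass
class ConservationReport:
    rows: List[ConservationRow]
    unmatched_a: List[str]
    unmatched_b: List[str]


def enzyme_overlap(ecs_a: Set[str], ecs_b: Set[str]) -> Tuple[int, int, int]:
    """(|A|, |B|, |A ∩ B|) for two enzyme-complement sets."""
    return len(ecs_a), len(ecs_b), len(ecs_a & ecs_b)


def conservation_ratio(n_a: int, overlap: int) -> float:
    """overlap / n_a truncated (not rounded) to two decimals.

    Truncation is the reporting convention: 7/8 prints as 0.87 and 9/11 as
    0.81.
    """
    if n_a <= 0:
        raise ValueError("n_a must be positive")
    return math.floor(100.0 * overlap / n_a) / 100.0


def conservation_table(
    model_a: MetabolicNetwork, model_b: MetabolicNetwork
) -> ConservationReport:
    """Per-pathway enzyme conservation of model B relative to model A.

    Pathways are aligned by name; unmatched pathways are reported
    separately.  Rows are sorted by descending ratio, ties by pathway name.
    Pathways with no (complete) A-side ECs are excluded and logged.
    """
    by_name_a = {pw.name: pid for pid, pw in model_a.pathways.items()}
    by_name_b = {pw.name: pid for pid, pw in model_b.pathways.items()}
    shared = sorted(by_name_a.keys() & by_name_b.keys())

    rows: List[ConservationRow] = []
    for name in shared:
        ecs_a = model_a.pathway_ec_set(by_name_a[name])
        ecs_b = model_b.pathway_ec_set(by_name_b[name])
        n_a, n_b, overlap = enzyme_overlap(ecs_a, ecs_b)
        if n_a == 0:
            logger.warning("conservation_table: pathway %r has no reference ECs; excluded", name)
            continue
        rows.append(
            ConservationRow(
                pathway=name,
                n_a=n_a,
                n_b=n_b,
                overlap=overlap,
                ratio=conservation_ratio(n_a, overlap),
                ratio_exact=overlap / n_a,
            )
        )
    rows.sort(key=lambda r: (-r.ratio_exact, r.pathway))
    return ConservationReport(
        rows=rows,
        unmatched_a=sorted(by_name_a.keys() - by_name_b.keys()),
        unmatched_b=sorted(by_name_b.keys() - by_name_a.keys()),
    )


def conservation_from_counts(
    rows: Sequence[Tuple[str, int, int, int]]
) -> ConservationReport:
    """Run the conservation table on models synthesised from count columns.

    Each ``(pathway, n_a, n_b, overlap)`` row becomes one shared pathway in
    a pair of models whose EC sets realise exactly those cardinalities (one
    single-EC reaction per enzyme, compounds private per reaction).  The
    table is then computed through the ordinary code path, so the reported
    ratio is derived, not copied in.
    """
    nets = (MetabolicNetwork(currency_list=set()), MetabolicNetwork(currency_list=set()))
    ec_counter = 0
    comp_counter = 0
    for p_idx, (name, n_a, n_b, overlap) in enumerate(rows):
        if overlap > min(n_a, n_b):
            raise ValueError(f"{name}: overlap exceeds min(n_a, n_b)")
        shared = [f"9.9.{p_idx + 1}.{i + 1}" for i in range(overlap)]
        only_a = [f"8.8.{p_idx + 1}.{i + 1}" for i in range(n_a - overlap)]
        only_b = [f"7.7.{p_idx + 1}.{i + 1}" for i in range(n_b - overlap)]
        for net, ecs in zip(nets, (shared + only_a, shared + only_b)):
            rxn_ids = set()
            for ec in ecs:
                ec_counter += 1
                comp_counter += 2
                rid = f"R{ec_counter:05d}"
                rxn_ids.add(rid)
                net.add_reaction(
                    Reaction(
                        id=rid,
                        enzymes={ec},
                        substrates={f"CB{comp_counter:05d}"},
                        products={f"CB{comp_counter + 1:05d}"},
                        source="benchmark",
                        pathways={name},
                    )
                )
            net.add_pathway(Pathway(id=name, name=name, reactions=rxn_ids))
    return conservation_table(*nets)


def duplication_excess(
    orthologs: Mapping[str, str], metabolic_genes: Set[str]
) -> Tuple[float, float]:
    """Percentage excess of species-A genes over their distinct ortholog
    targets, overall and for the metabolic subset.

    With a many-to-one ortholog map (several A genes per B gene, as after a
    lineage-specific genome duplication), the excess
    ``100 × (|A genes| − |distinct B genes|) / |distinct B genes|``
    measures retained duplicates.
    """
    if not orthologs:
        raise ValueError("empty ortholog map")

    def excess(pairs: Mapping[str, str]) -> float:
        targets = set(pairs.values())
        if not targets:
            raise ValueError("no ortholog targets")
        return 100.0 * (len(pairs) - len(targets)) / len(targets)

    metabolic_pairs = {g: t for g, t in orthologs.items() if g in metabolic_genes}
    if not metabolic_pairs:
        raise ValueError("no metabolic genes in the ortholog map")
    return excess(orthologs), excess(metabolic_pairs)
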