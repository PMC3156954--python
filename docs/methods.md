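# Methods

## The model

`metnet` represents metabolism as a bipartite graph with enzyme nodes (EC
numbers) and compound nodes; an edge records a (enzyme, compound) incidence
contributed by at least one reaction. Reactions — the unit of integration —
carry an enzyme set, substrate and product sets, a direction
(`forward`/`reversible`/`unknown`) and a provenance tag. Pathways are named
reaction sets whose enzyme and compound sets are derived on demand.

Simplifying assumptions, deliberate and shared with most first-generation
genome-scale reconstructions: no stoichiometric coefficients, no mass
balance, no cellular compartments, no thermodynamics, and no isozyme
distinction (all genes with the same EC collapse onto one enzyme node).
Unknown direction is treated as reversible for every connectivity
computation.

### Currency metabolites

Ubiquitous cofactors (ATP, NAD(H), H2O, …) would connect nearly everything;
they are excluded from reaction identity, reaction linking, module edges and
(by default) diagrams. The packaged default list covers fourteen common
cofactors under both display names and KEGG ids; it is configuration, not
biology — any file of compound ids can replace it, and
`derive_currency_list(network, k)` computes the degree-based alternative
(the k most connected compounds, ties broken lexicographically). The
packaged list is a pragmatic stand-in for externally curated currency lists,
which the degree criterion should approximately recover on real models.

## Annotation

Homology hits are accepted when the E-value is strictly under `1e-5`
("under") **and** the alignment contains at least 33 identical bases
("minimum", inclusive). The identical-base threshold is interpreted as an
absolute base count, not a percentage; both thresholds are configurable.
From 12-column tabular hits the identical-base count is derived as
`floor(pident × length / 100 + 0.5)` — half-up rounding, chosen over
banker's rounding for platform-stable determinism.

Subject databases form an ordered cascade (a well-annotated sister genome
first, reference sequences second): for each query the first database
yielding a retained hit wins. GO transfer takes the union over all retained
subjects — the evidence model is deliberately permissive since every
assignment is tentative anyway. A gene is *metabolic* when any GO term
reaches the metabolism root by `is_a` links (reflexively); this gate is
over-inclusive (transporters qualify), so only genes that additionally map
to an EC number enter network construction. EC inference runs two routes —
ortholog carry-over and consensus-sequence annotation — whose union is
kept, each EC tagged with its evidence; the ortholog tag wins on agreement.
A gene with an EC but no metabolic GO term is excluded (GO is the gate),
with a warning and a configurable override.

## Integration

Reaction identity is `(enzyme set, major compound set)` — direction is
ignored, currency garnish is ignored. This makes identity an equivalence
relation, so merging is order-independent: duplicates collapse to the
first-seen record, provenance and pathway memberships accumulate, and
direction conflicts (duplicates written in opposite orientations, detected
by orienting each against the canonical record's sides) resolve to
`reversible` with a logged conflict.

Pathway merging: two pathways merge when their shared reaction count
reaches 50 % of the smaller pathway's set (both motivating cases — a full
3-reaction containment and a 16-of-20 overlap — clear this bar); the
relation is closed transitively, the largest partner lends its id and name,
and all names survive in provenance. The threshold is configurable.

Restriction to a species keeps reactions whose enzymes intersect the
species' EC complement. EC-less (spontaneous) reactions are kept only when
they share a non-currency compound with a kept reaction of the same pathway
— keeping them unconditionally would smuggle in chemistry with no enzymatic
support, dropping them all would break pathway continuity. Redundant
reference reactions beyond deduplication are handled by an explicit
drop-list hook rather than heuristics.

## Module discovery

Reactions project onto a simple graph: nodes are reactions, an edge means a
shared non-currency compound. For directed linking of inferred reactions a
stricter rule applies (a product of one must be a substrate of the other
unless either side is reversible/unknown), but the module graph uses the
symmetric shared-compound rule.

The partitioner is the leading-eigenvector method: compute
`B = A − k kᵀ/2m`, split by the sign of the dominant eigenvector, recurse on
the generalised matrix `B^(g)` (diagonal corrected by subgraph row sums) so
every accepted bisection contributes a positive increment to the global
`Q = Σ_c (e_cc − a_c²)`. A part is indivisible when the leading eigenvalue
is non-positive, the eigenvector has one sign, or the split's ΔQ ≤ 0.

Numerical choices: the dominant eigenpair comes from power iteration on the
Gershgorin-shifted matrix (tolerance 1e-10, 10,000 iterations, deterministic
non-uniform start vector); sign ambiguity is fixed by making the
largest-magnitude entry positive, so extraction is fully deterministic.
Degenerate (tied) leading eigenvalues fail convergence and the part is
declared indivisible with a log message — robustness over completeness. No
Kernighan–Lin fine-tuning stage is applied; it is a documented extension
point, and the recovery tests pass without it.

Curation is declarative: each module maps to `accept` (new pathway),
`merge` (into an existing pathway) or `reject` (dismantle); undecided
modules default to accept at ≥ 3 reactions (the minimum pathway size; "too
few reactions" is not quantified upstream, 3 is configurable) and reject
below. Isolated reactions attach to a pathway when **two or more** of their
non-currency compounds occur in it — connecting metabolites of the pathway,
not merely touching one; the best-scoring pathway wins, ties attach to all.
The attach → extract → curate loop iterates until a round changes nothing;
each productive round strictly shrinks the unassigned pool, so it
terminates.

## Comparison

Per shared pathway (aligned by name) the conservation ratio is
`overlap / n_reference` where the counts are complete 4-field ECs (partial
ECs like `1.1.1.-` are excluded from all counting — they inflate overlap
ambiguously). Reported ratios are **truncated**, not rounded, to two
decimals (7/8 → 0.87, 9/11 → 0.81); full precision is kept internally and
used for sorting. The 23-row published count table ships as a regression
benchmark: replaying its count columns through the table code must
reproduce every printed ratio. Gene-duplication excess is
`100 × (|A genes| − |distinct B targets|) / |distinct B targets|` for a
many-to-one ortholog map, overall and restricted to metabolic genes; the
published duplication percentages depend on a counting protocol that is not
fully specified, so ours is fixture-tested, not claimed as a reproduction.

## Enrichment

Selected and universe gene lists map to deduplicated EC sets (the counting
unit is the enzyme, not the gene — three isozymes count once). The
background defaults to the enzymes mappable from the measured universe (the
platform), not the whole model; arrays measure only part of the genome and
a whole-model background would overstate significance. Each pathway's EC
set is restricted to the background; the p-value is the exact
hypergeometric upper tail `P(X ≥ k)` (via `scipy.stats.hypergeom.sf`).
Reports filter at raw `p < 0.05` by default — matching the convention of
ranked raw-p pathway tables — with a Benjamini–Hochberg column always
emitted alongside. GMT export writes one line per pathway (name,
description, member genes for the species) for use with rank-based
set-enrichment tools; the Kolmogorov–Smirnov statistic itself is export-only
interoperability, not reimplemented here.

### Null calibration

The calibration experiment selects every background enzyme independently at
a fixed rate (no pathway favoured) and measures the fraction of pathway
tests with `p < 0.05` over 1,000 draws. The hypergeometric tail is
discrete, hence conservative: with small pathways (≈ 8–30 ECs) the largest
attainable p-value under 0.05 sits well below it and the measured fraction
lands near 0.03. The calibration design therefore uses large sets — 6 sets
of 200 enzymes, selection rate 0.5 — where attainable p-values near 0.05
are finely spaced; the measured fraction (~0.045) then reflects calibration
rather than granularity and sits inside the 99 % binomial envelope of 0.05
computed at 1,000 draws. This is a property of the test statistic, not of
any biological fixture.

## Synthetic data

The generator produces every pipeline input at toy scale with recorded
truth, all deterministic in the seed:

- **Reference model pairs**: 5 pathways × 4 reactions per model by default,
  a planted 40 % duplicate fraction (same enzymes and major compounds;
  currency garnish attached at rate 0.5 and direction re-drawn, so
  duplicates are only detectable through the identity rule), manifest
  recording the duplicate pairs and expected merged count.
- **Planted-partition graphs**: k modules × n nodes, within-module edge
  probability `p_in = 0.8`, between `p_out = 0.02` (strong but not trivial
  signal at 12-node modules), truth labels returned.
- **Enrichment cases**: 20 pathways × 8 private ECs × 2 genes per EC;
  planted pathways select genes at 0.6 versus a 0.05 base rate — an effect
  size representative of a strongly perturbed pathway against a typical
  microarray selection fraction.
- **Annotation inputs**: 30 query genes of which 18 are metabolic, hit
  E-values log-uniform in [1e-30, 1e-6] for true hits and [1e-4, 1e-1] for
  decoys, split across a two-database cascade, with a 6-term metabolism-
  rooted ontology and ortholog/consensus EC routes.

Identifiers are format-valid but synthetic (`9.9.x.y` ECs, `CX####`
compounds, `G####` genes): no real biology is implied. What the fixtures do
**not** emulate: realistic sequence content, correlated gene expression,
pathway overlap (fixture pathways own disjoint EC sets), partial-EC noise
and annotation errors. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration at toy scale, not that a specific
genome's published network is reproduced — the full-scale enzyme, reaction
and pathway counts depend on external genome and array data and are out of
desk-test reach by design.

## Interchange formats

Reaction tables are 7-column TSV (id, source, `;`-joined EC/substrate/
product sets, direction, pathway list) with `#` comments; writers sort
reactions by id and pathways by name so files round-trip byte-identically.
The SBML subset is Level 2 with a single default compartment (matching the
no-compartment model); EC numbers, provenance, pathway memberships and the
unknown-direction flag travel in reaction notes, and `reversible` maps to
direction `reversible` on read. DOT output is deterministic text in a
restricted dialect (one statement per line, quoted identifiers) checked by
the package's own structural parser; image rendering is delegated to an
external `dot` binary when present and never required.

## Problem sizes

Default test and acceptance runs use toy scale throughout — 40-reaction
model pairs, 48-node planted graphs, 320-gene enrichment cases, exhaustive
oracles up to N = 12 (hypergeometric) and 8 nodes (bipartitions), 100
enrichment replicates and 1,000 calibration draws — sizes chosen so every
expected value is recomputable by brute force while the full suite stays
fast.

## Known limitations

- EC numbers inferred by homology are tentative; the model inherits every
  upstream annotation error.
- Pathway overlap makes enrichment hits non-independent (a pathway can be
  dragged in by enzymes it shares with a truly affected neighbour); the
  report cannot distinguish these without follow-up.
- The leading-eigenvector method only guarantees locally optimal
  bisections; modules are candidates for curation, not final pathways.
- Reaction identity keyed on (enzymes, major compounds) can over-merge
  reactions that genuinely differ only in cofactor usage.
- The bipartite model ignores stoichiometry and compartments, so it cannot
  support flux-balance reasoning without extension.
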