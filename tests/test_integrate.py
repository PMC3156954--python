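import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metnet.integrate import (
    ReferenceModel,
    merge_models,
    merge_pathways,
    reactions_equal,
    restrict_to_enzymes,
)
from metnet.model import Pathway, Reaction
from metnet.simulate import CURRENCY_FIXTURE, make_reference_models


def rxn(rid="R", ecs=("9.9.1.1",), subs=("A",), prods=("B",), direction="forward",
        source="m", pathways=()):
    return Reaction(id=rid, enzymes=set(ecs), substrates=set(subs),
                    products=set(prods), direction=direction, source=source,
                    pathways=set(pathways))


class TestReactionsEqual:
    def test_reflexive_on_identical_reactions(self):
        assert reactions_equal(rxn(), rxn(rid="other"), currency_list=set())

    def test_currency_garnish_is_ignored(self):
        plain = rxn()
        garnished = rxn(rid="g", subs=("A", "ATP"), prods=("B", "ADP"))
        assert reactions_equal(plain, garnished, currency_list={"ATP", "ADP"})

    def test_direction_is_ignored(self):
        assert reactions_equal(rxn(), rxn(rid="r", direction="reversible"),
                               currency_list=set())

    def test_single_field_perturbations_break_equality(self):
        """Only currency perturbations preserve identity; every major-field
        change breaks it (enumerated over all single perturbations)."""
        base = rxn()
        currency = {"ATP"}
        perturbations = {
            "ec": rxn(ecs=("9.9.1.2",)),
            "substrate": rxn(subs=("Z",)),
            "product": rxn(prods=("Z",)),
            "extra_major": rxn(subs=("A", "Z")),
            "extra_currency": rxn(subs=("A", "ATP")),
        }
        outcomes = {
            name: reactions_equal(base, p, currency) for name, p in perturbations.items()
        }
        assert outcomes == {
            "ec": False,
            "substrate": False,
            "product": False,
            "extra_major": False,
            "extra_currency": True,
        }


@st.composite
def random_reaction(draw):
    ecs = draw(st.sets(st.sampled_from(["9.9.1.1", "9.9.1.2", "9.9.1.3"]),
                       min_size=0, max_size=2))
    subs = draw(st.sets(st.sampled_from(["A", "B", "C", "ATP"]), min_size=1, max_size=2))
    prods = draw(st.sets(st.sampled_from(["D", "E", "ADP"]), min_size=1, max_size=2))
    return Reaction(id=draw(st.uuids().map(str)), enzymes=ecs,
                    substrates=subs, products=prods)


@settings(max_examples=100, deadline=None)
@given(r1=random_reaction(), r2=random_reaction(), r3=random_reaction())
def test_reaction_identity_is_an_equivalence_relation(r1, r2, r3):
    currency = {"ATP", "ADP"}
    assert reactions_equal(r1, r1, currency)
    assert reactions_equal(r1, r2, currency) == reactions_equal(r2, r1, currency)
    if reactions_equal(r1, r2, currency) and reactions_equal(r2, r3, currency):
        assert reactions_equal(r1, r3, currency)


class TestMergeModels:
    def test_merge_model_with_itself_is_idempotent(self):
        model = ReferenceModel(name="m", reactions=[rxn(rid="R1"), rxn(rid="R2", subs=("C",))])
        merged, report = merge_models([model, model], currency_list=set())
        assert report.merged_count == 2
        assert report.duplicate_count == 2

    def test_fixture_duplicate_accounting(self):
        model_a, model_b, manifest = make_reference_models(seed=11)
        merged, report = merge_models([model_a, model_b], CURRENCY_FIXTURE)
        assert report.merged_count == manifest.counts["merged_expected"]
        assert report.duplicate_count == manifest.counts["duplicates"]

    def test_duplicates_match_brute_force_pairwise_scan(self):
        model_a, model_b, _ = make_reference_models(seed=23)
        _, report = merge_models([model_a, model_b], CURRENCY_FIXTURE)
        brute = sum(
            1
            for ra in model_a.reactions
            for rb in model_b.reactions
            if reactions_equal(ra, rb, CURRENCY_FIXTURE)
        )
        assert report.duplicate_count == brute

    def test_single_model_passthrough(self):
        model = ReferenceModel(name="m", reactions=[rxn(rid="R1")])
        merged, report = merge_models([model], currency_list=set())
        assert [r.id for r in merged.reactions] == ["R1"]
        assert report.duplicate_count == 0

    def test_associative_up_to_reaction_relabeling(self):
        a, b, _ = make_reference_models(seed=31)
        c = ReferenceModel(name="refC", reactions=[rxn(rid="C1", subs=("CX0000",))])
        left, _ = merge_models([merge_models([a, b], CURRENCY_FIXTURE)[0], c],
                               CURRENCY_FIXTURE)
        right, _ = merge_models([a, merge_models([b, c], CURRENCY_FIXTURE)[0]],
                                CURRENCY_FIXTURE)
        def keys(m):
            return sorted(
                (frozenset(r.enzymes), frozenset(r.compounds - set(CURRENCY_FIXTURE)))
                for r in m.reactions
            )
        assert keys(left) == keys(right)

    def test_direction_conflict_resolves_to_reversible(self):
        m1 = ReferenceModel(name="m1", reactions=[rxn(direction="forward")])
        m2 = ReferenceModel(name="m2", reactions=[
            Reaction(id="R", enzymes={"9.9.1.1"}, substrates={"B"}, products={"A"},
                     direction="forward", source="m2")])
        merged, report = merge_models([m1, m2], currency_list=set())
        assert merged.reactions[0].direction == "reversible"
        assert report.direction_conflicts == ["R"]


class TestMergePathways:
    def test_full_containment_merges_into_larger(self):
        small = Pathway(id="Terpenoid biosynthesis", reactions={"r1", "r2", "r3"})
        large = Pathway(id="Squalene and cholesterol biosynthesis",
                        reactions={"r1", "r2", "r3", "r4", "r5", "r6"})
        merged, rename = merge_pathways([small, large])
        assert len(merged) == 1
        assert merged[0].name == "Squalene and cholesterol biosynthesis"
        assert rename["Terpenoid biosynthesis"] == "Squalene and cholesterol biosynthesis"
        assert "Terpenoid biosynthesis" in merged[0].provenance

    def test_majority_overlap_merges(self):
        # 16 shared reactions; smaller pathway has 20
        shared = {f"r{i}" for i in range(16)}
        p = Pathway(id="Cholesterol Metabolism", reactions=shared | {"x1", "x2", "x3", "x4"})
        q = Pathway(id="Squalene and cholesterol biosynthesis",
                    reactions=shared | {f"y{i}" for i in range(10)})
        merged, _ = merge_pathways([p, q])
        assert len(merged) == 1
        assert merged[0].name == "Squalene and cholesterol biosynthesis"

    def test_disjoint_pathways_unchanged(self):
        p = Pathway(id="p", reactions={"a", "b"})
        q = Pathway(id="q", reactions={"c", "d"})
        merged, rename = merge_pathways([p, q])
        assert {m.id for m in merged} == {"p", "q"}
        assert rename == {"p": "p", "q": "q"}

    def test_transitive_closure_of_merge_relation(self):
        p1 = Pathway(id="p1", reactions={"a", "b"})
        p2 = Pathway(id="p2", reactions={"b", "c"})
        p3 = Pathway(id="p3", reactions={"c", "d"})
        merged, _ = merge_pathways([p1, p2, p3], min_overlap_fraction=0.5)
        assert len(merged) == 1
        assert merged[0].reactions == {"a", "b", "c", "d"}


class TestRestrictToEnzymes:
    def test_keeps_reactions_with_matching_enzyme(self):
        model = ReferenceModel(
            name="ref",
            reactions=[rxn(rid="R1"), rxn(rid="R2", ecs=("9.9.1.2",), subs=("C",))],
            pathways=[Pathway(id="P", reactions={"R1", "R2"})],
        )
        out = restrict_to_enzymes(model, {"9.9.1.1"}, currency_list=set())
        assert [r.id for r in out.reactions] == ["R1"]
        assert out.pathways[0].reactions == {"R1"}

    def test_all_ecs_keeps_all_enzymatic_reactions(self):
        model_a, _, _ = make_reference_models(seed=3)
        all_ecs = {ec for r in model_a.reactions for ec in r.enzymes}
        out = restrict_to_enzymes(model_a, all_ecs, CURRENCY_FIXTURE)
        assert len(out.reactions) == len(model_a.reactions)

    def test_empty_ecs_keeps_nothing(self):
        model_a, _, _ = make_reference_models(seed=3)
        out = restrict_to_enzymes(model_a, set(), CURRENCY_FIXTURE)
        assert out.reactions == [] and out.pathways == []

    def test_nonenzymatic_reaction_kept_only_if_adjacent_in_pathway(self):
        enzymatic = rxn(rid="R1", pathways=("P",))
        spontaneous_linked = Reaction(id="R2", substrates={"B"}, products={"C"},
                                      pathways={"P"})
        spontaneous_apart = Reaction(id="R3", substrates={"X"}, products={"Y"},
                                     pathways={"P"})
        model = ReferenceModel(
            name="ref",
            reactions=[enzymatic, spontaneous_linked, spontaneous_apart],
            pathways=[Pathway(id="P", reactions={"R1", "R2", "R3"})],
        )
        out = restrict_to_enzymes(model, {"9.9.1.1"}, currency_list=set())
        assert {r.id for r in out.reactions} == {"R1", "R2"}
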