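import pytest
from hypothesis import given, settings, strategies as st

from sbmlfuse.composer import (
    CATEGORY_CONFLICT,
    CATEGORY_RENAMED,
    compose,
    merge_compartments,
    merge_reactions,
    merge_species,
    rename_with_prefix,
    union_namespaces,
)
from sbmlfuse.matching import MatchTable, build_match_table
from sbmlfuse.model import models_equal, validate_model
from sbmlfuse.modelgen import random_pair, worked_example_pair
from sbmlfuse.sbmlio import CompatibilityError, parse_sbml, write_sbml

from conftest import bare_model, conflict_base


def compose_auto(m1, m2, **kwargs):
    return compose(m1, m2, build_match_table(m1, m2), **kwargs)


class TestWorkedExample:
    def test_reaction_ids(self, worked_pair):
        result = compose_auto(*worked_pair)
        assert [r.id for r in result.composed.reactions] == [
            "reaction1",
            "reaction2",
            "case00020_reaction1",
            "case00020_reaction2",
        ]

    def test_species_each_once(self, worked_pair):
        result = compose_auto(*worked_pair)
        ids = [s.id for s in result.composed.species]
        assert sorted(ids) == ["S1", "S2", "S3", "S4"]
        assert len(ids) == len(set(ids))

    def test_prefixed_parameters(self, worked_pair):
        result = compose_auto(*worked_pair)
        params = {p.id for p in result.composed.parameters}
        assert {"case00020_k1", "case00020_k2"} <= params
        assert {"k1", "k2"} <= params

    def test_renamed_reaction_kinetic_law_rewritten(self, worked_pair):
        from sbmlfuse.mathexpr import to_infix

        result = compose_auto(*worked_pair)
        law = to_infix(result.composed.reaction("case00020_reaction1").kinetic_math)
        assert "case00020_k1" in law
        assert "S1" in law  # merged species keeps its shared id

    def test_id_maps(self, worked_pair):
        m1, m2 = worked_pair
        result = compose_auto(m1, m2)
        assert all(result.id_map1[eid] == eid for eid in result.id_map1)
        assert set(result.id_map2) >= {eid for eid in m2.element_ids() if eid != m2.model_id}
        assert result.id_map2["S1"] == "S1"
        assert result.id_map2["k1"] == "case00020_k1"

    def test_composed_roundtrips(self, worked_pair):
        result = compose_auto(*worked_pair)
        again = parse_sbml(write_sbml(result.composed))
        assert models_equal(again, result.composed)


class TestIdentityAndSelfCompose:
    def test_compose_with_empty_model(self, worked_pair):
        m1, _ = worked_pair
        empty = bare_model("empty", [])
        empty.compartments.clear()
        result = compose(m1, empty, build_match_table(m1, empty))
        assert len(result.composed.compartments) == len(m1.compartments)
        assert len(result.composed.species) == len(m1.species)
        assert len(result.composed.reactions) == len(m1.reactions)
        assert len(result.composed.parameters) == len(m1.parameters)
        assert result.warnings == []

    def test_self_compose_doubles_parameters_only(self, worked_pair):
        m1, _ = worked_pair
        result = compose_auto(m1, m1.copy())
        assert len(result.composed.compartments) == len(m1.compartments)
        assert len(result.composed.species) == len(m1.species)
        assert len(result.composed.reactions) == len(m1.reactions)
        assert len(result.composed.parameters) == 2 * len(m1.parameters)


class TestPivotMerges:
    def test_identical_compartments_no_warning(self):
        m = conflict_base()
        merged, warnings = merge_compartments(m.compartments[0], m.copy().compartments[0])
        assert warnings == []

    def test_size_conflict(self):
        c1 = conflict_base().compartments[0]
        c2 = conflict_base().compartments[0]
        c2.size = 2.0
        merged, warnings = merge_compartments(c1, c2)
        assert merged.size == 1.0
        assert len(warnings) == 1
        w = warnings[0]
        assert (w.attribute, w.value1, w.value2, w.chosen) == ("size", "1", "2", "1")

    def test_absent_attribute_is_not_a_conflict(self):
        c1 = conflict_base().compartments[0]
        c2 = conflict_base().compartments[0]
        c2.size = None
        merged, warnings = merge_compartments(c1, c2)
        assert merged.size == 1.0 and warnings == []

    def test_species_initial_value_conflict(self):
        s1 = conflict_base().species[0]
        s2 = conflict_base().species[0]
        s2.initial_value = 0.5
        merged, warnings = merge_species(s1, s2)
        assert merged.initial_value == 1.0
        assert [w.attribute for w in warnings] == ["initialValue"]
        assert warnings[0].chosen == warnings[0].value1 == "1"

    def test_species_value_form_conflict(self):
        s1 = conflict_base().species[0]
        s2 = conflict_base().species[0]
        s2.initial_kind = "amount"
        s2.initial_value = 0.5
        merged, warnings = merge_species(s1, s2)
        assert merged.initial_kind == "concentration"
        assert [w.attribute for w in warnings] == ["initialValue-form"]

    def test_reaction_stoichiometry_conflict(self):
        r1 = conflict_base().reactions[0]
        r2 = conflict_base().reactions[0]
        r2.reactants[0].stoichiometry = 2.0
        merged, warnings = merge_reactions(r1, r2)
        assert merged.reactants[0].stoichiometry == 1.0
        assert len(warnings) == 1
        assert warnings[0].attribute == "reactant:S1:stoichiometry"
        assert warnings[0].chosen == "1"

    def test_kinetic_law_conflict(self):
        from sbmlfuse.mathexpr import Apply, Num, Sym

        r1 = conflict_base().reactions[0]
        r2 = conflict_base().reactions[0]
        r2.kinetic_math = Apply("times", (Num(9.0), Sym("S1")))
        merged, warnings = merge_reactions(r1, r2)
        assert [w.attribute for w in warnings] == ["kineticLaw"]
        assert warnings[0].chosen == warnings[0].value1

    def test_modifier_union(self):
        r1 = conflict_base().reactions[0]
        r2 = conflict_base().reactions[0]
        r2.modifiers = ["S2"]
        merged, _ = merge_reactions(r1, r2)
        assert merged.modifiers == ["S2"]

    def test_identical_reactions_no_warnings(self):
        r1 = conflict_base().reactions[0]
        r2 = conflict_base().reactions[0]
        assert merge_reactions(r1, r2)[1] == []


class TestRename:
    def test_prefix_applied(self):
        assert (
            rename_with_prefix("reaction1", "case00020", {"reaction1", "reaction2"})
            == "case00020_reaction1"
        )

    def test_no_collision_keeps_id(self, worked_pair):
        m1, m2 = worked_pair
        m2.reactions[0].id = "reactionX"
        m2.reactions[0].name = "reactionX"
        result = compose_auto(m1, m2)
        assert "reactionX" in [r.id for r in result.composed.reactions]

    def test_prefixed_id_already_taken(self):
        taken = {"reaction1", "case00020_reaction1"}
        assert rename_with_prefix("reaction1", "case00020", taken) == "case00020_reaction1_2"

    def test_prefix_all_flag(self, worked_pair):
        m1, m2 = worked_pair
        result = compose_auto(m1, m2, prefix_all=True)
        ids = {s.id for s in result.composed.species}
        # unmatched model-2 survivors carry the prefix even without collision
        assert {"case00020_S2", "case00020_S4"} <= ids


class TestNamespaces:
    def test_identical_sets_unchanged(self, worked_pair):
        m1, m2 = worked_pair
        assert union_namespaces(m1, m2) == m1.namespaces

    def test_disjoint_sets_merged(self, worked_pair):
        m1, m2 = worked_pair
        m2.namespaces.add(("q", "http://example.org/B"))
        union = union_namespaces(m1, m2)
        assert ("q", "http://example.org/B") in union

    def test_prefix_collision_reprefixed(self, worked_pair):
        m1, m2 = worked_pair
        m1.namespaces.add(("m", "http://example.org/A"))
        m2.namespaces.add(("m", "http://example.org/B"))
        union = union_namespaces(m1, m2)
        uris = {uri for _, uri in union}
        assert {"http://example.org/A", "http://example.org/B"} <= uris
        prefixes = [p for p, _ in union]
        assert len(prefixes) == len(set(prefixes))

    def test_union_survives_serialization(self, worked_pair):
        m1, m2 = worked_pair
        m2.namespaces.add(("q", "http://example.org/B"))
        result = compose_auto(m1, m2)
        text = write_sbml(result.composed)
        assert "http://example.org/B" in text.split(">", 2)[1]


class TestContracts:
    def test_level_mismatch_strict_raises(self, worked_pair):
        m1, m2 = worked_pair
        m2.level, m2.version = 3, 1
        with pytest.raises(CompatibilityError):
            compose(m1, m2, MatchTable())

    def test_level_mismatch_warn_mode(self, worked_pair):
        m1, m2 = worked_pair
        m2.version = 1
        result = compose(m1, m2, MatchTable(), level_mismatch="warn")
        assert any(w.category == "level-note" for w in result.warnings)

    def test_determinism_byte_identical(self, worked_pair):
        m1, m2 = worked_pair
        a = write_sbml(compose_auto(m1, m2).composed)
        b = write_sbml(compose_auto(m1.copy(), m2.copy()).composed)
        assert a == b

    def test_warning_chosen_is_always_model1(self):
        m1 = conflict_base("mA")
        m2 = conflict_base("mB")
        m2.compartments[0].size = 3.0
        m2.species[0].initial_value = 0.25
        m2.reactions[0].products[0].stoichiometry = 5.0
        result = compose_auto(m1, m2)
        conflicts = [w for w in result.warnings if w.category == CATEGORY_CONFLICT]
        assert len(conflicts) == 3
        assert all(w.chosen == w.value1 for w in conflicts)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=5000))
    def test_count_conservation_property(self, seed):
        m1, m2 = random_pair(seed)
        table = build_match_table(m1, m2)
        result = compose(m1, m2, table)
        for cls in ("compartments", "species", "reactions"):
            assert len(getattr(result.composed, cls)) == len(getattr(m1, cls)) + len(
                getattr(m2, cls)
            ) - len(table.pairs(cls))
        assert len(result.composed.parameters) == len(m1.parameters) + len(m2.parameters)
        # no information loss: every model-2 id has an image
        for eid in m2.element_ids():
            if eid and eid != m2.model_id:
                assert eid in result.id_map2
        validate_model(result.composed)

    def test_rename_warnings_emitted(self, worked_pair):
        result = compose_auto(*worked_pair)
        renames = [w for w in result.warnings if w.category == CATEGORY_RENAMED]
        renamed_to = {w.ids[2] for w in renames}
        assert {
            "case00020_reaction1",
            "case00020_reaction2",
            "case00020_k1",
            "case00020_k2",
        } == renamed_to
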