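"""Model composition: merge two models under a validated match table.

Model 1 pivots: matched elements keep model-1 attributes (differences are
warned, never silently dropped), unmatched model-2 elements are carried
over, renamed with the ``<model2-id>_`` prefix when their id collides with
anything already in the composed document.  Global parameters are never
merged.  The composed model always satisfies the full set of structural
invariants or composition fails loudly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

from . import mathexpr
from .mathexpr import MATHML_NS, format_number, to_infix
from .model import (
    Compartment,
    Reaction,
    SbmlModel,
    Species,
    validate_model,
)
from .matching import MatchTable, validate_match_table
from .sbmlio import check_compatibility

CATEGORY_CONFLICT = "attribute-conflict"
CATEGORY_RENAMED = "id-renamed"
CATEGORY_NAME = "name-conflict"
CATEGORY_LEVEL = "level-note"


class ComposeError(ValueError):
    """Composition could not produce a valid model."""


@dataclass(frozen=True)
class MergeWarning:
    category: str
    element_class: str  # compartment|species|reaction|parameter|other|model
    ids: tuple[str, str, str]  # (model1-id, model2-id, composed-id)
    attribute: str = ""
    value1: str = ""
    value2: str = ""
    chosen: str = ""

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "elementClass": self.element_class,
            "ids": list(self.ids),
            "attribute": self.attribute,
            "value1": self.value1,
            "value2": self.value2,
            "chosen": self.chosen,
        }

    def describe(self) -> str:
        if self.category == CATEGORY_RENAMED:
            return (
                f"[{self.element_class}] model-2 id {self.ids[1]!r} renamed to "
                f"{self.ids[2]!r} in the composed model"
            )
        if self.category == CATEGORY_LEVEL:
            return f"[model] {self.value2}"
        return (
            f"[{self.element_class}] {self.ids[0]!r}/{self.ids[1]!r}: attribute "
            f"{self.attribute!r} differs ({self.value1!r} vs {self.value2!r}); "
            f"kept {self.chosen!r}"
        )


@dataclass
class MergeResult:
    composed: SbmlModel
    id_map1: dict[str, str]
    id_map2: dict[str, str]
    warnings: list[MergeWarning] = field(default_factory=list)

    def report_dict(self) -> dict:
        return {
            "composedModelId": self.composed.model_id,
            "warnings": [w.to_dict() for w in self.warnings],
            "idMap1": self.id_map1,
            "idMap2": self.id_map2,
        }


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format_number(value)
    return str(value)


def rename_with_prefix(element_id: str, m2_id: str, taken: set[str]) -> str:
    """``<m2-id>_<element-id>``, suffixed ``_2``, ``_3``, ... until free."""
    candidate = f"{m2_id}_{element_id}"
    if candidate not in taken:
        return candidate
    n = 2
    while f"{candidate}_{n}" in taken:
        n += 1
    return f"{candidate}_{n}"


def union_namespaces(m1: SbmlModel, m2: SbmlModel) -> set[tuple[str, str]]:
    """Union keyed by URI; a model-2 prefix already bound to a different
    URI is re-prefixed (XML well-formedness forces it)."""
    out = set(m1.namespaces)
    uris = {uri for _, uri in out}
    prefixes = {p for p, _ in out}
    for prefix, uri in sorted(m2.namespaces):
        if uri in uris:
            continue
        if prefix in prefixes:
            n = 2
            while f"{prefix}{n}" in prefixes:
                n += 1
            prefix = f"{prefix}{n}"
        out.add((prefix, uri))
        uris.add(uri)
        prefixes.add(prefix)
    return out


# ---------------------------------------------------------------------------
# pairwise element merges (model 1 pivots)

def _conflicts(element_class, e1, e2, composed_id, attrs, warnings):
    for label, v1, v2 in attrs:
        if v1 is not None and v2 is not None and v1 != v2:
            warnings.append(
                MergeWarning(
                    CATEGORY_CONFLICT,
                    element_class,
                    (e1.id, e2.id, composed_id),
                    attribute=label,
                    value1=_fmt(v1),
                    value2=_fmt(v2),
                    chosen=_fmt(v1),
                )
            )


def merge_compartments(c1: Compartment, c2: Compartment) -> tuple[Compartment, list[MergeWarning]]:
    """Model-1 compartment survives; each attribute present on both sides
    with different values yields one attribute-conflict warning."""
    warnings: list[MergeWarning] = []
    _conflicts(
        "compartment",
        c1,
        c2,
        c1.id,
        [
            ("name", c1.name, c2.name),
            ("units", c1.units, c2.units),
            ("size", c1.size, c2.size),
            ("sboTerm", c1.sbo_term, c2.sbo_term),
            ("constant", c1.constant, c2.constant),
        ],
        warnings,
    )
    return c1, warnings


def merge_species(s1: Species, s2: Species) -> tuple[Species, list[MergeWarning]]:
    warnings: list[MergeWarning] = []
    attrs: list[tuple[str, object, object]] = [("name", s1.name, s2.name)]
    if s1.initial_kind != s2.initial_kind and s1.initial_value is not None and s2.initial_value is not None:
        attrs.append(
            (
                "initialValue-form",
                f"{s1.initial_kind}={_fmt(s1.initial_value)}",
                f"{s2.initial_kind}={_fmt(s2.initial_value)}",
            )
        )
    else:
        attrs.append(("initialValue", s1.initial_value, s2.initial_value))
    attrs.extend(
        [
            ("substanceUnits", s1.substance_units, s2.substance_units),
            ("boundaryCondition", s1.boundary_condition, s2.boundary_condition),
            ("constant", s1.constant, s2.constant),
            ("hasOnlySubstanceUnits", s1.has_only_substance_units, s2.has_only_substance_units),
            ("sboTerm", s1.sbo_term, s2.sbo_term),
        ]
    )
    _conflicts("species", s1, s2, s1.id, attrs, warnings)
    return s1, warnings


def _stoich_by_species(refs, species_map) -> dict[str, float]:
    out: dict[str, float] = {}
    for ref in refs:
        sid = species_map.get(ref.species, ref.species)
        out[sid] = out.get(sid, 0.0) + ref.stoichiometry
    return out


def merge_reactions(
    r1: Reaction,
    r2: Reaction,
    species_map: Optional[dict[str, str]] = None,
    law_map: Optional[dict[str, str]] = None,
) -> tuple[Reaction, list[MergeWarning]]:
    """Model-1 reaction survives (kinetic law, local parameters, flags);
    stoichiometry differences on corresponding species references are
    warned; modifier lists are unioned.

    ``species_map`` translates model-2 species ids into composed ids for
    stoichiometry comparison and the modifier union.  ``law_map`` (default:
    ``species_map``) translates identifiers before comparing kinetic laws —
    the composition driver passes only matched-pair mappings here so that
    textually identical laws do not warn merely because unmerged global
    parameters were collision-renamed.
    """
    species_map = species_map or {}
    law_map = species_map if law_map is None else law_map
    warnings: list[MergeWarning] = []
    _conflicts(
        "reaction",
        r1,
        r2,
        r1.id,
        [
            ("name", r1.name, r2.name),
            ("reversible", r1.reversible, r2.reversible),
            ("sboTerm", r1.sbo_term, r2.sbo_term),
        ],
        warnings,
    )
    for side, refs1, refs2 in (
        ("reactant", r1.reactants, r2.reactants),
        ("product", r1.products, r2.products),
    ):
        st1 = _stoich_by_species(refs1, {})
        st2 = _stoich_by_species(refs2, species_map)
        for sid in st1:
            if sid in st2 and st1[sid] != st2[sid]:
                warnings.append(
                    MergeWarning(
                        CATEGORY_CONFLICT,
                        "reaction",
                        (r1.id, r2.id, r1.id),
                        attribute=f"{side}:{sid}:stoichiometry",
                        value1=_fmt(st1[sid]),
                        value2=_fmt(st2[sid]),
                        chosen=_fmt(st1[sid]),
                    )
                )
    # kinetic-law comparison after pulling model-2 identifiers into
    # model-1 vocabulary; model-2 local parameter ids shadow the map
    math2 = r2.kinetic_math
    if math2 is not None and law_map:
        shadow = {p.id for p in r2.local_parameters}
        math2 = mathexpr.rename(
            math2, {k: v for k, v in law_map.items() if k not in shadow}
        )
    law1 = to_infix(r1.kinetic_math) if r1.kinetic_math is not None else ""
    law2 = to_infix(math2) if math2 is not None else ""
    if law1 != law2:
        warnings.append(
            MergeWarning(
                CATEGORY_CONFLICT,
                "reaction",
                (r1.id, r2.id, r1.id),
                attribute="kineticLaw",
                value1=law1,
                value2=law2,
                chosen=law1,
            )
        )
    merged = r1
    for m in r2.modifiers:
        mapped = species_map.get(m, m)
        if mapped not in merged.modifiers:
            merged.modifiers.append(mapped)
    return merged, warnings


# ---------------------------------------------------------------------------
# reference rewriting inside carried opaque subtrees

def rewrite_opaque(elem: ET.Element, id_map: dict[str, str]) -> None:
    """Map every attribute value and every MathML ``<ci>`` text that
    exactly equals a renamed id."""
    for node in elem.iter():
        for attr, value in list(node.attrib.items()):
            if value in id_map:
                node.set(attr, id_map[value])
        if node.tag == f"{{{MATHML_NS}}}ci" and node.text:
            stripped = node.text.strip()
            if stripped in id_map:
                node.text = f" {id_map[stripped]} "


# ---------------------------------------------------------------------------
# the composition driver

def compose(
    m1: SbmlModel,
    m2: SbmlModel,
    table: MatchTable,
    *,
    prefix_all: bool = False,
    level_mismatch: str = "error",
    composed_id: Optional[str] = None,
    composed_name: Optional[str] = None,
) -> MergeResult:
    """Produce the composed model, per-source id maps, ordered warnings."""
    level_notes = check_compatibility(m1, m2, mode=level_mismatch)
    validate_match_table(table, m1, m2)

    composed = m1.copy()
    composed.model_id = composed_id or f"{m1.model_id}_{m2.model_id}"
    composed.model_name = composed_name or (
        f"Composition of {m1.model_name or m1.model_id} and {m2.model_name or m2.model_id}"
    )
    composed.namespaces = union_namespaces(m1, m2)

    warnings: list[MergeWarning] = [
        MergeWarning(CATEGORY_LEVEL, "model", (m1.model_id, m2.model_id, composed.model_id), value2=note)
        for note in level_notes
    ]
    id_map1 = {eid: eid for eid in m1.element_ids() if eid}
    taken = set(id_map1) | {composed.model_id}

    comp_map = table.mapping2to1("compartments")
    spec_map = table.mapping2to1("species")
    rxn_map = table.mapping2to1("reactions")

    # ---- pass 1: decide every model-2 id ------------------------------
    id_map2: dict[str, str] = {}
    renamed: set[str] = set()

    def assign(old_id: str) -> str:
        if not old_id:
            return old_id
        if prefix_all or old_id in taken:
            new_id = rename_with_prefix(old_id, m2.model_id, taken)
            renamed.add(old_id)
        else:
            new_id = old_id
        taken.add(new_id)
        id_map2[old_id] = new_id
        return new_id

    for c in m2.compartments:
        id_map2[c.id] = comp_map[c.id] if c.id in comp_map else assign(c.id)
    for s in m2.species:
        id_map2[s.id] = spec_map[s.id] if s.id in spec_map else assign(s.id)
    for p in m2.parameters:  # parameters never merge
        assign(p.id)
    for r in m2.reactions:
        id_map2[r.id] = rxn_map[r.id] if r.id in rxn_map else assign(r.id)
    for op in (*m2.unit_definitions, *m2.other_elements):
        if op.id and op.id not in id_map2:
            assign(op.id)

    def note_rename(element_class: str, old_id: str) -> None:
        if old_id in renamed:
            warnings.append(
                MergeWarning(
                    CATEGORY_RENAMED,
                    element_class,
                    ("", old_id, id_map2[old_id]),
                )
            )

    def retag(element, old_id: str) -> None:
        """Apply the assigned id; keep name aligned when it mirrored the id."""
        new_id = id_map2[old_id]
        if element.name is not None and element.name == old_id:
            element.name = new_id
        element.id = new_id

    # ---- pass 2: merge matched / carry unmatched ----------------------
    for c2 in m2.compartments:
        if c2.id in comp_map:
            c1 = composed.compartment(comp_map[c2.id])
            _, w = merge_compartments(c1, c2)
            warnings.extend(w)
        else:
            new = _copy(c2)
            retag(new, c2.id)
            new.units = id_map2.get(new.units, new.units) if new.units else new.units
            note_rename("compartment", c2.id)
            composed.compartments.append(new)

    for s2 in m2.species:
        if s2.id in spec_map:
            s1 = composed.species_by_id(spec_map[s2.id])
            _, w = merge_species(s1, s2)
            warnings.extend(w)
        else:
            new = _copy(s2)
            retag(new, s2.id)
            new.compartment = id_map2.get(new.compartment, new.compartment)
            if new.substance_units:
                new.substance_units = id_map2.get(new.substance_units, new.substance_units)
            if not new.annotations.is_empty():
                rewrite_opaque(new.annotations.raw, _strict_map(id_map2))
            note_rename("species", s2.id)
            composed.species.append(new)

    match_map = {**comp_map, **spec_map, **rxn_map}
    for r2 in m2.reactions:
        if r2.id in rxn_map:
            r1 = composed.reaction(rxn_map[r2.id])
            _, w = merge_reactions(r1, r2, id_map2, law_map=match_map)
            warnings.extend(w)
        else:
            new = _copy(r2)
            retag(new, r2.id)
            for ref in (*new.reactants, *new.products):
                ref.species = id_map2.get(ref.species, ref.species)
            new.modifiers = [id_map2.get(m, m) for m in new.modifiers]
            if new.kinetic_math is not None:
                shadow = {p.id for p in new.local_parameters}
                new.kinetic_math = mathexpr.rename(
                    new.kinetic_math,
                    {k: v for k, v in id_map2.items() if k not in shadow},
                )
            note_rename("reaction", r2.id)
            composed.reactions.append(new)

    for p2 in m2.parameters:
        new = _copy(p2)
        retag(new, p2.id)
        if new.units:
            new.units = id_map2.get(new.units, new.units)
        note_rename("parameter", p2.id)
        composed.parameters.append(new)

    strict = _strict_map(id_map2)
    for op in m2.unit_definitions:
        new_elem = _copy(op.element)
        if op.id and op.id in strict:
            new_elem.set("id", id_map2[op.id])
        rewrite_opaque(new_elem, strict)
        note_rename("other", op.id)
        composed.unit_definitions.append(type(op)(op.list_tag, new_elem))
    for op in m2.other_elements:
        new_elem = _copy(op.element)
        if op.id and op.id in strict:
            new_elem.set("id", id_map2[op.id])
        rewrite_opaque(new_elem, strict)
        note_rename("other", op.id)
        composed.other_elements.append(type(op)(op.list_tag, new_elem))

    try:
        validate_model(composed)
    except Exception as exc:
        raise ComposeError(f"internal consistency error in composed model: {exc}") from exc
    return MergeResult(composed=composed, id_map1=id_map1, id_map2=id_map2, warnings=warnings)


def _copy(obj):
    import copy as _copymod

    return _copymod.deepcopy(obj)


def _strict_map(id_map: dict[str, str]) -> dict[str, str]:
    """Only the entries that actually change an id (rewriting with
    identity entries would be wasted work)."""
    return {k: v for k, v in id_map.items() if k != v}
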