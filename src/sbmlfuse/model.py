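"""In-memory representation of one SBML document.

Only the element classes that participate in matching, composition and
simulation are modelled as first-class types; everything else (unit
definitions, function definitions, rules, events, initial assignments,
constraints) is carried as an opaque XML subtree and re-serialized
verbatim, participating in id-collision renaming but never in matching.
"""

from __future__ import annotations

import copy
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .mathexpr import MathExpr


class SbmlValidationError(ValueError):
    """Model violates an internal invariant (duplicate id, dangling
    reference, non-finite value)."""


@dataclass
class AnnotationBlock:
    """Opaque <annotation> subtree; MIRIAM keys are derived lazily by the
    annotations module, never stored here."""

    raw: Optional[ET.Element] = None

    def is_empty(self) -> bool:
        return self.raw is None

    def __deepcopy__(self, memo):
        return AnnotationBlock(copy.deepcopy(self.raw, memo))

    def __eq__(self, other):
        if not isinstance(other, AnnotationBlock):
            return NotImplemented
        return _canon(self.raw) == _canon(other.raw)


def _canon(elem: Optional[ET.Element]) -> str:
    if elem is None:
        return ""
    return ET.canonicalize(ET.tostring(elem, encoding="unicode"))


@dataclass
class Compartment:
    id: str
    name: Optional[str] = None
    size: Optional[float] = None
    units: Optional[str] = None
    sbo_term: Optional[str] = None
    constant: Optional[bool] = None
    annotations: AnnotationBlock = field(default_factory=AnnotationBlock)
    notes: Optional[ET.Element] = None


@dataclass
class Species:
    id: str
    compartment: str
    name: Optional[str] = None
    #: "concentration" or "amount"; exactly one form is carried
    initial_kind: str = "concentration"
    initial_value: Optional[float] = None
    substance_units: Optional[str] = None
    boundary_condition: bool = False
    constant: bool = False
    has_only_substance_units: bool = False
    sbo_term: Optional[str] = None
    annotations: AnnotationBlock = field(default_factory=AnnotationBlock)
    notes: Optional[ET.Element] = None


@dataclass
class SpeciesRef:
    species: str
    stoichiometry: float = 1.0


@dataclass
class Parameter:
    id: str
    value: Optional[float] = None
    name: Optional[str] = None
    units: Optional[str] = None
    constant: Optional[bool] = None
    sbo_term: Optional[str] = None
    annotations: AnnotationBlock = field(default_factory=AnnotationBlock)


@dataclass
class Reaction:
    id: str
    name: Optional[str] = None
    reversible: bool = True
    reactants: list[SpeciesRef] = field(default_factory=list)
    products: list[SpeciesRef] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    kinetic_math: Optional[MathExpr] = None
    local_parameters: list[Parameter] = field(default_factory=list)
    sbo_term: Optional[str] = None
    annotations: AnnotationBlock = field(default_factory=AnnotationBlock)
    notes: Optional[ET.Element] = None


@dataclass
class OpaqueElement:
    """Carried-but-unmodelled SBML construct (unit definition, rule,
    event, function definition, ...)."""

    list_tag: str  # e.g. "listOfUnitDefinitions"
    element: ET.Element

    @property
    def id(self) -> str:
        return self.element.get("id", "")

    def __eq__(self, other):
        if not isinstance(other, OpaqueElement):
            return NotImplemented
        return self.list_tag == other.list_tag and _canon(self.element) == _canon(other.element)


@dataclass
class SbmlModel:
    level: int = 2
    version: int = 4
    model_id: str = "model"
    model_name: Optional[str] = None
    #: root-level (prefix, URI) declarations; "" prefix = default namespace
    namespaces: set[tuple[str, str]] = field(default_factory=set)
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    unit_definitions: list[OpaqueElement] = field(default_factory=list)
    other_elements: list[OpaqueElement] = field(default_factory=list)
    notes: Optional[ET.Element] = None
    annotations: AnnotationBlock = field(default_factory=AnnotationBlock)

    # -- lookups ---------------------------------------------------------
    def compartment(self, cid: str) -> Compartment:
        return _find(self.compartments, cid, "compartment")

    def species_by_id(self, sid: str) -> Species:
        return _find(self.species, sid, "species")

    def reaction(self, rid: str) -> Reaction:
        return _find(self.reactions, rid, "reaction")

    def parameter(self, pid: str) -> Parameter:
        return _find(self.parameters, pid, "parameter")

    def element_ids(self) -> Iterator[str]:
        """Every id-bearing element id, in document order, model id first."""
        yield self.model_id
        for group in (self.compartments, self.species, self.reactions, self.parameters):
            for el in group:
                yield el.id
        for op in (*self.unit_definitions, *self.other_elements):
            if op.id:
                yield op.id

    def copy(self) -> "SbmlModel":
        return copy.deepcopy(self)


def _find(seq, eid, kind):
    for el in seq:
        if el.id == eid:
            return el
    raise KeyError(f"no {kind} with id {eid!r}")


def effective_name(element) -> str:
    """Name used for matching: the ``name`` attribute when present,
    otherwise the id (Test-Suite models carry ids only)."""
    name = getattr(element, "name", None)
    return name if name else element.id


def validate_model(model: SbmlModel) -> None:
    """Enforce the structural invariants; raises SbmlValidationError."""
    seen: set[str] = set()
    for eid in model.element_ids():
        if not eid:
            continue
        if eid in seen:
            raise SbmlValidationError(f"duplicate id {eid!r}")
        seen.add(eid)
    comp_ids = {c.id for c in model.compartments}
    for c in model.compartments:
        if c.size is not None and not math.isfinite(c.size):
            raise SbmlValidationError(f"compartment {c.id!r} has non-finite size")
    sp_ids = {s.id for s in model.species}
    for s in model.species:
        if s.compartment not in comp_ids:
            raise SbmlValidationError(
                f"species {s.id!r} references unknown compartment {s.compartment!r}"
            )
        if s.initial_kind not in ("concentration", "amount"):
            raise SbmlValidationError(
                f"species {s.id!r} has bad initial-value form {s.initial_kind!r}"
            )
        if s.initial_value is not None and (
            not math.isfinite(s.initial_value) or s.initial_value < 0
        ):
            raise SbmlValidationError(f"species {s.id!r} initial value must be >= 0 and finite")
    for r in model.reactions:
        for ref in (*r.reactants, *r.products):
            if ref.species not in sp_ids:
                raise SbmlValidationError(
                    f"reaction {r.id!r} references unknown species {ref.species!r}"
                )
            if not (ref.stoichiometry > 0):
                raise SbmlValidationError(
                    f"reaction {r.id!r}: stoichiometry of {ref.species!r} must be > 0"
                )
        for m in r.modifiers:
            if m not in sp_ids:
                raise SbmlValidationError(
                    f"reaction {r.id!r} references unknown modifier {m!r}"
                )
        local_seen: set[str] = set()
        for p in r.local_parameters:
            if p.id in local_seen:
                raise SbmlValidationError(
                    f"reaction {r.id!r}: duplicate local parameter {p.id!r}"
                )
            local_seen.add(p.id)
    for p in model.parameters:
        if p.value is not None and not math.isfinite(p.value):
            raise SbmlValidationError(f"parameter {p.id!r} has non-finite value")


def models_equal(a: SbmlModel, b: SbmlModel) -> bool:
    """Structural equality: levels, ids, attributes, stoichiometries, math
    ASTs, canonicalized opaque subtrees. Namespace sets are compared as
    sets of URIs (prefix spelling is not semantic)."""
    if (a.level, a.version, a.model_id, a.model_name) != (
        b.level,
        b.version,
        b.model_id,
        b.model_name,
    ):
        return False
    if {uri for _, uri in a.namespaces} != {uri for _, uri in b.namespaces}:
        return False
    if _canon(a.notes) != _canon(b.notes) or a.annotations != b.annotations:
        return False
    return (
        a.compartments == b.compartments
        and a.species == b.species
        and a.reactions == b.reactions
        and a.parameters == b.parameters
        and a.unit_definitions == b.unit_definitions
        and a.other_elements == b.other_elements
    )


def model_to_dict(model: SbmlModel) -> dict:
    """JSON-ready dump of the representation (``--dump-json``)."""

    def ann(block: AnnotationBlock):
        return None if block.is_empty() else ET.tostring(block.raw, encoding="unicode")

    from .mathexpr import to_infix

    return {
        "level": model.level,
        "version": model.version,
        "id": model.model_id,
        "name": model.model_name,
        "namespaces": sorted(model.namespaces),
        "compartments": [
            {
                "id": c.id,
                "name": c.name,
                "size": c.size,
                "units": c.units,
                "sboTerm": c.sbo_term,
                "constant": c.constant,
                "annotation": ann(c.annotations),
            }
            for c in model.compartments
        ],
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "compartment": s.compartment,
                "initialKind": s.initial_kind,
                "initialValue": s.initial_value,
                "substanceUnits": s.substance_units,
                "boundaryCondition": s.boundary_condition,
                "constant": s.constant,
                "hasOnlySubstanceUnits": s.has_only_substance_units,
                "sboTerm": s.sbo_term,
                "annotation": ann(s.annotations),
            }
            for s in model.species
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "reversible": r.reversible,
                "reactants": [
                    {"species": x.species, "stoichiometry": x.stoichiometry}
                    for x in r.reactants
                ],
                "products": [
                    {"species": x.species, "stoichiometry": x.stoichiometry}
                    for x in r.products
                ],
                "modifiers": list(r.modifiers),
                "kineticLaw": to_infix(r.kinetic_math) if r.kinetic_math is not None else None,
                "localParameters": [
                    {"id": p.id, "value": p.value} for p in r.local_parameters
                ],
                "sboTerm": r.sbo_term,
                "annotation": ann(r.annotations),
            }
            for r in model.reactions
        ],
        "parameters": [
            {
                "id": p.id,
                "name": p.name,
                "value": p.value,
                "units": p.units,
                "constant": p.constant,
            }
            for p in model.parameters
        ],
        "unitDefinitions": [u.id for u in model.unit_definitions],
        "otherElements": [
            {"list": o.list_tag, "id": o.id or None} for o in model.other_elements
        ],
    }
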