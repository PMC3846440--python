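"""SBML Level 2/3 reading and writing on top of ``xml.etree``.

The writer is hand-rolled rather than delegated to ElementTree's
serializer for two reasons: every namespace declared on either source
document must survive on the composed root element even when unused,
and opaque carried subtrees must round-trip with their own whitespace
intact while the structural skeleton stays pretty-printed and
byte-deterministic.
"""

from __future__ import annotations

import copy
import io
import xml.etree.ElementTree as ET
from typing import Optional
from xml.sax.saxutils import escape, quoteattr

from . import mathexpr
from .mathexpr import MATHML_NS, parse_mathml, to_element, format_number
from .model import (
    AnnotationBlock,
    Compartment,
    OpaqueElement,
    Parameter,
    Reaction,
    SbmlModel,
    Species,
    SpeciesRef,
    validate_model,
)

SBML_L2_PREFIX = "http://www.sbml.org/sbml/level2"
SBML_L3_PREFIX = "http://www.sbml.org/sbml/level3"

#: namespaces we can suggest friendly prefixes for when they appear only
#: inside carried subtrees
_SUGGESTED_PREFIXES = {
    "http://www.w3.org/1999/02/22-rdf-syntax-ns#": "rdf",
    "http://biomodels.net/biology-qualifiers/": "bqbiol",
    "http://biomodels.net/model-qualifiers/": "bqmodel",
    "http://purl.org/dc/elements/1.1/": "dc",
    "http://purl.org/dc/terms/": "dcterms",
    "http://www.w3.org/2001/vcard-rdf/3.0#": "vCard",
    "http://www.w3.org/1999/xhtml": "xhtml",
    MATHML_NS: "mml",
}

_OPAQUE_LISTS = (
    "listOfFunctionDefinitions",
    "listOfCompartmentTypes",
    "listOfSpeciesTypes",
    "listOfInitialAssignments",
    "listOfRules",
    "listOfConstraints",
    "listOfEvents",
)


class SbmlParseError(ValueError):
    """Malformed XML or unrecognizable SBML structure."""


class CompatibilityError(ValueError):
    """Documents are at different SBML level/version."""


def sbml_core_namespace(level: int, version: int) -> str:
    if level == 2:
        if version == 1:
            return SBML_L2_PREFIX
        return f"{SBML_L2_PREFIX}/version{version}"
    if level == 3:
        return f"{SBML_L3_PREFIX}/version{version}/core"
    raise SbmlParseError(f"unsupported SBML level {level}")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _detach(elem: ET.Element) -> ET.Element:
    out = copy.deepcopy(elem)
    out.tail = None
    return out


def _bool(value: Optional[str], default: bool) -> bool:
    if value is None:
        return default
    if value in ("true", "1"):
        return True
    if value in ("false", "0"):
        return False
    raise SbmlParseError(f"bad boolean attribute value {value!r}")


def _opt_bool(value: Optional[str]) -> Optional[bool]:
    return None if value is None else _bool(value, False)


def _opt_float(elem: ET.Element, attr: str, where: str) -> Optional[float]:
    raw = elem.get(attr)
    if raw is None:
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise SbmlParseError(f"bad numeric attribute {attr}={raw!r} on {where}") from exc


# ---------------------------------------------------------------------------
# parsing

def parse_sbml(text: str) -> SbmlModel:
    """Parse an SBML Level 2/3 document into the internal representation.

    Raises :class:`SbmlParseError` on malformed XML (naming the line) and
    :class:`~.model.SbmlValidationError` on invariant violations such as
    duplicate ids or dangling references.
    """
    root_ns: list[tuple[str, str]] = []
    seen_root = False
    try:
        it = ET.iterparse(io.StringIO(text), events=("start-ns", "start", "end"))
        root: Optional[ET.Element] = None
        for event, payload in it:
            if event == "start-ns" and not seen_root:
                root_ns.append(payload)
            elif event == "start":
                if root is None:
                    root = payload
                seen_root = True
    except ET.ParseError as exc:
        line, col = exc.position
        raise SbmlParseError(f"malformed XML at line {line}, column {col}: {exc.msg}") from exc
    if root is None or _local(root.tag) != "sbml":
        raise SbmlParseError("document root is not <sbml>")
    try:
        level = int(root.get("level", ""))
        version = int(root.get("version", ""))
    except ValueError:
        raise SbmlParseError("<sbml> is missing integer level/version attributes") from None
    if level not in (2, 3):
        raise SbmlParseError(f"SBML level {level} is not supported (levels 2 and 3 only)")

    model_elem = None
    for child in root:
        if _local(child.tag) == "model":
            model_elem = child
            break
    if model_elem is None:
        raise SbmlParseError("no <model> element in document")

    model = SbmlModel(
        level=level,
        version=version,
        model_id=model_elem.get("id", "model"),
        model_name=model_elem.get("name"),
        namespaces=set(root_ns) or {("", sbml_core_namespace(level, version))},
    )
    for child in model_elem:
        tag = _local(child.tag)
        if tag == "notes":
            model.notes = _detach(child)
        elif tag == "annotation":
            model.annotations = AnnotationBlock(_detach(child))
        elif tag == "listOfCompartments":
            model.compartments = [_parse_compartment(c) for c in child]
        elif tag == "listOfSpecies":
            model.species = [_parse_species(s) for s in child]
        elif tag == "listOfReactions":
            model.reactions = [_parse_reaction(r, level) for r in child]
        elif tag == "listOfParameters":
            model.parameters = [_parse_parameter(p) for p in child]
        elif tag == "listOfUnitDefinitions":
            model.unit_definitions = [
                OpaqueElement("listOfUnitDefinitions", _detach(u)) for u in child
            ]
        elif tag in _OPAQUE_LISTS:
            model.other_elements.extend(OpaqueElement(tag, _detach(e)) for e in child)
        # anything else hanging directly off <model> is dropped silently;
        # SBML core defines nothing else at this position in L2/L3
    validate_model(model)
    return model


def _sub_blocks(elem: ET.Element) -> tuple[AnnotationBlock, Optional[ET.Element]]:
    ann = AnnotationBlock()
    notes = None
    for child in elem:
        tag = _local(child.tag)
        if tag == "annotation":
            ann = AnnotationBlock(_detach(child))
        elif tag == "notes":
            notes = _detach(child)
    return ann, notes


def _require_id(elem: ET.Element, kind: str) -> str:
    eid = elem.get("id")
    if not eid:
        raise SbmlParseError(f"<{kind}> without an id attribute")
    return eid


def _parse_compartment(elem: ET.Element) -> Compartment:
    cid = _require_id(elem, "compartment")
    ann, notes = _sub_blocks(elem)
    return Compartment(
        id=cid,
        name=elem.get("name"),
        size=_opt_float(elem, "size", f"compartment {cid}"),
        units=elem.get("units"),
        sbo_term=elem.get("sboTerm"),
        constant=_opt_bool(elem.get("constant")),
        annotations=ann,
        notes=notes,
    )


def _parse_species(elem: ET.Element) -> Species:
    sid = _require_id(elem, "species")
    conc = _opt_float(elem, "initialConcentration", f"species {sid}")
    amount = _opt_float(elem, "initialAmount", f"species {sid}")
    if conc is not None and amount is not None:
        raise SbmlParseError(
            f"species {sid!r} carries both initialConcentration and initialAmount"
        )
    kind, value = ("amount", amount) if amount is not None else ("concentration", conc)
    ann, notes = _sub_blocks(elem)
    compartment = elem.get("compartment")
    if not compartment:
        raise SbmlParseError(f"species {sid!r} has no compartment attribute")
    return Species(
        id=sid,
        name=elem.get("name"),
        compartment=compartment,
        initial_kind=kind,
        initial_value=value,
        substance_units=elem.get("substanceUnits"),
        boundary_condition=_bool(elem.get("boundaryCondition"), False),
        constant=_bool(elem.get("constant"), False),
        has_only_substance_units=_bool(elem.get("hasOnlySubstanceUnits"), False),
        sbo_term=elem.get("sboTerm"),
        annotations=ann,
        notes=notes,
    )


def _parse_parameter(elem: ET.Element) -> Parameter:
    pid = _require_id(elem, "parameter")
    ann, _ = _sub_blocks(elem)
    return Parameter(
        id=pid,
        name=elem.get("name"),
        value=_opt_float(elem, "value", f"parameter {pid}"),
        units=elem.get("units"),
        constant=_opt_bool(elem.get("constant")),
        sbo_term=elem.get("sboTerm"),
        annotations=ann,
    )


def _parse_species_ref(elem: ET.Element) -> SpeciesRef:
    species = elem.get("species")
    if not species:
        raise SbmlParseError("<speciesReference> without species attribute")
    stoich = _opt_float(elem, "stoichiometry", f"speciesReference {species}")
    return SpeciesRef(species=species, stoichiometry=1.0 if stoich is None else stoich)


def _parse_reaction(elem: ET.Element, level: int) -> Reaction:
    rid = _require_id(elem, "reaction")
    ann, notes = _sub_blocks(elem)
    rxn = Reaction(
        id=rid,
        name=elem.get("name"),
        reversible=_bool(elem.get("reversible"), True),
        sbo_term=elem.get("sboTerm"),
        annotations=ann,
        notes=notes,
    )
    for child in elem:
        tag = _local(child.tag)
        if tag == "listOfReactants":
            rxn.reactants = [_parse_species_ref(r) for r in child]
        elif tag == "listOfProducts":
            rxn.products = [_parse_species_ref(r) for r in child]
        elif tag == "listOfModifiers":
            rxn.modifiers = [
                m.get("species") for m in child if m.get("species")
            ]
        elif tag == "kineticLaw":
            _parse_kinetic_law(child, rxn)
    return rxn


def _parse_kinetic_law(elem: ET.Element, rxn: Reaction) -> None:
    for child in elem:
        tag = _local(child.tag)
        if tag == "math":
            try:
                rxn.kinetic_math = parse_mathml(child)
            except mathexpr.MathParseError as exc:
                raise SbmlParseError(f"reaction {rxn.id!r}: {exc}") from exc
        elif tag in ("listOfParameters", "listOfLocalParameters"):
            rxn.local_parameters = [_parse_parameter(p) for p in child]


# ---------------------------------------------------------------------------
# compatibility

def check_compatibility(
    m1: SbmlModel, m2: SbmlModel, mode: str = "error"
) -> list[str]:
    """Verify both documents share an SBML (level, version).

    Returns an empty list on a clean pass.  On mismatch: raises
    :class:`CompatibilityError` in ``error`` mode, or returns a one-entry
    warning list in ``warn`` mode.
    """
    if (m1.level, m1.version) == (m2.level, m2.version):
        return []
    message = (
        f"SBML level/version mismatch: model {m1.model_id!r} is "
        f"L{m1.level}V{m1.version}, model {m2.model_id!r} is L{m2.level}V{m2.version}"
    )
    if mode == "warn":
        return [message]
    raise CompatibilityError(message)


# ---------------------------------------------------------------------------
# writing

def write_sbml(model: SbmlModel) -> str:
    """Serialize the model back to an SBML document string.

    The output is deterministic byte-for-byte for identical models;
    ``parse_sbml(write_sbml(m))`` is structurally equal to ``m``.
    """
    validate_model(model)
    root = _build_document(model)
    nsmap = _namespace_map(model, root)
    buf = ["<?xml version=\"1.0\" encoding=\"UTF-8\"?>\n"]
    _emit(root, nsmap, buf, indent=0, declare=nsmap)
    return "".join(buf)


def _namespace_map(model: SbmlModel, root: ET.Element) -> dict[str, str]:
    """uri -> prefix for every namespace to declare on the root element."""
    core = sbml_core_namespace(model.level, model.version)
    nsmap: dict[str, str] = {}
    taken: set[str] = set()
    ordered = sorted(model.namespaces, key=lambda pu: (pu[0] != "", pu))
    for prefix, uri in ordered:
        if uri in nsmap:
            continue
        if prefix in taken:  # same prefix bound twice: keep first, re-prefix
            prefix = _fresh_prefix(prefix or "ns", taken)
        nsmap[uri] = prefix
        taken.add(prefix)
    if core not in nsmap:
        if "" not in taken:
            nsmap[core] = ""
            taken.add("")
        else:
            nsmap[core] = _fresh_prefix("sbml", taken)
            taken.add(nsmap[core])
    # namespaces appearing in the tree (opaque subtrees, attributes) that
    # the root never declared get generated prefixes; MathML is handled
    # per-<math> element with a default-namespace override instead
    for uri in sorted(_collect_uris(root)):
        if uri in nsmap or uri == MATHML_NS:
            continue
        want = _SUGGESTED_PREFIXES.get(uri, "ns")
        prefix = want if want not in taken else _fresh_prefix(want, taken)
        nsmap[uri] = prefix
        taken.add(prefix)
    if MATHML_NS in _collect_uris(root) and MATHML_NS not in nsmap:
        nsmap[MATHML_NS] = None  # sentinel: declared locally on each <math>
    return nsmap


def _fresh_prefix(stem: str, taken: set[str]) -> str:
    i = 2
    while f"{stem}{i}" in taken:
        i += 1
    return f"{stem}{i}"


def _collect_uris(elem: ET.Element) -> set[str]:
    out: set[str] = set()
    for e in elem.iter():
        if isinstance(e.tag, str) and e.tag.startswith("{"):
            out.add(e.tag[1:].split("}", 1)[0])
        for attr in e.attrib:
            if attr.startswith("{"):
                out.add(attr[1:].split("}", 1)[0])
    return out


def _qname(tag: str, nsmap: dict[str, Optional[str]], *, is_attr: bool = False) -> str:
    if not tag.startswith("{"):
        return tag
    uri, local = tag[1:].split("}", 1)
    prefix = nsmap.get(uri)
    if prefix is None:
        raise SbmlParseError(f"no prefix bound for namespace {uri!r}")
    if prefix == "":
        if is_attr:
            raise SbmlParseError(f"attribute in default namespace {uri!r}")
        return local
    return f"{prefix}:{local}"


def _emit(
    elem: ET.Element,
    nsmap: dict[str, Optional[str]],
    buf: list[str],
    indent: int,
    declare: Optional[dict[str, Optional[str]]] = None,
) -> None:
    local_nsmap = nsmap
    extra_decl: list[tuple[str, str]] = []
    if elem.tag == f"{{{MATHML_NS}}}math" and nsmap.get(MATHML_NS) != "":
        # standard SBML style: MathML is the default namespace inside <math>
        local_nsmap = {u: p for u, p in nsmap.items() if p != ""}
        local_nsmap[MATHML_NS] = ""
        extra_decl.append(("", MATHML_NS))
    name = _qname(elem.tag, local_nsmap)
    buf.append(f"<{name}")
    if declare is not None:
        for uri, prefix in sorted(declare.items(), key=lambda kv: (kv[1] or "", kv[0])):
            if prefix is None:
                continue
            attr = "xmlns" if prefix == "" else f"xmlns:{prefix}"
            buf.append(f" {attr}={quoteattr(uri)}")
    for prefix, uri in extra_decl:
        attr = "xmlns" if prefix == "" else f"xmlns:{prefix}"
        buf.append(f" {attr}={quoteattr(uri)}")
    for attr, value in elem.attrib.items():
        buf.append(f" {_qname(attr, local_nsmap, is_attr=True)}={quoteattr(value)}")
    children = list(elem)
    text = elem.text or ""
    if not children and not text.strip():
        buf.append("/>")
        return
    buf.append(">")
    if text:
        buf.append(escape(text))
    for child in children:
        _emit(child, local_nsmap, buf, indent + 1)
        if child.tail:
            buf.append(escape(child.tail))
    buf.append(f"</{name}>")


# -- document construction ---------------------------------------------------

def _q(model: SbmlModel, local: str) -> str:
    return f"{{{sbml_core_namespace(model.level, model.version)}}}{local}"


def _layout(parent: ET.Element, depth: int) -> None:
    """Apply pretty-print whitespace to a constructed element's children,
    leaving the interior of opaque subtrees untouched."""
    children = list(parent)
    if not children:
        return
    pad = "\n" + "  " * depth
    if parent.text is None or not parent.text.strip():
        parent.text = pad + "  "
    for child in children[:-1]:
        child.tail = pad + "  "
    children[-1].tail = pad


def _build_document(model: SbmlModel) -> ET.Element:
    root = ET.Element(_q(model, "sbml"))
    root.set("level", str(model.level))
    root.set("version", str(model.version))
    melem = ET.SubElement(root, _q(model, "model"))
    melem.set("id", model.model_id)
    if model.model_name is not None:
        melem.set("name", model.model_name)
    if model.notes is not None:
        melem.append(copy.deepcopy(model.notes))
    if not model.annotations.is_empty():
        melem.append(copy.deepcopy(model.annotations.raw))
    if model.unit_definitions:
        lst = ET.SubElement(melem, _q(model, "listOfUnitDefinitions"))
        for op in model.unit_definitions:
            lst.append(copy.deepcopy(op.element))
        _layout(lst, 2)
    if model.compartments:
        lst = ET.SubElement(melem, _q(model, "listOfCompartments"))
        for c in model.compartments:
            lst.append(_build_compartment(model, c))
        _layout(lst, 2)
    if model.species:
        lst = ET.SubElement(melem, _q(model, "listOfSpecies"))
        for s in model.species:
            lst.append(_build_species(model, s))
        _layout(lst, 2)
    if model.parameters:
        lst = ET.SubElement(melem, _q(model, "listOfParameters"))
        for p in model.parameters:
            lst.append(_build_parameter(model, p, local=False))
        _layout(lst, 2)
    if model.reactions:
        lst = ET.SubElement(melem, _q(model, "listOfReactions"))
        for r in model.reactions:
            lst.append(_build_reaction(model, r))
        _layout(lst, 2)
    for list_tag in _OPAQUE_LISTS:
        members = [o for o in model.other_elements if o.list_tag == list_tag]
        if members:
            lst = ET.SubElement(melem, _q(model, list_tag))
            for op in members:
                lst.append(copy.deepcopy(op.element))
            _layout(lst, 2)
    _layout(melem, 1)
    _layout(root, 0)
    return root


def _attach_blocks(elem: ET.Element, ann: AnnotationBlock, notes: Optional[ET.Element]) -> None:
    if notes is not None:
        elem.append(copy.deepcopy(notes))
    if not ann.is_empty():
        elem.append(copy.deepcopy(ann.raw))


def _build_compartment(model: SbmlModel, c: Compartment) -> ET.Element:
    e = ET.Element(_q(model, "compartment"))
    e.set("id", c.id)
    if c.name is not None:
        e.set("name", c.name)
    if c.size is not None:
        e.set("size", format_number(c.size))
    if c.units is not None:
        e.set("units", c.units)
    if c.constant is not None:
        e.set("constant", "true" if c.constant else "false")
    if c.sbo_term is not None:
        e.set("sboTerm", c.sbo_term)
    _attach_blocks(e, c.annotations, c.notes)
    _layout(e, 3)
    return e


def _build_species(model: SbmlModel, s: Species) -> ET.Element:
    e = ET.Element(_q(model, "species"))
    e.set("id", s.id)
    if s.name is not None:
        e.set("name", s.name)
    e.set("compartment", s.compartment)
    if s.initial_value is not None:
        attr = "initialAmount" if s.initial_kind == "amount" else "initialConcentration"
        e.set(attr, format_number(s.initial_value))
    if s.substance_units is not None:
        e.set("substanceUnits", s.substance_units)
    if s.boundary_condition or model.level == 3:
        e.set("boundaryCondition", "true" if s.boundary_condition else "false")
    if s.constant or model.level == 3:
        e.set("constant", "true" if s.constant else "false")
    if s.has_only_substance_units or model.level == 3:
        e.set("hasOnlySubstanceUnits", "true" if s.has_only_substance_units else "false")
    if s.sbo_term is not None:
        e.set("sboTerm", s.sbo_term)
    _attach_blocks(e, s.annotations, s.notes)
    _layout(e, 3)
    return e


def _build_parameter(model: SbmlModel, p: Parameter, *, local: bool) -> ET.Element:
    tag = "localParameter" if (local and model.level == 3) else "parameter"
    e = ET.Element(_q(model, tag))
    e.set("id", p.id)
    if p.name is not None:
        e.set("name", p.name)
    if p.value is not None:
        e.set("value", format_number(p.value))
    if p.units is not None:
        e.set("units", p.units)
    if p.constant is not None and not local:
        e.set("constant", "true" if p.constant else "false")
    if p.sbo_term is not None:
        e.set("sboTerm", p.sbo_term)
    if not p.annotations.is_empty():
        e.append(copy.deepcopy(p.annotations.raw))
        _layout(e, 4)
    return e


def _build_species_ref(model: SbmlModel, ref: SpeciesRef) -> ET.Element:
    e = ET.Element(_q(model, "speciesReference"))
    e.set("species", ref.species)
    if ref.stoichiometry != 1.0 or model.level == 3:
        e.set("stoichiometry", format_number(ref.stoichiometry))
    if model.level == 3:
        e.set("constant", "true")
    return e


def _build_reaction(model: SbmlModel, r: Reaction) -> ET.Element:
    e = ET.Element(_q(model, "reaction"))
    e.set("id", r.id)
    if r.name is not None:
        e.set("name", r.name)
    e.set("reversible", "true" if r.reversible else "false")
    if model.level == 3 and model.version == 1:
        e.set("fast", "false")  # required attribute in L3V1
    if r.sbo_term is not None:
        e.set("sboTerm", r.sbo_term)
    _attach_blocks(e, r.annotations, r.notes)
    if r.reactants:
        lst = ET.SubElement(e, _q(model, "listOfReactants"))
        for ref in r.reactants:
            lst.append(_build_species_ref(model, ref))
        _layout(lst, 4)
    if r.products:
        lst = ET.SubElement(e, _q(model, "listOfProducts"))
        for ref in r.products:
            lst.append(_build_species_ref(model, ref))
        _layout(lst, 4)
    if r.modifiers:
        lst = ET.SubElement(e, _q(model, "listOfModifiers"))
        for m in r.modifiers:
            mr = ET.SubElement(lst, _q(model, "modifierSpeciesReference"))
            mr.set("species", m)
        _layout(lst, 4)
    if r.kinetic_math is not None or r.local_parameters:
        kl = ET.SubElement(e, _q(model, "kineticLaw"))
        if r.kinetic_math is not None:
            kl.append(to_element(r.kinetic_math))
        if r.local_parameters:
            tag = "listOfLocalParameters" if model.level == 3 else "listOfParameters"
            lst = ET.SubElement(kl, _q(model, tag))
            for p in r.local_parameters:
                lst.append(_build_parameter(model, p, local=True))
            _layout(lst, 5)
        _layout(kl, 4)
    _layout(e, 3)
    return e
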