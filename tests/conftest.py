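import xml.etree.ElementTree as ET

import pytest

from sbmlfuse.mathexpr import Apply, Num, Sym
from sbmlfuse.model import (
    AnnotationBlock,
    Compartment,
    Reaction,
    SbmlModel,
    Species,
    SpeciesRef,
)
from sbmlfuse.modelgen import parse_scheme, scheme_to_model, worked_example_pair
from sbmlfuse.sbmlio import sbml_core_namespace

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL = "http://biomodels.net/biology-qualifiers/"


def annotation_block(resources, qualifier="is") -> AnnotationBlock:
    """Minimal RDF annotation carrying the given resource URIs."""
    lis = "".join(f'<rdf:li rdf:resource="{r}"/>' for r in resources)
    xml = (
        f'<annotation><rdf:RDF xmlns:rdf="{RDF}" xmlns:bqbiol="{BQBIOL}">'
        f'<rdf:Description rdf:about="#meta"><bqbiol:{qualifier}><rdf:Bag>'
        f"{lis}</rdf:Bag></bqbiol:{qualifier}></rdf:Description></rdf:RDF></annotation>"
    )
    return AnnotationBlock(ET.fromstring(xml))


def bare_model(model_id="m", species_names=(), compartment="c") -> SbmlModel:
    """One compartment and a list of plainly named species; no reactions."""
    m = SbmlModel(
        model_id=model_id, namespaces={("", sbml_core_namespace(2, 4))}
    )
    m.compartments.append(Compartment(id=compartment, size=1.0))
    for sid in species_names:
        m.species.append(
            Species(id=sid, compartment=compartment, initial_value=1.0)
        )
    return m


def conflict_base(model_id="mA") -> SbmlModel:
    """Parameter-free one-reaction model used for engineered-conflict
    fixtures: identical copies compose with zero warnings."""
    m = bare_model(model_id, ["S1", "S2"])
    m.reactions.append(
        Reaction(
            id="reaction1",
            name="reaction1",
            reversible=False,
            reactants=[SpeciesRef("S1")],
            products=[SpeciesRef("S2")],
            kinetic_math=Apply("times", (Num(2.0), Sym("c"), Sym("S1"))),
        )
    )
    return m


@pytest.fixture
def worked_pair():
    return worked_example_pair()


@pytest.fixture
def decay_model():
    return scheme_to_model(parse_scheme("S1 -> S2"), "decay", {"k1": 1.0})


@pytest.fixture
def enzyme_model():
    return scheme_to_model(
        parse_scheme("E+S <-> ES, ES -> E+P"),
        "enzyme",
        {"k1": 2.0, "k1r": 1.0, "k2": 1.5},
    )
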