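"""MIRIAM annotation extraction and annotation-based identity.

Resource references are read from RDF blocks embedded in SBML
``<annotation>`` elements and normalized so that the URN form
(``urn:miriam:obo.chebi:CHEBI%3A17234``) and the identifiers.org URL form
(``http://identifiers.org/chebi/CHEBI:17234``) of the same entity compare
equal.  No network access; unparseable RDF degrades to "no annotation"
with a logged warning, never an error.
"""

from __future__ import annotations

import logging
import urllib.parse
import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .model import AnnotationBlock

logger = logging.getLogger(__name__)

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BIOLOGY_QUALIFIER_NS = "http://biomodels.net/biology-qualifiers/"
MODEL_QUALIFIER_NS = "http://biomodels.net/model-qualifiers/"

#: legacy registry names folded onto their current spelling
COLLECTION_ALIASES = {
    "obo.chebi": "chebi",
    "obo.go": "go",
    "obo.bto": "bto",
    "obo.sbo": "sbo",
    "kegg.orthology": "kegg.orthology",
    "ec-code": "ec-code",
    "ec": "ec-code",
    "uniprotkb": "uniprot",
}

#: qualifiers that certify identity in strict mode
STRICT_QUALIFIERS = frozenset({"is"})
#: additionally accepted in lenient mode
LENIENT_QUALIFIERS = frozenset({"is", "isVersionOf", "hasVersion"})


@dataclass(frozen=True)
class MiriamKey:
    qualifier: str  # e.g. "is", "isVersionOf"
    collection: str  # lowercase registry name, e.g. "chebi"
    identifier: str  # case-sensitive entity id, e.g. "CHEBI:17234"


def normalize_resource(qualifier: str, resource: str) -> MiriamKey | None:
    """Turn one ``rdf:resource`` URI into a normalized key, or None when
    the URI is in neither supported syntax."""
    resource = resource.strip()
    if resource.startswith("urn:miriam:"):
        rest = resource[len("urn:miriam:"):]
        collection, _, identifier = rest.partition(":")
        if not collection or not identifier:
            return None
        identifier = urllib.parse.unquote(identifier)
    else:
        parsed = urllib.parse.urlparse(resource)
        if parsed.netloc.lower() not in ("identifiers.org", "www.identifiers.org"):
            return None
        path = urllib.parse.unquote(parsed.path).strip("/")
        if "/" in path:
            collection, _, identifier = path.partition("/")
        elif ":" in path:  # compact identifiers.org form collection:id
            collection, _, identifier = path.partition(":")
        else:
            return None
        if not collection or not identifier:
            return None
    collection = collection.lower()
    collection = COLLECTION_ALIASES.get(collection, collection)
    return MiriamKey(qualifier=qualifier, collection=collection, identifier=identifier)


def normalize_key(key: MiriamKey) -> MiriamKey:
    """Idempotent normalization of an already-built key."""
    collection = key.collection.lower()
    return MiriamKey(
        qualifier=key.qualifier,
        collection=COLLECTION_ALIASES.get(collection, collection),
        identifier=key.identifier,
    )


def extract_miriam(block: AnnotationBlock) -> frozenset[MiriamKey]:
    """All normalized MIRIAM keys found under RDF description qualifiers
    inside the annotation block; empty set when there is no annotation or
    the RDF is unusable."""
    if block.is_empty():
        return frozenset()
    try:
        keys: set[MiriamKey] = set()
        for rdf in block.raw.iter(f"{{{RDF_NS}}}RDF"):
            for desc in rdf.iter(f"{{{RDF_NS}}}Description"):
                for child in desc:
                    if not isinstance(child.tag, str) or not child.tag.startswith("{"):
                        continue
                    ns, qualifier = child.tag[1:].split("}", 1)
                    if ns not in (BIOLOGY_QUALIFIER_NS, MODEL_QUALIFIER_NS):
                        continue
                    for li in child.iter(f"{{{RDF_NS}}}li"):
                        resource = li.get(f"{{{RDF_NS}}}resource")
                        if resource is None:
                            continue
                        key = normalize_resource(qualifier, resource)
                        if key is not None:
                            keys.add(key)
        return frozenset(keys)
    except (ET.ParseError, ValueError) as exc:  # pragma: no cover - defensive
        logger.warning("ignoring unparseable RDF annotation: %s", exc)
        return frozenset()


def identity_keys(block: AnnotationBlock, mode: str = "strict") -> frozenset[tuple[str, str]]:
    """(collection, identifier) pairs carried under identity qualifiers."""
    qualifiers = STRICT_QUALIFIERS if mode == "strict" else LENIENT_QUALIFIERS
    return frozenset(
        (k.collection, k.identifier)
        for k in extract_miriam(block)
        if k.qualifier in qualifiers
    )


def shared_annotation(a: AnnotationBlock, b: AnnotationBlock, mode: str = "strict") -> bool:
    """True iff the two blocks share at least one identity-qualified
    resource.  Two empty annotations never match (absence of evidence)."""
    if mode == "strict":
        # strict: both sides must assert identity with the *same* qualifier set
        keys_a = {(k.collection, k.identifier) for k in extract_miriam(a) if k.qualifier in STRICT_QUALIFIERS}
        keys_b = {(k.collection, k.identifier) for k in extract_miriam(b) if k.qualifier in STRICT_QUALIFIERS}
    else:
        keys_a = identity_keys(a, mode)
        keys_b = identity_keys(b, mode)
    return bool(keys_a & keys_b)
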