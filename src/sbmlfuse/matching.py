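"""Similarity indices and one-to-one element matching between two models.

Matching order is fixed — compartments, then species, then reactions —
because species identity depends on compartment correspondence and
reaction identity on species correspondence.  Manual pairs always win;
automatic pairing is greedy in model-1 document order, taking the first
unclaimed eligible model-2 candidate in document order, which makes the
outcome deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .annotations import shared_annotation
from .model import Reaction, SbmlModel, effective_name


class MatchError(ValueError):
    """Invalid match table (unknown id or one-to-one violation)."""


PROVENANCE_MANUAL = "manual"
PROVENANCE_NAME = "auto-name"
PROVENANCE_ANNOTATION = "auto-annotation"


@dataclass(frozen=True)
class MatchPair:
    id1: str
    id2: str
    provenance: str = PROVENANCE_MANUAL


@dataclass
class MatchTable:
    compartments: list[MatchPair] = field(default_factory=list)
    species: list[MatchPair] = field(default_factory=list)
    reactions: list[MatchPair] = field(default_factory=list)

    def pairs(self, element_class: str) -> list[MatchPair]:
        return getattr(self, element_class)

    def mapping2to1(self, element_class: str) -> dict[str, str]:
        return {p.id2: p.id1 for p in self.pairs(element_class)}

    def to_dict(self) -> dict:
        return {
            cls: [[p.id1, p.id2] for p in self.pairs(cls)]
            for cls in ("compartments", "species", "reactions")
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MatchTable":
        table = cls()
        for key in ("compartments", "species", "reactions"):
            for entry in data.get(key, []):
                id1, id2 = entry
                table.pairs(key).append(MatchPair(id1, id2, PROVENANCE_MANUAL))
        return table


@dataclass
class ClassSimilarity:
    percentage: float
    matched_names: list[str]
    n1: int
    n2: int
    n_matched: int


@dataclass
class SimilarityReport:
    compartments: ClassSimilarity
    species: ClassSimilarity
    reactions: ClassSimilarity

    def to_dict(self) -> dict:
        return {
            cls: {
                "percentage": sim.percentage,
                "matchedNames": sim.matched_names,
                "counts": [sim.n1, sim.n2, sim.n_matched],
            }
            for cls, sim in (
                ("compartments", self.compartments),
                ("species", self.species),
                ("reactions", self.reactions),
            )
        }


def _class_similarity(elems1, elems2, formula: str) -> ClassSimilarity:
    names1 = [effective_name(e) for e in elems1]
    names2 = [effective_name(e) for e in elems2]
    matched = [n for n in dict.fromkeys(names1) if n in set(names2)]
    n1, n2, nm = len(elems1), len(elems2), len(matched)
    if formula == "min":
        pct = 100.0 * nm / min(n1, n2) if min(n1, n2) else 0.0
    else:  # Dice coefficient: symmetric and bounded by construction
        pct = 100.0 * 2.0 * nm / (n1 + n2) if (n1 + n2) else 0.0
    return ClassSimilarity(pct, matched, n1, n2, nm)


def similarity_report(
    m1: SbmlModel, m2: SbmlModel, formula: str = "dice"
) -> SimilarityReport:
    """Exact, case-sensitive effective-name overlap per element class,
    expressed as a percentage."""
    return SimilarityReport(
        compartments=_class_similarity(m1.compartments, m2.compartments, formula),
        species=_class_similarity(m1.species, m2.species, formula),
        reactions=_class_similarity(m1.reactions, m2.reactions, formula),
    )


# ---------------------------------------------------------------------------
# match-table validation

def validate_match_table(table: MatchTable, m1: SbmlModel, m2: SbmlModel) -> None:
    """One-to-one within each class, all ids resolvable."""
    universes = {
        "compartments": ({c.id for c in m1.compartments}, {c.id for c in m2.compartments}),
        "species": ({s.id for s in m1.species}, {s.id for s in m2.species}),
        "reactions": ({r.id for r in m1.reactions}, {r.id for r in m2.reactions}),
    }
    for cls, (ids1, ids2) in universes.items():
        used1: dict[str, MatchPair] = {}
        used2: dict[str, MatchPair] = {}
        for pair in table.pairs(cls):
            if pair.id1 not in ids1:
                raise MatchError(f"{cls}: id {pair.id1!r} not found in model 1")
            if pair.id2 not in ids2:
                raise MatchError(f"{cls}: id {pair.id2!r} not found in model 2")
            if pair.id1 in used1:
                raise MatchError(
                    f"{cls}: model-1 id {pair.id1!r} used by both "
                    f"{_fmt(used1[pair.id1])} and {_fmt(pair)} (one-to-one violated)"
                )
            if pair.id2 in used2:
                raise MatchError(
                    f"{cls}: model-2 id {pair.id2!r} used by both "
                    f"{_fmt(used2[pair.id2])} and {_fmt(pair)} (one-to-one violated)"
                )
            used1[pair.id1] = pair
            used2[pair.id2] = pair


def _fmt(pair: MatchPair) -> str:
    return f"({pair.id1} <-> {pair.id2})"


# ---------------------------------------------------------------------------
# automatic matching

def _greedy_match(elems1, elems2, eligible, manual_pairs, provenance_of):
    """Greedy one-to-one pairing honoring manual pairs verbatim.

    ``eligible(e1, e2)`` decides candidate pairs; ties break by model-1
    document order then first unclaimed model-2 candidate.
    """
    pairs = list(manual_pairs)
    claimed1 = {p.id1 for p in manual_pairs}
    claimed2 = {p.id2 for p in manual_pairs}
    for e1 in elems1:
        if e1.id in claimed1:
            continue
        for e2 in elems2:
            if e2.id in claimed2:
                continue
            if eligible(e1, e2):
                pairs.append(MatchPair(e1.id, e2.id, provenance_of(e1, e2)))
                claimed1.add(e1.id)
                claimed2.add(e2.id)
                break
    return pairs


def auto_match_compartments(
    m1: SbmlModel, m2: SbmlModel, manual: MatchTable | None = None, mode: str = "strict"
) -> list[MatchPair]:
    manual_pairs = manual.compartments if manual else []

    def eligible(c1, c2):
        return effective_name(c1) == effective_name(c2) or shared_annotation(
            c1.annotations, c2.annotations, mode
        )

    def provenance(c1, c2):
        if shared_annotation(c1.annotations, c2.annotations, mode):
            return PROVENANCE_ANNOTATION
        return PROVENANCE_NAME

    return _greedy_match(m1.compartments, m2.compartments, eligible, manual_pairs, provenance)


def auto_match_species(
    m1: SbmlModel,
    m2: SbmlModel,
    compartment_pairs: list[MatchPair],
    manual: MatchTable | None = None,
    mode: str = "strict",
) -> list[MatchPair]:
    manual_pairs = manual.species if manual else []
    comp_map = {p.id2: p.id1 for p in compartment_pairs}

    def compartments_correspond(s1, s2):
        return s1.compartment == comp_map.get(s2.compartment, s2.compartment)

    def eligible(s1, s2):
        if shared_annotation(s1.annotations, s2.annotations, mode):
            return True
        return effective_name(s1) == effective_name(s2) and compartments_correspond(s1, s2)

    def provenance(s1, s2):
        if shared_annotation(s1.annotations, s2.annotations, mode):
            return PROVENANCE_ANNOTATION
        return PROVENANCE_NAME

    return _greedy_match(m1.species, m2.species, eligible, manual_pairs, provenance)


def _ref_multiset(refs, species_map) -> Counter:
    # identity of the referenced species only; stoichiometry conflicts are
    # the composer's business (surfaced as warnings, not match blockers)
    return Counter(species_map.get(r.species, r.species) for r in refs)


def auto_match_reactions(
    m1: SbmlModel,
    m2: SbmlModel,
    species_pairs: list[MatchPair],
    manual: MatchTable | None = None,
    mode: str = "strict",
) -> list[MatchPair]:
    manual_pairs = manual.reactions if manual else []
    species_map = {p.id2: p.id1 for p in species_pairs}
    identity = {}

    def eligible(r1: Reaction, r2: Reaction):
        named = effective_name(r1) == effective_name(r2) or shared_annotation(
            r1.annotations, r2.annotations, mode
        )
        if not named:
            return False
        return _ref_multiset(r1.reactants, identity) == _ref_multiset(
            r2.reactants, species_map
        ) and _ref_multiset(r1.products, identity) == _ref_multiset(r2.products, species_map)

    def provenance(r1, r2):
        if shared_annotation(r1.annotations, r2.annotations, mode):
            return PROVENANCE_ANNOTATION
        return PROVENANCE_NAME

    return _greedy_match(m1.reactions, m2.reactions, eligible, manual_pairs, provenance)


def build_match_table(
    m1: SbmlModel,
    m2: SbmlModel,
    manual: MatchTable | None = None,
    mode: str = "strict",
) -> MatchTable:
    """Full matching pipeline: validate manual pairs, then auto-match
    compartments, species and reactions in that order."""
    if manual is not None:
        validate_match_table(manual, m1, m2)
    table = MatchTable()
    table.compartments = auto_match_compartments(m1, m2, manual, mode)
    table.species = auto_match_species(m1, m2, table.compartments, manual, mode)
    table.reactions = auto_match_reactions(m1, m2, table.species, manual, mode)
    validate_match_table(table, m1, m2)
    return table
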