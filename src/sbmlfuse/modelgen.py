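"""Generation of small test-suite-style SBML models from reaction schemes.

A scheme is a comma-separated list of reactions written as
``2S1+S2 -> S3`` (irreversible) or ``S1 <-> S2`` (reversible) with
optional decimal stoichiometric coefficients (``S1 -> 0.3S2``).  Species
labelled ``X0``/``X1`` act as boundary species (external source/sink
pools).  Every generated model gets one unit compartment, unit initial
concentrations and mass-action kinetics with global rate constants, so
trajectories have simple closed-form or conservation checks.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from .mathexpr import Apply, MathExpr, Num, Sym
from .model import Compartment, Parameter, Reaction, SbmlModel, Species, SpeciesRef
from .sbmlio import sbml_core_namespace

#: the forty reaction-scheme groups used for fixture generation
GROUP_SCHEMES: dict[int, str] = {
    1: "S1 -> S2",
    2: "S1 -> S2, S2 -> S1",
    3: "S1 -> 2S2",
    4: "S1 -> 2S2, 2S2 -> S1",
    5: "S1+S2 -> S3, S3 -> S1+S2",
    6: "2S1+S2 -> S3, S3 -> 2S1+S2",
    7: "S1+S2 -> S3+S4, S3+S4 -> S1+S2",
    8: "S1+S2 -> S3+2S4, S3+S4 -> S1+S2",
    9: "S1 -> S2, S2 -> S1, S2 -> S3+S4, S3+S4 -> S2",
    10: "S1+S2 -> S3, S3 -> S1+S2, S3 -> S1+S4",
    11: "S1 -> S2, S2 -> S3, S3 -> S4",
    12: "S1 -> 0.3S2, 0.7S2 -> S1",
    13: "S1+S2 -> 2S2, S2 -> S3",
    14: "S1+S2 -> 2S2, S2 -> S3, S3+S4 -> 2S4",
    15: "S1 -> S3, S3 -> S1",
    16: "S1 -> S3, S3 -> S2",
    17: "S1+S2 -> S3, S3 -> 2S1+S2",
    18: "2S1 -> S2",
    19: "S1+2S2 -> S3, S3 -> S1+S2",
    20: "S1+S2 -> 2S3+S4, 2S3+S4 -> S1+S2",
    21: "S1+S2 -> S3+S4, 2S3+S4 -> S1+S2",
    22: "S1 -> S2, S2 -> S3, S3 -> S1",
    23: "S1+S2 -> 2S3, S3 -> S1+S2",
    24: "X0 -> T, T -> X1",
    25: "X0 -> 2T, T -> X1",
    26: "2X0 -> T, T -> X1",
    27: "S1+S2 -> S3, 2S3 -> S1+S2",
    28: "2S1 -> S3, S3 -> S1",
    29: "S1+S2 -> S3, S3 -> S1+2S2",
    30: "S1+S2+S3 -> S4",
    31: "S1 <-> S2",
    32: "S1+S2 <-> S3",
    33: "S1 <-> S2+S3",
    34: "S1 <-> 2S2",
    35: "S1+2S2 <-> S3",
    36: "S1 <-> S2+2S3",
    37: "S1 <-> S2, S3 <-> S4",
    38: "A4 <-> A2, A1+A2 <-> A3",
    39: "A4 -> A2, A1+A2 -> A3",
    40: "S1 -> S2, 2S2 -> S3, S3 -> S4",
}

#: labels treated as boundary (environment-fixed) species
BOUNDARY_LABELS = frozenset({"X0", "X1"})


class SchemeParseError(ValueError):
    """Malformed reaction-scheme text; message carries the position."""


@dataclass(frozen=True)
class SchemeReaction:
    reactants: tuple[tuple[str, float], ...]  # (label, stoichiometry)
    products: tuple[tuple[str, float], ...]
    reversible: bool = False


@dataclass
class ReactionScheme:
    reactions: list[SchemeReaction] = field(default_factory=list)
    species_labels: list[str] = field(default_factory=list)  # first-appearance order

    @property
    def boundary_labels(self) -> set[str]:
        return {s for s in self.species_labels if s in BOUNDARY_LABELS}


_TERM_RE = re.compile(r"^\s*(\d+(?:\.\d+)?|\.\d+)?\s*([A-Za-z_][A-Za-z0-9_]*)\s*$")


def _parse_side(text: str, rxn_index: int, side: str) -> tuple[tuple[str, float], ...]:
    terms = []
    for pos, raw in enumerate(text.split("+")):
        m = _TERM_RE.match(raw)
        if m is None:
            raise SchemeParseError(
                f"reaction {rxn_index + 1}, {side} term {pos + 1}: cannot parse {raw.strip()!r}"
            )
        coeff = float(m.group(1)) if m.group(1) else 1.0
        if coeff <= 0:
            raise SchemeParseError(
                f"reaction {rxn_index + 1}, {side} term {pos + 1}: coefficient must be positive"
            )
        terms.append((m.group(2), coeff))
    return tuple(terms)


def parse_scheme(text: str) -> ReactionScheme:
    """Parse ``"S1+S2 -> S3+S4, 2S3+S4 -> S1+S2"`` style scheme strings.

    Unicode arrows from printed tables are accepted as synonyms of ``->``
    and ``<->``.
    """
    text = text.replace("↔", "<->").replace("⇆", "<->").replace("→", "->")
    scheme = ReactionScheme()
    seen: dict[str, None] = {}
    chunks = [c for c in text.split(",") if c.strip()]
    if not chunks:
        return scheme
    for i, chunk in enumerate(chunks):
        if "<->" in chunk:
            left, _, right = chunk.partition("<->")
            reversible = True
        elif "->" in chunk:
            left, _, right = chunk.partition("->")
            reversible = False
        else:
            raise SchemeParseError(f"reaction {i + 1}: missing '->' or '<->' in {chunk.strip()!r}")
        if "->" in right:
            raise SchemeParseError(f"reaction {i + 1}: more than one arrow in {chunk.strip()!r}")
        reactants = _parse_side(left, i, "reactant")
        products = _parse_side(right, i, "product")
        scheme.reactions.append(SchemeReaction(reactants, products, reversible))
        for label, _ in (*reactants, *products):
            seen.setdefault(label)
    scheme.species_labels = list(seen)
    return scheme


def render_scheme(scheme: ReactionScheme) -> str:
    """Canonical textual form; ``parse_scheme(render_scheme(s))`` is the
    identity on canonical strings."""

    def side(terms):
        parts = []
        for label, coeff in terms:
            if coeff == 1.0:
                parts.append(label)
            elif coeff == int(coeff):
                parts.append(f"{int(coeff)}{label}")
            else:
                parts.append(f"{coeff}{label}")
        return "+".join(parts)

    return ", ".join(
        f"{side(r.reactants)} {'<->' if r.reversible else '->'} {side(r.products)}"
        for r in scheme.reactions
    )


# ---------------------------------------------------------------------------
# model construction

def _mass_action_product(k: str, terms) -> MathExpr:
    factors: list[MathExpr] = [Sym(k), Sym("compartment")]
    for label, coeff in terms:
        if coeff == 1.0:
            factors.append(Sym(label))
        else:
            factors.append(Apply("power", (Sym(label), Num(coeff))))
    return Apply("times", tuple(factors))


def rate_parameter_names(scheme: ReactionScheme) -> list[str]:
    """Global rate-constant ids, in document order: ``k1``, ``k2``, ...;
    a reversible reaction i additionally owns ``k<i>r``."""
    names = []
    for i, rxn in enumerate(scheme.reactions, start=1):
        names.append(f"k{i}")
        if rxn.reversible:
            names.append(f"k{i}r")
    return names


def scheme_to_model(
    scheme: ReactionScheme,
    model_id: str,
    rate_constants: dict[str, float] | None = None,
    seed: int | None = None,
) -> SbmlModel:
    """Build a Level 2 Version 4 model with one unit compartment, unit
    initial concentrations, mass-action kinetics and global parameters.

    ``rate_constants`` supplies values per parameter name; missing names
    are drawn uniformly from [0.1, 10] when ``seed`` is given, else 1.0.
    """
    rng = random.Random(seed) if seed is not None else None
    constants = dict(rate_constants or {})
    for name in rate_parameter_names(scheme):
        if name not in constants:
            constants[name] = round(rng.uniform(0.1, 10.0), 6) if rng else 1.0

    model = SbmlModel(
        level=2,
        version=4,
        model_id=model_id,
        namespaces={("", sbml_core_namespace(2, 4))},
    )
    model.compartments.append(Compartment(id="compartment", size=1.0))
    for label in scheme.species_labels:
        model.species.append(
            Species(
                id=label,
                compartment="compartment",
                initial_kind="concentration",
                initial_value=1.0,
                boundary_condition=label in BOUNDARY_LABELS,
            )
        )
    for name in rate_parameter_names(scheme):
        model.parameters.append(Parameter(id=name, value=constants[name], constant=True))
    for i, rxn in enumerate(scheme.reactions, start=1):
        forward = _mass_action_product(f"k{i}", rxn.reactants)
        if rxn.reversible:
            backward = _mass_action_product(f"k{i}r", rxn.products)
            law: MathExpr = Apply("minus", (forward, backward))
        else:
            law = forward
        model.reactions.append(
            Reaction(
                id=f"reaction{i}",
                name=f"reaction{i}",
                reversible=rxn.reversible,
                reactants=[SpeciesRef(label, coeff) for label, coeff in rxn.reactants],
                products=[SpeciesRef(label, coeff) for label, coeff in rxn.products],
                kinetic_math=law,
            )
        )
    return model


def group_model(
    group: int,
    model_id: str | None = None,
    rate_constants: dict[str, float] | None = None,
    seed: int | None = None,
) -> SbmlModel:
    """Model for one of the 40 scheme groups; default id ``case000NN``."""
    if group not in GROUP_SCHEMES:
        raise KeyError(f"unknown reaction group {group} (valid: 1..40)")
    scheme = parse_scheme(GROUP_SCHEMES[group])
    return scheme_to_model(
        scheme, model_id or f"case{group:05d}", rate_constants, seed
    )


def worked_example_pair() -> tuple[SbmlModel, SbmlModel]:
    """The fixture pair whose composition exercises every structural rule:
    reactions share names but differ in reactant/product lists (so none
    merge and model-2 reactions get the ``case00020_`` prefix), species
    S1/S3 are shared (merged), and both models carry global k1/k2 (which
    never merge, so model-2's become case00020_k1/case00020_k2)."""
    m15 = scheme_to_model(
        parse_scheme("S1 -> S3, S3 -> S1"),
        "case00015",
        rate_constants={"k1": 1.0, "k2": 0.5},
    )
    m20 = scheme_to_model(
        parse_scheme("S1 -> S2, S3 -> S4"),
        "case00020",
        rate_constants={"k1": 0.8, "k2": 0.3},
    )
    return m15, m20


def random_pair(seed: int) -> tuple[SbmlModel, SbmlModel]:
    """Two models from two distinct scheme groups, deterministically
    derived from the seed."""
    rng = random.Random(seed)
    g1, g2 = rng.sample(sorted(GROUP_SCHEMES), 2)
    m1 = group_model(g1, seed=rng.randrange(2**31))
    m2 = group_model(g2, seed=rng.randrange(2**31))
    return m1, m2
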