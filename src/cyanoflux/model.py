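"""In-memory representation of a compartmented stoichiometric network.

The container mirrors the structure of a genome-scale metabolic
reconstruction: metabolites carry a compartment, an elemental formula and a
charge; reactions carry a stoichiometry (negative coefficients consume),
flux bounds, an optional GPR rule and a kind tag (metabolic / transport /
exchange / biomass).  Infinite bounds are normalised to a conventional
big-M of ±1000 flux units on construction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

from .gpr import GPRExpression, genes_of

#: Conventional finite stand-in for an unbounded flux (mmol/gDW/h scale).
BIG_M = 1000.0

REACTION_KINDS = ("metabolic", "transport", "exchange", "biomass")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Element symbols accepted in formulas; wildcards like R/X/Z used for
#: polymeric or generic residues are rejected so they surface as unparseable.
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os "
    "Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U".split()
)


class ModelValidationError(ValueError):
    pass


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation elemental formula like ``C6H12O6`` into counts.

    Raises ``ValueError`` on text that is not a plain element/count sequence
    (polymeric formulas with ``(...)n`` groups, wildcards such as ``R`` or
    ``X`` are rejected so the balance checker can flag them as unparseable).
    """
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    counts: Dict[str, int] = {}
    while pos < len(formula):
        m = _FORMULA_RE.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"unparseable formula {formula!r}")
        element = m.group(1)
        if element not in _ELEMENTS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        count = int(m.group(2)) if m.group(2) else 1
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return counts


def format_formula(counts: Dict[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    elements = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(
        f"{e}{counts[e]}" if counts[e] != 1 else e for e in elements if counts[e]
    )


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None

    @property
    def balanceable(self) -> bool:
        return self.formula is not None and self.charge is not None


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -BIG_M
    upper_bound: float = BIG_M
    gpr: Optional[GPRExpression] = None
    kind: str = "metabolic"
    name: str = ""

    def __post_init__(self):
        self.lower_bound = _clamp(self.lower_bound)
        self.upper_bound = _clamp(self.upper_bound)
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(
                f"reaction {self.id}: unknown kind {self.kind!r}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def gpr_string(self) -> str:
        return str(self.gpr) if self.gpr is not None else ""


def _clamp(bound: float) -> float:
    if math.isinf(bound):
        return BIG_M if bound > 0 else -BIG_M
    return float(bound)


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    compartments: Set[str] = field(default_factory=set)
    biomass_reactions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._index()

    def _index(self):
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions:
            out |= genes_of(r.gpr)
        return out

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    # -- editing -----------------------------------------------------------
    def add_metabolite(self, met: Metabolite):
        if met.id in self._met_index:
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        self.metabolites.append(met)
        self._met_index[met.id] = met
        if met.compartment:
            self.compartments.add(met.compartment)

    def add_reaction(self, rxn: Reaction):
        if rxn.id in self._rxn_index:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ModelValidationError(
                    f"reaction {rxn.id} references undeclared metabolite {met_id}"
                )
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str):
        rxn = self._rxn_index.pop(rxn_id)
        self.reactions.remove(rxn)

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- validation --------------------------------------------------------
    def validate(self):
        """Check structural invariants; raise ModelValidationError on the first hit."""
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id}")
            seen.add(m.id)
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelValidationError(f"duplicate reaction id {r.id}")
            seen.add(r.id)
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id} references undeclared metabolite {met_id}"
                    )
            if r.kind == "exchange" and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {r.id} must touch exactly one metabolite"
                )
        for label, rxn_id in self.biomass_reactions.items():
            if rxn_id not in self._rxn_index:
                raise ModelValidationError(
                    f"biomass reaction {rxn_id!r} for scenario {label!r} not in model"
                )


@dataclass
class ModelComparison:
    """Id-level partition of two models' reactions and metabolites (Venn counts)."""

    shared_reaction_ids: Set[str]
    unique_to_a_reactions: Set[str]
    unique_to_b_reactions: Set[str]
    shared_metabolite_ids: Set[str]
    unique_to_a_metabolites: Set[str]
    unique_to_b_metabolites: Set[str]

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "shared_reactions": len(self.shared_reaction_ids),
            "unique_to_a_reactions": len(self.unique_to_a_reactions),
            "unique_to_b_reactions": len(self.unique_to_b_reactions),
            "shared_metabolites": len(self.shared_metabolite_ids),
            "unique_to_a_metabolites": len(self.unique_to_a_metabolites),
            "unique_to_b_metabolites": len(self.unique_to_b_metabolites),
        }


def compare_models(a: MetabolicModel, b: MetabolicModel) -> ModelComparison:
    """Partition reaction and metabolite ids of two models by exact-id matching.

    Both cyanobacterial reconstructions follow one naming convention, so a
    shared id means a shared reaction; no fuzzy matching is attempted.
    """
    ra, rb = set(a.reaction_ids), set(b.reaction_ids)
    ma, mb = set(a.metabolite_ids), set(b.metabolite_ids)
    return ModelComparison(
        shared_reaction_ids=ra & rb,
        unique_to_a_reactions=ra - rb,
        unique_to_b_reactions=rb - ra,
        shared_metabolite_ids=ma & mb,
        unique_to_a_metabolites=ma - mb,
        unique_to_b_metabolites=mb - ma,
    )


def infer_reaction_kind(rxn: Reaction, model: MetabolicModel) -> str:
    """Heuristic kind tag for reactions read from files that do not carry one."""
    if len(rxn.stoichiometry) == 1:
        return "exchange"
    compartments = {
        model.metabolite(m).compartment for m in rxn.stoichiometry
    }
    if len(compartments) > 1:
        return "transport"
    return "metabolic"
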