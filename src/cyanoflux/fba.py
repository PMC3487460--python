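"""Steady-state flux analysis: FBA, diurnal constraints, knockouts, FVA, yields.

The linear program is the standard flux-balance formulation: maximise an
objective flux v_obj subject to the steady-state mass balance S·v = 0 and box
constraints v_min <= v <= v_max.  Exchange fluxes follow the usual sign
convention (negative = uptake, positive = secretion).  Diurnal physiology is
expressed as extra bound constraints: in the light phase stored-carbon uptake
(glycogen/glycerol transport) is shut off; in the dark phase the light
reactions and carbon fixation carry zero flux and CO2 uptake is disabled.
Gene knockouts arrive as reaction shut-offs (bounds fixed to zero) computed
from the GPR rules.

All LPs are solved with HiGHS through :func:`scipy.optimize.linprog`; the
engine is deterministic and uses no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import BIG_M, MetabolicModel

#: Steady-state residual tolerance |S v|_inf for accepted solutions.
STEADY_STATE_TOL = 1e-6
#: Numerical tolerance for "zero flux" decisions (blocked reactions etc.).
FLUX_EPS = 1e-6


class ConfigurationError(ValueError):
    """A scenario or constraint refers to a reaction the model does not have."""


class InfeasibleFloorError(RuntimeError):
    """FVA biomass floor exceeds the achievable maximum."""

    def __init__(self, floor: float, achievable: float):
        super().__init__(
            f"biomass floor {floor:g} is infeasible; achievable maximum is "
            f"{achievable:g}"
        )
        self.floor = floor
        self.achievable = achievable


@dataclass
class Basis:
    """A substrate basis: total uptake across the listed exchanges is capped.

    Example: the photoautotrophic basis of 100 mmol CO2 + H2CO3 caps the
    combined uptake of the two inorganic-carbon exchanges at 100.
    """

    exchange_ids: Tuple[str, ...]
    amount: float


@dataclass
class ScenarioConfig:
    """A named growth condition.

    ``open_exchanges`` maps exchange ids to their maximum uptake (a positive
    number; the exchange's lower bound becomes its negative).  Exchanges not
    listed are closed to uptake but stay open for secretion.  ``phase_shutdown``
    lists reactions regulated off in this condition (e.g. the dark-phase
    inactivation list, or the aerobic ChlA_II/BchE shutdown).
    """

    label: str = "photoautotrophic"
    open_exchanges: Dict[str, float] = field(default_factory=dict)
    basis: Optional[Basis] = None
    biomass_reaction: Optional[str] = None
    phase_shutdown: Set[str] = field(default_factory=set)
    objective: Optional[str] = None

    @property
    def objective_reaction(self) -> str:
        obj = self.objective or self.biomass_reaction
        if obj is None:
            raise ConfigurationError(
                f"scenario {self.label!r} defines neither objective nor biomass"
            )
        return obj


@dataclass
class DiurnalSets:
    """Reaction-id sets that the light/dark constraints act on."""

    glycogen_transport: Set[str] = field(default_factory=set)
    glycerol_transport: Set[str] = field(default_factory=set)
    co2_transport: Set[str] = field(default_factory=set)
    light_reactions: Set[str] = field(default_factory=set)
    carbon_fixation: Set[str] = field(default_factory=set)


@dataclass
class FluxDistribution:
    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str  # "optimal" | "infeasible" | "unbounded"
    steady_state_residual: float = 0.0

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FluxRange:
    reaction_id: str
    min: float
    max: float
    biomass_floor: float = 0.0

    def __iter__(self):
        return iter((self.min, self.max))


class SteadyStateProblem:
    """S·v = 0 with per-reaction box bounds and optional extra linear rows."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.reaction_ids: List[str] = list(model.reaction_ids)
        self._ridx = {rid: i for i, rid in enumerate(self.reaction_ids)}
        met_ids = model.metabolite_ids
        midx = {mid: i for i, mid in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(model.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(midx[met_id])
                cols.append(j)
                vals.append(float(coef))
        n_m, n_r = len(met_ids), len(self.reaction_ids)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_m, n_r)
        ) if n_r else sparse.csr_matrix((n_m, max(n_r, 0)))
        self.lower = np.array([r.lower_bound for r in model.reactions], float)
        self.upper = np.array([r.upper_bound for r in model.reactions], float)
        # extra rows: (coefficient mapping, upper bound) meaning sum coef*v <= ub
        self.extra_ub: List[Tuple[Dict[str, float], float]] = []

    # -- plumbing ----------------------------------------------------------
    def copy(self) -> "SteadyStateProblem":
        new = object.__new__(SteadyStateProblem)
        new.model = self.model
        new.reaction_ids = self.reaction_ids
        new._ridx = self._ridx
        new.S = self.S
        new.lower = self.lower.copy()
        new.upper = self.upper.copy()
        new.extra_ub = list(self.extra_ub)
        return new

    def index(self, rxn_id: str) -> int:
        try:
            return self._ridx[rxn_id]
        except KeyError:
            raise ConfigurationError(f"unknown reaction id {rxn_id!r}") from None

    def bounds_of(self, rxn_id: str) -> Tuple[float, float]:
        i = self.index(rxn_id)
        return self.lower[i], self.upper[i]

    def set_bounds(self, rxn_id: str, lo: float, hi: float):
        i = self.index(rxn_id)
        self.lower[i] = lo
        self.upper[i] = hi

    def fix(self, rxn_id: str, value: float):
        self.set_bounds(rxn_id, value, value)

    def add_flux_cap(self, coefficients: Mapping[str, float], upper: float):
        """Add the row sum(coef * v) <= upper (used for joint-basis caps)."""
        for rid in coefficients:
            self.index(rid)  # validate
        self.extra_ub.append((dict(coefficients), float(upper)))

    # -- solving -----------------------------------------------------------
    def solve(self, objective: Mapping[str, float] | str, sense: str = "max"):
        """Solve the LP; returns (status, objective_value, flux_vector)."""
        n = len(self.reaction_ids)
        c = np.zeros(n)
        if isinstance(objective, str):
            c[self.index(objective)] = 1.0
        else:
            for rid, coef in objective.items():
                c[self.index(rid)] = coef
        sign = -1.0 if sense == "max" else 1.0
        a_ub = b_ub = None
        if self.extra_ub:
            rows = []
            b_ub = []
            for coeffs, ub in self.extra_ub:
                row = np.zeros(n)
                for rid, coef in coeffs.items():
                    row[self.index(rid)] = coef
                rows.append(row)
                b_ub.append(ub)
            a_ub = np.vstack(rows)
            b_ub = np.array(b_ub)
        res = linprog(
            sign * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=a_ub,
            b_ub=b_ub,
            bounds=np.column_stack([self.lower, self.upper]),
            method="highs",
        )
        if res.status == 2:
            return "infeasible", None, None
        if res.status == 3:
            return "unbounded", None, None
        if not res.success:
            raise RuntimeError(f"LP solver failure: {res.message}")
        return "optimal", sign * res.fun, res.x


# -- operations -------------------------------------------------------------

def build_problem(model: MetabolicModel, scenario: ScenarioConfig) -> SteadyStateProblem:
    """Instantiate the steady-state LP for a scenario.

    All exchanges are first closed to uptake (lower bound clipped at 0), then
    the scenario's listed exchanges are opened to their stated uptakes; a
    joint basis cap adds one extra inequality row over its exchanges.
    Phase-shutdown reactions are fixed to zero.
    """
    problem = SteadyStateProblem(model)
    for rxn in model.exchanges:
        i = problem.index(rxn.id)
        problem.lower[i] = max(problem.lower[i], 0.0)
    for exch_id, uptake in scenario.open_exchanges.items():
        i = problem.index(exch_id)
        problem.lower[i] = -abs(uptake)
    if scenario.basis is not None:
        for exch_id in scenario.basis.exchange_ids:
            i = problem.index(exch_id)
            problem.lower[i] = min(problem.lower[i], -scenario.basis.amount)
        # combined uptake <= amount: -(sum v) <= amount
        problem.add_flux_cap(
            {rid: -1.0 for rid in scenario.basis.exchange_ids},
            scenario.basis.amount,
        )
    for rxn_id in scenario.phase_shutdown:
        problem.fix(rxn_id, 0.0)
    return problem


def apply_diurnal(
    problem: SteadyStateProblem, phase: str, sets: DiurnalSets
) -> SteadyStateProblem:
    """Impose the light- or dark-phase constraints in place and return the problem.

    Light: no stored-carbon uptake — glycogen and glycerol transports are
    fixed to zero; light and carbon-fixation reactions stay unconstrained.
    Dark: light reactions and carbon fixation fixed to zero, CO2 uptake
    disabled (transport restricted to efflux), glycogen/glycerol uptake stays
    open.
    """
    if phase == "light":
        for rid in sets.glycogen_transport | sets.glycerol_transport:
            problem.fix(rid, 0.0)
    elif phase == "dark":
        for rid in sets.light_reactions | sets.carbon_fixation:
            problem.fix(rid, 0.0)
        for rid in sets.co2_transport:
            lo, hi = problem.bounds_of(rid)
            # uptake direction (positive flux = import) disabled
            problem.set_bounds(rid, lo, min(hi, 0.0))
    else:
        raise ConfigurationError(f"unknown diurnal phase {phase!r}")
    return problem


def apply_knockout(
    problem: SteadyStateProblem, disabled: Iterable[str]
) -> SteadyStateProblem:
    """Fix every disabled reaction's flux to zero (mutant constraint)."""
    for rxn_id in disabled:
        problem.fix(rxn_id, 0.0)
    return problem


def maximize(problem: SteadyStateProblem, objective: str) -> FluxDistribution:
    """Maximise one reaction's flux; returns one optimal vertex solution.

    Alternate optima generally exist; flux_variability is the canonical
    description of the optimal face.  Infeasibility and unboundedness are
    reported through the ``status`` field rather than raised.
    """
    status, obj, x = problem.solve(objective, sense="max")
    if status != "optimal":
        witness: Dict[str, float] = {}
        if status == "unbounded":
            # Provide a finite witness by clamping bounds to the big-M box.
            clamped = problem.copy()
            clamped.lower = np.maximum(clamped.lower, -BIG_M)
            clamped.upper = np.minimum(clamped.upper, BIG_M)
            st2, _, x2 = clamped.solve(objective, sense="max")
            if st2 == "optimal":
                witness = dict(zip(problem.reaction_ids, x2))
        return FluxDistribution(witness, None, status)
    residual = float(np.max(np.abs(problem.S @ x))) if len(x) else 0.0
    return FluxDistribution(dict(zip(problem.reaction_ids, x)), obj, "optimal", residual)


def minimize(problem: SteadyStateProblem, objective: str) -> FluxDistribution:
    status, obj, x = problem.solve(objective, sense="min")
    if status != "optimal":
        return FluxDistribution({}, None, status)
    residual = float(np.max(np.abs(problem.S @ x))) if len(x) else 0.0
    return FluxDistribution(dict(zip(problem.reaction_ids, x)), obj, "optimal", residual)


def flux_variability(
    problem: SteadyStateProblem,
    reactions: Optional[Sequence[str]] = None,
    biomass_floor: float = 0.0,
    biomass_reaction: Optional[str] = None,
) -> List[FluxRange]:
    """Per-reaction [min, max] flux over the region with biomass >= floor.

    Two LP solves per reaction.  The floor is imposed as a lower bound on the
    biomass reaction; pass ``biomass_floor=0`` (or omit the reaction) for
    unconstrained variability.
    """
    fva_problem = problem.copy()
    if biomass_reaction is not None and biomass_floor:
        lo, hi = fva_problem.bounds_of(biomass_reaction)
        if biomass_floor > hi + FLUX_EPS:
            raise InfeasibleFloorError(biomass_floor, hi)
        status, achievable, _ = fva_problem.solve(biomass_reaction, sense="max")
        if status != "optimal" or achievable < biomass_floor - FLUX_EPS:
            raise InfeasibleFloorError(
                biomass_floor, achievable if achievable is not None else float("nan")
            )
        fva_problem.set_bounds(biomass_reaction, max(lo, biomass_floor), hi)
    if reactions is None:
        reactions = fva_problem.reaction_ids
    ranges = []
    for rid in reactions:
        st_min, vmin, _ = fva_problem.solve(rid, sense="min")
        st_max, vmax, _ = fva_problem.solve(rid, sense="max")
        if st_min != "optimal" or st_max != "optimal":
            raise RuntimeError(
                f"FVA subproblem for {rid} returned {st_min}/{st_max}"
            )
        ranges.append(FluxRange(rid, vmin, vmax, biomass_floor))
    return ranges


def restricted_fva(
    problem: SteadyStateProblem,
    pin: Mapping[str, Tuple[float, float]],
    targets: Sequence[str],
    biomass_floor: float = 0.0,
    biomass_reaction: Optional[str] = None,
) -> List[FluxRange]:
    """FVA after tightening selected reactions to pinned intervals.

    Used to superimpose experimentally measured flux intervals (e.g. the
    13C-MFA transaldolase range) onto the model and observe how the remaining
    ranges contract.
    """
    pinned = problem.copy()
    for rid, (lo, hi) in pin.items():
        cur_lo, cur_hi = pinned.bounds_of(rid)
        pinned.set_bounds(rid, max(cur_lo, lo), min(cur_hi, hi))
    return flux_variability(pinned, targets, biomass_floor, biomass_reaction)


@dataclass
class YieldResult:
    value: float
    product_flux: float
    denominator_flux: float
    diagnostic: str = ""


def compute_yield(
    model: MetabolicModel,
    scenario: ScenarioConfig,
    product: str,
    per_reaction: Optional[str] = None,
    fix_biomass: bool = True,
    biomass_fraction: float = 1.0,
) -> YieldResult:
    """Maximum theoretical yield of a product flux per mole of basis substrate.

    The product flux is maximised after (optionally) fixing biomass at
    ``biomass_fraction`` of its scenario optimum ("under maximum biomass
    production").  The denominator is the flux of ``per_reaction`` when given
    (e.g. RuBisCO carboxylation for "per mole carbon fixed"), otherwise the
    total basis uptake.
    """
    problem = build_problem(model, scenario)
    if fix_biomass and scenario.biomass_reaction is not None:
        wt = maximize(problem, scenario.biomass_reaction)
        if wt.status != "optimal":
            return YieldResult(0.0, 0.0, 0.0, f"biomass LP {wt.status}")
        lo, hi = problem.bounds_of(scenario.biomass_reaction)
        problem.set_bounds(
            scenario.biomass_reaction,
            max(lo, biomass_fraction * wt.objective_value),
            hi,
        )
    sol = maximize(problem, product)
    if sol.status != "optimal":
        return YieldResult(0.0, 0.0, 0.0, f"product LP {sol.status}")
    if sol.objective_value <= FLUX_EPS:
        return YieldResult(
            0.0, 0.0, 0.0, _unreachable_diagnostic(model, problem, product)
        )
    # Alternate optima make the denominator flux vertex-dependent; fix the
    # product at its optimum and take the smallest denominator consistent
    # with it (the maximum-yield reading of "per mole consumed/fixed").
    pinned = problem.copy()
    lo, hi = pinned.bounds_of(product)
    pinned.set_bounds(product, sol.objective_value, hi)
    if per_reaction is not None:
        status, denom, _ = pinned.solve(per_reaction, sense="min")
        denom = abs(denom) if status == "optimal" else 0.0
    elif scenario.basis is not None:
        uptake_obj = {rid: -1.0 for rid in scenario.basis.exchange_ids}
        status, denom, _ = pinned.solve(uptake_obj, sense="min")
        if status != "optimal":
            denom = 0.0
    else:
        raise ConfigurationError(
            "yield denominator undefined: give per_reaction or a scenario basis"
        )
    if denom <= FLUX_EPS:
        return YieldResult(0.0, sol.objective_value, denom, "zero basis consumption")
    return YieldResult(sol.objective_value / denom, sol.objective_value, denom)


def _unreachable_diagnostic(
    model: MetabolicModel, problem: SteadyStateProblem, product: str
) -> str:
    """Name the first substrate of the product reaction that cannot be produced."""
    rxn = model.reaction(product)
    for met_id, coef in sorted(rxn.stoichiometry.items()):
        if coef >= 0:
            continue
        drained = problem.copy()
        n = len(drained.reaction_ids)
        # temporary drain column: met -> (sink)
        extra = sparse.csr_matrix(
            ([-1.0], ([drained.model.metabolite_ids.index(met_id)], [0])),
            shape=(drained.S.shape[0], 1),
        )
        drained.S = sparse.hstack([drained.S, extra], format="csr")
        drained.reaction_ids = drained.reaction_ids + ["__drain__"]
        drained._ridx = dict(drained._ridx)
        drained._ridx["__drain__"] = n
        drained.lower = np.append(drained.lower, 0.0)
        drained.upper = np.append(drained.upper, BIG_M)
        status, vmax, _ = drained.solve("__drain__", sense="max")
        if status != "optimal" or vmax <= FLUX_EPS:
            return f"product unreachable: precursor {met_id} is blocked"
    return "product unreachable under scenario constraints"
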