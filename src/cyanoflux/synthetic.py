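"""Small metabolic networks with known ground truth.

Every analysis stage of the package (FBA, FVA, diurnal constraints, GPR
knockouts, essentiality, balance linting, gap and loop detection) is
exercisable on these generated fixtures without any external model file.
Each generator returns ``(model, truth)`` where ``truth`` records the planted
features and hand-derived optima.

Identifiers follow the usual compartment-suffix style (``_c`` cytosol,
``_e`` extracellular) so compartment handling is exercised.  All randomness
flows from one explicit ``numpy`` Generator seeded by the caller; the same
seed yields a bit-identical model.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .fba import Basis, DiurnalSets, ScenarioConfig
from .gpr import parse_gpr
from .model import BIG_M, MetabolicModel, Metabolite, Reaction

_COMPARTMENT = {"c": "cytosol", "e": "extracellular", "p": "periplasm"}


def _met(mid: str, formula: Optional[Dict[str, int]] = None, charge: Optional[int] = 0):
    suffix = mid.rsplit("_", 1)[-1]
    return Metabolite(
        id=mid,
        name=mid,
        compartment=_COMPARTMENT.get(suffix, "cytosol"),
        formula=formula,
        charge=charge if formula is not None else None,
    )


# -- linear chains ----------------------------------------------------------

def make_linear_chain(
    length: int,
    uptake: float,
    middle_coefficient: float = 1.0,
) -> Tuple[MetabolicModel, Dict]:
    """A_ext -> M1 -> ... -> M_length -> biomass, 1:1 except one middle step.

    The step into the middle metabolite consumes ``middle_coefficient`` units
    per unit product, so the known biomass optimum is
    ``uptake / middle_coefficient``.  All metabolites carry consistent CH2-unit
    formulas, so every internal reaction is elementally and charge balanced.
    """
    if length < 2:
        raise ValueError("chain length must be >= 2")
    model = MetabolicModel(id=f"chain{length}")
    mid_step = length // 2  # reaction M_mid -> M_mid+1 carries the coefficient
    # carbon content doubles (etc.) downstream of the non-1:1 step
    carbons = [1] * mid_step + [int(round(middle_coefficient))] * (
        length - mid_step
    )
    model.add_metabolite(_met("a_e", {"C": 1, "H": 2}, 0))
    for i in range(1, length + 1):
        k = carbons[i - 1] if i - 1 < len(carbons) else 1
        model.add_metabolite(_met(f"m{i}_c", {"C": k, "H": 2 * k}, 0))
    model.add_reaction(
        Reaction("EX_a", {"a_e": -1.0}, -uptake, BIG_M, kind="exchange")
    )
    model.add_reaction(
        Reaction("TR_a", {"a_e": -1.0, "m1_c": 1.0}, 0.0, BIG_M, kind="transport")
    )
    for i in range(1, length):
        coef = middle_coefficient if i == mid_step else 1.0
        model.add_reaction(
            Reaction(
                f"R{i}",
                {f"m{i}_c": -coef, f"m{i + 1}_c": 1.0},
                0.0,
                BIG_M,
                kind="metabolic",
            )
        )
    model.add_reaction(
        Reaction("BIOMASS", {f"m{length}_c": -1.0}, 0.0, BIG_M, kind="biomass")
    )
    model.biomass_reactions["default"] = "BIOMASS"
    truth = {
        "max_biomass": uptake / middle_coefficient,
        "scenario": ScenarioConfig(
            label="chain",
            open_exchanges={"EX_a": uptake},
            basis=Basis(("EX_a",), uptake),
            biomass_reaction="BIOMASS",
            objective="BIOMASS",
        ),
    }
    return model, truth


# -- mini phototroph --------------------------------------------------------

#: photon-uptake cap of the subjective-dark scenario (photons per basis glycogen)
SUBJECTIVE_DARK_PHOTON_CAP = 20.0


def make_mini_phototroph(seed: int = 0) -> Tuple[MetabolicModel, Dict]:
    """A 16-reaction cyanobacterium in miniature.

    Photons drive a light reaction producing the energy/redox currencies; CO2
    is fixed into a 3-carbon unit; glycogen can be stored and re-consumed;
    respiration burns fixed carbon back to CO2 for ATP; a nitrogenase-style
    reaction makes H2 at an ATP cost; separate light and dark biomass drains.
    GPRs plant one light-essential gene (``gPsb``), one two-gene complex
    (``gCfxA and gCfxB``), one isozyme pair (``gGlgP1 or gGlgP2``) and one
    rule with an unknown complement (``gResp or unknown``).

    Hand-derived optima recorded in the returned truth record (uptake U,
    glycogen G, photon cap P):

    * light biomass = U (all fixed carbon to biomass; photons non-limiting);
    * dark biomass = 3G/4 (one quarter of the glycogen is respired for ATP);
    * subjective-dark H2 = 3(P+G)/8 per basis, i.e. 3(P+1)/8 per mole
      glycogen, via the carbon-fixation/respiration transhydrogenation cycle
      that converts NADPH into ATP.

    The topology is fixed; ``seed`` is accepted for interface uniformity with
    the randomised generators.
    """
    del seed  # deterministic topology
    model = MetabolicModel(id="mini_phototroph")
    for mid in (
        "photon_e", "photon_c", "co2_e", "co2_c", "g3p_c",
        "glycogen_e", "glycogen_c", "h2_e", "h2_c", "atp_c", "nadph_c",
    ):
        model.add_metabolite(_met(mid, formula=None, charge=None))

    def rxn(rid, stoich, lb, ub, gpr=None, kind="metabolic"):
        model.add_reaction(
            Reaction(rid, stoich, lb, ub, gpr=parse_gpr(gpr), kind=kind)
        )

    rxn("EX_photon", {"photon_e": -1.0}, 0.0, BIG_M, kind="exchange")
    rxn("EX_co2", {"co2_e": -1.0}, 0.0, BIG_M, kind="exchange")
    rxn("EX_glycogen", {"glycogen_e": -1.0}, 0.0, BIG_M, kind="exchange")
    rxn("EX_h2", {"h2_e": -1.0}, 0.0, BIG_M, kind="exchange")
    rxn("TR_photon", {"photon_e": -1.0, "photon_c": 1.0}, 0.0, BIG_M, kind="transport")
    rxn("TR_co2", {"co2_e": -1.0, "co2_c": 1.0}, -BIG_M, BIG_M, kind="transport")
    rxn("TR_glycogen", {"glycogen_e": -1.0, "glycogen_c": 1.0}, 0.0, BIG_M,
        kind="transport")
    rxn("TR_h2", {"h2_c": -1.0, "h2_e": 1.0}, 0.0, BIG_M, kind="transport")
    rxn("LIGHT", {"photon_c": -1.0, "atp_c": 1.0, "nadph_c": 1.0}, 0.0, BIG_M,
        gpr="gPsb")
    rxn("CF", {"co2_c": -1.0, "atp_c": -1.0, "nadph_c": -1.0, "g3p_c": 1.0},
        0.0, BIG_M, gpr="gCfxA and gCfxB")
    rxn("RESP", {"g3p_c": -1.0, "co2_c": 1.0, "atp_c": 3.0}, 0.0, BIG_M,
        gpr="gResp or unknown")
    rxn("GLY_SYN", {"g3p_c": -1.0, "atp_c": -1.0, "glycogen_c": 1.0}, 0.0, BIG_M,
        gpr="gGlgA")
    rxn("GLY_DEG", {"glycogen_c": -1.0, "g3p_c": 1.0}, 0.0, BIG_M,
        gpr="gGlgP1 or gGlgP2")
    rxn("H2ASE", {"atp_c": -4.0, "nadph_c": -2.0, "h2_c": 1.0}, 0.0, BIG_M,
        gpr="gNifH")
    rxn("BIOMASS_LIGHT", {"g3p_c": -1.0, "atp_c": -1.0, "nadph_c": -1.0},
        0.0, BIG_M, kind="biomass")
    rxn("BIOMASS_DARK", {"g3p_c": -1.0, "atp_c": -1.0}, 0.0, BIG_M, kind="biomass")
    model.biomass_reactions.update(
        {"light": "BIOMASS_LIGHT", "dark": "BIOMASS_DARK"}
    )

    co2_uptake = 10.0
    glycogen_uptake = 10.0
    photon_cap = 100.0
    diurnal = DiurnalSets(
        glycogen_transport={"TR_glycogen"},
        glycerol_transport=set(),
        co2_transport={"TR_co2"},
        light_reactions={"LIGHT"},
        carbon_fixation={"CF"},
    )
    light = ScenarioConfig(
        label="light",
        open_exchanges={"EX_co2": co2_uptake, "EX_photon": photon_cap},
        basis=Basis(("EX_co2",), co2_uptake),
        biomass_reaction="BIOMASS_LIGHT",
        phase_shutdown={"TR_glycogen"},
        objective="BIOMASS_LIGHT",
    )
    dark = ScenarioConfig(
        label="dark",
        open_exchanges={"EX_glycogen": glycogen_uptake},
        basis=Basis(("EX_glycogen",), glycogen_uptake),
        biomass_reaction="BIOMASS_DARK",
        phase_shutdown={"LIGHT", "CF"},
        objective="BIOMASS_DARK",
    )
    subjective_dark = ScenarioConfig(
        label="subjective-dark",
        open_exchanges={
            "EX_glycogen": 1.0,
            "EX_photon": SUBJECTIVE_DARK_PHOTON_CAP,
        },
        basis=Basis(("EX_glycogen",), 1.0),
        biomass_reaction=None,
        objective="EX_h2",
    )
    truth = {
        "scenarios": {"light": light, "dark": dark, "subjective_dark": subjective_dark},
        "diurnal_sets": diurnal,
        "max_biomass_light": co2_uptake,
        "max_biomass_dark": 0.75 * glycogen_uptake,
        "biomass_yield_per_carbon_fixed_light": 1.0,
        "h2_yield_per_glycogen": 3.0 * (SUBJECTIVE_DARK_PHOTON_CAP + 1.0) / 8.0,
        "essential_genes_light": {"gPsb", "gCfxA", "gCfxB"},
        "isozyme_pair": ("gGlgP1", "gGlgP2"),
        "complex_genes": ("gCfxA", "gCfxB"),
        "unknown_complement_reaction": "RESP",
        "carbon_fixation_reaction": "CF",
    }
    return model, truth


# -- branched networks for defect planting ---------------------------------

def make_branched_network(seed: int = 0) -> Tuple[MetabolicModel, Dict]:
    """A trunk chain plus a side branch ending in a secreted product.

    Trunk: a_e -> m1 -> ... -> m_k -> biomass.  Branch: m_b -> x1 -> x2 -> x_e
    (secreted).  Deleting the branch's internal consumer orphans the branch
    without touching the trunk, which keeps planted-gap ground truth local.
    Chain lengths and the branch point vary with the seed.
    """
    rng = np.random.default_rng(seed)
    trunk_len = int(rng.integers(3, 6))
    branch_at = int(rng.integers(1, trunk_len))
    model = MetabolicModel(id=f"branched{seed}")
    model.add_metabolite(_met("a_e", {"C": 1, "H": 2}, 0))
    model.add_metabolite(_met("h_c", {"H": 1}, 1))  # proton, for imbalance planting
    for i in range(1, trunk_len + 1):
        model.add_metabolite(_met(f"m{i}_c", {"C": 1, "H": 2}, 0))
    for i in (1, 2):
        model.add_metabolite(_met(f"x{i}_c", {"C": 1, "H": 2}, 0))
    model.add_metabolite(_met("x_e", {"C": 1, "H": 2}, 0))
    model.add_reaction(Reaction("EX_a", {"a_e": -1.0}, -10.0, BIG_M, kind="exchange"))
    model.add_reaction(
        Reaction("TR_a", {"a_e": -1.0, "m1_c": 1.0}, 0.0, BIG_M, kind="transport")
    )
    for i in range(1, trunk_len):
        reversible = bool(rng.integers(0, 2))
        model.add_reaction(
            Reaction(
                f"R{i}",
                {f"m{i}_c": -1.0, f"m{i + 1}_c": 1.0},
                -BIG_M if reversible else 0.0,
                BIG_M,
                kind="metabolic",
            )
        )
    model.add_reaction(
        Reaction(
            "BIOMASS", {f"m{trunk_len}_c": -1.0}, 0.0, BIG_M, kind="biomass"
        )
    )
    model.add_reaction(
        Reaction(
            "B1", {f"m{branch_at}_c": -1.0, "x1_c": 1.0}, 0.0, BIG_M, kind="metabolic"
        )
    )
    model.add_reaction(
        Reaction("B2", {"x1_c": -1.0, "x2_c": 1.0}, 0.0, BIG_M, kind="metabolic")
    )
    model.add_reaction(
        Reaction("TR_x", {"x2_c": -1.0, "x_e": 1.0}, 0.0, BIG_M, kind="transport")
    )
    model.add_reaction(Reaction("EX_x", {"x_e": -1.0}, 0.0, BIG_M, kind="exchange"))
    # proton sink so h_c itself is not a planted dead-end
    model.add_reaction(Reaction("EX_h", {"h_c": -1.0}, -BIG_M, BIG_M, kind="exchange"))
    model.biomass_reactions["default"] = "BIOMASS"
    truth = {
        "trunk_len": trunk_len,
        "branch_at": branch_at,
        "branch_reactions": ("B1", "B2", "TR_x"),
        "internal_reactions": [
            r.id for r in model.reactions if r.kind in ("metabolic", "transport")
        ],
    }
    return model, truth


def plant_defect(
    model: MetabolicModel, kind: str, seed: int = 0
) -> Tuple[MetabolicModel, Dict]:
    """Plant one defect into a copy of a branched-network fixture.

    loop      add a reversed duplicate of a random internal reaction; ground
              truth names the forced two-cycle pair.
    gap       delete the branch step B2 (the sole consumer of x1), orphaning
              x1 and starving x2/x_e; ground truth lists the newly blocked
              metabolites.
    imbalance add one stray proton to a random internal reaction's
              stoichiometry; ground truth names the flagged reaction.
    """
    rng = np.random.default_rng(seed)
    planted = model.copy()
    if kind == "loop":
        candidates = sorted(
            r.id
            for r in planted.reactions
            if r.kind in ("metabolic", "transport")
            and len(r.stoichiometry) > 1
            and "h_c" not in r.stoichiometry
        )
        if not candidates:
            raise ValueError("no eligible site for a loop")
        target = candidates[int(rng.integers(0, len(candidates)))]
        original = planted.reaction(target)
        dup = Reaction(
            f"{target}_rev_dup",
            {m: -c for m, c in original.stoichiometry.items()},
            0.0,
            BIG_M,
            kind=original.kind,
        )
        planted.add_reaction(dup)
        return planted, {"kind": "loop", "loop_pair": (target, dup.id)}
    if kind == "gap":
        if not planted.has_reaction("B2"):
            raise ValueError("no eligible site for a gap (needs the branch fixture)")
        planted.remove_reaction("B2")
        return planted, {
            "kind": "gap",
            "removed_reaction": "B2",
            "blocked_metabolites": {"x1_c", "x2_c", "x_e"},
        }
    if kind == "imbalance":
        candidates = sorted(
            r.id
            for r in planted.reactions
            if r.kind in ("metabolic", "transport")
            and "h_c" not in r.stoichiometry
        )
        if not candidates:
            raise ValueError("no eligible site for an imbalance")
        target = candidates[int(rng.integers(0, len(candidates)))]
        rxn = planted.reaction(target)
        rxn.stoichiometry = dict(rxn.stoichiometry)
        rxn.stoichiometry["h_c"] = rxn.stoichiometry.get("h_c", 0.0) + 1.0
        return planted, {"kind": "imbalance", "imbalanced_reaction": target}
    raise ValueError(f"unknown defect kind {kind!r}")


# -- random bounded toys for oracle testing ---------------------------------

def make_random_toy(seed: int, max_reactions: int = 8) -> Tuple[MetabolicModel, Dict]:
    """A random small bounded network for brute-force LP oracle comparison.

    An uptake exchange feeds a random acyclic internal network (random 1- or
    2-coefficient steps, some reversible) ending in a biomass drain.  All
    bounds are finite, so every LP over the network is bounded.
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(2, 5))
    model = MetabolicModel(id=f"toy{seed}")
    model.add_metabolite(_met("s_e", {"C": 1, "H": 2}, 0))
    for i in range(n_mets):
        model.add_metabolite(_met(f"m{i}_c", {"C": 1, "H": 2}, 0))
    uptake = float(rng.integers(1, 11))
    model.add_reaction(
        Reaction("EX_s", {"s_e": -1.0}, -uptake, BIG_M, kind="exchange")
    )
    model.add_reaction(
        Reaction("TR_s", {"s_e": -1.0, "m0_c": 1.0}, 0.0, BIG_M, kind="transport")
    )
    n_internal = int(rng.integers(1, max_reactions - 2))
    for k in range(n_internal):
        i = int(rng.integers(0, n_mets - 1)) if n_mets > 1 else 0
        j = int(rng.integers(i + 1, n_mets)) if i + 1 < n_mets else n_mets - 1
        coef = float(rng.choice([1.0, 2.0]))
        reversible = bool(rng.integers(0, 2))
        ub = float(rng.choice([5.0, 20.0, BIG_M]))
        model.add_reaction(
            Reaction(
                f"R{k}",
                {f"m{i}_c": -coef, f"m{j}_c": 1.0},
                -ub if reversible else 0.0,
                ub,
                kind="metabolic",
            )
        )
    model.add_reaction(
        Reaction(
            "BIOMASS", {f"m{n_mets - 1}_c": -1.0}, 0.0, BIG_M, kind="biomass"
        )
    )
    model.biomass_reactions["default"] = "BIOMASS"
    scenario = ScenarioConfig(
        label="toy",
        open_exchanges={"EX_s": uptake},
        biomass_reaction="BIOMASS",
        objective="BIOMASS",
    )
    return model, {"scenario": scenario, "uptake": uptake}
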