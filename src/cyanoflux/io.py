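"""Model I/O: SBML (Level 3 + fbc, with legacy Level 2 fallbacks) and tabular.

Reading tolerates the two encodings found in published cyanobacterial
reconstructions: flux bounds either as fbc flux-bound parameters or as
legacy kinetic-law parameters (``LOWER_BOUND``/``UPPER_BOUND``; fbc wins on
conflict), GPRs either as fbc gene-product associations or as
``GENE_ASSOCIATION:`` notes, and formulas/charges either as fbc species
attributes or as ``FORMULA:``/``CHARGE:`` notes.  Metabolites without
formula or charge are kept but flagged unbalanceable.

Writing emits Level 3 Version 1 with fbc v2 and is lossless for ids,
stoichiometry, bounds, compartments, GPR strings, reaction kinds and the
biomass-reaction registry (the latter two travel in notes).
"""

from __future__ import annotations

import re
from typing import Dict

import libsbml
import pandas as pd

from . import gpr as gpr_mod
from .gpr import And, Gene, Or, Unknown, parse_gpr
from .model import (
    BIG_M,
    MetabolicModel,
    Metabolite,
    Reaction,
    format_formula,
    infer_reaction_kind,
    parse_formula,
)


class SBMLReadError(ValueError):
    pass


_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str, prefix: str) -> str:
    s = _SID_RE.sub("_", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return prefix + s


def _strip(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


_NOTE_RE = re.compile(r"([A-Za-z_:]+)\s*:\s*([^<\n]+)")


def _parse_notes(sbase) -> Dict[str, str]:
    if not sbase.isSetNotes():
        return {}
    text = sbase.getNotesString()
    out = {}
    for key, value in _NOTE_RE.findall(text):
        out[key.strip().upper()] = value.strip()
    return out


def _set_notes(sbase, entries: Dict[str, str]):
    body = "".join(f"<p>{k}: {v}</p>" for k, v in entries.items())
    sbase.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


# -- reading ----------------------------------------------------------------

def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML Level 2 or 3 model into a MetabolicModel.

    Raises SBMLReadError naming the line of the first fatal parse error, or
    listing the reaction id when stoichiometry is structurally missing.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) or doc.getModel() is None:
        err = doc.getError(0)
        line = err.getLine() if err is not None else "?"
        msg = err.getMessage() if err is not None else "no model element"
        raise SBMLReadError(f"cannot parse {path} (line {line}): {msg}")
    smodel = doc.getModel()
    model = MetabolicModel(id=smodel.getId() or "model")

    compartment_names = {}
    for i in range(smodel.getNumCompartments()):
        comp = smodel.getCompartment(i)
        compartment_names[comp.getId()] = comp.getName() or comp.getId()
        model.compartments.add(compartment_names[comp.getId()])

    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are not balanced, drop
        notes = _parse_notes(sp)
        formula_text = None
        charge = None
        fbc_sp = sp.getPlugin("fbc")
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula_text = fbc_sp.getChemicalFormula()
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        if formula_text is None:
            formula_text = notes.get("FORMULA")
        if charge is None and "CHARGE" in notes:
            try:
                charge = int(float(notes["CHARGE"]))
            except ValueError:
                charge = None
        formula = None
        if formula_text:
            try:
                formula = parse_formula(formula_text)
            except ValueError:
                formula = None
        model.add_metabolite(
            Metabolite(
                id=_strip(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=compartment_names.get(
                    sp.getCompartment(), sp.getCompartment()
                ),
                formula=formula,
                charge=charge if formula is not None else charge,
            )
        )

    gene_labels = {}
    fbc_model = smodel.getPlugin("fbc")
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip(gp.getId(), "G_")

    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        rid = _strip(srxn.getId(), "R_")
        stoich: Dict[str, float] = {}
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            mid = _strip(ref.getSpecies(), "M_")
            if mid in model._met_index:
                stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            mid = _strip(ref.getSpecies(), "M_")
            if mid in model._met_index:
                stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        if not stoich:
            raise SBMLReadError(
                f"reaction {rid} in {path} has no stoichiometry over "
                "non-boundary species"
            )
        lb, ub = _read_bounds(srxn, smodel)
        notes = _parse_notes(srxn)
        gpr = _read_gpr(srxn, notes, gene_labels)
        kind = notes.get("CYANOFLUX_KIND")
        rxn = Reaction(rid, stoich, lb, ub, gpr=gpr,
                       kind=kind if kind else "metabolic",
                       name=srxn.getName() or "")
        if not kind:
            rxn.kind = infer_reaction_kind(rxn, model)
        model.add_reaction(rxn)

    model_notes = _parse_notes(smodel)
    for key, value in model_notes.items():
        if key.startswith("CYANOFLUX_BIOMASS_"):
            label = key[len("CYANOFLUX_BIOMASS_"):].lower()
            model.biomass_reactions[label] = value
    if not model.biomass_reactions:
        for rxn in model.reactions:
            if rxn.kind == "biomass" or "biomass" in rxn.id.lower():
                model.biomass_reactions.setdefault("default", rxn.id)
                break
    model.validate()
    return model


def _read_bounds(srxn, smodel):
    lb = ub = None
    fbc_rxn = srxn.getPlugin("fbc")
    if fbc_rxn is not None:
        if fbc_rxn.isSetLowerFluxBound():
            p = smodel.getParameter(fbc_rxn.getLowerFluxBound())
            if p is not None:
                lb = p.getValue()
        if fbc_rxn.isSetUpperFluxBound():
            p = smodel.getParameter(fbc_rxn.getUpperFluxBound())
            if p is not None:
                ub = p.getValue()
    if (lb is None or ub is None) and srxn.isSetKineticLaw():
        kl = srxn.getKineticLaw()
        for pname, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
            p = kl.getParameter(pname)
            if p is not None:
                if setter == "lb" and lb is None:
                    lb = p.getValue()
                elif setter == "ub" and ub is None:
                    ub = p.getValue()
    if lb is None:
        lb = -BIG_M if srxn.getReversible() else 0.0
    if ub is None:
        ub = BIG_M
    return lb, ub


def _read_gpr(srxn, notes, gene_labels):
    fbc_rxn = srxn.getPlugin("fbc")
    if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
        assoc = fbc_rxn.getGeneProductAssociation().getAssociation()
        if assoc is not None:
            return _assoc_to_expr(assoc, gene_labels)
    text = notes.get("GENE_ASSOCIATION") or notes.get("GPR_ASSOCIATION")
    if text:
        return parse_gpr(text)
    return None


def _assoc_to_expr(assoc, gene_labels):
    if assoc.isGeneProductRef():
        label = gene_labels.get(assoc.getGeneProduct(), assoc.getGeneProduct())
        label = _strip(label, "G_")
        if label.lower() in gpr_mod.UNKNOWN_TOKENS:
            return Unknown()
        return Gene(label)
    children = tuple(
        _assoc_to_expr(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    )
    if len(children) == 1:
        return children[0]
    if assoc.isFbcAnd():
        return And(children)
    if assoc.isFbcOr():
        return Or(children)
    raise SBMLReadError(f"unsupported gene association node {assoc!r}")


# -- writing ----------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write Level 3 + fbc v2 SBML; read_sbml(write_sbml(m)) is the identity
    on ids, stoichiometry, bounds, compartments, GPR strings and kinds."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(_sid(model.id, "") if model.id else "model")
    fbc_model = smodel.getPlugin("fbc")
    fbc_model.setStrict(False)

    if model.biomass_reactions:
        _set_notes(
            smodel,
            {
                f"CYANOFLUX_BIOMASS_{label}": rid
                for label, rid in model.biomass_reactions.items()
            },
        )

    comp_ids = {}
    compartments = set(model.compartments) | {
        m.compartment for m in model.metabolites if m.compartment
    }
    for name in sorted(compartments) or ["cytosol"]:
        cid = _sid(name, "c_")
        comp_ids[name] = cid
        comp = smodel.createCompartment()
        comp.setId(cid)
        comp.setName(name)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = smodel.createSpecies()
        sp.setId(_sid(met.id, "M_"))
        sp.setName(met.name or met.id)
        sp.setCompartment(comp_ids.get(met.compartment, next(iter(comp_ids.values()))))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula is not None:
            fbc_sp.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            fbc_sp.setCharge(int(met.charge))

    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = smodel.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_products = set()
    for rxn in model.reactions:
        srxn = smodel.createReaction()
        srxn.setId(_sid(rxn.id, "R_"))
        srxn.setName(rxn.name or rxn.id)
        srxn.setReversible(rxn.lower_bound < 0)
        srxn.setFast(False)
        _set_notes(srxn, {"CYANOFLUX_KIND": rxn.kind})
        for mid, coef in sorted(rxn.stoichiometry.items()):
            ref = (
                srxn.createReactant() if coef < 0 else srxn.createProduct()
            )
            ref.setSpecies(_sid(mid, "M_"))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        fbc_rxn = srxn.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_param(rxn.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = fbc_rxn.createGeneProductAssociation()
            gpa.setAssociation(_expr_to_assoc_infix(rxn.gpr), False, True)
            gene_products |= gpr_mod.genes_of(rxn.gpr)

    # label gene products with the raw gene ids for round-trip fidelity
    for i in range(fbc_model.getNumGeneProducts()):
        gp = fbc_model.getGeneProduct(i)
        if not gp.isSetLabel():
            gp.setLabel(_strip(gp.getId(), "G_"))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def _expr_to_assoc_infix(expr) -> str:
    """Render the GPR for libsbml's infix association parser.

    The always-true `unknown` leaf is written as the pseudo gene product
    ``unknown_gene`` (reader maps it back).
    """
    if isinstance(expr, Unknown):
        return "unknown_gene"
    if isinstance(expr, Gene):
        return expr.id
    if isinstance(expr, And):
        return " and ".join(
            f"({_expr_to_assoc_infix(c)})" if isinstance(c, Or)
            else _expr_to_assoc_infix(c)
            for c in expr.children
        )
    if isinstance(expr, Or):
        return " or ".join(_expr_to_assoc_infix(c) for c in expr.children)
    raise TypeError(f"not a GPR node: {expr!r}")


# -- tabular ----------------------------------------------------------------

_ARROW_RE = re.compile(r"<=>|<->|-->|->|=>|<=|<-")


def parse_equation(text: str) -> Dict[str, float]:
    """Parse '2 a_c + b_c <=> c_c' into signed stoichiometry."""
    m = _ARROW_RE.search(text)
    if m is None:
        raise ValueError(f"no reaction arrow in equation {text!r}")
    left, right = text[: m.start()], text[m.end():]
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coef, mid = float(parts[0]), parts[1]
            else:
                coef, mid = 1.0, parts[0]
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    return {k: v for k, v in stoich.items() if v != 0.0}


def format_equation(stoich: Dict[str, float], reversible: bool) -> str:
    def side(items):
        return " + ".join(
            f"{abs(c):g} {m}" if abs(c) != 1 else m for m, c in items
        )

    left = [(m, c) for m, c in sorted(stoich.items()) if c < 0]
    right = [(m, c) for m, c in sorted(stoich.items()) if c > 0]
    arrow = "<=>" if reversible else "-->"
    return f"{side(left)} {arrow} {side(right)}".strip()


def read_tabular(reactions_path: str, metabolites_path: str) -> MetabolicModel:
    """Read the two-sheet tabular layout (TSV or XLSX).

    Reactions sheet columns: id, equation, lower_bound, upper_bound, gpr,
    kind (optional), name (optional).  Metabolites sheet: id, name,
    compartment, formula, charge.
    """
    rxns = _read_sheet(reactions_path)
    mets = _read_sheet(metabolites_path)
    model = MetabolicModel(id="tabular")
    for _, row in mets.iterrows():
        formula = None
        raw = row.get("formula")
        if isinstance(raw, str) and raw.strip():
            try:
                formula = parse_formula(raw.strip())
            except ValueError:
                formula = None
        charge = row.get("charge")
        charge = int(charge) if pd.notna(charge) else None
        model.add_metabolite(
            Metabolite(
                id=str(row["id"]),
                name=str(row.get("name", "") or ""),
                compartment=str(row.get("compartment", "cytosol") or "cytosol"),
                formula=formula,
                charge=charge,
            )
        )
    for _, row in rxns.iterrows():
        stoich = parse_equation(str(row["equation"]))
        kind = row.get("kind")
        rxn = Reaction(
            id=str(row["id"]),
            stoichiometry=stoich,
            lower_bound=float(row.get("lower_bound", -BIG_M)),
            upper_bound=float(row.get("upper_bound", BIG_M)),
            gpr=parse_gpr(str(row["gpr"])) if pd.notna(row.get("gpr")) else None,
            kind=str(kind) if isinstance(kind, str) and kind else "metabolic",
            name=str(row.get("name", "") or ""),
        )
        if not (isinstance(kind, str) and kind):
            rxn.kind = infer_reaction_kind(rxn, model)
        model.add_reaction(rxn)
    model.validate()
    return model


def write_tabular(model: MetabolicModel, reactions_path: str, metabolites_path: str):
    rxn_rows = [
        {
            "id": r.id,
            "name": r.name,
            "equation": format_equation(r.stoichiometry, r.reversible),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "gpr": r.gpr_string,
            "kind": r.kind,
        }
        for r in model.reactions
    ]
    met_rows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": format_formula(m.formula) if m.formula else "",
            "charge": m.charge if m.charge is not None else "",
        }
        for m in model.metabolites
    ]
    pd.DataFrame(rxn_rows).to_csv(reactions_path, sep="\t", index=False)
    pd.DataFrame(met_rows).to_csv(metabolites_path, sep="\t", index=False)


def _read_sheet(path: str) -> pd.DataFrame:
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        return pd.read_excel(path)
    return pd.read_csv(path, sep="\t")


def comparison_to_frame(comparison) -> pd.DataFrame:
    """ModelComparison counts as a one-row DataFrame (TSV/JSON export)."""
    return pd.DataFrame([comparison.counts])
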