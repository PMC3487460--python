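"""End-to-end reproduction runs: yields, FVA-vs-MFA tables, essentiality, QC.

Each ``run_*`` helper composes the library modules into one reproducible
analysis and returns tidy pandas DataFrames plus a manifest describing the
inputs and parameters, so a re-run with the same manifest reproduces the
report body byte for byte (the LP engine is deterministic).

Genome-scale inputs are SBML files (e.g. the published iSyn731 / iCyt773
reconstructions placed under ``data/external/``); every stage also runs on
the packaged synthetic fixtures, which need no files at all.  The
photoautotrophic 13C-MFA flux intervals for Synechocystis (measured ranges
and the ranges two published models predict at maximum biomass) ship with
the package as a TSV.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .essentiality import classify, read_invivo_table, single_gene_deletions, summarize
from .fba import ScenarioConfig, build_problem, compute_yield, flux_variability, maximize
from .model import MetabolicModel, compare_models
from .quality import check_balance, detect_infeasible_loops, find_blocked_metabolites

MFA_TABLE_RESOURCE = "synechocystis_mfa_fluxes.tsv"


@dataclass
class RunManifest:
    subcommand: str
    model_ids: List[str]
    parameters: Dict[str, object] = field(default_factory=dict)
    solver: str = "scipy-highs"
    tolerance: float = 1e-6
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds")
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def load_mfa_table() -> pd.DataFrame:
    """The packaged photoautotrophic 13C-MFA flux intervals (basis: 100 mmol
    CO2 + H2CO3 uptake)."""
    with resources.files("cyanoflux.data").joinpath(MFA_TABLE_RESOURCE).open() as fh:
        return pd.read_csv(fh, sep="\t")


def classify_overlap(
    measured: Tuple[float, float], predicted: Tuple[float, float]
) -> str:
    """Overlap taxonomy between a measured interval and a model flux range.

    contained  measured interval lies fully inside the model range
    under      model range lies strictly below the measured interval
    over       model range lies strictly above the measured interval
    partial    the intervals overlap without containment
    """
    m_lo, m_hi = measured
    p_lo, p_hi = predicted
    if p_lo <= m_lo and m_hi <= p_hi:
        return "contained"
    if p_hi < m_lo:
        return "under"
    if p_lo > m_hi:
        return "over"
    return "partial"


def run_fva_table(
    model: Optional[MetabolicModel] = None,
    scenario: Optional[ScenarioConfig] = None,
    mfa_table: Optional[pd.DataFrame] = None,
    reaction_map: Optional[Mapping[str, str]] = None,
    floor_fraction: float = 1.0,
    predicted_columns: Tuple[str, str] = ("isyn731_lb", "isyn731_ub"),
) -> Tuple[pd.DataFrame, RunManifest]:
    """Compare measured flux intervals against model flux ranges.

    With a model, ranges come from FVA at ``floor_fraction`` of the maximum
    biomass; without one, the packaged model-predicted columns of the MFA
    table are classified as shipped.  MFA reactions that cannot be mapped to
    the model are listed with classification ``unmapped``, never dropped.
    """
    if mfa_table is None:
        mfa_table = load_mfa_table()
    reaction_map = dict(reaction_map or {})
    rows = []
    ranges: Dict[str, Tuple[float, float]] = {}
    model_ids = []
    if model is not None:
        if scenario is None:
            raise ValueError("scenario required when a model is given")
        model_ids = [model.id]
        problem = build_problem(model, scenario)
        biomass = scenario.biomass_reaction
        wt = maximize(problem, biomass)
        floor = floor_fraction * wt.objective_value
        mapped = {
            row["reaction"]: reaction_map.get(row["reaction"], row["reaction"])
            for _, row in mfa_table.iterrows()
        }
        present = [rid for rid in mapped.values() if model.has_reaction(rid)]
        for fr in flux_variability(problem, present, floor, biomass):
            ranges[fr.reaction_id] = (fr.min, fr.max)
    for _, row in mfa_table.iterrows():
        name = row["reaction"]
        measured = (row["measured_lb"], row["measured_ub"])
        if model is not None:
            rid = reaction_map.get(name, name)
            if rid not in ranges:
                rows.append(
                    {"reaction": name, "measured_lb": measured[0],
                     "measured_ub": measured[1], "model_lb": None,
                     "model_ub": None, "classification": "unmapped"}
                )
                continue
            predicted = ranges[rid]
        else:
            predicted = (row[predicted_columns[0]], row[predicted_columns[1]])
            if pd.isna(predicted[0]) or pd.isna(predicted[1]):
                rows.append(
                    {"reaction": name, "measured_lb": measured[0],
                     "measured_ub": measured[1], "model_lb": None,
                     "model_ub": None, "classification": "unmapped"}
                )
                continue
        rows.append(
            {
                "reaction": name,
                "measured_lb": measured[0],
                "measured_ub": measured[1],
                "model_lb": predicted[0],
                "model_ub": predicted[1],
                "classification": classify_overlap(measured, predicted),
            }
        )
    manifest = RunManifest(
        "fva",
        model_ids,
        {"floor_fraction": floor_fraction, "predicted_columns": predicted_columns},
    )
    return pd.DataFrame(rows), manifest


def run_yields(
    jobs: Sequence[Tuple[MetabolicModel, ScenarioConfig, str, Optional[str]]],
) -> Tuple[pd.DataFrame, RunManifest]:
    """Yield table over (model, scenario, product, denominator-reaction) jobs.

    The denominator reaction (e.g. RuBisCO carboxylation for "per mole carbon
    fixed") may be None to use the scenario basis uptake instead.  Biomass is
    fixed at its scenario optimum when the scenario declares a biomass
    reaction distinct from the product.
    """
    rows = []
    for model, scenario, product, per_reaction in jobs:
        fix = (
            scenario.biomass_reaction is not None
            and scenario.biomass_reaction != product
        )
        result = compute_yield(
            model, scenario, product, per_reaction=per_reaction, fix_biomass=fix
        )
        rows.append(
            {
                "model": model.id,
                "scenario": scenario.label,
                "product": product,
                "per": per_reaction or "basis",
                "yield": result.value,
                "diagnostic": result.diagnostic,
            }
        )
    manifest = RunManifest("yields", sorted({m.id for m, *_ in jobs}))
    return pd.DataFrame(rows), manifest


def run_essentiality(
    model: MetabolicModel,
    scenario: ScenarioConfig,
    invivo: Mapping[str, str] | str | Path,
    threshold_fraction: float = 0.10,
) -> Tuple[pd.DataFrame, dict, RunManifest]:
    """Single-gene-deletion screen joined to in vivo viability calls."""
    if not isinstance(invivo, Mapping):
        invivo = read_invivo_table(invivo)
    calls = single_gene_deletions(
        model, scenario, genes=sorted(invivo), threshold_fraction=threshold_fraction
    )
    calls = classify(calls, invivo)
    summary = summarize(calls)
    frame = pd.DataFrame(
        [
            {
                "gene": c.gene,
                "wild_type_growth": c.wild_type_growth,
                "mutant_growth": c.mutant_growth,
                "in_silico": c.in_silico,
                "in_vivo": c.in_vivo,
                "category": c.category,
            }
            for c in calls
        ]
    )
    summary_dict = {
        "counts": summary.counts,
        "specificity": summary.specificity,
        "sensitivity": summary.sensitivity,
    }
    manifest = RunManifest(
        "essentiality", [model.id], {"threshold_fraction": threshold_fraction}
    )
    return frame, summary_dict, manifest


def run_qc(
    model: MetabolicModel, scenario: Optional[ScenarioConfig] = None
) -> Tuple[dict, RunManifest]:
    """Balance lint + blocked metabolites + infeasible loops, bundled."""
    balance = check_balance(model)
    blocked = find_blocked_metabolites(model, scenario) if model.reactions else set()
    loops = detect_infeasible_loops(model) if model.reactions else None
    bundle = {
        "balance": {
            "imbalanced": sorted(e.reaction_id for e in balance.imbalanced),
            "skipped": sorted(e.reaction_id for e in balance.skipped),
            "n_checked": len(balance.entries),
        },
        "blocked_metabolites": sorted(blocked),
        "loop_groups": [list(g.reaction_ids) for g in loops.groups] if loops else [],
    }
    manifest = RunManifest("qc", [model.id])
    return bundle, manifest


def run_compare(a: MetabolicModel, b: MetabolicModel) -> Tuple[dict, RunManifest]:
    comparison = compare_models(a, b)
    manifest = RunManifest("compare", [a.id, b.id])
    return comparison.counts, manifest
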