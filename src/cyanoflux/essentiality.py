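"""In silico single-gene-deletion screening and comparison with in vivo viability.

Each gene is deleted in turn; the reactions whose GPR rule goes false are shut
off and biomass is re-maximised.  A mutant grows in silico (G) when its
optimum reaches at least ``threshold_fraction`` (default 10%) of the wild-type
optimum, otherwise it does not (NG).  Joining the in silico verdict with an
in vivo viability table gives the four standard outcome categories:

    GG    grows in silico and in vivo        (true negative for essentiality)
    GNG   grows in silico, not in vivo       (missed essential gene)
    NGG   no growth in silico, grows in vivo (over-prediction of essentiality)
    NGNG  no growth either way               (correctly predicted essential)

with specificity = GG/(GG+NGG) and sensitivity = NGNG/(NGNG+GNG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

from .fba import ScenarioConfig, apply_knockout, build_problem, maximize
from .gpr import reactions_disabled_by
from .model import MetabolicModel

DEFAULT_THRESHOLD_FRACTION = 0.10


@dataclass
class EssentialityCall:
    gene: str
    wild_type_growth: float
    mutant_growth: float
    in_silico: str  # "G" | "NG"
    in_vivo: str = "unknown"  # "G" | "NG" | "unknown"
    category: str = "unclassified"  # GG | GNG | NGG | NGNG | unclassified


@dataclass
class ScreenSummary:
    counts: Dict[str, int] = field(default_factory=dict)
    specificity: Optional[float] = None
    sensitivity: Optional[float] = None


class ScreenError(RuntimeError):
    pass


def single_gene_deletions(
    model: MetabolicModel,
    scenario: ScenarioConfig,
    genes: Optional[Iterable[str]] = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> List[EssentialityCall]:
    """Screen single-gene knockouts for in silico growth.

    Genes appearing in no GPR trivially grow at the wild-type optimum and are
    not re-solved.  Aborts if the wild-type problem itself cannot grow.
    """
    if genes is None:
        genes = sorted(model.genes)
    else:
        genes = list(genes)
    base_problem = build_problem(model, scenario)
    objective = scenario.objective_reaction
    wt = maximize(base_problem, objective)
    if wt.status != "optimal" or wt.objective_value <= 0:
        raise ScreenError(
            f"wild-type problem under scenario {scenario.label!r} is "
            f"{wt.status} with objective {wt.objective_value!r}; cannot screen"
        )
    wt_growth = wt.objective_value
    threshold = threshold_fraction * wt_growth
    calls = []
    for gene in genes:
        disabled = reactions_disabled_by(model, {gene})
        if not disabled:
            mutant_growth = wt_growth
        else:
            problem = apply_knockout(base_problem.copy(), disabled)
            sol = maximize(problem, objective)
            mutant_growth = (
                sol.objective_value if sol.status == "optimal" else 0.0
            )
        verdict = "G" if mutant_growth >= threshold else "NG"
        calls.append(
            EssentialityCall(
                gene=gene,
                wild_type_growth=wt_growth,
                mutant_growth=mutant_growth,
                in_silico=verdict,
            )
        )
    return calls


def classify(
    calls: Iterable[EssentialityCall], invivo_table: Mapping[str, str]
) -> List[EssentialityCall]:
    """Attach in vivo verdicts and the GG/GNG/NGG/NGNG category to each call.

    ``invivo_table`` maps gene id to "G" or "NG"; genes missing from it stay
    unclassified (the upstream convention is to drop incompletely segregated
    mutants before the join).  A duplicate-key mapping cannot be constructed
    in Python, so duplicates must be caught by the table reader
    (:func:`read_invivo_table`).
    """
    out = []
    for call in calls:
        in_vivo = invivo_table.get(call.gene, "unknown")
        if in_vivo not in ("G", "NG"):
            category = "unclassified"
            in_vivo = "unknown"
        else:
            category = call.in_silico + in_vivo  # e.g. "NG"+"G" -> "NGG"
        out.append(
            EssentialityCall(
                gene=call.gene,
                wild_type_growth=call.wild_type_growth,
                mutant_growth=call.mutant_growth,
                in_silico=call.in_silico,
                in_vivo=in_vivo,
                category=category,
            )
        )
    return out


def summarize(calls: Iterable[EssentialityCall]) -> ScreenSummary:
    """Category counts plus specificity and sensitivity.

    A metric with a zero denominator is reported as ``None`` (undefined),
    never as 0.
    """
    counts = {"GG": 0, "GNG": 0, "NGG": 0, "NGNG": 0, "unclassified": 0}
    total_classified = 0
    for call in calls:
        counts[call.category] += 1
        if call.category != "unclassified":
            total_classified += 1
    if total_classified == 0:
        raise ScreenError("no classified calls to summarize")
    spec_denom = counts["GG"] + counts["NGG"]
    sens_denom = counts["NGNG"] + counts["GNG"]
    return ScreenSummary(
        counts=counts,
        specificity=counts["GG"] / spec_denom if spec_denom else None,
        sensitivity=counts["NGNG"] / sens_denom if sens_denom else None,
    )


def read_invivo_table(path) -> Dict[str, str]:
    """Read a 2-3 column TSV of (gene_id, viability[, segregation_flag]).

    Viability is "G"/"NG" (case-insensitive; "viable"/"lethal" synonyms
    accepted).  Rows flagged with incomplete segregation are dropped.
    Duplicate gene ids raise, listing the offenders.
    """
    table: Dict[str, str] = {}
    duplicates = []
    synonyms = {"g": "G", "viable": "G", "ng": "NG", "lethal": "NG", "nonviable": "NG"}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("gene", "gene_id"):
                continue
            gene, verdict = parts[0].strip(), parts[1].strip().lower()
            if len(parts) > 2 and parts[2].strip().lower() in (
                "incomplete",
                "incomplete_segregation",
            ):
                continue
            if gene in table:
                duplicates.append(gene)
                continue
            if verdict not in synonyms:
                raise ValueError(f"unrecognised viability {parts[1]!r} for {gene}")
            table[gene] = synonyms[verdict]
    if duplicates:
        raise ValueError(f"duplicate genes in in vivo table: {sorted(set(duplicates))}")
    return table


def essential_genes(calls: Iterable[EssentialityCall]) -> set:
    return {c.gene for c in calls if c.in_silico == "NG"}
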