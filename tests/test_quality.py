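"""QC diagnostics: balance lint, blocked metabolites, gap fill, loops."""

import pytest

from cyanoflux import synthetic
from cyanoflux.fba import BIG_M
from cyanoflux.model import MetabolicModel, Metabolite, Reaction
from cyanoflux.quality import (
    check_balance,
    detect_infeasible_loops,
    filter_proposals_by_loops,
    find_blocked_metabolites,
    propose_gapfill,
    suggest_direction_restrictions,
)


def _water_model(perturb_charge=False):
    m = MetabolicModel(id="water")
    m.add_metabolite(Metabolite("h_c", formula={"H": 1}, charge=1))
    m.add_metabolite(Metabolite("o_c", formula={"O": 1}, charge=0))
    m.add_metabolite(
        Metabolite("h2o_c", formula={"H": 2, "O": 1}, charge=3 if perturb_charge else 2)
    )
    m.add_reaction(
        Reaction("WATER", {"h_c": -2.0, "o_c": -1.0, "h2o_c": 1.0}, 0, 10)
    )
    return m


class TestBalance:
    def test_balanced_water_formation(self):
        report = check_balance(_water_model())
        entry = report.entries[0]
        assert entry.status == "balanced"

    def test_charge_perturbation_flagged(self):
        report = check_balance(_water_model(perturb_charge=True))
        entry = report.entries[0]
        assert entry.status == "imbalanced"
        assert entry.charge_imbalance == pytest.approx(1.0)
        assert entry.element_imbalance == {}

    def test_exchanges_and_biomass_skipped_by_design(self, mini_phototroph):
        model, _ = mini_phototroph
        report = check_balance(model)
        by_id = {e.reaction_id: e for e in report.entries}
        assert by_id["EX_co2"].status == "skipped"
        assert by_id["BIOMASS_LIGHT"].status == "skipped"

    def test_missing_formula_skipped_with_reason(self, mini_phototroph):
        model, _ = mini_phototroph
        report = check_balance(model)
        by_id = {e.reaction_id: e for e in report.entries}
        assert by_id["CF"].status == "skipped"
        assert "missing formula" in by_id["CF"].skip_reason

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_proton_imbalance_recovered_exactly(self, seed):
        model, _ = synthetic.make_branched_network(seed)
        assert check_balance(model).imbalanced == []
        planted, record = synthetic.plant_defect(model, "imbalance", seed)
        flagged = [e.reaction_id for e in check_balance(planted).imbalanced]
        assert flagged == [record["imbalanced_reaction"]]


class TestBlocked:
    def test_chain_has_no_blocked_metabolites(self):
        model, _ = synthetic.make_linear_chain(4, 10.0)
        assert find_blocked_metabolites(model) == set()

    def test_dead_end_with_producers_is_blocked(self):
        m = MetabolicModel(id="deadend")
        for mid in ("a_e", "a_c", "d_c"):
            m.add_metabolite(Metabolite(mid))
        m.add_reaction(Reaction("EX_a", {"a_e": -1.0}, -10, BIG_M, kind="exchange"))
        m.add_reaction(Reaction("TR_a", {"a_e": -1.0, "a_c": 1.0}, 0, BIG_M))
        m.add_reaction(Reaction("MK_D", {"a_c": -1.0, "d_c": 1.0}, 0, BIG_M))
        # d_c has a producer but no consumer and no drain -> blocked,
        # and the blockage cascades upstream
        assert "d_c" in find_blocked_metabolites(m)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_gap_recovered_exactly(self, seed):
        model, _ = synthetic.make_branched_network(seed)
        baseline = find_blocked_metabolites(model)
        planted, record = synthetic.plant_defect(model, "gap", seed)
        newly = find_blocked_metabolites(planted) - baseline
        assert newly == record["blocked_metabolites"]


class TestGapfill:
    def test_single_missing_exchange_proposal(self):
        """A blocked dead-end is reconnected by exactly one exchange addition
        (the glucose/thyaminose-style repair)."""
        model, _ = synthetic.make_branched_network(3)
        planted, record = synthetic.plant_defect(model, "gap", 3)
        pool = [
            Reaction("EX_x1", {"x1_c": -1.0}, -BIG_M, BIG_M, kind="exchange"),
            Reaction("ZZ_unrelated", {"m1_c": -1.0, "m2_c": 1.0}, 0, BIG_M),
        ]
        proposals = propose_gapfill(planted, pool, "x1_c", max_additions=2)
        assert proposals, "expected at least one proposal"
        assert proposals[0].added_reaction_ids == ("EX_x1",)

    def test_unblocked_target_needs_nothing(self):
        model, _ = synthetic.make_branched_network(3)
        pool = [Reaction("EX_x1", {"x1_c": -1.0}, -BIG_M, BIG_M, kind="exchange")]
        assert propose_gapfill(model, pool, "x1_c") == []

    def test_no_solution_within_budget_returns_empty(self):
        model, _ = synthetic.make_branched_network(3)
        planted, _ = synthetic.plant_defect(model, "gap", 3)
        pool = [Reaction("ZZ_unrelated", {"m1_c": -1.0, "m2_c": 1.0}, 0, BIG_M)]
        assert propose_gapfill(planted, pool, "x1_c", max_additions=2) == []

    def test_matches_exhaustive_subset_search(self):
        """Proposal minimality against explicit search over pool subsets."""
        import itertools

        model, _ = synthetic.make_branched_network(5)
        planted, _ = synthetic.plant_defect(model, "gap", 5)
        pool = [
            Reaction("ADD_cons", {"x1_c": -1.0, "x2_c": 1.0}, 0, BIG_M),
            Reaction("EX_x1", {"x1_c": -1.0}, -BIG_M, BIG_M, kind="exchange"),
        ]
        proposals = propose_gapfill(planted, pool, "x1_c", max_additions=2)
        got = {p.added_reaction_ids for p in proposals}
        # by hand: either addition alone reconnects x1_c (ADD_cons restores the
        # consumer chain to the existing secreted sink; EX_x1 drains directly)
        assert got == {("ADD_cons",), ("EX_x1",)}

    def test_accepted_proposal_unblocks_target(self):
        model, _ = synthetic.make_branched_network(4)
        planted, record = synthetic.plant_defect(model, "gap", 4)
        pool = [Reaction("EX_x1", {"x1_c": -1.0}, -BIG_M, BIG_M, kind="exchange")]
        proposals = propose_gapfill(planted, pool, "x1_c")
        accepted, rejected = filter_proposals_by_loops(planted, proposals, pool)
        assert len(accepted) == 1 and not rejected
        from cyanoflux.quality import _with_added

        fixed = _with_added(planted, pool)
        assert "x1_c" not in find_blocked_metabolites(fixed)


class TestLoops:
    def test_loop_free_chain_reports_empty(self):
        model, _ = synthetic.make_linear_chain(4, 10.0)
        assert detect_infeasible_loops(model).groups == []

    def test_duplicate_reversed_pair_is_one_group(self, branched):
        model, _ = branched
        planted, record = synthetic.plant_defect(model, "loop", 2)
        report = detect_infeasible_loops(planted)
        assert len(report.groups) == 1
        assert set(report.groups[0].reaction_ids) == set(record["loop_pair"])

    def test_witness_is_internal_steady_state_cycle(self, branched):
        import numpy as np

        model, _ = branched
        planted, record = synthetic.plant_defect(model, "loop", 5)
        report = detect_infeasible_loops(planted)
        witness = report.groups[0].witness
        assert witness, "expected nonzero witness"
        from cyanoflux.fba import SteadyStateProblem

        problem = SteadyStateProblem(planted)
        v = np.zeros(len(problem.reaction_ids))
        for rid, val in witness.items():
            v[problem.index(rid)] = val
        assert np.max(np.abs(problem.S @ v)) <= 1e-6
        for rxn in planted.exchanges:
            assert witness.get(rxn.id, 0.0) == 0.0

    def test_resolving_direction_empties_report(self, branched):
        """Making one member irreversible (the published repair strategy)
        removes the cycle."""
        model, _ = branched
        planted, record = synthetic.plant_defect(model, "loop", 2)
        a, b = record["loop_pair"]
        rxn = planted.reaction(a)
        if rxn.lower_bound >= 0:  # already irreversible: drop the duplicate
            planted.remove_reaction(b)
        else:
            rxn.lower_bound = 0.0
            planted.reaction(b).upper_bound = 0.0
        report = detect_infeasible_loops(planted)
        assert report.groups == [] or set(record["loop_pair"]) - report.members

    def test_invariant_under_bound_scaling(self, branched):
        model, _ = branched
        planted, record = synthetic.plant_defect(model, "loop", 9)
        base = detect_infeasible_loops(planted).members
        scaled = planted.copy()
        for rxn in scaled.reactions:
            rxn.lower_bound *= 10.0
            rxn.upper_bound *= 10.0
        assert detect_infeasible_loops(scaled, big_m=10.0 * BIG_M).members == base

    def test_loop_forming_proposal_rejected(self):
        """A proposal duplicating an existing reaction in reverse is rejected;
        a fresh exchange is accepted."""
        model, _ = synthetic.make_branched_network(6)
        planted, _ = synthetic.plant_defect(model, "gap", 6)
        trunk = planted.reaction("R1")
        pool = [
            Reaction("EX_x1", {"x1_c": -1.0}, -BIG_M, BIG_M, kind="exchange"),
            Reaction(
                "R1_rev",
                {m: -c for m, c in trunk.stoichiometry.items()},
                -BIG_M,
                BIG_M,
            ),
        ]
        from cyanoflux.quality import GapFillProposal

        proposals = [
            GapFillProposal("x1_c", ("EX_x1",)),
            GapFillProposal("x1_c", ("R1_rev",)),
        ]
        accepted, rejected = filter_proposals_by_loops(planted, proposals, pool)
        assert [p.added_reaction_ids for p in accepted] == [("EX_x1",)]
        assert [p.added_reaction_ids for p in rejected] == [("R1_rev",)]

    def test_direction_suggestions_cover_groups(self, branched):
        model, _ = branched
        planted, _ = synthetic.plant_defect(model, "loop", 1)
        report = detect_infeasible_loops(planted)
        suggestions = suggest_direction_restrictions(report)
        assert len(suggestions) == len(report.groups)
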