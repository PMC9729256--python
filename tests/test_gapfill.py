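import itertools

import pytest

from orthogem import (
    EvidenceTable,
    apply_gapfill,
    curate_gapfill,
    find_dead_end_metabolites,
    gap_fill,
    growth_test,
    solve_fba,
    summarize_model,
)
from orthogem.gapfill import (
    VERDICT_EVIDENCE,
    VERDICT_FORCED,
    VERDICT_NO_EVIDENCE,
    _candidate_pool,
)
from orthogem.synthetic import default_medium, make_gapfill_scenario
from orthogem.model_core import Reaction


@pytest.fixture(scope="module")
def gf_scenario(family):
    return make_gapfill_scenario(
        family, "G01", n_removed_essential=2, n_decoys=5, n_no_evidence=2,
        seed=7,
    )


def _add_reactions(draft, template, rxn_ids):
    """Test-side merge helper, independent of the solver path."""
    merged = draft.copy()
    for rxn_id in rxn_ids:
        rxn = template.reactions[rxn_id]
        for met_id in rxn.stoichiometry:
            if met_id not in merged.metabolites:
                met = template.metabolites[met_id]
                merged.add_metabolite(type(met)(
                    id=met.id, name=met.name, formula=met.formula,
                    charge=met.charge, compartment=met.compartment,
                ))
        merged.add_reaction(Reaction(
            id=rxn.id, stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            is_exchange=rxn.is_exchange,
        ))
    return merged


def _brute_force_minimal_sets(draft, template, medium, max_size=3):
    """Exhaustive subset search over the candidate pool, sizes ascending."""
    pool = _candidate_pool(draft, template, medium)
    for size in range(max_size + 1):
        feasible = [
            set(combo)
            for combo in itertools.combinations(pool, size)
            if growth_test(_add_reactions(draft, template, combo), medium)
        ]
        if feasible:
            return size, feasible
    return None, []


def test_single_missing_reaction_found_exactly(family):
    scenario = make_gapfill_scenario(
        family, "G02", n_removed_essential=1, n_decoys=5, seed=3
    )
    medium = default_medium()
    solution = gap_fill(scenario.gapped_draft, scenario.template, medium)
    assert solution.minimal
    assert set(solution.added_reactions) == scenario.expected_minimal["G02"]
    assert len(solution.added_reactions) == 1
    assert solution.achieved_growth > 1e-6


def test_two_gap_solution_matches_exhaustive_search(gf_scenario):
    medium = default_medium()
    draft, template = gf_scenario.gapped_draft, gf_scenario.template
    assert not growth_test(draft, medium)
    solution = gap_fill(draft, template, medium)
    size, feasible_sets = _brute_force_minimal_sets(draft, template, medium)
    assert solution.minimal
    assert len(solution.added_reactions) == size == 2
    assert set(solution.added_reactions) in feasible_sets
    assert set(solution.added_reactions) == gf_scenario.expected_minimal["G01"]


def test_gap_fill_deterministic(gf_scenario):
    medium = default_medium()
    a = gap_fill(gf_scenario.gapped_draft, gf_scenario.template, medium)
    b = gap_fill(gf_scenario.gapped_draft, gf_scenario.template, medium)
    assert a.added_reactions == b.added_reactions


def test_unfillable_reports_blocked_precursors(family):
    scenario = make_gapfill_scenario(
        family, "G04", n_removed_essential=1, n_decoys=2, seed=5
    )
    draft = scenario.gapped_draft
    template = scenario.template.copy()
    # template stripped of the needed reactions: nothing can restore growth
    for rxn_id in scenario.expected_minimal["G04"]:
        del template.reactions[rxn_id]
    for rxn_id in list(template.reactions):
        if rxn_id not in draft.reactions and not rxn_id.startswith("R_decoy"):
            del template.reactions[rxn_id]
    medium = default_medium()
    solution = gap_fill(draft, template, medium)
    assert solution.unfillable
    assert solution.added_reactions == []
    assert solution.blocked_precursors  # names at least one biomass substrate


def test_curation_excludes_exactly_planted_no_evidence(gf_scenario):
    medium = default_medium()
    solution = gap_fill(gf_scenario.gapped_draft, gf_scenario.template, medium)
    curated = curate_gapfill(
        solution, gf_scenario.evidence, "G01", gf_scenario.template
    )
    expected = gf_scenario.expected_verdicts["G01"]
    assert curated.verdicts == expected
    planted_no_evidence = {
        r for r, v in expected.items() if v == VERDICT_NO_EVIDENCE
    }
    assert set(curated.excluded) == planted_no_evidence


def test_curation_force_overrides(gf_scenario):
    medium = default_medium()
    solution = gap_fill(gf_scenario.gapped_draft, gf_scenario.template, medium)
    target = solution.added_reactions[0]
    curated = curate_gapfill(
        solution, gf_scenario.evidence, "G01", gf_scenario.template,
        force_include={target},
    )
    assert curated.verdicts[target] == VERDICT_FORCED
    curated = curate_gapfill(
        solution, gf_scenario.evidence, "G01", gf_scenario.template,
        force_exclude={target},
    )
    assert curated.verdicts[target] == VERDICT_NO_EVIDENCE


def test_reaction_with_ec_evidence_found(gf_scenario):
    evidence = EvidenceTable()
    rxn_id = sorted(gf_scenario.expected_minimal["G01"])[0]
    ec = sorted(gf_scenario.template.reactions[rxn_id].ec_numbers)[0]
    evidence.add("G01", "someGene", {ec}, source="manual")
    sol = gap_fill(gf_scenario.gapped_draft, gf_scenario.template,
                   default_medium())
    curated = curate_gapfill(sol, evidence, "G01", gf_scenario.template)
    assert curated.verdicts[rxn_id] == VERDICT_EVIDENCE


def test_apply_gapfill_monotone_and_heals_dead_ends(family):
    scenario = make_gapfill_scenario(
        family, "G01", n_removed_essential=2, n_decoys=3, n_no_evidence=0,
        seed=11,
    )
    medium = default_medium()
    draft = scenario.gapped_draft
    solution = gap_fill(draft, scenario.template, medium)
    curated = curate_gapfill(solution, scenario.evidence, "G01",
                             scenario.template)
    final = apply_gapfill(draft, curated, scenario.template)
    before, after = summarize_model(draft), summarize_model(final)
    assert set(draft.reactions) <= set(final.reactions)
    assert after.reactions > before.reactions
    assert after.dead_end_metabolites <= before.dead_end_metabolites
    assert growth_test(final, medium)


def test_apply_empty_solution_is_identity(gf_scenario):
    from orthogem import GapfillSolution

    empty = GapfillSolution(added_reactions=[], achieved_growth=None)
    final = apply_gapfill(gf_scenario.gapped_draft, empty,
                          gf_scenario.template)
    assert set(final.reactions) == set(gf_scenario.gapped_draft.reactions)


def test_decoys_never_selected(gf_scenario):
    medium = default_medium()
    solution = gap_fill(gf_scenario.gapped_draft, gf_scenario.template, medium)
    assert not any(r.startswith("R_decoy") for r in solution.added_reactions)
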