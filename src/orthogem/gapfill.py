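"""Minimal-addition gap filling with annotation-evidence curation.

A draft model transferred from a reference often cannot grow in silico on a
medium the organism grows on in vitro: transfer only removes reactions, so
biosynthetic routes can be interrupted.  Gap filling finds a
minimum-cardinality set of reactions from a template repository (here: the
reference GEM itself) whose addition restores growth.  The problem is posed
as a mixed-integer linear program — one binary indicator per candidate
reaction, candidate flux coupled to its indicator through the reaction's own
bounds — and solved with HiGHS.  Ties among equal-cardinality solutions are
broken deterministically towards lexicographically earlier reaction ids via
a second solve with the cardinality pinned at the certified minimum.

Gap filling proposes; annotation evidence disposes: each proposed reaction
is matched against the target genome's functional-annotation evidence (EC
numbers first, then exact annotation keywords), and only evidence-backed
reactions are carried into the final model unless the user forces a verdict.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import coo_matrix

from .model_core import Model, Reaction, carbon_count
from .simulate import (
    DEFAULT_GROWTH_THRESHOLD,
    MediumSpec,
    _effective_bounds,
    growth_test,
    solve_fba,
)

__all__ = [
    "EvidenceTable",
    "GapfillSolution",
    "gap_fill",
    "curate_gapfill",
    "apply_gapfill",
    "read_evidence",
]

VERDICT_EVIDENCE = "evidence-found"
VERDICT_NO_EVIDENCE = "no-evidence"
VERDICT_FORCED = "forced-by-user"


@dataclass
class EvidenceTable:
    """Flat functional-annotation evidence: genome → gene → annotations.

    Each row carries a source tag (which annotation pipeline produced it) so
    curation decisions remain traceable.  ``ec_index`` supports the primary
    matching route (EC-number intersection).
    """

    rows: list[tuple[str, str, frozenset[str], str, str]] = field(
        default_factory=list
    )  # (genome, gene, ECs, annotation text, source tag)

    def add(self, genome: str, gene: str, ecs: set[str] | frozenset[str],
            annotation: str = "", source: str = "unspecified") -> None:
        self.rows.append((genome, gene, frozenset(ecs), annotation, source))

    def genes_with_ec(self, genome: str, ec: str) -> set[str]:
        return {
            gene for g, gene, ecs, _, _ in self.rows if g == genome and ec in ecs
        }

    def genes_with_keyword(self, genome: str, keyword: str) -> set[str]:
        kw = keyword.strip().lower()
        return {
            gene
            for g, gene, _, ann, _ in self.rows
            if g == genome and ann.strip().lower() == kw
        }

    def genomes(self) -> set[str]:
        return {g for g, *_ in self.rows}

    def has_genome(self, genome: str) -> bool:
        return any(g == genome for g, *_ in self.rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["genome", "gene", "ec_numbers", "annotation", "source"])
            for genome, gene, ecs, ann, source in self.rows:
                writer.writerow([genome, gene, ";".join(sorted(ecs)), ann, source])


def read_evidence(path: str | Path) -> EvidenceTable:
    """Read evidence TSV (genome, gene, EC list ';'-joined, annotation, source)."""
    table = EvidenceTable()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        for row in reader:
            if not row:
                continue
            genome, gene, ecs, ann, source = (row + [""] * 5)[:5]
            table.add(
                genome, gene,
                {e.strip() for e in ecs.split(";") if e.strip()},
                ann, source or "unspecified",
            )
    return table


@dataclass
class GapfillSolution:
    added_reactions: list[str]
    achieved_growth: float | None
    verdicts: dict[str, str] = field(default_factory=dict)
    minimal: bool = False
    unfillable: bool = False
    blocked_precursors: list[str] = field(default_factory=list)
    evidence_detail: dict[str, list[str]] = field(default_factory=dict)

    @property
    def accepted(self) -> list[str]:
        return [
            r for r in self.added_reactions
            if self.verdicts.get(r) in (VERDICT_EVIDENCE, VERDICT_FORCED)
        ]

    @property
    def excluded(self) -> list[str]:
        return [
            r for r in self.added_reactions
            if self.verdicts.get(r) == VERDICT_NO_EVIDENCE
        ]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["reaction", "verdict", "matched_genes"])
            for rxn_id in self.added_reactions:
                writer.writerow([
                    rxn_id,
                    self.verdicts.get(rxn_id, ""),
                    ",".join(self.evidence_detail.get(rxn_id, [])),
                ])


def _merged(draft: Model, template: Model, candidates: list[str]) -> Model:
    """Draft plus candidate reactions (and their metabolites) from template."""
    merged = draft.copy()
    for rxn_id in candidates:
        rxn = template.reactions[rxn_id]
        for met_id in rxn.stoichiometry:
            if met_id not in merged.metabolites:
                met = template.metabolites[met_id]
                merged.add_metabolite(type(met)(
                    id=met.id, name=met.name, formula=met.formula,
                    charge=met.charge, compartment=met.compartment,
                ))
        merged.add_reaction(Reaction(
            id=rxn.id, name=rxn.name, stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            gpr=rxn.gpr, ec_numbers=set(rxn.ec_numbers),
            is_exchange=rxn.is_exchange, notes=rxn.notes,
        ))
    return merged


def _candidate_pool(draft: Model, template: Model, medium: MediumSpec) -> list[str]:
    """Template reactions absent from the draft; exchanges only if the medium
    needs them (named in the medium's uptake map or always-open set)."""
    pool = []
    for rxn_id in sorted(template.reactions):
        if rxn_id in draft.reactions:
            continue
        rxn = template.reactions[rxn_id]
        if rxn.is_exchange and rxn_id not in medium.uptake \
                and rxn_id not in medium.always_open:
            continue
        pool.append(rxn_id)
    return pool


def _blocked_precursors(
    merged: Model, medium: MediumSpec, objective: str
) -> list[str]:
    """Biomass substrates that cannot be produced even with every candidate
    available — the diagnostic attached to an unfillable result."""
    blocked = []
    biomass = merged.reactions[objective]
    substrates = sorted(m for m, c in biomass.stoichiometry.items() if c < 0)
    for met_id in substrates:
        probe = merged.copy()
        sink_id = f"__demand_{met_id}"
        probe.add_reaction(Reaction(
            id=sink_id, stoichiometry={met_id: -1.0},
            lower_bound=0.0, upper_bound=1000.0, is_exchange=True,
        ))
        sol = solve_fba(probe, medium, objective=sink_id)
        if not sol.optimal or sol.objective_value <= 1e-9:
            blocked.append(met_id)
    return blocked


def _solve_milp(
    merged: Model,
    medium: MediumSpec,
    candidates: list[str],
    objective: str,
    growth_floor: float,
    fixed_cardinality: int | None = None,
) -> tuple[str, set[str] | None]:
    """One gap-fill MILP solve.

    Stage 1 (``fixed_cardinality=None``) minimizes the number of opened
    candidates; stage 2 pins that cardinality and minimizes the sum of
    lexicographic ranks, making the returned set deterministic.
    """
    rxn_ids = sorted(merged.reactions)
    ridx = {r: i for i, r in enumerate(rxn_ids)}
    met_ids = sorted(merged.metabolites)
    midx = {m: i for i, m in enumerate(met_ids)}
    n = len(rxn_ids)
    m_cand = len(candidates)
    cidx = {r: n + j for j, r in enumerate(candidates)}

    eff = _effective_bounds(merged, medium)

    carbon = {}
    capped: list[str] = []
    if medium.carbon_cap is not None:
        for rxn in merged.reactions.values():
            if rxn.is_exchange:
                (met_id,) = rxn.stoichiometry
                f = merged.metabolites[met_id].formula
                cc = carbon_count(f) if f else 0
                if cc > 0 and eff[rxn.id][0] < 0:
                    carbon[rxn.id] = cc
                    capped.append(rxn.id)
    n_aux = len(capped)
    uidx = {r: n + m_cand + k for k, r in enumerate(capped)}
    n_var = n + m_cand + n_aux

    rows, cols, vals = [], [], []
    for rxn_id in rxn_ids:
        for met_id, coeff in merged.reactions[rxn_id].stoichiometry.items():
            rows.append(midx[met_id])
            cols.append(ridx[rxn_id])
            vals.append(coeff)
    S = coo_matrix((vals, (rows, cols)), shape=(len(met_ids), n_var))
    constraints = [LinearConstraint(S, 0.0, 0.0)]

    # candidate flux coupling: lb_j * y_j <= v_j <= ub_j * y_j
    for rxn_id in candidates:
        lb, ub = eff[rxn_id]
        i, j = ridx[rxn_id], cidx[rxn_id]
        if ub > 0:
            a = coo_matrix(([1.0, -ub], ([0, 0], [i, j])), shape=(1, n_var))
            constraints.append(LinearConstraint(a, -np.inf, 0.0))
        if lb < 0:
            a = coo_matrix(([-1.0, lb], ([0, 0], [i, j])), shape=(1, n_var))
            constraints.append(LinearConstraint(a, -np.inf, 0.0))

    for rxn_id in capped:
        a = coo_matrix(
            ([-1.0, -1.0], ([0, 0], [ridx[rxn_id], uidx[rxn_id]])),
            shape=(1, n_var),
        )
        constraints.append(LinearConstraint(a, -np.inf, 0.0))
    if capped:
        a = coo_matrix(
            ([float(carbon[r]) for r in capped],
             ([0] * n_aux, [uidx[r] for r in capped])),
            shape=(1, n_var),
        )
        constraints.append(LinearConstraint(a, -np.inf, float(medium.carbon_cap)))

    if fixed_cardinality is not None:
        a = coo_matrix(
            (np.ones(m_cand), ([0] * m_cand, [cidx[r] for r in candidates])),
            shape=(1, n_var),
        )
        constraints.append(
            LinearConstraint(a, float(fixed_cardinality), float(fixed_cardinality))
        )

    lbs = np.zeros(n_var)
    ubs = np.full(n_var, np.inf)
    for rxn_id in rxn_ids:
        lb, ub = eff[rxn_id]
        if rxn_id in cidx:
            # coupling constraints own the candidate bounds; keep box loose
            lbs[ridx[rxn_id]] = min(lb, 0.0)
            ubs[ridx[rxn_id]] = max(ub, 0.0)
        else:
            lbs[ridx[rxn_id]] = lb
            ubs[ridx[rxn_id]] = ub
    lbs[ridx[objective]] = max(lbs[ridx[objective]], growth_floor)
    for j in range(m_cand):
        lbs[n + j], ubs[n + j] = 0.0, 1.0

    c = np.zeros(n_var)
    if fixed_cardinality is None:
        for rxn_id in candidates:
            c[cidx[rxn_id]] = 1.0
    else:
        for rank, rxn_id in enumerate(candidates):  # candidates sorted lexicographically
            c[cidx[rxn_id]] = float(rank + 1)

    integrality = np.zeros(n_var)
    for j in range(m_cand):
        integrality[n + j] = 1
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lbs, ubs),
    )
    if res.status != 0 or res.x is None:
        return ("infeasible", None)
    chosen = {
        rxn_id for rxn_id in candidates if res.x[cidx[rxn_id]] > 0.5
    }
    return ("optimal", chosen)


def gap_fill(
    draft: Model,
    template: Model,
    medium: MediumSpec,
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
    candidate_cap: int = 2000,
) -> GapfillSolution:
    """Certified-minimal set of template reactions restoring in-silico growth.

    The candidate pool is every template reaction absent from the draft
    (exchanges only when the medium opens them).  When the pool does not
    exceed ``candidate_cap`` the returned set is certified minimal;
    otherwise the pool is truncated and the result flagged best-found.
    """
    if draft.objective is None:
        raise ValueError("draft has no objective reaction to restore")
    objective = draft.objective
    candidates = _candidate_pool(draft, template, medium)
    certified = len(candidates) <= candidate_cap
    candidates = candidates[:candidate_cap]

    if objective not in draft.reactions and objective not in candidates:
        if objective in template.reactions:
            candidates.append(objective)
            candidates.sort()

    merged = _merged(draft, template, candidates)
    if objective not in merged.reactions:
        raise ValueError(f"objective {objective} absent from draft and template")

    # the MILP growth floor must sit well above the solver's feasibility
    # tolerance (~1e-7), or "no additions" can slip through as feasible
    growth_floor = max(threshold, 1e-3)
    status, chosen = _solve_milp(
        merged, medium, candidates, objective, growth_floor
    )
    if status != "optimal":
        return GapfillSolution(
            added_reactions=[],
            achieved_growth=None,
            unfillable=True,
            blocked_precursors=_blocked_precursors(merged, medium, objective),
        )
    k = len(chosen)
    if k > 0:
        status2, chosen2 = _solve_milp(
            merged, medium, candidates, objective, growth_floor,
            fixed_cardinality=k,
        )
        if status2 == "optimal":
            chosen = chosen2
    added = sorted(chosen)

    filled = _merged(draft, template, added)
    sol = solve_fba(filled, medium)
    achieved = sol.objective_value if sol.optimal else None
    return GapfillSolution(
        added_reactions=added,
        achieved_growth=achieved,
        verdicts={r: "" for r in added},
        minimal=certified,
    )


def curate_gapfill(
    solution: GapfillSolution,
    evidence: EvidenceTable,
    target_genome: str,
    template: Model,
    force_include: set[str] | None = None,
    force_exclude: set[str] | None = None,
    match_rules: tuple[str, ...] = ("ec", "keyword"),
) -> GapfillSolution:
    """Assign an evidence verdict to every gap-filled reaction.

    A reaction is ``evidence-found`` if any of its EC numbers occurs in the
    target genome's evidence (rule ``ec``), or — failing that — if its name
    matches an annotation string exactly (rule ``keyword``).  Reactions with
    no evidence are excluded from the final model but stay listed; user
    overrides win over both outcomes and are marked ``forced-by-user``.
    """
    force_include = force_include or set()
    force_exclude = force_exclude or set()
    verdicts: dict[str, str] = {}
    detail: dict[str, list[str]] = {}
    for rxn_id in solution.added_reactions:
        if rxn_id in force_include:
            verdicts[rxn_id] = VERDICT_FORCED
            continue
        if rxn_id in force_exclude:
            verdicts[rxn_id] = VERDICT_NO_EVIDENCE
            continue
        rxn = template.reactions[rxn_id]
        matched: set[str] = set()
        if "ec" in match_rules:
            for ec in sorted(rxn.ec_numbers):
                matched |= evidence.genes_with_ec(target_genome, ec)
        if not matched and "keyword" in match_rules and rxn.name:
            matched |= evidence.genes_with_keyword(target_genome, rxn.name)
        if matched:
            verdicts[rxn_id] = VERDICT_EVIDENCE
            detail[rxn_id] = sorted(matched)
        else:
            verdicts[rxn_id] = VERDICT_NO_EVIDENCE
    return GapfillSolution(
        added_reactions=list(solution.added_reactions),
        achieved_growth=solution.achieved_growth,
        verdicts=verdicts,
        minimal=solution.minimal,
        unfillable=solution.unfillable,
        blocked_precursors=list(solution.blocked_precursors),
        evidence_detail=detail,
    )


def apply_gapfill(
    draft: Model,
    solution: GapfillSolution,
    template: Model,
    orthotable=None,
    reference_genome: str | None = None,
    target_genome: str | None = None,
) -> Model:
    """Copy accepted reactions (with metabolites and rules) into the draft.

    When orthology data are supplied the template rules are re-substituted
    for the target genome; otherwise the reference rule is carried over with
    a provenance note.  Never removes anything; id collisions are an error.
    """
    final = draft.copy()
    final.id = draft.id.replace("_draft_", "_gapfilled_") \
        if "_draft_" in draft.id else f"{draft.id}_gapfilled"
    for rxn_id in solution.accepted:
        if rxn_id in final.reactions:
            raise ValueError(f"gap-fill reaction {rxn_id} already in draft")
        rxn = template.reactions[rxn_id]
        for met_id in rxn.stoichiometry:
            if met_id not in final.metabolites:
                met = template.metabolites[met_id]
                final.add_metabolite(type(met)(
                    id=met.id, name=met.name, formula=met.formula,
                    charge=met.charge, compartment=met.compartment,
                ))
        gpr = rxn.gpr
        notes = rxn.notes
        if gpr is not None and orthotable is not None and target_genome:
            from .gpr import substitute_rule

            ref = reference_genome or template.id
            new_rule, _ = substitute_rule(gpr, orthotable, ref, target_genome)
            if not new_rule.is_false:
                gpr = new_rule
            else:
                notes = (notes + " | " if notes else "") + \
                    "gap-filled; reference rule unresolvable in target"
                gpr = None
        elif gpr is not None:
            notes = (notes + " | " if notes else "") + \
                f"gap-filled from {template.id}; rule carried from reference"
        final.add_reaction(Reaction(
            id=rxn.id, name=rxn.name, stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            gpr=gpr, ec_numbers=set(rxn.ec_numbers),
            is_exchange=rxn.is_exchange, notes=notes,
        ))
    return final
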