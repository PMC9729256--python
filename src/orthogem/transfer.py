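"""Reaction-presence prediction and draft-model assembly.

Given a curated reference GEM and an orthogroup table, each reference
reaction's gene-reaction rule is rewritten for a target genome
(:func:`orthogem.gpr.substitute_rule`) and evaluated against the target's
full gene complement.  Reactions without a GPR — spontaneous reactions,
macromolecular syntheses, the biomass reaction — are transferred
unconditionally.  Reactions whose rules reference only reference genes that
appear in no orthogroup are flagged rather than silently dropped: such
identifier mismatches demand a manual decision, optionally supplied back to
:func:`build_draft_model` as an allowlist.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .gpr import GprRule, SubstitutionReport, parse_rule, substitute_rule
from .model_core import Model, Reaction
from .orthology import OrthogroupTable

__all__ = [
    "PresenceCall",
    "ReactionPresenceMatrix",
    "predict_presence",
    "build_presence_matrix",
    "build_draft_model",
]

STATUS_GPR = "gpr-evaluated"
STATUS_NO_GPR = "no-gpr-transferred"
STATUS_UNMAPPED = "unmapped-gene-flagged"


@dataclass
class PresenceCall:
    reaction_id: str
    genome: str
    call: str  # present | absent
    status: str  # gpr-evaluated | no-gpr-transferred | unmapped-gene-flagged
    substituted_rule: GprRule | None = None
    unmapped_genes: tuple[str, ...] = ()
    report: SubstitutionReport | None = None

    @property
    def present(self) -> bool:
        return self.call == "present"


def predict_presence(
    reference: Model,
    table: OrthogroupTable,
    target_genome: str,
    reference_genome: str | None = None,
) -> list[PresenceCall]:
    """Presence call for every reference reaction in ``target_genome``.

    ``reference_genome`` names the orthogroup-table column holding the
    reference organism's genes; it defaults to the reference model id.
    """
    if target_genome not in table.genomes:
        raise ValueError(
            f"target genome {target_genome!r} not in orthogroup table "
            f"(columns: {table.genomes})"
        )
    ref_genome = reference_genome if reference_genome is not None else reference.id
    if ref_genome not in table.genomes:
        raise ValueError(
            f"reference genome column {ref_genome!r} not in orthogroup table"
        )
    target_genes = table.genes_of_genome(target_genome)
    calls: list[PresenceCall] = []
    for rxn_id in sorted(reference.reactions):
        rxn = reference.reactions[rxn_id]
        if rxn.gpr is None:
            calls.append(
                PresenceCall(rxn_id, target_genome, "present", STATUS_NO_GPR)
            )
            continue
        new_rule, report = substitute_rule(rxn.gpr, table, ref_genome, target_genome)
        unmapped = tuple(report.unmapped_genes)
        if unmapped and set(unmapped) == rxn.gpr.genes():
            # every gene of the rule is unresolvable: manual-decision case
            calls.append(
                PresenceCall(
                    rxn_id,
                    target_genome,
                    "absent",
                    STATUS_UNMAPPED,
                    substituted_rule=None,
                    unmapped_genes=unmapped,
                    report=report,
                )
            )
            continue
        present = (not new_rule.is_false) and new_rule.evaluate(target_genes)
        calls.append(
            PresenceCall(
                rxn_id,
                target_genome,
                "present" if present else "absent",
                STATUS_UNMAPPED if unmapped else STATUS_GPR,
                substituted_rule=None if new_rule.is_false else new_rule,
                unmapped_genes=unmapped,
                report=report,
            )
        )
    return calls


@dataclass
class ReactionPresenceMatrix:
    """Reactions × genomes grid of presence calls (the pan-reactome view)."""

    reactions: list[str]
    genomes: list[str]
    calls: dict[tuple[str, str], PresenceCall]

    def call(self, reaction_id: str, genome: str) -> PresenceCall:
        return self.calls[(reaction_id, genome)]

    def missing_genomes(self, reaction_id: str) -> list[str]:
        return [g for g in self.genomes if not self.calls[(reaction_id, g)].present]

    def most_frequently_missing(self) -> list[tuple[str, int]]:
        """Reactions ranked by how many genomes lack them (desc, then by id)."""
        tallies = [(r, len(self.missing_genomes(r))) for r in self.reactions]
        return sorted(tallies, key=lambda t: (-t[1], t[0]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["reaction"] + self.genomes + ["missing_in"])
            for rxn_id in self.reactions:
                row = [rxn_id]
                for g in self.genomes:
                    c = self.calls[(rxn_id, g)]
                    row.append("1" if c.present else "0")
                row.append(",".join(self.missing_genomes(rxn_id)))
                writer.writerow(row)


def build_presence_matrix(
    reference: Model,
    table: OrthogroupTable,
    genomes: list[str],
    reference_genome: str | None = None,
) -> ReactionPresenceMatrix:
    """Cell-wise :func:`predict_presence` over a user-supplied genome list."""
    calls: dict[tuple[str, str], PresenceCall] = {}
    for genome in genomes:
        for call in predict_presence(reference, table, genome, reference_genome):
            calls[(call.reaction_id, genome)] = call
    return ReactionPresenceMatrix(
        reactions=sorted(reference.reactions), genomes=list(genomes), calls=calls
    )


def _used_metabolites(model: Model) -> set[str]:
    used: set[str] = set()
    for rxn in model.reactions.values():
        used.update(rxn.stoichiometry)
    return used


def build_draft_model(
    reference: Model,
    calls: list[PresenceCall],
    target_genome: str,
    allowlist: dict[str, str] | None = None,
) -> tuple[Model, list[PresenceCall]]:
    """Assemble a draft GEM from presence calls.

    The draft holds exactly the present-called reactions with their rules
    rewritten in target-genome genes; metabolites are pruned to those used
    (biomass precursors are retained even if temporarily orphaned, so gap
    filling has stable targets).  Flagged reactions (rules referencing only
    unmapped reference genes) are *not* auto-added; they are returned as a
    manual-decision report.  ``allowlist`` maps reaction id → replacement
    rule text ("" for no GPR) for reactions the curator decided to re-add.

    Returns ``(draft, flagged_calls)``.
    """
    call_by_rxn = {c.reaction_id: c for c in calls}
    missing = set(reference.reactions) - set(call_by_rxn)
    if missing:
        raise ValueError(
            f"presence calls incomplete; no call for {sorted(missing)[:5]}..."
        )
    allowlist = allowlist or {}

    draft = Model(
        id=f"{reference.id}_draft_{target_genome}",
        objective=reference.objective,
        balance_exempt=set(reference.balance_exempt),
        notes=f"draft transferred from {reference.id} for {target_genome}",
    )
    flagged: list[PresenceCall] = []

    chosen: dict[str, GprRule | None] = {}
    for rxn_id in sorted(reference.reactions):
        call = call_by_rxn[rxn_id]
        if call.status == STATUS_UNMAPPED and not call.present:
            flagged.append(call)
            if rxn_id in allowlist:
                chosen[rxn_id] = parse_rule(allowlist[rxn_id])
            continue
        if call.present:
            chosen[rxn_id] = (
                None if call.status == STATUS_NO_GPR else call.substituted_rule
            )

    # metabolites used by chosen reactions, plus biomass precursors
    needed: set[str] = set()
    for rxn_id in chosen:
        needed.update(reference.reactions[rxn_id].stoichiometry)
    if reference.objective and reference.objective in reference.reactions:
        needed.update(reference.reactions[reference.objective].stoichiometry)
    for met_id in sorted(needed):
        met = reference.metabolites[met_id]
        draft.add_metabolite(
            type(met)(
                id=met.id,
                name=met.name,
                formula=met.formula,
                charge=met.charge,
                compartment=met.compartment,
            )
        )
    for rxn_id in sorted(chosen):
        ref_rxn = reference.reactions[rxn_id]
        draft.add_reaction(
            Reaction(
                id=ref_rxn.id,
                name=ref_rxn.name,
                stoichiometry=dict(ref_rxn.stoichiometry),
                lower_bound=ref_rxn.lower_bound,
                upper_bound=ref_rxn.upper_bound,
                gpr=chosen[rxn_id],
                ec_numbers=set(ref_rxn.ec_numbers),
                is_exchange=ref_rxn.is_exchange,
                notes=ref_rxn.notes,
            )
        )
    if reference.objective and reference.objective not in draft.reactions:
        import warnings

        warnings.warn(
            f"objective reaction {reference.objective} absent from draft "
            f"for {target_genome}; gap filling will be required",
            stacklevel=2,
        )
        draft.objective = reference.objective  # kept as declared target
    if draft.objective is None or draft.objective in draft.reactions:
        draft.validate()
    return draft, flagged


def write_flagged_report(
    flagged: list[PresenceCall], path: str | Path
) -> None:
    """Manual-decision report for reactions blocked by unmapped gene ids."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["reaction", "genome", "unmapped_reference_genes"])
        for call in flagged:
            writer.writerow(
                [call.reaction_id, call.genome, ",".join(call.unmapped_genes)]
            )
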