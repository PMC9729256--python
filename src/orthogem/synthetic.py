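"""Synthetic reference GEMs, genome families, and gap-fill scenarios.

Every pipeline stage (rule substitution, reaction transfer, gap filling,
curation, screening) is exercised against generated inputs with recorded
ground truth, so the whole reconstruction procedure is testable without
downloading genomes or deposited models.

The generated reference model is a small but complete aerobic heterotroph
skeleton: two carbon sources (glucose C6, acetate C2) with transporters, a
catabolic backbone producing pyruvate, ammonium assimilation into an amino
acid, a respiration sink, and a biomass reaction draining precursors.  All
internal reactions are elementally balanced by construction; exchange and
biomass reactions are exempt by convention.  Gene-reaction rules are drawn
per a configurable mix of structures (no GPR / single gene / OR pair / AND
pair / nested (AND)-OR), with genes private to their reaction so each
reference gene founds exactly one orthogroup.

Genome families are simulated by independent gene loss and co-ortholog
duplication per target genome; the induced orthogroup table and per-genome
annotation-evidence tables are emitted alongside the ground-truth reactomes
(original rules evaluated under each genome's retained reference genes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gapfill import EvidenceTable
from .model_core import Metabolite, Model, Reaction, write_model
from .gpr import parse_rule
from .orthology import OrthogroupTable
from .simulate import MediumSpec, solve_fba

__all__ = [
    "SyntheticScenario",
    "DEFAULT_GPR_MIX",
    "make_reference_model",
    "default_medium",
    "simulate_genome_family",
    "make_gapfill_scenario",
    "write_scenario",
]

DEFAULT_GPR_MIX = {
    "no-gpr": 0.15,
    "single": 0.35,
    "OR": 0.20,
    "AND": 0.20,
    "nested": 0.10,
}

REFERENCE_GENOME = "REF"


def default_medium(carbon_cap: float | None = None,
                   carbon_source: str = "EX_glc_e",
                   uptake: float = 10.0) -> MediumSpec:
    """Glucose (or another single carbon source) plus open inorganic exchanges."""
    return MediumSpec(
        uptake={carbon_source: uptake},
        carbon_cap=carbon_cap,
        always_open={"EX_o2_e", "EX_nh4_e", "EX_pi_e", "EX_h2o_e", "EX_co2_e"},
    )


def _skeleton(model: Model) -> list[str]:
    """Fixed, elementally balanced core network; returns internal reaction ids
    eligible for GPR assignment (transporters + catabolism, not exchanges or
    biomass)."""
    mets = [
        ("glc_e", "D-glucose", "C6H12O6", "e"),
        ("glc_c", "D-glucose", "C6H12O6", "c"),
        ("ac_e", "acetate", "C2H4O2", "e"),
        ("ac_c", "acetate", "C2H4O2", "c"),
        ("o2_e", "oxygen", "O2", "e"),
        ("o2_c", "oxygen", "O2", "c"),
        ("nh4_e", "ammonium", "H3N", "e"),
        ("nh4_c", "ammonium", "H3N", "c"),
        ("pi_e", "phosphate", "HO4P", "e"),
        ("pi_c", "phosphate", "HO4P", "c"),
        ("h2o_e", "water", "H2O", "e"),
        ("h2o_c", "water", "H2O", "c"),
        ("co2_e", "carbon dioxide", "CO2", "e"),
        ("co2_c", "carbon dioxide", "CO2", "c"),
        ("hex1", "hexose intermediate", "C6H12O6", "c"),
        ("tri1", "triose intermediate", "C3H6O3", "c"),
        ("pyr", "pyruvate-like acid", "C3H4O2", "c"),
        ("ala", "L-alanine-like amino acid", "C3H7NO2", "c"),
    ]
    for mid, name, formula, comp in mets:
        model.add_metabolite(Metabolite(mid, name, formula, 0, comp))

    def rxn(rid, name, stoich, lb=0.0, ub=1000.0, exch=False):
        model.add_reaction(Reaction(
            id=rid, name=name, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, is_exchange=exch,
        ))

    for mid in ("glc_e", "ac_e", "o2_e", "nh4_e", "pi_e", "h2o_e", "co2_e"):
        rxn(f"EX_{mid}", f"{mid} exchange", {mid: -1.0}, lb=-1000.0, exch=True)

    gpr_eligible = []
    transports = [
        ("T_glc", "glucose transport", {"glc_e": -1.0, "glc_c": 1.0}),
        ("T_ac", "acetate transport", {"ac_e": -1.0, "ac_c": 1.0}),
        ("T_o2", "oxygen diffusion", {"o2_e": -1.0, "o2_c": 1.0}),
        ("T_nh4", "ammonium transport", {"nh4_e": -1.0, "nh4_c": 1.0}),
        ("T_pi", "phosphate transport", {"pi_e": -1.0, "pi_c": 1.0}),
        ("T_h2o", "water diffusion", {"h2o_c": -1.0, "h2o_e": 1.0}),
        ("T_co2", "CO2 diffusion", {"co2_c": -1.0, "co2_e": 1.0}),
    ]
    for rid, name, stoich in transports:
        lb = -1000.0 if rid in ("T_h2o", "T_co2", "T_o2") else 0.0
        rxn(rid, name, stoich, lb=lb)
        gpr_eligible.append(rid)

    internals = [
        ("R_glc_iso", "glucose isomerase", {"glc_c": -1.0, "hex1": 1.0}),
        ("R_ac_assim", "acetate assimilation",
         {"ac_c": -3.0, "hex1": 1.0}),
        ("R_cleave", "hexose cleavage", {"hex1": -1.0, "tri1": 2.0}),
        ("R_tri_pyr", "triose dehydratase",
         {"tri1": -1.0, "pyr": 1.0, "h2o_c": 1.0}),
        ("R_pyr_ala", "alanine synthase",
         {"pyr": -1.0, "nh4_c": -1.0, "ala": 1.0}),
        ("R_resp", "pyruvate respiration",
         {"pyr": -1.0, "o2_c": -3.0, "co2_c": 3.0, "h2o_c": 2.0}),
    ]
    for rid, name, stoich in internals:
        rxn(rid, name, stoich)
        gpr_eligible.append(rid)

    rxn("BIOMASS", "biomass assembly",
        {"ala": -1.0, "pyr": -1.0, "pi_c": -0.1})
    model.objective = "BIOMASS"
    model.balance_exempt = {"BIOMASS"}
    return gpr_eligible


def make_reference_model(
    n_core_reactions: int = 30,
    gpr_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> Model:
    """Generate a feasible reference GEM with ``n_core_reactions`` reactions.

    Beyond the fixed skeleton, padding adds parallel catabolic branches
    (hexose → alternative isomer → triose pairs and duplicate triose
    dehydratases), keeping the network free of structural dead ends.
    Feasibility of biomass formation on the default glucose medium is
    verified at build time; GPR structures are drawn per ``gpr_mix``.
    """
    if n_core_reactions < 10:
        raise ValueError("n_core_reactions must be >= 10")
    gpr_mix = dict(gpr_mix or DEFAULT_GPR_MIX)
    total = sum(gpr_mix.values())
    if total <= 0:
        raise ValueError("gpr_mix proportions must sum to a positive value")
    kinds = sorted(gpr_mix)
    probs = np.array([gpr_mix[k] / total for k in kinds])

    for attempt in range(5):
        rng = np.random.default_rng((seed + 7919 * attempt) % 2**31)
        model = Model(id=f"synthref_{seed}", compartments={"c", "e"})
        eligible = _skeleton(model)

        n_pad = n_core_reactions - len(model.reactions)
        j = 0
        while n_pad > 0:
            j += 1
            if n_pad >= 2:
                alt = f"hexalt{j}"
                model.add_metabolite(
                    Metabolite(alt, f"hexose isomer {j}", "C6H12O6", 0, "c")
                )
                model.add_reaction(Reaction(
                    id=f"R_hex_alt{j}", name=f"hexose isomerase {j}",
                    stoichiometry={"hex1": -1.0, alt: 1.0},
                ))
                model.add_reaction(Reaction(
                    id=f"R_alt_cleave{j}", name=f"isomer cleavage {j}",
                    stoichiometry={alt: -1.0, "tri1": 2.0},
                ))
                eligible += [f"R_hex_alt{j}", f"R_alt_cleave{j}"]
                n_pad -= 2
            else:
                model.add_reaction(Reaction(
                    id=f"R_tri_pyr_alt{j}", name=f"triose dehydratase {j}",
                    stoichiometry={"tri1": -1.0, "pyr": 1.0, "h2o_c": 1.0},
                ))
                eligible.append(f"R_tri_pyr_alt{j}")
                n_pad -= 1

        gene_counter = 0

        def new_gene() -> str:
            nonlocal gene_counter
            gene_counter += 1
            return f"rg{gene_counter:04d}"

        ec_counter = 0
        for rid in eligible:
            kind = rng.choice(kinds, p=probs)
            rxn = model.reactions[rid]
            ec_counter += 1
            rxn.ec_numbers = {f"1.1.1.{ec_counter}"}
            if kind == "no-gpr":
                continue
            if kind == "single":
                text = new_gene()
            elif kind == "OR":
                text = f"{new_gene()} or {new_gene()}"
            elif kind == "AND":
                text = f"{new_gene()} and {new_gene()}"
            else:  # nested
                text = f"({new_gene()} and {new_gene()}) or {new_gene()}"
            rxn.gpr = parse_rule(text)
            model.genes |= rxn.gpr.genes()

        model.notes = json.dumps({
            "generator": "orthogem.synthetic.make_reference_model",
            "seed": seed,
            "n_core_reactions": n_core_reactions,
        })
        model.validate()
        sol = solve_fba(model, default_medium())
        if sol.optimal and sol.objective_value > 1e-6:
            return model
    raise RuntimeError(
        f"could not build a feasible reference model for seed {seed}"
    )


@dataclass
class SyntheticScenario:
    """A generated study: reference GEM, genome family, orthogroups, evidence,
    ground-truth reactomes, and (optionally) a gap-fill setup with its
    expected answer."""

    reference: Model
    genomes: dict[str, set[str]]  # genome id -> target gene set
    orthotable: OrthogroupTable
    truth_reactomes: dict[str, set[str]]
    evidence: EvidenceTable
    seed: int
    removed_for_gapfill: dict[str, set[str]] = field(default_factory=dict)
    template: Model | None = None
    expected_minimal: dict[str, set[str]] = field(default_factory=dict)
    expected_verdicts: dict[str, dict[str, str]] = field(default_factory=dict)
    retained_ref_genes: dict[str, set[str]] = field(default_factory=dict)


def simulate_genome_family(
    reference: Model,
    n_genomes: int = 20,
    gene_loss_rate: float = 0.1,
    duplication_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticScenario:
    """Derive a family of target genomes from the reference by gene loss and
    co-ortholog duplication; build the induced orthogroup table, evidence
    tables, and ground-truth reactomes."""
    if not (0 <= gene_loss_rate < 1 and 0 <= duplication_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed % 2**31)
    genome_ids = [f"G{i + 1:02d}" for i in range(n_genomes)]
    ref_genes = sorted(reference.genes)

    orthogroups: dict[str, dict[str, list[str]]] = {}
    genomes: dict[str, set[str]] = {g: set() for g in genome_ids}
    retained: dict[str, set[str]] = {g: set() for g in genome_ids}

    for i, gene in enumerate(ref_genes):
        og = f"OG{i + 1:07d}"
        per_genome: dict[str, list[str]] = {REFERENCE_GENOME: [gene]}
        for genome in genome_ids:
            if rng.random() < gene_loss_rate:
                per_genome[genome] = []
                continue
            copies = [f"t_{genome}_{gene}"]
            if rng.random() < duplication_rate:
                copies.append(f"t_{genome}_{gene}_2")
            per_genome[genome] = copies
            genomes[genome].update(copies)
            retained[genome].add(gene)
        orthogroups[og] = per_genome

    table = OrthogroupTable(
        orthogroups=orthogroups, genomes=[REFERENCE_GENOME] + genome_ids
    )

    # ground truth: original rules evaluated under retained reference genes
    truth: dict[str, set[str]] = {}
    for genome in genome_ids:
        present = set()
        for rxn_id, rxn in reference.reactions.items():
            if rxn.gpr is None or rxn.gpr.evaluate(retained[genome]):
                present.add(rxn_id)
        truth[genome] = present

    # evidence: every retained target gene carries the EC numbers and name of
    # the reaction(s) its ancestral reference gene participates in
    gene_to_rxns: dict[str, list[str]] = {}
    for rxn_id, rxn in reference.reactions.items():
        for g in rxn.genes():
            gene_to_rxns.setdefault(g, []).append(rxn_id)
    evidence = EvidenceTable()
    for genome in genome_ids:
        for gene in sorted(retained[genome]):
            for rxn_id in sorted(gene_to_rxns.get(gene, [])):
                rxn = reference.reactions[rxn_id]
                for copy_name in orthogroups[
                    f"OG{ref_genes.index(gene) + 1:07d}"
                ][genome]:
                    evidence.add(
                        genome, copy_name, set(rxn.ec_numbers),
                        annotation=rxn.name, source="synthetic-annotation",
                    )

    return SyntheticScenario(
        reference=reference,
        genomes=genomes,
        orthotable=table,
        truth_reactomes=truth,
        evidence=evidence,
        seed=seed,
        retained_ref_genes=retained,
    )


def make_gapfill_scenario(
    scenario: SyntheticScenario,
    genome: str,
    n_removed_essential: int = 2,
    n_decoys: int = 5,
    n_no_evidence: int = 0,
    seed: int = 0,
    medium: MediumSpec | None = None,
) -> SyntheticScenario:
    """Extend a scenario with a gap-fill problem of known answer.

    Essential reactions (verified by single-deletion FBA on the genome's
    draft) are removed from the draft; decoy reactions over fresh, isolated
    metabolites are added to the template pool so the minimal fill set stays
    unique; evidence is stripped for a chosen number of removed reactions to
    plant no-evidence curation verdicts.
    """
    from .transfer import build_draft_model, predict_presence

    medium = medium or default_medium()
    rng = np.random.default_rng(seed % 2**31)

    calls = predict_presence(
        scenario.reference, scenario.orthotable, genome, REFERENCE_GENOME
    )
    draft, _ = build_draft_model(scenario.reference, calls, genome)
    base = solve_fba(draft, medium)
    if not (base.optimal and base.objective_value > 1e-6):
        raise ValueError(
            f"genome {genome}: draft does not grow before removal; "
            "pick another genome or seed"
        )

    # single-deletion essentiality, judged on the full reference so that no
    # template candidate can substitute for a removed reaction: this makes
    # the planted minimal fill set unique
    essentials = []
    for rxn_id in sorted(draft.reactions):
        rxn = draft.reactions[rxn_id]
        if rxn.is_exchange or rxn_id == draft.objective or not rxn.ec_numbers \
                or rxn.gpr is None:
            # only gene-backed reactions are removed, so curation verdicts
            # are controlled by the planted evidence, not by orphan status
            continue
        probe = scenario.reference.copy()
        del probe.reactions[rxn_id]
        sol = solve_fba(probe, medium)
        if not sol.optimal or sol.objective_value <= 1e-6:
            essentials.append(rxn_id)
    if len(essentials) < n_removed_essential:
        raise ValueError(
            f"genome {genome}: only {len(essentials)} essential candidates, "
            f"need {n_removed_essential}"
        )
    removed = sorted(
        rng.choice(essentials, size=n_removed_essential, replace=False).tolist()
    )
    gapped = draft.copy()
    for rxn_id in removed:
        del gapped.reactions[rxn_id]
    gapped.id = f"{draft.id}_gapped"

    template = scenario.reference.copy()
    template.id = f"{scenario.reference.id}_template"
    for j in range(n_decoys):
        a, b = f"decoy{j}a", f"decoy{j}b"
        template.add_metabolite(Metabolite(a, f"decoy metabolite {j}a",
                                           "C4H8O4", 0, "c"))
        template.add_metabolite(Metabolite(b, f"decoy metabolite {j}b",
                                           "C4H8O4", 0, "c"))
        template.add_reaction(Reaction(
            id=f"R_decoy{j}", name=f"decoy isomerase {j}",
            stoichiometry={a: -1.0, b: 1.0},
            lower_bound=-1000.0, upper_bound=1000.0,
        ))

    # strip evidence for a subset of removed reactions
    no_evidence = sorted(
        rng.choice(removed, size=n_no_evidence, replace=False).tolist()
    ) if n_no_evidence else []
    evidence = EvidenceTable(rows=list(scenario.evidence.rows))
    for rxn_id in no_evidence:
        rxn = scenario.reference.reactions[rxn_id]
        evidence.rows = [
            row for row in evidence.rows
            if not (
                row[0] == genome
                and (row[2] & frozenset(rxn.ec_numbers) or row[3] == rxn.name)
            )
        ]

    expected_verdicts = {
        rxn_id: ("no-evidence" if rxn_id in no_evidence else "evidence-found")
        for rxn_id in removed
    }
    out = SyntheticScenario(
        reference=scenario.reference,
        genomes=scenario.genomes,
        orthotable=scenario.orthotable,
        truth_reactomes=scenario.truth_reactomes,
        evidence=evidence,
        seed=scenario.seed,
        retained_ref_genes=scenario.retained_ref_genes,
        removed_for_gapfill={genome: set(removed)},
        template=template,
        expected_minimal={genome: set(removed)},
        expected_verdicts={genome: expected_verdicts},
    )
    out.gapped_draft = gapped  # type: ignore[attr-defined]
    return out


def write_scenario(scenario: SyntheticScenario, directory: str | Path) -> None:
    """Serialize a scenario bundle: models (JSON + SBML), Orthogroups.tsv,
    evidence and truth TSVs, and a manifest with the seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_model(scenario.reference, directory / "reference.json")
    write_model(scenario.reference, directory / "reference.xml")
    scenario.orthotable.to_tsv(directory / "Orthogroups.tsv")
    scenario.evidence.to_tsv(directory / "evidence.tsv")
    with open(directory / "truth_reactomes.tsv", "w") as fh:
        fh.write("genome\treactions\n")
        for genome in sorted(scenario.truth_reactomes):
            fh.write(
                f"{genome}\t{','.join(sorted(scenario.truth_reactomes[genome]))}\n"
            )
    if scenario.template is not None:
        write_model(scenario.template, directory / "template.json")
    manifest = {
        "seed": scenario.seed,
        "reference_id": scenario.reference.id,
        "genomes": sorted(scenario.genomes),
        "reference_genome_column": REFERENCE_GENOME,
        "removed_for_gapfill": {
            g: sorted(v) for g, v in scenario.removed_for_gapfill.items()
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
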