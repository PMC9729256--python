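"""Core data model for genome-scale metabolic models (GEMs).

A GEM is a stoichiometric reaction network annotated with gene-reaction
rules (GPRs): positive Boolean formulas over gene presence that state which
gene content suffices for a reaction to be catalysed.  This module holds the
in-memory containers, the canonical JSON dialect, and structural quality
checks (composition summary, dead-end metabolites, elemental mass balance,
carbon content) used throughout the reconstruction pipeline.

Conventions
-----------
* Flux units are mmol gCDW^-1 h^-1; the biomass flux is the specific growth
  rate in h^-1.
* Exchange reactions touch exactly one metabolite; negative flux is uptake,
  positive flux is secretion (standard COBRA sign convention).
* An *orphan* reaction is a non-exchange reaction without a GPR
  (spontaneous reactions, lumped macromolecular syntheses, biomass).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .gpr import GprRule, parse_rule

__all__ = [
    "Metabolite",
    "Reaction",
    "Model",
    "ModelSummary",
    "ModelValidationError",
    "FormulaError",
    "parse_formula",
    "carbon_count",
    "read_model",
    "write_model",
    "summarize_model",
    "find_dead_end_metabolites",
    "check_mass_balance",
]


class ModelValidationError(ValueError):
    """A model or model file violates a structural invariant."""


class FormulaError(ValueError):
    """An elemental formula string could not be parsed."""


_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``"C6H12O6"`` into an element→count map.

    Raises :class:`FormulaError` naming the offending token if the string
    contains anything but element symbols followed by optional counts.
    """
    if not isinstance(formula, str) or formula == "":
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _ELEMENT_RE.match(formula, pos)
        if m is None or m.end() == pos:
            raise FormulaError(
                f"unparsable token {formula[pos:]!r} in formula {formula!r}"
            )
        element, digits = m.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts


def carbon_count(formula: str) -> int:
    """Number of carbon atoms per molecule of ``formula`` (0 if carbon-free)."""
    return parse_formula(formula).get("C", 0)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = "c"

    def element_counts(self) -> dict[str, int] | None:
        """Element→count map, or None when no formula is recorded."""
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GprRule | None = None
    ec_numbers: set[str] = field(default_factory=set)
    is_exchange: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id} must touch exactly one metabolite, "
                f"touches {len(self.stoichiometry)}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def irreversible(self) -> bool:
        return self.lower_bound >= 0 or self.upper_bound <= 0

    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()


@dataclass
class Model:
    """A genome-scale metabolic model.

    ``objective`` names the biomass reaction; its flux under FBA is the
    in-silico specific growth rate.
    """

    id: str
    compartments: set[str] = field(default_factory=set)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: set[str] = field(default_factory=set)
    objective: str | None = None
    # reactions exempt from mass-balance checking beyond exchanges
    # (biomass, lumped macromolecular syntheses), by explicit id
    balance_exempt: set[str] = field(default_factory=set)
    notes: str = ""

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        self.compartments.add(met.compartment)
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolite {met_id}"
                )
        self.reactions[rxn.id] = rxn
        self.genes |= rxn.genes()

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
            missing = rxn.genes() - self.genes
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id} GPR uses undeclared genes {sorted(missing)}"
                )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id} in undeclared compartment {met.compartment}"
                )
        if self.objective is not None and self.objective not in self.reactions:
            raise ModelValidationError(
                f"objective reaction {self.objective} not in model"
            )

    def copy(self) -> "Model":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass(frozen=True)
class ModelSummary:
    compartments: int
    genes: int
    reactions: int
    exchange_reactions: int
    irreversible_reactions: int
    orphan_reactions: int
    metabolites: int
    dead_end_metabolites: int

    def to_tsv(self) -> str:
        rows = [
            ("Compartments", self.compartments),
            ("Genes", self.genes),
            ("Reactions", self.reactions),
            ("Exchange reactions", self.exchange_reactions),
            ("Irreversible reactions", self.irreversible_reactions),
            ("Orphan reactions", self.orphan_reactions),
            ("Metabolites", self.metabolites),
            ("Dead-end metabolites", self.dead_end_metabolites),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def summarize_model(model: Model) -> ModelSummary:
    """Composition counts of a model (the usual GEM report card)."""
    exchange = sum(1 for r in model.reactions.values() if r.is_exchange)
    irreversible = sum(1 for r in model.reactions.values() if r.irreversible)
    orphan = sum(
        1
        for r in model.reactions.values()
        if not r.is_exchange and r.gpr is None
    )
    return ModelSummary(
        compartments=len(model.compartments),
        genes=len(model.genes),
        reactions=len(model.reactions),
        exchange_reactions=exchange,
        irreversible_reactions=irreversible,
        orphan_reactions=orphan,
        metabolites=len(model.metabolites),
        dead_end_metabolites=len(find_dead_end_metabolites(model)),
    )


def _channels(model: Model) -> dict[str, tuple[set[str], set[str]]]:
    """Per metabolite: (producing reaction ids, consuming reaction ids).

    Direction-resolved: a reversible reaction is both a producer and a
    consumer of every participant; an irreversible reaction produces its
    products and consumes its substrates (orientation-aware for reactions
    fixed in the reverse direction). Exchange reactions count.
    """
    chans: dict[str, tuple[set[str], set[str]]] = {
        m: (set(), set()) for m in model.metabolites
    }
    for rxn in model.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff == 0:
                continue
            producers, consumers = chans[met_id]
            if (coeff > 0 and fwd) or (coeff < 0 and rev):
                producers.add(rxn.id)
            if (coeff < 0 and fwd) or (coeff > 0 and rev):
                consumers.add(rxn.id)
    return chans


def find_dead_end_metabolites(model: Model) -> set[str]:
    """Metabolites that cannot be both produced and consumed by the network.

    A metabolite is dead-end unless some reaction can produce it and a
    *different* reaction can consume it.  A metabolite whose only channels
    come from one reversible reaction is therefore dead-end (its production
    and consumption channels coincide), matching the conventional gap
    criterion used when auditing draft reconstructions.
    """
    dead: set[str] = set()
    for met_id, (producers, consumers) in _channels(model).items():
        if not producers or not consumers or len(producers | consumers) == 1:
            dead.add(met_id)
    return dead


def check_mass_balance(
    model: Model,
) -> tuple[list[tuple[str, dict[str, float]]], list[str]]:
    """Elemental balance check over all non-exempt internal reactions.

    Returns ``(imbalanced, unchecked)`` where ``imbalanced`` lists
    ``(reaction id, element → net delta)`` for every checked reaction that
    does not conserve every element, and ``unchecked`` lists reactions that
    could not be checked because a participant lacks a formula.  Exchange
    reactions and reactions in ``model.balance_exempt`` (biomass,
    macromolecular syntheses) are excluded by contract.
    """
    imbalanced: list[tuple[str, dict[str, float]]] = []
    unchecked: list[str] = []
    for rxn in model.reactions.values():
        if rxn.is_exchange or rxn.id in model.balance_exempt:
            continue
        delta: dict[str, float] = {}
        ok = True
        for met_id, coeff in rxn.stoichiometry.items():
            counts = model.metabolites[met_id].element_counts()
            if counts is None:
                unchecked.append(rxn.id)
                ok = False
                break
            for element, n in counts.items():
                delta[element] = delta.get(element, 0.0) + coeff * n
        if not ok:
            continue
        delta = {e: d for e, d in delta.items() if abs(d) > 1e-9}
        if delta:
            imbalanced.append((rxn.id, delta))
    return imbalanced, unchecked


# ---------------------------------------------------------------------------
# JSON dialect (canonical round-trip format; schema in docs/json_model.md)
# ---------------------------------------------------------------------------

def _model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "compartments": sorted(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_text() if r.gpr is not None else None,
                "ec_numbers": sorted(r.ec_numbers),
                "is_exchange": r.is_exchange,
                "notes": r.notes,
            }
            for r in model.reactions.values()
        ],
        "genes": sorted(model.genes),
        "objective": model.objective,
        "balance_exempt": sorted(model.balance_exempt),
        "notes": model.notes,
    }


def _model_from_dict(data: Mapping) -> Model:
    model = Model(
        id=data["id"],
        compartments=set(data.get("compartments", [])),
        objective=data.get("objective"),
        balance_exempt=set(data.get("balance_exempt", [])),
        notes=data.get("notes", ""),
    )
    for m in data.get("metabolites", []):
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=m.get("formula"),
                charge=m.get("charge"),
                compartment=m.get("compartment", "c"),
            )
        )
    for r in data.get("reactions", []):
        gpr_text = r.get("gpr")
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -1000.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=parse_rule(gpr_text) if gpr_text else None,
                ec_numbers=set(r.get("ec_numbers", [])),
                is_exchange=bool(r.get("is_exchange", False)),
                notes=r.get("notes", ""),
            )
        )
    model.genes |= set(data.get("genes", []))
    model.validate()
    return model


def read_model(path: str | Path, format: str | None = None) -> Model:
    """Read a model from SBML (Level 3 + FBC) or the JSON dialect.

    ``format`` is inferred from the suffix (``.xml``/``.sbml`` → sbml,
    ``.json`` → json) when not given.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelValidationError(f"malformed JSON model {path}: {exc}")
        return _model_from_dict(data)
    if format == "sbml":
        from .io_sbml import read_sbml_model

        return read_sbml_model(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: Model, path: str | Path, format: str | None = None) -> None:
    """Write a model to the JSON dialect or SBML L3V1 + FBC v2."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if format == "sbml":
        from .io_sbml import write_sbml_model

        write_sbml_model(model, path)
        return
    raise ValueError(f"unknown model format {format!r}")
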