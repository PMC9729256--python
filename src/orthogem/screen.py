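"""Pathway-presence screening across genomes.

Screens ask, per genome, whether a named pathway module is encoded —
e.g. the glyoxylate cycle (isocitrate lyase EC 4.1.3.1 + malate synthase
EC 2.3.3.9), whose presence is the genomic correlate of growth on C2
compounds (ethanol, acetate) as sole carbon source in acetic acid bacteria.
Members resolve either against a reaction-presence matrix built from a
second reference model, or against EC-annotated evidence tables; ``unknown``
is reported only when a genome lacks annotation coverage, never silently
coerced to absent.

Packaged fixtures carry the published screen read-outs for *Acetobacter*:
growth-on-ethanol phenotypes with glyoxylate-enzyme presence per species,
and the membrane/soluble transhydrogenase pattern across the eleven
complete genomes, where the two forms are mutually exclusive except in one
species (*A. aceti*).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .gapfill import EvidenceTable
from .transfer import ReactionPresenceMatrix

__all__ = [
    "ScreenDefinition",
    "ScreenMember",
    "ScreenResult",
    "screen_genomes",
    "mutual_exclusivity_report",
    "concordance_with_phenotype",
    "GLYOXYLATE_CYCLE",
    "RESPIRATORY_CHAIN",
    "TRANSHYDROGENASES",
    "load_glyoxylate_fixture",
    "load_transhydrogenase_fixture",
]

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


@dataclass(frozen=True)
class ScreenMember:
    label: str
    ecs: frozenset[str] = frozenset()
    reaction_id: str | None = None

    def __post_init__(self) -> None:
        if not self.ecs and self.reaction_id is None:
            raise ValueError(f"member {self.label}: needs EC set or reaction id")
        for ec in self.ecs:
            if not _EC_RE.match(ec):
                raise ValueError(f"member {self.label}: invalid EC {ec!r}")


@dataclass(frozen=True)
class ScreenDefinition:
    name: str
    members: tuple[ScreenMember, ...]
    rule: str = "all-members"  # all-members | any-member | member-wise

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"screen {self.name}: needs at least one member")
        if self.rule not in ("all-members", "any-member", "member-wise"):
            raise ValueError(f"screen {self.name}: unknown rule {self.rule!r}")


GLYOXYLATE_CYCLE = ScreenDefinition(
    "glyoxylate_cycle",
    (
        ScreenMember("isocitrate_lyase", frozenset({"4.1.3.1"})),
        ScreenMember("malate_synthase", frozenset({"2.3.3.9"})),
    ),
    "all-members",
)

RESPIRATORY_CHAIN = ScreenDefinition(
    "aerobic_respiratory_chain",
    (
        ScreenMember("nadh_dehydrogenase_I", frozenset({"7.1.1.2"})),
        ScreenMember("nadh_dehydrogenase_II", frozenset({"1.6.5.9"})),
        ScreenMember("cytochrome_bo3_oxidase", frozenset({"7.1.1.3"})),
        ScreenMember("cytochrome_bd_oxidase", frozenset({"7.1.1.7"})),
    ),
    "all-members",
)

TRANSHYDROGENASES = ScreenDefinition(
    "transhydrogenases",
    (
        ScreenMember("membrane_transhydrogenase", frozenset({"7.1.1.1"})),
        ScreenMember("soluble_transhydrogenase", frozenset({"1.6.1.1"})),
    ),
    "member-wise",
)


@dataclass
class ScreenResult:
    definition: ScreenDefinition
    genomes: list[str]
    grid: dict[tuple[str, str], str]  # (genome, member label) -> yes|no|unknown
    verdicts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.verdicts:
            self.verdicts = {
                g: self._verdict(g) for g in self.genomes
            }

    def _verdict(self, genome: str) -> str:
        cells = [self.grid[(genome, m.label)] for m in self.definition.members]
        if self.definition.rule == "member-wise":
            return "member-wise"
        if self.definition.rule == "all-members":
            if any(c == "no" for c in cells):
                return "no"
            if all(c == "yes" for c in cells):
                return "yes"
            return "unknown"
        # any-member
        if any(c == "yes" for c in cells):
            return "yes"
        if all(c == "no" for c in cells):
            return "no"
        return "unknown"

    def to_tsv(self, path: str | Path) -> None:
        labels = [m.label for m in self.definition.members]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["genome"] + labels + ["verdict"])
            for g in self.genomes:
                writer.writerow(
                    [g] + [self.grid[(g, l)] for l in labels] + [self.verdicts[g]]
                )


def _cell_from_matrix(
    matrix: ReactionPresenceMatrix, member: ScreenMember, genome: str
) -> str:
    if member.reaction_id is None:
        raise ValueError(
            f"member {member.label} has no reaction id; cannot resolve against a "
            "presence matrix"
        )
    if member.reaction_id not in matrix.reactions:
        raise ValueError(
            f"member {member.label}: reaction {member.reaction_id} not in matrix"
        )
    return "yes" if matrix.call(member.reaction_id, genome).present else "no"


def _cell_from_evidence(
    evidence: EvidenceTable, member: ScreenMember, genome: str
) -> str:
    if not member.ecs:
        raise ValueError(
            f"member {member.label} has no EC numbers; cannot resolve against "
            "an evidence table"
        )
    if not evidence.has_genome(genome):
        return "unknown"
    for ec in member.ecs:
        if evidence.genes_with_ec(genome, ec):
            return "yes"
    return "no"


def screen_genomes(
    definitions: list[ScreenDefinition],
    source: ReactionPresenceMatrix | EvidenceTable,
    genomes: list[str] | None = None,
) -> dict[str, ScreenResult]:
    """Fill the genomes × members grid for each screen definition.

    ``source`` is either a presence matrix (members resolved by reference
    reaction id) or an evidence table (members resolved by EC lookup).
    """
    if isinstance(source, ReactionPresenceMatrix):
        genome_list = genomes or source.genomes
        cell = lambda m, g: _cell_from_matrix(source, m, g)  # noqa: E731
    elif isinstance(source, EvidenceTable):
        genome_list = genomes or sorted(source.genomes())
        cell = lambda m, g: _cell_from_evidence(source, m, g)  # noqa: E731
    else:
        raise TypeError(
            "source must be a ReactionPresenceMatrix or an EvidenceTable"
        )
    results: dict[str, ScreenResult] = {}
    for definition in definitions:
        grid = {
            (g, m.label): cell(m, g)
            for g in genome_list
            for m in definition.members
        }
        results[definition.name] = ScreenResult(
            definition=definition, genomes=list(genome_list), grid=grid
        )
    return results


def mutual_exclusivity_report(
    result: ScreenResult, member_pair: tuple[str, str]
) -> tuple[dict[str, str], int]:
    """Classify each genome for a pair of members; count "both" exceptions.

    Classifications: ``first-only``, ``second-only``, ``both``, ``neither``
    (genomes with an unknown cell for either member are classified
    ``unknown``). Returns ``(classification per genome, number of "both")``.
    """
    first, second = member_pair
    labels = {m.label for m in result.definition.members}
    for label in member_pair:
        if label not in labels:
            raise ValueError(f"member {label!r} not in screen {result.definition.name}")
    classes: dict[str, str] = {}
    for g in result.genomes:
        a, b = result.grid[(g, first)], result.grid[(g, second)]
        if "unknown" in (a, b):
            classes[g] = "unknown"
        elif a == "yes" and b == "yes":
            classes[g] = "both"
        elif a == "yes":
            classes[g] = "first-only"
        elif b == "yes":
            classes[g] = "second-only"
        else:
            classes[g] = "neither"
    return classes, sum(1 for c in classes.values() if c == "both")


def concordance_with_phenotype(
    result: ScreenResult,
    phenotype: dict[str, str],
    weak_as: str = "+",
) -> list[tuple[str, str, str, str]]:
    """Discordance report between a growth phenotype and a screen verdict.

    ``phenotype`` maps genome → {+, −, w, ?}; "?" rows are excluded from the
    tallies, "w" (weak growth) maps to ``weak_as`` (default "+", matching the
    convention of counting weak growers as able to grow).  Returns rows
    ``(genome, phenotype, screen verdict, discordance type)`` where type is
    ``phenotype-positive-screen-negative`` (candidate false-positive growth
    test) or ``phenotype-negative-screen-positive``.
    """
    report: list[tuple[str, str, str, str]] = []
    for genome in result.genomes:
        pheno = phenotype.get(genome, "?")
        effective = weak_as if pheno == "w" else pheno
        if effective == "?":
            continue
        verdict = result.verdicts.get(genome, "unknown")
        if verdict == "unknown":
            continue
        if effective == "+" and verdict == "no":
            report.append(
                (genome, pheno, verdict, "phenotype-positive-screen-negative")
            )
        elif effective in ("-", "−") and verdict == "yes":
            report.append(
                (genome, pheno, verdict, "phenotype-negative-screen-positive")
            )
    return report


# --- packaged fixtures ------------------------------------------------------


def _data_path(name: str):
    return resources.files("orthogem.data").joinpath(name)


def load_glyoxylate_fixture() -> tuple[ScreenResult, dict[str, str]]:
    """Published glyoxylate-cycle screen per *Acetobacter* species.

    Returns the screen result (isocitrate lyase / malate synthase presence
    per species; species without a sequenced genome are ``unknown``) and the
    growth-on-ammonium+ethanol phenotype column ({+, −, w, ?}).
    """
    grid: dict[tuple[str, str], str] = {}
    phenotype: dict[str, str] = {}
    genomes: list[str] = []
    with _data_path("glyoxylate_screen.tsv").open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for species, growth, n_genomes, icl, ms in reader:
            genomes.append(species)
            phenotype[species] = growth
            to_cell = {"Yes": "yes", "No": "no", "?": "unknown"}
            grid[(species, "isocitrate_lyase")] = to_cell[icl]
            grid[(species, "malate_synthase")] = to_cell[ms]
    result = ScreenResult(
        definition=GLYOXYLATE_CYCLE, genomes=genomes, grid=grid
    )
    return result, phenotype


def load_transhydrogenase_fixture() -> ScreenResult:
    """Membrane vs soluble NAD(P)+ transhydrogenase presence across the
    eleven complete *Acetobacter* genomes, as published: the two forms are
    mutually exclusive except in *A. aceti*, which encodes both."""
    grid: dict[tuple[str, str], str] = {}
    genomes: list[str] = []
    with _data_path("transhydrogenase_screen.tsv").open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for genome, membrane, soluble in reader:
            genomes.append(genome)
            grid[(genome, "membrane_transhydrogenase")] = membrane
            grid[(genome, "soluble_transhydrogenase")] = soluble
    return ScreenResult(
        definition=TRANSHYDROGENASES, genomes=genomes, grid=grid
    )
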