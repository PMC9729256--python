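"""Orthogroup tables and identifier maps.

Orthogroups — sets of genes across genomes descended from one ancestral
gene — are the unit of cross-genome gene equivalence used to rewrite
gene-reaction rules.  Orthology inference itself is upstream (OrthoFinder);
this module only consumes its ``Orthogroups.tsv`` output: first column the
orthogroup id, one column per genome, cells holding comma-plus-space
separated gene (or protein) id lists, empty cells allowed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "OrthogroupTable",
    "IdMap",
    "OrthologyError",
    "read_orthogroups",
    "read_idmap",
    "single_copy_orthogroups",
    "core_orthogroups",
]


class OrthologyError(ValueError):
    pass


@dataclass
class IdMap:
    """Protein→gene identifier translation for one or more genomes."""

    mapping: dict[str, dict[str, str]] = field(default_factory=dict)

    def translate(self, genome: str, protein_id: str) -> str | None:
        return self.mapping.get(genome, {}).get(protein_id)


def read_idmap(paths: dict[str, str | Path]) -> IdMap:
    """Read per-genome 2-column TSVs (protein_id, gene_id) into one IdMap."""
    mapping: dict[str, dict[str, str]] = {}
    for genome, path in paths.items():
        df = pd.read_csv(path, sep="\t", header=None, names=["protein", "gene"],
                         dtype=str, comment="#")
        mapping[genome] = dict(zip(df["protein"], df["gene"]))
    return IdMap(mapping)


@dataclass
class OrthogroupTable:
    orthogroups: dict[str, dict[str, list[str]]]
    genomes: list[str]
    gene_index: dict[tuple[str, str], str] = field(default_factory=dict)
    unmapped_proteins: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_index:
            for og, per_genome in self.orthogroups.items():
                for genome, genes in per_genome.items():
                    for gene in genes:
                        key = (genome, gene)
                        if key in self.gene_index:
                            raise OrthologyError(
                                f"gene {gene} of genome {genome} appears in both "
                                f"{self.gene_index[key]} and {og}"
                            )
                        self.gene_index[key] = og

    def orthogroup_of(self, genome: str, gene: str) -> str | None:
        return self.gene_index.get((genome, gene))

    def members(self, orthogroup: str, genome: str) -> list[str]:
        return self.orthogroups.get(orthogroup, {}).get(genome, [])

    def genes_of_genome(self, genome: str) -> set[str]:
        out: set[str] = set()
        for per_genome in self.orthogroups.values():
            out.update(per_genome.get(genome, []))
        return out

    def counts(self, orthogroup: str) -> dict[str, int]:
        per_genome = self.orthogroups[orthogroup]
        return {g: len(per_genome.get(g, [])) for g in self.genomes}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["Orthogroup"] + self.genomes)
            for og in sorted(self.orthogroups):
                row = [og] + [
                    ", ".join(self.orthogroups[og].get(g, [])) for g in self.genomes
                ]
                writer.writerow(row)


def read_orthogroups(path: str | Path, idmap: IdMap | None = None) -> OrthogroupTable:
    """Parse an ``Orthogroups.tsv`` table, optionally translating protein ids.

    Proteins that cannot be translated are dropped from the table but kept
    in ``unmapped_proteins`` (orthogroup, genome, protein) so they can be
    reported — identifier mismatches between annotation versions are a known
    failure mode of reference-based transfer and must surface.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise OrthologyError(f"{path}: empty orthogroup table")
        genomes = [h.strip() for h in header[1:]]
        if not genomes:
            raise OrthologyError(f"{path}: no genome columns in header")
        orthogroups: dict[str, dict[str, list[str]]] = {}
        unmapped: list[tuple[str, str, str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0].strip() == ""):
                continue
            if len(row) != len(genomes) + 1:
                raise OrthologyError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, "
                    f"expected {len(genomes) + 1})"
                )
            og = row[0].strip()
            per_genome: dict[str, list[str]] = {}
            for genome, cell in zip(genomes, row[1:]):
                ids = [t.strip() for t in cell.split(",") if t.strip()]
                if idmap is not None:
                    translated = []
                    for pid in ids:
                        gid = idmap.translate(genome, pid)
                        if gid is None:
                            unmapped.append((og, genome, pid))
                        else:
                            translated.append(gid)
                    ids = translated
                per_genome[genome] = ids
            orthogroups[og] = per_genome
    table = OrthogroupTable(orthogroups=orthogroups, genomes=genomes)
    table.unmapped_proteins = unmapped
    return table


def single_copy_orthogroups(table: OrthogroupTable) -> set[str]:
    """Orthogroups with exactly one gene in every genome of the table."""
    return {
        og
        for og in table.orthogroups
        if all(n == 1 for n in table.counts(og).values())
    }


def core_orthogroups(table: OrthogroupTable) -> set[str]:
    """Orthogroups with at least one gene in every genome of the table."""
    return {
        og
        for og in table.orthogroups
        if all(n >= 1 for n in table.counts(og).values())
    }
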