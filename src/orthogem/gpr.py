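"""Boolean gene-reaction rules (GPRs): parsing, evaluation, substitution.

GPRs here are *positive* Boolean formulas — gene literals combined with AND
(enzyme complexes: all subunits required) and OR (isoenzymes/co-orthologs:
any one suffices).  There is no negation; evaluation is therefore monotone
in the present-gene set.

The parser accepts ``and``/``or`` case-insensitively with parentheses; AND
binds tighter than OR.  Rules are kept as explicit expression trees and are
never simplified behind the caller's back — orthology substitution only
prunes branches that became logically false, so the rewritten rule remains
auditable against the reference rule it came from.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "GprParseError",
    "GprRule",
    "Gene",
    "And",
    "Or",
    "FALSE",
    "parse_rule",
    "evaluate_rule",
    "substitute_rule",
    "SubstitutionReport",
    "GeneSubstitution",
]


class GprParseError(ValueError):
    """Raised on malformed rule text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# --- expression tree -------------------------------------------------------


class _Node:
    def genes(self) -> set[str]:
        raise NotImplementedError

    def evaluate(self, present: frozenset[str]) -> bool:
        raise NotImplementedError

    def to_text(self, parent: str | None = None) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Gene(_Node):
    name: str

    def genes(self) -> set[str]:
        return {self.name}

    def evaluate(self, present: frozenset[str]) -> bool:
        return self.name in present

    def to_text(self, parent: str | None = None) -> str:
        return self.name


@dataclass(frozen=True)
class _False(_Node):
    """Logical false: a reference gene with no ortholog in the target."""

    def genes(self) -> set[str]:
        return set()

    def evaluate(self, present: frozenset[str]) -> bool:
        return False

    def to_text(self, parent: str | None = None) -> str:
        return "__absent__"


FALSE = _False()


@dataclass(frozen=True)
class And(_Node):
    children: tuple[_Node, ...]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, present: frozenset[str]) -> bool:
        return all(c.evaluate(present) for c in self.children)

    def to_text(self, parent: str | None = None) -> str:
        inner = " and ".join(c.to_text("and") for c in self.children)
        return f"({inner})" if parent == "and" else inner


@dataclass(frozen=True)
class Or(_Node):
    children: tuple[_Node, ...]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, present: frozenset[str]) -> bool:
        return any(c.evaluate(present) for c in self.children)

    def to_text(self, parent: str | None = None) -> str:
        inner = " or ".join(c.to_text("or") for c in self.children)
        # OR under AND (or under another OR's operand slot) needs parentheses
        return f"({inner})" if parent in ("and", "or") else inner


@dataclass(frozen=True)
class GprRule:
    """A parsed gene-reaction rule.

    ``source_text`` preserves the text the rule was parsed from (audit
    trail); structural equality ignores it.
    """

    tree: _Node
    source_text: str = field(default="", compare=False)

    def genes(self) -> set[str]:
        return self.tree.genes()

    def evaluate(self, present_genes: Iterable[str]) -> bool:
        return self.tree.evaluate(frozenset(present_genes))

    def to_text(self) -> str:
        return self.tree.to_text()

    @property
    def is_false(self) -> bool:
        return isinstance(self.tree, _False)


# --- parser ----------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tok = m.group(1)
        start = m.start(1)
        low = tok.lower()
        if tok in "()":
            tokens.append((tok, tok, start))
        elif low in ("and", "or"):
            tokens.append(("op", low, start))
        else:
            tokens.append(("gene", tok, start))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; grammar: or := and ('or' and)*;
    and := atom ('and' atom)*; atom := gene | '(' or ')'."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> _Node:
        node = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def parse_or(self) -> _Node:
        children = [self.parse_and()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0] == "op" and tok[1] == "or":
                self.next()
                children.append(self.parse_and())
            else:
                break
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and(self) -> _Node:
        children = [self.parse_atom()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0] == "op" and tok[1] == "and":
                self.next()
                children.append(self.parse_atom())
            else:
                break
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_atom(self) -> _Node:
        tok = self.next()
        kind, value, pos = tok
        if kind == "gene":
            return Gene(value)
        if kind == "(":
            node = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GprParseError("unbalanced parenthesis", pos)
            self.next()
            return node
        raise GprParseError(f"dangling operator or misplaced {value!r}", pos)


def parse_rule(text: str) -> GprRule | None:
    """Parse GPR text into a rule tree; empty/whitespace text yields ``None``.

    ``None`` (no GPR at all) is deliberately distinct from any gene-bearing
    rule: reactions without rules are transferred unconditionally, while a
    rule that evaluates false makes its reaction absent.
    """
    if text is None or text.strip() == "":
        return None
    tree = _Parser(text).parse()
    return GprRule(tree=tree, source_text=text)


def evaluate_rule(rule: GprRule, present_genes: Iterable[str]) -> bool:
    """Standard Boolean semantics; genes outside ``present_genes`` are false.

    Passing an empty rule (``None``) is a contract violation — the caller
    (reaction transfer) owns the no-GPR policy.
    """
    if rule is None:
        raise ValueError(
            "evaluate_rule called with an empty rule; no-GPR reactions are "
            "handled by the transfer layer, not by rule evaluation"
        )
    return rule.evaluate(present_genes)


# --- orthology-based substitution -----------------------------------------


@dataclass(frozen=True)
class GeneSubstitution:
    """Fate of one reference gene during rule rewriting."""

    gene: str
    status: str  # mapped | absent-in-target | unmapped-no-orthogroup
    orthogroup: str | None
    replacements: tuple[str, ...]


@dataclass
class SubstitutionReport:
    """Per-gene outcomes of substituting a reference rule for a target genome.

    ``and_shared_orthogroup_flag`` is set when two or more AND-joined
    reference genes fall into the same orthogroup that also holds target
    genes — the situation the reconstruction protocol singles out for manual
    curation (an apparent complex whose subunits collapse onto one ortholog
    family cannot be rewritten mechanically with confidence).
    """

    substitutions: list[GeneSubstitution] = field(default_factory=list)
    and_shared_orthogroup_flag: bool = False

    @property
    def unmapped_genes(self) -> list[str]:
        return [
            s.gene for s in self.substitutions if s.status == "unmapped-no-orthogroup"
        ]

    @property
    def absent_genes(self) -> list[str]:
        return [s.gene for s in self.substitutions if s.status == "absent-in-target"]


def _and_joined_gene_groups(node: _Node) -> list[tuple[str, ...]]:
    """Collect, for every AND node, its directly AND-joined gene leaves."""
    groups: list[tuple[str, ...]] = []

    def visit(n: _Node) -> None:
        if isinstance(n, And):
            leaves = tuple(c.name for c in n.children if isinstance(c, Gene))
            if len(leaves) >= 2:
                groups.append(leaves)
            for c in n.children:
                visit(c)
        elif isinstance(n, Or):
            for c in n.children:
                visit(c)

    visit(node)
    return groups


def _prune_false(node: _Node) -> _Node:
    """Remove logically-false branches without other restructuring.

    OR drops false children (an absent isoenzyme does not disable the
    reaction); AND collapses to false if any child is false.  Single-child
    operators unwrap.  No further simplification is performed.
    """
    if isinstance(node, Or):
        kept = [
            p for c in node.children if not isinstance(p := _prune_false(c), _False)
        ]
        if not kept:
            return FALSE
        return kept[0] if len(kept) == 1 else Or(tuple(kept))
    if isinstance(node, And):
        pruned = [_prune_false(c) for c in node.children]
        if any(isinstance(p, _False) for p in pruned):
            return FALSE
        return pruned[0] if len(pruned) == 1 else And(tuple(pruned))
    return node


def substitute_rule(
    rule: GprRule,
    orthotable,
    reference_genome: str,
    target_genome: str,
) -> tuple[GprRule, SubstitutionReport]:
    """Rewrite a reference-genome rule in terms of target-genome genes.

    Each reference gene is replaced by the OR over all target-genome genes
    of its orthogroup (the co-ortholog assumption: any member of the family
    can supply the function).  A gene whose orthogroup holds no target gene
    becomes logical false; a gene in no orthogroup at all also becomes false
    but is reported as ``unmapped-no-orthogroup`` so the transfer layer can
    surface it for manual checking rather than silently dropping the
    reaction.
    """
    report = SubstitutionReport()
    gene_to_og: dict[str, str | None] = {}
    replacements: dict[str, _Node] = {}

    for gene in sorted(rule.genes()):
        if not gene or not isinstance(gene, str):
            raise ValueError(f"malformed reference gene id {gene!r}")
        og = orthotable.orthogroup_of(reference_genome, gene)
        gene_to_og[gene] = og
        if og is None:
            report.substitutions.append(
                GeneSubstitution(gene, "unmapped-no-orthogroup", None, ())
            )
            replacements[gene] = FALSE
            continue
        target_genes = tuple(sorted(orthotable.members(og, target_genome)))
        if not target_genes:
            report.substitutions.append(
                GeneSubstitution(gene, "absent-in-target", og, ())
            )
            replacements[gene] = FALSE
        else:
            report.substitutions.append(
                GeneSubstitution(gene, "mapped", og, target_genes)
            )
            if len(target_genes) == 1:
                replacements[gene] = Gene(target_genes[0])
            else:
                replacements[gene] = Or(tuple(Gene(g) for g in target_genes))

    # curation flag: >=2 AND-joined reference genes sharing one orthogroup
    # that maps to target genes
    for group in _and_joined_gene_groups(rule.tree):
        by_og: dict[str, int] = {}
        for g in group:
            og = gene_to_og.get(g)
            if og is not None and orthotable.members(og, target_genome):
                by_og[og] = by_og.get(og, 0) + 1
        if any(n >= 2 for n in by_og.values()):
            report.and_shared_orthogroup_flag = True

    def rewrite(n: _Node) -> _Node:
        if isinstance(n, Gene):
            return replacements[n.name]
        if isinstance(n, And):
            return And(tuple(rewrite(c) for c in n.children))
        if isinstance(n, Or):
            return Or(tuple(rewrite(c) for c in n.children))
        return n

    new_tree = _prune_false(rewrite(rule.tree))
    return GprRule(tree=new_tree, source_text=""), report
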