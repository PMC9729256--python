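# Methods

## Model and pipeline

A genome-scale metabolic model (GEM) is a stoichiometric network — matrix
**S** (metabolites × reactions), flux bounds, a biomass reaction — whose
reactions carry gene-reaction rules (GPRs): positive Boolean formulas over
gene presence. The reconstruction pipeline treats the GPRs of a curated
reference GEM as transferable hypotheses: if an orthogroup table says which
target-genome genes descend from the same ancestral gene as each reference
gene, a reference rule can be rewritten in target genes and evaluated, and
the reference reactome projected onto any genome in the panel.

The pipeline's stages and their contracts:

- **Rule substitution.** Each reference gene is replaced by the OR over its
  orthogroup's target-genome members (co-orthologs are assumed functionally
  interchangeable). An orthogroup empty in the target makes the gene false.
  A reference gene in *no* orthogroup is also false but is reported as
  `unmapped-no-orthogroup`; reactions whose rules contain only such genes
  are flagged and excluded from the draft rather than auto-resolved, because
  identifier mismatches between a model's gene ids and the annotation
  version used for orthology are common and demand human judgement. An
  explicit allowlist (reaction id → replacement rule text) re-adds flagged
  reactions after manual checking. Substituted rules are only pruned of
  logically-false branches, never restructured, so each transferred rule
  remains auditable against its source. When two or more AND-joined
  reference genes map into one target-bearing orthogroup, the substitution
  is mechanically ambiguous (an apparent complex collapsing onto one
  ortholog family) and the report sets a curation flag.
- **Transfer.** Reactions without GPR — spontaneous reactions, lumped
  macromolecular syntheses, biomass — transfer unconditionally. The draft
  model keeps only present-called reactions; metabolites are pruned to those
  used, except biomass precursors, which are retained so gap filling has
  stable targets. Transfer is monotone (adding genes never removes a
  reaction) and self-transfer reproduces the reference exactly; both are
  tested properties.
- **FBA / pFBA.** Linear programs over sorted (hence deterministic) variable
  orderings, solved with HiGHS via `scipy.optimize.linprog`. The carbon cap
  is enforced with nonnegative uptake split variables `u_e ≥ -v_e`,
  `Σ c_e·u_e ≤ cap`, so secretion can never relax it — the cap bounds
  consumption, not net exchange. Exchange metabolites without formulas
  contribute zero carbon (the cap is then a lower bound on true
  consumption). pFBA linearizes Σ|v| by forward/reverse flux splitting and
  pins the biomass flux inside `[opt − s, opt + s]` with
  `s = max(10⁻³·tol·|opt|, 10⁻⁹)` (default tol 10⁻⁶ relative), so the
  returned biomass sits orders of magnitude inside the documented 10⁻⁶
  relative tolerance rather than exactly on it.
- **Gap filling.** Mixed-integer program (HiGHS via `scipy.optimize.milp`):
  binary `y_j` per candidate, candidate flux coupled by its own bounds
  (`lb_j·y_j ≤ v_j ≤ ub_j·y_j`; default bounds ±1000 mmol gCDW⁻¹ h⁻¹ play
  the big-M role), biomass flux floored at `max(threshold, 10⁻³)` — the
  floor must sit well above the solver's ~10⁻⁷ feasibility tolerance or an
  empty addition set can slip through as spuriously feasible. Stage one
  minimizes Σy (certified-minimal cardinality when the candidate pool is
  within the configured cap, default 2000); stage two pins that cardinality
  and minimizes the sum of lexicographic ranks of the chosen candidates,
  making the returned set deterministic and biased toward lexicographically
  earlier reaction ids. The candidate pool is every template reaction absent
  from the draft, excluding exchanges the medium does not open. An
  unfillable draft returns the list of biomass precursors that cannot be
  produced even with the full pool available (per-precursor demand LPs).
- **Evidence curation.** Gap-fill proposals are matched against per-genome
  annotation evidence: EC-number intersection first, then exact
  annotation-keyword match against the reaction name; the match-rule order
  is a parameter, not code. Unmatched reactions are excluded from the final
  model but stay in the report; user overrides force inclusion or exclusion
  and are marked as such. Curation can therefore legitimately leave a model
  non-growing — missing evidence for an essential reaction is a finding,
  not an error.
- **Screening.** Pathway modules are (label, EC set or reference reaction
  id) member lists with an `all-members` / `any-member` / `member-wise`
  decision rule. Cells are `unknown` only when a genome lacks annotation
  coverage — never silently coerced to absent. Shipped definitions:
  glyoxylate cycle (isocitrate lyase EC 4.1.3.1 + malate synthase
  EC 2.3.3.9, all-members), aerobic respiratory chain (EC 7.1.1.2,
  EC 1.6.5.9, EC 7.1.1.3, EC 7.1.1.7, all-members), and the
  membrane/soluble NAD(P)⁺ transhydrogenase pair (EC 7.1.1.1 / EC 1.6.1.1,
  member-wise). Published *Acetobacter* read-outs ship as small TSV
  fixtures: the species-level glyoxylate table with growth-on-ethanol
  phenotypes, and the transhydrogenase pattern across the eleven complete
  genomes. Weak growth ("w") maps to "+" by default in concordance tallies
  — with that convention the shipped table counts 8 of 19 species as
  growers and flags three of them as candidate false-positive growth tests;
  the mapping is a parameter.

## Numerical choices

- Growth threshold for "grows in silico": 10⁻⁶ h⁻¹, configurable; returned
  optimal solutions keep the steady-state residual ‖S·v‖∞ ≤ 10⁻⁷.
- Infeasible and unbounded solves are reported as statuses, never as silent
  zeros.
- Dead-end metabolites: a metabolite is dead-end iff no producing channel
  and consuming channel come from two *distinct* reactions
  (direction-resolved; a reversible reaction is both producer and consumer
  of all participants; exchanges count). This makes a metabolite touched by
  a single reversible reaction dead-end — its production and consumption
  channels coincide — which is the conventional gap-audit criterion. Other
  reasonable definitions exist, so dead-end counts from other toolchains
  may differ slightly.
- Mass-balance checking covers every internal reaction whose participants
  all carry formulas; exchanges and an explicit `balance_exempt` id list
  (biomass, macromolecular syntheses) are excluded by contract, and
  formula-less reactions are reported separately rather than assumed
  balanced.

## Synthetic data: what it emulates, what it does not

The generator builds a small aerobic heterotroph: glucose (C6) and acetate
(C2) exchanges and transporters, a catabolic backbone to a pyruvate-like
intermediate, ammonium assimilation into an amino-acid precursor, a
respiration sink, and a biomass reaction — all internal reactions
elementally balanced by construction, feasibility of growth verified by FBA
at build time, no structural dead ends. Padding beyond the skeleton adds
parallel isomerase branches, so some reactions are essential and others
redundant, as in real networks. GPR structures are drawn per a mix
(defaults: 15% no rule, 35% single gene, 20% OR pair, 20% AND pair, 10%
nested), with genes private to their reaction so each reference gene founds
exactly one orthogroup.

Genome families apply independent per-gene loss (default 10%, a moderate
accessory-genome scale for congeneric bacteria) and co-ortholog duplication
(default 5%); 20 genomes by default. Ground-truth reactomes are the original
rules evaluated under each genome's retained reference genes — exactly the
semantics transfer is supposed to realize, which is what makes recovery a
meaningful end-to-end test. Evidence tables list each retained gene with the
EC numbers and name of its reaction(s).

Gap-fill scenarios remove reactions that are (a) GPR-backed and (b)
essential *in the full reference*, so no template candidate can substitute
for them — the planted minimal set is then provably the unique optimum,
letting tests assert exact set equality against exhaustive subset search.
Decoy candidates are isomerizations over fresh, disconnected metabolites and
can never enter a minimal solution. Stripping a removed reaction's evidence
rows plants known `no-evidence` verdicts.

Deliberately not emulated: phylogenetic structure in gene loss (losses are
independent, not tree-correlated), gene fusions or orthogroup splits/merges,
annotation noise (evidence is complete and correct unless stripped),
sequence-level artifacts (frameshifts, pseudogenes), and realistic network
size (tens of reactions, not hundreds). Passing tests therefore demonstrate
the pipeline's logical correctness — substitution semantics, minimality,
determinism, curation bookkeeping — not robustness to noisy annotations or
the biological fidelity of any particular transferred model.

## Scale of the shipped checks

Tests and the acceptance script run the study-shaped conditions at desk
scale: a 30-reaction reference, 20-genome families, exhaustive truth tables
to 5 genes (2⁵ presence sets each), 500-rule substitution/commutation
sweeps, and gap-fill pools of ≲12 candidates so the exhaustive subset oracle
stays exact. The whole suite completes in a few seconds on one CPU.

## Known limitations

- Certified minimality of gap filling assumes the candidate pool fits the
  per-run cap; larger pools return a best-found set flagged non-minimal.
- The 12%-of-citrate-through-citrate-lyase style of flux read-out depends on
  alternate-optima structure; pFBA values should be accompanied by a flux
  range at the optimum before being quoted (not yet implemented).
- SBML round-trips preserve structure (ids, stoichiometry, bounds, rules,
  formulas, objective) but not arbitrary third-party annotations.
- The `reproduce` harness requires the user to fetch the deposited models;
  nothing in the package performs network access.
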