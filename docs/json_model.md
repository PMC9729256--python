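# JSON model dialect

The canonical serialization used in tests and by the CLI; it mirrors the
in-memory model one-to-one, so `write → read` reproduces every structural
field bit-identically. SBML Level 3 + FBC v2 is supported in parallel for
interoperability (`.xml`/`.sbml` suffixes select it automatically).

```json
{
 "id": "model id",
 "compartments": ["c", "e"],
 "metabolites": [
  {
   "id": "glc_c",
   "name": "D-glucose",
   "formula": "C6H12O6",
   "charge": 0,
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "R_glc_iso",
   "name": "glucose isomerase",
   "stoichiometry": {"glc_c": -1.0, "hex1": 1.0},
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gpr": "g1 and (g2 or g3)",
   "ec_numbers": ["5.3.1.5"],
   "is_exchange": false,
   "notes": ""
  }
 ],
 "genes": ["g1", "g2", "g3"],
 "objective": "BIOMASS",
 "balance_exempt": ["BIOMASS"],
 "notes": ""
}
```

Field notes:

- `stoichiometry` maps metabolite id → signed coefficient (negative =
  substrate, positive = product). Exchange reactions have exactly one entry;
  negative flux through them is uptake, positive is secretion.
- `formula` is an elemental formula (`C6H12O6`) or `null` when unknown;
  metabolites without formulas are excluded from mass-balance checking and
  contribute zero carbon to the carbon-uptake cap.
- `gpr` is rule text over gene ids with `and`/`or` (case-insensitive) and
  parentheses; AND binds tighter than OR. `null` or `""` means no rule
  (orphan reaction). No other operators are accepted — rules are positive
  Boolean formulas.
- `lower_bound`/`upper_bound` are flux bounds in mmol gCDW⁻¹ h⁻¹; a reaction
  is irreversible iff `lower_bound >= 0` or `upper_bound <= 0`.
- `genes` lists every gene appearing in any rule (plus any extra declared
  genes); `objective` names the biomass reaction.
- `balance_exempt` lists reaction ids excluded from elemental balance checks
  (biomass, lumped macromolecular syntheses) — an explicit list, never a
  heuristic.
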