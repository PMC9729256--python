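import numpy as np
import pytest

from orthogem import (
    Metabolite,
    Model,
    Reaction,
    ModelValidationError,
    carbon_count,
    check_mass_balance,
    find_dead_end_metabolites,
    parse_formula,
    summarize_model,
)
from orthogem.model_core import FormulaError


@pytest.mark.parametrize(
    "formula,expected",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("H2O", {"H": 2, "O": 1}),
        ("C6H5O7", {"C": 6, "H": 5, "O": 7}),
        ("H3N", {"H": 3, "N": 1}),
        ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
        ("Fe", {"Fe": 1}),
        ("CHO", {"C": 1, "H": 1, "O": 1}),
    ],
)
def test_formula_parsing(formula, expected):
    assert parse_formula(formula) == expected


@pytest.mark.parametrize(
    "formula,carbons", [("C6H12O6", 6), ("H2O", 0), ("C6H5O7", 6), ("CO2", 1)]
)
def test_carbon_count(formula, carbons):
    assert carbon_count(formula) == carbons


@pytest.mark.parametrize("bad", ["", "c6h12", "C6@H12", "6CH12"])
def test_bad_formulas_raise_with_token(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_empty_model_summary_all_zero():
    m = Model(id="empty")
    s = summarize_model(m)
    assert (
        s.compartments, s.genes, s.reactions, s.exchange_reactions,
        s.irreversible_reactions, s.orphan_reactions, s.metabolites,
        s.dead_end_metabolites,
    ) == (0, 0, 0, 0, 0, 0, 0, 0)


def test_summary_counts_on_generated_model(reference):
    s = summarize_model(reference)
    assert s.reactions == 30
    assert s.exchange_reactions == 7
    assert s.metabolites == len(reference.metabolites)
    assert s.genes == len(reference.genes)
    # orphans = non-exchange reactions without GPR
    orphans = [
        r.id for r in reference.reactions.values()
        if not r.is_exchange and r.gpr is None
    ]
    assert s.orphan_reactions == len(orphans)
    assert "BIOMASS" in orphans
    # partition arithmetic: exchange + orphan + GPR-bearing = total
    gpr_bearing = sum(
        1 for r in reference.reactions.values() if r.gpr is not None
    )
    assert s.exchange_reactions + s.orphan_reactions + gpr_bearing == s.reactions


def test_exchange_must_touch_single_metabolite():
    m = Model(id="x", compartments={"c"})
    m.add_metabolite(Metabolite("a", compartment="c"))
    m.add_metabolite(Metabolite("b", compartment="c"))
    with pytest.raises(ModelValidationError):
        Reaction("EX_bad", stoichiometry={"a": -1.0, "b": 1.0}, is_exchange=True)


def test_inverted_bounds_rejected():
    with pytest.raises(ModelValidationError):
        Reaction("r", stoichiometry={"a": -1.0}, lower_bound=5.0, upper_bound=1.0)


# --- dead-end metabolites ---------------------------------------------------


def _only_product_model():
    m = Model(id="d", compartments={"c"})
    for mid in ("a", "b", "orphaned"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("src", stoichiometry={"a": 1.0}, lower_bound=0.0))
    m.add_reaction(Reaction("r1", stoichiometry={"a": -1.0, "b": 1.0,
                                                 "orphaned": 1.0},
                            lower_bound=0.0))
    m.add_reaction(Reaction("snk", stoichiometry={"b": -1.0}, lower_bound=0.0))
    return m


def test_only_produced_metabolite_is_dead_end():
    m = _only_product_model()
    assert find_dead_end_metabolites(m) == {"orphaned"}


def test_single_reversible_reaction_metabolite_is_dead_end():
    m = Model(id="d", compartments={"c"})
    m.add_metabolite(Metabolite("a", compartment="c"))
    m.add_metabolite(Metabolite("b", compartment="c"))
    m.add_reaction(Reaction("r", stoichiometry={"a": -1.0, "b": 1.0},
                            lower_bound=-1000.0))
    # both a and b: production and consumption channels coincide in one reaction
    assert find_dead_end_metabolites(m) == {"a", "b"}


def _brute_force_dead_ends(model):
    """Independent oracle: enumerate per-metabolite producing/consuming
    (reaction, direction) pairs and demand a cross-reaction pair."""
    dead = set()
    for met in model.metabolites:
        producing = []
        consuming = []
        for rxn in model.reactions.values():
            coeff = rxn.stoichiometry.get(met, 0.0)
            if coeff == 0.0:
                continue
            for direction in ("fwd", "rev"):
                if direction == "fwd" and rxn.upper_bound <= 0:
                    continue
                if direction == "rev" and rxn.lower_bound >= 0:
                    continue
                signed = coeff if direction == "fwd" else -coeff
                if signed > 0:
                    producing.append((rxn.id, direction))
                else:
                    consuming.append((rxn.id, direction))
        ok = any(
            p[0] != c[0] for p in producing for c in consuming
        )
        if not ok:
            dead.add(met)
    return dead


def test_dead_end_agrees_with_brute_force_on_random_networks():
    rng = np.random.default_rng(2024)
    for _ in range(60):
        n_mets = int(rng.integers(3, 12))
        n_rxns = int(rng.integers(2, 25))
        m = Model(id="rand", compartments={"c"})
        mets = [f"m{i}" for i in range(n_mets)]
        for mid in mets:
            m.add_metabolite(Metabolite(mid, compartment="c"))
        for j in range(n_rxns):
            k = int(rng.integers(1, min(4, n_mets) + 1))
            chosen = rng.choice(mets, size=k, replace=False)
            stoich = {
                mid: float(rng.choice([-2.0, -1.0, 1.0, 2.0])) for mid in chosen
            }
            kind = rng.integers(0, 3)
            lb, ub = ((-1000.0, 1000.0), (0.0, 1000.0), (-1000.0, 0.0))[kind]
            m.add_reaction(Reaction(f"r{j}", stoichiometry=stoich,
                                    lower_bound=lb, upper_bound=ub))
        assert find_dead_end_metabolites(m) == _brute_force_dead_ends(m)


# --- mass balance -----------------------------------------------------------


def test_balanced_network_reports_nothing(reference):
    imbalanced, unchecked = check_mass_balance(reference)
    assert imbalanced == [] and unchecked == []


def test_injected_imbalance_is_detected(reference):
    corrupted = reference.copy()
    corrupted.reactions["R_cleave"].stoichiometry["tri1"] = 3.0  # was 2.0
    imbalanced, _ = check_mass_balance(corrupted)
    assert [rid for rid, _ in imbalanced] == ["R_cleave"]
    (_, delta), = imbalanced
    assert delta["C"] == pytest.approx(3.0)  # one extra C3 triose


def test_exchange_and_exempt_reactions_never_listed(reference):
    imbalanced, _ = check_mass_balance(reference)
    listed = {rid for rid, _ in imbalanced}
    assert "BIOMASS" not in listed
    assert all(not reference.reactions[r].is_exchange for r in listed)


def test_formula_free_metabolite_reported_not_balanced():
    m = Model(id="nf", compartments={"c"})
    m.add_metabolite(Metabolite("a", formula="C2H4O2", compartment="c"))
    m.add_metabolite(Metabolite("b", formula=None, compartment="c"))
    m.add_reaction(Reaction("r", stoichiometry={"a": -1.0, "b": 1.0},
                            lower_bound=0.0))
    imbalanced, unchecked = check_mass_balance(m)
    assert imbalanced == [] and unchecked == ["r"]
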