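import pytest

from orthogem import (
    Metabolite,
    Model,
    Reaction,
    MediumSpec,
    make_reference_model,
    simulate_genome_family,
)


@pytest.fixture(scope="session")
def reference():
    """Synthetic reference GEM: 30 reactions, mixed GPR structures."""
    return make_reference_model(30, seed=1)


@pytest.fixture(scope="session")
def family(reference):
    """20-genome family at 10% gene loss, 5% co-ortholog duplication."""
    return simulate_genome_family(
        reference, n_genomes=20, gene_loss_rate=0.1, duplication_rate=0.05,
        seed=42,
    )


def chain_model():
    """EX_a (uptake <= 10) -> a -> b -> biomass, yield 1. Optimum: 10."""
    m = Model(id="chain", compartments={"c", "e"})
    m.add_metabolite(Metabolite("a_e", "A", "C6H12O6", 0, "e"))
    m.add_metabolite(Metabolite("a", "A", "C6H12O6", 0, "c"))
    m.add_metabolite(Metabolite("b", "B", "C6H12O6", 0, "c"))
    m.add_reaction(Reaction("EX_a_e", stoichiometry={"a_e": -1.0},
                            lower_bound=-1000.0, is_exchange=True))
    m.add_reaction(Reaction("T_a", stoichiometry={"a_e": -1.0, "a": 1.0},
                            lower_bound=0.0))
    m.add_reaction(Reaction("R1", stoichiometry={"a": -1.0, "b": 1.0},
                            lower_bound=0.0))
    m.add_reaction(Reaction("BIOMASS", stoichiometry={"b": -1.0},
                            lower_bound=0.0))
    m.objective = "BIOMASS"
    m.balance_exempt = {"BIOMASS"}
    medium = MediumSpec(uptake={"EX_a_e": 10.0})
    return m, medium


def branch_model():
    """Two routes a -> b: R1 yield 1, R2 yield 2 (uncapped cofactor-free toy).

    With uptake <= 10 the optimum routes everything through R2: biomass 20.
    """
    m, _ = chain_model()
    m.add_reaction(Reaction("R2", stoichiometry={"a": -1.0, "b": 2.0},
                            lower_bound=0.0))
    medium = MediumSpec(uptake={"EX_a_e": 10.0})
    return m, medium


def futile_cycle_model():
    """Chain plus a 2-reaction loop b -> c -> b able to carry arbitrary flux.

    The loop does not change the biomass optimum (10); parsimonious FBA must
    drive its flux to zero.
    """
    m, medium = chain_model()
    m.add_metabolite(Metabolite("c_met", "C", "C6H12O6", 0, "c"))
    m.add_reaction(Reaction("LOOP1", stoichiometry={"b": -1.0, "c_met": 1.0},
                            lower_bound=0.0))
    m.add_reaction(Reaction("LOOP2", stoichiometry={"c_met": -1.0, "b": 1.0},
                            lower_bound=0.0))
    return m, medium
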