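import pytest

from rumenflux.amg import apply_amg
from rumenflux.model_io import MetabolicModel, Metabolite, Reaction
from rumenflux.synthetic import make_toy3


@pytest.fixture(scope="session")
def toy3():
    return make_toy3()


@pytest.fixture()
def toy3_members(toy3):
    # fresh copies so tests can mutate freely
    return [m.copy() for m in toy3.members]


@pytest.fixture(scope="session")
def toy3_filled(toy3):
    return toy3.filled_members()


@pytest.fixture(scope="session")
def toy3_amg(toy3):
    out = []
    for m in toy3.filled_members():
        if m.id in toy3.amg_sets:
            m = apply_amg(m, toy3.amg_sets[m.id]).model
        out.append(m)
    return out


def linear_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_A (uptake-limited) -> A -> B -> biomass, yield 1."""
    m = MetabolicModel(id="chain", biomass_reaction_id="BIO")
    m.metabolites = [
        Metabolite(id="A[e]", compartment="e"),
        Metabolite(id="A[c]", compartment="c"),
        Metabolite(id="B[c]", compartment="c"),
    ]
    m.reactions = [
        Reaction(id="EX_A", stoichiometry={"A[e]": -1.0}, lb=-uptake, ub=1000.0,
                 is_exchange=True),
        Reaction(id="T_A", stoichiometry={"A[e]": -1.0, "A[c]": 1.0}, ub=1000.0),
        Reaction(id="A2B", stoichiometry={"A[c]": -1.0, "B[c]": 1.0}, ub=1000.0),
        Reaction(id="BIO", stoichiometry={"B[c]": -1.0}, ub=1000.0, is_biomass=True),
    ]
    m.validate()
    return m


@pytest.fixture()
def chain_model():
    return linear_chain_model()
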