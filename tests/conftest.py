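import pytest

from teflux.model import MetabolicModel, Metabolite, make_reaction


@pytest.fixture
def chain_model() -> MetabolicModel:
    """Uptake (cap 10) -> A -> B -> C -> export; B->C carried by sole gene
    gmid, A->B by an isozyme pair."""
    mets = [Metabolite(f"{x}_c", compartment="c") for x in "ABC"]
    rxns = [
        make_reaction("EA", {"A_c": 1.0}, 0.0, 10.0),
        make_reaction("R_AB", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0,
                      gpr="(giso1 or giso2)"),
        make_reaction("R_BC", {"B_c": -1.0, "C_c": 1.0}, 0.0, 1000.0,
                      gpr="gmid"),
        make_reaction("EC", {"C_c": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel(mets, rxns, model_id="chain")


@pytest.fixture
def parallel_model() -> MetabolicModel:
    """A -> C through two equivalent branches (each cap 10), export cap 10:
    the branch split is free while the total is pinned."""
    mets = [Metabolite(m, compartment="c") for m in
            ("A_c", "B1_c", "B2_c", "C_c")]
    rxns = [
        make_reaction("EA", {"A_c": 1.0}, 0.0, 10.0),
        make_reaction("B1a", {"A_c": -1.0, "B1_c": 1.0}, 0.0, 10.0),
        make_reaction("B1b", {"B1_c": -1.0, "C_c": 1.0}, 0.0, 10.0),
        make_reaction("B2a", {"A_c": -1.0, "B2_c": 1.0}, 0.0, 10.0),
        make_reaction("B2b", {"B2_c": -1.0, "C_c": 1.0}, 0.0, 10.0),
        make_reaction("EC", {"C_c": -1.0}, 0.0, 10.0),
    ]
    return MetabolicModel(mets, rxns, model_id="parallel")


@pytest.fixture
def compensated_model() -> MetabolicModel:
    """The gene-dependent A->B step has a gene-free alternate of equal
    capacity: knocking the gene changes nothing (network compensation)."""
    mets = [Metabolite(m, compartment="c") for m in ("A_c", "B_c")]
    rxns = [
        make_reaction("EA", {"A_c": 1.0}, 0.0, 10.0),
        make_reaction("R_enz", {"A_c": -1.0, "B_c": 1.0}, 0.0, 10.0, gpr="gk"),
        make_reaction("R_alt", {"A_c": -1.0, "B_c": 1.0}, 0.0, 10.0),
        make_reaction("EB", {"B_c": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel(mets, rxns, model_id="compensated")
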