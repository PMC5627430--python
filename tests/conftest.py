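import pytest

from ascoflux import (
    FluxDistribution,
    MetabolicModel,
    Metabolite,
    Reaction,
    make_core_ascomycin_toy,
    wild_type_reference,
)

PRODUCT_BASELINE = 5e-4


@pytest.fixture(scope="session")
def curated_toy() -> MetabolicModel:
    return make_core_ascomycin_toy()


@pytest.fixture(scope="session")
def curated_reference(curated_toy) -> FluxDistribution:
    ref = wild_type_reference(curated_toy, product_baseline=PRODUCT_BASELINE)
    assert ref.optimal
    return ref


@pytest.fixture()
def chain_toy() -> MetabolicModel:
    """Single linear path: uptake (ub 1) -> transport -> unit-yield biomass."""
    return MetabolicModel(
        id="chain",
        metabolites=[Metabolite("a_e", compartment="e"), Metabolite("a_c")],
        reactions=[
            Reaction("EX_a", {"a_e": 1.0}, lower_bound=0.0, upper_bound=1.0),
            Reaction("At", {"a_e": -1.0, "a_c": 1.0}, lower_bound=0.0, upper_bound=1000.0),
            Reaction("BIO", {"a_c": -1.0}, lower_bound=0.0, upper_bound=1000.0),
        ],
        objective_id="BIO",
    )


@pytest.fixture()
def pp_toy() -> MetabolicModel:
    """Mini oxidative-PP/anaplerosis toy carrying the curated reaction ids
    GND2/GND/G1DH/PGL/PPC, for exercising the documented bound edits."""
    mets = [
        Metabolite("g6p_c"),
        Metabolite("pg_c"),
        Metabolite("ru5p_c"),
        Metabolite("oaa_c"),
    ]
    rxns = [
        Reaction("EX_g6p", {"g6p_c": 1.0}, lower_bound=0.0, upper_bound=1.0),
        Reaction("PGL", {"g6p_c": -1.0, "pg_c": 1.0}, lower_bound=0.0,
                 upper_bound=1000.0, subsystem="pentose_phosphate"),
        Reaction("G1DH", {"g6p_c": -1.0, "pg_c": 1.0}, lower_bound=0.0,
                 upper_bound=1000.0, subsystem="pentose_phosphate"),
        Reaction("GND", {"pg_c": -1.0, "ru5p_c": 1.0}, lower_bound=0.0,
                 upper_bound=1000.0, subsystem="pentose_phosphate"),
        Reaction("GND2", {"pg_c": -1.0, "ru5p_c": 1.0}, lower_bound=0.0,
                 upper_bound=1000.0, subsystem="pentose_phosphate"),
        Reaction("PPC", {"g6p_c": -1.0, "oaa_c": 1.0}, lower_bound=0.0,
                 upper_bound=1000.0, subsystem="anaplerosis"),
        Reaction("BIO", {"ru5p_c": -0.5, "oaa_c": -0.5}, lower_bound=0.0,
                 upper_bound=1000.0, subsystem="biomass"),
    ]
    return MetabolicModel(id="pp_toy", metabolites=mets, reactions=rxns, objective_id="BIO")
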