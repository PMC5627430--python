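"""FBA linear program and the parsimonious reference distribution."""

import random

import numpy as np
import pytest

from ascoflux import (
    BoundEdit,
    MetabolicModel,
    Metabolite,
    Reaction,
    fba,
    fix_flux,
    random_small_model,
    reference_flux,
)
from ascoflux.bruteforce import brute_force_fba
from ascoflux.fba import check_distribution

STEADY_TOL = 1e-6
BOUND_TOL = 1e-9


def test_chain_toy_saturates_uptake(chain_toy):
    result = fba(chain_toy)
    assert result.optimal
    assert result.objective_value == pytest.approx(1.0, abs=1e-9)


def test_branched_yields_match_vertex_oracle():
    """Competing branches of yield 1 and 2: LP optimum equals brute force."""
    model = MetabolicModel(
        metabolites=[Metabolite("a_c"), Metabolite("b_c")],
        reactions=[
            Reaction("IN", {"a_c": 1.0}, lower_bound=0.0, upper_bound=1.0),
            Reaction("B1", {"a_c": -1.0, "b_c": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("B2", {"a_c": -1.0, "b_c": 2.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("BIO", {"b_c": -1.0}, lower_bound=0.0, upper_bound=10.0),
        ],
        objective_id="BIO",
    )
    result = fba(model)
    oracle = brute_force_fba(model)
    assert result.objective_value == pytest.approx(oracle, abs=1e-6)
    assert result.objective_value == pytest.approx(2.0, abs=1e-6)


@pytest.mark.parametrize("seed", range(25))
def test_random_models_match_vertex_oracle(seed):
    model = random_small_model(seed)
    result = fba(model)
    oracle = brute_force_fba(model)
    assert result.optimal and oracle is not None
    assert result.objective_value == pytest.approx(oracle, abs=1e-6)


@pytest.mark.parametrize("seed", range(10))
def test_optimal_distributions_satisfy_invariants(seed):
    model = random_small_model(seed)
    for dist in (fba(model), reference_flux(model)):
        assert dist.optimal
        residual, violation = check_distribution(model, dist)
        assert residual <= STEADY_TOL
        assert violation <= BOUND_TOL


def test_objective_invariant_to_declaration_order(curated_toy):
    shuffled = MetabolicModel(
        id="shuffled",
        metabolites=list(reversed(list(curated_toy.metabolites.values()))),
        reactions=list(reversed(list(curated_toy.reactions.values()))),
        objective_id=curated_toy.objective_id,
        product_id=curated_toy.product_id,
    )
    assert fba(shuffled).objective_value == pytest.approx(
        fba(curated_toy).objective_value, rel=1e-9
    )


def test_fba_objective_bounds_random_feasible_points():
    """Convex combinations of polytope vertices never beat the LP optimum."""
    from ascoflux.bruteforce import _candidate, _patterns

    rng = random.Random(42)
    for seed in range(5):
        model = random_small_model(seed)
        S, _, rxn_ids = model.stoichiometric_matrix()
        lb, ub = model.bounds_arrays(rxn_ids)
        obj = rxn_ids.index(model.objective.id)
        vertices = []
        for pattern in _patterns(len(rxn_ids)):
            v = _candidate(S, lb, ub, np.array(pattern))
            if v is not None:
                vertices.append(v)
        opt = fba(model).objective_value
        for _ in range(200):
            weights = np.array([rng.random() for _ in vertices])
            point = (weights / weights.sum()) @ np.array(vertices)
            assert point[obj] <= opt + 1e-6


def test_reference_flux_unique_optimum_matches_fba(chain_toy):
    plain, reference = fba(chain_toy), reference_flux(chain_toy)
    assert reference.objective_value == pytest.approx(plain.objective_value, abs=1e-9)
    for rid in chain_toy.reactions:
        assert reference.fluxes[rid] == pytest.approx(plain.fluxes[rid], abs=1e-8)


def test_reference_flux_parallel_paths_deterministic_l1_minimal():
    """Two identical parallel paths: combined flux preserved and the split
    matches the L1-minimization oracle (any split is L1-optimal; the solve
    must at least be reproducible and not inflate total flux)."""
    model = MetabolicModel(
        metabolites=[Metabolite("a_c"), Metabolite("b_c")],
        reactions=[
            Reaction("IN", {"a_c": 1.0}, lower_bound=0.0, upper_bound=1.0),
            Reaction("P1", {"a_c": -1.0, "b_c": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("P2", {"a_c": -1.0, "b_c": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("BIO", {"b_c": -1.0}, lower_bound=0.0, upper_bound=10.0),
        ],
        objective_id="BIO",
    )
    first = reference_flux(model)
    second = reference_flux(model)
    assert first.fluxes == second.fluxes  # bit-identical repeat
    assert first.fluxes["P1"] + first.fluxes["P2"] == pytest.approx(1.0, abs=1e-8)
    # L1 oracle: total |v| cannot be reduced below 3 (in + through + out)
    total = sum(abs(v) for v in first.fluxes.values())
    assert total == pytest.approx(3.0, abs=1e-6)


def test_reference_flux_total_flux_never_exceeds_plain_fba():
    for seed in range(10):
        model = random_small_model(seed)
        plain, parsimonious = fba(model), reference_flux(model)
        assert parsimonious.objective_value == pytest.approx(plain.objective_value, abs=1e-6)
        assert sum(abs(v) for v in parsimonious.fluxes.values()) <= (
            sum(abs(v) for v in plain.fluxes.values()) + 1e-6
        )


def test_forced_flux_on_blocked_reaction_infeasible(chain_toy):
    model = chain_toy.copy()
    model.add_reaction(
        Reaction("BLOCKED", {"a_c": -1.0, "dead_c": 1.0}, lower_bound=0.2, upper_bound=1.0),
        allow_new_metabolites=True,
    )
    # dead_c has no consumer: the 0.2 lower bound cannot be satisfied
    assert fba(model).status == "infeasible"
    assert reference_flux(model).status == "infeasible"


def test_extra_bounds_fix_fluxes(curated_toy):
    result = fba(curated_toy, fix_flux("EX_glc", 0.5) + [BoundEdit("DRAIN", "lower", 0.05)])
    assert result.optimal
    assert result.fluxes["EX_glc"] == pytest.approx(0.5, abs=1e-9)


def test_validation_scenario_growth_scales_with_uptake(curated_toy):
    """The model-validation protocol: fix uptake and a small product rate,
    maximize growth. Growth responds linearly to the glucose allowance."""
    low = fba(curated_toy, fix_flux("EX_glc", 0.45) + fix_flux("EX_asco", 5e-4))
    high = fba(curated_toy, fix_flux("EX_glc", 0.90) + fix_flux("EX_asco", 5e-4))
    assert low.optimal and high.optimal
    assert high.objective_value > low.objective_value
    # carbon accounting: each glucose yields 3 acetyl units; biomass costs 3;
    # the forced product flux ties up 5 acetyl units per product unit
    # (2 condensation + 2 succinyl + 1 malonyl)
    expected = (3 * 0.90 - 0.05 - 5 * 5e-4) / 3
    assert high.objective_value == pytest.approx(expected, rel=1e-6)


def test_cobra_cross_check(curated_toy):
    """Independent FBA cross-check through the cobra/GLPK stack."""
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model("xcheck")
    cm.add_metabolites(
        [cobra.Metabolite(mid, compartment=m.compartment) for mid, m in curated_toy.metabolites.items()]
    )
    for rid, rxn in curated_toy.reactions.items():
        cr = cobra.Reaction(rid, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({cm.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()})
    cm.objective = "BIO"
    assert cm.slim_optimize() == pytest.approx(fba(curated_toy).objective_value, rel=1e-6)
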