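"""FBA correctness: mass balance, objectives, Warburg-number imposition.

The toy-network optimum is checked against hand enumeration and against
cobrapy/GLPK as an independent LP implementation.
"""

import math

import numpy as np
import pytest

from tumorflux.fba import (
    FBAError,
    FluxSolution,
    PhenotypeSpec,
    impose_warburg_number,
    solve_fba,
    warburg_number,
    yield_from_flux,
)
from tumorflux.fixtures import make_fixtures
from tumorflux.network import build_core_network


@pytest.fixture(scope="module")
def toy_net(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    path = make_fixtures("toy_network", out)
    return build_core_network(path)


def test_steady_state_mass_balance(net):
    spec = PhenotypeSpec("Warburg Tumor Cell", "Aerobic, WN = 0", "fix_growth", 0.018)
    sol = solve_fba(net, spec)
    assert sol.optimal
    S = net.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in net.reaction_ids])
    assert np.abs(S @ v).max() < 1e-8


def test_maintenance_flux_fixed_in_every_solve(net):
    for obj, mu in [("fix_growth", 0.018), ("minimize_oxygen_uptake", 1e-6)]:
        sol = solve_fba(net, PhenotypeSpec("c", "p", obj, mu))
        assert sol.fluxes[net.maintenance_id] == pytest.approx(5.0)


def test_zero_growth_zero_maintenance_gives_zero_fluxes():
    net0 = build_core_network(maintenance_rate=0.0)
    sol = solve_fba(net0, PhenotypeSpec("c", "p", "fix_growth", 0.0))
    assert sol.optimal
    assert max(abs(v) for v in sol.fluxes.values()) < 1e-9


def test_infeasible_when_all_uptakes_closed(net):
    spec = PhenotypeSpec(
        "c", "p", "fix_growth", 0.018,
        extra_bounds={"GLCt": (0, 0), "O2t": (0, 0), "GLNt": (0, 0)},
    )
    sol = solve_fba(net, spec)
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


def test_healthy_stromal_aerobic_rates(net):
    """Quiescent aerobic metabolism: maintenance ATP from full oxidation."""
    sol = solve_fba(
        net, PhenotypeSpec("Healthy Stromal Cell", "Aerobic", "fix_growth", 1e-6)
    )
    q = sol.exchange_rates()
    assert q["glucose"] == pytest.approx(-0.045, rel=0.05)
    assert q["oxygen"] == pytest.approx(-0.048, rel=0.05)


# -- Warburg number ----------------------------------------------------

def _sol(lac, mito):
    return FluxSolution({"LDH": lac, "PYRtm": mito}, "optimal")


@pytest.mark.parametrize(
    "lac,mito,expected",
    [(2.0, 1.0, 2.0), (0.0, 5.0, 0.0), (3.4, 0.1, 34.0), (0.0, 0.0, 0.0)],
)
def test_warburg_number_ratio(lac, mito, expected):
    assert warburg_number(_sol(lac, mito)) == pytest.approx(expected)


def test_warburg_number_infinite_when_no_mito_import():
    assert math.isinf(warburg_number(_sol(1.0, 0.0)))


def test_unconstrained_optimum_produces_no_lactate(net):
    """With oxygen free the LP prefers oxidation: WN = 0."""
    sol = solve_fba(
        net, PhenotypeSpec("Warburg Tumor Cell", "Aerobic", "fix_growth", 0.018)
    )
    assert warburg_number(sol) == 0.0


def test_impose_wn_zero_equals_unconstrained(net):
    spec = PhenotypeSpec("Warburg Tumor Cell", "Aerobic", "fix_growth", 0.018)
    a = solve_fba(net, spec)
    b = impose_warburg_number(net, spec, 0.0)
    for rid in a.fluxes:
        assert a.fluxes[rid] == pytest.approx(b.fluxes[rid], abs=1e-9)


def test_impose_wn_converges_to_target(net):
    spec = PhenotypeSpec("Warburg Tumor Cell", "Aerobic", "fix_growth", 0.018)
    for target in (2.0, 10.0, 34.0):
        sol = impose_warburg_number(net, spec, target, tol=0.01)
        assert warburg_number(sol) == pytest.approx(target, abs=0.01)


def test_wn_monotone_in_oxygen_bound(net):
    """WN is non-increasing as the oxygen-uptake bound is raised."""
    spec = PhenotypeSpec("Warburg Tumor Cell", "Aerobic", "fix_growth", 0.018)
    base = solve_fba(net, spec)
    b0 = base.fluxes["O2t"]
    bounds = np.linspace(0.06, 1.0, 20) * b0
    wns = []
    for b in bounds:
        s = PhenotypeSpec(
            "Warburg Tumor Cell", "Aerobic", "fix_growth", 0.018,
            extra_bounds={"O2t": (0.0, float(b))},
        )
        wns.append(warburg_number(solve_fba(net, s)))
    assert all(w1 >= w2 - 1e-6 for w1, w2 in zip(wns, wns[1:]))


def test_unreachable_wn_raises_with_limiting_constraint(net):
    spec = PhenotypeSpec("Warburg Tumor Cell", "Aerobic", "fix_growth", 0.018)
    with pytest.raises(FBAError, match="unreachable"):
        impose_warburg_number(net, spec, 1e6)


# -- yields ------------------------------------------------------------

@pytest.mark.parametrize(
    "mu,q,expected",
    [
        (0.018, -0.183, 0.0984),   # aerobic WN=2 glucose yield
        (0.018, -0.018, 1.0),
        (1e-6, -0.45, 2.2222e-6),  # anaerobic stromal glucose yield
        (1e-6, 0.45, -2.2222e-6),  # lactate production: negative yield
    ],
)
def test_yield_from_flux(mu, q, expected):
    assert yield_from_flux(mu, q) == pytest.approx(expected, rel=1e-3)


def test_yield_undefined_for_zero_exchange():
    assert yield_from_flux(0.018, 0.0) is None


# -- toy network (independent oracles) ---------------------------------

def test_toy_network_optimum_matches_hand_enumeration(toy_net):
    """Respiration is bounded by oxygen (4): 4*5 + 6*2 = 32 by enumeration."""
    sol = solve_fba(toy_net, PhenotypeSpec("toy", "max", "maximize_growth"))
    assert sol.optimal
    assert sol.fluxes["BIO"] == pytest.approx(32.0)
    assert sol.fluxes["R2"] == pytest.approx(4.0)
    assert sol.fluxes["R1"] == pytest.approx(6.0)


def test_toy_network_optimum_matches_cobra(toy_net):
    cobra = pytest.importorskip("cobra")
    model = toy_net.to_cobra()
    model.objective = "BIO"
    model.reactions.get_by_id("MAINT").bounds = (0.0, 0.0)
    ref = model.optimize()
    assert ref.status == "optimal"
    sol = solve_fba(toy_net, PhenotypeSpec("toy", "max", "maximize_growth"))
    assert sol.fluxes["BIO"] == pytest.approx(ref.objective_value)


def test_core_network_stromal_solve_matches_cobra(net):
    """Cross-check one core-network phenotype against an independent solver."""
    cobra = pytest.importorskip("cobra")
    model = net.to_cobra()
    model.reactions.get_by_id(net.biomass_id).bounds = (1e-6, 1e-6)
    model.reactions.get_by_id(net.maintenance_id).bounds = (5.0, 5.0)
    model.objective = {model.reactions.get_by_id("GLCt"): -1.0}  # minimize
    ref = model.optimize(objective_sense="max")  # max(-glc) == min(glc)
    sol = solve_fba(
        net, PhenotypeSpec("Healthy Stromal Cell", "Aerobic", "fix_growth", 1e-6)
    )
    assert sol.fluxes["GLCt"] == pytest.approx(-ref.objective_value, rel=1e-6)
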