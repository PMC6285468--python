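"""Monod growth terms: limits, switches, and the brute-force exchange oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorflux.kinetics import (
    CellKineticModel,
    GrowthTerm,
    MonodFactor,
    build_kinetic_models,
)


@pytest.fixture(scope="module")
def models(ref_tables, params):
    return {
        s: build_kinetic_models(s, table=ref_tables[s], params=params)
        for s in ("warburg", "reverse_warburg", "glutamine")
    }


def _sat(params, tank_frac=100.0):
    """Concentrations at tank_frac times K for every metabolite."""
    return {
        name: tank_frac * m.K for name, m in params.metabolites.items()
    }


def test_monod_factor_bounds_and_modes():
    sat = MonodFactor("x", K=0.5)
    inh = MonodFactor("x", K=0.5, mode="inhibitory")
    C = np.linspace(0, 100, 501)
    assert np.all((sat.value({"x": C}["x"]) >= 0) & (sat.value(C) <= 1))
    assert np.all((inh.value(C) >= 0) & (inh.value(C) <= 1))
    assert sat.value(0.5) == pytest.approx(0.5)
    assert inh.value(0.5) == pytest.approx(0.5)


def test_negative_concentration_rejected():
    with pytest.raises(ValueError):
        MonodFactor("x", 1.0).value(-0.1)


def test_nonpositive_K_rejected():
    with pytest.raises(ValueError):
        MonodFactor("x", 0.0)


def test_stromal_half_saturation(models, params):
    """Glucose at K with saturating oxygen: half the quiescent rate."""
    m = models["warburg"]["Healthy Stromal Cell"]
    C = _sat(params)
    C["glucose"] = params.metabolites["glucose"].K
    # aerobic term: 0.5 * ~1; anaerobic term ~0 at high O2
    assert m.growth_rate(C) == pytest.approx(0.5e-6, rel=0.02)


def test_warburg_aerobic_limit(models, params):
    """Saturating glucose and oxygen approach the aerobic maximum 0.018/hr."""
    m = models["warburg"]["Warburg Tumor Cell"]
    assert m.growth_rate(_sat(params, 100.0)) == pytest.approx(0.018, rel=0.02)


def test_pasteur_switch_exact_at_zero_oxygen(models, params):
    """At C_O = 0 only the anaerobic term survives, exactly."""
    for cell in ("Healthy Stromal Cell", "Warburg Tumor Cell"):
        m = models["warburg"][cell]
        C = _sat(params)
        C["oxygen"] = 0.0
        ana = m.terms[1]
        expected = ana.mu_max * ana.monod_product(C)
        assert m.growth_rate(C) == expected


def test_reverse_warburg_lactate_independence(models, params):
    """Aerobic growth of RW tumor cells does not depend on lactate when the
    RW and Warburg aerobic maxima are equal (terms 1+2 combine)."""
    m = models["reverse_warburg"]["Reverse Warburg Tumor Cell"]
    C0 = _sat(params)
    C0["lactate"] = 0.0
    C1 = _sat(params)
    C1["lactate"] = 100.0 * params.metabolites["lactate"].K
    # compare only the two aerobic terms (hypoglycemic term is ~0 at high G)
    aer = lambda C: sum(t.mu_max * t.monod_product(C) for t in m.terms[:2])
    assert aer(C0) == pytest.approx(aer(C1), rel=1e-12)


def test_exchange_rate_saturating_matches_table(models, params, ref_tables):
    m = models["warburg"]["Warburg Tumor Cell"]
    q = m.exchange_rate("glucose", _sat(params, 1e4))
    ref = ref_tables["warburg"].q("Warburg Tumor Cell", "Aerobic, WN = 2", "glucose")
    assert q == pytest.approx(ref, rel=1e-3)


def test_exchange_rate_zero_at_zero_concentrations(models, params):
    C = {name: 0.0 for name in params.metabolites}
    for scen, mm in models.items():
        for m in mm.values():
            for met in ("glucose", "oxygen", "lactate", "glutamine"):
                assert m.exchange_rate(met, C) == 0.0


def test_exchange_rate_unknown_metabolite_is_zero(models, params):
    m = models["warburg"]["Warburg Tumor Cell"]
    assert m.exchange_rate("serine", _sat(params)) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    cg=st.floats(0.0, 2.0), co=st.floats(0.0, 0.005),
    cl=st.floats(0.0, 1.0),
)
def test_exchange_equals_term_by_term_sum(cg, co, cl):
    """Four-term RW exchange equals an independent brute-force summation."""
    from tumorflux.params import load_params
    from tumorflux.phenotypes import build_phenotype_table

    params = load_params()
    table = build_phenotype_table(scenario="reverse_warburg", mode="table")
    m = build_kinetic_models("reverse_warburg", table=table, params=params)[
        "Reverse Warburg Tumor Cell"
    ]
    C = {"glucose": cg, "oxygen": co, "lactate": cl}
    for met in ("glucose", "oxygen", "lactate"):
        brute = 0.0
        for t in m.terms:
            f = 1.0
            for fac in t.factors:
                c = C[fac.metabolite_id]
                f *= c / (fac.K + c) if fac.mode == "saturating" else fac.K / (fac.K + c)
            brute += t.q_row.get(met, 0.0) * f
        assert m.exchange_rate(met, C) == pytest.approx(brute, rel=1e-12, abs=1e-15)


def test_growth_monotone_in_saturating_metabolites(models, params):
    m = models["warburg"]["Warburg Tumor Cell"]
    C = _sat(params, 1.0)
    lo = m.growth_rate(C)
    C2 = dict(C)
    C2["glucose"] *= 2
    assert m.growth_rate(C2) >= lo


def test_dominant_phenotype_switches_with_oxygen(models, params):
    m = models["warburg"]["Warburg Tumor Cell"]
    hi = _sat(params, 100.0)
    lo = dict(hi)
    lo["oxygen"] = 0.0
    assert m.dominant_phenotype(hi)[1].startswith("Aerobic")
    assert m.dominant_phenotype(lo)[1] == "Anaerobic"


def test_dominant_phenotype_hypoglycemic_term(models, params):
    m = models["reverse_warburg"]["Reverse Warburg Tumor Cell"]
    C = _sat(params, 100.0)
    C["glucose"] = 0.0
    assert m.dominant_phenotype(C)[1] == "Hypoglycemic"


def test_term_structure_matches_growth_laws(models):
    """Factor counts/modes per cell type follow the published equations."""
    counts = {
        ("warburg", "Healthy Stromal Cell"): [2, 2],
        ("warburg", "Warburg Tumor Cell"): [2, 2],
        ("reverse_warburg", "Hijacked Stromal Cell"): [1],
        ("reverse_warburg", "Reverse Warburg Tumor Cell"): [3, 3, 3, 2],
        ("glutamine", "Glutamine-addicted Tumor Cell"): [3, 3],
    }
    for (scen, cell), sizes in counts.items():
        m = models[scen][cell]
        assert [len(t.factors) for t in m.terms] == sizes


def test_linearization_consistent_with_exchange(models, params):
    """a*C + b evaluated at the linearization point equals the full rate."""
    m = models["reverse_warburg"]["Reverse Warburg Tumor Cell"]
    C = {k: v / 3.0 for k, v in _sat(params, 1.0).items()}
    for met in ("glucose", "oxygen", "lactate"):
        a, b = m.exchange_linearization(met, C)
        assert a * C[met] + b == pytest.approx(m.exchange_rate(met, C), rel=1e-12)
        assert a <= 0.0
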