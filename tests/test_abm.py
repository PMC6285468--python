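"""Agent-based model unit behavior: seeding, growth, division, shoving."""

import math

import numpy as np
import pytest

from tumorflux.abm import (
    SeedingLayout,
    breakthrough_time,
    divide,
    radius_from_biomass,
    run_replicate,
    seed,
    shove_relax,
    step,
)


SMALL = dict(width_elements=8, depth_elements=40)


def _layout(layers=1, seed_value=42, geometry="axial", **kw):
    return SeedingLayout(
        geometry=geometry, n_stromal_layers=layers, seed=seed_value,
        **{**SMALL, **kw},
    )


def test_radius_biomass_relation(params):
    X = 4.0e-10  # ~division mass
    r = radius_from_biomass(X, params.cell_dry_density_g_per_L)
    V = 4.0 / 3.0 * math.pi * r**3 * 1e-15  # um^3 -> L
    assert V * params.cell_dry_density_g_per_L == pytest.approx(X, rel=1e-12)
    assert 2.0 * r == pytest.approx(params.division_diameter_um, rel=0.01)


def test_seed_deterministic_under_fixed_seed():
    a = seed(_layout(), "warburg")
    b = seed(_layout(), "warburg")
    assert np.array_equal(a.pos, b.pos)
    assert np.array_equal(a.biomass, b.biomass)


def test_seed_identical_across_scenarios():
    """Initial layouts are shared across metabolic scenarios at equal seed."""
    a = seed(_layout(), "warburg")
    b = seed(_layout(), "reverse_warburg")
    c = seed(_layout(), "glutamine")
    assert np.array_equal(a.pos, b.pos)
    assert np.array_equal(a.pos, c.pos)


@pytest.mark.parametrize("layers", [1, 3, 5])
def test_axial_tumor_below_stroma_at_t0(layers):
    s = seed(_layout(layers=layers), "warburg")
    tum = s.pos[s.type_idx == 1, 1]
    stro = s.pos[s.type_idx == 0, 1]
    assert tum.min() > stro.max()


def test_radial_seed_tumor_inside_stroma():
    s = seed(_layout(layers=2, geometry="radial", depth_elements=8), "warburg")
    center = np.array([8, 8]) * s.params.grid_h_um / 2.0 * np.array([1, 1])
    center = np.array([s.grid.nx, s.grid.ny]) * s.grid.h / 2.0
    d_t = np.linalg.norm(s.pos[s.type_idx == 1] - center, axis=1)
    d_s = np.linalg.norm(s.pos[s.type_idx == 0] - center, axis=1)
    assert d_t.max() < d_s.min() + s.grid.h  # tumor cluster inside the shells


def test_overfull_domain_rejected():
    with pytest.raises(ValueError, match="shallow"):
        seed(_layout(layers=45), "warburg")


def test_single_cell_exponential_growth(params):
    """Within-step integration is the exact exponential exp(mu(C_local) dt).

    The accumulated growth factor over 10 one-hour steps equals the product
    of per-step exponentials at the cell's local concentrations to 1e-6.
    """
    s = seed(_layout(layers=0, depth_elements=30), "warburg")
    # keep exactly one tumor cell, far from depletion
    keep = np.flatnonzero(s.type_idx == 1)[:1]
    s.pos, s.biomass, s.type_idx = s.pos[keep], s.biomass[keep], s.type_idx[keep]
    s.ids = s.ids[keep]
    s.biomass[:] = 1e-10  # small enough not to divide over 10 hours
    X0 = float(s.biomass[0])
    model = s.models[s.tumor_type]
    factor = 1.0
    for _ in range(10):
        X_before = float(s.biomass[0])
        step(s, 1.0)
        iy, ix = s.grid.element_of(s.pos[:1, 0], s.pos[:1, 1])
        # fields are frozen during the growth sub-step; recompute mu at them
        C = {k: v[iy, ix][0] for k, v in s.fields.concentrations.items()}
        mu = float(model.growth_rate(C))
        assert float(s.biomass[0]) == pytest.approx(
            X_before * math.exp(mu * 1.0), rel=1e-6
        )
        factor *= math.exp(mu * 1.0)
    assert 0.8 * math.exp(0.18) < factor < math.exp(0.18)  # near-saturated tank
    assert float(s.biomass[0]) == pytest.approx(X0 * factor, rel=1e-6)


def test_quiescent_at_zero_tank_concentrations(params):
    s = seed(_layout(layers=0, depth_elements=20), "warburg")
    for name in s.grid.tank_concentrations:
        s.grid.tank_concentrations[name] = 0.0
        s.fields.concentrations[name][:] = 0.0
    n0 = s.n_agents
    X0 = s.biomass.copy()
    for _ in range(50):
        step(s, 1.0)
    assert s.n_agents == n0
    assert np.allclose(s.biomass, X0)


# -- division ----------------------------------------------------------

def test_divide_conserves_biomass_and_splits_nearly_evenly():
    rng = np.random.default_rng(0)
    (xb, xp), (db, dp) = divide(2.0e-10, np.array([5.0, 5.0]), 5.0, rng)
    assert xb + db == pytest.approx(2.0e-10, rel=1e-15)
    assert 0.45 <= xb / 2.0e-10 <= 0.55
    assert np.linalg.norm(dp - xp) == pytest.approx(5.0)


def test_divide_split_fraction_distribution():
    """Monte-Carlo: mean split fraction 0.50 +/- 0.01 over 1000 draws."""
    rng = np.random.default_rng(7)
    fracs = []
    for _ in range(1000):
        (xb, _), _ = divide(1.0, np.zeros(2), 1.0, rng)
        fracs.append(xb)
    assert np.mean(fracs) == pytest.approx(0.5, abs=0.01)
    assert np.min(fracs) >= 0.45 and np.max(fracs) <= 0.55


def test_no_division_below_threshold(params):
    s = seed(_layout(layers=0, depth_elements=20), "warburg")
    s.biomass[:] = 0.5 * (
        params.cell_dry_density_g_per_L * math.pi / 6.0
        * params.division_diameter_um**3 * 1e-15
    )
    n0 = s.n_agents
    from tumorflux.abm import _divide_all
    _divide_all(s)
    assert s.n_agents == n0


def test_division_substep_conserves_total_biomass(params):
    s = seed(_layout(layers=0, depth_elements=20), "warburg")
    s.biomass[:] = 1.05 * (
        params.cell_dry_density_g_per_L * math.pi / 6.0
        * params.division_diameter_um**3 * 1e-15
    )
    before = float(s.biomass.sum())
    from tumorflux.abm import _divide_all
    _divide_all(s)
    assert float(s.biomass.sum()) == pytest.approx(before, rel=1e-14)
    assert s.n_agents == 2 * len(s.type_idx) // 2  # every agent divided


# -- shoving -----------------------------------------------------------

def test_shove_separates_two_overlapping_spheres():
    pos = np.array([[50.0, 50.0], [53.0, 50.0]])  # 50% overlap at r=3
    radii = np.array([3.0, 3.0])
    out = shove_relax((pos, radii), tol=0.05)
    dist = np.linalg.norm(out[1] - out[0])
    # residual overlap at most 5% of the radius
    assert dist >= radii.sum() - 0.05 * 3.0 - 1e-9


def test_shove_fixed_point_without_overlap():
    pos = np.array([[10.0, 10.0], [30.0, 30.0]])
    radii = np.array([3.0, 3.0])
    out = shove_relax((pos, radii), tol=0.05)
    assert np.array_equal(out, pos)


def test_shove_resolves_random_crowd():
    rng = np.random.default_rng(3)
    pos = rng.uniform(0, 60, size=(100, 2))
    radii = np.full(100, 3.0)
    out = shove_relax((pos, radii), tol=0.05, max_iter=500)
    from scipy.spatial.distance import pdist
    assert pdist(out).min() >= 2 * 3.0 - 0.05 * 3.0 - 0.02


def test_step_overlap_invariant(params):
    s = seed(_layout(layers=1, depth_elements=40), "warburg")
    for _ in range(24 * 4):
        step(s, 1.0)
    pos, r = s.pos, s.radii
    # pairwise overlap audit with periodic x
    W = s.grid.nx * s.grid.h
    n = s.n_agents
    worst = 0.0
    for i in range(n):
        dx = np.abs(pos[:, 0] - pos[i, 0])
        dx = np.minimum(dx, W - dx)
        dy = pos[:, 1] - pos[i, 1]
        d = np.hypot(dx, dy)
        d[i] = np.inf
        pen = (r + r[i]) - d  # raw overlap
        allowed = params.shove_tolerance * np.minimum(r, r[i])
        worst = max(worst, (pen - allowed).max())
    # residual above the 5%-of-radius budget stays at the termination
    # threshold scale (tens of nm), far below the cell scale
    assert worst <= 0.05


# -- trajectories ------------------------------------------------------

def test_trajectory_counts_non_decreasing():
    tr = run_replicate("warburg", _layout(layers=1), days=3.0,
                       dump_interval_days=0.5)
    assert np.all(np.diff(tr.tumor_count) >= 0)
    assert np.all(np.diff(tr.stromal_count) >= 0)


def test_replicate_reproducible_byte_exact():
    a = run_replicate("warburg", _layout(layers=1), days=2.0,
                      dump_interval_days=0.5)
    b = run_replicate("warburg", _layout(layers=1), days=2.0,
                      dump_interval_days=0.5)
    assert np.array_equal(a.tumor_count, b.tumor_count)
    assert np.array_equal(a.total_biomass, b.total_biomass)


def test_breakthrough_zero_without_stroma():
    s = seed(_layout(layers=0, depth_elements=20), "warburg")
    assert breakthrough_time(s) == 0.0


def test_breakthrough_infinite_when_quiescent():
    s = seed(_layout(layers=2, depth_elements=20), "warburg")
    for name in s.grid.tank_concentrations:
        s.grid.tank_concentrations[name] = 0.0
        s.fields.concentrations[name][:] = 0.0
    for _ in range(48):
        step(s, 1.0)
    assert math.isinf(breakthrough_time(s))
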