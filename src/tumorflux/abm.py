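"""Agent-based tissue growth coupled to the metabolite field solver.

Cells are hard spheres with dry biomass X; radius follows from X through a
fixed dry density.  Each one-hour step: (1) agents are binned onto the
grid and the steady-state metabolite fields are solved; (2) every agent
grows as X <- X * exp(mu(C_local) * dt), the exact within-step integral
of the Monod growth law for frozen fields; (3) radii are updated; (4)
agents whose diameter reaches the division threshold split into two, the
split fraction drawn uniformly from a narrow band around one half; (5)
steric overlaps are relaxed by iterative pairwise shoving.

No cell death is modelled; severely starved cells are simply quiescent,
so population counts are non-decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fields import (
    ConcentrationField,
    Grid,
    SinkMap,
    pressure_displacement,
    solve_steady_state,
)
from .kinetics import CellKineticModel, build_kinetic_models
from .params import Params, load_params

__all__ = [
    "CellAgent",
    "SeedingLayout",
    "SimulationState",
    "GrowthTrajectory",
    "seed",
    "step",
    "divide",
    "shove_relax",
    "run_replicate",
    "run_scenario",
    "breakthrough_time",
]


def radius_from_biomass(X, dry_density_g_per_L: float):
    """Hard-sphere radius (um) from dry biomass (g) at fixed dry density."""
    V_um3 = np.asarray(X) / dry_density_g_per_L / 1e-15  # L -> um^3
    return (3.0 * V_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class CellAgent:
    """Read-only view of one agent (the state itself is array-backed)."""

    id: int
    cell_type: str
    x: float
    y: float
    biomass: float
    radius: float


@dataclass(frozen=True)
class SeedingLayout:
    geometry: str = "axial"
    n_stromal_layers: int = 1
    tumor_layers: int = 2
    width_elements: int = 32
    depth_elements: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("axial", "radial"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_stromal_layers < 0 or self.tumor_layers < 1:
            raise ValueError("invalid layer counts")


@dataclass
class GrowthTrajectory:
    times_days: np.ndarray
    tumor_count: np.ndarray
    stromal_count: np.ndarray
    total_biomass: np.ndarray
    replicate: int = 0
    breakthrough_days: float = math.inf


class SimulationState:
    """Agents + concentration fields + clock + RNG state."""

    def __init__(
        self,
        grid: Grid,
        models: dict[str, CellKineticModel],
        tumor_type: str,
        stromal_type: str,
        params: Params,
        rng: np.random.Generator,
    ):
        self.grid = grid
        self.models = models
        self.tumor_type = tumor_type
        self.stromal_type = stromal_type
        self.params = params
        self.rng = rng
        self.t_hours = 0.0
        self.pos = np.zeros((0, 2))  # um; columns x, y (y = depth)
        self.biomass = np.zeros(0)  # g dry
        self.type_idx = np.zeros(0, dtype=int)  # 0 = stromal, 1 = tumor
        self.next_id = 0
        self.ids = np.zeros(0, dtype=int)
        self.fields = ConcentrationField(
            {
                name: np.full((grid.ny, grid.nx), c)
                for name, c in grid.tank_concentrations.items()
            },
            {
                name: params.metabolites[name].D_um2_per_hr
                for name in grid.tank_concentrations
            },
        )
        self.initial_stromal_min_depth = math.inf
        self.min_tumor_depth_log: list[tuple[float, float]] = []  # (t_hours, depth)
        self.event_log: list[str] = []

    # -- derived ---------------------------------------------------------
    @property
    def n_agents(self) -> int:
        return self.pos.shape[0]

    @property
    def radii(self) -> np.ndarray:
        return radius_from_biomass(self.biomass, self.params.cell_dry_density_g_per_L)

    @property
    def type_names(self) -> tuple[str, str]:
        return (self.stromal_type, self.tumor_type)

    def agents(self) -> list[CellAgent]:
        r = self.radii
        names = self.type_names
        return [
            CellAgent(
                int(self.ids[i]),
                names[self.type_idx[i]],
                float(self.pos[i, 0]),
                float(self.pos[i, 1]),
                float(self.biomass[i]),
                float(r[i]),
            )
            for i in range(self.n_agents)
        ]

    def counts(self) -> tuple[int, int]:
        tumor = int(np.sum(self.type_idx == 1))
        return tumor, self.n_agents - tumor

    def min_tumor_depth(self) -> float:
        mask = self.type_idx == 1
        return float(self.pos[mask, 1].min()) if mask.any() else math.inf

    def _add_agents(self, pos, biomass, type_idx) -> None:
        n = len(biomass)
        self.pos = np.vstack([self.pos, pos])
        self.biomass = np.concatenate([self.biomass, biomass])
        self.type_idx = np.concatenate([self.type_idx, type_idx])
        self.ids = np.concatenate(
            [self.ids, np.arange(self.next_id, self.next_id + n)]
        )
        self.next_id += n

    def sink_map(self) -> SinkMap:
        g = self.grid
        densities = {}
        vol = g.element_volume_L
        for ti, name in enumerate(self.type_names):
            mask = self.type_idx == ti
            rho = np.zeros((g.ny, g.nx))
            if mask.any():
                iy, ix = g.element_of(self.pos[mask, 0], self.pos[mask, 1])
                np.add.at(rho, (iy, ix), self.biomass[mask])
            densities[name] = rho / vol
        return SinkMap(densities, {n: self.models[n] for n in self.type_names})


def _tile_positions(cols, rows, h, jitter, rng):
    """Jittered-grid positions: one cell per h-sized tile, random offset."""
    cc, rr = np.meshgrid(cols, rows)
    x = (cc.ravel() + 0.5) * h + rng.uniform(-jitter, jitter, cc.size)
    y = (rr.ravel() + 0.5) * h + rng.uniform(-jitter, jitter, cc.size)
    return np.column_stack([x, y])


def seed(
    layout: SeedingLayout,
    scenario: str = "warburg",
    wn: float = 2,
    mode: str = "table",
    params: Params | None = None,
    models: dict[str, CellKineticModel] | None = None,
    explicit_metabolites: tuple[str, ...] | None = None,
) -> SimulationState:
    """Create the initial state for one replicate.

    The layout RNG depends only on the layout seed, so the same seed gives
    identical initial positions across metabolic scenarios.
    """
    params = params or load_params()
    if models is None:
        models = build_kinetic_models(scenario, params=params, wn=wn, mode=mode)
    stromal_type, tumor_type = _cell_type_names(scenario)

    if explicit_metabolites is None:
        explicit_metabolites = _explicit_metabolites(scenario)
    tank = {m: params.metabolites[m].tank for m in explicit_metabolites}

    h = params.grid_h_um
    grid = Grid(
        nx=layout.width_elements,
        ny=layout.depth_elements,
        h=h,
        geometry=layout.geometry,
        boundary_layer_um=params.boundary_layer_um,
        tank_concentrations=tank,
    )

    layout_rng = np.random.default_rng([layout.seed, 0])
    dynamics_rng = np.random.default_rng([layout.seed, 1])
    state = SimulationState(
        grid, models, tumor_type, stromal_type, params, dynamics_rng
    )

    jitter = 0.2 * h
    X_div = (
        params.cell_dry_density_g_per_L
        * (math.pi / 6.0)
        * params.division_diameter_um**3
        * 1e-15
    )
    bl = grid.boundary_layer_elements
    nl = layout.n_stromal_layers
    cols = np.arange(layout.width_elements)

    if layout.geometry == "axial":
        stromal_rows = np.arange(bl, bl + nl)
        tumor_rows = np.arange(bl + nl, bl + nl + layout.tumor_layers)
        if tumor_rows[-1] >= grid.ny:
            raise ValueError("domain too shallow for the requested layers")
        pos_s = _tile_positions(cols, stromal_rows, h, jitter, layout_rng)
        pos_t = _tile_positions(cols, tumor_rows, h, jitter, layout_rng)
    else:  # radial: central tumor cluster wrapped by stromal shells
        all_rows = np.arange(grid.ny)
        tiles = _tile_positions(cols, all_rows, h, jitter, layout_rng)
        center = np.array([grid.nx, grid.ny]) * h / 2.0
        dist = np.linalg.norm(tiles - center, axis=1)
        r_t = layout.tumor_layers * h
        pos_t = tiles[dist < r_t]
        pos_s = tiles[(dist >= r_t) & (dist < r_t + nl * h)]

    n_s, n_t = len(pos_s), len(pos_t)
    bio = layout_rng.uniform(
        params.seed_biomass_low * X_div, params.seed_biomass_high * X_div, n_s + n_t
    )
    state._add_agents(
        np.vstack([pos_s, pos_t]) if n_s else pos_t,
        bio,
        np.concatenate([np.zeros(n_s, int), np.ones(n_t, int)]),
    )
    shove_relax(state)
    if n_s:
        state.initial_stromal_min_depth = float(pos_s[:, 1].min())
    state.min_tumor_depth_log.append((0.0, state.min_tumor_depth()))
    return state


def _cell_type_names(scenario: str) -> tuple[str, str]:
    return {
        "warburg": ("Healthy Stromal Cell", "Warburg Tumor Cell"),
        "reverse_warburg": ("Hijacked Stromal Cell", "Reverse Warburg Tumor Cell"),
        "glutamine": ("Healthy Stromal Cell", "Glutamine-addicted Tumor Cell"),
    }[scenario]


def _explicit_metabolites(scenario: str) -> tuple[str, ...]:
    return {
        "warburg": ("glucose", "oxygen"),
        "reverse_warburg": ("glucose", "oxygen", "lactate"),
        "glutamine": ("glucose", "oxygen", "glutamine"),
    }[scenario]


# ----------------------------------------------------------------------
# stepping
# ----------------------------------------------------------------------

def _solve_fields_truncated(state: SimulationState) -> None:
    """Solve fields on the active depth only (flat below the deepest cell)."""
    g = state.grid
    if state.n_agents:
        max_iy = int(np.max(state.pos[:, 1]) // g.h)
    else:
        max_iy = 0
    ny_active = min(g.ny, max_iy + 4)
    sub = Grid(
        nx=g.nx,
        ny=ny_active,
        h=g.h,
        geometry=g.geometry,
        boundary_layer_um=g.boundary_layer_um,
        tank_concentrations=g.tank_concentrations,
    )
    if g.geometry == "radial":
        sub = g  # truncation only makes sense with a single source side
        ny_active = g.ny

    sinks = state.sink_map()
    sinks_sub = SinkMap(
        {m: rho[:ny_active, :] for m, rho in sinks.densities.items()}, sinks.models
    )
    init = ConcentrationField(
        {
            name: state.fields[name][:ny_active, :].copy()
            for name in state.fields.concentrations
        },
        dict(state.fields.diffusivities),
    )
    solved = solve_steady_state(sub, init, sinks_sub)
    for name, arr in solved.concentrations.items():
        state.fields.concentrations[name][:ny_active, :] = arr
        if ny_active < g.ny:  # zero-flux below: constant continuation
            state.fields.concentrations[name][ny_active:, :] = arr[-1, :]


def step(state: SimulationState, dt: float | None = None) -> SimulationState:
    """Advance one time step: fields, growth, division, shoving."""
    dt = dt if dt is not None else state.params.dt_hours

    _solve_fields_truncated(state)

    if state.n_agents:
        iy, ix = state.grid.element_of(state.pos[:, 0], state.pos[:, 1])
        local = {
            name: state.fields[name][iy, ix]
            for name in state.fields.concentrations
        }
        mu = np.zeros(state.n_agents)
        for ti, name in enumerate(state.type_names):
            mask = state.type_idx == ti
            if mask.any():
                sel = {k: v[mask] for k, v in local.items()}
                mu[mask] = state.models[name].growth_rate(sel)
        dX = state.biomass * (np.exp(mu * dt) - 1.0)
        state.biomass = state.biomass + dX

        # volumetric growth expels tissue: pressure-driven displacement
        g = state.grid
        phi = np.zeros((g.ny, g.nx))
        np.add.at(phi, (iy, ix), dX / state.params.cell_dry_density_g_per_L)
        phi /= g.element_volume_L
        if phi.any():
            disp_x, disp_y = pressure_displacement(g, phi)
            jy, jx = g.element_of(state.pos[:, 0], state.pos[:, 1])
            state.pos[:, 0] += disp_x[jy, jx]
            state.pos[:, 1] += disp_y[jy, jx]

        _divide_all(state)
        shove_relax(state)

    state.t_hours += dt
    state.min_tumor_depth_log.append((state.t_hours, state.min_tumor_depth()))
    return state


def divide(
    biomass: float,
    position: np.ndarray,
    radius: float,
    rng: np.random.Generator,
    split_low: float = 0.45,
    split_high: float = 0.55,
) -> tuple[tuple[float, np.ndarray], tuple[float, np.ndarray]]:
    """Split one agent; total biomass is conserved exactly.

    The mother keeps a fraction f ~ U(split_low, split_high); the daughter
    is placed one radius away in a uniform-random direction.
    """
    f = rng.uniform(split_low, split_high)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    offset = radius * np.array([math.cos(theta), math.sin(theta)])
    return (biomass * f, position.copy()), (biomass * (1.0 - f), position + offset)


def _divide_all(state: SimulationState) -> None:
    p = state.params
    r = state.radii
    dividing = np.flatnonzero(2.0 * r >= p.division_diameter_um)
    if dividing.size == 0:
        return
    new_pos, new_bio, new_type = [], [], []
    for i in dividing:
        (xb, xp), (db, dp) = divide(
            state.biomass[i],
            state.pos[i],
            r[i],
            state.rng,
            p.split_fraction_low,
            p.split_fraction_high,
        )
        state.biomass[i] = xb
        state.pos[i] = xp
        new_pos.append(dp)
        new_bio.append(db)
        new_type.append(state.type_idx[i])
    state._add_agents(
        np.asarray(new_pos), np.asarray(new_bio), np.asarray(new_type, int)
    )


def shove_relax(state_or_arrays, **kw):
    """Relax steric overlaps by iterative pairwise half-displacements.

    Accepts either a :class:`SimulationState` (relaxed in place) or
    ``(positions, radii)`` arrays via keyword-free tuple unpacking.
    Iterates until the moving fraction drops below 0.1% or the iteration
    cap; a cap hit is logged as a warning, not an error.
    """
    if isinstance(state_or_arrays, SimulationState):
        state = state_or_arrays
        pos, radii = state.pos, state.radii
        width = state.grid.nx * state.grid.h
        tol = state.params.shove_tolerance
        max_iter = state.params.shove_max_iter
        periodic_x = state.grid.geometry == "axial"
        new = _shove_arrays(pos, radii, width, tol, max_iter, periodic_x,
                            log=state.event_log)
        # keep agents inside the domain
        depth = state.grid.ny * state.grid.h
        new[:, 1] = np.clip(new[:, 1], radii, depth - radii)
        if periodic_x:
            new[:, 0] = np.mod(new[:, 0], width)
        else:
            new[:, 0] = np.clip(new[:, 0], radii, width - radii)
        state.pos = new
        return state
    pos, radii = state_or_arrays
    return _shove_arrays(np.asarray(pos, float), np.asarray(radii, float), **kw)


def _shove_arrays(
    pos: np.ndarray,
    radii: np.ndarray,
    width: float = math.inf,
    tol: float = 0.05,
    max_iter: int = 60,
    periodic_x: bool = False,
    log: list | None = None,
) -> np.ndarray:
    n = len(radii)
    if n < 2:
        return pos.copy()
    pos = pos.copy()
    for it in range(max_iter):
        pts = pos
        idx_map = np.arange(n)
        if periodic_x and math.isfinite(width):
            margin = 2.0 * float(radii.max())
            left = np.flatnonzero(pos[:, 0] < margin)
            right = np.flatnonzero(pos[:, 0] > width - margin)
            ghosts = np.vstack(
                [pos[left] + [width, 0.0], pos[right] - [width, 0.0]]
            )
            pts = np.vstack([pos, ghosts])
            idx_map = np.concatenate([idx_map, left, right])
        tree = cKDTree(pts)
        pairs = tree.query_pairs(2.0 * float(radii.max()), output_type="ndarray")
        if pairs.size == 0:
            return pos
        a = idx_map[pairs[:, 0]]
        b = idx_map[pairs[:, 1]]
        keep = a != b
        a, b = a[keep], b[keep]
        d = pts[pairs[keep, 1]] - pts[pairs[keep, 0]]
        dist = np.linalg.norm(d, axis=1)
        # allow residual overlap of at most `tol` of the smaller radius
        touch = radii[a] + radii[b] - tol * np.minimum(radii[a], radii[b])
        over = dist < touch
        if not over.any():
            return pos
        a, b, d, dist, touch = a[over], b[over], d[over], dist[over], touch[over]
        dist = np.maximum(dist, 1e-9)
        push = 0.5 * (touch - dist) / dist
        disp = np.zeros_like(pos)
        np.add.at(disp, a, -d * push[:, None])
        np.add.at(disp, b, d * push[:, None])
        moved = np.linalg.norm(disp, axis=1) > 1e-2  # 10 nm: effectively static
        pos += disp
        if moved.sum() <= 1e-3 * n:
            return pos
    if log is not None:
        log.append(
            f"shove relaxation hit the iteration cap ({max_iter}); "
            f"{int(moved.sum())} agents still moving"
        )
    return pos


# ----------------------------------------------------------------------
# scenario runs
# ----------------------------------------------------------------------

def breakthrough_time(state: SimulationState) -> float:
    """First time (days) a tumor cell sits shallower than the shallowest
    initial stromal position; 0 with no stromal layer, inf if never."""
    if not math.isfinite(state.initial_stromal_min_depth):
        return 0.0
    for t_hours, depth in state.min_tumor_depth_log:
        if depth < state.initial_stromal_min_depth:
            return t_hours / 24.0
    return math.inf


def run_replicate(
    scenario: str,
    layout: SeedingLayout,
    days: float,
    dump_interval_days: float = 1.0,
    wn: float = 2,
    mode: str = "table",
    params: Params | None = None,
    models: dict[str, CellKineticModel] | None = None,
    replicate: int = 0,
    on_dump=None,
) -> GrowthTrajectory:
    params = params or load_params()
    state = seed(layout, scenario, wn=wn, mode=mode, params=params, models=models)
    dt = params.dt_hours
    n_steps = int(round(days * 24.0 / dt))
    dump_every = max(1, int(round(dump_interval_days * 24.0 / dt)))

    times, tumor, stromal, biomass = [0.0], [], [], []
    tc, sc = state.counts()
    tumor.append(tc)
    stromal.append(sc)
    biomass.append(float(state.biomass.sum()))
    if on_dump is not None:
        on_dump(state, 0.0)
    for i in range(1, n_steps + 1):
        step(state, dt)
        if i % dump_every == 0 or i == n_steps:
            times.append(state.t_hours / 24.0)
            tc, sc = state.counts()
            tumor.append(tc)
            stromal.append(sc)
            biomass.append(float(state.biomass.sum()))
            if on_dump is not None:
                on_dump(state, state.t_hours / 24.0)

    return GrowthTrajectory(
        times_days=np.asarray(times),
        tumor_count=np.asarray(tumor),
        stromal_count=np.asarray(stromal),
        total_biomass=np.asarray(biomass),
        replicate=replicate,
        breakthrough_days=breakthrough_time(state),
    )


def run_scenario(
    scenario: str,
    layers: int = 1,
    geometry: str = "axial",
    days: float = 10.0,
    dump_interval_days: float = 1.0,
    replicates: int = 11,
    base_seed: int = 0,
    wn: float = 2,
    mode: str = "table",
    width_elements: int | None = None,
    depth_elements: int | None = None,
    params: Params | None = None,
) -> list[GrowthTrajectory]:
    """Run one scenario for several replicates.

    Replicate seeds are ``base_seed + replicate index``; reusing the same
    base seed across scenarios reproduces identical initial layouts, so
    scenario comparisons are not confounded by seeding noise.
    """
    params = params or load_params()
    models = build_kinetic_models(scenario, params=params, wn=wn, mode=mode)
    out = []
    for rep in range(replicates):
        layout = SeedingLayout(
            geometry=geometry,
            n_stromal_layers=layers,
            tumor_layers=params.tumor_layers,
            width_elements=width_elements or params.domain_width_elements,
            depth_elements=depth_elements or params.domain_depth_elements,
            seed=base_seed + rep,
        )
        out.append(
            run_replicate(
                scenario,
                layout,
                days,
                dump_interval_days,
                wn=wn,
                mode=mode,
                params=params,
                models=models,
                replicate=rep,
            )
        )
    return out
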