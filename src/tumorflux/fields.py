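"""Steady-state reaction-diffusion of metabolites on a square grid.

Every explicit metabolite obeys ``D * lap(C) + sum_m rho_m * sum_n
q_i/n * f_n(C) = 0`` at each simulation step (the one-hour step is long
compared with metabolic transients, so the fields equilibrate).  The
domain has a nutrient "tank" beyond a thin cell-free boundary layer:
in the axial geometry the tank sits above the top edge (Dirichlet via a
ghost row), the bottom edge is zero-flux and the sides are periodic; in
the radial geometry the tank surrounds the domain on all four edges.

The nonlinear Monod sinks are handled by Picard iteration with the
metabolite's own saturating factor taken semi-implicitly, which keeps the
linear systems an M-matrix and the iterates non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .kinetics import CellKineticModel

__all__ = [
    "Grid",
    "ConcentrationField",
    "SinkMap",
    "FieldSolverError",
    "solve_steady_state",
    "boundary_flux",
    "total_consumption",
]

UM3_TO_L = 1e-15  # 1 um^3 in litres


class FieldSolverError(RuntimeError):
    pass


@dataclass
class Grid:
    nx: int  # width (periodic direction in axial geometry)
    ny: int  # depth
    h: float = 10.0  # um
    geometry: str = "axial"
    boundary_layer_um: float = 20.0
    tank_concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("grid spacing must be positive")
        if self.geometry not in ("axial", "radial"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if any(v < 0 for v in self.tank_concentrations.values()):
            raise ValueError("tank concentrations must be non-negative")

    @property
    def boundary_layer_elements(self) -> int:
        return int(round(self.boundary_layer_um / self.h))

    @property
    def element_volume_L(self) -> float:
        return self.h**3 * UM3_TO_L

    def element_of(self, x, y):
        """Map positions (um) to (iy, ix) element indices, clipped in y."""
        ix = np.floor(np.asarray(x) / self.h).astype(int) % self.nx
        iy = np.clip(np.floor(np.asarray(y) / self.h).astype(int), 0, self.ny - 1)
        return iy, ix


@dataclass
class ConcentrationField:
    """Per-metabolite concentration arrays (ny, nx) in g/L plus D in um^2/hr."""

    concentrations: dict[str, np.ndarray]
    diffusivities: dict[str, float]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.concentrations[name]

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(
            {k: v.copy() for k, v in self.concentrations.items()},
            dict(self.diffusivities),
        )


@dataclass
class SinkMap:
    """Biomass densities per cell type plus the kinetic models behind them.

    ``densities[m]`` is a (ny, nx) array of dry biomass per tissue volume
    (g-DW/L), the sum of resident agent biomass over the element volume.
    """

    densities: dict[str, np.ndarray]
    models: dict[str, CellKineticModel]

    def __post_init__(self) -> None:
        for m, rho in self.densities.items():
            if np.any(rho < 0):
                raise ValueError(f"negative biomass density for cell type {m!r}")

    def total_exchange(self, metabolite: str, C: dict[str, np.ndarray]):
        """Volumetric exchange rate field in g/L/hr (negative = consumption)."""
        total = 0.0
        for m, rho in self.densities.items():
            total = total + rho * self.models[m].exchange_rate(metabolite, C)
        return total

    def linearized_exchange(self, metabolite: str, C: dict[str, np.ndarray]):
        """(a, b) fields with exchange ~= a*C_i + b, a <= 0."""
        a = 0.0
        b = 0.0
        for m, rho in self.densities.items():
            am, bm = self.models[m].exchange_linearization(metabolite, C)
            a = a + rho * am
            b = b + rho * bm
        return a, b


def _laplacian_with_bc(grid: Grid, D: float, tank: float, a_field: np.ndarray):
    """Assemble A x = rhs for D*lap(C) + a*C + b = 0 (b added by caller).

    Returns (A, rhs_bc) where rhs_bc carries the Dirichlet tank
    contributions.  Row ordering is C[iy, ix] flattened C-style.
    """
    nx, ny, h = grid.nx, grid.ny, grid.h
    n = nx * ny
    k = D / h**2
    ids = np.arange(n).reshape(ny, nx)
    diag = np.zeros((ny, nx))
    rhs = np.zeros((ny, nx))
    rows_l: list[np.ndarray] = []
    cols_l: list[np.ndarray] = []
    dirichlet_sides = grid.geometry == "radial"

    def couple(r, c):
        rows_l.append(r.ravel())
        cols_l.append(c.ravel())

    # vertical neighbors
    couple(ids[1:, :], ids[:-1, :])   # up
    couple(ids[:-1, :], ids[1:, :])   # down
    diag[1:, :] -= k
    diag[:-1, :] -= k
    # top edge: tank held at the element face (ghost value 2*tank - C)
    diag[0, :] -= 2 * k
    rhs[0, :] -= 2 * k * tank
    # bottom edge: axial zero-flux (nothing), radial Dirichlet
    if dirichlet_sides:
        diag[-1, :] -= 2 * k
        rhs[-1, :] -= 2 * k * tank

    # horizontal neighbors
    if dirichlet_sides:
        couple(ids[:, 1:], ids[:, :-1])
        couple(ids[:, :-1], ids[:, 1:])
        diag[:, 1:] -= k
        diag[:, :-1] -= k
        diag[:, 0] -= 2 * k
        diag[:, -1] -= 2 * k
        rhs[:, 0] -= 2 * k * tank
        rhs[:, -1] -= 2 * k * tank
    else:  # periodic sides
        left = np.roll(ids, 1, axis=1)
        right = np.roll(ids, -1, axis=1)
        couple(ids, left)
        couple(ids, right)
        diag -= 2 * k

    diag += a_field
    rows = np.concatenate(rows_l + [ids.ravel()])
    cols = np.concatenate(cols_l + [ids.ravel()])
    vals = np.concatenate(
        [np.full(rows.size - n, k), diag.ravel()]
    )
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return A, rhs.ravel()


def pressure_displacement(grid: Grid, volume_fraction_source: np.ndarray):
    """Incompressible displacement field from volumetric growth.

    Solves lap(psi) = -phi with phi the volume fraction of new biomass per
    element this step; the displacement d = -grad(psi) expels exactly that
    volume.  Axial geometry: zero-flux at the top (the vessel is a wall, so
    growth pushes tissue deeper), open (psi = 0) at the bottom, periodic
    sides.  Radial: open on all four edges.  Returns (dx, dy) arrays in um.
    """
    phi = np.asarray(volume_fraction_source, float)
    ny, nx = phi.shape
    h = grid.h
    n = nx * ny
    k = 1.0 / h**2
    ids = np.arange(n).reshape(ny, nx)
    diag = np.zeros((ny, nx))
    rows_l, cols_l = [], []

    def couple(r, c):
        rows_l.append(r.ravel())
        cols_l.append(c.ravel())

    couple(ids[1:, :], ids[:-1, :])
    couple(ids[:-1, :], ids[1:, :])
    diag[1:, :] -= k
    diag[:-1, :] -= k
    radial = grid.geometry == "radial"
    if radial:
        diag[0, :] -= 2 * k  # open top (psi = 0 at face)
        diag[-1, :] -= 2 * k
    else:
        diag[-1, :] -= 2 * k  # open bottom; top stays zero-flux
    if radial:
        couple(ids[:, 1:], ids[:, :-1])
        couple(ids[:, :-1], ids[:, 1:])
        diag[:, 1:] -= k
        diag[:, :-1] -= k
        diag[:, 0] -= 2 * k
        diag[:, -1] -= 2 * k
    else:
        couple(ids, np.roll(ids, 1, axis=1))
        couple(ids, np.roll(ids, -1, axis=1))
        diag -= 2 * k

    rows = np.concatenate(rows_l + [ids.ravel()])
    cols = np.concatenate(cols_l + [ids.ravel()])
    vals = np.concatenate([np.full(rows.size - n, k), diag.ravel()])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    psi = spsolve(A.tocsc(), -phi.ravel()).reshape(ny, nx)

    # central-difference gradient with matching BC ghosts
    if radial:
        pad_x = np.pad(psi, ((0, 0), (1, 1)), mode="constant")
        pad_y = np.pad(psi, ((1, 1), (0, 0)), mode="constant")
    else:
        pad_x = np.concatenate([psi[:, -1:], psi, psi[:, :1]], axis=1)
        pad_y = np.pad(psi, ((1, 1), (0, 0)), mode="edge")  # zero-flux top
        pad_y[-1, :] = -psi[-1, :]  # open bottom face: ghost = -edge
    dx = -(pad_x[:, 2:] - pad_x[:, :-2]) / (2 * h)
    dy = -(pad_y[2:, :] - pad_y[:-2, :]) / (2 * h)
    return dx, dy


def solve_steady_state(
    grid: Grid,
    fields: ConcentrationField,
    sinks: SinkMap,
    rel_tol: float = 1e-6,
    max_iter: int = 200,
) -> ConcentrationField:
    """Picard-iterate the coupled steady-state balances to convergence.

    Raises :class:`FieldSolverError` with residual diagnostics if the
    iteration cap is reached.
    """
    names = list(fields.concentrations)
    C = {k: v.copy() for k, v in fields.concentrations.items()}

    for iteration in range(max_iter):
        max_change = 0.0
        for name in names:
            D = fields.diffusivities[name]
            tank = grid.tank_concentrations.get(name, 0.0)
            a, b = sinks.linearized_exchange(name, C)
            a_arr = np.broadcast_to(np.asarray(a, float), C[name].shape).copy()
            b_arr = np.broadcast_to(np.asarray(b, float), C[name].shape)
            A, rhs_bc = _laplacian_with_bc(grid, D, tank, a_arr)
            rhs = rhs_bc - b_arr.ravel()
            new = spsolve(A.tocsc(), rhs).reshape(C[name].shape)
            new = np.maximum(new, 0.0)
            scale = max(tank, float(np.max(new)), 1e-300)
            max_change = max(max_change, float(np.max(np.abs(new - C[name]))) / scale)
            C[name] = new
        if max_change <= rel_tol:
            return ConcentrationField(C, dict(fields.diffusivities))

    raise FieldSolverError(
        f"field solver did not converge in {max_iter} Picard iterations "
        f"(last relative change {max_change:.3e}, metabolites {names})"
    )


def boundary_flux(
    field: ConcentrationField, grid: Grid, metabolite: str
) -> float:
    """Diffusive influx through the tank boundary in g/day.

    At steady state this balances the total consumption in the tissue,
    which makes it a cheap conservation audit.
    """
    C = field[metabolite]
    D = field.diffusivities[metabolite]
    tank = grid.tank_concentrations.get(metabolite, 0.0)
    h = grid.h
    # flux per boundary element: D * (tank - C_edge)/(h/2) through area h*h,
    # the tank being held at the element face
    area = h * h  # um^2, implicit thickness one element
    total = 2 * D * (tank - C[0, :]).sum() / h * area  # top edge
    if grid.geometry == "radial":
        total += 2 * D * (tank - C[-1, :]).sum() / h * area
        total += 2 * D * (tank - C[:, 0]).sum() / h * area
        total += 2 * D * (tank - C[:, -1]).sum() / h * area
    return float(total * UM3_TO_L * 24.0)  # (um^3 g/L/hr) -> g/day


def total_consumption(
    field: ConcentrationField, grid: Grid, sinks: SinkMap, metabolite: str
) -> float:
    """Net consumption (positive) summed over the tissue, g/day."""
    rate = sinks.total_exchange(metabolite, field.concentrations)
    rate = np.broadcast_to(np.asarray(rate, float), field[metabolite].shape)
    return float(-rate.sum() * grid.element_volume_L * 24.0)
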