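"""Flux balance analysis on the reduced network.

Each metabolic phenotype is an LP: steady-state mass balance ``S v = 0``,
reaction bounds, a fixed growth rate (the biomass flux) and a fixed
maintenance ATP flux, plus an objective that encodes the phenotype
(minimal glucose uptake, minimal oxygen uptake, ...).  Degenerate optima
are resolved by a lexicographic second stage that minimizes the total
absolute flux, so reported flux distributions are unique and reproducible.

The Warburg number (WN) -- the ratio of the pyruvate-to-lactate flux to the
pyruvate flux imported into the mitochondrion -- is imposed by bisecting
the upper bound on oxygen uptake, starting from the unconstrained optimum
(which has WN = 0) and tightening until the target ratio is met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import EXCHANGE_IDS, MOLECULAR_WEIGHTS, MetabolicNetwork

__all__ = [
    "PhenotypeSpec",
    "FluxSolution",
    "FBAError",
    "solve_fba",
    "warburg_number",
    "impose_warburg_number",
    "yield_from_flux",
]

OBJECTIVES = (
    "fix_growth",
    "minimize_oxygen_uptake",
    "minimize_glucose_uptake",
    "maximize_growth",
)

#: reaction ids of the pyruvate branch point
LACTATE_PRODUCTION_ID = "LDH"
MITO_IMPORT_ID = "PYRtm"
OXYGEN_TRANSPORT_ID = "O2t"
GLUCOSE_TRANSPORT_ID = "GLCt"


class FBAError(RuntimeError):
    pass


@dataclass
class PhenotypeSpec:
    """One metabolic phenotype of one cell type, as FBA constraints."""

    cell_type: str
    phenotype: str
    objective: str = "fix_growth"
    growth_rate: float = 1e-6  # hr^-1
    warburg_number_target: float | None = None
    gln_glc_molar_ratio: float | None = None
    allow_lactate_uptake: bool = False
    allow_glutamine_uptake: bool = False
    extra_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: additional equality constraints sum_j coef_j * v_j = rhs
    linear_constraints: list[tuple[dict[str, float], float]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.warburg_number_target is not None and self.warburg_number_target < 0:
            raise ValueError("Warburg number target must be non-negative")

    @property
    def key(self) -> tuple[str, str]:
        return (self.cell_type, self.phenotype)


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    status: str  # 'optimal' | 'infeasible'
    objective_value: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def exchange_rates(self) -> dict[str, float]:
        """Mass-specific exchange rates q_i in g/g-DW-hr (uptake < 0)."""
        out = {}
        for rid, name in EXCHANGE_IDS.items():
            if rid in self.fluxes:
                out[name] = self.fluxes[rid] * MOLECULAR_WEIGHTS[name]
        return out


def _assemble_bounds(net: MetabolicNetwork, spec: PhenotypeSpec):
    bounds = {}
    for rxn in net.reactions:
        bounds[rxn.id] = [rxn.lower_bound, rxn.upper_bound]
    if spec.objective == "maximize_growth":
        bounds[net.biomass_id] = [0.0, math.inf]
    else:
        bounds[net.biomass_id] = [spec.growth_rate, spec.growth_rate]
    bounds[net.maintenance_id] = [net.maintenance_rate, net.maintenance_rate]
    if spec.allow_lactate_uptake and "EX_lac" in bounds:
        bounds["EX_lac"][0] = -math.inf
    if spec.allow_glutamine_uptake and "EX_gln" in bounds:
        bounds["EX_gln"][0] = -math.inf
    for rid, (lb, ub) in spec.extra_bounds.items():
        bounds[rid] = [lb, ub]
    return bounds


def _objective_vector(net: MetabolicNetwork, spec: PhenotypeSpec) -> np.ndarray:
    c = np.zeros(len(net.reactions))
    idx = {r.id: j for j, r in enumerate(net.reactions)}
    if spec.objective == "maximize_growth":
        c[idx[net.biomass_id]] = -1.0
    elif spec.objective == "minimize_oxygen_uptake":
        c[idx[OXYGEN_TRANSPORT_ID]] = 1.0
    else:
        # fix_growth and minimize_glucose_uptake both pin the growth rate via
        # the biomass bound; the resource objective is minimal glucose uptake
        c[idx[GLUCOSE_TRANSPORT_ID]] = 1.0
    return c


def solve_fba(net: MetabolicNetwork, spec: PhenotypeSpec) -> FluxSolution:
    """Solve one phenotype LP with a lexicographic min-|flux| second stage."""
    rids = net.reaction_ids
    idx = {rid: j for j, rid in enumerate(rids)}
    n = len(rids)
    S = net.stoichiometric_matrix()
    b_eq = np.zeros(S.shape[0])

    A_extra = []
    b_extra = []
    for coeffs, rhs in spec.linear_constraints:
        row = np.zeros(n)
        for rid, coef in coeffs.items():
            row[idx[rid]] = coef
        A_extra.append(row)
        b_extra.append(rhs)
    A_eq = np.vstack([S] + A_extra) if A_extra else S
    b_eq = np.concatenate([b_eq, np.asarray(b_extra)]) if b_extra else b_eq

    bounds = _assemble_bounds(net, spec)
    lb = np.array([bounds[r][0] for r in rids])
    ub = np.array([bounds[r][1] for r in rids])
    c = _objective_vector(net, spec)

    res = linprog(
        c, A_eq=A_eq, b_eq=b_eq, bounds=list(zip(lb, ub)), method="highs"
    )
    if res.status != 0:
        return FluxSolution(fluxes={}, status="infeasible")

    obj = float(res.fun)

    # -- stage 2: minimize total absolute flux at the primary optimum -----
    # split v = p - m with p, m >= 0; at a min of sum(p+m) the pair is
    # complementary, so per-variable bounds map cleanly onto p and m
    p_ub = np.maximum(ub, 0.0)
    p_lb = np.maximum(lb, 0.0)
    m_ub = np.maximum(-lb, 0.0)
    m_lb = np.maximum(-ub, 0.0)
    A_eq2 = np.hstack([A_eq, -A_eq])
    c2 = np.ones(2 * n)
    # keep the primary objective at its optimum (tiny slack for LP noise)
    slack = 1e-11 * max(1.0, abs(obj))
    A_ub2 = np.hstack([c, -c])[None, :]
    b_ub2 = np.array([obj + slack])
    res2 = linprog(
        c2,
        A_eq=A_eq2,
        b_eq=b_eq,
        A_ub=A_ub2,
        b_ub=b_ub2,
        bounds=list(zip(np.concatenate([p_lb, m_lb]), np.concatenate([p_ub, m_ub]))),
        method="highs",
    )
    if res2.status == 0:
        v = res2.x[:n] - res2.x[n:]
    else:  # fall back on the stage-1 vertex
        v = res.x
    v = np.where(np.abs(v) < 1e-10, 0.0, v)  # strip solver noise

    fluxes = {rid: float(v[j]) for rid, j in idx.items()}
    return FluxSolution(fluxes=fluxes, status="optimal", objective_value=obj)


def warburg_number(sol: FluxSolution, zero_tol: float = 1e-9) -> float:
    """Pyruvate-to-lactate flux over pyruvate flux into the mitochondrion.

    Zero lactate production gives WN = 0; positive lactate production with
    zero mitochondrial import gives +inf.
    """
    if not sol.optimal:
        raise FBAError("Warburg number requires an optimal solution")
    lac = max(sol.fluxes.get(LACTATE_PRODUCTION_ID, 0.0), 0.0)
    mito = sol.fluxes.get(MITO_IMPORT_ID, 0.0)
    if lac <= zero_tol:
        return 0.0
    if mito <= zero_tol:
        return math.inf
    return lac / mito


def impose_warburg_number(
    net: MetabolicNetwork,
    spec: PhenotypeSpec,
    wn_target: float,
    tol: float = 0.01,
    max_iter: int = 100,
) -> FluxSolution:
    """Constrain the phenotype to a target WN by bisecting the O2 bound.

    Starting from the unconstrained optimum (WN = 0), the upper bound on
    oxygen uptake is lowered; forcing ATP production away from oxidative
    phosphorylation raises glycolytic flux and lactate production, so WN is
    monotone non-increasing in the oxygen bound and a bisection converges.
    """
    if wn_target < 0:
        raise ValueError("WN target must be non-negative")

    base = solve_fba(net, spec)
    if not base.optimal:
        raise FBAError(f"phenotype {spec.key} infeasible without oxygen constraint")
    if wn_target <= tol:
        return base

    b_hi = base.fluxes[OXYGEN_TRANSPORT_ID]  # uptake magnitude at WN = 0

    def solve_at(bound: float) -> tuple[FluxSolution, float]:
        s = PhenotypeSpec(
            cell_type=spec.cell_type,
            phenotype=spec.phenotype,
            objective=spec.objective,
            growth_rate=spec.growth_rate,
            allow_lactate_uptake=spec.allow_lactate_uptake,
            allow_glutamine_uptake=spec.allow_glutamine_uptake,
            extra_bounds={**spec.extra_bounds, OXYGEN_TRANSPORT_ID: (0.0, bound)},
            linear_constraints=list(spec.linear_constraints),
        )
        sol = solve_fba(net, s)
        if not sol.optimal:
            raise FBAError(
                f"phenotype {spec.key} infeasible at oxygen uptake bound {bound:.4g}"
            )
        return sol, warburg_number(sol)

    # The smallest feasible oxygen bound is set by redox closure of the
    # biomass template; probe reachability there rather than at zero.
    min_o2_spec = PhenotypeSpec(
        cell_type=spec.cell_type,
        phenotype=spec.phenotype,
        objective="minimize_oxygen_uptake",
        growth_rate=spec.growth_rate,
        allow_lactate_uptake=spec.allow_lactate_uptake,
        allow_glutamine_uptake=spec.allow_glutamine_uptake,
        extra_bounds=dict(spec.extra_bounds),
        linear_constraints=list(spec.linear_constraints),
    )
    sol_min = solve_fba(net, min_o2_spec)
    if not sol_min.optimal:
        raise FBAError(f"phenotype {spec.key} infeasible at any oxygen bound")
    b_lo = sol_min.fluxes[OXYGEN_TRANSPORT_ID] * (1 + 1e-9)
    _, wn_lo = solve_at(max(b_lo, 1e-12))
    if wn_lo < wn_target - tol:
        raise FBAError(
            f"WN = {wn_target} unreachable at growth rate {spec.growth_rate}: "
            f"at the minimal feasible oxygen uptake ({b_lo:.4g} mmol/g-DW-hr, "
            f"set by redox closure of the biomass template) WN only reaches "
            f"{wn_lo:.2f}"
        )

    lo, hi = b_lo, b_hi
    sol, wn = base, 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        sol, wn = solve_at(mid)
        if abs(wn - wn_target) <= tol:
            return sol
        if wn > wn_target:
            lo = mid  # oxygen too scarce, relax
        else:
            hi = mid  # oxygen too abundant, tighten
    raise FBAError(
        f"WN bisection did not converge to {wn_target} within {max_iter} "
        f"iterations (last WN = {wn:.4f})"
    )


def yield_from_flux(mu: float, q: float) -> float | None:
    """Yield coefficient Y = -mu / q in g-DW per g of metabolite.

    Uptake (q < 0) gives a positive yield, production a negative one.  A
    zero exchange rate has no defined yield and returns None.
    """
    if q == 0:
        return None
    return -mu / q
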