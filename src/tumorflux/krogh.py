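"""Krogh-length analysis: closed-form depletion depths in a continuum slab.

With uniform zeroth-order consumption R = rho_X * q (g/L/hr) and a surface
concentration C0, the steady 1-D profile with a no-flux condition at the
depletion depth is C(x) = C0 * (1 - x/L)^2 with

    L = sqrt(2 * D * C0 / (rho_X * q)),

the Krogh length: the depth at which a metabolite is fully depleted.  The
metabolite with the smaller L is the one limiting growth.  Sweeping the
Warburg number trades oxygen uptake against glucose uptake, so the oxygen
Krogh length rises with WN while the glucose one falls; their crossover
marks the switch from oxygen- to glucose-limited growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .fba import impose_warburg_number, solve_fba
from .network import MetabolicNetwork, build_core_network
from .params import Params, load_params
from .phenotypes import PhenotypeSpec, PhenotypeTable, build_phenotype_table

__all__ = ["KroghInput", "krogh_length", "wn_sweep"]

M2_PER_S_TO_UM2_PER_HR = 3.6e15


@dataclass(frozen=True)
class KroghInput:
    D: float  # m^2/s
    C0: float  # g/L at the surface
    q: float  # g/g-DW-hr uptake magnitude of the growing phenotype
    rho_X: float  # g-DW/L tissue biomass density

    def __post_init__(self) -> None:
        for name in ("D", "C0", "q", "rho_X"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KroghInput.{name} must be strictly positive")


def krogh_length(inp: KroghInput) -> float:
    """Depletion depth in micrometres."""
    D_um2 = inp.D * M2_PER_S_TO_UM2_PER_HR
    return math.sqrt(2.0 * D_um2 * inp.C0 / (inp.rho_X * inp.q))


def _q_of_wn_fba(
    net: MetabolicNetwork, wn_values: np.ndarray, mu: float, wn_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    q_o2 = np.empty_like(wn_values, dtype=float)
    q_glc = np.empty_like(wn_values, dtype=float)
    for i, wn in enumerate(wn_values):
        spec = PhenotypeSpec(
            "Warburg Tumor Cell", f"Aerobic, WN = {wn:g}", "fix_growth", mu
        )
        if wn <= wn_tol:
            sol = solve_fba(net, spec)
        else:
            sol = impose_warburg_number(net, spec, float(wn), tol=wn_tol)
        q = sol.exchange_rates()
        q_o2[i] = abs(q["oxygen"])
        q_glc[i] = abs(q["glucose"])
    return q_o2, q_glc


def _q_of_wn_table(
    table: PhenotypeTable, wn_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone interpolation of |q| between the tabulated WN points."""
    pts = []
    for (cell, phen) in table.keys():
        if cell == "Warburg Tumor Cell" and phen.startswith("Aerobic, WN ="):
            wn = float(phen.split("=")[1])
            q = table.q_row(cell, phen)
            pts.append((wn, abs(q["oxygen"]), abs(q["glucose"])))
    pts.sort()
    wn_k = np.array([p[0] for p in pts])
    if np.any(wn_values < wn_k[0]) or np.any(wn_values > wn_k[-1]):
        raise ValueError(
            f"table mode interpolates within WN in [{wn_k[0]:g}, {wn_k[-1]:g}]"
        )
    f_o2 = PchipInterpolator(wn_k, [p[1] for p in pts])
    f_glc = PchipInterpolator(wn_k, [p[2] for p in pts])
    return f_o2(wn_values), f_glc(wn_values)


def wn_sweep(
    wn_values=(0, 2, 10, 34),
    mode: str = "fba",
    net: MetabolicNetwork | None = None,
    table: PhenotypeTable | None = None,
    params: Params | None = None,
    mu: float = 0.018,
) -> pd.DataFrame:
    """Krogh lengths of oxygen and glucose across a Warburg-number grid.

    Returns a DataFrame (WN, q_O2, q_Glu, L_O2_um, L_Glu_um) with a
    ``crossover_wn`` attribute: the WN at which the two lengths are equal
    (NaN if they do not cross inside the grid).
    """
    params = params or load_params()
    wn_values = np.asarray(sorted(wn_values), dtype=float)
    if mode == "fba":
        net = net or build_core_network()
        q_o2, q_glc = _q_of_wn_fba(net, wn_values, mu, params.wn_tolerance)
    elif mode == "table":
        table = table or build_phenotype_table(scenario="warburg", mode="table")
        q_o2, q_glc = _q_of_wn_table(table, wn_values)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rho = params.krogh_tissue_density_g_per_L
    mo = params.metabolites["oxygen"]
    mg = params.metabolites["glucose"]
    L_o2 = np.array(
        [krogh_length(KroghInput(mo.D, mo.tank, q, rho)) for q in q_o2]
    )
    L_glc = np.array(
        [krogh_length(KroghInput(mg.D, mg.tank, q, rho)) for q in q_glc]
    )

    df = pd.DataFrame(
        {
            "WN": wn_values,
            "q_O2": q_o2,
            "q_Glu": q_glc,
            "L_O2_um": L_o2,
            "L_Glu_um": L_glc,
        }
    )
    gap = np.log(L_o2 / L_glc)
    crossover = math.nan
    if gap[0] < 0 and gap[-1] > 0:
        f = PchipInterpolator(wn_values, gap)
        crossover = float(brentq(f, wn_values[0], wn_values[-1]))
    df.attrs["crossover_wn"] = crossover
    return df
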