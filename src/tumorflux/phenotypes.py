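"""Phenotype presets and the phenotype rate/yield table.

Each metabolic scenario (Warburg, reverse Warburg, glutamine addiction)
defines a set of (cell type, phenotype) pairs, each encoded as an FBA
problem.  Solving them produces the scenario's phenotype table: the
mass-specific exchange rate q_i (g/g-DW-hr, uptake negative) and the yield
coefficient Y_i = -mu/q_i (g-DW/g) for each exchanged metabolite.

Two build modes exist:

* ``fba``   -- solve the calibrated reduced network (rates within the
               calibration tolerance of the reference values);
* ``table`` -- load the reference rates verbatim, bypassing the LP, for
               bit-reproducible downstream simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .fba import (
    FBAError,
    PhenotypeSpec,
    impose_warburg_number,
    solve_fba,
    yield_from_flux,
)
from .network import MOLECULAR_WEIGHTS, MetabolicNetwork, build_core_network

__all__ = [
    "SCENARIOS",
    "PhenotypeTable",
    "scenario_specs",
    "build_phenotype_table",
]

SCENARIOS = ("warburg", "reverse_warburg", "glutamine")

#: metabolites reported per scenario (others are printed as N/A upstream)
SCENARIO_METABOLITES = {
    "warburg": ("glucose", "oxygen"),
    "reverse_warburg": ("glucose", "oxygen", "lactate"),
    "glutamine": ("glucose", "oxygen", "glutamine"),
}

#: short column suffixes used in the CSV interface
COLUMN_SUFFIX = {
    "glucose": "Glu",
    "oxygen": "O2",
    "lactate": "Lac",
    "glutamine": "Gln",
}
SUFFIX_TO_NAME = {v: k for k, v in COLUMN_SUFFIX.items()}

MU_GROWTH = 0.018  # hr^-1, proliferative phenotypes
MU_QUIESCENT = 1e-6  # hr^-1, quiescent phenotypes
WARBURG_NUMBERS = (0, 2, 10, 34)


def scenario_specs(
    scenario: str,
    mu_growth: float = MU_GROWTH,
    mu_quiescent: float = MU_QUIESCENT,
    gln_glc_molar_ratio: float = 0.3,
    warburg_numbers: tuple[float, ...] = WARBURG_NUMBERS,
    wn: float = 2,
) -> list[tuple[PhenotypeSpec, float | None]]:
    """Preset (spec, WN-target) list for one scenario.

    A non-None second element means the spec is solved with the
    oxygen-bound bisection to reach that Warburg number.
    """
    if scenario == "warburg":
        specs: list[tuple[PhenotypeSpec, float | None]] = [
            (
                PhenotypeSpec("Healthy Stromal Cell", "Aerobic",
                              "fix_growth", mu_quiescent),
                None,
            ),
            (
                PhenotypeSpec("Healthy Stromal Cell", "Anaerobic",
                              "minimize_oxygen_uptake", mu_quiescent),
                None,
            ),
        ]
        for w in warburg_numbers:
            specs.append(
                (
                    PhenotypeSpec(
                        "Warburg Tumor Cell",
                        f"Aerobic, WN = {w:g}",
                        "fix_growth",
                        mu_growth,
                        warburg_number_target=float(w),
                    ),
                    float(w),
                )
            )
        specs.append(
            (
                PhenotypeSpec("Warburg Tumor Cell", "Anaerobic",
                              "minimize_oxygen_uptake", mu_quiescent),
                None,
            )
        )
        return specs

    if scenario == "reverse_warburg":
        return [
            (
                PhenotypeSpec("Hijacked Stromal Cell", "Aerobic",
                              "minimize_oxygen_uptake", mu_quiescent),
                None,
            ),
            (
                PhenotypeSpec("Hijacked Stromal Cell", "Anaerobic",
                              "minimize_oxygen_uptake", mu_quiescent),
                None,
            ),
            (
                PhenotypeSpec(
                    "Reverse Warburg Tumor Cell",
                    f"Aerobic, WN = {wn:g}",
                    "fix_growth",
                    mu_growth,
                    warburg_number_target=float(wn),
                ),
                float(wn),
            ),
            (
                PhenotypeSpec(
                    "Reverse Warburg Tumor Cell",
                    "Aerobic, RW",
                    "minimize_glucose_uptake",
                    mu_growth,
                    allow_lactate_uptake=True,
                ),
                None,
            ),
            (
                PhenotypeSpec(
                    "Reverse Warburg Tumor Cell",
                    "Hypoglycemic",
                    "minimize_glucose_uptake",
                    mu_quiescent,
                    allow_lactate_uptake=True,
                ),
                None,
            ),
            (
                PhenotypeSpec("Reverse Warburg Tumor Cell", "Anaerobic",
                              "minimize_oxygen_uptake", mu_quiescent),
                None,
            ),
        ]

    if scenario == "glutamine":
        # The aerobic glutamine-addicted phenotype carries a WN = 2
        # constraint plus a fixed glutamine:glucose molar uptake ratio;
        # both are linear in the fluxes and imposed directly.
        aer = PhenotypeSpec(
            "Glutamine-addicted Tumor Cell",
            "Aerobic",
            "fix_growth",
            mu_growth,
            warburg_number_target=float(wn),
            gln_glc_molar_ratio=gln_glc_molar_ratio,
            allow_glutamine_uptake=True,
            linear_constraints=[
                ({"LDH": 1.0, "PYRtm": -float(wn)}, 0.0),
                ({"EX_gln": 1.0, "EX_glc": -gln_glc_molar_ratio}, 0.0),
            ],
        )
        hypo = PhenotypeSpec(
            "Glutamine-addicted Tumor Cell",
            "Anaerobic",
            "minimize_glucose_uptake",
            mu_quiescent,
            allow_glutamine_uptake=True,
        )
        return [
            (
                PhenotypeSpec("Healthy Stromal Cell", "Aerobic",
                              "fix_growth", mu_quiescent),
                None,
            ),
            (
                PhenotypeSpec("Healthy Stromal Cell", "Anaerobic",
                              "minimize_oxygen_uptake", mu_quiescent),
                None,
            ),
            (aer, None),
            (hypo, None),
        ]

    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


@dataclass
class PhenotypeTable:
    """Rows keyed by (cell type, phenotype) with q and Y per metabolite."""

    data: pd.DataFrame
    scenario: str
    mode: str = "fba"

    def __post_init__(self) -> None:
        self.data = self.data.set_index(["cell_type", "phenotype"], drop=False)

    # -- access ----------------------------------------------------------
    def row(self, cell_type: str, phenotype: str) -> pd.Series:
        return self.data.loc[(cell_type, phenotype)]

    def mu(self, cell_type: str, phenotype: str) -> float:
        return float(self.row(cell_type, phenotype)["mu"])

    def q(self, cell_type: str, phenotype: str, metabolite: str) -> float:
        col = f"q_{COLUMN_SUFFIX[metabolite]}"
        v = self.row(cell_type, phenotype).get(col, np.nan)
        return float(v)

    def q_row(self, cell_type: str, phenotype: str) -> dict[str, float]:
        """Exchange rates of one row as {metabolite: g/g-DW-hr}, NaN dropped."""
        r = self.row(cell_type, phenotype)
        out = {}
        for name, suf in COLUMN_SUFFIX.items():
            v = r.get(f"q_{suf}", np.nan)
            if pd.notna(v):
                out[name] = float(v)
        return out

    def keys(self) -> list[tuple[str, str]]:
        return list(self.data.index)

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        cols = ["cell_type", "phenotype", "mu"]
        for suf in COLUMN_SUFFIX.values():
            cols.append(f"q_{suf}")
        for suf in COLUMN_SUFFIX.values():
            cols.append(f"Y_{suf}")
        out = self.data.reset_index(drop=True)
        for c in cols:
            if c not in out.columns:
                out[c] = np.nan
        out[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, scenario: str = "custom") -> "PhenotypeTable":
        df = pd.read_csv(path)
        return cls(data=df, scenario=scenario, mode="file")


def _with_yields(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute Y = -mu/q for every populated q column (exact closure)."""
    for suf in COLUMN_SUFFIX.values():
        qc, yc = f"q_{suf}", f"Y_{suf}"
        if qc in df.columns:
            y = []
            for mu, q in zip(df["mu"], df[qc]):
                if pd.isna(q) or q == 0:
                    y.append(np.nan)
                else:
                    y.append(yield_from_flux(float(mu), float(q)))
            df[yc] = y
        else:
            df[qc] = np.nan
            df[yc] = np.nan
    return df


def _reference_rates() -> pd.DataFrame:
    path = Path(str(resources.files("tumorflux").joinpath("data/phenotype_rates.csv")))
    return pd.read_csv(path)


def build_phenotype_table(
    net: MetabolicNetwork | None = None,
    scenario: str = "warburg",
    mode: str = "fba",
    wn: float = 2,
    wn_tolerance: float = 0.01,
    gln_glc_molar_ratio: float = 0.3,
) -> PhenotypeTable:
    """Build the phenotype table for one scenario.

    ``mode='table'`` loads the reference exchange rates verbatim and only
    recomputes the yields; ``mode='fba'`` solves every phenotype on the
    reduced network.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")

    if mode == "table":
        ref = _reference_rates()
        df = ref[ref["scenario"] == scenario].drop(columns=["scenario"]).copy()
        df = _with_yields(df)
        return PhenotypeTable(data=df, scenario=scenario, mode="table")

    if mode != "fba":
        raise ValueError(f"unknown mode {mode!r}; expected 'fba' or 'table'")

    if net is None:
        net = build_core_network()

    rows = []
    reported = SCENARIO_METABOLITES[scenario]
    for spec, wn_target in scenario_specs(
        scenario, gln_glc_molar_ratio=gln_glc_molar_ratio, wn=wn
    ):
        try:
            if wn_target is not None and wn_target > 0:
                sol = impose_warburg_number(net, spec, wn_target, tol=wn_tolerance)
            else:
                sol = solve_fba(net, spec)
        except FBAError as err:
            raise FBAError(
                f"phenotype table build aborted at {spec.key}: {err}"
            ) from err
        if not sol.optimal:
            raise FBAError(f"phenotype table build aborted at {spec.key}: infeasible")
        q = sol.exchange_rates()
        row = {
            "cell_type": spec.cell_type,
            "phenotype": spec.phenotype,
            "mu": spec.growth_rate,
        }
        for name in reported:
            row[f"q_{COLUMN_SUFFIX[name]}"] = q.get(name, 0.0)
        rows.append(row)

    df = _with_yields(pd.DataFrame(rows))
    return PhenotypeTable(data=df, scenario=scenario, mode="fba")


def gln_glc_molar_uptake_ratio(table: PhenotypeTable,
                               cell_type: str = "Glutamine-addicted Tumor Cell",
                               phenotype: str = "Aerobic") -> float:
    """Molar glutamine:glucose uptake ratio of one row (mass rates / MW)."""
    q = table.q_row(cell_type, phenotype)
    return (q["glutamine"] / MOLECULAR_WEIGHTS["glutamine"]) / (
        q["glucose"] / MOLECULAR_WEIGHTS["glucose"]
    )
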