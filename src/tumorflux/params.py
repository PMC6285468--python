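"""Parameter file handling.

All physiological constants (tank concentrations, half-saturation
constants, diffusion coefficients, densities) live in one YAML file so
that nothing is hard-coded in the numerics; the packaged defaults are the
calibrated study conditions described in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["MetaboliteParams", "Params", "load_params", "METABOLITE_NAMES"]

METABOLITE_NAMES = ("glucose", "oxygen", "lactate", "glutamine")


@dataclass(frozen=True)
class MetaboliteParams:
    molecular_weight: float  # g/mmol
    tank: float  # g/L, physiological blood-side concentration
    K: float  # g/L, Monod half-saturation
    D: float  # m^2/s, tissue diffusion coefficient

    @property
    def D_um2_per_hr(self) -> float:
        return self.D * 3.6e15


@dataclass(frozen=True)
class Params:
    metabolites: dict[str, MetaboliteParams]
    mu_aerobic: float
    mu_quiescent: float
    maintenance_rate: float
    wn_tolerance: float
    gln_glc_molar_ratio: float
    grid_h_um: float
    boundary_layer_um: float
    cell_dry_density_g_per_L: float
    krogh_tissue_density_g_per_L: float
    dt_hours: float
    division_diameter_um: float
    split_fraction_low: float
    split_fraction_high: float
    shove_tolerance: float
    shove_max_iter: int
    domain_width_elements: int
    domain_depth_elements: int
    tumor_layers: int
    seed_biomass_low: float
    seed_biomass_high: float
    raw: dict = field(default_factory=dict, compare=False)


def _default_params_path() -> Path:
    return Path(str(resources.files("tumorflux").joinpath("data/params.yaml")))


def load_params(path: str | Path | None = None) -> Params:
    p = Path(path) if path is not None else _default_params_path()
    raw = yaml.safe_load(p.read_text())
    mets = {
        name: MetaboliteParams(**vals) for name, vals in raw["metabolites"].items()
    }
    g, f, t, a = raw["growth"], raw["fba"], raw["tissue"], raw["abm"]
    return Params(
        metabolites=mets,
        mu_aerobic=float(g["mu_aerobic"]),
        mu_quiescent=float(g["mu_quiescent"]),
        maintenance_rate=float(f["maintenance_rate"]),
        wn_tolerance=float(f["wn_tolerance"]),
        gln_glc_molar_ratio=float(f["gln_glc_molar_ratio"]),
        grid_h_um=float(t["grid_h_um"]),
        boundary_layer_um=float(t["boundary_layer_um"]),
        cell_dry_density_g_per_L=float(t["cell_dry_density_g_per_L"]),
        krogh_tissue_density_g_per_L=float(t["krogh_tissue_density_g_per_L"]),
        dt_hours=float(a["dt_hours"]),
        division_diameter_um=float(a["division_diameter_um"]),
        split_fraction_low=float(a["split_fraction_low"]),
        split_fraction_high=float(a["split_fraction_high"]),
        shove_tolerance=float(a["shove_tolerance"]),
        shove_max_iter=int(a["shove_max_iter"]),
        domain_width_elements=int(a["domain_width_elements"]),
        domain_depth_elements=int(a["domain_depth_elements"]),
        tumor_layers=int(a["tumor_layers"]),
        seed_biomass_low=float(a["seed_biomass_low"]),
        seed_biomass_high=float(a["seed_biomass_high"]),
        raw=raw,
    )
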