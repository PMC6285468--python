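"""Scenario configuration and end-to-end orchestration.

``run_pipeline`` chains the stages: phenotype table (FBA or table mode)
-> kinetic models -> agent-based simulation replicates -> replicate
statistics and growth-rate extraction, writing every artefact plus a
provenance record (config, hash, seeds, version) to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abm import SeedingLayout, run_replicate
from .analysis import average_replicates, early_rate, late_rate
from .kinetics import build_kinetic_models
from .params import load_params
from .phenotypes import SCENARIOS, build_phenotype_table

__all__ = ["ScenarioConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    scenario: str = "warburg"
    wn: float = 2.0
    layers: int = 1
    geometry: str = "axial"
    days: float = 10.0
    dump_interval_days: float = 2.5
    replicates: int = 11
    base_seed: int = 0
    mode: str = "table"  # 'table' (bit-reproducible) or 'fba'
    width_elements: int | None = None
    depth_elements: int | None = None
    window_scale: float = 1.0  # rate-window shrink factor for scaled domains
    params_file: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.geometry not in ("axial", "radial"):
            raise ConfigError(f"unknown geometry {self.geometry!r}")
        if self.mode not in ("table", "fba"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.scenario != "warburg" and self.wn != 2.0:
            raise ConfigError(
                "the Warburg number is only tunable in the warburg scenario"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_agents(state, outdir: Path, t_days: float) -> None:
    rows = [
        {
            "id": a.id,
            "cell_type": a.cell_type,
            "x_um": a.x,
            "y_um": a.y,
            "radius_um": a.radius,
            "biomass_g": a.biomass,
        }
        for a in state.agents()
    ]
    pd.DataFrame(rows).to_csv(outdir / f"agents_t{t_days:g}.csv", index=False)


def _write_fields(state, outdir: Path, t_days: float) -> None:
    for name, arr in state.fields.concentrations.items():
        np.savetxt(
            outdir / f"field_{name}_t{t_days:g}.csv", arr, delimiter=",", fmt="%.6e"
        )


def run_pipeline(config: ScenarioConfig, outdir: str | Path) -> Path:
    """Run the full chain and write all declared outputs.

    Snapshots (agents + fields) are dumped for the first replicate only;
    growth curves and statistics cover all replicates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = load_params(config.params_file)

    provenance = {
        "config": config.to_dict(),
        "config_sha256_16": config.digest(),
        "package_version": __version__,
        "replicate_seeds": [config.base_seed + i for i in range(config.replicates)],
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    # stage 1: phenotype table
    table = build_phenotype_table(scenario=config.scenario, mode=config.mode,
                                  wn=config.wn)
    table.to_csv(outdir / "phenotype_table.csv")

    # stage 2+3: kinetics + ABM replicates
    models = build_kinetic_models(
        config.scenario, table=table, params=params, wn=config.wn, mode=config.mode
    )
    width = config.width_elements or params.domain_width_elements
    depth = config.depth_elements or params.domain_depth_elements
    trajectories = []
    for rep in range(config.replicates):
        layout = SeedingLayout(
            geometry=config.geometry,
            n_stromal_layers=config.layers,
            tumor_layers=params.tumor_layers,
            width_elements=width,
            depth_elements=depth,
            seed=config.base_seed + rep,
        )
        on_dump = None
        if rep == 0:
            on_dump = lambda st, t: (_write_agents(st, outdir, t),
                                     _write_fields(st, outdir, t))
        trajectories.append(
            run_replicate(
                config.scenario,
                layout,
                config.days,
                config.dump_interval_days,
                wn=config.wn,
                mode=config.mode,
                params=params,
                models=models,
                replicate=rep,
                on_dump=on_dump,
            )
        )

    rows = []
    for tr in trajectories:
        for t, tc, sc, bm in zip(
            tr.times_days, tr.tumor_count, tr.stromal_count, tr.total_biomass
        ):
            rows.append(
                {
                    "replicate": tr.replicate,
                    "day": t,
                    "tumor_count": tc,
                    "stromal_count": sc,
                    "biomass_g": bm,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "growth_curves.csv", index=False)

    # stage 4: statistics and rates
    curve = average_replicates(trajectories)
    summary = {
        "timepoints_days": curve["t_days"].tolist(),
        "tumor_count_mean": curve["mean"].tolist(),
        "tumor_count_sd": curve["sd"].tolist(),
        "breakthrough_days": [
            (None if math.isinf(tr.breakthrough_days) else tr.breakthrough_days)
            for tr in trajectories
        ],
    }
    rates: dict[str, float | None] = {}
    try:
        rates["early_rate_cells_per_day"] = early_rate(
            curve, config.layers, config.window_scale
        )
    except ValueError:
        rates["early_rate_cells_per_day"] = None
    try:
        rates["late_rate_cells_per_day"] = late_rate(
            curve, config.layers, config.window_scale
        )
    except ValueError:
        rates["late_rate_cells_per_day"] = None
    summary["rates"] = rates
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "analysis.json").write_text(json.dumps(rates, indent=2))
    return outdir
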