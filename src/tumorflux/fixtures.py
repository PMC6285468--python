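"""Deterministic toy fixtures for tests and demos.

Everything here is tiny, text-based and reproducible from a seed: a
six-reaction toy network whose LP optimum can be enumerated by hand, an
8x8 seeding layout, and an analytic parabolic slab concentration field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .abm import SeedingLayout, seed

__all__ = ["make_fixtures", "toy_network_text", "toy_layout_frame", "toy_slab_frame"]

#: A toy network: substrate S can be burned directly (2 ATP) or, with
#: oxygen, through R2 (5 ATP).  With S limited to 10 and O2 to 4, the LP
#: optimum routes 4 units through R2 and 6 through R1:
#: max ATP sink = 4*5 + 6*2 = 32 (hand enumeration of the two vertices).
TOY_NETWORK = """\
# toy network for LP sanity checks
# biomass_fractions\tamino_acids=0.78\tnucleotides=0.06\tlipids=0.16
# maintenance_rate\t0.0
id\tname\tequation\tlb\tub\tkind
EX_S\tsubstrate exchange\ts_e <=>\t-10\tinf\texchange
EX_O2\toxygen exchange\to2_e <=>\t-4\tinf\texchange
St\tsubstrate transport\ts_e --> s_c\t0\tinf\ttransport
O2t\toxygen transport\to2_e --> o2_c\t0\tinf\ttransport
R1\tfermentation\ts_c --> 2 atp_c\t0\tinf\tinternal
R2\trespiration\ts_c + o2_c --> 5 atp_c\t0\tinf\tinternal
BIO\ttoy biomass\t1 atp_c -->\t0\tinf\tbiomass
MAINT\ttoy maintenance\tatp_c -->\t0\tinf\tmaintenance
"""


def toy_network_text() -> str:
    return TOY_NETWORK


def toy_layout_frame(seed_value: int = 0) -> pd.DataFrame:
    """An 8x8 axial seeding layout as a deterministic agent table."""
    layout = SeedingLayout(
        geometry="axial",
        n_stromal_layers=1,
        tumor_layers=2,
        width_elements=8,
        depth_elements=8,
        seed=seed_value,
    )
    state = seed(layout, "warburg", mode="table")
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
    return pd.DataFrame(rows)


def toy_slab_frame(
    C0: float = 0.1, R: float = 5.0, D: float = 7.2e6, depth_um: float = 120.0,
    n: int = 12,
) -> pd.DataFrame:
    """Analytic 1-D slab profile C(y) = C0 - (R/D)(L y - y^2/2).

    Constant zeroth-order sink R (g/L/hr) with zero flux at depth L; valid
    while the depth is shallower than the Krogh length so C stays positive.
    """
    h = depth_um / n
    y = (np.arange(n) + 0.5) * h
    C = C0 - (R / D) * (depth_um * y - y**2 / 2.0)
    return pd.DataFrame({"y_um": y, "C_g_per_L": C})


def make_fixtures(kind: str, outdir: str | Path) -> Path:
    """Write one fixture kind (toy_network | toy_layout | toy_fields)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "toy_network":
        path = outdir / "toy_network.tsv"
        path.write_text(TOY_NETWORK)
    elif kind == "toy_layout":
        path = outdir / "toy_layout.csv"
        toy_layout_frame().to_csv(path, index=False)
    elif kind == "toy_fields":
        path = outdir / "toy_slab.csv"
        toy_slab_frame().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path
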