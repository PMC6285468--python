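"""Monod-form growth laws and phenotype-weighted metabolite exchange.

Each cell type carries a sum of growth terms; a term is a maximum growth
rate multiplied by a product of Monod factors, one per limiting
metabolite.  Saturating factors C/(K+C) switch a phenotype on as a
metabolite becomes abundant; inhibitory factors K/(K+C) switch it off
(e.g. the anaerobic term of the Pasteur switch turns on as oxygen
vanishes).  Each term references one row of the phenotype table, whose
exchange rates q weight the term's contribution to the reaction term of
the tissue-scale diffusion balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Params, load_params
from .phenotypes import PhenotypeTable, build_phenotype_table

__all__ = [
    "MonodFactor",
    "GrowthTerm",
    "CellKineticModel",
    "build_kinetic_models",
]


@dataclass(frozen=True)
class MonodFactor:
    metabolite_id: str
    K: float  # g/L half-saturation
    mode: str = "saturating"  # 'saturating' C/(K+C) or 'inhibitory' K/(K+C)

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"half-saturation constant for {self.metabolite_id} "
                             "must be positive")
        if self.mode not in ("saturating", "inhibitory"):
            raise ValueError(f"unknown Monod mode {self.mode!r}")

    def value(self, C):
        C = np.asarray(C, dtype=float)
        if np.any(C < 0):
            raise ValueError(
                f"negative concentration for {self.metabolite_id}"
            )
        if self.mode == "saturating":
            return C / (self.K + C)
        return self.K / (self.K + C)


@dataclass
class GrowthTerm:
    """mu_max times a product of Monod factors, tied to one q-row."""

    phenotype_key: tuple[str, str]
    mu_max: float  # hr^-1
    factors: list[MonodFactor]
    q_row: dict[str, float] = field(default_factory=dict)  # g/g-DW-hr per metabolite

    def monod_product(self, C: dict[str, object]):
        f = 1.0
        for fac in self.factors:
            f = f * fac.value(C[fac.metabolite_id])
        return f


@dataclass
class CellKineticModel:
    cell_type: str
    terms: list[GrowthTerm]

    @property
    def metabolites(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            for fac in t.factors:
                if fac.metabolite_id not in seen:
                    seen.append(fac.metabolite_id)
            for m in t.q_row:
                if m not in seen:
                    seen.append(m)
        return seen

    def growth_rate(self, C: dict[str, object]):
        """Specific growth rate sum_n mu_max,n * prod(factors) in hr^-1."""
        total = 0.0
        for t in self.terms:
            total = total + t.mu_max * t.monod_product(C)
        return total

    def exchange_rate(self, metabolite: str, C: dict[str, object]):
        """Mass-specific exchange sum_n q_i/n * f_n(C), g/g-DW-hr.

        Negative values are consumption, positive production; a metabolite
        absent from every phenotype row contributes zero.
        """
        total = 0.0
        for t in self.terms:
            q = t.q_row.get(metabolite)
            if q is None or q == 0.0:
                continue
            total = total + q * t.monod_product(C)
        return total

    def exchange_linearization(self, metabolite: str, C: dict[str, object]):
        """Split the exchange rate as a*C_i + b around the state ``C``.

        Consumption terms with a saturating self-factor are made implicit
        in the metabolite's own concentration (a < 0), which keeps a
        discretized diffusion-reaction solve positivity-preserving; all
        other contributions stay explicit in b.
        """
        a = 0.0
        b = 0.0
        for t in self.terms:
            q = t.q_row.get(metabolite)
            if q is None or q == 0.0:
                continue
            self_fac = next(
                (f for f in t.factors
                 if f.metabolite_id == metabolite and f.mode == "saturating"),
                None,
            )
            if q < 0 and self_fac is not None:
                rest = 1.0
                for fac in t.factors:
                    if fac is not self_fac:
                        rest = rest * fac.value(C[fac.metabolite_id])
                a = a + q * rest / (self_fac.K + np.asarray(C[metabolite], float))
            else:
                b = b + q * t.monod_product(C)
        return a, b

    def dominant_phenotype(self, C: dict[str, object]) -> tuple[str, str]:
        """Key of the term with the largest mu_max * f product.

        Ties break deterministically in term order.
        """
        best_key = self.terms[0].phenotype_key
        best = -1.0
        for t in self.terms:
            v = float(t.mu_max * t.monod_product(C))
            if v > best:
                best = v
                best_key = t.phenotype_key
        return best_key


def _fac(params: Params, name: str, mode: str = "saturating") -> MonodFactor:
    return MonodFactor(name, params.metabolites[name].K, mode)


def build_kinetic_models(
    scenario: str,
    table: PhenotypeTable | None = None,
    params: Params | None = None,
    wn: float = 2,
    mode: str = "table",
) -> dict[str, CellKineticModel]:
    """Kinetic models (cell type -> model) for one scenario.

    The term structure follows the published growth laws: a Pasteur switch
    (aerobic + anaerobic terms) for healthy stromal and Warburg tumor
    cells; a single glucose-limited term for hijacked stromal cells; four
    terms (reverse-Warburg aerobic, Warburg aerobic, hypoglycemic,
    anaerobic) for reverse-Warburg tumor cells; and two terms (aerobic,
    hypoglycemic) for glutamine-addicted tumor cells.
    """
    params = params or load_params()
    if table is None:
        table = build_phenotype_table(scenario=scenario, mode=mode, wn=wn)
    if table.scenario != scenario:
        raise ValueError(
            f"phenotype table is for scenario {table.scenario!r}, not {scenario!r}"
        )

    mu_hi = params.mu_aerobic
    mu_lo = params.mu_quiescent
    G = lambda: _fac(params, "glucose")
    Gi = lambda: _fac(params, "glucose", "inhibitory")
    O = lambda: _fac(params, "oxygen")
    Oi = lambda: _fac(params, "oxygen", "inhibitory")
    L = lambda: _fac(params, "lactate")
    Li = lambda: _fac(params, "lactate", "inhibitory")
    N = lambda: _fac(params, "glutamine")

    def term(cell, phen, mu, factors):
        return GrowthTerm((cell, phen), mu, factors, table.q_row(cell, phen))

    if scenario == "warburg":
        s = "Healthy Stromal Cell"
        t = "Warburg Tumor Cell"
        return {
            s: CellKineticModel(s, [
                term(s, "Aerobic", mu_lo, [G(), O()]),
                term(s, "Anaerobic", mu_lo, [G(), Oi()]),
            ]),
            t: CellKineticModel(t, [
                term(t, f"Aerobic, WN = {wn:g}", mu_hi, [G(), O()]),
                term(t, "Anaerobic", mu_lo, [G(), Oi()]),
            ]),
        }

    if scenario == "reverse_warburg":
        s = "Hijacked Stromal Cell"
        t = "Reverse Warburg Tumor Cell"
        return {
            s: CellKineticModel(s, [
                term(s, "Aerobic", mu_lo, [G()]),
            ]),
            t: CellKineticModel(t, [
                term(t, "Aerobic, RW", mu_hi, [G(), L(), O()]),
                term(t, f"Aerobic, WN = {wn:g}", mu_hi, [G(), Li(), O()]),
                term(t, "Hypoglycemic", mu_lo, [L(), O(), Gi()]),
                term(t, "Anaerobic", mu_lo, [G(), Oi()]),
            ]),
        }

    if scenario == "glutamine":
        s = "Healthy Stromal Cell"
        t = "Glutamine-addicted Tumor Cell"
        return {
            s: CellKineticModel(s, [
                term(s, "Aerobic", mu_lo, [G(), O()]),
                term(s, "Anaerobic", mu_lo, [G(), Oi()]),
            ]),
            t: CellKineticModel(t, [
                term(t, "Aerobic", mu_hi, [G(), N(), O()]),
                term(t, "Anaerobic", mu_lo, [N(), O(), Gi()]),
            ]),
        }

    raise ValueError(f"unknown scenario {scenario!r}")
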