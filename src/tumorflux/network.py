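"""Reduced central-carbon metabolic network.

The network is a deliberately small, calibrated stand-in for a genome-scale
reconstruction: lumped glycolysis, an explicit pyruvate branch point
(lactate dehydrogenase vs. mitochondrial import), lumped pyruvate oxidation
with an effective ATP yield, glutaminolysis entering at alpha-ketoglutarate,
a three-precursor biomass template and a fixed ATP maintenance drain.  The
observable surface -- exchange rates of glucose, oxygen, lactate and
glutamine for each metabolic phenotype -- is calibrated against the
phenotype flux table (see docs/methods.md).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkValidationError",
    "build_core_network",
    "MOLECULAR_WEIGHTS",
    "BIOMASS_FRACTIONS",
]

#: g/mmol for the exchanged species (fixed for all gram <-> mmol conversions)
MOLECULAR_WEIGHTS = {
    "glucose": 0.18016,
    "oxygen": 0.032,
    "lactate": 0.09008,
    "glutamine": 0.14615,
}

#: biomass template mass fractions, g per g-DW; must sum to 1.00
BIOMASS_FRACTIONS = {"amino_acids": 0.78, "nucleotides": 0.06, "lipids": 0.16}

#: exchange reaction id -> metabolite name for the four exchanged species
EXCHANGE_IDS = {
    "EX_glc": "glucose",
    "EX_o2": "oxygen",
    "EX_lac": "lactate",
    "EX_gln": "glutamine",
}

_COMPARTMENTS = {"e": "extracellular", "c": "cytosol", "m": "mitochondrion"}

REACTION_KINDS = ("exchange", "transport", "internal", "biomass", "maintenance")


class NetworkValidationError(ValueError):
    """Raised when a network definition violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    molecular_weight: float | None = None  # g/mmol, exchanged species only

    def __post_init__(self) -> None:
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise NetworkValidationError(
                f"metabolite {self.id}: molecular weight must be positive"
            )


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    kind: str = "internal"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise NetworkValidationError(
                f"reaction {self.id}: unknown kind {self.kind!r}"
            )
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id}: lower bound exceeds upper bound"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


_ARROWS = ("<=>", "-->", "->")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``'a + 2 b --> c'`` into signed stoichiometry.

    Returns (stoichiometry, reversible).  An empty side denotes a boundary
    (exchange/sink) reaction.
    """
    for arrow in _ARROWS:
        if arrow in eq:
            lhs, rhs = eq.split(arrow, 1)
            reversible = arrow == "<=>"
            break
    else:
        raise NetworkValidationError(f"no reaction arrow in equation {eq!r}")

    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$", term)
            if m is None:
                raise NetworkValidationError(f"cannot parse term {term!r} in {eq!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return stoich, reversible


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str
    maintenance_id: str
    maintenance_rate: float = 5.0  # mmol ATP/g-DW-hr, fixed in every solve
    biomass_fractions: dict[str, float] = field(
        default_factory=lambda: dict(BIOMASS_FRACTIONS)
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self):
        """Dense S (metabolites x reactions); small enough to stay dense."""
        import numpy as np

        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_index[met], j] = coef
        return S

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            raise NetworkValidationError("duplicate metabolite ids")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            raise NetworkValidationError("duplicate reaction ids")

        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise NetworkValidationError(
                    f"reaction {rxn.id}: unknown metabolites {sorted(missing)}"
                )

        n_bio = sum(r.kind == "biomass" for r in self.reactions)
        n_mnt = sum(r.kind == "maintenance" for r in self.reactions)
        if n_bio != 1:
            raise NetworkValidationError(
                f"network must contain exactly one biomass reaction (found {n_bio})"
            )
        if n_mnt != 1:
            raise NetworkValidationError(
                f"network must contain exactly one maintenance reaction (found {n_mnt})"
            )
        if self.reaction(self.biomass_id).kind != "biomass":
            raise NetworkValidationError("biomass_id does not name a biomass reaction")
        if self.reaction(self.maintenance_id).kind != "maintenance":
            raise NetworkValidationError(
                "maintenance_id does not name a maintenance reaction"
            )

        total = sum(self.biomass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise NetworkValidationError(
                f"biomass template fractions of reaction {self.biomass_id!r} sum to "
                f"{total:.4f}, expected 1.00"
            )
        if self.maintenance_rate < 0:
            raise NetworkValidationError("maintenance rate must be non-negative")

    # -- interoperability ------------------------------------------------
    def to_cobra(self):
        """Export as a cobrapy model (for SBML export / cross-checks)."""
        import cobra

        model = cobra.Model("tumorflux_core")
        mets = {}
        for m in self.metabolites:
            cm = cobra.Metabolite(
                m.id, name=m.name, compartment=m.compartment[0] if m.compartment else "c"
            )
            mets[m.id] = cm
        big = 1e6  # cobra/GLPK dislike true infinities
        for r in self.reactions:
            cr = cobra.Reaction(r.id, name=r.name)
            cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
            cr.lower_bound = max(r.lower_bound, -big)
            cr.upper_bound = min(r.upper_bound, big)
            model.add_reactions([cr])
        return model

    def to_sbml(self, path: str | Path) -> None:
        from cobra.io import write_sbml_model

        write_sbml_model(self.to_cobra(), str(path))


def _default_network_path() -> Path:
    return Path(str(resources.files("tumorflux").joinpath("data/core_network.tsv")))


def build_core_network(
    config: str | Path | None = None,
    maintenance_rate: float | None = None,
) -> MetabolicNetwork:
    """Build the core network from a tab-separated reaction table.

    The table has columns ``id, name, equation, lb, ub, kind`` plus comment
    lines ``# biomass_fractions`` and ``# maintenance_rate``.  With no
    argument the packaged calibrated network is used.
    """
    path = Path(config) if config is not None else _default_network_path()
    text = path.read_text()

    fractions = dict(BIOMASS_FRACTIONS)
    maint = 5.0
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("biomass_fractions"):
                fractions = {}
                for tok in body.split("\t")[1:]:
                    k, v = tok.split("=")
                    fractions[k.strip()] = float(v)
            elif body.startswith("maintenance_rate"):
                maint = float(body.split("\t")[1])
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            continue
        rows.append(dict(zip(header, cells)))
    if header is None or not rows:
        raise NetworkValidationError(f"no reaction rows found in {path}")

    if maintenance_rate is not None:
        maint = maintenance_rate

    reactions: list[Reaction] = []
    met_ids: set[str] = set()
    biomass_id = maintenance_id = None
    for row in rows:
        stoich, reversible = parse_equation(row["equation"])
        lb = float(row["lb"]) if row["lb"] not in ("", "-inf") else -math.inf
        ub = float(row["ub"]) if row["ub"] not in ("", "inf") else math.inf
        kind = row["kind"].strip()
        if not reversible and lb < 0:
            lb = 0.0
        rxn = Reaction(
            id=row["id"].strip(),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            kind=kind,
            name=row.get("name", "").strip(),
        )
        reactions.append(rxn)
        met_ids.update(stoich)
        if kind == "biomass":
            biomass_id = rxn.id
        elif kind == "maintenance":
            maintenance_id = rxn.id

    if biomass_id is None or maintenance_id is None:
        raise NetworkValidationError(
            "network table must define one biomass and one maintenance reaction"
        )

    name_by_suffix = {
        "glc": "glucose",
        "o2": "oxygen",
        "lac": "lactate",
        "gln": "glutamine",
        "hex": "hexose pool",
        "g3p": "triose phosphate",
        "pyr": "pyruvate",
        "nadh": "NADH",
        "atp": "ATP",
        "akg": "alpha-ketoglutarate",
    }
    metabolites = []
    for mid in sorted(met_ids):
        stem, _, comp = mid.rpartition("_")
        name = name_by_suffix.get(stem, stem)
        mw = MOLECULAR_WEIGHTS.get(name) if comp == "e" else None
        metabolites.append(
            Metabolite(
                id=mid,
                name=name,
                compartment=_COMPARTMENTS.get(comp, "cytosol"),
                molecular_weight=mw,
            )
        )

    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=biomass_id,
        maintenance_id=maintenance_id,
        maintenance_rate=maint,
        biomass_fractions=fractions,
    )
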