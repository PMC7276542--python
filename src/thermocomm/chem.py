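"""Chemical bookkeeping and Gibbs free energy evaluation.

Species carry an elemental composition, a formal charge and standard
formation energies; reactions are signed stoichiometric maps normalized to
a reference substrate.  Reaction free energies are evaluated at arbitrary
temperature, pH and activities via

    dG = dG0(T) + R*T*ln(Q)

with the mass-action ratio ``Q`` built from species activities, the proton
activity fixed at ``10**(-pH)`` and water activity fixed at 1.

Temperature adjustment of formation energies uses the linear
Gibbs-Helmholtz form, applied whenever an enthalpy of formation is
available:

    dGf(T) = dHf - (T/T_ref) * (dHf - dGf)
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Optional

from .constants import ATOMIC_WEIGHTS, R_KJ, T_REF

__all__ = [
    "ConfigurationError",
    "ElementComposition",
    "ChemSpecies",
    "Reaction",
    "BalanceReport",
    "molar_mass",
    "formation_energy",
    "standard_reaction_energy",
    "reaction_energy",
    "balance_check",
    "load_default_species",
]


class ConfigurationError(ValueError):
    """A user-supplied chemical definition is invalid."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")

#: Species name conventionally used for the proton; its activity is always
#: 10**(-pH) and it never carries a formation energy.
PROTON = "H+"

#: Species name conventionally used for water; its activity is always 1.
WATER = "H2O"


@dataclass(frozen=True)
class ElementComposition:
    """Elemental composition of one formula unit; counts may be fractional
    (the generic biomass molecule is C1 H1.8 O0.5 N0.2)."""

    counts: Mapping[str, float]
    charge: float = 0.0

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        if not counts or all(v == 0 for v in counts.values()):
            raise ConfigurationError("composition must contain at least one element")
        for elem, n in counts.items():
            if elem not in ATOMIC_WEIGHTS:
                raise ConfigurationError(f"unknown element symbol {elem!r}")
            if n < 0:
                raise ConfigurationError(f"negative count for element {elem!r}")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def parse(cls, formula: str, charge: float = 0.0) -> "ElementComposition":
        """Parse a condensed formula such as ``"C1H1.8O0.5N0.2"`` or ``"H2O"``."""
        counts: Dict[str, float] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ConfigurationError(f"cannot parse formula {formula!r}")
            pos = m.end()
            elem, num = m.group(1), m.group(2)
            counts[elem] = counts.get(elem, 0.0) + (float(num) if num else 1.0)
        if pos != len(formula):
            raise ConfigurationError(f"cannot parse formula {formula!r}")
        return cls(counts, charge)

    def count(self, element: str) -> float:
        return self.counts.get(element, 0.0)


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical species, bound to one phase.

    Aqueous/gas twins of a substance (H2(aq) vs H2(g)) are distinct
    species.  ``dgf``/``dhf`` are standard formation energies at 298.15 K
    in kJ mol^-1; a missing ``dhf`` disables temperature correction for
    the species.  ``fixed_activity`` pins the species' activity in every
    mass-action ratio (water at 1; biomass is conventionally treated the
    same way, as a separate solid-like phase).
    """

    name: str
    phase: str = "aqueous"
    composition: Optional[ElementComposition] = None
    dgf: Optional[float] = None
    dhf: Optional[float] = None
    fixed_activity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phase not in ("aqueous", "gas"):
            raise ConfigurationError(
                f"species {self.name!r}: phase must be 'aqueous' or 'gas'"
            )

    @property
    def charge(self) -> float:
        return self.composition.charge if self.composition is not None else 0.0

    @property
    def is_proton(self) -> bool:
        return self.name == PROTON


@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometric map (reactants negative, products positive),
    normalized to its reference species: coefficient -1 for a consumed
    reference substrate (catabolic convention) or +1 for a produced
    reference such as biomass (anabolic convention)."""

    coefficients: Mapping[str, float]
    reference: str

    def __post_init__(self) -> None:
        coeffs = {k: float(v) for k, v in self.coefficients.items() if v != 0}
        if not coeffs:
            raise ConfigurationError("reaction has an empty coefficient map")
        if self.reference not in coeffs:
            raise ConfigurationError(
                f"reference species {self.reference!r} absent from reaction"
            )
        if not math.isclose(
            abs(coeffs[self.reference]), 1.0, rel_tol=0, abs_tol=1e-12
        ):
            raise ConfigurationError(
                f"reference species {self.reference!r} must carry coefficient "
                f"+-1 (got {coeffs[self.reference]})"
            )
        object.__setattr__(self, "coefficients", coeffs)

    def normalized_to(self, species: str) -> "Reaction":
        """Rescale so that ``species`` carries coefficient -1 (it must be
        consumed by the reaction)."""
        nu = self.coefficients.get(species, 0.0)
        if nu >= 0:
            raise ConfigurationError(
                f"cannot normalize to {species!r}: not a reactant of the reaction"
            )
        scale = -1.0 / nu
        return Reaction(
            {k: v * scale for k, v in self.coefficients.items()}, reference=species
        )

    def items(self):
        return self.coefficients.items()


def molar_mass(composition: ElementComposition) -> float:
    """Mass of one formula unit, g mol^-1."""
    return sum(n * ATOMIC_WEIGHTS[e] for e, n in composition.counts.items())


def formation_energy(species: ChemSpecies, T: float) -> float:
    """Formation energy of a species at temperature ``T`` (kJ mol^-1)."""
    if species.is_proton:
        return 0.0
    if species.dgf is None:
        raise ConfigurationError(
            f"species {species.name!r} lacks a standard formation energy"
        )
    if species.dhf is None:
        return species.dgf
    return species.dhf - (T / T_REF) * (species.dhf - species.dgf)


def standard_reaction_energy(
    reaction: Reaction, species: Mapping[str, ChemSpecies], T: float = T_REF
) -> float:
    """dG0(T) per mol of the reference substrate, kJ mol^-1."""
    total = 0.0
    for name, nu in reaction.items():
        sp = species.get(name)
        if sp is None:
            raise ConfigurationError(f"species {name!r} not declared")
        total += nu * formation_energy(sp, T)
    return total


def reaction_energy(
    reaction: Reaction,
    species: Mapping[str, ChemSpecies],
    activities: Mapping[str, float],
    pH: float,
    T: float,
) -> float:
    """dG = dG0(T) + R*T*ln(Q), kJ per mol of the reference substrate.

    Proton activity is 10**(-pH); species with a ``fixed_activity`` (water,
    biomass) use it; every other participant must appear in ``activities``
    with a strictly positive value (callers apply a concentration floor).
    """
    dg = standard_reaction_energy(reaction, species, T)
    log_q = 0.0
    for name, nu in reaction.items():
        sp = species[name]
        if sp.is_proton:
            a = 10.0 ** (-pH)
        elif sp.fixed_activity is not None:
            a = sp.fixed_activity
        else:
            a = activities.get(name)
            if a is None:
                raise ConfigurationError(
                    f"no activity supplied for species {name!r}"
                )
            if a <= 0:
                raise ValueError(
                    f"non-positive activity {a} for species {name!r}; "
                    "apply a concentration floor before evaluating dG"
                )
        log_q += nu * math.log(a)
    return dg + R_KJ * T * log_q


@dataclass
class BalanceReport:
    """Per-element and charge imbalance of a reaction (products minus
    reactants, per mol of reference substrate)."""

    imbalance: Dict[str, float] = field(default_factory=dict)
    tolerance: float = 1e-6

    @property
    def flagged(self) -> Dict[str, float]:
        return {k: v for k, v in self.imbalance.items() if abs(v) > self.tolerance}

    @property
    def balanced(self) -> bool:
        return not self.flagged


def balance_check(
    reaction: Reaction,
    species: Mapping[str, ChemSpecies],
    tolerance: float = 1e-6,
) -> BalanceReport:
    """Sum nu * element count (and nu * charge) over the reaction.

    Printed reactions commonly carry rounding, so the tolerance is
    configurable; the default flags anything above 1e-6.
    """
    totals: Dict[str, float] = {"charge": 0.0}
    for name, nu in reaction.items():
        sp = species.get(name)
        if sp is None:
            raise ConfigurationError(f"species {name!r} not declared")
        if sp.composition is None:
            raise ConfigurationError(f"species {name!r} lacks a composition")
        for elem, n in sp.composition.counts.items():
            totals[elem] = totals.get(elem, 0.0) + nu * n
        totals["charge"] += nu * sp.composition.charge
    return BalanceReport(imbalance=totals, tolerance=tolerance)


def load_default_species() -> Dict[str, ChemSpecies]:
    """Load the bundled species table (delimited text, user-overridable).

    The table covers the dissolved and gaseous species of the sulfate
    reducer / methanogen model system; see the file header for the
    provenance of the formation energies.
    """
    out: Dict[str, ChemSpecies] = {}
    text = resources.files("thermocomm.data").joinpath("formation_energies.csv")
    with text.open("r", encoding="utf-8") as fh:
        rows = csv.DictReader(row for row in fh if not row.startswith("#"))
        for row in rows:
            comp = None
            if row["composition"]:
                comp = ElementComposition.parse(
                    row["composition"], float(row["charge"] or 0.0)
                )
            out[row["name"]] = ChemSpecies(
                name=row["name"],
                phase=row["phase"],
                composition=comp,
                dgf=float(row["dgf"]) if row["dgf"] else None,
                dhf=float(row["dhf"]) if row["dhf"] else None,
                fixed_activity=(
                    float(row["fixed_activity"]) if row["fixed_activity"] else None
                ),
            )
    return out
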