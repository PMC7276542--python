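"""The core growth law: energy-coupled catabolism/anabolism with dynamic
yield, and Monod x thermodynamic-inhibition kinetics.

Each population runs one or more catabolic pathways, all coupled to a
single anabolic (biomass-forming) reaction.  The number of catabolic
turnovers needed per biomass turnover closes the energy balance,

    lambda_cat = (dG_met - dG_an) / dG_cat        [mol_S mol_X^-1]

with dG_met the (negative) energy dissipated per C-mol of biomass formed,
dG_an the anabolic reaction energy and dG_cat the catabolic reaction
energy, the latter two evaluated dynamically from the current species
concentrations.  The pathway-specific catabolic rate is

    r = v_max * F_D * F_T
    F_D = prod_k [S_k] / (K_S,k + [S_k])
    F_T = 1 - exp(min(0, dG_cat - dG_min) / (R*T))

so the pathway shuts down exactly when dG_cat reaches the pathway's
minimum-energy threshold dG_min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .chem import (
    ChemSpecies,
    ConfigurationError,
    Reaction,
    reaction_energy,
)
from .constants import R_KJ

__all__ = [
    "CatabolicPathway",
    "AnabolicReaction",
    "Population",
    "PathwayState",
    "lambda_cat",
    "growth_yield",
    "kinetic_factor",
    "thermodynamic_factor",
    "pathway_specific_rate",
    "community_derivatives",
    "DEFAULT_DECAY",
]

#: Default linear biomass decay coefficient, h^-1.
DEFAULT_DECAY = 8.33e-4

#: Concentration floor applied before evaluating ln(Q), mol L^-1.
CONCENTRATION_FLOOR = 1e-12


@dataclass(frozen=True)
class CatabolicPathway:
    """A growth-supporting catabolic reaction with its kinetic constants
    and energy parameters.

    ``reaction`` is normalized to 1 mol of the reference substrate;
    ``v_max`` is the maximum catabolic turnover in mol_S (mol_X h)^-1;
    ``k_s`` maps each limiting substrate to its half-saturation constant
    (mol L^-1); ``dg_min`` (kJ mol_S^-1) is the calibratable minimum-energy
    threshold; ``dg_met`` (kJ mol_X^-1) the dissipated metabolic energy.
    """

    name: str
    reaction: Reaction
    v_max: float
    k_s: Mapping[str, float]
    dg_min: float
    dg_met: float

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ConfigurationError(f"pathway {self.name!r}: v_max must be > 0")
        for sub, ks in self.k_s.items():
            if ks <= 0:
                raise ConfigurationError(
                    f"pathway {self.name!r}: K_S for {sub!r} must be > 0"
                )
        if self.dg_min >= 0:
            raise ConfigurationError(f"pathway {self.name!r}: dG_min must be < 0")
        if self.dg_met >= 0:
            raise ConfigurationError(f"pathway {self.name!r}: dG_met must be < 0")


@dataclass(frozen=True)
class AnabolicReaction:
    """The biomass-forming reaction, normalized to +1 mol of biomass.

    ``biomass`` names the biomass species; ``electron_donor`` names the
    anabolic carbon/electron donor whose (positive) coefficient magnitude
    gamma_D enters the yield Y = 1/(lambda_cat + gamma_D).
    """

    reaction: Reaction
    biomass: str
    electron_donor: str

    def __post_init__(self) -> None:
        nu_x = self.reaction.coefficients.get(self.biomass)
        if nu_x is None or not math.isclose(nu_x, 1.0, abs_tol=1e-12):
            raise ConfigurationError(
                f"anabolic reaction must produce exactly +1 {self.biomass!r} "
                f"(got {nu_x})"
            )
        if self.reaction.coefficients.get(self.electron_donor, 0.0) >= 0:
            raise ConfigurationError(
                f"electron donor {self.electron_donor!r} must be consumed by "
                "the anabolic reaction"
            )

    @property
    def gamma_d(self) -> float:
        return -self.reaction.coefficients[self.electron_donor]


@dataclass(frozen=True)
class Population:
    """A microbial population: one biomass pool, >= 1 catabolic pathways,
    one shared anabolic reaction, and a linear decay coefficient."""

    name: str
    biomass_species: str
    pathways: Tuple[CatabolicPathway, ...]
    anabolic: AnabolicReaction
    k_d: float = DEFAULT_DECAY

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ConfigurationError(f"population {self.name!r} has no pathways")
        if self.k_d < 0:
            raise ConfigurationError(f"population {self.name!r}: k_d must be >= 0")


@dataclass
class PathwayState:
    """Per-evaluation derived quantities of one pathway."""

    dg_cat: float
    f_d: float
    f_t: float
    rate: float
    dg_an: Optional[float] = None
    lambda_cat: Optional[float] = None
    yield_x: Optional[float] = None

    @property
    def growing(self) -> bool:
        return self.rate > 0 and self.lambda_cat is not None and self.lambda_cat > 0


def lambda_cat(dg_met: float, dg_an: float, dg_cat: float) -> float:
    """Catabolic turnovers per biomass turnover, (dG_met - dG_an)/dG_cat.

    Only meaningful for a running pathway (dG_cat < 0); callers gate on the
    thermodynamic factor first.
    """
    if dg_cat >= 0:
        raise ValueError(
            "lambda_cat is undefined for a non-exergonic catabolic reaction "
            f"(dG_cat = {dg_cat:.3f} kJ/mol); gate on F_T > 0 first"
        )
    return (dg_met - dg_an) / dg_cat


def growth_yield(lam: float, gamma_d: float) -> float:
    """Biomass per substrate, Y = 1/(lambda_cat + gamma_D), mol_X mol_S^-1.

    Total substrate drawn per biomass formed is the catabolic draw
    (lambda_cat) plus the anabolic draw (gamma_D).
    """
    denom = lam + gamma_d
    if denom <= 0:
        raise ValueError(f"non-positive substrate draw per biomass ({denom})")
    return 1.0 / denom


def kinetic_factor(
    concentrations: Mapping[str, float], k_s: Mapping[str, float]
) -> float:
    """Multiplicative Monod factor over the declared limiting substrates."""
    f = 1.0
    for sub, ks in k_s.items():
        c = concentrations.get(sub)
        if c is None:
            raise ConfigurationError(
                f"no concentration available for limiting substrate {sub!r}"
            )
        c = max(c, 0.0)
        f *= c / (ks + c)
    return f


def thermodynamic_factor(dg_cat: float, dg_min: float, T: float) -> float:
    """F_T = 1 - exp(min(0, dG_cat - dG_min)/(R*T)), in [0, 1).

    Exactly 0 whenever dG_cat >= dG_min (the pathway is shut down), and
    approaching 1 as dG_cat becomes strongly negative.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 - math.exp(min(0.0, dg_cat - dg_min) / (R_KJ * T))


def pathway_specific_rate(
    pathway: CatabolicPathway,
    anabolic: AnabolicReaction,
    species: Mapping[str, ChemSpecies],
    concentrations: Mapping[str, float],
    pH: float,
    T: float,
    thermodynamics: bool = True,
    floor: float = CONCENTRATION_FLOOR,
) -> PathwayState:
    """Evaluate one pathway at the current (speciated) concentrations.

    With ``thermodynamics=False`` the thermodynamic factor is forced to 1
    (the forward-reaction-kinetics variant) and the energy coupling is
    gated on dG_cat < 0 only.
    """
    floored = {k: max(v, floor) for k, v in concentrations.items()}
    dg_cat = reaction_energy(pathway.reaction, species, floored, pH, T)
    f_d = kinetic_factor(concentrations, pathway.k_s)
    f_t = thermodynamic_factor(dg_cat, pathway.dg_min, T) if thermodynamics else 1.0
    rate = pathway.v_max * f_d * f_t
    state = PathwayState(dg_cat=dg_cat, f_d=f_d, f_t=f_t, rate=rate)
    coupled = (f_t > 0.0) if thermodynamics else (dg_cat < 0.0)
    if coupled and dg_cat < 0.0:
        dg_an = reaction_energy(anabolic.reaction, species, floored, pH, T)
        lam = lambda_cat(pathway.dg_met, dg_an, dg_cat)
        state.dg_an = dg_an
        if lam > 0:
            state.lambda_cat = lam
            state.yield_x = growth_yield(lam, anabolic.gamma_d)
    return state


def community_derivatives(
    populations: Mapping[str, Tuple[Population, float]],
    species: Mapping[str, ChemSpecies],
    concentrations: Mapping[str, float],
    pH: float,
    T: float,
    thermodynamics: bool = True,
    floor: float = CONCENTRATION_FLOOR,
    depleted: Optional[Mapping[str, bool]] = None,
) -> Tuple[Dict[str, float], Dict[str, float], Dict[Tuple[str, str], PathwayState]]:
    """Biochemical derivative terms for every chemical and every biomass.

    ``populations`` maps population name to (Population, biomass conc).
    Returns (per-species chemical rates mol L^-1 h^-1, per-population
    biomass rates, per-(population, pathway) diagnostic states).  Proton,
    water and fixed-activity species (biomass) are excluded from the
    chemical map; biomass dynamics are reported separately.

    ``depleted`` optionally marks pools at the solver floor; any pathway
    consuming a depleted species is halted (overshoot guard).
    """
    d_chem: Dict[str, float] = {}
    d_bio: Dict[str, float] = {}
    states: Dict[Tuple[str, str], PathwayState] = {}

    def add(name: str, amount: float) -> None:
        sp = species[name]
        if sp.is_proton or sp.fixed_activity is not None:
            return
        d_chem[name] = d_chem.get(name, 0.0) + amount

    for pop_name, (pop, x) in populations.items():
        growth_rate = 0.0
        for pw in pop.pathways:
            st = pathway_specific_rate(
                pw, pop.anabolic, species, concentrations, pH, T,
                thermodynamics=thermodynamics, floor=floor,
            )
            if depleted is not None and st.rate > 0:
                for name, nu in pw.reaction.items():
                    if nu < 0 and depleted.get(name, False):
                        st.rate = 0.0
                        break
            states[(pop_name, pw.name)] = st
            if st.rate == 0.0 or x == 0.0:
                continue
            flux = x * st.rate  # mol_S L^-1 h^-1
            for name, nu in pw.reaction.items():
                add(name, flux * nu)
            if st.growing:
                anab_flux = flux / st.lambda_cat  # mol_X L^-1 h^-1
                growth_rate += st.rate / st.lambda_cat
                for name, nu in pop.anabolic.reaction.items():
                    if name == pop.anabolic.biomass:
                        continue
                    add(name, anab_flux * nu)
        d_bio[pop_name] = x * (growth_rate - pop.k_d)
    return d_chem, d_bio, states
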