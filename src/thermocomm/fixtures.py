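"""Self-contained builders for the sulfate-reducer/methanogen batch system
and synthetic observation data.

The generated configuration emulates sealed anaerobic tubes: 5 mL medium
with 30 mM Na-lactate and 7.5 mM Na2SO4 under an N2/CO2 headspace at
37 degC, inoculated with any subset of

* ``Dv`` - a sulfate reducer (lactate fermentation, lactate + sulfate
  respiration, H2 + sulfate respiration),
* ``Mm`` - a hydrogenotrophic methanogen,
* ``Mb`` - a methanogen running both hydrogenotrophic and acetoclastic
  methanogenesis,

sampled daily for 21 days with multiplicative lognormal measurement noise.
Pathway stoichiometries, metabolic energies, the biomass formation energy
(-67 kJ mol^-1) and the decay coefficient (8.33e-4 h^-1) follow the model
system's published energetics; maximum turnover rates, half-saturation
constants, Henry/k_La constants and the headspace make-up are
literature-plausible defaults and are documented as assumptions in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import ObservationSet
from .chem import ConfigurationError, Reaction, load_default_species
from .constants import P_ATM, R_J
from .equilibria import AcidBaseFamily
from .gas_liquid import PhaseExchangeSpec, PhaseGeometry, integrate_transfer
from .growth import DEFAULT_DECAY, AnabolicReaction, CatabolicPathway, Population
from .simulator import SimulationConfig, SolverOptions, Trajectory, simulate

__all__ = [
    "FixtureOptions",
    "build_dv_mm_mb_system",
    "synthesize_observations",
    "gas_equilibration_fixture",
    "DEFAULT_DG_MIN",
]

#: Default minimum-energy thresholds, kJ mol^-1.  Lactate fermentation and
#: the methanogenesis pathways sit in the ranges reported for this model
#: system; the sulfate-respiration pathways use the monoculture estimate
#: of -44.66 kJ mol^-1 from earlier work on Desulfovibrio.
DEFAULT_DG_MIN = {
    "Dv:lactate_fermentation": -30.0,
    "Dv:lactate_sulfate_respiration": -44.66,
    "Dv:hydrogen_sulfate_respiration": -44.66,
    "Mm:hydrogenotrophic_methanogenesis": -25.0,
    "Mb:hydrogenotrophic_methanogenesis": -25.0,
    "Mb:acetoclastic_methanogenesis": -40.0,
}

#: Metabolite variables entering calibration, mirroring what the wet
#: experiment measures by chromatography.
OBSERVED_VARIABLES = ("lactate", "acetate", "H2(g)", "CH4(g)")

#: Everything the synthetic experiment records, including pH and the
#: OD-proxy total biomass.
SAMPLED_VARIABLES = OBSERVED_VARIABLES + ("pH", "biomass_total")


@dataclass(frozen=True)
class FixtureOptions:
    """Study-condition knobs of the synthetic experiment."""

    cultures: Tuple[str, ...] = ("Dv",)
    lactate: float = 0.030
    sulfate: float = 0.0075
    schedule: Tuple[float, ...] = tuple(24.0 * d for d in range(22))
    sigma: float = 0.05
    seed: int = 0
    initial_od: float = 0.05
    duration: float = 504.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("noise sigma must be >= 0")
        known = {"Dv", "Mm", "Mb"}
        unknown = set(self.cultures) - known
        if unknown:
            raise ConfigurationError(f"unknown cultures: {sorted(unknown)}")
        if self.schedule and max(self.schedule) > self.duration:
            raise ConfigurationError("sampling schedule exceeds the horizon")


def _populations(options: FixtureOptions) -> list:
    lac, h2, ac, hco3, so4, h2s, ch4, nh4, h2o, hp, x = (
        "lactate-", "H2(aq)", "acetate-", "HCO3-", "SO4-2", "H2S(aq)",
        "CH4(aq)", "NH4+", "H2O", "H+", "biomass",
    )
    dv = Population(
        name="Dv",
        biomass_species=x,
        k_d=DEFAULT_DECAY,
        anabolic=AnabolicReaction(
            # as printed for the lactate-assimilating anabolism; carries a
            # small C/H rounding imbalance that balance_check reports
            reaction=Reaction(
                {lac: -0.35, nh4: -0.2, hp: -0.1, x: 1.0, ac: 0.05, h2o: 0.4},
                reference=x,
            ),
            biomass=x,
            electron_donor=lac,
        ),
        pathways=(
            CatabolicPathway(
                name="lactate_fermentation",
                reaction=Reaction(
                    {lac: -1.0, h2o: -2.0, ac: 1.0, h2: 2.0, hco3: 1.0, hp: 1.0},
                    reference=lac,
                ),
                v_max=0.2,
                k_s={lac: 5e-4},
                dg_min=DEFAULT_DG_MIN["Dv:lactate_fermentation"],
                dg_met=-265.1,
            ),
            CatabolicPathway(
                name="lactate_sulfate_respiration",
                reaction=Reaction(
                    {lac: -1.0, so4: -0.5, ac: 1.0, hco3: 1.0, h2s: 0.5},
                    reference=lac,
                ),
                v_max=0.25,
                k_s={lac: 5e-4, so4: 2e-4},
                dg_min=DEFAULT_DG_MIN["Dv:lactate_sulfate_respiration"],
                dg_met=-228.2,
            ),
            CatabolicPathway(
                name="hydrogen_sulfate_respiration",
                reaction=Reaction(
                    {h2: -1.0, so4: -0.25, hp: -0.5, h2s: 0.25, h2o: 1.0},
                    reference=h2,
                ),
                v_max=1.5,
                k_s={h2: 1e-6, so4: 2e-4},
                dg_min=DEFAULT_DG_MIN["Dv:hydrogen_sulfate_respiration"],
                dg_met=-362.1,
            ),
        ),
    )
    mm = Population(
        name="Mm",
        biomass_species=x,
        k_d=DEFAULT_DECAY,
        anabolic=AnabolicReaction(
            reaction=Reaction(
                {hco3: -1.0, h2: -2.1, nh4: -0.2, hp: -0.8, x: 1.0, h2o: 2.5},
                reference=x,
            ),
            biomass=x,
            electron_donor=h2,
        ),
        pathways=(
            CatabolicPathway(
                name="hydrogenotrophic_methanogenesis",
                reaction=Reaction(
                    {hco3: -0.25, h2: -1.0, hp: -0.25, ch4: 0.25, h2o: 0.75},
                    reference=h2,
                ),
                v_max=1.2,
                k_s={h2: 6e-6, hco3: 1e-4},
                dg_min=DEFAULT_DG_MIN["Mm:hydrogenotrophic_methanogenesis"],
                dg_met=-876.4,
            ),
        ),
    )
    mb = Population(
        name="Mb",
        biomass_species=x,
        k_d=DEFAULT_DECAY,
        anabolic=AnabolicReaction(
            reaction=Reaction(
                {ac: -0.525, nh4: -0.2, hp: -0.275, x: 1.0, hco3: 0.05, h2o: 0.4},
                reference=x,
            ),
            biomass=x,
            electron_donor=ac,
        ),
        pathways=(
            CatabolicPathway(
                name="hydrogenotrophic_methanogenesis",
                reaction=Reaction(
                    {hco3: -0.25, h2: -1.0, hp: -0.25, ch4: 0.25, h2o: 0.75},
                    reference=h2,
                ),
                v_max=0.6,
                k_s={h2: 1e-5, hco3: 1e-4},
                dg_min=DEFAULT_DG_MIN["Mb:hydrogenotrophic_methanogenesis"],
                dg_met=-1059.8,
            ),
            CatabolicPathway(
                name="acetoclastic_methanogenesis",
                reaction=Reaction(
                    {ac: -1.0, h2o: -1.0, ch4: 1.0, hco3: 1.0},
                    reference=ac,
                ),
                v_max=0.12,
                k_s={ac: 3e-3},
                dg_min=DEFAULT_DG_MIN["Mb:acetoclastic_methanogenesis"],
                dg_met=-268.3,
            ),
        ),
    )
    by_name = {"Dv": dv, "Mm": mm, "Mb": mb}
    return [by_name[c] for c in ("Dv", "Mm", "Mb") if c in options.cultures]


def _gas_conc(pressure_atm: float, temperature: float) -> float:
    """Headspace content (mol per L of gas) of a partial pressure."""
    return pressure_atm * P_ATM / (R_J * temperature) / 1000.0


def build_dv_mm_mb_system(
    options: Optional[FixtureOptions] = None,
) -> SimulationConfig:
    """Full simulation config for the selected culture composition."""
    options = options or FixtureOptions()
    species = load_default_species()
    temperature = 310.15
    families = [
        AcidBaseFamily("lactate", ("lactate(H)", "lactate-"), (3.86,)),
        AcidBaseFamily("acetate", ("acetate(H)", "acetate-"), (4.76,)),
        AcidBaseFamily("carbonate", ("CO2(aq)", "HCO3-", "CO3-2"), (6.35, 10.33)),
        AcidBaseFamily("sulfide", ("H2S(aq)", "HS-"), (7.05,)),
        AcidBaseFamily("ammonium", ("NH4+", "NH3(aq)"), (9.25,)),
    ]
    exchanges = [
        PhaseExchangeSpec("H2(aq)", "H2(g)", kla=0.5, h_ref=7.8e-6, dh_sol=530.0),
        PhaseExchangeSpec("CO2(aq)", "CO2(g)", kla=0.6, h_ref=3.3e-4, dh_sol=2400.0),
        PhaseExchangeSpec("CH4(aq)", "CH4(g)", kla=0.4, h_ref=1.4e-5, dh_sol=1900.0),
        PhaseExchangeSpec("H2S(aq)", "H2S(g)", kla=0.5, h_ref=1.0e-3, dh_sol=2100.0),
    ]
    bicarbonate = 0.010
    ammonium = 0.005
    sodium = options.lactate + 2.0 * options.sulfate + bicarbonate
    return SimulationConfig(
        species=species,
        populations=_populations(options),
        geometry=PhaseGeometry(v_aq=0.005, v_gas=0.0123, temperature=temperature),
        families=families,
        exchanges=exchanges,
        fixed_ions={"Na+": sodium, "Cl-": ammonium},
        initial_aqueous={
            "lactate": options.lactate,
            "SO4-2": options.sulfate,
            "carbonate": bicarbonate,
            "ammonium": ammonium,
        },
        initial_gas={
            "N2(g)": _gas_conc(0.8, temperature),
            "CO2(g)": _gas_conc(0.2, temperature),
        },
        initial_od=options.initial_od,
        duration=options.duration,
    )


def synthesize_observations(
    config: SimulationConfig,
    true_dg_min: Mapping[str, float],
    options: Optional[FixtureOptions] = None,
    variables: Sequence[str] = SAMPLED_VARIABLES,
    solver: Optional[SolverOptions] = None,
    trajectory: Optional[Trajectory] = None,
) -> Tuple[ObservationSet, Dict[str, float]]:
    """Simulate under known thresholds and sample noisy observations.

    Multiplicative lognormal noise, value * exp(sigma * z), keeps samples
    positive and unbiased in log space.  A precomputed ``trajectory`` (for
    the same thresholds) may be passed to re-sample noise without
    re-integrating.  Returns the observation set and the ground-truth
    record for recovery tests.
    """
    options = options or FixtureOptions()
    rng = np.random.default_rng(options.seed)
    if trajectory is None:
        cfg = config.with_dg_min(dict(true_dg_min))
        trajectory = simulate(cfg, solver=solver)
    rows = []
    times = np.asarray(options.schedule, dtype=float)
    for var in variables:
        model = trajectory.interpolate(var, times)
        noise = (
            np.exp(options.sigma * rng.standard_normal(times.size))
            if options.sigma > 0
            else np.ones(times.size)
        )
        for t, v in zip(times, model * noise):
            rows.append({"time": float(t), "variable": var, "value": float(v)})
    obs = ObservationSet(pd.DataFrame(rows))
    truth = {f"{p}": float(v) for p, v in true_dg_min.items()}
    return obs, truth


def gas_equilibration_fixture(
    true_kla: float,
    schedule: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0),
    partial_pressure_atm: float = 0.3,
) -> Tuple[np.ndarray, np.ndarray, PhaseExchangeSpec, PhaseGeometry, float, float]:
    """Transfer-only outgassing series for k_La round-trip tests.

    Emulates a tube whose liquid was pre-equilibrated with dissolved H2 and
    whose headspace was then flushed with N2: the dissolved gas re-enters
    the (initially empty) headspace, sampled on the stated schedule.
    Returns (times, gas series, spec, geometry, aq0, gas0).
    """
    if true_kla <= 0:
        raise ConfigurationError("true k_La must be positive")
    geom = PhaseGeometry(v_aq=0.005, v_gas=0.0123, temperature=310.15)
    spec = PhaseExchangeSpec(
        "H2(aq)", "H2(g)", kla=true_kla, h_ref=7.8e-6, dh_sol=530.0
    )
    from .gas_liquid import henry_at_temperature

    aq0 = (
        henry_at_temperature(spec, geom.temperature)
        * partial_pressure_atm
        * P_ATM
        / 1000.0
    )
    gas0 = 0.0
    times = np.asarray(schedule, dtype=float)
    series = integrate_transfer(spec, geom, aq0, gas0, times)[:, 1]
    return times, series, spec, geom, aq0, gas0
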