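"""System assembly and ODE integration.

The simulator carries, as state variables, the acid-base family totals,
the free (non-speciating) aqueous species, the headspace gas contents and
one biomass pool per population.  At every derivative evaluation it

  (i)   solves the charge balance for pH and speciates every family,
  (ii)  computes the biochemical and the gas/liquid-transfer derivative
        terms separately at that state, and
  (iii) sums the two terms.

pH is therefore an algebraic constraint, never a state variable.
Integration uses a stiff-capable adaptive solver (LSODA by default).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .chem import (
    ChemSpecies,
    ConfigurationError,
    ElementComposition,
    Reaction,
    balance_check,
    molar_mass,
)
from .equilibria import AcidBaseFamily, ChargeBalanceSolver, PhSolverError
from .gas_liquid import PhaseExchangeSpec, PhaseGeometry, transfer_derivatives
from .growth import (
    AnabolicReaction,
    CatabolicPathway,
    PathwayState,
    Population,
    community_derivatives,
)

__all__ = [
    "SolverOptions",
    "ODCalibration",
    "SimulationConfig",
    "Trajectory",
    "SimulationError",
    "biomass_from_od",
    "simulate",
    "state_derivative",
    "load_config",
    "dump_config",
]


class SimulationError(RuntimeError):
    """Integration failed; carries the last good state for diagnosis."""

    def __init__(self, message: str, state: Optional[Mapping[str, float]] = None):
        super().__init__(message)
        self.state = dict(state) if state else None


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-6
    atol: float = 1e-12
    method: str = "LSODA"


@dataclass(frozen=True)
class ODCalibration:
    """Log-linear OD600 -> dry weight calibration, ln(DW) = slope*OD - intercept
    with DW in g L^-1."""

    slope: float = 5.12
    intercept: float = 4.987


@dataclass
class SimulationConfig:
    """Complete declaration of a batch system.

    ``initial_aqueous`` is keyed by *pool* name: an acid-base family name
    (the family's total) or a free aqueous species name.  ``fixed_ions``
    are spectator ions entering only the charge balance.
    """

    species: Dict[str, ChemSpecies]
    populations: List[Population]
    geometry: PhaseGeometry
    families: List[AcidBaseFamily] = field(default_factory=list)
    exchanges: List[PhaseExchangeSpec] = field(default_factory=list)
    fixed_ions: Dict[str, float] = field(default_factory=dict)
    initial_aqueous: Dict[str, float] = field(default_factory=dict)
    initial_gas: Dict[str, float] = field(default_factory=dict)
    initial_biomass: Optional[Dict[str, float]] = None
    initial_od: Optional[float] = None
    pkw: float = 14.0
    duration: float = 504.0
    n_output: int = 253
    floor: float = 1e-12
    od_calibration: ODCalibration = field(default_factory=ODCalibration)
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ConfigurationError("duration must be >= 0")
        self.families = [
            f if f.charges else f.resolve_charges(self.species) for f in self.families
        ]
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigurationError("population names must be unique")
        for ion in self.fixed_ions:
            if ion not in self.species:
                raise ConfigurationError(f"fixed ion {ion!r} not declared in species")

    # -- parameter addressing ------------------------------------------------
    def dg_min_parameters(self) -> List[str]:
        """Names of every calibratable threshold, '<population>:<pathway>'."""
        return [
            f"{pop.name}:{pw.name}" for pop in self.populations for pw in pop.pathways
        ]

    def with_dg_min(self, overrides: Mapping[str, float]) -> "SimulationConfig":
        """Copy of the config with selected dG_min values replaced."""
        unknown = set(overrides) - set(self.dg_min_parameters())
        if unknown:
            raise ConfigurationError(f"unknown dG_min parameters: {sorted(unknown)}")
        new_pops = []
        for pop in self.populations:
            pws = tuple(
                replace(pw, dg_min=overrides.get(f"{pop.name}:{pw.name}", pw.dg_min))
                for pw in pop.pathways
            )
            new_pops.append(replace(pop, pathways=pws))
        cfg = copy.copy(self)
        cfg.populations = new_pops
        return cfg

    def validate_reactions(self, tolerance: float = 1e-6) -> Dict[str, Dict[str, float]]:
        """Balance-check every declared reaction; returns flagged imbalances
        per reaction (printed stoichiometries commonly carry rounding)."""
        warnings: Dict[str, Dict[str, float]] = {}
        for pop in self.populations:
            for pw in pop.pathways:
                rep = balance_check(pw.reaction, self.species, tolerance)
                if not rep.balanced:
                    warnings[f"{pop.name}:{pw.name}"] = rep.flagged
            rep = balance_check(pop.anabolic.reaction, self.species, tolerance)
            if not rep.balanced:
                warnings[f"{pop.name}:anabolism"] = rep.flagged
        return warnings


def biomass_from_od(
    od600: float, config: SimulationConfig
) -> Dict[str, float]:
    """Total biomass from an OD600 reading, evenly split across populations.

    DW = exp(slope*OD - intercept) g L^-1, converted to C-mol L^-1 with the
    molar mass of the configured biomass molecule.
    """
    if od600 <= 0:
        raise ValueError("OD600 must be positive")
    cal = config.od_calibration
    dw = math.exp(cal.slope * od600 - cal.intercept)
    bm_name = config.populations[0].biomass_species
    bm = config.species[bm_name]
    if bm.composition is None:
        raise ConfigurationError(f"biomass species {bm_name!r} lacks a composition")
    total = dw / molar_mass(bm.composition)
    n = len(config.populations)
    return {pop.name: total / n for pop in config.populations}


class CompiledSystem:
    """Index maps and fast evaluation paths for one configuration."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        sp = config.species
        self.member_to_family: Dict[str, str] = {}
        for fam in config.families:
            for m in fam.species:
                self.member_to_family[m] = fam.name

        referenced: List[str] = []

        def note(name: str) -> None:
            if name not in sp:
                raise ConfigurationError(f"species {name!r} not declared")
            if name not in referenced:
                referenced.append(name)

        for pop in config.populations:
            for pw in pop.pathways:
                for name in pw.reaction.coefficients:
                    note(name)
                for name in pw.k_s:
                    note(name)
            for name in pop.anabolic.reaction.coefficients:
                note(name)
        for ex in config.exchanges:
            note(ex.aqueous)
            note(ex.gas)

        biomass_names = {pop.biomass_species for pop in config.populations}

        # pool order: families, free aqueous, gas, biomass
        self.family_pools = [fam.name for fam in config.families]
        self.free_pools: List[str] = []
        self.gas_pools: List[str] = []
        for name in referenced:
            s = sp[name]
            if s.phase == "gas":
                if name not in self.gas_pools:
                    self.gas_pools.append(name)
            elif (
                name in self.member_to_family
                or s.is_proton
                or s.fixed_activity is not None
                or name in biomass_names
            ):
                continue
            elif name not in self.free_pools:
                self.free_pools.append(name)
        for name in config.initial_aqueous:
            if name in self.family_pools or name in self.free_pools:
                continue
            if name in sp and sp[name].phase == "aqueous":
                if name in self.member_to_family:
                    raise ConfigurationError(
                        f"initial_aqueous entry {name!r} is a family member; "
                        f"declare the family total {self.member_to_family[name]!r}"
                    )
                self.free_pools.append(name)
            else:
                raise ConfigurationError(
                    f"initial_aqueous pool {name!r} is neither a family nor a "
                    "declared aqueous species"
                )
        for name in config.initial_gas:
            if name not in self.gas_pools:
                if name not in sp or sp[name].phase != "gas":
                    raise ConfigurationError(
                        f"initial_gas pool {name!r} is not a declared gas species"
                    )
                self.gas_pools.append(name)

        self.bio_pools = [pop.name for pop in config.populations]
        self.pools = (
            self.family_pools + self.free_pools + self.gas_pools + self.bio_pools
        )
        self.index = {name: i for i, name in enumerate(self.pools)}
        self.n = len(self.pools)
        self.n_fam = len(self.family_pools)

        self.free_charges = np.array(
            [sp[name].charge for name in self.free_pools], dtype=float
        )
        self.fixed_charge = sum(
            sp[name].charge * conc for name, conc in config.fixed_ions.items()
        )
        self.ph_solver = ChargeBalanceSolver(config.families, pkw=config.pkw)
        self.populations = {pop.name: pop for pop in config.populations}

    # -- state assembly ------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        cfg = self.config
        y0 = np.zeros(self.n)
        for name, conc in cfg.initial_aqueous.items():
            y0[self.index[name]] = conc
        for name, conc in cfg.initial_gas.items():
            y0[self.index[name]] = conc
        biomass = cfg.initial_biomass
        if biomass is None:
            if cfg.initial_od is None:
                raise ConfigurationError(
                    "either initial_biomass or initial_od must be provided"
                )
            biomass = biomass_from_od(cfg.initial_od, cfg)
        for pop in cfg.populations:
            y0[self.index[pop.name]] = biomass[pop.name]
        return y0

    def solve_ph(self, y: np.ndarray) -> float:
        fam_totals = np.maximum(y[: self.n_fam], 0.0)
        fixed = self.fixed_charge
        if self.free_pools:
            fixed += float(
                np.dot(self.free_charges, np.maximum(y[self.n_fam:self.n_fam + len(self.free_pools)], 0.0))
            )
        return self.ph_solver.solve(fam_totals, fixed)

    def speciate(self, y: np.ndarray, ph: float) -> Dict[str, float]:
        """Free concentrations of every aqueous species at the given pH."""
        conc: Dict[str, float] = {}
        fracs = self.ph_solver.fractions(ph)
        for fam in self.config.families:
            tot = max(y[self.index[fam.name]], 0.0)
            for m in fam.species:
                conc[m] = tot * fracs[m]
        for name in self.free_pools:
            conc[name] = max(y[self.index[name]], 0.0)
        for name in self.gas_pools:
            conc[name] = max(y[self.index[name]], 0.0)
        return conc

    def _pool_of(self, species_name: str) -> Optional[int]:
        pool = self.member_to_family.get(species_name, species_name)
        return self.index.get(pool)

    # -- derivative terms ----------------------------------------------------
    def biochem_derivative(
        self,
        y: np.ndarray,
        ph: float,
        conc: Mapping[str, float],
        thermodynamics: bool = True,
    ) -> Tuple[np.ndarray, Dict[Tuple[str, str], PathwayState]]:
        cfg = self.config
        dy = np.zeros(self.n)
        depleted = {
            name: (y[self._pool_of(name)] <= cfg.floor)
            for name in conc
            if self._pool_of(name) is not None
        }
        pops = {
            name: (pop, max(y[self.index[name]], 0.0))
            for name, pop in self.populations.items()
        }
        d_chem, d_bio, states = community_derivatives(
            pops,
            cfg.species,
            conc,
            ph,
            cfg.geometry.temperature,
            thermodynamics=thermodynamics,
            floor=cfg.floor,
            depleted=depleted,
        )
        for name, rate in d_chem.items():
            idx = self._pool_of(name)
            if idx is None:
                raise ConfigurationError(
                    f"reaction species {name!r} is not carried by any state pool"
                )
            dy[idx] += rate
        for name, rate in d_bio.items():
            dy[self.index[name]] += rate
        return dy, states

    def transfer_derivative(
        self, y: np.ndarray, conc: Mapping[str, float]
    ) -> np.ndarray:
        cfg = self.config
        dy = np.zeros(self.n)
        for ex in cfg.exchanges:
            aq = conc[ex.aqueous]
            gas = max(y[self.index[ex.gas]], 0.0)
            daq, dgas = transfer_derivatives(aq, gas, ex, cfg.geometry)
            aq_idx = self._pool_of(ex.aqueous)
            dy[aq_idx] += daq
            dy[self.index[ex.gas]] += dgas
        return dy

    def derivative(
        self, y: np.ndarray, thermodynamics: bool = True
    ) -> np.ndarray:
        y = np.maximum(y, 0.0)
        ph = self.solve_ph(y)
        conc = self.speciate(y, ph)
        bio, _ = self.biochem_derivative(y, ph, conc, thermodynamics)
        return bio + self.transfer_derivative(y, conc)


@dataclass
class Trajectory:
    """Integrated output on the requested grid.

    ``frame`` is a wide table (one row per time, one column per pool plus
    pH); ``diagnostics`` holds the per-pathway rate decomposition on the
    same grid.
    """

    frame: pd.DataFrame
    diagnostics: pd.DataFrame
    pools: List[str]

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    def series(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    def to_tidy(self) -> pd.DataFrame:
        return self.frame.melt(id_vars="time", var_name="variable", value_name="value")

    def interpolate(self, name: str, times: Sequence[float]) -> np.ndarray:
        return np.interp(np.asarray(times, float), self.times, self.series(name))


def state_derivative(
    state: np.ndarray, config: SimulationConfig, thermodynamics: bool = True
) -> np.ndarray:
    """One-off derivative evaluation of a raw state vector (pool order as
    compiled: families, free aqueous, gas, biomass)."""
    system = CompiledSystem(config)
    try:
        return system.derivative(np.asarray(state, float), thermodynamics)
    except PhSolverError as exc:
        raise SimulationError(
            f"pH solver failed: {exc}",
            state=dict(zip(system.pools, state)),
        ) from exc


def simulate(
    config: SimulationConfig,
    thermodynamics: bool = True,
    solver: Optional[SolverOptions] = None,
    system: Optional[CompiledSystem] = None,
) -> Trajectory:
    """Integrate the batch system over ``config.duration`` hours.

    ``thermodynamics=False`` forces F_T = 1 in every pathway (the
    forward-reaction-kinetics variant).  A pre-compiled ``system`` may be
    supplied to amortize setup across repeated runs (calibration sweeps).
    """
    if system is None:
        system = CompiledSystem(config)
    solver = solver or config.solver
    y0 = system.initial_state()
    grid = np.linspace(0.0, config.duration, max(2, config.n_output))
    if config.duration == 0:
        grid = np.array([0.0])
        ys = y0[None, :]
    else:
        def rhs(_t, y):
            return system.derivative(y, thermodynamics)

        try:
            sol = solve_ivp(
                rhs,
                (0.0, config.duration),
                y0,
                method=solver.method,
                rtol=solver.rtol,
                atol=solver.atol,
                t_eval=grid,
            )
        except PhSolverError as exc:
            raise SimulationError(f"pH solver failed during integration: {exc}") from exc
        if not sol.success:
            last = dict(zip(system.pools, sol.y[:, -1])) if sol.y.size else None
            raise SimulationError(
                f"integration failed: {sol.message}", state=last
            )
        grid = sol.t
        ys = np.maximum(sol.y.T, 0.0)

    rows = []
    diag_rows = []
    for t, y in zip(grid, ys):
        ph = system.solve_ph(y)
        conc = system.speciate(y, ph)
        row = {"time": t, **{p: y[system.index[p]] for p in system.pools}, "pH": ph}
        rows.append(row)
        _, states = system.biochem_derivative(y, ph, conc, thermodynamics)
        for (pop, pw), st in states.items():
            diag_rows.append(
                {
                    "time": t,
                    "population": pop,
                    "pathway": pw,
                    "rate": st.rate,
                    "F_D": st.f_d,
                    "F_T": st.f_t,
                    "dG_cat": st.dg_cat,
                    "lambda_cat": st.lambda_cat,
                    "yield": st.yield_x,
                }
            )
    frame = pd.DataFrame(rows)
    if system.bio_pools:
        frame["biomass_total"] = frame[system.bio_pools].sum(axis=1)
    diagnostics = pd.DataFrame(diag_rows)
    return Trajectory(frame=frame, diagnostics=diagnostics, pools=list(system.pools))


# ---------------------------------------------------------------------------
# Config (de)serialization: structured YAML with sections
#   species / equilibria / exchanges / populations / initial / solver
# ---------------------------------------------------------------------------

def _species_to_dict(sp: ChemSpecies) -> dict:
    out: dict = {"phase": sp.phase}
    if sp.composition is not None:
        formula = "".join(
            f"{e}{n:g}" for e, n in sorted(sp.composition.counts.items())
        )
        out["composition"] = formula
        out["charge"] = sp.composition.charge
    if sp.dgf is not None:
        out["dgf"] = sp.dgf
    if sp.dhf is not None:
        out["dhf"] = sp.dhf
    if sp.fixed_activity is not None:
        out["fixed_activity"] = sp.fixed_activity
    return out


def _species_from_dict(name: str, d: Mapping) -> ChemSpecies:
    comp = None
    if "composition" in d:
        comp = ElementComposition.parse(d["composition"], float(d.get("charge", 0.0)))
    return ChemSpecies(
        name=name,
        phase=d.get("phase", "aqueous"),
        composition=comp,
        dgf=d.get("dgf"),
        dhf=d.get("dhf"),
        fixed_activity=d.get("fixed_activity"),
    )


def _reaction_to_dict(rxn: Reaction) -> dict:
    return {"coefficients": dict(rxn.coefficients), "reference": rxn.reference}


def _reaction_from_dict(d: Mapping, where: str) -> Reaction:
    try:
        return Reaction(dict(d["coefficients"]), d["reference"])
    except KeyError as exc:
        raise ConfigurationError(f"{where}: missing key {exc}") from exc


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "species": {n: _species_to_dict(s) for n, s in config.species.items()},
        "equilibria": {
            "pkw": config.pkw,
            "families": [
                {"name": f.name, "species": list(f.species), "pks": list(f.pks)}
                for f in config.families
            ],
        },
        "exchanges": [
            {
                "aqueous": e.aqueous,
                "gas": e.gas,
                "kla": e.kla,
                "h_ref": e.h_ref,
                "dh_sol": e.dh_sol,
            }
            for e in config.exchanges
        ],
        "populations": [
            {
                "name": p.name,
                "biomass_species": p.biomass_species,
                "k_d": p.k_d,
                "anabolic": {
                    **_reaction_to_dict(p.anabolic.reaction),
                    "biomass": p.anabolic.biomass,
                    "electron_donor": p.anabolic.electron_donor,
                },
                "pathways": [
                    {
                        "name": pw.name,
                        **_reaction_to_dict(pw.reaction),
                        "v_max": pw.v_max,
                        "k_s": dict(pw.k_s),
                        "dg_min": pw.dg_min,
                        "dg_met": pw.dg_met,
                    }
                    for pw in p.pathways
                ],
            }
            for p in config.populations
        ],
        "initial": {
            "aqueous": dict(config.initial_aqueous),
            "gas": dict(config.initial_gas),
            "biomass": dict(config.initial_biomass)
            if config.initial_biomass is not None
            else None,
            "od600": config.initial_od,
            "fixed_ions": dict(config.fixed_ions),
        },
        "system": {
            "v_aq": config.geometry.v_aq,
            "v_gas": config.geometry.v_gas,
            "temperature": config.geometry.temperature,
            "duration": config.duration,
            "n_output": config.n_output,
            "floor": config.floor,
            "od_slope": config.od_calibration.slope,
            "od_intercept": config.od_calibration.intercept,
        },
        "solver": {
            "rtol": config.solver.rtol,
            "atol": config.solver.atol,
            "method": config.solver.method,
        },
    }


def config_from_dict(doc: Mapping) -> SimulationConfig:
    def need(section: str) -> Mapping:
        if section not in doc:
            raise ConfigurationError(f"config: missing section {section!r}")
        return doc[section]

    species = {
        name: _species_from_dict(name, d) for name, d in need("species").items()
    }
    eq = doc.get("equilibria", {})
    families = [
        AcidBaseFamily(f["name"], tuple(f["species"]), tuple(f["pks"]))
        for f in eq.get("families", [])
    ]
    exchanges = [
        PhaseExchangeSpec(
            aqueous=e["aqueous"],
            gas=e["gas"],
            kla=float(e.get("kla", 0.0)),
            h_ref=float(e["h_ref"]),
            dh_sol=float(e.get("dh_sol", 0.0)),
        )
        for e in doc.get("exchanges", [])
    ]
    populations = []
    for p in need("populations"):
        where = f"populations[{p.get('name', '?')}]"
        anab_d = p["anabolic"]
        anab = AnabolicReaction(
            reaction=_reaction_from_dict(anab_d, f"{where}.anabolic"),
            biomass=anab_d["biomass"],
            electron_donor=anab_d["electron_donor"],
        )
        pathways = tuple(
            CatabolicPathway(
                name=pw["name"],
                reaction=_reaction_from_dict(pw, f"{where}.pathways[{pw.get('name')}]"),
                v_max=float(pw["v_max"]),
                k_s={k: float(v) for k, v in pw.get("k_s", {}).items()},
                dg_min=float(pw["dg_min"]),
                dg_met=float(pw["dg_met"]),
            )
            for pw in p["pathways"]
        )
        populations.append(
            Population(
                name=p["name"],
                biomass_species=p["biomass_species"],
                pathways=pathways,
                anabolic=anab,
                k_d=float(p.get("k_d", 8.33e-4)),
            )
        )
    sysd = need("system")
    init = doc.get("initial", {})
    solver_d = doc.get("solver", {})
    return SimulationConfig(
        species=species,
        populations=populations,
        geometry=PhaseGeometry(
            v_aq=float(sysd["v_aq"]),
            v_gas=float(sysd["v_gas"]),
            temperature=float(sysd.get("temperature", 310.15)),
        ),
        families=families,
        exchanges=exchanges,
        fixed_ions={k: float(v) for k, v in init.get("fixed_ions", {}).items()},
        initial_aqueous={k: float(v) for k, v in init.get("aqueous", {}).items()},
        initial_gas={k: float(v) for k, v in init.get("gas", {}).items()},
        initial_biomass=(
            {k: float(v) for k, v in init["biomass"].items()}
            if init.get("biomass") is not None
            else None
        ),
        initial_od=init.get("od600"),
        pkw=float(eq.get("pkw", 14.0)),
        duration=float(sysd.get("duration", 504.0)),
        n_output=int(sysd.get("n_output", 253)),
        floor=float(sysd.get("floor", 1e-12)),
        od_calibration=ODCalibration(
            slope=float(sysd.get("od_slope", 5.12)),
            intercept=float(sysd.get("od_intercept", 4.987)),
        ),
        solver=SolverOptions(
            rtol=float(solver_d.get("rtol", 1e-6)),
            atol=float(solver_d.get("atol", 1e-12)),
            method=solver_d.get("method", "LSODA"),
        ),
    )


def dump_config(config: SimulationConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path: str) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"config file {path!r} is not a mapping")
    return config_from_dict(doc)
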