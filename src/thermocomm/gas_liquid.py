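"""Two-film gas/liquid transfer, Henry-law temperature adjustment and
k_La estimation from headspace equilibration time series.

Both phases are tracked in mol per litre of their own volume.  The driving
force of transfer is the departure of the dissolved concentration from the
Henry-equilibrium concentration implied by the current headspace content:

    d[A(aq)]/dt = -k_La * ([A(aq)] - C_eq)
    d[A(g)]/dt  = +k_La * (V_aq/V_g) * ([A(aq)] - C_eq)

with C_eq = H(T) * p and the partial pressure p obtained from the ideal-gas
relation on the headspace concentration; collapsing the unit conversions,
C_eq = H(T) * R * T * [A(g)] with H in mol m^-3 Pa^-1 and R in SI units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .constants import R_J, T_REF

__all__ = [
    "PhaseExchangeSpec",
    "PhaseGeometry",
    "henry_at_temperature",
    "equilibrium_aqueous_concentration",
    "transfer_derivatives",
    "integrate_transfer",
    "fit_kla",
    "KlaFitError",
]


class KlaFitError(RuntimeError):
    """The k_La objective carries no information (system already at
    equilibrium)."""


@dataclass(frozen=True)
class PhaseExchangeSpec:
    """One aqueous/gas species pair linked by mass transfer.

    ``h_ref`` is the Henry solubility at 298.15 K (mol m^-3 Pa^-1) and
    ``dh_sol`` the van 't Hoff temperature-dependence coefficient in K,
    positive by the standard solubility-compilation convention (solubility
    decreases with temperature).
    """

    aqueous: str
    gas: str
    kla: float = 0.0
    h_ref: float = 1.0
    dh_sol: float = 0.0

    def __post_init__(self) -> None:
        if self.kla < 0:
            raise ValueError(f"exchange {self.aqueous}/{self.gas}: k_La must be >= 0")
        if self.h_ref <= 0:
            raise ValueError(f"exchange {self.aqueous}/{self.gas}: H_ref must be > 0")


@dataclass(frozen=True)
class PhaseGeometry:
    """Liquid volume, headspace volume (L) and system temperature (K)."""

    v_aq: float
    v_gas: float
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.v_aq <= 0 or self.v_gas <= 0:
            raise ValueError("phase volumes must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def henry_at_temperature(spec: PhaseExchangeSpec, T: float) -> float:
    """Henry solubility at temperature ``T``:
    H(T) = H_ref * exp(dh_sol * (1/T - 1/T_ref))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return spec.h_ref * math.exp(spec.dh_sol * (1.0 / T - 1.0 / T_REF))


def equilibrium_aqueous_concentration(
    gas_conc: float, spec: PhaseExchangeSpec, T: float
) -> float:
    """Dissolved concentration in Henry equilibrium with the headspace,
    mol L^-1: C_eq = H(T) * R * T * [A(g)]."""
    return henry_at_temperature(spec, T) * R_J * T * gas_conc


def transfer_derivatives(
    aq_conc: float,
    gas_conc: float,
    spec: PhaseExchangeSpec,
    geom: PhaseGeometry,
) -> Tuple[float, float]:
    """(d[aq]/dt, d[gas]/dt) in mol L^-1 h^-1 of the respective phases.

    The pair conserves total moles identically:
    V_aq*d[aq]/dt + V_g*d[gas]/dt = 0.
    """
    c_eq = equilibrium_aqueous_concentration(gas_conc, spec, geom.temperature)
    drive = aq_conc - c_eq
    return -spec.kla * drive, spec.kla * (geom.v_aq / geom.v_gas) * drive


def integrate_transfer(
    spec: PhaseExchangeSpec,
    geom: PhaseGeometry,
    aq0: float,
    gas0: float,
    times: Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-14,
) -> np.ndarray:
    """Integrate pure transfer dynamics; returns an array of shape
    (len(times), 2) with columns [aq, gas]."""
    times = np.asarray(times, dtype=float)

    def rhs(_t, y):
        daq, dgas = transfer_derivatives(y[0], y[1], spec, geom)
        return [daq, dgas]

    t_span = (min(0.0, times.min()), times.max())
    sol = solve_ivp(
        rhs, t_span, [aq0, gas0], t_eval=times, rtol=rtol, atol=atol, method="LSODA"
    )
    if not sol.success:  # pragma: no cover - linear system, never expected
        raise RuntimeError(f"transfer integration failed: {sol.message}")
    return sol.y.T


def fit_kla(
    times: Sequence[float],
    observed_gas: Sequence[float],
    spec: PhaseExchangeSpec,
    geom: PhaseGeometry,
    aq0: float,
    gas0: float,
    bounds: Tuple[float, float] = (1e-4, 1e3),
) -> float:
    """Estimate k_La (h^-1) by least squares against a headspace
    equilibration series.

    Minimizes the sum of squared error between the integrated transfer
    dynamics and the observed gas-phase concentrations, by bounded scalar
    minimization of k_La on ``bounds``.
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed_gas, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 time points to estimate k_La")
    c_eq0 = equilibrium_aqueous_concentration(gas0, spec, geom.temperature)
    scale = max(abs(aq0), abs(gas0), 1e-30)
    if abs(aq0 - c_eq0) <= 1e-9 * scale:
        raise KlaFitError(
            "system starts at Henry equilibrium: the k_La objective is flat "
            "and the coefficient is unidentifiable"
        )

    def sse(kla: float) -> float:
        candidate = replace(spec, kla=float(kla))
        model = integrate_transfer(candidate, geom, aq0, gas0, times)[:, 1]
        return float(np.sum((model - observed) ** 2))

    # minimize on log10(kLa): the response spans seven decades
    res = minimize_scalar(
        lambda x: sse(10.0 ** x),
        bounds=(math.log10(bounds[0]), math.log10(bounds[1])),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(10.0 ** res.x)
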