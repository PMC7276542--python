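"""Acid-base speciation and pH from the charge balance of the solution.

State variables carried by the simulator are *family totals* (e.g. total
lactate = lactic acid + lactate anion) plus non-speciating free ions; the
free member concentrations entering free-energy evaluation are derived at
the current pH from the closed-form speciation ladder.  The pH itself is
the root of the net charge of the solution,

    Q(pH) = sum_families total * sum_i z_i f_i(pH)
          + sum_free z*c + [H+] - [OH-],

found by bracketed derivative-free root finding (Brent) on pH in [0, 14].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .chem import ChemSpecies, ConfigurationError

__all__ = [
    "AcidBaseFamily",
    "SolutionTotals",
    "speciation_fractions",
    "charge_imbalance",
    "solve_ph",
    "PhSolverError",
]

LN10 = np.log(10.0)


class PhSolverError(RuntimeError):
    """The charge balance has no root on the pH bracket (unphysical ion
    inventory)."""


@dataclass(frozen=True)
class AcidBaseFamily:
    """An ordered ladder of conjugate species, most protonated first,
    with one pK per deprotonation step (strictly increasing)."""

    name: str
    species: Tuple[str, ...]
    pks: Tuple[float, ...]
    charges: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.pks) != len(self.species) - 1:
            raise ConfigurationError(
                f"family {self.name!r}: need exactly one pK per deprotonation "
                f"step ({len(self.species)} species, {len(self.pks)} pKs)"
            )
        if any(b <= a for a, b in zip(self.pks, self.pks[1:])):
            raise ConfigurationError(
                f"family {self.name!r}: pK list must be strictly increasing"
            )
        if self.charges and len(self.charges) != len(self.species):
            raise ConfigurationError(
                f"family {self.name!r}: charges must match species"
            )

    def resolve_charges(self, species: Mapping[str, ChemSpecies]) -> "AcidBaseFamily":
        """Fill member charges from the species registry (each step removes
        one proton, so charges must decrease by 1 down the ladder)."""
        charges = []
        for name in self.species:
            sp = species.get(name)
            if sp is None:
                raise ConfigurationError(
                    f"family {self.name!r}: species {name!r} not declared"
                )
            if sp.phase != "aqueous":
                raise ConfigurationError(
                    f"family {self.name!r}: member {name!r} is not aqueous"
                )
            charges.append(sp.charge)
        return AcidBaseFamily(self.name, self.species, self.pks, tuple(charges))


def speciation_fractions(family: AcidBaseFamily, pH: float) -> np.ndarray:
    """Fraction of the family total held by each member at the given pH.

    Member ``i`` satisfies log10([A_i]/[A_0]) = i*pH - sum(pK_1..pK_i);
    fractions are normalized with max-subtraction for numerical safety.
    """
    n = len(family.species)
    idx = np.arange(n)
    cum = np.concatenate(([0.0], np.cumsum(family.pks)))
    logw = idx * pH - cum
    logw -= logw.max()
    w = 10.0 ** logw
    return w / w.sum()


@dataclass
class SolutionTotals:
    """Ion inventory of the solution: acid-base family totals, free ion
    concentrations (with their charges) and the water autoionization pK."""

    families: Sequence[AcidBaseFamily]
    totals: Mapping[str, float]
    free_ions: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    pkw: float = 14.0

    def __post_init__(self) -> None:
        for fam in self.families:
            if not fam.charges:
                raise ConfigurationError(
                    f"family {fam.name!r}: member charges unresolved; call "
                    "resolve_charges() against the species registry first"
                )
            if self.totals.get(fam.name, 0.0) < 0:
                raise ConfigurationError(f"negative total for family {fam.name!r}")


def charge_imbalance(totals: SolutionTotals, pH: float) -> float:
    """Net charge of the solution at a candidate pH, eq L^-1."""
    q = 10.0 ** (-pH) - 10.0 ** (pH - totals.pkw)
    for name, (charge, conc) in totals.free_ions.items():
        q += charge * conc
    for fam in totals.families:
        tot = totals.totals.get(fam.name, 0.0)
        if tot == 0.0:
            continue
        frac = speciation_fractions(fam, pH)
        q += tot * float(np.dot(frac, fam.charges))
    return q


def solve_ph(
    totals: SolutionTotals,
    bracket: Tuple[float, float] = (0.0, 14.0),
    tolerance: float = 1e-12,
) -> float:
    """pH at which the charge balance closes (|residual| < tolerance).

    Brent's method guarantees convergence on a sign-changing bracket; the
    tolerance applies to the charge residual, not to the pH itself.
    """
    lo, hi = bracket
    f_lo = charge_imbalance(totals, lo)
    f_hi = charge_imbalance(totals, hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise PhSolverError(
            "charge balance does not change sign on the pH bracket "
            f"[{lo}, {hi}]: residuals {f_lo:.3e} and {f_hi:.3e}; "
            "the declared ion inventory is unphysical"
        )
    ph = brentq(lambda x: charge_imbalance(totals, x), lo, hi, xtol=1e-14, rtol=1e-15)
    residual = charge_imbalance(totals, ph)
    if abs(residual) > tolerance:
        raise PhSolverError(
            f"pH root found at {ph:.6f} but charge residual {residual:.3e} "
            f"exceeds tolerance {tolerance:.1e}"
        )
    return float(ph)


class ChargeBalanceSolver:
    """Vectorized, warm-startable charge-balance solver used inside ODE
    derivative evaluations.

    Repeated derivative calls see nearly identical states, so a safeguarded
    Newton iteration seeded with the previous root converges in a handful
    of steps; it falls back to Brent on the full bracket whenever Newton
    misbehaves.  Results agree with :func:`solve_ph` (same residual
    equation, tighter-than-request convergence).
    """

    def __init__(self, families: Sequence[AcidBaseFamily], pkw: float = 14.0):
        self.families = list(families)
        self.pkw = pkw
        # per family: cumulative-pK array and member charges
        self._cum = [
            np.concatenate(([0.0], np.cumsum(f.pks))) for f in self.families
        ]
        self._idx = [np.arange(len(f.species), dtype=float) for f in self.families]
        self._z = [np.asarray(f.charges, dtype=float) for f in self.families]
        self._last_ph: float | None = None

    def residual_and_slope(
        self, pH: float, fam_totals: np.ndarray, fixed_charge: float
    ) -> Tuple[float, float]:
        h = 10.0 ** (-pH)
        oh = 10.0 ** (pH - self.pkw)
        q = fixed_charge + h - oh
        dq = -LN10 * h - LN10 * oh
        for tot, cum, idx, z in zip(fam_totals, self._cum, self._idx, self._z):
            if tot == 0.0:
                continue
            logw = idx * pH - cum
            logw -= logw.max()
            w = 10.0 ** logw
            s = w.sum()
            f = w / s
            zbar = float(np.dot(f, z))
            # d f_i/dpH = ln10 * f_i * (i - <i>)
            ibar = float(np.dot(f, idx))
            dzbar = LN10 * float(np.dot(f * (idx - ibar), z))
            q += tot * zbar
            dq += tot * dzbar
        return q, dq

    def solve(self, fam_totals: np.ndarray, fixed_charge: float) -> float:
        ph = self._last_ph if self._last_ph is not None else 7.0
        for _ in range(30):
            q, dq = self.residual_and_slope(ph, fam_totals, fixed_charge)
            if abs(q) < 1e-14 * max(1.0, abs(fixed_charge)):
                self._last_ph = ph
                return ph
            if dq == 0.0:
                break
            step = -q / dq
            if not np.isfinite(step) or abs(step) > 2.0:
                break
            ph_new = ph + step
            if ph_new < -2.0 or ph_new > 16.0:
                break
            if abs(step) < 1e-12:
                self._last_ph = ph_new
                return ph_new
            ph = ph_new
        # fall back to Brent on the full physical bracket
        f = lambda x: self.residual_and_slope(x, fam_totals, fixed_charge)[0]
        lo, hi = 0.0, 14.0
        f_lo, f_hi = f(lo), f(hi)
        if np.sign(f_lo) == np.sign(f_hi):
            raise PhSolverError(
                "charge balance does not change sign on [0, 14]: residuals "
                f"{f_lo:.3e}, {f_hi:.3e}"
            )
        ph = brentq(f, lo, hi, xtol=1e-12, rtol=1e-15)
        self._last_ph = float(ph)
        return self._last_ph

    def fractions(self, pH: float) -> Dict[str, float]:
        """Free-member fractions of every family at a given pH."""
        out: Dict[str, float] = {}
        for fam, cum, idx in zip(self.families, self._cum, self._idx):
            logw = idx * pH - cum
            logw -= logw.max()
            w = 10.0 ** logw
            f = w / w.sum()
            for name, fi in zip(fam.species, f):
                out[name] = float(fi)
        return out
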