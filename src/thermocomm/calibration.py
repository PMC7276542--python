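"""Hierarchical estimation of minimum-energy thresholds from time-series
observations, and one-dimensional error-landscape sweeps.

The calibratable parameters are the per-pathway dG_min values, addressed
as ``"<population>:<pathway>"``.  Parameters are treated hierarchically by
the *extent* (number of observed variables affected by perturbing the
parameter) and *scale* (largest normalized change induced) of their
effect: the parameter with the strongest effect on the fewest variables is
optimized first, against data re-weighted toward the variables it affects,
then fixed; the loop repeats until every parameter is fixed, and the whole
pass is restarted from jittered starts until it no longer improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .chem import ConfigurationError
from .simulator import (
    CompiledSystem,
    SimulationConfig,
    SimulationError,
    SolverOptions,
    Trajectory,
    simulate,
)

__all__ = [
    "ObservationSet",
    "CalibrationSpec",
    "CalibrationError",
    "ParameterEffect",
    "SweepResult",
    "weighted_sse",
    "parameter_effect",
    "hierarchical_calibrate",
    "sweep",
]

#: Solver settings used inside calibration loops: slightly coarser than the
#: simulation defaults, traded for the many repeated integrations.
CALIBRATION_SOLVER = SolverOptions(rtol=1e-5, atol=1e-10)

#: Floor on the per-variable standardization constant, mol L^-1.  A variable
#: whose observed maximum sits at (or below) instrument detection carries no
#: information; without the floor, standardizing by a near-zero maximum
#: amplifies integrator noise into the objective.
NORMALIZATION_FLOOR = 1e-6


class CalibrationError(RuntimeError):
    pass


@dataclass
class ObservationSet:
    """Observed time series in long form: columns time, variable, value
    and optionally replicate."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time", "variable", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigurationError(
                f"observation table lacks columns {sorted(missing)}"
            )
        if (self.frame["value"] < 0).any():
            bad = self.frame.loc[self.frame["value"] < 0, "variable"].unique()
            raise ConfigurationError(
                f"negative observed values for variables {list(bad)}"
            )

    @classmethod
    def from_series(
        cls, series: Mapping[str, Sequence[Tuple[float, float]]]
    ) -> "ObservationSet":
        rows = [
            {"time": t, "variable": var, "value": v}
            for var, pairs in series.items()
            for t, v in pairs
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str) -> "ObservationSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)

    def variables(self) -> List[str]:
        return list(dict.fromkeys(self.frame["variable"]))

    def series(self, variable: str) -> Tuple[np.ndarray, np.ndarray]:
        sub = self.frame[self.frame["variable"] == variable]
        return sub["time"].to_numpy(float), sub["value"].to_numpy(float)

    def observed_max(self, variable: str) -> float:
        _, v = self.series(variable)
        return float(np.max(np.abs(v))) if v.size else 0.0


@dataclass
class CalibrationSpec:
    """Settings of the hierarchical calibration.

    ``parameters`` lists dG_min entries by name; the bounds deliberately
    exclude 0 (a vanishing threshold is biologically infeasible: it would
    mean no catabolic energy is ever stored as driving force)."""

    parameters: List[str]
    bounds: Tuple[float, float] = (-60.0, -1.0)
    start: float = -40.0
    perturbation: float = 5.0
    effect_threshold: float = 0.01
    tolerance: float = 1e-4
    max_outer: int = 3
    jitter: float = 3.0
    seed: int = 0
    solver: SolverOptions = field(default_factory=lambda: CALIBRATION_SOLVER)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (lo < hi <= 0) or hi == 0:
            raise ConfigurationError(
                "dG_min bounds must be negative (0 is biologically infeasible)"
            )
        if not self.parameters:
            raise ConfigurationError("no parameters to calibrate")


def weighted_sse(
    trajectory: Trajectory,
    observations: ObservationSet,
    weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Weighted sum of squared model-observation distances.

    Each variable is standardized by its own observed maximum before
    squaring, so that millimolar metabolites and headspace gas contents
    contribute on a common scale; ``weights`` (default: 1 per variable)
    multiply each variable's standardized SSE.
    """
    total = 0.0
    for var in observations.variables():
        w = 1.0 if weights is None else weights.get(var, 0.0)
        if w == 0.0:
            continue
        if var not in trajectory.frame.columns:
            raise ConfigurationError(
                f"observed variable {var!r} is not among the model outputs"
            )
        t_obs, v_obs = observations.series(var)
        if t_obs.size == 0:
            continue
        if t_obs.max() > trajectory.times.max() + 1e-9:
            raise ConfigurationError(
                f"observations of {var!r} extend beyond the simulated horizon"
            )
        model = trajectory.interpolate(var, t_obs)
        norm = max(observations.observed_max(var), NORMALIZATION_FLOOR)
        total += w * float(np.sum(((model - v_obs) / norm) ** 2))
    return total


@dataclass
class ParameterEffect:
    """Extent (variables affected) and scale (max normalized change) of a
    parameter perturbation, with the per-variable sensitivities."""

    parameter: str
    extent: int
    scale: float
    per_variable: Dict[str, float]
    failed: bool = False


def _simulate_for(
    config: SimulationConfig,
    values: Mapping[str, float],
    solver: SolverOptions,
) -> Trajectory:
    cfg = config.with_dg_min(dict(values))
    return simulate(cfg, solver=solver)


def parameter_effect(
    parameter: str,
    config: SimulationConfig,
    observations: ObservationSet,
    values: Optional[Mapping[str, float]] = None,
    perturbation: float = 5.0,
    effect_threshold: float = 0.01,
    bounds: Tuple[float, float] = (-60.0, -1.0),
    solver: SolverOptions = CALIBRATION_SOLVER,
    baseline: Optional[Trajectory] = None,
) -> ParameterEffect:
    """Perturb one dG_min by +-``perturbation`` kJ/mol, re-simulate, and
    report how many observed variables move beyond the threshold.

    Changes are normalized per variable by the baseline trajectory's own
    maximum, so the threshold reads as a relative change.
    """
    values = dict(values or {})
    current = values.get(parameter)
    if current is None:
        current = _lookup_dg_min(config, parameter)
    if baseline is None:
        baseline = _simulate_for(config, values, solver)
    per_var: Dict[str, float] = {v: 0.0 for v in observations.variables()}
    failed = False
    for sign in (+1.0, -1.0):
        cand = float(np.clip(current + sign * perturbation, *bounds))
        if cand == current:
            continue
        try:
            traj = _simulate_for(config, {**values, parameter: cand}, solver)
        except SimulationError:
            failed = True
            continue
        for var in per_var:
            if var not in baseline.frame.columns:
                raise ConfigurationError(
                    f"observed variable {var!r} is not among the model outputs"
                )
            base = baseline.series(var)
            norm = max(
                float(np.max(np.abs(base))),
                observations.observed_max(var),
                NORMALIZATION_FLOOR,
            )
            delta = float(
                np.max(np.abs(traj.interpolate(var, baseline.times) - base))
            )
            per_var[var] = max(per_var[var], delta / norm)
    affected = {v: s for v, s in per_var.items() if s > effect_threshold}
    scale = max(per_var.values()) if per_var else 0.0
    return ParameterEffect(
        parameter=parameter,
        extent=len(affected),
        scale=scale,
        per_variable=per_var,
        failed=failed,
    )


def _lookup_dg_min(config: SimulationConfig, parameter: str) -> float:
    for pop in config.populations:
        for pw in pop.pathways:
            if f"{pop.name}:{pw.name}" == parameter:
                return pw.dg_min
    raise ConfigurationError(f"unknown dG_min parameter {parameter!r}")


@dataclass
class CalibrationResult:
    values: Dict[str, float]
    sse: float
    trace: List[dict]
    uncalibrated: List[str] = field(default_factory=list)


def hierarchical_calibrate(
    spec: CalibrationSpec,
    config: SimulationConfig,
    observations: ObservationSet,
) -> CalibrationResult:
    """Fit the requested dG_min parameters hierarchically.

    Ranking: fewest affected variables first, ties broken by larger effect
    scale, then by declaration order.  The single selected parameter is
    optimized by bounded truncated-Newton minimization of the weighted SSE
    with variable weights proportional to that parameter's per-variable
    sensitivity, then fixed.  The full pass restarts from seeded jittered
    starts until the outer improvement drops below ``spec.tolerance``.
    """
    if not observations.variables():
        raise CalibrationError("no observed variables provided")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.bounds
    decl_order = {p: i for i, p in enumerate(spec.parameters)}

    best_values: Optional[Dict[str, float]] = None
    best_sse = np.inf
    trace: List[dict] = []
    uncalibrated: List[str] = []

    for outer in range(spec.max_outer):
        if outer == 0 or best_values is None:
            current = {p: float(np.clip(spec.start, lo, hi)) for p in spec.parameters}
        else:
            current = {
                p: float(np.clip(best_values[p] + rng.normal(0.0, spec.jitter), lo, hi))
                for p in spec.parameters
            }
        remaining = list(spec.parameters)
        pass_uncal: List[str] = []
        while remaining:
            baseline = _simulate_for(config, current, spec.solver)
            effects = {
                p: parameter_effect(
                    p,
                    config,
                    observations,
                    values=current,
                    perturbation=spec.perturbation,
                    effect_threshold=spec.effect_threshold,
                    bounds=spec.bounds,
                    solver=spec.solver,
                    baseline=baseline,
                )
                for p in remaining
            }
            identifiable = [p for p in remaining if effects[p].extent >= 1]
            if not identifiable:
                if outer == 0 and len(remaining) == len(spec.parameters):
                    raise CalibrationError(
                        "all parameters have zero extent: unidentifiable under "
                        "the provided observations"
                    )
                pass_uncal.extend(remaining)
                break
            identifiable.sort(
                key=lambda p: (
                    effects[p].extent,
                    -effects[p].scale,
                    decl_order[p],
                )
            )
            chosen = identifiable[0]
            sens = effects[chosen].per_variable
            s_total = sum(sens.values())
            weights = (
                {v: s / s_total for v, s in sens.items()}
                if s_total > 0
                else {v: 1.0 for v in sens}
            )

            def objective(x: np.ndarray) -> float:
                try:
                    traj = _simulate_for(
                        config, {**current, chosen: float(x[0])}, spec.solver
                    )
                except SimulationError:
                    return 1e6
                return weighted_sse(traj, observations, weights)

            res = minimize(
                objective,
                x0=[current[chosen]],
                method="TNC",
                bounds=[(lo, hi)],
                options={"maxfun": 60, "eps": 0.05, "xtol": 1e-3},
            )
            current[chosen] = float(res.x[0])
            trace.append(
                {
                    "outer": outer,
                    "parameter": chosen,
                    "extent": effects[chosen].extent,
                    "scale": effects[chosen].scale,
                    "weights": weights,
                    "fitted": current[chosen],
                    "objective": float(res.fun),
                }
            )
            remaining.remove(chosen)

        final = weighted_sse(
            _simulate_for(config, current, spec.solver), observations
        )
        improvement = best_sse - final
        if final < best_sse:
            best_sse = final
            best_values = dict(current)
            uncalibrated = pass_uncal
        if outer > 0 and improvement < spec.tolerance:
            break

    assert best_values is not None
    return CalibrationResult(
        values=best_values, sse=best_sse, trace=trace, uncalibrated=uncalibrated
    )


@dataclass
class SweepResult:
    """Error landscapes along one parameter's grid, each curve normalized
    by its own maximum."""

    parameter: str
    grid: np.ndarray
    per_variable: Dict[str, np.ndarray]
    per_subset: Dict[Tuple[str, ...], np.ndarray] = field(default_factory=dict)

    def minimum(self, variable: str) -> float:
        curve = self.per_variable[variable]
        return float(self.grid[np.nanargmin(curve)])


def sweep(
    parameter: str,
    grid: Sequence[float],
    config: SimulationConfig,
    observations: ObservationSet,
    subsets: Optional[Sequence[Sequence[str]]] = None,
    values: Optional[Mapping[str, float]] = None,
    solver: SolverOptions = CALIBRATION_SOLVER,
) -> SweepResult:
    """Simulate along a grid of one dG_min (others fixed) and record the
    standardized per-variable error curves; simulation failures become
    missing points rather than aborts."""
    grid = np.asarray(list(grid), dtype=float)
    variables = observations.variables()
    raw = {v: np.full(grid.shape, np.nan) for v in variables}
    for i, g in enumerate(grid):
        try:
            traj = _simulate_for(config, {**dict(values or {}), parameter: g}, solver)
        except SimulationError:
            continue
        for v in variables:
            raw[v][i] = weighted_sse(traj, observations, weights={v: 1.0})

    def normalize(curve: np.ndarray) -> np.ndarray:
        m = np.nanmax(curve)
        return curve / m if m and np.isfinite(m) and m > 0 else curve

    per_variable = {v: normalize(c) for v, c in raw.items()}
    per_subset: Dict[Tuple[str, ...], np.ndarray] = {}
    for sub in subsets or []:
        combined = np.sum([raw[v] for v in sub], axis=0)
        per_subset[tuple(sub)] = normalize(combined)
    return SweepResult(
        parameter=parameter, grid=grid, per_variable=per_variable, per_subset=per_subset
    )
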