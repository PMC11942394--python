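"""Fitting model parameters to observed front trajectories.

The forward model maps a parameter set through the solver and front tracker
to front-radius-versus-time curves; the objective is the summed squared
radius mismatch across all observed trajectories (simulated radii linearly
interpolated to the observed times; once the simulated front has vanished
its radius counts as zero).  Optimisation works in log-parameter space —
every trial parameter stays positive and the order-of-magnitude scales of
the eight constants are treated evenly — with a damped least-squares descent
by default and a derivative-free simplex alternative.

Joint recovery of all eight parameters from front radii alone is not
expected to be identifiable; recovery is exercised for small subsets (e.g.
the primary attachment rate together with the barium diffusivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize

from .errors import ContractError, SolverError
from .front_analysis import FrontTrajectory, build_trajectory
from .kinetics import ModelParameters
from .scenarios import Scenario
from .solver import SolverOptions, integrate

__all__ = [
    "CalibrationResult",
    "trajectory_objective",
    "fit_parameters",
    "COARSE_SOLVER_OPTIONS",
]

PARAMETER_NAMES = tuple(f.name for f in dataclass_fields(ModelParameters))

#: Reduced-accuracy settings used inside optimisation loops; final results
#: should be re-evaluated at production settings.
COARSE_SOLVER_OPTIONS = SolverOptions(rtol=1e-5, atol=1e-10)


@dataclass
class CalibrationResult:
    """Outcome of a parameter fit."""

    params: ModelParameters
    objective: float  # SSE, mm^2
    initial_objective: float
    iterations: int
    nfev: int
    converged: bool
    free_params: Tuple[str, ...]
    residuals: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective < 0.0:
            raise ContractError("CalibrationResult.objective must be >= 0")


def _simulated_radius_at(
    sim_traj: FrontTrajectory, times: np.ndarray
) -> np.ndarray:
    """Simulated front radius interpolated to observation times.

    Beyond the simulated gelation time (or wherever the simulated front is
    missing) the radius is taken as zero, so an already-gelled simulation is
    penalised by the full observed radius.
    """
    t, r = sim_traj.valid_points()
    if t.size == 0:
        return np.zeros_like(times)
    out = np.interp(times, t, r, left=r[0], right=0.0)
    if sim_traj.gelation_time is not None:
        out = np.where(times >= sim_traj.gelation_time, 0.0, out)
    return out


def trajectory_objective(
    p: ModelParameters,
    observed: Sequence[Tuple[Scenario, FrontTrajectory]],
    options: Optional[SolverOptions] = None,
    *,
    return_residuals: bool = False,
):
    """Summed squared front-radius mismatch (mm^2) across all observations."""
    if len(observed) == 0:
        raise ContractError("trajectory_objective: observed set is empty")
    options = options or COARSE_SOLVER_OPTIONS
    sse = 0.0
    residuals: Dict[str, np.ndarray] = {}
    for scenario, obs in observed:
        t_obs, r_obs = obs.valid_points()
        if t_obs.size < 5:
            raise ContractError(
                f"trajectory_objective: trajectory {scenario.label!r} has "
                f"fewer than 5 points"
            )
        try:
            result = integrate(scenario, p, options)
        except SolverError as exc:
            raise SolverError(
                f"forward simulation failed for {scenario.label!r} with "
                f"parameters {p}: {exc}",
                last_time=exc.last_time,
            ) from exc
        sim = build_trajectory(result, p, fit_velocities=False)
        r_sim = _simulated_radius_at(sim, t_obs)
        res = r_sim - r_obs
        residuals[scenario.label] = res
        sse += float(res @ res)
    if return_residuals:
        return sse, residuals
    return sse


def fit_parameters(
    observed: Sequence[Tuple[Scenario, FrontTrajectory]],
    free_params: Sequence[str],
    init: Optional[ModelParameters] = None,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
    *,
    options: Optional[SolverOptions] = None,
    method: str = "gauss-newton",
    maxiter: int = 120,
    xatol: float = 0.01,
    fatol_rel: float = 1e-4,
) -> CalibrationResult:
    """Descent over the chosen parameters in log space.

    ``method='gauss-newton'`` (default) runs a damped trust-region
    least-squares fit on the stacked front-radius residuals; it handles the
    strong correlation between rate and transport parameters in a few dozen
    forward evaluations.  ``method='simplex'`` is a derivative-free
    Nelder-Mead alternative (markedly slower along correlated valleys; kept
    for non-smooth objectives).

    Deterministic given ``init`` (the seed only matters for optional restart
    jitter, unused by default).  The returned objective never exceeds the
    initial one.  ``bounds`` are enforced by projection inside the objective.
    """
    free = tuple(free_params)
    if len(free) == 0:
        raise ContractError("fit_parameters: free_params must be non-empty")
    for name in free:
        if name not in PARAMETER_NAMES:
            raise ContractError(
                f"fit_parameters: unknown parameter {name!r}; "
                f"valid names: {PARAMETER_NAMES}"
            )
    init = init or ModelParameters.default()
    if bounds:
        for name, (lo, hi) in bounds.items():
            if lo <= 0.0 or hi <= lo:
                raise ContractError(
                    f"fit_parameters: bounds for {name!r} must satisfy "
                    "0 < lo < hi"
                )
    options = options or COARSE_SOLVER_OPTIONS

    x0 = np.log([getattr(init, name) for name in free])

    def build(x: np.ndarray) -> ModelParameters:
        vals = np.exp(x)
        if bounds:
            for j, name in enumerate(free):
                if name in bounds:
                    vals[j] = float(np.clip(vals[j], *bounds[name]))
        return init.with_updates(**dict(zip(free, vals)))

    if method not in ("gauss-newton", "simplex"):
        raise ContractError(
            f"fit_parameters: unknown method {method!r}; expected "
            "'gauss-newton' or 'simplex'"
        )

    eval_count = 0

    def residual_vector(x: np.ndarray) -> np.ndarray:
        nonlocal eval_count
        eval_count += 1
        _, res = trajectory_objective(
            build(x), observed, options, return_residuals=True
        )
        return np.concatenate(list(res.values()))

    def objective(x: np.ndarray) -> float:
        nonlocal eval_count
        eval_count += 1
        try:
            return trajectory_objective(build(x), observed, options)
        except (SolverError, ContractError):
            return 1e12  # infeasible trial point

    f0 = objective(x0)
    if not math.isfinite(f0) or f0 >= 1e12:
        raise ContractError(
            "fit_parameters: objective non-finite at the initial parameters"
        )

    if method == "gauss-newton":
        sol = least_squares(
            residual_vector,
            x0,
            diff_step=0.05,
            xtol=xatol * 1e-2,
            ftol=fatol_rel * 1e-2,
            gtol=1e-12,
            max_nfev=maxiter,
        )
        x_best, f_best = sol.x, float(2.0 * sol.cost)
        nit = int(sol.nfev)
        success = bool(sol.success)
    else:
        sol = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": xatol,
                "fatol": max(fatol_rel * f0, 1e-12),
                "initial_simplex": _initial_simplex(x0, step=0.35),
                "adaptive": False,
            },
        )
        x_best, f_best = sol.x, float(sol.fun)
        nit = int(sol.nit)
        success = bool(sol.success)

    if f_best > f0:  # never report worse than the start
        x_best, f_best = x0, f0
    p_best = build(x_best)
    f_final, residuals = trajectory_objective(
        p_best, observed, options, return_residuals=True
    )
    return CalibrationResult(
        params=p_best,
        objective=min(f_best, f_final),
        initial_objective=f0,
        iterations=nit,
        nfev=eval_count,
        converged=success,
        free_params=free,
        residuals=residuals,
    )


def _initial_simplex(x0: np.ndarray, step: float) -> np.ndarray:
    """Regular initial simplex around x0 in log space."""
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for j in range(n):
        simplex[j + 1, j] += step
    return simplex
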