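"""Extraction and quantification of the travelling gelation front.

The experimental observable is a bright ring where the cross-linking reaction
is most intense, shrinking from the rim towards the centre.  Its simulated
counterpart is the radius of maximum instantaneous cross-link production.
The trajectory of that radius is segmented into the characteristic two linear
phases (fast early, slower late) by a continuous one-breakpoint piecewise
least-squares fit, and the run's total gelation time is the first instant the
front reaches the core (radius <= 2 % of R0) or dissipates (peak production
below 1 % of the run's historical maximum, measured after the front detaches
from the rim so the initial boundary transient does not dominate).
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ContractError
from .kinetics import ModelParameters, _raw_rates
from .solver import FieldState, SimulationResult

__all__ = [
    "FrontTrajectory",
    "VelocityFit",
    "production_profile",
    "extract_front_radius",
    "build_trajectory",
    "segment_and_fit_velocities",
]

#: Front has "reached the core" below this fraction of the initial radius.
CORE_FRACTION = 0.02
#: Front has "dissipated" below this fraction of the historical peak production.
DISSIPATION_FRACTION = 0.01
#: Fraction of R0 inside which the front counts as detached from the rim
#: (the historical production maximum is taken over detached states only).
DETACH_FRACTION = 0.95

_MIN_POINTS_FOR_FIT = 8


@dataclass
class VelocityFit:
    """Two-phase piecewise-linear fit of a front trajectory."""

    breakpoint_s: Optional[float]
    v_early_mm_s: float
    v_late_mm_s: float
    sse: float
    degenerate: bool = False  # single line fits (near-)equally well


@dataclass
class FrontTrajectory:
    """Front radius versus time, with derived phase velocities."""

    times: np.ndarray  # s
    front_radius: np.ndarray  # mm; NaN where no front was found
    R0: float  # mm
    gelation_time: Optional[float] = None  # s; None if not reached
    fit: Optional[VelocityFit] = None

    @property
    def front_diameter(self) -> np.ndarray:
        return 2.0 * self.front_radius

    @property
    def breakpoint_s(self) -> Optional[float]:
        return self.fit.breakpoint_s if self.fit else None

    @property
    def v_early(self) -> Optional[float]:
        return self.fit.v_early_mm_s if self.fit else None

    @property
    def v_late(self) -> Optional[float]:
        return self.fit.v_late_mm_s if self.fit else None

    def valid_points(self) -> Tuple[np.ndarray, np.ndarray]:
        """Times and radii where a front was detected."""
        ok = np.isfinite(self.front_radius)
        return self.times[ok], self.front_radius[ok]


def _refine_peak(radii: np.ndarray, values: np.ndarray, idx: int) -> float:
    """Sub-grid peak location by parabolic interpolation through the three
    nodes around ``idx`` (handles non-uniform spacing); falls back to the
    node radius at the domain ends or for degenerate curvature."""
    if idx <= 0 or idx >= len(radii) - 1:
        return float(radii[idx])
    x0, x1, x2 = radii[idx - 1], radii[idx], radii[idx + 1]
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    d0 = (y1 - y0) / (x1 - x0)
    d1 = (y2 - y1) / (x2 - x1)
    curv = (d1 - d0) / (x2 - x0)
    if curv >= 0.0:
        return float(x1)
    # vertex of the Newton-form interpolating parabola
    vertex = 0.5 * (x0 + x1) - d0 / (2.0 * curv)
    lo, hi = 0.5 * (x0 + x1), 0.5 * (x1 + x2)
    return float(min(max(vertex, lo), hi))


def production_profile(state: FieldState, p: ModelParameters) -> np.ndarray:
    """Per-node instantaneous cross-link production rate (>= 0).

    This is the source term of the cross-linked phase: brighter regions in
    the experimental images correspond to larger values here.
    """
    state.validate()
    return _raw_rates(
        state.rho_poly, state.rho_ba, state.rho_cross, state.kappa, p
    )[2]


def extract_front_radius(
    state: FieldState,
    p: ModelParameters,
    radii: np.ndarray,
    historical_max: Optional[float] = None,
) -> Optional[float]:
    """Radius of peak cross-link production, or None when no front exists.

    Ties between equal peaks break towards the outermost radius (the front
    travels inward, so the outer peak is the advancing interface).  When
    ``historical_max`` is given, a peak below ``DISSIPATION_FRACTION`` of it
    counts as dissipated.
    """
    prod = production_profile(state, p)
    peak = float(prod.max())
    if peak <= 0.0:
        return None
    if historical_max is not None and peak < DISSIPATION_FRACTION * historical_max:
        return None
    # outermost argmax (scan the reversed array), refined to sub-grid
    # accuracy so the radius varies smoothly under parameter changes
    idx = len(prod) - 1 - int(np.argmax(prod[::-1]))
    return _refine_peak(np.asarray(radii, dtype=float), prod, idx)


def build_trajectory(
    result: SimulationResult,
    p: Optional[ModelParameters] = None,
    *,
    fit_velocities: bool = True,
) -> FrontTrajectory:
    """Track the front through a simulation and derive its kinetics.

    Gelation time is the first output time at which the front radius is at
    most 2 % of R0 or the front has dissipated; detections after that instant
    are reported as NaN.
    """
    p = p or result.params
    n_states = len(result)
    if n_states < 5:
        raise ContractError(
            f"build_trajectory: need >= 5 states, got {n_states}"
        )
    radii_grid = result.grid.r
    R0 = result.grid.R
    prod = _raw_rates(
        result.rho_poly, result.rho_ba, result.rho_cross, result.kappa, p
    )[2]
    peaks = prod.max(axis=1)
    # outermost argmax per state, refined to sub-grid accuracy
    rev_idx = prod.shape[1] - 1 - np.argmax(prod[:, ::-1], axis=1)
    radii = np.array([
        _refine_peak(radii_grid, prod[i], int(rev_idx[i]))
        for i in range(n_states)
    ])
    radii = np.where(peaks > 0.0, radii, np.nan)

    # historical production maximum once the front has left the rim: the
    # boundary-reaction transient at t=0 is orders of magnitude stronger
    # than the travelling front and must not define the dissipation scale
    detached = peaks[np.isfinite(radii) & (radii <= DETACH_FRACTION * R0)]
    hist_max = float(detached.max()) if detached.size else float(peaks.max())

    dissipated = peaks < DISSIPATION_FRACTION * hist_max
    at_core = np.isfinite(radii) & (radii <= CORE_FRACTION * R0)
    gelled = dissipated | at_core

    # gelation must persist for two consecutive outputs: during the initial
    # ingress transient (before a coherent front forms) the argmax can
    # transiently visit the core, which is not the end of the run
    gel_time: Optional[float] = None
    front = np.array(radii, dtype=float)
    for i in range(1, n_states):
        if gelled[i] and (i == n_states - 1 or gelled[i + 1]):
            gel_time = float(result.times[i])
            front[i:] = np.nan
            break
        if dissipated[i]:
            front[i] = np.nan  # momentary dropout, keep tracking

    traj = FrontTrajectory(
        times=np.asarray(result.times, dtype=float),
        front_radius=front,
        R0=R0,
        gelation_time=gel_time,
    )
    if fit_velocities:
        t, r = traj.valid_points()
        if t.size >= _MIN_POINTS_FOR_FIT:
            traj.fit = segment_and_fit_velocities(traj)
    return traj


def _two_segment_fit(
    t: np.ndarray, r: np.ndarray, t_break: float
) -> Tuple[float, np.ndarray]:
    """Continuous two-segment OLS with a fixed breakpoint.

    Basis: intercept, t, hinge max(t - t_break, 0).  Returns (SSE, coeffs).
    """
    X = np.column_stack(
        [np.ones_like(t), t, np.maximum(t - t_break, 0.0)]
    )
    coef, _, _, _ = np.linalg.lstsq(X, r, rcond=None)
    resid = r - X @ coef
    return float(resid @ resid), coef


def segment_and_fit_velocities(traj: FrontTrajectory) -> VelocityFit:
    """Fit the two-phase front kinetics by exhaustive breakpoint search.

    Every interior observation time is tried as the breakpoint of a
    continuous two-segment least-squares line; the SSE-minimising fit wins.
    Slopes are reported with the inward-travel sign convention (negative).
    A trajectory that a single line explains essentially as well is flagged
    ``degenerate`` and both phase velocities equal the global slope.
    """
    t, r = traj.valid_points()
    if t.size < _MIN_POINTS_FOR_FIT:
        raise ContractError(
            f"segment_and_fit_velocities: need >= {_MIN_POINTS_FOR_FIT} "
            f"detected points, got {t.size}"
        )
    if np.ptp(r) == 0.0:
        return VelocityFit(
            breakpoint_s=None, v_early_mm_s=0.0, v_late_mm_s=0.0,
            sse=0.0, degenerate=True,
        )

    # single-line reference
    X1 = np.column_stack([np.ones_like(t), t])
    coef1, _, _, _ = np.linalg.lstsq(X1, r, rcond=None)
    resid1 = r - X1 @ coef1
    sse1 = float(resid1 @ resid1)

    best: Optional[Tuple[float, np.ndarray, float]] = None
    # leave >= 3 points on each side so both slopes are well determined
    for tb in t[2:-3]:
        sse, coef = _two_segment_fit(t, r, float(tb))
        if best is None or sse < best[0]:
            best = (sse, coef, float(tb))
    assert best is not None
    sse2, coef, t_break = best

    scale = max(sse1, float(r @ r), 1e-300)
    if sse1 - sse2 <= 1e-8 * scale:
        # a single line explains the data: breakpoint unidentifiable
        return VelocityFit(
            breakpoint_s=None,
            v_early_mm_s=float(coef1[1]),
            v_late_mm_s=float(coef1[1]),
            sse=sse1,
            degenerate=True,
        )
    return VelocityFit(
        breakpoint_s=t_break,
        v_early_mm_s=float(coef[1]),
        v_late_mm_s=float(coef[1] + coef[2]),
        sse=sse2,
    )
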