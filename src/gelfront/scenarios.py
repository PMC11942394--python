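"""Simulation setups for disc- and sphere-shaped alginate bodies.

Unit convention (the single place it is defined)
------------------------------------------------
* length: millimetres; time: seconds.
* barium density: a 10 mM BaCl2 bath maps to 1.0 model units, so the three
  standard baths 10/20/40 mM map to 1.0/2.0/4.0.
* polymer density: the initial alginate solution (a 1:1 mix of two
  0.65 % w/v solutions, i.e. 0.65 % w/v total) maps to 1.0; cross-linked
  polymer is expressed in the same unit.

The bath is treated as an unlimited reservoir: barium is held at the bath
value on the outer boundary for the whole run (Dirichlet), while polymer sees
a zero-flux outer boundary (the gelled rim traps it).  The disc's thin
vertical dimension is ignored; transport is radial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ContractError
from .kinetics import ModelParameters
from .solver import FieldState, Grid1D

__all__ = [
    "UnitSystem",
    "Scenario",
    "make_disc_scenario",
    "make_sphere_scenario",
    "to_model_units",
    "from_model_units",
]

#: Default disc droplet volume (uL) and chamber height (um).
DISC_VOLUME_UL = 4.0
DISC_HEIGHT_UM = 200.0

#: Sphere diameters outside this range (um) are rejected as implausible.
SPHERE_DIAMETER_RANGE_UM = (500.0, 3000.0)

#: Default node count for production grids.
DEFAULT_NODES = 600


@dataclass(frozen=True)
class UnitSystem:
    """Linear physical <-> model unit conversions.

    ``ba_ref_mM`` is the bath concentration mapping to barium density 1.0;
    ``poly_ref_percent_wv`` is the alginate concentration mapping to polymer
    density 1.0.
    """

    ba_ref_mM: float = 10.0
    poly_ref_percent_wv: float = 0.65

    # unit -> (scale to model, model quantity name)
    def _factor(self, unit: str) -> float:
        factors = {
            "mM": 1.0 / self.ba_ref_mM,
            "%w/v": 1.0 / self.poly_ref_percent_wv,
            "mm": 1.0,
            "um": 1e-3,
            "µm": 1e-3,
            "s": 1.0,
            "min": 60.0,
        }
        try:
            return factors[unit]
        except KeyError:
            raise ContractError(
                f"unknown unit {unit!r}; expected one of {sorted(factors)}"
            ) from None

    def to_model(self, value: float, unit: str) -> float:
        return value * self._factor(unit)

    def from_model(self, value: float, unit: str) -> float:
        return value / self._factor(unit)


_DEFAULT_UNITS = UnitSystem()


def to_model_units(value: float, unit: str, units: UnitSystem = _DEFAULT_UNITS) -> float:
    """Convert a physical value (mM, %w/v, mm, um, s, min) to model units."""
    return units.to_model(value, unit)


def from_model_units(value: float, unit: str, units: UnitSystem = _DEFAULT_UNITS) -> float:
    """Inverse of :func:`to_model_units`."""
    return units.from_model(value, unit)


@dataclass
class Scenario:
    """A complete simulation setup."""

    grid: Grid1D
    initial_state: FieldState
    bath_ba: float  # model units, Dirichlet value at the outer boundary
    horizon: float  # s
    output_cadence: float  # s
    label: str = ""
    bath_mM: Optional[float] = None

    def __post_init__(self) -> None:
        if self.horizon <= 0.0 or self.output_cadence <= 0.0:
            raise ContractError(
                "Scenario: horizon and output_cadence must be > 0"
            )
        if self.bath_ba <= 0.0:
            raise ContractError("Scenario.bath_ba must be > 0")
        s0 = self.initial_state
        if np.any(s0.kappa != 0.0) or np.any(s0.rho_cross != 0.0):
            raise ContractError(
                "Scenario: initial kappa and rho_cross must be 0 everywhere"
            )
        if np.any(s0.rho_ba[:-1] != 0.0):
            raise ContractError(
                "Scenario: initial rho_ba must be 0 inside the body"
            )

    @property
    def R0(self) -> float:
        """Initial body radius (mm)."""
        return self.grid.R

    def output_times(self) -> np.ndarray:
        t = np.arange(0.0, self.horizon + 0.5 * self.output_cadence,
                      self.output_cadence)
        return t[t <= self.horizon]


def _initial_state(grid: Grid1D, bath_ba: float, rho_poly0: float) -> FieldState:
    n = grid.n
    rho_ba = np.zeros(n)
    rho_ba[-1] = bath_ba  # boundary node carries the Dirichlet value
    return FieldState(
        time=0.0,
        rho_poly=np.full(n, rho_poly0),
        rho_ba=rho_ba,
        rho_cross=np.zeros(n),
        kappa=np.zeros(n),
    )


def _default_horizon(
    bath_mM: float, R0_mm: float, p: ModelParameters, symmetry: int
) -> float:
    """Heuristic horizon long enough for the front to reach the core.

    Calibrated against full reference-parameter runs: gelation time scales
    with R0^2 (barium transport through the hindered shell), decreases
    roughly as bath^(2/3), and spheres gel ~1.9x faster than discs of equal
    radius (more boundary per volume).  A 1.7x headroom factor is applied.
    For strongly non-default parameters pass ``horizon_s`` explicitly.
    """
    base = 20200.0  # s/mm^2, disc at the 10 mM reference bath
    geom = {0: 0.5, 1: 1.0, 2: 1.9}[symmetry]
    # rescale if transport or hindrance deviates from the reference set
    ref = ModelParameters.default()
    transport = (p.D0_ba * np.exp(-p.K_ba * 1.5)) / (
        ref.D0_ba * np.exp(-ref.K_ba * 1.5)
    )
    est = base * R0_mm**2 / (geom * (bath_mM / 10.0) ** (2.0 / 3.0) * transport)
    return 1.7 * est


def make_disc_scenario(
    bath_mM: float,
    p: Optional[ModelParameters] = None,
    *,
    volume_uL: float = DISC_VOLUME_UL,
    height_um: float = DISC_HEIGHT_UM,
    n_nodes: int = DEFAULT_NODES,
    horizon_s: Optional[float] = None,
    output_cadence_s: Optional[float] = None,
    units: UnitSystem = _DEFAULT_UNITS,
    label: Optional[str] = None,
) -> Scenario:
    """Disc (thin cylinder) scenario: a droplet spread under a spacer.

    The radius follows from the droplet volume and chamber height,
    ``R0 = sqrt(V / (pi h))`` (defaults give R0 = 2.523 mm); symmetry is
    cylindrical (m=1) with Dirichlet barium at r=R0.
    """
    p = p or ModelParameters.default()
    if bath_mM <= 0.0:
        raise ContractError("make_disc_scenario: bath_mM must be > 0")
    if volume_uL <= 0.0 or height_um <= 0.0:
        raise ContractError(
            "make_disc_scenario: volume_uL and height_um must be > 0"
        )
    V_mm3 = volume_uL  # 1 uL == 1 mm^3
    h_mm = height_um * 1e-3
    R0 = float(np.sqrt(V_mm3 / (np.pi * h_mm)))
    grid = Grid1D.graded(R0, n_nodes, symmetry_exponent=1)
    bath = units.to_model(bath_mM, "mM")
    horizon = horizon_s if horizon_s is not None else _default_horizon(bath_mM, R0, p, 1)
    cadence = output_cadence_s if output_cadence_s is not None else horizon / 400.0
    return Scenario(
        grid=grid,
        initial_state=_initial_state(grid, bath, rho_poly0=1.0),
        bath_ba=bath,
        horizon=float(horizon),
        output_cadence=float(cadence),
        label=label or f"disc_{bath_mM:g}mM",
        bath_mM=bath_mM,
    )


def make_sphere_scenario(
    diameter_um: float,
    bath_mM: float,
    p: Optional[ModelParameters] = None,
    *,
    n_nodes: int = DEFAULT_NODES,
    horizon_s: Optional[float] = None,
    output_cadence_s: Optional[float] = None,
    units: UnitSystem = _DEFAULT_UNITS,
    label: Optional[str] = None,
) -> Scenario:
    """Sphere (bead) scenario: a droplet gelled free-floating in the bath."""
    p = p or ModelParameters.default()
    lo, hi = SPHERE_DIAMETER_RANGE_UM
    if not (lo <= diameter_um <= hi):
        raise ContractError(
            f"make_sphere_scenario: diameter_um={diameter_um:g} outside the "
            f"plausible range [{lo:g}, {hi:g}] um"
        )
    if bath_mM <= 0.0:
        raise ContractError("make_sphere_scenario: bath_mM must be > 0")
    R0 = diameter_um * 1e-3 / 2.0
    grid = Grid1D.graded(R0, n_nodes, symmetry_exponent=2)
    bath = units.to_model(bath_mM, "mM")
    horizon = horizon_s if horizon_s is not None else _default_horizon(bath_mM, R0, p, 2)
    cadence = output_cadence_s if output_cadence_s is not None else horizon / 400.0
    return Scenario(
        grid=grid,
        initial_state=_initial_state(grid, bath, rho_poly0=1.0),
        bath_ba=bath,
        horizon=float(horizon),
        output_cadence=float(cadence),
        label=label or f"sphere_{diameter_um:g}um_{bath_mM:g}mM",
        bath_mM=bath_mM,
    )
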