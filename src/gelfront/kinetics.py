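"""Pointwise gelation kinetics: reaction source terms and hindered diffusivities.

The model tracks four local quantities: free polymer density, free barium
density, cross-linked polymer density, and the binding-occupancy fraction
``kappa`` (occupied binding sites / available binding sites in the network).

Source terms
------------
Free polymer attaches to the network at a rate proportional to the product of
free-polymer and barium densities.  Barium is consumed both by that primary
attachment and by a secondary absorption into unoccupied binding sites of the
existing network.  All mass lost by the mobile constituents appears in the
cross-linked phase, so the three density source terms sum to zero identically.

Unit convention
---------------
Lengths are millimetres and times seconds throughout the package.  Densities
are nondimensional: a 10 mM bath maps to a barium density of 1.0 and the
initial alginate solution (0.65 % w/v mixture) maps to a polymer density of
1.0; cross-linked polymer is expressed in the same polymer reference unit.
The rate coefficients ``C_*`` act on these model-unit densities and carry
units of 1/s per unit density product; the hindrance exponents ``K_*`` are
1/(model cross-link density).  See :mod:`gelfront.scenarios` for conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields, replace
from typing import Tuple, Union

import numpy as np

from .errors import ContractError

__all__ = [
    "ModelParameters",
    "LocalState",
    "reaction_rates",
    "effective_diffusivity",
]

#: Minimum allowed ratio of barium to polymer base diffusivity.  The ions are
#: far smaller than the polymer chains, so their diffusivity must dominate.
MIN_DIFFUSIVITY_RATIO = 10.0

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ModelParameters:
    """The eight rate/transport constants of the gelation model.

    Diffusivities are in mm^2/s (model length/time units); the ``C_*`` and
    ``K_*`` constants act on model-unit densities (see module docstring).
    """

    D0_poly: float
    D0_ba: float
    K_poly: float
    K_ba: float
    C_poly: float
    C_ba: float
    C_kba: float
    C_k: float

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0.0:
                raise ContractError(
                    f"ModelParameters.{f.name} must be strictly positive and "
                    f"finite, got {v!r}"
                )
        if self.D0_ba / self.D0_poly < MIN_DIFFUSIVITY_RATIO:
            raise ContractError(
                "ModelParameters.D0_ba must exceed D0_poly by at least a factor "
                f"of {MIN_DIFFUSIVITY_RATIO:g} (got ratio "
                f"{self.D0_ba / self.D0_poly:.3g})"
            )

    @classmethod
    def default(cls) -> "ModelParameters":
        """Calibrated reference parameter set (model units: mm, s).

        The diffusivities correspond to 6.78e-12 and 6.78e-9 m^2/s.
        """
        return cls(
            D0_poly=6.78e-6,
            D0_ba=6.78e-3,
            K_poly=2.5,
            K_ba=2.3,
            C_poly=1.6e-1,
            C_ba=8.0e-2,
            C_kba=2.5e-2,
            C_k=2.5e-2,
        )

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the named fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LocalState:
    """Pointwise state: three partial densities plus binding occupancy."""

    rho_poly: float
    rho_ba: float
    rho_cross: float
    kappa: float

    def __post_init__(self) -> None:
        for name in ("rho_poly", "rho_ba", "rho_cross"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise ContractError(
                    f"LocalState.{name} must be finite and nonnegative, got {v!r}"
                )
        if not np.isfinite(self.kappa) or not (0.0 <= self.kappa <= 1.0):
            raise ContractError(
                f"LocalState.kappa must lie in [0, 1], got {self.kappa!r}"
            )


def _raw_rates(
    rho_poly: ArrayLike,
    rho_ba: ArrayLike,
    rho_cross: ArrayLike,
    kappa: ArrayLike,
    p: ModelParameters,
) -> Tuple[ArrayLike, ArrayLike, ArrayLike, ArrayLike]:
    """Vectorised source terms without contract checks (solver hot path).

    ``rate_cross`` is computed as ``-(rate_poly + rate_ba)`` so the mass-
    conservation identity holds to the last floating-point bit; algebraically
    it equals ``(C_poly + C_ba)*rho_poly*rho_ba + secondary``.
    """
    primary = rho_poly * rho_ba
    secondary = rho_ba * (1.0 - kappa) * rho_cross
    rate_poly = -p.C_poly * primary
    rate_ba = -p.C_ba * primary - p.C_kba * secondary
    rate_cross = -(rate_poly + rate_ba)
    rate_kappa = p.C_k * secondary
    return rate_poly, rate_ba, rate_cross, rate_kappa


def reaction_rates(
    s: LocalState, p: ModelParameters
) -> Tuple[float, float, float, float]:
    """Evaluate the four reaction source terms at a single point.

    Parameters
    ----------
    s
        Local state; must satisfy its invariants (checked on construction).
    p
        Model parameters.

    Returns
    -------
    tuple
        ``(rate_poly, rate_ba, rate_cross, rate_kappa)`` in model units per
        second.  The first three sum to zero exactly; ``rate_cross`` and
        ``rate_kappa`` are nonnegative.
    """
    return _raw_rates(s.rho_poly, s.rho_ba, s.rho_cross, s.kappa, p)


def effective_diffusivity(
    rho_cross: ArrayLike, D0: float, K: float
) -> ArrayLike:
    """Cross-link-hindered diffusivity ``D0 * exp(-K * rho_cross)``.

    As the network densifies its mesh size shrinks, exponentially hindering
    transport of both mobile constituents.  Strictly decreasing in
    ``rho_cross``; equals ``D0`` at zero cross-link density.
    """
    rho_cross = np.asarray(rho_cross, dtype=float)
    if np.any(rho_cross < 0.0):
        raise ContractError("effective_diffusivity: rho_cross must be >= 0")
    if D0 <= 0.0:
        raise ContractError("effective_diffusivity: D0 must be > 0")
    if K < 0.0:
        raise ContractError("effective_diffusivity: K must be >= 0")
    out = D0 * np.exp(-K * rho_cross)
    return float(out) if out.ndim == 0 else out
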