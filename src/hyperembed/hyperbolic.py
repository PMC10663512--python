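"""Purely geometric representation in (D+1)-dimensional hyperbolic space.

The S^D model maps exactly onto a hyperbolic ball: sending each hidden
degree to a radial coordinate r_i = R_hat - (2/D) ln(kappa_i/kappa_0) turns
the gravity law into the logistic form p = 1/(1 + exp[(beta/2)(x - R_hat)])
with the effective distance x_ij = r_i + r_j + 2 ln(dtheta_ij / 2).  ``x`` is
a good approximation of the true hyperbolic geodesic whenever
dtheta >> 2*sqrt(exp(-2 r_i) + exp(-2 r_j)); we use it as the working
distance (greedy routing ranks neighbors by it), not as an exact geodesic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ModelParams, angular_distance

__all__ = ["HyperbolicCoordinates", "to_hyperbolic", "hyperbolic_connection_probability", "effective_distance"]


@dataclass
class HyperbolicCoordinates:
    """Radial coordinates plus the angular unit vectors they pair with."""

    radial: np.ndarray
    R_hat: float
    unit_directions: np.ndarray
    D: int
    beta: float


def to_hyperbolic(
    positions: np.ndarray,
    kappa: np.ndarray,
    params: ModelParams,
    kappa0: float | None = None,
) -> HyperbolicCoordinates:
    """Map hidden degrees to radial coordinates.

    ``kappa0`` defaults to the smallest hidden degree, which pins the
    outermost node at the ball radius R_hat = 2 ln(2R / (mu*kappa0^2)^(1/D)).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("hidden degrees must be positive")
    if kappa0 is None:
        kappa0 = float(kappa.min())
    D = params.D
    R_hat = 2.0 * math.log(2.0 * params.R / (params.mu * kappa0**2) ** (1.0 / D))
    radial = R_hat - (2.0 / D) * np.log(kappa / kappa0)
    return HyperbolicCoordinates(
        radial=radial, R_hat=R_hat, unit_directions=np.asarray(positions, float), D=D, beta=params.beta
    )


def effective_distance(i: int, j: int, coords: HyperbolicCoordinates) -> float:
    """x_ij = r_i + r_j + 2 ln(dtheta_ij / 2); -inf at zero separation."""
    dtheta = angular_distance(coords.unit_directions[i], coords.unit_directions[j])
    if dtheta == 0.0:
        return float("-inf")
    return float(coords.radial[i] + coords.radial[j] + 2.0 * math.log(dtheta / 2.0))


def hyperbolic_connection_probability(i: int, j: int, coords: HyperbolicCoordinates, beta: float | None = None):
    """Logistic connection probability in the hyperbolic picture.

    Returns ``(p, x)``; identical to the gravity law of the spherical
    picture, pair by pair, up to round-off.
    """
    if beta is None:
        beta = coords.beta
    x = effective_distance(i, j, coords)
    if x == float("-inf"):
        return 1.0, x
    arg = 0.5 * beta * (x - coords.R_hat)
    if arg > 700.0:
        return 0.0, x
    return 1.0 / (1.0 + math.exp(arg)), x
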