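"""Vectorized quadrature for the gravity-law integrals.

Both the expected-degree and expected-distance formulas reduce to moments of

    f(theta) = theta**m * sin(theta)**(D-1) / (1 + (theta/theta_star)**beta)

on [0, pi], where theta_star = (mu*kappa*kappa')**(1/D) / R locates the knee
of the connection probability.  The integrand is smooth on each side of the
knee, so composite Gauss-Legendre with panel edges at theta_star (and at
4*theta_star, where the beta-power tail has largely died off) is accurate and
lets us evaluate thousands of (kappa, kappa') pairs in one shot.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_GL_X, _GL_W = np.polynomial.legendre.leggauss(48)


def angular_pdf_prefactor(D: int) -> float:
    """Gamma((D+1)/2) / (sqrt(pi)*Gamma(D/2)): normalizes sin**(D-1) on [0, pi]."""
    return float(np.exp(gammaln((D + 1) / 2) - gammaln(D / 2)) / np.sqrt(np.pi))


def gravity_moments(theta_star, beta: float, D: int, moments=(0,)) -> list[np.ndarray]:
    """Integrals of theta**m * sin(theta)**(D-1) / (1+(theta/theta_star)**beta).

    ``theta_star`` may be any array; one integral array per requested moment
    is returned, with the same shape.
    """
    ts = np.atleast_1d(np.asarray(theta_star, dtype=float))
    shape = ts.shape
    ts = ts.ravel()
    e0 = np.zeros_like(ts)
    e1 = np.clip(ts, 1e-12, np.pi)
    e2 = np.clip(4.0 * ts, e1, np.pi)
    e3 = np.full_like(ts, np.pi)
    totals = [np.zeros_like(ts) for _ in moments]
    for a, b in ((e0, e1), (e1, e2), (e2, e3)):
        half = (b - a) / 2.0
        mid = (b + a) / 2.0
        theta = mid[:, None] + half[:, None] * _GL_X[None, :]
        with np.errstate(over="ignore", divide="ignore"):
            ratio = (theta / ts[:, None]) ** beta
        base = np.sin(theta) ** (D - 1) / (1.0 + ratio)
        for k, m in enumerate(moments):
            f = base if m == 0 else base * theta**m
            totals[k] += half * (f @ _GL_W)
    return [t.reshape(shape) for t in totals]


def connected_distance_cdf_tables(
    theta_star: np.ndarray, beta: float, D: int, n_grid: int = 2048, n_quantiles: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse CDF tables of the connected-pair separation density.

    The density of the angular distance between two *connected* nodes is
    proportional to sin**(D-1)(t) / (1 + (t/theta_star)**beta).  For each
    entry of ``theta_star`` the CDF is tabulated on an ``n_grid``-point theta
    grid and inverted onto ``n_quantiles`` equally spaced quantiles, so that
    sampling reduces to linear interpolation of uniforms.

    Returns ``(quantile_grid, table)`` with ``table[i, q]`` the separation at
    quantile ``quantile_grid[q]`` for ``theta_star[i]``.
    """
    ts = np.asarray(theta_star, dtype=float).ravel()
    grid = np.linspace(0.0, np.pi, n_grid)
    with np.errstate(over="ignore", divide="ignore"):
        ratio = (grid[None, 1:] / ts[:, None]) ** beta
    pdf = np.empty((ts.shape[0], n_grid))
    pdf[:, 0] = 0.0 if D > 1 else 1.0
    pdf[:, 1:] = np.sin(grid[1:]) ** (D - 1) / (1.0 + ratio)
    cdf = np.cumsum((pdf[:, 1:] + pdf[:, :-1]) / 2.0 * np.diff(grid)[None, :], axis=1)
    cdf = np.concatenate([np.zeros((ts.shape[0], 1)), cdf], axis=1)
    cdf /= cdf[:, -1:]
    q = np.linspace(0.0, 1.0, n_quantiles)
    table = np.empty((ts.shape[0], n_quantiles))
    for i in range(ts.shape[0]):
        table[i] = np.interp(q, cdf[i], grid)
    return q, table


def sample_from_tables(table: np.ndarray, rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Draw separations: linear interpolation of uniforms ``u`` into the
    inverse-CDF ``table`` rows selected by ``rows``."""
    nq = table.shape[1]
    x = u * (nq - 1)
    lo = np.minimum(x.astype(int), nq - 2)
    frac = x - lo
    left = table[rows, lo]
    right = table[rows, lo + 1]
    return left + frac * (right - left)
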