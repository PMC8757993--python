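"""Analytic two-boundary Wiener first-passage solution.

Validation oracle for the simulator: closed-form absorption probabilities and
the classical large-time series for the first-passage density of a drifted
Brownian motion between absorbing boundaries at 0 and B.  Used only in tests
and diagnostics, never as the simulation path.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "choice_probability",
    "first_passage_density",
    "first_passage_cdf",
]

_TERM_TOL = 1e-12
_MAX_TERMS = 5000


def choice_probability(mu: float, sigma: float, B: float, z0: float) -> float:
    """P(absorb at the upper boundary B | start z0), drift mu, diffusion sigma.

    P(upper) = (1 - exp(-2 mu z0 / sigma^2)) / (1 - exp(-2 mu B / sigma^2)),
    with the driftless limit z0 / B.
    """
    _check(sigma, B, z0)
    if mu == 0:
        return z0 / B
    a = 2.0 * mu / sigma**2
    # numerically stable for large |a|*B
    num = -np.expm1(-a * z0)
    den = -np.expm1(-a * B)
    return float(num / den)


def _check(sigma: float, B: float, z0: float) -> None:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (0.0 < z0 < B):
        raise ValueError("z0 must lie strictly between 0 and B")


def _density_lower(
    t: np.ndarray, mu: float, sigma: float, B: float, z0: float
) -> np.ndarray:
    """Series density of absorption at the *lower* boundary 0 at time t.

    f0(t) = (pi s^2 / B^2) exp(-mu z0/s^2 - mu^2 t/(2 s^2))
            * sum_k k sin(k pi z0 / B) exp(-k^2 pi^2 s^2 t / (2 B^2)),
    terms added until they fall below 1e-12 of the running sum.
    """
    t = np.asarray(t, dtype=float)
    s2 = sigma**2
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    acc = np.zeros_like(tp)
    lam = np.pi**2 * s2 / (2.0 * B**2)
    small_run = 0
    for k in range(1, _MAX_TERMS + 1):
        term = k * np.sin(k * np.pi * z0 / B) * np.exp(-(k**2) * lam * tp)
        acc += term
        # sin() zeros make single terms vanish identically, so only stop on
        # two consecutive negligible terms (envelope decays in exp(-k^2 lam t))
        if np.all(np.abs(term) < _TERM_TOL * np.maximum(np.abs(acc), 1e-300)):
            small_run += 1
            if small_run >= 2:
                break
        else:
            small_run = 0
    pref = (np.pi * s2 / B**2) * np.exp(-mu * z0 / s2 - mu**2 * tp / (2.0 * s2))
    out[pos] = pref * acc
    return np.clip(out, 0.0, None)


def first_passage_density(
    t: np.ndarray, mu: float, sigma: float, B: float, z0: float, boundary: str = "both"
) -> np.ndarray:
    """First-passage time density at ``t`` for the chosen boundary.

    ``boundary``: "lower", "upper", or "both" (defect, i.e. the unconditional
    RT density marginalised over the response).  Upper-boundary density is the
    lower-boundary one under the reflection z0 -> B - z0, mu -> -mu.
    """
    if boundary == "lower":
        return _density_lower(t, mu, sigma, B, z0)
    if boundary == "upper":
        return _density_lower(t, -mu, sigma, B, B - z0)
    if boundary == "both":
        return _density_lower(t, mu, sigma, B, z0) + _density_lower(
            t, -mu, sigma, B, B - z0
        )
    raise ValueError(f"unknown boundary {boundary!r}")


def first_passage_cdf(
    t_grid: np.ndarray,
    mu: float,
    sigma: float,
    B: float,
    z0: float,
    boundary: str = "both",
) -> np.ndarray:
    """CDF of the first-passage time on ``t_grid`` by trapezoidal quadrature.

    The grid should start at (or near) 0 and be fine relative to the density's
    scale; tests use ~1 ms spacing.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    f = first_passage_density(t_grid, mu, sigma, B, z0, boundary=boundary)
    cdf = np.concatenate(
        [[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(t_grid))]
    )
    return cdf + _partial_mass(t_grid[0], mu, sigma, B, z0, boundary)


def _partial_mass(t0, mu, sigma, B, z0, boundary):
    if t0 <= 0:
        return 0.0
    # integrate [0, t0] on a fine auxiliary grid
    aux = np.linspace(0.0, t0, 256)
    f = first_passage_density(aux, mu, sigma, B, z0, boundary=boundary)
    return float(np.trapezoid(f, aux))
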