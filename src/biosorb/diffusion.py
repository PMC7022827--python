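"""Radial diffusion in a long cylinder and its reduction to first-order
kinetics.

The biosorbent filament is idealised as an infinite cylinder of radius R
(radius much smaller than length, so axial transport is ignored). The dye
concentration C(r, t) obeys the radial diffusion equation

    (1/r) d/dr (r dC/dr) = (1/alpha) dC/dt,

separable as C(r, t) = R(r) * T(t). The radial factor solves the order-zero
Bessel equation; with an absorbing boundary C(R, t) = 0 the admissible
separation constants are gamma_k = j_{0,k} / R, where j_{0,k} is the k-th
positive root of J0. Each temporal factor decays as exp(-alpha gamma_k^2 t),
so the slowest (first) mode is exactly the pseudo-first-order law with
K1 = alpha * gamma_1^2. The module is illustrative: time-course data alone
identify only the product alpha*gamma^2, never alpha and the geometry
separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1

from .errors import InvalidInputError


class BoundaryKind(str, Enum):
    ABSORBING = "absorbing"


@dataclass(frozen=True)
class CylinderModel:
    radius: float                 # R, arbitrary length units
    alpha: float                  # diffusivity-like rate, 1/h per 1/length^2
    n_modes: int = 50
    boundary_kind: BoundaryKind = BoundaryKind.ABSORBING

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidInputError("radius must be positive")
        if self.n_modes < 1:
            raise InvalidInputError("need at least one eigenmode")
        if self.boundary_kind is not BoundaryKind.ABSORBING:
            raise InvalidInputError("only the absorbing boundary is implemented")


def bessel_j0_roots(n: int) -> np.ndarray:
    """First ``n`` positive roots of J0, by bracketed bisection.

    Root k lies in ((k - 3/4)pi, (k + 1/4)pi); Brent's method on that
    bracket gives machine-precision roots without relying on tabulated
    zeros, so tests can cross-check against an independent source.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    roots = np.empty(n)
    for k in range(1, n + 1):
        lo, hi = (k - 0.75) * np.pi, (k + 0.25) * np.pi
        roots[k - 1] = brentq(j0, lo, hi, xtol=1e-14, rtol=1e-15)
    return roots


def radial_eigenvalues(radius: float, n: int) -> np.ndarray:
    """gamma_k = j_{0,k} / R for the absorbing boundary C(R, t) = 0."""
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    return bessel_j0_roots(n) / radius


def temporal_mode(ci: float, alpha: float, gamma: float, t) -> np.ndarray | float:
    """Single-mode decay Ct = Ci * exp(-alpha * gamma^2 * t).

    Identical to the first-order law with K1 = alpha * gamma^2.
    """
    if ci <= 0 or alpha < 0 or gamma < 0:
        raise InvalidInputError("require Ci > 0, alpha >= 0, gamma >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    out = ci * np.exp(-alpha * gamma**2 * t)
    return out if out.ndim else float(out)


def _series_terms(model: CylinderModel, ci: float):
    """Roots, eigenvalues and Fourier-Bessel coefficients for C(r,0) = Ci.

    Projecting the uniform initial profile onto the J0 basis gives
    A_k = 2 Ci / (j_{0,k} J1(j_{0,k})).
    """
    roots = bessel_j0_roots(model.n_modes)
    gammas = roots / model.radius
    coeffs = 2.0 * ci / (roots * j1(roots))
    return roots, gammas, coeffs


def concentration_profile(model: CylinderModel, ci: float, r, t) -> np.ndarray | float:
    """Truncated eigenmode series C(r, t) = sum_k A_k J0(gamma_k r) e^{-alpha gamma_k^2 t}.

    The boundary value C(R, t) vanishes for every t (absorbing wall); at
    t = 0 the series converges to the uniform profile Ci for r < R.
    """
    if ci <= 0:
        raise InvalidInputError("Ci must be positive")
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((r < 0) | (r > model.radius)):
        raise InvalidInputError("r must lie in [0, R]")
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    _, gammas, coeffs = _series_terms(model, ci)
    rr = r[..., None] if r.ndim else r
    tt = t[..., None] if t.ndim else t
    terms = coeffs * j0(gammas * rr) * np.exp(-model.alpha * gammas**2 * tt)
    out = np.sum(terms, axis=-1)
    return out if np.ndim(out) else float(out)


def mean_concentration(model: CylinderModel, ci: float, t) -> np.ndarray | float:
    """Volume-averaged concentration of the truncated series.

    Integrating each mode over the cross-section gives
    C_bar(t) = Ci * sum_k (4 / j_{0,k}^2) e^{-alpha gamma_k^2 t};
    the weights 4/j_{0,k}^2 sum to 1, so C_bar(0) -> Ci as modes are added.
    """
    if ci <= 0:
        raise InvalidInputError("Ci must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    roots, gammas, _ = _series_terms(model, ci)
    weights = 4.0 / roots**2
    tt = t[..., None] if t.ndim else t
    out = ci * np.sum(weights * np.exp(-model.alpha * gammas**2 * tt), axis=-1)
    return out if np.ndim(out) else float(out)
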