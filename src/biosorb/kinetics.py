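"""Kinetic models of dye adsorption and their one-parameter fits.

Two rate laws are compared:

* Pseudo-first-order (Lagergren) with the equilibrium capacity fixed:

      q(t) = Qe * (1 - exp(-K1 * t)),   Qe = f * Ci  (f = 0.91 by default)

  Only the rate constant K1 (1/h) is fitted; Qe is pinned at a fixed
  fraction of the initial concentration, reflecting the observation that
  equilibrium adsorption settles at ~91% of Ci regardless of Ci. The pure
  exponential decay of the remaining concentration, Ct = Ci*exp(-K1*t),
  is exposed separately (it is the single-mode solution of the radial
  diffusion model, see :mod:`biosorb.diffusion`).

* Ho second-order, whose linearized form is 1/Ct = k2*t + 1/Ci. Again only
  the rate constant k2 (L/(mg.h)) is fitted; the intercept is pinned at
  1/Ci.

Both fits minimise pooled squared residuals across replicates. The
second-order fit is done by nonlinear least squares in concentration space
by default because reciprocal-space noise is heteroscedastic; the
linearized reciprocal regression is available as ``method="linearized"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateInputError,
    FitFailureError,
    InvalidInputError,
)

K_BOUNDS = (1e-8, 10.0)  # admissible range for either rate constant
DEFAULT_EQUILIBRIUM_FRACTION = 0.91


@dataclass(frozen=True)
class TimeCourse:
    """One kinetic experiment: replicate measurements over time.

    ``values`` has shape (n_replicates, n_times) and holds either remaining
    concentrations Ct (mg/L) or adsorbed amounts q (mg/g), as indicated by
    ``value_kind``. With biomass fixed at 1 g/L the two scales are related
    by q = Ci - Ct.
    """

    initial_concentration: float      # Ci, mg/L
    times: np.ndarray                 # hours, ascending, starts at 0
    values: np.ndarray                # (n_replicates, n_times)
    value_kind: str = "remaining"     # "remaining" | "adsorbed"
    ph: float | None = None
    temperature_c: float | None = None
    biomass: float = 1.0
    n_truncated: int = 0              # points floored at 0 by the generator

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.initial_concentration <= 0:
            raise InvalidInputError("Ci must be positive")
        if self.value_kind not in ("remaining", "adsorbed"):
            raise InvalidInputError(f"unknown value_kind {self.value_kind!r}")
        if times.ndim != 1 or times.size < 1:
            raise InvalidInputError("times must be a 1-D array")
        if times[0] != 0:
            raise InvalidInputError("first sampling time must be 0")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly ascending")
        if values.shape[1] != times.size:
            raise InvalidInputError("values must have one column per time point")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def adsorbed(self) -> np.ndarray:
        """Replicate matrix on the adsorbed-amount scale q (mg/g)."""
        if self.value_kind == "adsorbed":
            return self.values
        return (self.initial_concentration - self.values) / self.biomass

    def remaining(self) -> np.ndarray:
        """Replicate matrix on the remaining-concentration scale Ct (mg/L)."""
        if self.value_kind == "remaining":
            return self.values
        return self.initial_concentration - self.values * self.biomass

    def pooled(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        """Flatten replicates: (times tiled per replicate, observations)."""
        mat = self.adsorbed() if kind == "adsorbed" else self.remaining()
        t = np.tile(self.times, self.n_replicates)
        return t, mat.ravel()


@dataclass(frozen=True)
class FirstOrderFit:
    rate_constant: float              # K1, 1/h
    rate_constant_se: float           # 1/h
    equilibrium_fraction: float       # dimensionless
    fixed_qe: float                   # mg/L (== fraction * Ci)
    residual_rmse: float              # mg/L
    residual_rse: float               # mg/L, (d - 1) denominator
    n_obs: int
    residuals: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class SecondOrderFit:
    rate_constant: float              # k2, L/(mg.h)
    rate_constant_se: float
    residual_rmse: float              # mg/L, in concentration space
    residual_rse: float
    n_obs: int
    method: str = "nls"
    residuals: np.ndarray = field(repr=False, default=None)


# --- model curves -----------------------------------------------------------

def first_order_remaining(ci, k1, t):
    """Ct = Ci * exp(-K1 * t): exponential decay of the remaining dye."""
    ci, k1 = float(ci), float(k1)
    t = np.asarray(t, dtype=float)
    if ci <= 0 or k1 < 0:
        raise InvalidInputError("require Ci > 0 and K1 >= 0")
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    out = ci * np.exp(-k1 * t)
    return out if out.ndim else float(out)


def first_order_adsorbed(ci, k1, t, equilibrium_fraction=DEFAULT_EQUILIBRIUM_FRACTION):
    """q(t) = f*Ci*(1 - exp(-K1*t)) with the equilibrium capacity fixed at
    f*Ci (biomass 1 g/L, so mg/g and mg/L coincide)."""
    ci, k1, f = float(ci), float(k1), float(equilibrium_fraction)
    if ci <= 0:
        raise InvalidInputError("Ci must be positive")
    if not 0 < f <= 1:
        raise InvalidInputError("equilibrium_fraction must lie in (0, 1]")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    out = f * ci * (1.0 - np.exp(-k1 * t))
    return out if out.ndim else float(out)


def second_order_remaining(ci, k2, t):
    """Ct = 1 / (k2*t + 1/Ci): Ho second-order decay of the remaining dye."""
    ci, k2 = float(ci), float(k2)
    if ci <= 0 or k2 < 0:
        raise InvalidInputError("require Ci > 0 and k2 >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    out = 1.0 / (k2 * t + 1.0 / ci)
    return out if out.ndim else float(out)


def second_order_adsorbed(ci, k2, t, biomass=1.0):
    """q(t) implied by the second-order law via mass balance q = (Ci - Ct)/B."""
    return (ci - second_order_remaining(ci, k2, t)) / biomass


# --- fitting ----------------------------------------------------------------

def _one_param_nls(residual_fn, jac_fn, x0: float, n_obs: int):
    """Bounded single-parameter least squares with an asymptotic SE from the
    Gauss-Newton curvature. Returns (estimate, se, residuals)."""
    x0 = float(np.clip(x0, *K_BOUNDS))
    sol = least_squares(
        lambda x: residual_fn(x[0]),
        x0=[x0],
        jac=lambda x: jac_fn(x[0]).reshape(-1, 1),
        bounds=([K_BOUNDS[0]], [K_BOUNDS[1]]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitFailureError(
            f"rate-constant fit did not converge: {sol.message}",
            diagnostics={"status": sol.status, "nfev": sol.nfev, "x": sol.x.tolist()},
        )
    k = float(sol.x[0])
    res = residual_fn(k)
    rss = float(res @ res)
    jtj = float(jac_fn(k) @ jac_fn(k))
    dof = max(n_obs - 1, 1)
    se = float(np.sqrt(rss / dof / jtj)) if jtj > 0 else float("inf")
    return k, se, res


def fit_first_order(
    tc: TimeCourse,
    equilibrium_fraction: float = DEFAULT_EQUILIBRIUM_FRACTION,
) -> FirstOrderFit:
    """Fit K1 in q(t) = f*Ci*(1 - exp(-K1 t)) by pooled least squares.

    All replicate observations enter the objective individually (pooled
    residuals), not replicate means. Qe is fixed, so the model has a single
    free parameter.
    """
    if tc.times.size < 3:
        raise DegenerateInputError("need at least 3 time points to fit a rate")
    f = float(equilibrium_fraction)
    if not 0 < f <= 1:
        raise InvalidInputError("equilibrium_fraction must lie in (0, 1]")
    ci = tc.initial_concentration
    qe = f * ci
    t, q_obs = tc.pooled("adsorbed")
    if np.allclose(q_obs, 0.0):
        raise DegenerateInputError("no adsorption signal (all q == 0)")

    def residual(k1):
        return q_obs - qe * (1.0 - np.exp(-k1 * t))

    def jac(k1):
        # d residual / d K1
        return -qe * t * np.exp(-k1 * t)

    # crude initial guess from the latest time point
    q_end = np.clip(np.mean(q_obs[t == t.max()]) / qe, 0.05, 0.99)
    x0 = -np.log(1.0 - q_end) / t.max()
    k1, se, res = _one_param_nls(residual, jac, x0, q_obs.size)
    rss = float(res @ res)
    return FirstOrderFit(
        rate_constant=k1,
        rate_constant_se=se,
        equilibrium_fraction=f,
        fixed_qe=qe,
        residual_rmse=float(np.sqrt(rss / q_obs.size)),
        residual_rse=float(np.sqrt(rss / max(q_obs.size - 1, 1))),
        n_obs=int(q_obs.size),
        residuals=res,
    )


def fit_second_order(tc: TimeCourse, method: str = "nls") -> SecondOrderFit:
    """Fit k2 in Ct = 1/(k2 t + 1/Ci) with the intercept pinned at 1/Ci.

    ``method="nls"`` (default) minimises squared residuals in concentration
    space; ``method="linearized"`` regresses 1/Ct - 1/Ci on t through the
    origin, the printed linear form of the rate law.
    """
    if tc.times.size < 3:
        raise DegenerateInputError("need at least 3 time points to fit a rate")
    ci = tc.initial_concentration
    t, ct_obs = tc.pooled("remaining")
    if np.any(ct_obs <= 0):
        raise InvalidInputError(
            "second-order fit requires strictly positive remaining concentrations"
        )

    if method == "linearized":
        y = 1.0 / ct_obs - 1.0 / ci
        sxx = float(t @ t)
        k2 = float((t @ y) / sxx)
        res_lin = y - k2 * t
        dof = max(t.size - 1, 1)
        se = float(np.sqrt((res_lin @ res_lin) / dof / sxx))
        res = ct_obs - second_order_remaining(ci, max(k2, 0.0), t)
    elif method == "nls":
        def residual(k2):
            return ct_obs - 1.0 / (k2 * t + 1.0 / ci)

        def jac(k2):
            return t / (k2 * t + 1.0 / ci) ** 2

        y0 = 1.0 / ct_obs - 1.0 / ci
        x0 = max(float((t @ y0) / (t @ t)), K_BOUNDS[0])  # linearized warm start
        k2, se, res = _one_param_nls(residual, jac, x0, ct_obs.size)
    else:
        raise InvalidInputError(f"unknown method {method!r}")

    rss = float(res @ res)
    return SecondOrderFit(
        rate_constant=k2,
        rate_constant_se=se,
        residual_rmse=float(np.sqrt(rss / ct_obs.size)),
        residual_rse=float(np.sqrt(rss / max(ct_obs.size - 1, 1))),
        n_obs=int(ct_obs.size),
        method=method,
        residuals=res,
    )
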