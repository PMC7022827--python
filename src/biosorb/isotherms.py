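"""Equilibrium isotherms and the through-origin linear (C-type) fit.

At equilibrium the adsorbed amount per gram of biomass, qe (mg/g), is
plotted against the residual solution concentration Ce (mg/L) at fixed
temperature. Over the measured range the isotherms are linear with no sign
of saturation (constant-partitioning, "C-type"), so the model is a single
slope through the origin:

    qe = b_o * Ce,    b_o = sum(Ce*qe) / sum(Ce^2)  (L/g).

Combining the isotherm with the mass balance Ci = Ce + qe*B gives the
equilibrium removed fraction b_o*B / (1 + b_o*B); a slope of 10.22 L/g at
1 g/L biomass therefore implies ~91% removal, tying the isotherm to the
fixed-Qe convention of the kinetic fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError


@dataclass(frozen=True)
class IsothermDataset:
    """Equilibrium (Ce, qe) points at one temperature.

    ``mass_balance_ok`` flags points where Ce + qe*B reproduces Ci within
    tolerance; noisy points may violate it without being dropped.
    """

    temperature_c: float
    ce: np.ndarray                    # mg/L remaining at equilibrium
    qe: np.ndarray                    # mg/g adsorbed at equilibrium
    biomass: float
    initial_concentrations: np.ndarray
    mass_balance_ok: np.ndarray = None

    def __post_init__(self):
        ce = np.asarray(self.ce, dtype=float)
        qe = np.asarray(self.qe, dtype=float)
        ci = np.asarray(self.initial_concentrations, dtype=float)
        object.__setattr__(self, "ce", ce)
        object.__setattr__(self, "qe", qe)
        object.__setattr__(self, "initial_concentrations", ci)
        if self.mass_balance_ok is None:
            ok = np.isclose(ce + qe * self.biomass, ci, rtol=1e-6, atol=1e-9)
            object.__setattr__(self, "mass_balance_ok", ok)

    @property
    def n_points(self) -> int:
        return self.ce.size


@dataclass(frozen=True)
class IsothermFit:
    slope: float                      # b_o, L/g
    slope_se: float
    p_value: float                    # two-sided t test of b_o = 0, n-1 dof
    r_squared: float                  # uncentered (headline for no-intercept fits)
    r_squared_centered: float
    n_points: int
    temperature_c: float | None = None


def build_isotherm(initial, final, biomass: float, temperature_c: float) -> IsothermDataset:
    """Assemble (Ce, qe) points from initial/final concentrations.

    Per point: Ce = final, qe = (initial - final) / B. Final concentrations
    above the initial (noise) yield negative qe, which is kept with a
    warning — dropping such points would bias the slope upward.
    """
    ci = np.asarray(initial, dtype=float)
    cf = np.asarray(final, dtype=float)
    if ci.shape != cf.shape:
        raise InvalidInputError("initial and final lists must have equal length")
    if biomass <= 0:
        raise InvalidInputError("biomass must be positive")
    if np.any(cf > ci):
        warnings.warn("final concentration exceeds initial (negative qe kept)", stacklevel=2)
    qe = (ci - cf) / biomass
    return IsothermDataset(
        temperature_c=temperature_c,
        ce=cf,
        qe=qe,
        biomass=biomass,
        initial_concentrations=ci,
    )


def fit_linear_origin(dataset: IsothermDataset) -> IsothermFit:
    """Through-origin least squares qe = b_o * Ce.

    Closed-form slope sum(Ce*qe)/sum(Ce^2); the standard error uses the
    residual variance with n - 1 degrees of freedom (one parameter); the
    p-value is the two-sided Student-t test of b_o = 0. The headline R^2 is
    the uncentered coefficient 1 - RSS/sum(qe^2), which is the natural
    definition for a no-intercept model (the centered version, also
    reported, can be negative).
    """
    x, y = dataset.ce, dataset.qe
    if x.size < 2:
        raise DegenerateInputError("need at least 2 isotherm points")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateInputError("all Ce are zero; slope undefined")
    slope = float((x @ y) / sxx)
    res = y - slope * x
    rss = float(res @ res)
    dof = x.size - 1
    if dof > 0 and rss > 0:
        se = float(np.sqrt(rss / dof / sxx))
        tstat = slope / se
        p = float(2.0 * stats.t.sf(abs(tstat), dof))
    else:
        se, p = 0.0, 0.0 if slope != 0 else 1.0
    syy_raw = float(y @ y)
    r2_unc = 1.0 - rss / syy_raw if syy_raw > 0 else float("nan")
    syy_cen = float(np.sum((y - y.mean()) ** 2))
    r2_cen = 1.0 - rss / syy_cen if syy_cen > 0 else float("nan")
    return IsothermFit(
        slope=slope,
        slope_se=se,
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        r_squared=r2_unc,
        r_squared_centered=r2_cen,
        n_points=int(x.size),
        temperature_c=dataset.temperature_c,
    )


def implied_removal_fraction(b_o: float, biomass: float = 1.0) -> float:
    """Equilibrium removed fraction implied by a C-type isotherm.

    From qe = b_o*Ce and Ci = Ce + qe*B: removed/initial = b_o*B/(1 + b_o*B).
    Strictly increasing in b_o, 0 at b_o = 0, -> 1 as b_o -> inf.
    """
    if b_o < 0:
        raise InvalidInputError("b_o must be non-negative")
    if biomass <= 0:
        raise InvalidInputError("biomass must be positive")
    x = b_o * biomass
    return x / (1.0 + x)
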