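"""Definitional adsorption quantities.

Three quantities describe dye uptake from solution:

* removal percentage    D = 100 * (Ci - Ct) / Ci
* total adsorption      Q = Ci - Ct              (mg/L)
* adsorption capacity   q = Q / B                (mg of dye per g of biomass)

where Ci is the initial dye concentration, Ct the concentration remaining at
time t, and B the biomass loading (g/L). With B = 1 g/L, q and Q coincide
numerically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class AdsorptionRecord:
    """One (Ci, Ct, B) observation; validates the basic sign constraints."""

    initial_concentration: float  # Ci, mg/L
    concentration_at_time: float  # Ct, mg/L
    biomass: float = 1.0          # B, g/L

    def __post_init__(self):
        if self.initial_concentration <= 0:
            raise InvalidInputError("Ci must be positive")
        if self.biomass <= 0:
            raise InvalidInputError("biomass must be positive")
        if self.concentration_at_time < 0:
            raise InvalidInputError("Ct must be non-negative")


def removal_percent(ci, ct):
    """Percent of the initial dye removed from solution, 100*(Ci-Ct)/Ci."""
    ci = np.asarray(ci, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if np.any(ci <= 0):
        raise InvalidInputError("Ci must be positive")
    _warn_if_negative_uptake(ci, ct)
    out = 100.0 * (ci - ct) / ci
    return out if out.ndim else float(out)


def total_adsorption(ci, ct):
    """Total adsorbed quantity Q = Ci - Ct (mg/L)."""
    ci = np.asarray(ci, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if np.any(ci <= 0):
        raise InvalidInputError("Ci must be positive")
    _warn_if_negative_uptake(ci, ct)
    out = ci - ct
    return out if out.ndim else float(out)


def adsorption_capacity(q_total, biomass):
    """Adsorption capacity q = Q / B (mg dye per g biomass)."""
    biomass = np.asarray(biomass, dtype=float)
    if np.any(biomass <= 0):
        raise InvalidInputError("biomass must be positive")
    out = np.asarray(q_total, dtype=float) / biomass
    return out if out.ndim else float(out)


def round_reported(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching the reporting convention
    (e.g. 46.845 -> 46.85). Internal computations keep full precision."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def _warn_if_negative_uptake(ci, ct):
    # Ct > Ci (negative adsorption) can happen with measurement noise; it is
    # propagated, not clipped, so calibration problems stay visible.
    if np.any(ct > ci):
        warnings.warn(
            "Ct exceeds Ci (negative adsorption); value propagated unclipped",
            stacklevel=3,
        )
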