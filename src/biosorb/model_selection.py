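"""Fit-quality metrics and the model selection criterion (MSC).

Because the kinetic fits are nonlinear, goodness of fit is reported as
RMSE / RSE rather than R^2, and models are ranked by the weighted MSC

    MSC = ln( sum_j w_j (C_j - Cbar)^2 / sum_j w_j (C_j - Cm_j)^2 ) - 2*lambda/d

where d is the number of observations, lambda the number of fitted
parameters, C_j the pooled replicate observations, Cbar their (weighted)
mean and Cm_j the model predictions. Larger MSC is better; the 2*lambda/d
term penalises parameters, so MSC behaves like a scale-free AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, PerfectFitError
from .kinetics import (
    FirstOrderFit,
    SecondOrderFit,
    TimeCourse,
    first_order_adsorbed,
    second_order_adsorbed,
)


@dataclass(frozen=True)
class ModelComparison:
    """Side-by-side fit quality of the two kinetic models on one time course."""

    initial_concentration: float
    first_order_msc: float
    second_order_msc: float
    first_order_rmse: float
    second_order_rmse: float
    first_order_rse: float
    second_order_rse: float
    n_obs: int
    n_params: int
    preferred_model: str          # "first_order" | "second_order" | "tie"


def rmse(observed, modeled) -> float:
    """Root mean squared error, RSS/d denominator."""
    obs, mod = _paired(observed, modeled)
    return float(np.sqrt(np.mean((obs - mod) ** 2)))


def rse(observed, modeled, n_params: int) -> float:
    """Residual standard error, RSS/(d - lambda) denominator."""
    obs, mod = _paired(observed, modeled)
    d = obs.size
    if d <= n_params:
        raise InvalidInputError("RSE needs more observations than parameters")
    return float(np.sqrt(np.sum((obs - mod) ** 2) / (d - n_params)))


def msc(observed, modeled, n_params: int, weights=None) -> float:
    """Weighted model selection criterion; larger is better.

    Weights default to uniform. The criterion is invariant to rescaling all
    weights by a common factor. A zero residual sum of squares raises
    :class:`PerfectFitError` (the criterion would be infinite); a constant
    observed series has zero total sum of squares and returns ``-inf``.
    """
    obs, mod = _paired(observed, modeled)
    d = obs.size
    if d < 2:
        raise InvalidInputError("MSC needs at least 2 observations")
    if weights is None:
        w = np.ones(d)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != obs.shape or np.any(w <= 0):
            raise InvalidInputError("weights must be positive and match the data")
    wbar = float(np.sum(w * obs) / np.sum(w))
    tss = float(np.sum(w * (obs - wbar) ** 2))
    rss = float(np.sum(w * (obs - mod) ** 2))
    if rss == 0.0:
        raise PerfectFitError("zero residual sum of squares; MSC is infinite")
    if tss == 0.0:
        return float("-inf")
    return float(np.log(tss / rss) - 2.0 * n_params / d)


def compare_models(
    tc: TimeCourse,
    first_fit: FirstOrderFit,
    second_fit: SecondOrderFit,
    weights=None,
) -> ModelComparison:
    """Rank the two fitted kinetic models on one time course by MSC.

    Both models are evaluated on the adsorbed-amount scale — the series the
    fits target (the second-order prediction is mapped through the mass
    balance q = Ci - Ct, biomass 1 g/L) — with lambda = 1 for each (single
    fitted rate constant).
    """
    ci = tc.initial_concentration
    t, q_obs = tc.pooled("adsorbed")
    q1 = first_order_adsorbed(
        ci, first_fit.rate_constant, t, first_fit.equilibrium_fraction
    )
    q2 = second_order_adsorbed(ci, second_fit.rate_constant, t, tc.biomass)
    msc1 = msc(q_obs, q1, 1, weights)
    msc2 = msc(q_obs, q2, 1, weights)
    if msc1 > msc2:
        preferred = "first_order"
    elif msc2 > msc1:
        preferred = "second_order"
    else:
        preferred = "tie"
    return ModelComparison(
        initial_concentration=ci,
        first_order_msc=msc1,
        second_order_msc=msc2,
        first_order_rmse=rmse(q_obs, q1),
        second_order_rmse=rmse(q_obs, q2),
        first_order_rse=rse(q_obs, q1, 1),
        second_order_rse=rse(q_obs, q2, 1),
        n_obs=int(q_obs.size),
        n_params=1,
        preferred_model=preferred,
    )


def _paired(observed, modeled):
    obs = np.asarray(observed, dtype=float).ravel()
    mod = np.asarray(modeled, dtype=float).ravel()
    if obs.shape != mod.shape:
        raise InvalidInputError("observed and modeled series must have equal length")
    return obs, mod
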