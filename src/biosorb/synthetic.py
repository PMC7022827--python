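"""Seeded synthetic datasets mirroring the study's experimental designs.

Four generators emulate the statistical structure of the laboratory study —
a calibration series, a pH screen, kinetic time courses and equilibrium
isotherms — so every analysis stage can be exercised and validated without
raw data. Generators mimic measurement statistics only (additive Gaussian
noise on the observed quantity, floored at zero with the truncations
counted); no biological mechanism is simulated.

Determinism contract: one global integer seed drives a named stream per
design (seed material = (seed, crc32(design), replicate index)), so equal
configs give bit-identical output and adding a new design never perturbs
existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import study
from .errors import ConfigError
from .isotherms import IsothermDataset
from .kinetics import (
    TimeCourse,
    first_order_remaining,
    first_order_adsorbed,
    second_order_remaining,
)

DESIGNS = ("calibration", "ph_screen", "time_course", "isotherm")

# Default noise scales per design, on the generated observable. The kinetic
# and isotherm defaults follow the residual scales of the reference fits
# (~1 mg/L at Ci = 50; ~0.5 mg/g on qe); OD noise reflects a typical
# spectrophotometer repeatability.
DEFAULT_NOISE_SD = {
    "calibration": 0.005,   # OD units
    "ph_screen": 1.0,       # removal percentage points
    "time_course": 1.0,     # mg/L (or mg/g)
    "isotherm": 0.5,        # mg/g on qe
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for one synthetic dataset.

    ``params`` carries design-specific settings (see each generator);
    anything not given falls back to the reference study design.
    """

    seed: int
    design: str
    noise_sd: float | None = None
    n_replicates: int = 3
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ConfigError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        sd = self.noise_sd if self.noise_sd is not None else DEFAULT_NOISE_SD[self.design]
        if sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        object.__setattr__(self, "noise_sd", float(sd))

    def with_params(self, **kw) -> "GeneratorConfig":
        return replace(self, params={**self.params, **kw})


def stream(seed: int, design: str, index: int = 0) -> np.random.Generator:
    """Named RNG stream: independent per (seed, design, index)."""
    tag = zlib.crc32(design.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, int(index)]))


def _add_noise(truth: np.ndarray, sd: float, rng: np.random.Generator):
    """Additive Gaussian noise, floored at 0; returns (values, n_truncated)."""
    if sd == 0:
        return truth.copy(), 0
    noisy = truth + rng.normal(0.0, sd, size=truth.shape)
    n_trunc = int(np.sum(noisy < 0))
    return np.clip(noisy, 0.0, None), n_trunc


def generate_calibration(config: GeneratorConfig) -> pd.DataFrame:
    """Calibration points over the standard 50-800 mg/L series.

    params: ``slope`` (default 0.003), ``intercept`` (0.0348),
    ``concentrations`` (the reference 16-point grid). One OD reading per
    concentration per replicate, Gaussian OD noise.
    """
    p = config.params
    slope = float(p.get("slope", study.CALIBRATION_SLOPE))
    intercept = float(p.get("intercept", study.CALIBRATION_INTERCEPT))
    if slope <= 0:
        raise ConfigError("calibration slope must be positive")
    conc = np.asarray(p.get("concentrations", study.CALIBRATION_RANGE_MG_PER_L), dtype=float)
    rng = stream(config.seed, "calibration")
    conc_rep = np.tile(conc, config.n_replicates)
    truth = slope * conc_rep + intercept
    od, _ = _add_noise(truth, config.noise_sd, rng)
    return pd.DataFrame({"concentration_mg_per_L": conc_rep, "od": od})


def generate_ph_screen(config: GeneratorConfig) -> pd.DataFrame:
    """Removal-vs-pH profile at 50 mg/L dye after 24 h.

    The true profile is an invented unimodal (Gaussian-in-pH) shape — only
    the peak location and height are anchored to the reference study
    (46.84% at pH 4); params: ``peak_ph``, ``peak_removal``, ``width``
    (pH units, default 2.0), ``ph_grid``.
    """
    p = config.params
    grid = np.asarray(p.get("ph_grid", study.PH_GRID), dtype=float)
    peak_ph = float(p.get("peak_ph", study.PH_OPTIMUM))
    peak = float(p.get("peak_removal", study.PH_PEAK_REMOVAL_PERCENT))
    width = float(p.get("width", 2.0))
    if not (grid.min() <= peak_ph <= grid.max()):
        raise ConfigError("peak_ph must lie within the pH grid")
    rng = stream(config.seed, "ph_screen")
    truth = peak * np.exp(-0.5 * ((grid - peak_ph) / width) ** 2)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        vals, _ = _add_noise(truth, config.noise_sd, rng)
        for ph, t, v in zip(grid, truth, vals):
            rows.append({"ph": ph, "replicate": rep, "removal_percent": v,
                         "removal_percent_true": t})
    return pd.DataFrame(rows)


def generate_time_course(config: GeneratorConfig, index: int = 0) -> TimeCourse:
    """One kinetic time course from a named generating model.

    params: ``model`` ("first_order" | "second_order"), ``ci`` (mg/L),
    ``rate_constant`` (K1 or k2 for the chosen model),
    ``equilibrium_fraction`` (first-order only, default 0.91), ``times``
    (default 0..96 h daily), ``value_kind`` — the observable noise is added
    to: "remaining" (Ct, default) or "adsorbed" (q).

    ``index`` selects an independent replication stream for Monte-Carlo
    studies without changing the global seed.
    """
    p = config.params
    model = p.get("model", "first_order")
    ci = float(p.get("ci", 50.0))
    times = np.asarray(p.get("times", study.KINETIC_TIMES_H), dtype=float)
    value_kind = p.get("value_kind", "remaining")
    frac = float(p.get("equilibrium_fraction", study.EQUILIBRIUM_FRACTION))
    if model == "first_order":
        k = float(p.get("rate_constant", study.FIRST_ORDER_K1[50.0][0]))
        if value_kind == "remaining":
            # remaining dye consistent with the fixed-Qe convention:
            # Ct = Ci - q(t), floor Ci*(1 - f) at t -> inf
            truth = ci - first_order_adsorbed(ci, k, times, frac)
        else:
            truth = first_order_adsorbed(ci, k, times, frac)
    elif model == "second_order":
        k = float(p.get("rate_constant", study.SECOND_ORDER_K2[50.0][0]))
        ct = second_order_remaining(ci, k, times)
        truth = ct if value_kind == "remaining" else ci - ct
    else:
        raise ConfigError(f"unknown generating model {model!r}")
    rng = stream(config.seed, "time_course", index)
    reps = np.empty((config.n_replicates, times.size))
    n_trunc = 0
    for i in range(config.n_replicates):
        reps[i], nt = _add_noise(truth, config.noise_sd, rng)
        n_trunc += nt
    return TimeCourse(
        initial_concentration=ci,
        times=times,
        values=reps,
        value_kind=value_kind,
        ph=p.get("ph", study.PH_OPTIMUM),
        temperature_c=p.get("temperature_c", 25.0),
        biomass=float(p.get("biomass", study.BIOMASS_G_PER_L)),
        n_truncated=n_trunc,
    )


def generate_isotherm(config: GeneratorConfig, index: int = 0) -> IsothermDataset:
    """One equilibrium isotherm from a C-type (linear) generating truth.

    Per initial concentration Ci: true Ce = Ci/(1 + b_o*B), qe = b_o*Ce;
    Gaussian noise (sd on qe) is added and Ce is left at truth (the noise
    model targets the adsorbed amount). params: ``slope`` (b_o, L/g),
    ``ci`` list, ``biomass``, ``temperature_c``.
    """
    p = config.params
    b_o = float(p.get("slope", study.ISOTHERM_SLOPES[50.0][0]))
    if b_o <= 0:
        raise ConfigError("generating slope b_o must be positive")
    biomass = float(p.get("biomass", study.BIOMASS_G_PER_L))
    temperature = float(p.get("temperature_c", 50.0))
    ci = np.asarray(p.get("ci", study.ISOTHERM_INITIAL_CONCENTRATIONS), dtype=float)
    rng = stream(config.seed, "isotherm", index)
    ci_rep = np.tile(ci, config.n_replicates)
    ce = ci_rep / (1.0 + b_o * biomass)
    qe_truth = b_o * ce
    qe, _ = _add_noise(qe_truth, config.noise_sd, rng)
    return IsothermDataset(
        temperature_c=temperature,
        ce=ce,
        qe=qe,
        biomass=biomass,
        initial_concentrations=ci_rep,
    )
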