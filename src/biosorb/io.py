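"""CSV dialects shared by the analysis stages, the generators and the CLI.

All on-disk formats are plain CSV with fixed headers:

* calibration:  ``concentration_mg_per_L,od``
* time course:  ``ci_mg_per_L,time_h,replicate,ct_mg_per_L`` (an ``od``
  column may stand in for ``ct_mg_per_L``; it is routed through a
  calibration curve on read)
* isotherm:     ``temperature_C,ci_mg_per_L,ce_mg_per_L,biomass_g_per_L``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, od_to_concentration
from .errors import DegenerateInputError
from .isotherms import IsothermDataset, build_isotherm
from .kinetics import TimeCourse

TIME_COURSE_COLUMNS = ("ci_mg_per_L", "time_h", "replicate", "ct_mg_per_L")
ISOTHERM_COLUMNS = ("temperature_C", "ci_mg_per_L", "ce_mg_per_L", "biomass_g_per_L")


def read_time_courses(
    path: str | Path, curve: CalibrationCurve | None = None
) -> list[TimeCourse]:
    """Read a time-course CSV into one :class:`TimeCourse` per Ci.

    If the file carries an ``od`` column instead of ``ct_mg_per_L``, a
    calibration curve must be supplied to back-calculate concentrations.
    """
    df = pd.read_csv(path)
    if "ct_mg_per_L" not in df.columns:
        if "od" not in df.columns:
            raise DegenerateInputError("time-course CSV needs ct_mg_per_L or od")
        if curve is None:
            raise DegenerateInputError("od column requires a calibration curve")
        df = df.assign(ct_mg_per_L=od_to_concentration(df["od"].to_numpy(), curve))
    missing = set(TIME_COURSE_COLUMNS) - set(df.columns)
    if missing:
        raise DegenerateInputError(f"time-course CSV missing columns: {sorted(missing)}")
    out = []
    for ci, grp in df.groupby("ci_mg_per_L", sort=True):
        piv = grp.pivot_table(
            index="replicate", columns="time_h", values="ct_mg_per_L", sort=True
        )
        out.append(
            TimeCourse(
                initial_concentration=float(ci),
                times=piv.columns.to_numpy(dtype=float),
                values=piv.to_numpy(dtype=float),
                value_kind="remaining",
            )
        )
    return out


def write_time_courses(tcs: list[TimeCourse], path: str | Path) -> None:
    rows = []
    for tc in tcs:
        ct = tc.remaining()
        for rep in range(tc.n_replicates):
            for j, t in enumerate(tc.times):
                rows.append({
                    "ci_mg_per_L": tc.initial_concentration,
                    "time_h": t,
                    "replicate": rep + 1,
                    "ct_mg_per_L": ct[rep, j],
                })
    pd.DataFrame(rows, columns=list(TIME_COURSE_COLUMNS)).to_csv(path, index=False)


def read_isotherms(path: str | Path) -> list[IsothermDataset]:
    """Read an isotherm CSV into one dataset per temperature."""
    df = pd.read_csv(path)
    missing = set(ISOTHERM_COLUMNS) - set(df.columns)
    if missing:
        raise DegenerateInputError(f"isotherm CSV missing columns: {sorted(missing)}")
    out = []
    for temp, grp in df.groupby("temperature_C", sort=True):
        biomass = grp["biomass_g_per_L"].to_numpy(dtype=float)
        if not np.allclose(biomass, biomass[0]):
            raise DegenerateInputError("mixed biomass within one isotherm")
        ds = build_isotherm(
            initial=grp["ci_mg_per_L"].to_numpy(dtype=float),
            final=grp["ce_mg_per_L"].to_numpy(dtype=float),
            biomass=float(biomass[0]),
            temperature_c=float(temp),
        )
        # an explicit qe column (measured adsorbed amount) overrides the
        # mass-balance reconstruction, so noisy qe survives a round-trip
        if "qe_mg_per_g" in grp.columns:
            ds = IsothermDataset(
                temperature_c=ds.temperature_c,
                ce=ds.ce,
                qe=grp["qe_mg_per_g"].to_numpy(dtype=float),
                biomass=ds.biomass,
                initial_concentrations=ds.initial_concentrations,
            )
        out.append(ds)
    return out


def write_isotherms(datasets: list[IsothermDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for ci, ce, qe in zip(ds.initial_concentrations, ds.ce, ds.qe):
            rows.append({
                "temperature_C": ds.temperature_c,
                "ci_mg_per_L": ci,
                "ce_mg_per_L": ce,
                "biomass_g_per_L": ds.biomass,
                "qe_mg_per_g": qe,
            })
    cols = list(ISOTHERM_COLUMNS) + ["qe_mg_per_g"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
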