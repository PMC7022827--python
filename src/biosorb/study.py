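"""Reference study design and published estimates for indigo blue biosorption
by *Spirulina platensis*.

These constants describe the laboratory study the synthetic generators
emulate: a pH screen, four adsorption time courses, and three equilibrium
isotherms, all at a biomass loading of 1 g/L. The fitted estimates recorded
here serve as generating truths for parameter-recovery simulations and as
defaults throughout the pipeline; they are inputs, not outputs, of this
package.
"""

from __future__ import annotations

# Biomass loading used in every experiment (g/L). Because B == 1, adsorption
# capacity q (mg/g) is numerically equal to the total adsorption Q (mg/L).
BIOMASS_G_PER_L = 1.0

# Standard curve: optical density = CALIBRATION_SLOPE * C + CALIBRATION_INTERCEPT
# over 50-800 mg/L, read at 600 nm.
CALIBRATION_SLOPE = 0.003          # OD per mg/L
CALIBRATION_INTERCEPT = 0.0348     # OD
CALIBRATION_RANGE_MG_PER_L = tuple(float(c) for c in range(50, 801, 50))
CALIBRATION_WAVELENGTH_NM = 600.0

# pH screen: 50 mg/L dye, 24 h, removal peaks at pH 4.
PH_GRID = (4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)
PH_OPTIMUM = 4.0
PH_PEAK_REMOVAL_PERCENT = 46.84

# Kinetic design: initial concentrations (mg/L) sampled daily over four days.
KINETIC_INITIAL_CONCENTRATIONS = (25.0, 50.0, 75.0, 100.0)
KINETIC_TIMES_H = (0.0, 24.0, 48.0, 72.0, 96.0)

# Equilibrium adsorption settles at ~91% of the initial concentration, so the
# pseudo-first-order fits fix Qe = 0.91 * Ci.
EQUILIBRIUM_FRACTION = 0.91

# Observed mean equilibrium adsorption Qe (mg/L) with 95% half-widths, per Ci.
OBSERVED_EQUILIBRIUM = {
    25.0: (23.1, 0.3),
    50.0: (45.4, 2.3),
    75.0: (67.7, 4.5),
    100.0: (89.9, 7.21),
}

# Fitted rate constants per Ci: pseudo-first-order K1 (1/h) and Ho
# second-order k2 (L/(mg.h)), each as (estimate, standard error).
FIRST_ORDER_K1 = {
    25.0: (0.046, 0.0047),
    50.0: (0.052, 0.0027),
    75.0: (0.047, 0.0081),
    100.0: (0.067, 0.015),
}
SECOND_ORDER_K2 = {
    25.0: (0.00265, 0.00050),
    50.0: (0.00180, 0.00013),
    75.0: (0.00088, 0.00022),
    100.0: (0.00095, 0.00021),
}

# Residual scales of the kinetic fits (mg/L), used as default noise levels.
FIRST_ORDER_RMSE = {25.0: 1.146, 50.0: 0.993, 75.0: 5.64, 100.0: 8.774}
SECOND_ORDER_RMSE = {25.0: 1.954, 50.0: 1.128, 75.0: 7.648, 100.0: 8.722}

# Isotherm design: five initial concentrations, three temperatures, 96 h.
ISOTHERM_INITIAL_CONCENTRATIONS = (6.25, 12.5, 25.0, 50.0, 100.0)
ISOTHERM_TEMPERATURES_C = (30.0, 40.0, 50.0)

# Through-origin isotherm slopes b_o (L/g) per temperature: (estimate, SE).
ISOTHERM_SLOPES = {
    30.0: (0.260, 0.047),
    40.0: (3.104, 0.1622),
    50.0: (10.220, 0.500),
}

# Surface point of zero charge of the biosorbent (metadata only).
PH_ZPC = 7.7
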