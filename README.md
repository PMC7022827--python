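# biosorb

Kinetic and equilibrium modelling of indigo blue dye biosorption by
*Spirulina platensis* biomass.

Textile dyes such as indigo blue resist conventional biological treatment;
passive binding onto microalgal biomass (biosorption) is a low-cost removal
route. This package implements the complete analysis chain of a bench
biosorption study for researchers working on dye bioremediation: an
OD/concentration standard curve, removal and adsorption-capacity
quantities, two competing kinetic models, model ranking, and equilibrium
isotherms — plus seeded synthetic-data generators so the whole pipeline is
verifiable by parameter recovery.

## Models

With Ci the initial dye concentration (mg/L), Ct the concentration
remaining at time t, and B the biomass loading (1 g/L throughout):

* quantities: D = 100·(Ci − Ct)/Ci, Q = Ci − Ct, q = Q/B
* pseudo-first-order (fixed capacity): q(t) = Qe·(1 − e^(−K1·t)) with
  Qe = 0.91·Ci; only K1 (1/h) is fitted. The 91% plateau is the observed
  average equilibrium adsorption across Ci = 25–100 mg/L.
* Ho second-order: 1/Ct = k2·t + 1/Ci; only k2 (L/(mg·h)) is fitted.
* model ranking: MSC = ln(ΣwΔ²_about-mean / ΣwΔ²_residual) − 2λ/d
  (larger is better), plus RMSE/RSE.
* isotherms (C-type, linear): qe = b_o·Ce through the origin, per
  temperature; the implied equilibrium removal is b_o·B/(1 + b_o·B).
* diffusion geometry: radial diffusion in a long cylinder with absorbing
  wall reduces, mode by mode, to the first-order law with K1 = α·γ₁²
  (γ_k = j_{0,k}/R from the zeros of the Bessel function J0).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Run the whole study synthetically from one seed:

```sh
biosorb run --synthetic --seed 7 --out out/
```

or drive the numbered analyses:

```sh
python analysis/01_generate_study.py   # materialise synthetic CSVs
python analysis/02_fit_kinetics.py     # kinetic fits + MSC ranking
python analysis/03_fit_isotherms.py    # through-origin isotherms
python analysis/04_parameter_recovery.py
```

`02_fit_kinetics.py` prints, for the seeded synthetic study:

```
observed equilibrium adsorption averages 89.3% of Ci (the fits fix Qe at 91%)
Ci=   25 mg/L: K1=0.0455±0.0016 1/h (MSC 4.99), k2=0.00304±0.00018 L/(mg·h) (MSC 4.45) -> prefers first_order
Ci=   50 mg/L: K1=0.0541±0.0019 1/h (MSC 5.30), k2=0.00185±0.00009 L/(mg·h) (MSC 5.18) -> prefers first_order
Ci=   75 mg/L: K1=0.0477±0.0009 1/h (MSC 6.48), k2=0.00108±0.00005 L/(mg·h) (MSC 5.13) -> prefers first_order
Ci=  100 mg/L: K1=0.0691±0.0012 1/h (MSC 7.23), k2=0.00123±0.00006 L/(mg·h) (MSC 5.70) -> prefers first_order
```

Each row fits both rate laws to one time course (pooled replicates, one
free parameter each) and ranks them by MSC: the recovered K1 values sit on
the generating truths, and the first-order model — the generating model —
wins at every concentration. `03_fit_isotherms.py` prints:

```
  30 C: b_o = 0.260 ± 0.002 L/g, p = 8.7e-22, R² = 0.999, implied equilibrium removal 20.7%
  40 C: b_o = 3.086 ± 0.015 L/g, p = 6.13e-26, R² = 1.000, implied equilibrium removal 75.5%
  50 C: b_o = 10.255 ± 0.026 L/g, p = 7.93e-30, R² = 1.000, implied equilibrium removal 91.1%
```

— slope (and hence removal capacity) increases with temperature, and the
50 °C slope implies the same ~91% equilibrium removal the kinetic fits fix.

The library surface mirrors these steps: `fit_calibration` /
`od_to_concentration`, `fit_first_order` / `fit_second_order`,
`compare_models`, `build_isotherm` / `fit_linear_origin`,
`generate_*` for synthetic designs, and `run_pipeline` for the whole chain.

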