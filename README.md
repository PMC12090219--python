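# photoxen

Quantitative analytics for **photoswitchable enzymes** ("photoxenases"):
proteins carrying an azobenzene-type photoswitchable amino acid whose
catalytic activity can be toggled with light. The package implements the
complete characterization workflow around such an enzyme — here, a
tetrameric bacterial L-asparaginase with dual asparaginase/glutaminase
activity — for experimentalists who need reproducible numbers out of
plate-reader, spectrometer, CD and MD data:

* **Initial rates from coupled-assay progress curves.** The quasi-linear
  phase of an absorbance time course is fitted by OLS and converted with
  the Lambert–Beer law, v = |m| / (ε·d) (ε = 6300 M⁻¹cm⁻¹ for NADH at
  340 nm, 6400 M⁻¹cm⁻¹ for quinoneimine at 505 nm; d = 0.535 cm for a
  200 µL well). Replicates over enzyme concentrations are pooled in a
  weighted regression through the origin whose slope is v/E₀ (s⁻¹).
* **Light-regulation factors (LRF) by dummy-constant global fits.** Two
  illumination states (as-isolated AIS, photostationary PSS³⁶⁵/PSS⁴²⁰) are
  fitted *jointly* with the activity constant shared and multiplied by a
  per-state dummy constant D; the reference (slower) state's D is fixed to
  1, so the other state's fitted D ± SE *is* the LRF ± SE. Works on linear
  activity data (y = D·m′·x) and on Michaelis–Menten data
  v/E₀ = D·k꜀ₐₜ·c/(K_m + c) with k꜀ₐₜ, K_m, or k꜀ₐₜ/K_m shared.
* **Photostationary-state spectroscopy.** Two-Gaussian deconvolution of
  the ππ* (≈330 nm) and nπ* (≈430–440 nm) bands, exponential fits of PSS
  formation with t₁⁄₂ = ln 2 / k, and estimation of the E-isomer fraction
  f_E of a mixed spectrum by requiring the implied pure-Z spectrum
  A_Z = (A_i − f_E·A_E)/(1 − f_E) to carry zero ππ* intensity (automated
  bisection instead of manual adjustment), plus f_E-vs-A(330 nm) standard
  curves and cycle-reversibility analysis.
* **Thermal stability.** Mean-residue-ellipticity normalization and
  Boltzmann sigmoid fits y(T) = A2 + (A1 − A2)/(1 + e^((T−Tm)/dT)) for the
  denaturation midpoint Tm.
* **Conformational landscapes.** 2-D probability histograms of MD
  collective variables (loop-opening distance d1, nucleophilic-attack
  distance d2, deprotonation distance d3, catalytic angle a1), −ln(p/p_max)
  surfaces, minima detection, representative-frame extraction, and
  closed-state fractions (d1 < 15 Å).
* **Synthetic data for everything** (`photoxen.synthetic_data`): seeded
  generators that are exact members of each analysis model class at zero
  noise, so every fit is testable end to end without instrument data.

Fitted models follow the model/results idiom: build a model from data,
call `fit()`, get a results object with estimates, standard errors and a
`summary()` table.

## Worked example

Recover steady-state constants and an LRF from synthetic triplicates
(12 asparagine concentrations, 0.005–2 mM, 2% multiplicative noise):

```python
import numpy as np
import photoxen as px
from photoxen.synthetic_data import SimConfig, gen_mm_dataset

grid = np.geomspace(0.005, 2.0, 12)
ais = gen_mm_dataset(20.0, 0.03, grid, replicates=3, noise_sd=0.02,
                     config=SimConfig(seed=1), state="AIS")
pss = gen_mm_dataset(12.5, 0.03, grid, replicates=3, noise_sd=0.02,
                     config=SimConfig(seed=2), state="PSS365")

print(px.fit_michaelis_menten(ais).summary())
print(px.fit_lrf_mm(ais, pss, target="kcat").summary())
```

```
Michaelis-Menten fit  [AIS]  (n = 36)
----------------------------------------------------
kcat     =       19.969 +/- 0.0877  s^-1
Km       =     0.029748 +/- 0.000293  mM
kcat/Km  =   6.7125e+05 +/- 4.83e+03  s^-1 M^-1
red. chi-square = 0.7691

Light-regulation global fit  (AIS vs PSS365)
----------------------------------------------------
shared kcat       = 12.489 +/- 0.0687
D (AIS, reference PSS365 fixed at 1) = 1.599 +/- 0.0124
LRF = 1.599 +/- 0.0124
  free Km_0           = 0.029994 +/- 0.000371
  free Km_1           = 0.029748 +/- 0.000367
```

The first block recovers the generating turnover number (kcat ≈ 20 s⁻¹)
and Michaelis constant (Km ≈ 0.03 mM) within their standard errors. In
the second block both states share kcat while each keeps its own Km; the
dummy constant D of the faster (AIS) state is the light-regulation factor:
activity drops ~1.6-fold on 365 nm irradiation.

The same workflows are available from the shell:

```bash
photoxen simulate mm --seed 11 --out-dir run/
photoxen mm --input run/sim_mm.csv --state AIS --out-dir run/
photoxen lrf --input rates.csv --model mm --target kcat --states AIS,PSS365
photoxen uvvis --spectra spectra.csv --reference AIS
photoxen melt --input melt.csv
photoxen landscape --input dof.csv --x d2 --y d1 --bins 60
photoxen cycles --input curve.csv --events events.csv
```

Every command writes a JSON provenance record (config + seed + version)
next to its outputs; re-running from it reproduces stochastic results
bit-identically.

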