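# Methods

This note documents the models implemented in `photoxen`, the assumptions
they make, the defaults chosen where the procedure is genuinely open, and
what the synthetic-data generators do and do not emulate.

## Rate extraction (`assay_kinetics`)

A coupled assay reports enzymatic turnover through an optical signal:
NADH depletion at 340 nm (differential ε = 6300 M⁻¹cm⁻¹) for the
asparaginase reaction, quinoneimine formation at 505 nm (ε = 6400
M⁻¹cm⁻¹) for the glutaminase reaction. The initial quasi-linear phase is
fitted by ordinary least squares and converted with Lambert–Beer,
v = |m|/(ε·d) in µM/s; standard errors propagate linearly. The default
path length d = 0.535 cm corresponds to a 200 µL fill of a standard
96-well plate. **The path length of other fill volumes (e.g. the 100 µL
glutaminase screening format) is not a constant of nature and must be
configured explicitly** — the package never silently reuses 0.535 cm for
a different geometry; `AssayConstants` makes ε and d per-assay arguments.

*Automatic window selection.* "Initial quasi-linear phase" is
operationalized as: detect the end of any reporter lag as the first point
where the local slope reaches 50% of the maximum local slope, then slide a
fixed-width window (default 30% of the points) from there and keep the
window maximizing R². Both the width fraction and an explicit window are
caller-controllable; the chosen window is recorded in the result.

*Concatenated activity fit.* Replicate (E₀, v) points are pooled and
fitted through the origin, v = m′·E₀ — the model has no intercept because
v/E₀ *is* the slope. "Direct weighting" is interpreted as inverse-variance
weights w = 1/SE². For weighted fits the slope SE uses the known-variance
form 1/√(Σw·x²) (so duplicating a dataset shrinks the SE by √2, as
expected for doubled information); unweighted fits use the residual-based
SE.

## Light-regulation factors (`photoresponse`)

The LRF between two illumination states is estimated by a *global* fit in
which the activity constant of interest is shared across states and
multiplied by a per-state dummy constant D. The reference state's D is
fixed to exactly 1; the other state's fitted D ± SE is the LRF ± SE. This
yields a direct standard error for the *ratio*, which dividing two
independent fits would not.

* Linear model: y = D·m′·x, m′ shared.
* Michaelis–Menten, kcat shared: v/E₀ = D·kcat·c/(K_m,state + c); each
  state keeps its own K_m (only the shared parameter is shared — the
  nuisance parameter stays free per state, and this choice is recorded in
  the JSON output metadata under `shared_across_states`).
* K_m shared: v/E₀ = kcat_state·c/(D·K_m + c); the reference is the
  *lower*-K_m state so D ≥ 1.
* Efficiency shared: v/E₀ = D·(kcat/K_m)·c/(1 + c/K_m,state). The
  Michaelis–Menten law is reparameterized in (kcat/K_m, K_m) so the
  efficiency's SE comes directly from a fitted parameter rather than from
  error propagation.

Reference-state selection: quick independent per-state fits identify the
slower (or lower-K_m) state. When the two states are numerically
indistinguishable the tie breaks to AIS, else PSS365; whenever
|LRF − 1| ≤ SE the result is flagged `uncertain`.

Nonlinear fits use Levenberg–Marquardt (via lmfit) with multi-start over
5 log-spaced K_m initializations spanning the concentration grid, which
removes dependence on a single starting guess. Convergence tolerance is
the solver default (~1e-8); all noise-free model-class datasets are
recovered with zero residuals.

*Cycle analysis.* An alternating-irradiation run is cut at each
irradiation event; a settling gap (default 60 s, configurable) after each
event is discarded so the steady state can re-establish before the linear
refit. The LRF of each adjacent segment pair is the larger/smaller
activity ratio; with the standard three-cycle alternating design every
adjacent pair carries the same true ratio, so the per-pair series is the
natural per-cycle report. A dark-control curve, segmented at the same
times, gives the activity-drift slope vs cycle index.

## UV/vis photoswitch analytics (`uvvis`)

Azobenzene photochemistry in 310–600 nm is modeled as two Gaussian bands
in wavelength: ππ* near 330 nm (strong in the elongated E isomer) and nπ*
near 430–440 nm (weak). Spectra are baseline-corrected at 600 nm (nearest
grid point, no interpolation — likewise A(330 nm) is read at the nearest
grid point). Band count is fixed at two unless configured otherwise.

*E-fraction estimation.* For a mixture cumulative A_i and an as-isolated
(100% E) reference cumulative A_E, a candidate fraction f implies a pure-Z
spectrum A_Z = (A_i − f·A_E)/(1 − f). Pure Z carries essentially no ππ*
intensity, so f_E is the root of the ππ* amplitude of A_Z as a function of
f, located by bisection to 1e-4 — a deterministic replacement for manual
adjustment. The signed amplitude is measured by a linear amplitude-only
refit of A_Z against the reference's band shapes; the nπ* nuisance shape
is augmented with its first two center-derivatives because the Z isomer's
nπ* band need not sit exactly at the E-band position, and without that
freedom the center mismatch leaks a few-tenths-of-a-percent bias into
f_E. A_i ≈ A_E returns f_E = 1 with a singularity flag; simulated A_Z
dipping below zero sets an over-subtraction diagnostic flag. The standard
curve f_E = a·A330 + b is plain OLS (not forced through any endpoint);
predictions clamp to [0, 1].

*Switching kinetics.* PSS formation is y(t) = y_inf + A·e^(−kt) fitted to
the A(330 nm) trace, with the half-time t₁⁄₂ = ln 2/k; the declared signal
direction (decreasing for 365 nm E→Z, increasing for 420 nm Z→E) is
validated against the data's trend.

*Spectral cycles.* Per-cycle f_E values per state give min/max ranges; a
fatigue flag is raised when a state's series drifts monotonically by more
than a tolerance (default 0.05).

## Thermal melts (`thermal_melt`)

Mean residue ellipticity is MRE = θ_mdeg/(10·d_cm·c_M·N_res) — factor 10
with *molar* protein concentration; this convention is stated in the CLI
output metadata. Unfolding is the two-state Boltzmann sigmoid
y(T) = A2 + (A1 − A2)/(1 + e^((T−Tm)/dT)) with flat pre/post-transition
baselines (no sloping-baseline terms). Initialization: Tm at the
half-span crossing, dT at 5% of the scanned range; a fit is refused when
the signal never crosses half-span inside the inner 90% of the scan (no
transition in range). Tm is invariant under affine rescaling of the
signal and under curve orientation.

## Conformational landscapes (`landscape`)

Frames are projected onto named collective variables (distances in Å,
angles in degrees); the 2-D histogram of two DOFs, pooled over replicas
(each frame equal weight), normalized to unit mass, is the landscape.
−ln(p/p_max) anchored at 0 serves as a population free-energy surrogate in
kT units; no temperature conversion is applied because only probability
ratios are defended. Unoccupied bins are reported as NaN, not zero —
absence of sampling is not evidence of zero probability.

Defaults chosen where no convention exists: 60×60 bins over [min, max]
padded by 2% per axis; minima are local maxima of the box-filtered
(3×3) probability, at least 8 bins apart, carrying at least 2% of the
tallest smoothed peak (raw-occupied bins only) — the population filter
suppresses sampling-noise bumps at MD-like sample sizes. Ties break to
the lowest flat bin index. A degenerate zero-variance DOF collapses to a
unit-width axis so all frames land in one central bin (probability 1)
rather than erroring, preserving mass conservation for any input.
Representative frames minimize Euclidean distance to the minimum's bin
center in per-axis range-normalized coordinates, ties to the lowest frame
index. The closed-state fraction is the strict fraction of frames with
d1 < 15 Å.

The d2 selection ("substrate carbonyl") defaults to the carbon of the
side-chain amide carbonyl; the atom key is caller-supplied, so any
carbonyl atom can be configured.

## Synthetic data (`synthetic_data`)

Every generator is an exact member of its analysis model class at zero
noise and bit-reproducible under a fixed seed (independent generators are
salted from the master seed). Defaults encode the characterized system's
operating points: asparaginase MM datasets at kcat = 20 s⁻¹, K_m =
0.03 mM on a 0.005–2 mM grid; glutaminase at kcat = 0.37 s⁻¹, K_m =
1.1 mM on 0.05–15 mM; triplicates with 2% multiplicative noise (the SE
column is the generating dispersion, making inverse-variance weighting
exact); melt curves at Tm = 60 °C, dT = 2 °C on 25–95 °C; E/Z template
bands ππ*(330 nm, 0.8 AU, 20 nm) and nπ*(430 nm, 0.08 AU, 30 nm) for pure
E and nπ*(440 nm, 0.15 AU, 30 nm) with *zero* ππ* intensity for pure Z —
an idealization that makes the zero-ππ* stopping criterion exact by
construction; three-cycle alternating-irradiation curves with rates
switching by the published cycle LRFs (2.3 glutaminase, 1.3
asparaginase); and Markov-switching Gaussian wells with AR(1)
within-well correlation for DOF series.

Progress-curve modes cover the mechanistically interesting regimes: pure
linear; first-order reporter lag; exponentially declining activity (the
slow-inactivation signature of the glutaminase reaction), whose apparent
per-cycle activities decline near-linearly in the sampled regime; and a
stiffly integrated (LSODA, rtol 1e-8) mass-action chain
substrate → product → reporter with optional slow-binding product
inhibition.

*What passing tests do and do not show.* The generators share the exact
functional families the fitters assume — Gaussian bands, single-
exponential switching, two-state melts, Michaelis–Menten rates, Gaussian
wells. Real data add baseline drift, correlated instrument noise,
non-Gaussian band shapes (vibronic structure), auxiliary-enzyme
limitations and photobleaching, none of which are emulated. Recovery on
synthetic data therefore validates the estimators and their error
propagation, not instrument-level robustness.

## Problem sizes

The shipped tests and the acceptance script use desk-scale problems:
12-concentration triplicates (36 points) per MM fit, 1 nm spectral grids
(301–351 points), 71-point melt curves, 2–6·10⁴-frame DOF trajectories,
and three-cycle runs of ~560 points — sizes a laptop handles in seconds
and representative of the corresponding bench datasets.

## Known limitations

* The LRF's SE comes from the local covariance of the global fit;
  strongly non-Gaussian error structure would call for bootstrap or
  profile-likelihood intervals, which are not implemented.
* The E-fraction estimator assumes the reference spectrum is truly 100% E;
  a thermally incomplete reference biases f_E proportionally.
* Gaussian-in-wavelength band shapes are an approximation; deconvolution
  in energy units is not offered.
* The landscape module deliberately stops at probability surfaces: no
  Markov-state modelling, kinetics, or structural superposition.
* Binary MD trajectory formats are out of scope; convert to multi-MODEL
  PDB, XYZ or a DOF CSV first.
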