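"""Synthetic generators for every input class the analyses consume.

Each generator is an exact member of the corresponding analysis model class
at zero noise (a noise-free generated dataset is fitted with zero residuals),
and bit-reproducible under a fixed seed. Default parameters emulate the
characterized system: a tetrameric L-asparaginase photoenzyme assayed by
NADH-coupled (340 nm, ε = 6300 M⁻¹cm⁻¹) or quinoneimine-coupled (505 nm,
ε = 6400 M⁻¹cm⁻¹) reporters in 0.535 cm wells, an azobenzene side chain
with a strong ππ* band at 330 nm and a weak nπ* band near 430–440 nm, and
MD collective-variable series with metastable wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .datatypes import (AssayConstants, DOFTrajectory, IlluminationState,
                        MeltCurve, PhotostateDataset, ProgressCurve, Spectrum)

__all__ = [
    "SimConfig",
    "gen_progress_curves",
    "gen_cycle_curve",
    "gen_mm_dataset",
    "E_TEMPLATE_BANDS",
    "Z_TEMPLATE_BANDS",
    "band_spectrum",
    "gen_switch_spectra",
    "gen_pss_timecourse",
    "gen_melt_curve",
    "gen_dof_trajectory",
]


@dataclass
class SimConfig:
    """Noise levels and the master seed shared by all generators."""

    seed: int = 0
    absorbance_sd: float = 0.0    # AU, additive, progress curves
    spectral_sd: float = 0.0      # AU, additive, spectra
    rate_mult_sd: float = 0.0     # multiplicative, rate datasets

    def __post_init__(self):
        for name in ("absorbance_sd", "spectral_sd", "rate_mult_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


# ---------------------------------------------------------------------------
# progress curves
# ---------------------------------------------------------------------------

def _reporter_sign(constants: AssayConstants) -> float:
    return -1.0 if constants.direction == "decreasing" else 1.0


def gen_progress_curves(mode: str, constants: AssayConstants,
                        v: float, E0: float,
                        t_end: float = 600.0, n_points: int = 121,
                        A0: float = 1.0,
                        lag_tau: float = 60.0,
                        decline_lambda: float = 1e-3,
                        ode_params: Optional[Dict[str, float]] = None,
                        config: SimConfig = SimConfig(),
                        state: IlluminationState = IlluminationState.AIS,
                        ) -> ProgressCurve:
    """Generate one coupled-assay progress curve.

    Modes
    -----
    linear
        A(t) = A0 ± ε·d·v·t (constant rate v in µM/s).
    lagged
        First-order reporter lag τ: the observed turnover is
        v·(t − τ(1 − e^(−t/τ))), giving a flat start before the linear phase.
    exponential_decline
        Activity decays as v(t) = v·e^(−λt); the integrated product is
        (v/λ)(1 − e^(−λt}) — the slow-inactivation signature seen for the
        glutaminase reaction.
    coupled_ode
        Mass-action chain substrate →(enzyme, MM kinetics)→ product
        →(auxiliary enzyme)→ reporter, integrated stiffly (LSODA,
        rtol 1e-8), with optional slow-binding product inhibition of the
        target enzyme. ode_params keys: S0_uM, Km_mM, k_aux (s⁻¹),
        ki_on (µM⁻¹s⁻¹, default 0).
    """
    t = np.linspace(0.0, t_end, n_points)
    eps_d = constants.epsilon_d
    sign = _reporter_sign(constants)
    if mode == "linear":
        conc = v * t
    elif mode == "lagged":
        conc = v * (t - lag_tau * (1.0 - np.exp(-t / lag_tau)))
    elif mode == "exponential_decline":
        conc = v / decline_lambda * (1.0 - np.exp(-decline_lambda * t))
    elif mode == "coupled_ode":
        p = dict(S0_uM=1000.0, Km_mM=0.03, k_aux=1.0, ki_on=0.0)
        p.update(ode_params or {})
        Km_uM = p["Km_mM"] * 1e3
        vmax = v * (p["S0_uM"] + Km_uM) / p["S0_uM"]  # so initial rate == v

        def rhs(_t, yv):
            S, P, Q, f_act = yv
            if S < -1e-9:
                raise ValueError("negative substrate concentration in ODE")
            rate = vmax * max(S, 0.0) / (Km_uM + max(S, 0.0)) * f_act
            return [-rate, rate - p["k_aux"] * P, p["k_aux"] * P,
                    -p["ki_on"] * P * f_act]

        sol = solve_ivp(rhs, (0.0, t_end), [p["S0_uM"], 0.0, 0.0, 1.0],
                        t_eval=t, method="LSODA", rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        conc = sol.y[2]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    A = A0 + sign * eps_d * conc
    if config.absorbance_sd > 0:
        A = A + config.rng(1).normal(0.0, config.absorbance_sd, size=A.shape)
    return ProgressCurve(t, A, wavelength=340.0 if sign < 0 else 505.0,
                         state=state, enzyme_conc=E0)


def gen_cycle_curve(constants: AssayConstants, v_base: float, lrf: float,
                    E0: float, n_cycles: int = 3,
                    segment_duration: float = 400.0, dt: float = 5.0,
                    A0: float = 1.0, start_fast: bool = True,
                    config: SimConfig = SimConfig(),
                    ) -> Tuple[ProgressCurve, List[float], List[IlluminationState]]:
    """Simulate an alternating-irradiation cycle experiment.

    The underlying rate switches between v_base·lrf (fast) and v_base (slow)
    at each irradiation event; the progress curve is piecewise linear with
    2·n_cycles + 1 segments. Returns the curve, the event times, and the
    per-segment illumination-state labels (irradiations alternate 365/420 nm
    starting from the curve's initial state).
    """
    if lrf <= 0:
        raise ValueError("lrf must be > 0")
    n_seg = 2 * n_cycles + 1
    rates = [v_base * (lrf if (i % 2 == 0) == start_fast else 1.0)
             for i in range(n_seg)]
    seg_pts = int(round(segment_duration / dt))
    t = np.arange(n_seg * seg_pts + 1) * dt
    conc = np.zeros_like(t)
    events = []
    c0 = 0.0
    for i, r in enumerate(rates):
        lo, hi = i * seg_pts, (i + 1) * seg_pts
        t0 = t[lo]
        sl = slice(lo, hi + 1)
        conc[sl] = c0 + r * (t[sl] - t0)
        c0 = conc[hi]
        if i < n_seg - 1:
            events.append(float(t[hi]))
    A = A0 + _reporter_sign(constants) * constants.epsilon_d * conc
    if config.absorbance_sd > 0:
        A = A + config.rng(2).normal(0.0, config.absorbance_sd, size=A.shape)
    states = [IlluminationState.PSS420 if (i % 2 == 0) == start_fast
              else IlluminationState.PSS365 for i in range(n_seg)]
    curve = ProgressCurve(t, A, wavelength=340.0, state=states[0],
                          enzyme_conc=E0)
    return curve, events, states


# ---------------------------------------------------------------------------
# Michaelis–Menten datasets
# ---------------------------------------------------------------------------

def gen_mm_dataset(kcat: float, Km: float,
                   conc_grid: Sequence[float],
                   replicates: int = 3,
                   noise_sd: float = 0.0,
                   config: SimConfig = SimConfig(),
                   state: IlluminationState = IlluminationState.AIS,
                   ) -> PhotostateDataset:
    """Triplicate-style v/E0 vs substrate dataset from MM kinetics.

    Multiplicative Gaussian noise: y = kcat·c/(Km+c)·(1 + η), η ~ N(0, sd).
    The SE column is sd·(model value) — the known generating dispersion —
    so inverse-variance weighting is exact.
    """
    c = np.tile(np.asarray(conc_grid, float), replicates)
    if np.any(c <= 0):
        raise ValueError("substrate grid must be positive")
    truth = kcat * c / (Km + c)
    y = truth.copy()
    if noise_sd > 0:
        y = truth * (1.0 + config.rng(3).normal(0.0, noise_sd, size=c.shape))
    se = noise_sd * truth if noise_sd > 0 else None
    rep = np.repeat(np.arange(replicates), len(conc_grid))
    return PhotostateDataset(state=state, x=c, y=y, y_se=se,
                             replicate_id=rep, x_kind="substrate_mM")


def gen_linear_activity_dataset(m_prime: float, E0_grid: Sequence[float],
                                replicates: int = 2, noise_sd: float = 0.0,
                                config: SimConfig = SimConfig(),
                                state: IlluminationState = IlluminationState.AIS,
                                ) -> PhotostateDataset:
    """Rate vs enzyme-concentration dataset from v = m'·E0."""
    x = np.tile(np.asarray(E0_grid, float), replicates)
    truth = m_prime * x
    y = truth.copy()
    if noise_sd > 0:
        y = truth * (1.0 + config.rng(4).normal(0.0, noise_sd, size=x.shape))
    se = noise_sd * truth if noise_sd > 0 else None
    return PhotostateDataset(state=state, x=x, y=y, y_se=se, x_kind="enzyme_uM")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

# Idealized band templates (center nm, amplitude AU, width nm). The pure-Z
# template carries no ππ* intensity at all, so the zero-ππ* stopping
# criterion of the E-fraction estimator holds exactly by construction.
E_TEMPLATE_BANDS = {"pipi": (330.0, 0.80, 20.0), "npi": (430.0, 0.08, 30.0)}
Z_TEMPLATE_BANDS = {"npi": (440.0, 0.15, 30.0)}

DEFAULT_GRID = np.arange(300.0, 651.0, 1.0)


def band_spectrum(bands: Dict[str, Tuple[float, float, float]],
                  grid: np.ndarray = DEFAULT_GRID) -> np.ndarray:
    a = np.zeros_like(grid, dtype=float)
    for center, amp, width in bands.values():
        a = a + amp * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
    return a


def gen_switch_spectra(f_E: float,
                       grid: np.ndarray = DEFAULT_GRID,
                       e_bands: Dict = E_TEMPLATE_BANDS,
                       z_bands: Dict = Z_TEMPLATE_BANDS,
                       config: SimConfig = SimConfig(),
                       state: IlluminationState = IlluminationState.INTERMEDIATE,
                       cycle: Optional[int] = None,
                       ) -> Spectrum:
    """Two-component mixture spectrum A = f_E·A_E + (1 − f_E)·A_Z."""
    if not 0.0 <= f_E <= 1.0:
        raise ValueError("f_E must lie in [0, 1]")
    a = f_E * band_spectrum(e_bands, grid) + (1.0 - f_E) * band_spectrum(z_bands, grid)
    if config.spectral_sd > 0:
        a = a + config.rng(5).normal(0.0, config.spectral_sd, size=a.shape)
    return Spectrum(grid.copy(), a, state=state, cycle=cycle)


def gen_pss_timecourse(k: float, f_start: float, f_end: float,
                       times: Sequence[float],
                       grid: np.ndarray = DEFAULT_GRID,
                       config: SimConfig = SimConfig()) -> List[Spectrum]:
    """Spectra along an exponential approach to a photostationary state.

    f(t) = f_end + (f_start − f_end)·e^(−k·t); each time point yields a
    mixture spectrum tagged with its irradiation time.
    """
    out = []
    for t in np.asarray(times, float):
        f = f_end + (f_start - f_end) * np.exp(-k * t)
        s = gen_switch_spectra(f, grid=grid, config=config)
        s.irradiation_time = float(t)
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

def gen_melt_curve(A1: float, A2: float, Tm: float, dT: float,
                   grid: Sequence[float],
                   noise_sd_frac: float = 0.0,
                   config: SimConfig = SimConfig()) -> MeltCurve:
    """Boltzmann melt curve with additive noise of sd = frac·|A2 − A1|."""
    if dT <= 0:
        raise ValueError("dT must be > 0")
    T = np.asarray(grid, float)
    y = A2 + (A1 - A2) / (1.0 + np.exp((T - Tm) / dT))
    if noise_sd_frac > 0:
        y = y + config.rng(6).normal(0.0, noise_sd_frac * abs(A2 - A1),
                                     size=T.shape)
    return MeltCurve(T, y, units="mdeg")


# ---------------------------------------------------------------------------
# DOF trajectories
# ---------------------------------------------------------------------------

def gen_dof_trajectory(wells: Sequence[Dict], n_frames: int,
                       ar1_coeff: float = 0.0,
                       switch_prob: float = 0.01,
                       config: SimConfig = SimConfig(),
                       replica: str = "r0") -> DOFTrajectory:
    """Markov-switching Gaussian-well trajectory of collective variables.

    Each well is {"center": {dof: value}, "sd": {dof: value}, "weight": w}.
    Frames follow a Markov chain over wells whose stationary distribution
    matches the weights (switching probability ``switch_prob`` per frame);
    within a well, deviations from the center follow an AR(1) process with
    coefficient ``ar1_coeff`` and the stated marginal sd.
    """
    weights = np.array([w["weight"] for w in wells], float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("well weights must sum to 1")
    if not 0.0 <= ar1_coeff < 1.0:
        raise ValueError("ar1_coeff must lie in [0, 1)")
    dofs = list(wells[0]["center"].keys())
    rng = config.rng(7)
    # Markov chain: with prob switch_prob, re-draw the well from the weights
    state = int(rng.choice(len(wells), p=weights))
    states = np.empty(n_frames, dtype=int)
    for i in range(n_frames):
        if rng.random() < switch_prob:
            state = int(rng.choice(len(wells), p=weights))
        states[i] = state
    # AR(1) innovations per DOF with the stated marginal sd
    innov_scale = np.sqrt(1.0 - ar1_coeff**2)
    cols = {d: np.empty(n_frames) for d in dofs}
    dev = {d: 0.0 for d in dofs}
    for i in range(n_frames):
        w = wells[states[i]]
        for d in dofs:
            dev[d] = ar1_coeff * dev[d] + innov_scale * rng.normal(0.0, 1.0)
            cols[d][i] = w["center"][d] + w["sd"][d] * dev[d]
    df = pd.DataFrame({"frame": np.arange(n_frames), "replica": replica, **cols})
    for d in ("d1", "d2", "d3"):
        if d in df.columns:
            df[d] = df[d].clip(lower=0.0)
    if "a1" in df.columns:
        df["a1"] = df["a1"].clip(0.0, 180.0)
    return DOFTrajectory(df)
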