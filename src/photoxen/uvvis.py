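"""Photoswitch UV/vis analytics.

Azobenzene-type photoswitches show a strong ππ* band near 330 nm (dominant
in the elongated *E* isomer) and a weak nπ* band near 430–440 nm. This
module provides the standard processing chain:

* baseline correction at a reference wavelength (600 nm, outside all bands),
* exponential fits of the approach to a photostationary state (PSS) with
  the isomerization half-time t½ = ln 2 / k,
* two-Gaussian band deconvolution over 310–600 nm,
* estimation of the *E*-isomer fraction f_E of a mixed spectrum: the pure-Z
  spectrum implied by a candidate f_E,

      A_Z = (A_i − f_E · A_E) / (1 − f_E),

  must have zero ππ* amplitude (pure *Z* barely absorbs there); f_E is
  located by bisection on that amplitude,
* a linear standard curve f_E vs A(330 nm), and
* cycle analysis of alternating-irradiation spectra series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import lmfit
import numpy as np

from .datatypes import IlluminationState, Spectrum

__all__ = [
    "baseline_correct",
    "IsomerizationKinetics",
    "SwitchKineticsResults",
    "fit_isomerization_kinetics",
    "GaussianBands",
    "BandFitResults",
    "deconvolute_bands",
    "estimate_E_fraction",
    "EZEstimate",
    "FEStandardCurve",
    "build_fE_standard_curve",
    "analyze_cycles_spectra",
    "SpectralCycleResult",
]

PIPI_CENTER = 330.0   # nm, ππ* transition
NPI_CENTER = 430.0    # nm, nπ* transition
DECONV_RANGE = (310.0, 600.0)


def baseline_correct(spectrum: Spectrum, ref_wavelength: float = 600.0) -> Spectrum:
    """Subtract the absorbance at ``ref_wavelength`` from the whole spectrum.

    The reference is looked up at the nearest grid point; it must lie within
    the grid span. Afterwards A(ref) == 0.
    """
    wl = spectrum.wavelength
    if ref_wavelength < wl[0] or ref_wavelength > wl[-1]:
        raise ValueError(f"reference wavelength {ref_wavelength} nm outside grid "
                         f"[{wl[0]}, {wl[-1]}]")
    return spectrum.copy_with(spectrum.absorbance - spectrum.at(ref_wavelength))


# ---------------------------------------------------------------------------
# PSS formation kinetics
# ---------------------------------------------------------------------------

@dataclass
class SwitchKineticsResults:
    """Exponential PSS-approach fit: y(t) = y_inf + A·exp(−k·t)."""

    k: float          # s^-1
    k_se: float
    y_inf: float      # plateau
    span_A: float     # y0 − y_inf
    y0: float

    @property
    def t_half(self) -> float:
        """Isomerization half-time, ln 2 / k (s)."""
        return float(np.log(2.0) / self.k)

    def summary(self) -> str:
        return ("PSS formation kinetics\n" + "-" * 40 + "\n"
                f"k       = {self.k:.5g} +/- {self.k_se:.3g}  s^-1\n"
                f"t_1/2   = {self.t_half:.5g}  s\n"
                f"plateau = {self.y_inf:.5g}  AU\n"
                f"span    = {self.span_A:.5g}  AU")


class IsomerizationKinetics:
    """Exponential model for the approach of A(330 nm) to a photostationary state.

    ``direction`` states whether the tracked signal decreases (E→Z switching
    under 365 nm light) or increases (Z→E under 420 nm); it is validated
    against the data's overall trend.
    """

    def __init__(self, irradiation_time: np.ndarray, signal: np.ndarray,
                 direction: str = "decreasing"):
        t = np.asarray(irradiation_time, float)
        y = np.asarray(signal, float)
        if t.size < 5:
            raise ValueError("need at least 5 time points")
        if direction not in ("decreasing", "increasing"):
            raise ValueError("direction must be 'decreasing' or 'increasing'")
        trend = y[-1] - y[0]
        if direction == "decreasing" and trend > 0.05 * abs(y).max():
            raise ValueError("signal trend contradicts direction='decreasing'")
        if direction == "increasing" and trend < -0.05 * abs(y).max():
            raise ValueError("signal trend contradicts direction='increasing'")
        self.t, self.y, self.direction = t, y, direction

    def fit(self) -> SwitchKineticsResults:
        t, y = self.t, self.y
        span0 = y[0] - y[-1]
        k0 = 1.0 / max(t[-1] / 3.0, 1e-9)

        def resid(p):
            return y - (p["y_inf"] + p["A"] * np.exp(-p["k"] * t))

        params = lmfit.Parameters()
        params.add("y_inf", value=float(y[-1]))
        params.add("A", value=float(span0) if span0 != 0 else 1e-3)
        params.add("k", value=k0, min=1e-12)
        out = lmfit.minimize(resid, params, method="leastsq")
        if not out.success or out.params["k"].value <= 0:
            raise RuntimeError("isomerization kinetics fit did not converge")
        k, k_se = out.params["k"].value, out.params["k"].stderr or np.nan
        y_inf = out.params["y_inf"].value
        A = out.params["A"].value
        return SwitchKineticsResults(k=float(k), k_se=float(k_se),
                                     y_inf=float(y_inf), span_A=float(A),
                                     y0=float(y_inf + A))


def fit_isomerization_kinetics(irradiation_time, signal,
                               direction: str = "decreasing") -> SwitchKineticsResults:
    """Fit the exponential approach of the ππ* signal to its PSS plateau."""
    return IsomerizationKinetics(irradiation_time, signal, direction).fit()


# ---------------------------------------------------------------------------
# Gaussian band deconvolution
# ---------------------------------------------------------------------------

def _gauss(wl, center, amp, width):
    return amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))


@dataclass
class BandFitResults:
    """Two-Gaussian deconvolution of a photoswitch spectrum."""

    bands: Dict[str, Dict[str, float]]   # {"pipi": {center, amplitude, width}, "npi": ...}
    wavelength: np.ndarray
    cumulative: np.ndarray
    rss: float

    @property
    def pipi_amplitude(self) -> float:
        return self.bands["pipi"]["amplitude"]

    def as_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelength, self.cumulative)

    def band_curve(self, name: str) -> np.ndarray:
        b = self.bands[name]
        return _gauss(self.wavelength, b["center"], b["amplitude"], b["width"])

    def summary(self) -> str:
        lines = ["Gaussian band deconvolution", "-" * 44]
        for name, b in self.bands.items():
            lines.append(f"{name:5s}: center {b['center']:7.2f} nm   "
                         f"amp {b['amplitude']:8.4g} AU   width {b['width']:6.2f} nm")
        lines.append(f"RSS = {self.rss:.4g} AU^2")
        return "\n".join(lines)


class GaussianBands:
    """Sum-of-two-Gaussians model for the ππ*/nπ* region (310–600 nm)."""

    def __init__(self, spectrum: Spectrum,
                 fit_range: Tuple[float, float] = DECONV_RANGE):
        wl = spectrum.wavelength
        if fit_range[0] < wl[0] or fit_range[1] > wl[-1]:
            raise ValueError("fit range must lie within the wavelength grid")
        mask = (wl >= fit_range[0]) & (wl <= fit_range[1])
        self.wl = wl[mask]
        self.a = spectrum.absorbance[mask]
        self.fit_range = fit_range

    def fit(self) -> BandFitResults:
        wl, a = self.wl, self.a

        def resid(p):
            model = (_gauss(wl, p["c1"], p["a1"], p["w1"])
                     + _gauss(wl, p["c2"], p["a2"], p["w2"]))
            return a - model

        amax = float(np.max(np.abs(a))) or 1.0
        params = lmfit.Parameters()
        params.add("c1", value=PIPI_CENTER, min=self.fit_range[0], max=390)
        params.add("a1", value=float(a[np.argmin(np.abs(wl - PIPI_CENTER))]) or 0.5 * amax)
        params.add("w1", value=20.0, min=1.0, max=120.0)
        params.add("c2", value=NPI_CENTER, min=390, max=self.fit_range[1])
        params.add("a2", value=float(a[np.argmin(np.abs(wl - NPI_CENTER))]) or 0.1 * amax)
        params.add("w2", value=30.0, min=1.0, max=150.0)
        out = lmfit.minimize(resid, params, method="leastsq")
        if not out.success:
            raise RuntimeError(f"band deconvolution did not converge "
                               f"(residual {out.chisqr:.3g})")
        p = out.params
        bands = {
            "pipi": {"center": p["c1"].value, "amplitude": p["a1"].value,
                     "width": p["w1"].value},
            "npi": {"center": p["c2"].value, "amplitude": p["a2"].value,
                    "width": p["w2"].value},
        }
        cumulative = (_gauss(wl, **{"center": p["c1"].value, "amp": p["a1"].value,
                                    "width": p["w1"].value})
                      + _gauss(wl, center=p["c2"].value, amp=p["a2"].value,
                               width=p["w2"].value))
        return BandFitResults(bands=bands, wavelength=wl, cumulative=cumulative,
                              rss=float(out.chisqr))


def deconvolute_bands(spectrum: Spectrum,
                      fit_range: Tuple[float, float] = DECONV_RANGE) -> BandFitResults:
    """Deconvolute the ππ* and nπ* bands with two Gaussians."""
    return GaussianBands(spectrum, fit_range).fit()


# ---------------------------------------------------------------------------
# E-fraction estimation
# ---------------------------------------------------------------------------

@dataclass
class EZEstimate:
    f_E: float
    method: str = "eq_direct"
    reference_id: str = ""
    negative_AZ: bool = False    # simulated pure-Z spectrum dips below zero
    at_singularity: bool = False  # A_i indistinguishable from A_E (f_E -> 1)

    @property
    def percent_E(self) -> float:
        return 100.0 * self.f_E


def _pipi_amplitude_on(shapes: np.ndarray, a: np.ndarray) -> float:
    """Signed ππ* amplitude of ``a`` by linear refit on fixed band shapes."""
    coef, *_ = np.linalg.lstsq(shapes, a, rcond=None)
    return float(coef[0])


def estimate_E_fraction(mixture: BandFitResults, reference: BandFitResults,
                        tol: float = 1e-4, reference_id: str = "AIS",
                        ) -> EZEstimate:
    """Estimate the *E*-isomer fraction of a mixed spectrum.

    ``mixture`` and ``reference`` are the cumulative band fits of the
    spectrum in question (A_i) and of the as-isolated 100%-E reference
    (A_E), on identical grids. For a candidate f_E the implied pure-Z
    spectrum A_Z = (A_i − f_E·A_E)/(1 − f_E) is formed and its ππ*
    amplitude measured by an amplitude-only refit against the reference's
    band shapes; the f_E at which that amplitude crosses zero is found by
    bisection (resolution ``tol``), replacing manual adjustment with a
    deterministic root search.
    """
    if mixture.wavelength.shape != reference.wavelength.shape or \
            not np.allclose(mixture.wavelength, reference.wavelength):
        raise ValueError("mixture and reference must share the wavelength grid")
    wl = reference.wavelength
    A_i, A_E = mixture.cumulative, reference.cumulative
    amp_E = reference.pipi_amplitude
    if amp_E <= 0:
        raise ValueError("reference spectrum has no positive ππ* amplitude")

    # band shapes from the reference deconvolution; the nπ* nuisance band is
    # allowed to shift and re-shape locally (first/second center derivatives)
    # because the Z isomer's nπ* band need not sit exactly at the E position
    c_n, w_n = reference.bands["npi"]["center"], reference.bands["npi"]["width"]
    g_npi = _gauss(wl, c_n, 1.0, w_n)
    shapes = np.column_stack([
        _gauss(wl, reference.bands["pipi"]["center"], 1.0,
               reference.bands["pipi"]["width"]),
        g_npi,
        (wl - c_n) / w_n**2 * g_npi,
        ((wl - c_n) ** 2 / w_n**4 - 1.0 / w_n**2) * g_npi,
    ])

    # near-singular case: the mixture is (numerically) the reference
    if np.max(np.abs(A_i - A_E)) <= 1e-6 * max(np.max(np.abs(A_E)), 1e-12):
        return EZEstimate(1.0, reference_id=reference_id, at_singularity=True)

    def pipi_of(f):
        A_Z = (A_i - f * A_E) / (1.0 - f)
        return _pipi_amplitude_on(shapes, A_Z)

    lo, hi = 0.0, 1.0 - 1e-9
    g_lo, g_hi = pipi_of(lo), pipi_of(hi)
    if g_lo <= tol * amp_E:      # already (numerically) Z-pure
        return EZEstimate(0.0, reference_id=reference_id)
    if g_lo * g_hi > 0:
        raise ValueError("no sign change of the ππ* amplitude in [0, 1); "
                         "cannot estimate f_E")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pipi_of(mid) > 0:
            lo = mid
        else:
            hi = mid
    f = 0.5 * (lo + hi)
    A_Z = (A_i - f * A_E) / (1.0 - f)
    return EZEstimate(float(np.clip(f, 0.0, 1.0)), reference_id=reference_id,
                      negative_AZ=bool(np.min(A_Z) < -tol))


# ---------------------------------------------------------------------------
# standard curve
# ---------------------------------------------------------------------------

@dataclass
class FEStandardCurve:
    """Linear standard curve f_E = a·A330 + b, fitted by ordinary LS."""

    a: float
    b: float
    a_se: float
    b_se: float

    def predict(self, A330) -> np.ndarray:
        """Predicted f_E, clamped to [0, 1]."""
        return np.clip(self.a * np.asarray(A330, float) + self.b, 0.0, 1.0)


def build_fE_standard_curve(f_E: Sequence[float],
                            A330: Sequence[float]) -> FEStandardCurve:
    """Fit the linear standard curve relating f_E estimates to A(330 nm)."""
    f = np.asarray(f_E, float)
    x = np.asarray(A330, float)
    if np.unique(x).size < 2:
        raise ValueError("rank deficiency: need at least 2 distinct A330 values")
    X = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(X, f, rcond=None)
    resid = f - X @ coef
    dof = x.size - 2
    if dof > 0:
        s2 = np.sum(resid**2) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        a_se, b_se = np.sqrt(np.diag(cov))
    else:
        a_se = b_se = 0.0
    return FEStandardCurve(float(coef[0]), float(coef[1]), float(a_se), float(b_se))


# ---------------------------------------------------------------------------
# spectral cycle analysis
# ---------------------------------------------------------------------------

@dataclass
class SpectralCycleResult:
    per_cycle: List[Dict]                 # {"cycle", "state", "f_E", "A330"}
    state_ranges: Dict[str, Tuple[float, float]]
    fatigue: bool


def analyze_cycles_spectra(spectra: Sequence[Spectrum],
                           reference: Optional[Spectrum] = None,
                           method: str = "eq_direct",
                           fatigue_tolerance: float = 0.05,
                           ) -> SpectralCycleResult:
    """Track the E-fraction through alternating-irradiation cycles.

    Each spectrum must carry ``cycle`` and ``state`` labels. The reference
    (100% E, as-isolated) spectrum is either passed explicitly or found
    among the inputs by its AIS state label. f_E per spectrum comes from the
    band-deconvolution estimator; per-state min/max ranges are reported, and
    a fatigue flag is raised when a state's f_E series drifts monotonically
    by more than ``fatigue_tolerance``.
    """
    if reference is None:
        ais = [s for s in spectra if s.state == IlluminationState.AIS]
        if not ais:
            raise ValueError("no reference: supply an AIS spectrum")
        reference = ais[0]
    ref_fit = deconvolute_bands(baseline_correct(reference))

    rows = []
    for s in spectra:
        if s.cycle is None:
            raise ValueError("every spectrum needs a cycle label")
        fit = deconvolute_bands(baseline_correct(s))
        est = estimate_E_fraction(fit, ref_fit)
        rows.append({"cycle": int(s.cycle), "state": s.state.value,
                     "f_E": est.f_E, "A330": s.at(PIPI_CENTER)})
    rows.sort(key=lambda r: (r["cycle"], r["state"]))

    by_state: Dict[str, List[float]] = {}
    for r in rows:
        by_state.setdefault(r["state"], []).append(r["f_E"])
    ranges = {st: (float(np.min(v)), float(np.max(v))) for st, v in by_state.items()}

    fatigue = False
    for vals in by_state.values():
        if len(vals) >= 3:
            diffs = np.diff(vals)
            monotone = np.all(diffs >= 0) or np.all(diffs <= 0)
            if monotone and abs(vals[-1] - vals[0]) > fatigue_tolerance:
                fatigue = True
    return SpectralCycleResult(per_cycle=rows, state_ranges=ranges, fatigue=fatigue)
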