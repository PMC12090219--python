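"""Initial-rate extraction from coupled-assay progress curves.

A coupled enzymatic assay reports substrate turnover through an optical
reporter (NADH depletion at 340 nm, or quinoneimine formation at 505 nm).
The initial quasi-linear phase of the absorbance time course is fitted with
ordinary least squares; the Lambert–Beer law converts the slope m (AU/s)
into a molar rate

    v = |m| / (ε · d)          [µM/s]

and division by the enzyme concentration E0 gives the normalized activity
v/E0 (s⁻¹). Replicate rates measured at several enzyme concentrations are
combined by a weighted regression through the origin whose slope is v/E0.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .datatypes import AssayConstants, PhotostateDataset, ProgressCurve, RateResult

__all__ = [
    "fit_linear_phase",
    "slope_to_rate",
    "fit_activity_vs_concentration",
    "weighted_origin_fit",
]

MIN_POINTS = 5


def _ols_slope(t: np.ndarray, a: np.ndarray) -> Tuple[float, float, float]:
    """OLS slope, its standard error and R² for a straight-line fit."""
    n = t.size
    tbar, abar = t.mean(), a.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx == 0:
        raise ValueError("degenerate input: zero time variance in window")
    sxy = np.sum((t - tbar) * (a - abar))
    slope = sxy / sxx
    intercept = abar - slope * tbar
    resid = a - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((a - abar) ** 2))
    dof = n - 2
    se = np.sqrt(ss_res / dof / sxx) if dof > 0 else np.nan
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(se), float(r2)


def _auto_window(t: np.ndarray, a: np.ndarray, width_frac: float = 0.3) -> Tuple[int, int]:
    """Select the steady quasi-linear phase of a progress curve.

    A reporter lag is detected from local slopes (the first point where the
    local slope magnitude reaches 50% of the maximum local slope); a fixed-
    width window (default 30% of the points) sliding from there is chosen to
    maximize R².
    """
    n = t.size
    width = max(MIN_POINTS, int(round(width_frac * n)))
    # local slopes over short chunks to find the end of any lag phase
    k = max(3, n // 20)
    local = np.array([
        _ols_slope(t[i:i + k], a[i:i + k])[0] for i in range(0, n - k + 1)
    ])
    thresh = 0.5 * np.max(np.abs(local))
    above = np.nonzero(np.abs(local) >= thresh)[0]
    start0 = int(above[0]) if above.size else 0
    best = (-np.inf, start0)
    for s in range(start0, n - width + 1):
        _, _, r2 = _ols_slope(t[s:s + width], a[s:s + width])
        if r2 > best[0]:
            best = (r2, s)
    s = best[1]
    return s, s + width


def fit_linear_phase(curve: ProgressCurve,
                     window: Optional[Tuple[float, float]] = None,
                     width_frac: float = 0.3) -> RateResult:
    """Fit the initial quasi-linear phase of a progress curve by OLS.

    Parameters
    ----------
    curve : ProgressCurve
    window : (t_start, t_end) in seconds, optional
        Explicit fit window. When omitted, an automatic window is chosen:
        a fixed-width window (``width_frac`` of the points) maximizing R²,
        anchored after a detected reporter lag.

    Returns
    -------
    RateResult with slope ± SE, the window actually used and R².
    """
    t, a = curve.time, curve.absorbance
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, a = t[mask], a[mask]
        if t.size < MIN_POINTS:
            raise ValueError(f"fewer than {MIN_POINTS} points in window")
        slope, se, r2 = _ols_slope(t, a)
        return RateResult(slope, se, (float(t[0]), float(t[-1])), r2)
    if t.size < MIN_POINTS:
        raise ValueError(f"fewer than {MIN_POINTS} points in curve")
    i0, i1 = _auto_window(t, a, width_frac)
    slope, se, r2 = _ols_slope(t[i0:i1], a[i0:i1])
    return RateResult(slope, se, (float(t[i0]), float(t[i1 - 1])), r2)


def slope_to_rate(slope: float, slope_se: float, constants: AssayConstants,
                  E0: Optional[float] = None,
                  window: Tuple[float, float] = (np.nan, np.nan),
                  r_squared: float = np.nan) -> RateResult:
    """Convert an absorbance slope into a molar rate via Lambert–Beer.

    v = |slope| / (ε·d), in µM/s; the SE propagates linearly. When the
    enzyme concentration ``E0`` (µM) is given, the normalized activity
    v/E0 (s⁻¹) is included.
    """
    eps_d = constants.epsilon_d  # AU per µM
    v = abs(slope) / eps_d
    v_se = abs(slope_se) / eps_d
    res = RateResult(slope, slope_se, window, r_squared, v=v, v_se=v_se)
    if E0 is not None:
        if E0 <= 0:
            raise ValueError("E0 must be > 0 for normalization")
        res.v_over_E0 = v / E0
        res.v_over_E0_se = v_se / E0
    return res


def subtract_dark_control(curve: ProgressCurve,
                          dark: ProgressCurve) -> ProgressCurve:
    """Subtract a dark-control (non-irradiated blank) curve pointwise.

    Removes shared baseline drift. Both curves must be sampled on the same
    time grid; this correction is opt-in, not applied by default.
    """
    if curve.time.shape != dark.time.shape or \
            not np.allclose(curve.time, dark.time):
        raise ValueError("dark control must share the curve's time grid")
    return ProgressCurve(curve.time, curve.absorbance - dark.absorbance,
                         curve.wavelength, curve.well_id, curve.state,
                         curve.enzyme_conc, curve.assay)


def rate_from_curve(curve: ProgressCurve, constants: AssayConstants,
                    window: Optional[Tuple[float, float]] = None,
                    dark_control: Optional[ProgressCurve] = None) -> RateResult:
    """Convenience: linear-phase fit followed by Lambert–Beer conversion."""
    if dark_control is not None:
        curve = subtract_dark_control(curve, dark_control)
    lin = fit_linear_phase(curve, window)
    return slope_to_rate(lin.slope_m, lin.slope_se, constants,
                         E0=curve.enzyme_conc, window=lin.window,
                         r_squared=lin.r_squared)


def weighted_origin_fit(x: np.ndarray, y: np.ndarray,
                        weights: Optional[np.ndarray] = None) -> Tuple[float, float]:
    """Weighted least-squares slope of y = m·x through the origin.

    With inverse-variance weights w = 1/σ² the slope is Σwxy/Σwx² and its
    standard error 1/sqrt(Σwx²) (known-variance form). Unweighted fits use
    the residual-based SE instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 2:
        raise ValueError("rank deficiency: need at least 2 distinct x values")
    if weights is not None:
        w = np.asarray(weights, float)
        sxx = np.sum(w * x * x)
        m = np.sum(w * x * y) / sxx
        se = 1.0 / np.sqrt(sxx)
        return float(m), float(se)
    sxx = np.sum(x * x)
    m = np.sum(x * y) / sxx
    resid = y - m * x
    dof = x.size - 1
    se = np.sqrt(np.sum(resid**2) / dof / sxx) if dof > 0 else 0.0
    return float(m), float(se)


def fit_activity_vs_concentration(E0: Sequence[float], v: Sequence[float],
                                  v_se: Optional[Sequence[float]] = None,
                                  ) -> Tuple[float, float]:
    """Concatenated rate-vs-enzyme-concentration fit through the origin.

    All replicate (E0, v) points — the screening-style dataset — are pooled
    and fitted with v = m'·E0, weighted by 1/SE² when standard errors are
    supplied. The slope m' is the normalized activity v/E0 (s⁻¹).

    Returns
    -------
    (m_prime, se) in s⁻¹.
    """
    E0 = np.asarray(E0, float)
    v = np.asarray(v, float)
    weights = None
    if v_se is not None:
        v_se = np.asarray(v_se, float)
        if np.any(v_se <= 0):
            raise ValueError("all SE must be > 0 for weighting")
        weights = 1.0 / v_se**2
    return weighted_origin_fit(E0, v, weights)


def dataset_activity(dataset: PhotostateDataset) -> Tuple[float, float]:
    """fit_activity_vs_concentration applied to a PhotostateDataset."""
    return fit_activity_vs_concentration(dataset.x, dataset.y, dataset.y_se)
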