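"""CD melt-curve normalization and Boltzmann denaturation fits.

Thermal unfolding followed by circular dichroism at a single wavelength is
summarized by a two-state Boltzmann sigmoid

    y(T) = A2 + (A1 − A2) / (1 + exp((T − Tm)/dT)),

where A1 and A2 are the pre- and post-transition signal plateaus, Tm the
denaturation midpoint and dT the transition slope parameter. At T = Tm the
model passes exactly through (A1 + A2)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .datatypes import MeltCurve

__all__ = ["normalize_mre", "BoltzmannMelt", "BoltzmannFitResults",
           "fit_boltzmann", "boltzmann"]


def normalize_mre(curve: MeltCurve) -> MeltCurve:
    """Convert raw ellipticity (mdeg) into mean residue ellipticity.

    MRE = θ_mdeg / (10 · path_cm · conc_M · n_residues), in
    deg·cm²·dmol⁻¹; the factor 10 with molar protein concentration is the
    convention used throughout (recorded in output metadata).
    """
    if curve.units != "mdeg":
        raise ValueError(f"expected raw mdeg signal, got units={curve.units!r}")
    for name in ("protein_conc_M", "n_residues", "path_cm"):
        val = getattr(curve, name)
        if val is None or val <= 0:
            raise ValueError(f"missing or non-positive metadata: {name}")
    factor = 10.0 * curve.path_cm * curve.protein_conc_M * curve.n_residues
    return MeltCurve(curve.temperature.copy(), curve.signal / factor,
                     units="deg_cm2_dmol", protein_conc_M=curve.protein_conc_M,
                     n_residues=curve.n_residues, path_cm=curve.path_cm)


def boltzmann(T, A1, A2, Tm, dT):
    """Two-state Boltzmann sigmoid; A1 is the low-temperature plateau."""
    return A2 + (A1 - A2) / (1.0 + np.exp((np.asarray(T, float) - Tm) / dT))


@dataclass
class BoltzmannFitResults:
    A1: float
    A2: float
    Tm: float        # °C
    Tm_se: float
    dT: float        # °C
    dT_se: float
    redchi: float

    def predict(self, T):
        return boltzmann(T, self.A1, self.A2, self.Tm, self.dT)

    def summary(self) -> str:
        return ("Boltzmann melt fit\n" + "-" * 40 + "\n"
                f"Tm = {self.Tm:.3f} +/- {self.Tm_se:.3g} degC\n"
                f"dT = {self.dT:.3f} +/- {self.dT_se:.3g} degC\n"
                f"A1 (low-T plateau)  = {self.A1:.5g}\n"
                f"A2 (high-T plateau) = {self.A2:.5g}\n"
                f"red. chi-square = {self.redchi:.4g}")


class BoltzmannMelt:
    """Boltzmann sigmoid model for a thermal denaturation curve.

    The fit requires a visible transition: the signal must span both
    plateaus (checked by requiring that the half-span crossing lies inside
    the inner 90% of the temperature range). Initialization: Tm at the
    half-span crossing, dT = 5% of the temperature span.
    """

    def __init__(self, curve: MeltCurve):
        if len(curve.temperature) < 10:
            raise ValueError("need at least 10 temperature points")
        self.curve = curve

    def fit(self) -> BoltzmannFitResults:
        T, y = self.curve.temperature, self.curve.signal
        span = y.max() - y.min()
        if span == 0:
            raise ValueError("no transition detected: flat signal")
        half = 0.5 * (y.max() + y.min())
        cross = np.nonzero(np.diff(np.sign(y - half)) != 0)[0]
        if cross.size == 0:
            raise ValueError("no transition detected: signal never crosses half-span")
        Tm0 = float(T[cross[0]])
        lo, hi = T.min(), T.max()
        if not (lo + 0.05 * (hi - lo) < Tm0 < hi - 0.05 * (hi - lo)):
            raise ValueError("no transition detected within the scanned range")

        def resid(p):
            return y - boltzmann(T, p["A1"], p["A2"], p["Tm"], p["dT"])

        params = lmfit.Parameters()
        params.add("A1", value=float(y[0]))
        params.add("A2", value=float(y[-1]))
        params.add("Tm", value=Tm0, min=lo, max=hi)
        params.add("dT", value=0.05 * (hi - lo), min=1e-6)
        out = lmfit.minimize(resid, params, method="leastsq")
        if not out.success:
            raise RuntimeError("Boltzmann fit did not converge")
        p = out.params
        return BoltzmannFitResults(
            A1=float(p["A1"].value), A2=float(p["A2"].value),
            Tm=float(p["Tm"].value), Tm_se=float(p["Tm"].stderr or np.nan),
            dT=float(p["dT"].value), dT_se=float(p["dT"].stderr or np.nan),
            redchi=float(out.redchi),
        )


def fit_boltzmann(curve: MeltCurve) -> BoltzmannFitResults:
    """Fit the Boltzmann sigmoid to a melt curve and report Tm ± SE."""
    return BoltzmannMelt(curve).fit()
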