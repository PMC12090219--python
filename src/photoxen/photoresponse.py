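"""Light-regulation-factor (LRF) global fits and photostate kinetics.

The central statistic of photoenzyme characterization is the light
regulation factor: the fold change of an activity constant (v/E0, kcat,
Km or kcat/Km) between two illumination states. Rather than dividing two
independently fitted constants, both states are fitted globally with the
constant of interest shared and multiplied by a per-state dummy constant D;
the D of the reference (slower, or lower-Km) state is fixed to 1, so the
fitted D ± SE of the other state is directly the LRF ± SE.

Two model classes are supported:

* linear activity data, v = D·m'·E0 (rate vs enzyme concentration), and
* Michaelis–Menten data, v/E0 = D·kcat·c/(Km + c) (rate vs substrate),
  with the shared parameter being kcat, Km or the efficiency kcat/Km.

All fits use inverse-variance weighting when standard errors are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import lmfit
import numpy as np

from .assay_kinetics import fit_linear_phase, slope_to_rate, weighted_origin_fit
from .datatypes import (AssayConstants, IlluminationState, PhotostateDataset,
                        ProgressCurve)

__all__ = [
    "MichaelisMenten",
    "MichaelisMentenResults",
    "LightRegulation",
    "LightRegulationResults",
    "fit_michaelis_menten",
    "fit_lrf_linear",
    "fit_lrf_mm",
    "analyze_cycles_activity",
    "CycleActivityResult",
]

# Order of preference when two states are statistically indistinguishable:
# fix the dummy constant on the as-isolated state first.
_STATE_PREFERENCE = [IlluminationState.AIS, IlluminationState.PSS365,
                     IlluminationState.PSS420]


def _mm(c, kcat, Km):
    return kcat * c / (Km + c)


def _param_tuple(par: lmfit.Parameter) -> Tuple[float, float]:
    se = par.stderr if par.stderr is not None else np.nan
    return float(par.value), float(se)


@dataclass
class MichaelisMentenResults:
    """Results of a concatenated weighted Michaelis–Menten fit."""

    kcat: float
    kcat_se: float
    Km: float                 # mM
    Km_se: float
    kcat_over_Km: float       # s^-1 M^-1
    kcat_over_Km_se: float
    redchi: float
    nobs: int
    state: IlluminationState

    def summary(self) -> str:
        lines = [
            f"Michaelis-Menten fit  [{self.state.value}]  (n = {self.nobs})",
            "-" * 52,
            f"kcat     = {self.kcat:12.5g} +/- {self.kcat_se:.3g}  s^-1",
            f"Km       = {self.Km:12.5g} +/- {self.Km_se:.3g}  mM",
            f"kcat/Km  = {self.kcat_over_Km:12.5g} +/- {self.kcat_over_Km_se:.3g}  s^-1 M^-1",
            f"red. chi-square = {self.redchi:.4g}",
        ]
        return "\n".join(lines)


class MichaelisMenten:
    """Michaelis–Menten model for one illumination state's rate data.

    Built from a :class:`PhotostateDataset` whose x are substrate
    concentrations (mM) and y normalized activities v/E0 (s⁻¹), typically
    concatenated triplicates. ``fit()`` performs a weighted Levenberg–
    Marquardt fit of v/E0 = kcat·c/(Km + c), multi-started over log-spaced
    Km initializations, and then refits the reparameterized form
    v/E0 = (kcat/Km)·c / (1 + c/Km) so the catalytic efficiency's SE comes
    directly from a fitted parameter.
    """

    N_STARTS = 5

    def __init__(self, dataset: PhotostateDataset):
        if len(dataset) < 3:
            raise ValueError("need at least 3 points for a Michaelis-Menten fit")
        if np.unique(dataset.x).size < 5:
            raise ValueError("need >= 5 distinct substrate concentrations")
        if np.any(dataset.x <= 0):
            raise ValueError("substrate concentrations must be positive")
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, df, state=None) -> "MichaelisMenten":
        """Build from a tidy frame with columns substrate_mM, v_over_E0 [, se, state]."""
        if state is not None:
            df = df[df["state"] == str(getattr(state, "value", state))]
        se = df["se"].to_numpy() if "se" in df.columns else None
        st = df["state"].iloc[0] if "state" in df.columns else IlluminationState.AIS
        return cls(PhotostateDataset(state=st, x=df["substrate_mM"].to_numpy(),
                                     y=df["v_over_E0"].to_numpy(), y_se=se))

    def _weights_sqrt(self) -> Optional[np.ndarray]:
        w = self.dataset.weights
        return None if w is None else np.sqrt(w)

    def fit(self) -> MichaelisMentenResults:
        c, y = self.dataset.x, self.dataset.y
        sw = self._weights_sqrt()

        def resid(params):
            r = y - _mm(c, params["kcat"], params["Km"])
            return r if sw is None else r * sw

        best = None
        for Km0 in np.geomspace(c.min(), c.max(), self.N_STARTS):
            params = lmfit.Parameters()
            params.add("kcat", value=float(np.max(y)), min=0)
            params.add("Km", value=float(Km0), min=0)
            out = lmfit.minimize(resid, params, method="leastsq")
            if best is None or out.chisqr < best.chisqr:
                best = out
        if best is None or not best.success:
            raise RuntimeError("Michaelis-Menten fit did not converge")
        kcat, kcat_se = _param_tuple(best.params["kcat"])
        Km, Km_se = _param_tuple(best.params["Km"])

        # efficiency from the reparameterized fit (eff = kcat/Km, per mM)
        def resid_eff(params):
            r = y - params["eff"] * c / (1.0 + c / params["Km"])
            return r if sw is None else r * sw

        params = lmfit.Parameters()
        params.add("eff", value=kcat / Km, min=0)
        params.add("Km", value=Km, min=0)
        out_eff = lmfit.minimize(resid_eff, params, method="leastsq")
        eff, eff_se = _param_tuple(out_eff.params["eff"])
        if not np.isfinite(eff_se):
            eff_se = eff * np.hypot(kcat_se / kcat, Km_se / Km) if kcat and Km else np.nan

        return MichaelisMentenResults(
            kcat=kcat, kcat_se=kcat_se, Km=Km, Km_se=Km_se,
            kcat_over_Km=eff * 1e3, kcat_over_Km_se=eff_se * 1e3,
            redchi=float(best.redchi), nobs=len(self.dataset),
            state=self.dataset.state,
        )


def fit_michaelis_menten(dataset: PhotostateDataset) -> MichaelisMentenResults:
    """Concatenated weighted Michaelis–Menten fit of one state's triplicates."""
    return MichaelisMenten(dataset).fit()


@dataclass
class LightRegulationResults:
    """Global dummy-constant fit results.

    ``lrf`` equals the fitted D of the non-reference state; the reference
    state's D is fixed at exactly 1, so lrf >= 1 by construction (for the
    Km target, "faster" means the higher-Km state).
    """

    shared_name: str
    shared_value: float
    shared_se: float
    D: float
    D_se: float
    reference_state: IlluminationState
    fast_state: IlluminationState
    comparison: Tuple[IlluminationState, IlluminationState]
    free_params: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    uncertain: bool = False
    redchi: float = np.nan

    @property
    def lrf(self) -> float:
        return self.D

    @property
    def lrf_se(self) -> float:
        return self.D_se

    def summary(self) -> str:
        a, b = self.comparison
        lines = [
            f"Light-regulation global fit  ({a.value} vs {b.value})",
            "-" * 52,
            f"shared {self.shared_name:10s} = {self.shared_value:.5g} +/- {self.shared_se:.3g}",
            f"D ({self.fast_state.value}, reference {self.reference_state.value} fixed at 1)"
            f" = {self.D:.5g} +/- {self.D_se:.3g}",
            f"LRF = {self.lrf:.4g} +/- {self.lrf_se:.3g}"
            + ("   [uncertain: |LRF-1| < SE]" if self.uncertain else ""),
        ]
        for name, (v, se) in self.free_params.items():
            lines.append(f"  free {name:14s} = {v:.5g} +/- {se:.3g}")
        return "\n".join(lines)


def _prefer(state_a: IlluminationState, state_b: IlluminationState) -> IlluminationState:
    """Tie-break: which of two indistinguishable states carries D = 1."""
    for s in _STATE_PREFERENCE:
        if s in (state_a, state_b):
            return s
    return state_a


class LightRegulation:
    """Global dummy-constant model for the LRF between two illumination states.

    Parameters
    ----------
    datasets : pair of PhotostateDataset
        The two states to compare, with identical x/y semantics.
    kind : {"linear", "mm"}
        "linear": y = D·m'·x (rate vs enzyme concentration, m' shared).
        "mm": Michaelis–Menten data with the ``target`` parameter shared.
    target : {"kcat", "Km", "kcat_over_Km"}
        Shared parameter for the "mm" kind; the other MM parameter stays
        free per state.
    """

    def __init__(self, datasets: Sequence[PhotostateDataset], kind: str = "linear",
                 target: str = "kcat"):
        if len(datasets) != 2:
            raise ValueError("exactly two photostate datasets are required")
        if kind not in ("linear", "mm"):
            raise ValueError("kind must be 'linear' or 'mm'")
        if target not in ("kcat", "Km", "kcat_over_Km"):
            raise ValueError("target must be kcat, Km or kcat_over_Km")
        for ds in datasets:
            if len(ds) == 0:
                raise ValueError("empty photostate dataset")
            if np.all(ds.y == 0):
                raise ValueError(f"unidentifiable: all-zero activities in state {ds.state.value}")
        self.datasets = list(datasets)
        self.kind = kind
        self.target = target

    # -- reference-state selection -------------------------------------
    def _independent_values(self) -> List[float]:
        vals = []
        for ds in self.datasets:
            if self.kind == "linear":
                m, _ = weighted_origin_fit(ds.x, ds.y, ds.weights)
                vals.append(m)
            else:
                r = MichaelisMenten(ds).fit()
                vals.append({"kcat": r.kcat, "Km": r.Km,
                             "kcat_over_Km": r.kcat_over_Km}[self.target])
        return vals

    def _reference_index(self, vals: List[float]) -> int:
        # reference = slower state (lower value); for Km it is the lower-Km
        # state, which the same rule delivers.
        if np.isclose(vals[0], vals[1], rtol=1e-12, atol=1e-15):
            pref = _prefer(self.datasets[0].state, self.datasets[1].state)
            return 0 if self.datasets[0].state == pref else 1
        return int(np.argmin(vals))

    # -- fitting --------------------------------------------------------
    def fit(self) -> LightRegulationResults:
        ref = self._reference_index(self._independent_values())
        other = 1 - ref
        if self.kind == "linear":
            return self._fit_linear(ref, other)
        return self._fit_mm(ref, other)

    def _fit_linear(self, ref: int, other: int) -> LightRegulationResults:
        ds_r, ds_o = self.datasets[ref], self.datasets[other]
        sw_r = None if ds_r.weights is None else np.sqrt(ds_r.weights)
        sw_o = None if ds_o.weights is None else np.sqrt(ds_o.weights)

        m0, _ = weighted_origin_fit(ds_r.x, ds_r.y, ds_r.weights)

        def resid(params):
            r1 = ds_r.y - params["m_prime"] * ds_r.x
            r2 = ds_o.y - params["D"] * params["m_prime"] * ds_o.x
            if sw_r is not None:
                r1 = r1 * sw_r
            if sw_o is not None:
                r2 = r2 * sw_o
            return np.concatenate([r1, r2])

        params = lmfit.Parameters()
        params.add("m_prime", value=m0 if m0 != 0 else 1.0)
        params.add("D", value=1.0, min=0)
        out = lmfit.minimize(resid, params, method="leastsq")
        m, m_se = _param_tuple(out.params["m_prime"])
        D, D_se = _param_tuple(out.params["D"])
        return self._package(out, "m_prime", m, m_se, D, D_se, ref, other, {})

    def _fit_mm(self, ref: int, other: int) -> LightRegulationResults:
        ds_r, ds_o = self.datasets[ref], self.datasets[other]
        fits = [MichaelisMenten(ds).fit() for ds in (ds_r, ds_o)]
        sws = [None if ds.weights is None else np.sqrt(ds.weights)
               for ds in (ds_r, ds_o)]

        def model_state(params, c, i):
            D = 1.0 if i == 0 else params["D"]
            if self.target == "kcat":
                return D * params["kcat"] * c / (params[f"Km_{i}"] + c)
            if self.target == "Km":
                return params[f"kcat_{i}"] * c / (D * params["Km"] + c)
            # kcat_over_Km shared (per-mM efficiency), Km free per state
            return D * params["eff"] * c / (1.0 + c / params[f"Km_{i}"])

        def resid(params):
            out = []
            for i, ds in enumerate((ds_r, ds_o)):
                r = ds.y - model_state(params, ds.x, i)
                if sws[i] is not None:
                    r = r * sws[i]
                out.append(r)
            return np.concatenate(out)

        params = lmfit.Parameters()
        params.add("D", value=1.0, min=0)
        if self.target == "kcat":
            params.add("kcat", value=fits[0].kcat, min=0)
            for i, f in enumerate(fits):
                params.add(f"Km_{i}", value=f.Km, min=0)
            shared_name = "kcat"
        elif self.target == "Km":
            params.add("Km", value=fits[0].Km, min=0)
            for i, f in enumerate(fits):
                params.add(f"kcat_{i}", value=f.kcat, min=0)
            shared_name = "Km"
        else:
            params.add("eff", value=fits[0].kcat_over_Km / 1e3, min=0)
            for i, f in enumerate(fits):
                params.add(f"Km_{i}", value=f.Km, min=0)
            shared_name = "eff"
        out = lmfit.minimize(resid, params, method="leastsq")
        if not out.success:
            raise RuntimeError("global LRF fit did not converge")
        sh, sh_se = _param_tuple(out.params[shared_name])
        D, D_se = _param_tuple(out.params["D"])
        free = {name: _param_tuple(out.params[name]) for name in out.params
                if name not in ("D", shared_name)}
        label = "kcat_over_Km" if shared_name == "eff" else shared_name
        if shared_name == "eff":
            sh, sh_se = sh * 1e3, sh_se * 1e3   # report in s^-1 M^-1
        return self._package(out, label, sh, sh_se, D, D_se, ref, other, free)

    def _package(self, out, shared_name, sh, sh_se, D, D_se, ref, other,
                 free) -> LightRegulationResults:
        ds_r, ds_o = self.datasets[ref], self.datasets[other]
        D_se_val = D_se if np.isfinite(D_se) else 0.0
        uncertain = abs(D - 1.0) <= D_se_val
        return LightRegulationResults(
            shared_name=shared_name, shared_value=sh, shared_se=sh_se,
            D=D, D_se=D_se, reference_state=ds_r.state,
            fast_state=ds_o.state,
            comparison=(self.datasets[0].state, self.datasets[1].state),
            free_params=free, uncertain=uncertain,
            redchi=float(out.redchi),
        )


def fit_lrf_linear(dataset_a: PhotostateDataset,
                   dataset_b: PhotostateDataset) -> LightRegulationResults:
    """LRF from linear activity data: global fit of y = D·m'·x, m' shared."""
    return LightRegulation([dataset_a, dataset_b], kind="linear").fit()


def fit_lrf_mm(dataset_a: PhotostateDataset, dataset_b: PhotostateDataset,
               target: str = "kcat") -> LightRegulationResults:
    """LRF on a Michaelis–Menten parameter via the shared-parameter global fit."""
    return LightRegulation([dataset_a, dataset_b], kind="mm", target=target).fit()


# ---------------------------------------------------------------------------
# cycle (alternating-irradiation) analysis
# ---------------------------------------------------------------------------

@dataclass
class CycleSegment:
    index: int
    state: IlluminationState
    t_start: float
    t_end: float
    v_over_E0: float
    v_over_E0_se: float


@dataclass
class CycleActivityResult:
    """Per-segment activities and per-cycle LRFs of an irradiation-cycle run."""

    segments: List[CycleSegment]
    per_cycle_lrf: List[float]
    dark_drift: Optional[Tuple[float, float]] = None  # slope of activity vs cycle, SE

    @property
    def mean_lrf(self) -> float:
        return float(np.mean(self.per_cycle_lrf))


def _segment_bounds(time: np.ndarray, events: Sequence[float],
                    settling_gap: float) -> List[Tuple[float, float]]:
    ev = list(events)
    if any(b <= a for a, b in zip(ev, ev[1:])):
        raise ValueError("irradiation events overlap or are unordered")
    edges = [time[0] - settling_gap] + ev + [np.inf]
    return [(edges[i] + settling_gap, edges[i + 1]) for i in range(len(edges) - 1)]


def analyze_cycles_activity(curve: ProgressCurve, events: Sequence[float],
                            constants: AssayConstants,
                            states: Optional[Sequence] = None,
                            settling_gap: float = 60.0,
                            dark_control: Optional[ProgressCurve] = None,
                            ) -> CycleActivityResult:
    """Per-cycle activities and LRFs from an alternating-irradiation run.

    The progress curve is cut at each irradiation event; within each segment
    the points after a settling gap (default 60 s, allowing the steady state
    to re-establish) are fitted linearly and converted to v/E0. The LRF of
    each adjacent segment pair is the ratio of the larger to the smaller
    activity. When a dark-control curve is given, its per-segment activities
    are regressed against the segment index to quantify activity drift in
    the non-irradiated sample.

    Parameters
    ----------
    curve : ProgressCurve with ``enzyme_conc`` set.
    events : irradiation times in seconds, strictly increasing.
    constants : AssayConstants for the Lambert–Beer conversion.
    states : optional per-segment illumination-state labels
        (len(events) + 1 entries); defaults to the curve's state followed by
        alternating PSS365/PSS420.
    """
    if curve.enzyme_conc is None or curve.enzyme_conc <= 0:
        raise ValueError("curve.enzyme_conc (E0) must be set and positive")
    bounds = _segment_bounds(curve.time, events, settling_gap)
    n_seg = len(bounds)
    if states is None:
        alt = [IlluminationState.PSS365, IlluminationState.PSS420]
        states = [curve.state] + [alt[i % 2] for i in range(n_seg - 1)]
    states = [IlluminationState(str(getattr(s, "value", s))) for s in states]
    if len(states) != n_seg:
        raise ValueError(f"need {n_seg} state labels, got {len(states)}")

    segments: List[CycleSegment] = []
    for i, (t0, t1) in enumerate(bounds):
        sub = curve.slice_time(t0, t1)
        if len(sub) < 5:
            raise ValueError(f"segment {i} has fewer than 5 points after settling gap")
        lin = fit_linear_phase(sub, window=(sub.time[0], sub.time[-1]))
        rate = slope_to_rate(lin.slope_m, lin.slope_se, constants,
                             E0=curve.enzyme_conc, window=lin.window,
                             r_squared=lin.r_squared)
        segments.append(CycleSegment(i, states[i], lin.window[0], lin.window[1],
                                     rate.v_over_E0, rate.v_over_E0_se))

    lrfs = []
    for a, b in zip(segments, segments[1:]):
        hi, lo = max(a.v_over_E0, b.v_over_E0), min(a.v_over_E0, b.v_over_E0)
        lrfs.append(hi / lo if lo > 0 else np.inf)

    drift = None
    if dark_control is not None:
        if dark_control.enzyme_conc is None or dark_control.enzyme_conc <= 0:
            raise ValueError("dark_control.enzyme_conc must be set and positive")
        acts = []
        for i, (t0, t1) in enumerate(_segment_bounds(dark_control.time, events,
                                                     settling_gap)):
            sub = dark_control.slice_time(t0, t1)
            lin = fit_linear_phase(sub, window=(sub.time[0], sub.time[-1]))
            rate = slope_to_rate(lin.slope_m, lin.slope_se, constants,
                                 E0=dark_control.enzyme_conc)
            acts.append(rate.v_over_E0)
        idx = np.arange(len(acts), dtype=float)
        A = np.vstack([idx, np.ones_like(idx)]).T
        coef, res_, rank_, sv_ = np.linalg.lstsq(A, np.asarray(acts), rcond=None)
        resid = np.asarray(acts) - A @ coef
        dof = len(acts) - 2
        sxx = np.sum((idx - idx.mean()) ** 2)
        se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 and sxx > 0 else 0.0
        drift = (float(coef[0]), se)

    return CycleActivityResult(segments=segments, per_cycle_lrf=lrfs,
                               dark_drift=drift)
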