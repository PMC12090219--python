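"""Core containers shared across the package.

Units follow bench conventions throughout: time in seconds, absorbance in AU,
wavelength in nm, enzyme concentration in µM, substrate concentration in mM,
temperature in °C, distances in Å and angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "IlluminationState",
    "ProgressCurve",
    "AssayConstants",
    "RateResult",
    "PhotostateDataset",
    "Spectrum",
    "MeltCurve",
    "DOFTrajectory",
]


class IlluminationState(str, Enum):
    """Illumination state of a photoswitchable enzyme sample.

    AIS is the as-isolated, thermally equilibrated (~100% *E*) state;
    PSS365/PSS420 are the photostationary states after 365 nm (Z-enriched)
    or 420 nm (E-enriched) irradiation.
    """

    AIS = "AIS"
    PSS365 = "PSS365"
    PSS420 = "PSS420"
    DARK_CONTROL = "dark-control"
    INTERMEDIATE = "intermediate"


def _as_state(state) -> IlluminationState:
    if isinstance(state, IlluminationState):
        return state
    return IlluminationState(str(state))


@dataclass
class ProgressCurve:
    """One well's absorbance time course from a coupled enzymatic assay.

    Parameters
    ----------
    time : array-like
        Measurement times in seconds, strictly increasing.
    absorbance : array-like
        Absorbance readings in AU (same length as ``time``).
    wavelength : float
        Detection wavelength in nm (340 for the NADH-coupled asparaginase
        assay, 505 for the quinoneimine-coupled glutaminase assay).
    well_id : str
        Plate-well label.
    state : IlluminationState or str
        Illumination state of the enzyme in this well.
    enzyme_conc : float or None
        Final (post-dilution) enzyme concentration E0 in µM; ``None`` when
        unknown (normalized activities are then unavailable).
    assay : str
        Assay label, e.g. ``"asparaginase"`` or ``"glutaminase"``.
    """

    time: np.ndarray
    absorbance: np.ndarray
    wavelength: float = 340.0
    well_id: str = "A1"
    state: IlluminationState = IlluminationState.AIS
    enzyme_conc: Optional[float] = None
    assay: str = "asparaginase"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.state = _as_state(self.state)
        if self.time.ndim != 1 or self.time.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must be 1-D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.enzyme_conc is not None and self.enzyme_conc < 0:
            raise ValueError("enzyme_conc must be >= 0")

    def __len__(self) -> int:
        return self.time.size

    def slice_time(self, t_start: float, t_end: float) -> "ProgressCurve":
        """Return the sub-curve with t_start <= time <= t_end."""
        mask = (self.time >= t_start) & (self.time <= t_end)
        return ProgressCurve(
            self.time[mask], self.absorbance[mask], self.wavelength,
            self.well_id, self.state, self.enzyme_conc, self.assay,
        )


@dataclass(frozen=True)
class AssayConstants:
    """Optical constants converting an absorbance slope into a rate.

    epsilon is the (differential) extinction coefficient in M⁻¹cm⁻¹ — 6300
    for NADH/NAD⁺ at 340 nm, 6400 for the quinoneimine product at 505 nm —
    and path_length the optical path in cm (0.535 cm for a 200 µL well).
    direction records whether the reporter signal decreases (NADH depletion)
    or increases (product formation); rates are reported as magnitudes either
    way.
    """

    epsilon: float
    path_length: float
    direction: str = "decreasing"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError("direction must be 'decreasing' or 'increasing'")

    @property
    def epsilon_d(self) -> float:
        """ε·d in AU per µM of converted reporter (AU·µM⁻¹)."""
        return self.epsilon * self.path_length * 1e-6


# Default constants for the two coupled assays used throughout.
ASPARAGINASE_CONSTANTS = AssayConstants(epsilon=6300.0, path_length=0.535,
                                        direction="decreasing")
GLUTAMINASE_CONSTANTS = AssayConstants(epsilon=6400.0, path_length=0.535,
                                       direction="increasing")


@dataclass
class RateResult:
    """A fitted initial rate: raw slope, molar rate and normalized activity."""

    slope_m: float                    # AU/s
    slope_se: float                   # AU/s
    window: tuple = (np.nan, np.nan)  # seconds
    r_squared: float = np.nan
    v: Optional[float] = None         # µM/s
    v_se: Optional[float] = None
    v_over_E0: Optional[float] = None  # s^-1
    v_over_E0_se: Optional[float] = None

    def __post_init__(self):
        if self.slope_se < 0:
            raise ValueError("SE must be >= 0")


@dataclass
class PhotostateDataset:
    """Replicate measurements for one illumination state.

    ``x`` is either enzyme concentration E0 (µM, linear activity model) or
    substrate concentration (mM, Michaelis–Menten model); ``y`` the matching
    rate v (µM/s) or normalized activity v/E0 (s⁻¹), with optional standard
    errors ``y_se`` used for inverse-variance weighting.
    """

    state: IlluminationState
    x: np.ndarray
    y: np.ndarray
    y_se: Optional[np.ndarray] = None
    replicate_id: Optional[np.ndarray] = None
    x_kind: str = "substrate_mM"   # or "enzyme_uM"

    def __post_init__(self):
        self.state = _as_state(self.state)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y_se is not None:
            self.y_se = np.asarray(self.y_se, dtype=float)
            if np.any(self.y_se < 0):
                raise ValueError("y_se must be >= 0")
            if self.y_se.shape != self.y.shape:
                raise ValueError("y_se must match y in shape")
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must match in shape")

    def __len__(self) -> int:
        return self.x.size

    @property
    def weights(self) -> Optional[np.ndarray]:
        """Inverse-variance weights, or None when no SEs are available."""
        if self.y_se is None or np.any(self.y_se == 0):
            return None
        return 1.0 / self.y_se**2


@dataclass
class Spectrum:
    """A UV/vis absorbance spectrum on an ascending wavelength grid."""

    wavelength: np.ndarray          # nm
    absorbance: np.ndarray          # AU
    state: IlluminationState = IlluminationState.AIS
    irradiation_time: float = 0.0   # s
    sample: str = ""
    cycle: Optional[int] = None

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.state = _as_state(self.state)
        if self.wavelength.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance must match in shape")
        if self.wavelength.size >= 2 and not np.all(np.diff(self.wavelength) > 0):
            raise ValueError("wavelength grid must be strictly ascending")

    def at(self, wavelength: float) -> float:
        """Absorbance at the grid point nearest ``wavelength`` (no interpolation)."""
        idx = int(np.argmin(np.abs(self.wavelength - wavelength)))
        return float(self.absorbance[idx])

    def copy_with(self, absorbance: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavelength.copy(), np.asarray(absorbance, float),
                        self.state, self.irradiation_time, self.sample, self.cycle)


@dataclass
class MeltCurve:
    """A CD thermal denaturation curve (signal vs temperature).

    ``signal`` is raw ellipticity in mdeg or mean residue ellipticity in
    deg·cm²·dmol⁻¹ (see ``units``); metadata needed for MRE normalization is
    optional.
    """

    temperature: np.ndarray   # °C, ascending
    signal: np.ndarray
    units: str = "mdeg"
    protein_conc_M: Optional[float] = None
    n_residues: Optional[int] = None
    path_cm: Optional[float] = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must match in shape")
        if self.temperature.size >= 2 and not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperature must be ascending")


DOF_COLUMNS = ("d1", "d2", "d3", "a1")


@dataclass
class DOFTrajectory:
    """Per-frame values of named collective variables from MD trajectories.

    Distances (d1, d2, d3) are in Å, the angle a1 in degrees. d1 is the
    active-site flexible-loop opening distance whose closed state is
    conventionally d1 < 15 Å.
    """

    data: pd.DataFrame   # columns: frame, replica, then any of d1,d2,d3,a1

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        if "frame" not in df.columns:
            df = df.reset_index().rename(columns={"index": "frame"})
        if "replica" not in df.columns:
            df["replica"] = "r0"
        dof_cols = [c for c in df.columns if c in DOF_COLUMNS]
        if not dof_cols:
            raise ValueError(f"no DOF columns found (expected any of {DOF_COLUMNS})")
        for c in ("d1", "d2", "d3"):
            if c in df.columns and np.any(df[c].to_numpy() < 0):
                raise ValueError(f"distance {c} must be >= 0")
        if "a1" in df.columns:
            a = df["a1"].to_numpy()
            if np.any((a < 0) | (a > 180)):
                raise ValueError("angle a1 must lie in [0, 180] degrees")
        if df.duplicated(subset=["replica", "frame"]).any():
            raise ValueError("frames must be unique within each replica")
        self.data = df

    @property
    def dofs(self) -> list:
        return [c for c in self.data.columns if c in DOF_COLUMNS]

    def __len__(self) -> int:
        return len(self.data)

    def values(self, dof: str) -> np.ndarray:
        if dof not in self.data.columns:
            raise KeyError(f"DOF {dof!r} not present (have {self.dofs})")
        return self.data[dof].to_numpy(dtype=float)

    @staticmethod
    def concat(trajectories) -> "DOFTrajectory":
        """Pool several replicas into one trajectory (frame-count weighting)."""
        frames = [t.data for t in trajectories]
        return DOFTrajectory(pd.concat(frames, ignore_index=True))
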