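"""Conformational-landscape reconstruction from collective variables.

MD trajectories are projected onto a small set of named degrees of freedom
(DOFs) — for the asparaginase active site: d1, the flexible-loop opening
distance Thr21(Cα)–Met115(Cα); d2, the nucleophilic-attack distance
Thr12(OG1)–substrate carbonyl; d3, the Thr12–Tyr25 deprotonation distance;
and a1, the Thr12(OG1)-Tyr25(Cα)-Tyr25(OH) angle. The 2-D histogram of two
DOFs, normalized to unit mass, is the conformational landscape: a maximum
of the probability is a most-visited conformation, and −ln(p/p_max) serves
as a population free-energy surrogate (kT units, anchored at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .datatypes import DOFTrajectory

__all__ = [
    "compute_dof_series",
    "reconstruct_landscape",
    "Landscape2D",
    "find_minima",
    "representative_frame",
    "closed_state_fraction",
]

CLOSED_D1_THRESHOLD = 15.0   # Å; frames with d1 below this are "closed"


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _distance(p, q) -> float:
    return float(np.linalg.norm(np.asarray(q, float) - np.asarray(p, float)))


def _angle(p, q, r) -> float:
    """Angle at q in degrees."""
    v1 = np.asarray(p, float) - np.asarray(q, float)
    v2 = np.asarray(r, float) - np.asarray(q, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def compute_dof_series(frames: Sequence[Dict[str, np.ndarray]],
                       selections: Dict[str, Sequence[str]],
                       replica: str = "r0") -> DOFTrajectory:
    """Compute per-frame DOF values from atom coordinates.

    Parameters
    ----------
    frames : sequence of {atom_key: xyz} mappings, one per frame (Å).
    selections : {dof_name: (atom_key, atom_key[, atom_key])}
        Pairs give Euclidean distances; triplets give the angle at the
        middle atom, in degrees.

    Raises
    ------
    KeyError naming the frame and selection when an atom is missing.
    """
    records = []
    for i, atoms in enumerate(frames):
        row = {"frame": i, "replica": replica}
        for name, sel in selections.items():
            for key in sel:
                if key not in atoms:
                    raise KeyError(f"frame {i}: atom {key!r} missing for "
                                   f"selection {name!r}")
            if len(sel) == 2:
                row[name] = _distance(atoms[sel[0]], atoms[sel[1]])
            elif len(sel) == 3:
                row[name] = _angle(atoms[sel[0]], atoms[sel[1]], atoms[sel[2]])
            else:
                raise ValueError(f"selection {name!r} must have 2 or 3 atoms")
        records.append(row)
    import pandas as pd
    return DOFTrajectory(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

@dataclass
class Landscape2D:
    """A 2-D probability landscape over two collective variables.

    ``probability`` sums to 1 over all bins. ``neg_log_p`` is −ln(p/p_max)
    on occupied bins and NaN on unoccupied ones (absence of sampling, not
    zero probability).
    """

    x_dof: str
    y_dof: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray   # shape (nx, ny)
    n_frames: int

    def __post_init__(self):
        total = self.probability.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("probability mass must sum to 1")

    @property
    def occupied(self) -> np.ndarray:
        return self.probability > 0

    @property
    def neg_log_p(self) -> np.ndarray:
        out = np.full_like(self.probability, np.nan)
        occ = self.occupied
        out[occ] = -np.log(self.probability[occ] / self.probability.max())
        return out

    @property
    def most_populated(self) -> Tuple[int, int]:
        """Bin index (ix, iy) of the global probability maximum (lowest
        index wins ties)."""
        flat = int(np.argmax(self.probability))
        return np.unravel_index(flat, self.probability.shape)

    def bin_center(self, ix: int, iy: int) -> Tuple[float, float]:
        cx = 0.5 * (self.x_edges[ix] + self.x_edges[ix + 1])
        cy = 0.5 * (self.y_edges[iy] + self.y_edges[iy + 1])
        return float(cx), float(cy)


def reconstruct_landscape(traj: DOFTrajectory, x_dof: str, y_dof: str,
                          bins: int = 60, pad_frac: float = 0.02,
                          min_frames: int = 100) -> Landscape2D:
    """Build the 2-D probability landscape of two DOFs (replicas pooled).

    Bins default to 60×60 over [min, max] per axis, padded by 2% of the
    range on each side. Frames from all replicas are pooled, i.e. each
    frame carries equal weight.
    """
    import warnings
    x = traj.values(x_dof)
    y = traj.values(y_dof)
    if x.size < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {x.size}")
    if x.size < bins * bins:
        warnings.warn(f"{x.size} frames for {bins}x{bins} bins: histogram "
                      "will be sparse", stacklevel=2)

    def edges(v):
        # a zero-variance DOF degenerates to a unit-width axis so that all
        # frames land in the central bin (single occupied bin, probability 1)
        span = np.ptp(v)
        pad = pad_frac * span if span > 0 else 0.5
        return np.linspace(v.min() - pad, v.max() + pad, bins + 1)

    ex, ey = edges(x), edges(y)
    H, _, _ = np.histogram2d(x, y, bins=[ex, ey])
    return Landscape2D(x_dof=x_dof, y_dof=y_dof, x_edges=ex, y_edges=ey,
                       probability=H / H.sum(), n_frames=int(x.size))


@dataclass
class Minimum:
    """A local landscape minimum (probability maximum)."""

    bin: Tuple[int, int]
    center: Tuple[float, float]
    probability: float      # raw bin probability
    rank: int               # 0 = most populated


def find_minima(landscape: Landscape2D, min_separation: int = 8,
                smoothing: int = 3,
                min_population_frac: float = 0.02) -> List[Minimum]:
    """Locate landscape minima (local maxima of smoothed probability).

    The probability grid is smoothed with a box filter (default 3×3), local
    maxima are detected, required to be occupied in the raw histogram, to
    carry at least ``min_population_frac`` of the tallest smoothed peak
    (suppressing sampling-noise bumps in the tails), and to sit at least
    ``min_separation`` bins apart (Chebyshev distance); they are ranked by
    smoothed population with ties broken to the lowest flat bin index.
    """
    p = landscape.probability
    ps = ndimage.uniform_filter(p, size=smoothing, mode="constant") \
        if smoothing and smoothing > 1 else p
    footprint = np.ones((3, 3), bool)
    local_max = ((ps == ndimage.maximum_filter(ps, footprint=footprint,
                                               mode="constant"))
                 & (p > 0) & (ps >= min_population_frac * ps.max()))
    cand = np.argwhere(local_max)
    # order: population descending, then flat index ascending (tie-break)
    flat = cand[:, 0] * p.shape[1] + cand[:, 1]
    order = np.lexsort((flat, -ps[cand[:, 0], cand[:, 1]]))
    chosen: List[Tuple[int, int]] = []
    for idx in order:
        ix, iy = map(int, cand[idx])
        if all(max(abs(ix - jx), abs(iy - jy)) >= min_separation
               for jx, jy in chosen):
            chosen.append((ix, iy))
    return [Minimum(bin=(ix, iy), center=landscape.bin_center(ix, iy),
                    probability=float(p[ix, iy]), rank=r)
            for r, (ix, iy) in enumerate(chosen)]


def representative_frame(traj: DOFTrajectory, landscape: Landscape2D,
                         minimum: Minimum) -> int:
    """Frame closest to a minimum's bin center in range-normalized DOF space.

    Distances are Euclidean after dividing each DOF by its landscape axis
    range, so both axes contribute comparably; ties break to the lowest
    frame index. The minimum's bin must be occupied.
    """
    if landscape.probability[minimum.bin] <= 0:
        raise ValueError(f"minimum bin {minimum.bin} is unoccupied")
    x = traj.values(landscape.x_dof)
    y = traj.values(landscape.y_dof)
    cx, cy = minimum.center
    rx = landscape.x_edges[-1] - landscape.x_edges[0]
    ry = landscape.y_edges[-1] - landscape.y_edges[0]
    d2 = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
    best = int(np.argmin(d2))   # argmin returns the first (lowest) index on ties
    return int(traj.data["frame"].iloc[best])


def closed_state_fraction(traj: DOFTrajectory,
                          threshold: float = CLOSED_D1_THRESHOLD) -> float:
    """Fraction of frames in the closed loop conformation (d1 < threshold)."""
    d1 = traj.values("d1")
    return float(np.mean(d1 < threshold))
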