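"""Quantifying simulated inflamed areas: masks, traces, fronts, outcomes.

The inflamed area is the region where the mediator concentration exceeds a
threshold (by default the unstable steady state S_T, the concentration
separating the basins of the noninflamed and inflamed states).  This module
measures its diameter along a row, its area, the number of connected
regions (fusion events), the front profile (interface width and gradient),
and fits a constant front velocity to diameter traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import linregress

from .kinetics import SteadyStateSet
from .solver import Field, SimulationResult

__all__ = [
    "FrontTrace",
    "VelocityEstimate",
    "ProfileSnapshot",
    "RowDiameter",
    "NoFrontError",
    "inflamed_mask",
    "diameter_along_row",
    "count_regions",
    "track_front",
    "estimate_velocity",
    "front_profile",
    "classify_outcome",
]

#: |fitted v| below this is classified "stationary" rather than moving.
OUTCOME_V_TOL = 1e-3


class NoFrontError(ValueError):
    """Raised when a front profile is requested but no interface exists."""


@dataclass(frozen=True)
class RowDiameter:
    """Diameter measurement along one row; valid only for a single
    contiguous run that does not touch the periodic wrap seam."""

    value: float
    valid: bool
    n_runs: int


@dataclass(frozen=True)
class FrontTrace:
    """Time series of inflamed-area measurements.

    ``diameters`` are along the measurement row (length units; nan where the
    scalar measure is undefined), ``areas`` are cell count x dx*dy,
    ``n_regions`` counts 4-connected components with periodic adjacency, and
    ``valid`` flags times where the row diameter is well defined (single run
    away from the wrap seam).
    """

    times: np.ndarray
    diameters: np.ndarray
    areas: np.ndarray
    n_regions: np.ndarray
    valid: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "diameter": self.diameters,
                "area": self.areas,
                "n_regions": self.n_regions,
                "valid": self.valid,
            }
        )


@dataclass(frozen=True)
class VelocityEstimate:
    """Least-squares front velocity: slope of radius (= diameter/2) vs time."""

    v: float
    intercept: float
    r_squared: float
    window: tuple[float, float]


@dataclass(frozen=True)
class ProfileSnapshot:
    """Concentration profile along a row with interface-width measures.

    ``interface_width`` is the distance between the 10% and 90% crossings of
    the span S_I - S_NI on the right-moving interface; ``gradient`` is the
    mean slope over that stretch, 0.8 (S_I - S_NI) / width.
    """

    positions: np.ndarray
    q: np.ndarray
    interface_width: float
    gradient: float


def inflamed_mask(f: Field, threshold: float) -> np.ndarray:
    """Boolean mask of cells with q strictly above ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return f.q > threshold


def diameter_along_row(mask: np.ndarray, row: int, dx: float = 1.0) -> RowDiameter:
    """Extent of the inflamed area along one grid row.

    Returns count-of-true-cells x dx when the true cells form exactly one
    contiguous run that does not touch the wrap seam; an empty row gives 0.
    Multiple runs (pre-fusion spots) or wrap contact make the scalar measure
    ill-defined and are flagged invalid with the value withheld (nan).
    """
    mask = np.atleast_2d(mask)
    if not 0 <= row < mask.shape[0]:
        raise IndexError(f"row {row} outside grid of {mask.shape[0]} rows")
    line = mask[row]
    count = int(line.sum())
    if count == 0:
        return RowDiameter(value=0.0, valid=True, n_runs=0)
    edges = np.diff(line.astype(int))
    n_runs = int(np.sum(edges == 1)) + int(line[0])
    touches_seam = bool(line[0]) and bool(line[-1])
    if n_runs == 1 and not touches_seam:
        return RowDiameter(value=count * dx, valid=True, n_runs=1)
    return RowDiameter(value=math.nan, valid=False, n_runs=n_runs)


def count_regions(mask: np.ndarray) -> int:
    """4-connected components of the mask with periodic wrap adjacency."""
    mask = np.atleast_2d(mask)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    parent = list(range(n + 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # merge labels across the periodic seams
    for l_left, l_right in zip(labels[:, 0], labels[:, -1]):
        if l_left and l_right:
            union(int(l_left), int(l_right))
    if mask.shape[0] > 1:
        for l_top, l_bot in zip(labels[0, :], labels[-1, :]):
            if l_top and l_bot:
                union(int(l_top), int(l_bot))
    return len({find(i) for i in range(1, n + 1)})


def track_front(
    result: SimulationResult,
    threshold: float,
    row: int | None = None,
) -> FrontTrace:
    """Measure diameter, area and region count over a snapshot trajectory.

    ``row`` defaults to the middle grid row (mirroring measurements along a
    line through the stimulation site).
    """
    g = result.grid
    if row is None:
        row = g.ny // 2
    times, diameters, areas, n_regions, valid = [], [], [], [], []
    for t, q in zip(result.times, result.snapshots):
        f = Field(q=q, grid=g, t=float(t))
        mask = inflamed_mask(f, threshold)
        dia = diameter_along_row(mask, row, g.dx)
        times.append(float(t))
        diameters.append(dia.value)
        areas.append(float(mask.sum()) * g.cell_area)
        n_regions.append(count_regions(mask))
        valid.append(dia.valid)
    return FrontTrace(
        times=np.asarray(times),
        diameters=np.asarray(diameters),
        areas=np.asarray(areas),
        n_regions=np.asarray(n_regions),
        valid=np.asarray(valid),
    )


def estimate_velocity(
    trace: FrontTrace, window: tuple[float, float] | None = None
) -> VelocityEstimate:
    """Front velocity as the least-squares slope of radius vs time.

    The radius is diameter/2 (both fronts of the area move; the theoretical
    velocity is a single-front speed).  The default window drops the first
    and last 20% of valid points, discarding the formation transient and any
    late boundary interaction.  Requires at least 5 valid points.
    """
    idx = np.where(trace.valid)[0]
    if window is not None:
        t_lo, t_hi = window
        idx = idx[(trace.times[idx] >= t_lo) & (trace.times[idx] <= t_hi)]
    else:
        n = len(idx)
        drop = int(math.floor(0.2 * n))
        idx = idx[drop : n - drop]
    if len(idx) < 5:
        raise ValueError(
            f"velocity estimation needs >= 5 valid trace points, got {len(idx)}"
        )
    t = trace.times[idx]
    r = trace.diameters[idx] / 2.0
    if np.ptp(r) == 0.0:
        # perfectly flat radius: slope 0 with an exact fit
        return VelocityEstimate(
            v=0.0, intercept=float(r[0]), r_squared=1.0, window=(float(t[0]), float(t[-1]))
        )
    fit = linregress(t, r)
    return VelocityEstimate(
        v=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        window=(float(t[0]), float(t[-1])),
    )


def _crossing(x: np.ndarray, q: np.ndarray, level: float) -> float | None:
    """Linearly interpolated position of the last level crossing."""
    above = q > level
    for i in range(len(q) - 2, -1, -1):
        if above[i] and not above[i + 1]:
            frac = (q[i] - level) / (q[i] - q[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    return None


def front_profile(f: Field, row: int, ss: SteadyStateSet) -> ProfileSnapshot:
    """Interface width and gradient of the right-moving front in one row.

    Locates, right of the row maximum, the crossings of the 90% and 10%
    levels of the span S_I - S_NI (linear interpolation between grid points)
    and reports width = x_10% - x_90% and gradient = 0.8 (S_I - S_NI)/width.
    """
    q_row = np.atleast_2d(f.q)[row].astype(float)
    x = np.arange(len(q_row)) * f.grid.dx
    span = ss.S_I - ss.S_NI
    lo = ss.S_NI + 0.1 * span
    hi = ss.S_NI + 0.9 * span
    if q_row.max() <= hi or q_row.min() >= lo:
        raise NoFrontError("row does not span the 10%-90% interface levels")
    i_peak = int(np.argmax(q_row))
    seg_q = q_row[i_peak:]
    seg_x = x[i_peak:]
    x_hi = _crossing(seg_x, seg_q, hi)
    x_lo = _crossing(seg_x, seg_q, lo)
    if x_hi is None or x_lo is None or x_lo <= x_hi:
        raise NoFrontError("no right-moving interface found in the row")
    width = x_lo - x_hi
    return ProfileSnapshot(
        positions=x,
        q=q_row,
        interface_width=width,
        gradient=0.8 * span / width,
    )


def classify_outcome(trace: FrontTrace, v_tol: float = OUTCOME_V_TOL) -> str:
    """Classify a run as expansion / shrinkage / stationary / extinct.

    "extinct" when the final inflamed area has vanished; otherwise by the
    sign of the fitted radius velocity when its magnitude exceeds ``v_tol``,
    falling back to "stationary".
    """
    if trace.areas[-1] == 0.0:
        return "extinct"
    try:
        est = estimate_velocity(trace)
    except ValueError:
        return "stationary"
    if est.v > v_tol:
        return "expansion"
    if est.v < -v_tol:
        return "shrinkage"
    return "stationary"
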