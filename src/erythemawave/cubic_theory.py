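"""Cubic approximation of the bistable kinetics and traveling-wave theory.

Near bistability the Hill kinetics can be approximated by a cubic with the
same three steady states,

    g(q) = A (q - S_NI) (S_T - q) (q - S_I),      A = 1 / (S_T**n + 1),

for which the bistable reaction-diffusion equation has a classical
traveling-front solution connecting S_NI and S_I with velocity

    v = sqrt(A d / 2) * (S_NI + S_I - 2 S_T).

The sign of v is set purely by the balance of the stable states about the
threshold: the front converts noninflamed tissue to inflamed (expansion,
v > 0) when S_T is closer to S_NI, and the reverse (shrinkage, v < 0) when
S_T is closer to S_I.  This module evaluates that prediction, locates the
v = 0 locus in the (a, b) plane, and builds regime maps (phase diagrams).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import (
    CUSP_B,
    KineticParams,
    SteadyStateSet,
    bistable_interval,
    steady_states,
)

__all__ = [
    "CubicApprox",
    "VelocityPrediction",
    "RegimeMap",
    "BistabilityError",
    "LocusNotFoundError",
    "cubic_approximation",
    "theoretical_velocity",
    "v_zero_locus",
    "phase_diagram",
    "STATIONARY_TOL",
]

#: |v| at or below this is labeled "stationary" rather than a moving front.
STATIONARY_TOL = 1e-10

EXPANSION = "expansion"
SHRINKAGE = "shrinkage"
STATIONARY = "stationary"
MONOSTABLE = "monostable"


class BistabilityError(ValueError):
    """Raised when an operation requires bistable kinetics but got none."""


class LocusNotFoundError(RuntimeError):
    """Raised when no v = 0 crossing exists in the bistable interval."""


@dataclass(frozen=True)
class CubicApprox:
    """Cubic stand-in for the Hill kinetics sharing its three steady states."""

    A: float
    roots: tuple[float, float, float]

    def rate(self, q):
        """Cubic reaction rate g(q) = A (q - S_NI)(S_T - q)(q - S_I)."""
        s_ni, s_t, s_i = self.roots
        q = np.asarray(q, dtype=float)
        out = self.A * (q - s_ni) * (s_t - q) * (q - s_i)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class VelocityPrediction:
    """Theoretical front velocity and the regime it implies."""

    v: float
    regime: str


def cubic_approximation(ss: SteadyStateSet, n: int = 2) -> CubicApprox:
    """Cubic approximation with A = 1/(S_T^n + 1) and the same roots."""
    if not ss.bistable:
        raise BistabilityError(
            "cubic approximation requires bistable kinetics (three steady states)"
        )
    A = 1.0 / (ss.S_T**n + 1.0)
    return CubicApprox(A=A, roots=(ss.S_NI, ss.S_T, ss.S_I))


def theoretical_velocity(
    ss: SteadyStateSet, n: int = 2, d: float = 0.5
) -> VelocityPrediction:
    """Front velocity v = sqrt(A d / 2) (S_NI + S_I - 2 S_T) of the cubic wave.

    Monostable input yields regime "monostable" with v = nan; otherwise the
    regime is expansion / shrinkage / stationary by the sign of v with a
    1e-10 tolerance.
    """
    if d < 0:
        raise ValueError("diffusion coefficient d must be non-negative")
    if not ss.bistable:
        return VelocityPrediction(v=math.nan, regime=MONOSTABLE)
    approx = cubic_approximation(ss, n=n)
    v = math.sqrt(approx.A * d / 2.0) * (ss.S_NI + ss.S_I - 2.0 * ss.S_T)
    if abs(v) <= STATIONARY_TOL:
        regime = STATIONARY
    else:
        regime = EXPANSION if v > 0 else SHRINKAGE
    return VelocityPrediction(v=v, regime=regime)


def _balance(a: float, b: float, n: int) -> float:
    ss = steady_states(KineticParams(a=a, b=b, n=n))
    if not ss.bistable:
        raise BistabilityError(f"(a={a}, b={b}) is not bistable")
    return ss.S_NI + ss.S_I - 2.0 * ss.S_T

def v_zero_locus(b: float, n: int = 2) -> float:
    """a* at which the front is stationary (S_NI + S_I = 2 S_T) for given b.

    Root-finds the balance expression over the analytic bistable a-interval;
    the returned a* satisfies |S_NI + S_I - 2 S_T| < 1e-10.  Raises
    ``LocusNotFoundError`` when b admits no bistability or no sign change.
    """
    try:
        a_lo, a_hi = bistable_interval(b, n=n)
    except ValueError as exc:
        raise LocusNotFoundError(str(exc)) from exc
    # shrink marginally off the saddle-node edges where a root pair degenerates
    eps = 1e-9 * max(1.0, a_hi)
    lo, hi = a_lo + eps, a_hi - eps
    f_lo, f_hi = _balance(lo, b, n), _balance(hi, b, n)
    if f_lo * f_hi > 0:
        raise LocusNotFoundError(
            f"balance expression has no sign change on a in ({a_lo}, {a_hi}) at b={b}"
        )
    a_star = brentq(lambda a: _balance(a, b, n), lo, hi, xtol=1e-13, rtol=1e-15)
    # bisection refinement until the balance itself is < 1e-10
    while abs(_balance(a_star, b, n)) > 1e-10:  # pragma: no cover - brentq suffices
        lo2, hi2 = a_star - 1e-12, a_star + 1e-12
        a_star = brentq(lambda a: _balance(a, b, n), lo2, hi2, xtol=1e-15)
    return a_star


@dataclass(frozen=True)
class RegimeMap:
    """Regime labels over an (a, b) grid with the theoretical v = 0 locus.

    ``labels[i, j]`` and ``v_values[i, j]`` correspond to
    (a_grid[j], b_grid[i]); v is nan outside the bistable region.
    ``v_zero_locus`` is an array of (a, b) points where the predicted front
    is stationary.
    """

    a_grid: np.ndarray
    b_grid: np.ndarray
    labels: np.ndarray
    v_values: np.ndarray
    v_zero_locus: np.ndarray
    d: float

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns a, b, regime, v."""
        rows = []
        for i, b in enumerate(self.b_grid):
            for j, a in enumerate(self.a_grid):
                rows.append(
                    {"a": a, "b": b, "regime": self.labels[i, j], "v": self.v_values[i, j]}
                )
        return pd.DataFrame(rows, columns=["a", "b", "regime", "v"])


def phase_diagram(
    a_range: tuple[float, float],
    b_range: tuple[float, float],
    d: float = 0.5,
    resolution: int = 50,
) -> RegimeMap:
    """Classify each (a, b) cell as monostable / expansion / shrinkage.

    Evaluates the theoretical velocity on a ``resolution`` x ``resolution``
    grid and traces the v = 0 locus per b-row by root-finding (accurate near
    the cusp, unlike contouring the coarse v grid).
    """
    if a_range[0] <= 0 or b_range[0] < 0 or a_range[1] <= a_range[0] or b_range[1] <= b_range[0]:
        raise ValueError("ranges must be positive and increasing")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    a_grid = np.linspace(a_range[0], a_range[1], resolution)
    b_grid = np.linspace(b_range[0], b_range[1], resolution)
    labels = np.empty((resolution, resolution), dtype=object)
    v_values = np.full((resolution, resolution), np.nan)
    for i, b in enumerate(b_grid):
        for j, a in enumerate(a_grid):
            ss = steady_states(KineticParams(a=a, b=b))
            pred = theoretical_velocity(ss, n=2, d=d)
            labels[i, j] = pred.regime
            if ss.bistable:
                v_values[i, j] = pred.v
    locus = []
    for b in b_grid:
        if not 0 < b < CUSP_B:
            continue
        try:
            a_star = v_zero_locus(b)
        except LocusNotFoundError:
            continue
        if a_range[0] <= a_star <= a_range[1]:
            locus.append((a_star, b))
    return RegimeMap(
        a_grid=a_grid,
        b_grid=b_grid,
        labels=labels,
        v_values=v_values,
        v_zero_locus=np.asarray(locus, dtype=float).reshape(-1, 2),
        d=d,
    )
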