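"""Reaction kinetics of the inflammatory-mediator model.

The single state variable is the (normalized) concentration ``q`` of an
inflammatory mediator in the dermis.  Production is autocatalytic through a
Hill-type positive feedback, on top of basal secretion and first-order
degradation:

    dq/dt = a * q**n / (q**n + 1) + b - q

where ``a`` is the normalized maximum production rate, ``b`` the normalized
basal secretion rate and ``n`` the Hill coefficient (default 2, the simplest
cooperativity producing bistability).  For suitable ``(a, b)`` the kinetics
are bistable: a noninflamed state ``S_NI``, an unstable threshold ``S_T`` and
an inflamed state ``S_I``.

This module computes steady states and their stability, the analytic
saddle-node boundary of the bistable region in the ``(a, b)`` plane (for
n = 2), and conversions between dimensional and nondimensional parameter
sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "DimensionalParams",
    "SteadyStateSet",
    "BoundaryCurve",
    "reaction_rate",
    "reaction_derivative",
    "steady_states",
    "bistable_boundary",
    "bistable_interval",
    "nondimensionalize",
    "dimensionalize",
    "CUSP_A",
    "CUSP_B",
    "CUSP_Q",
    "STABLE",
    "UNSTABLE",
    "MARGINAL",
]

STABLE = "stable"
UNSTABLE = "unstable"
MARGINAL = "marginal"

#: Saddle-node cusp for n = 2: the apex of the bistable region in (a, b).
CUSP_Q = 1.0 / math.sqrt(3.0)
CUSP_A = 8.0 * math.sqrt(3.0) / 9.0
CUSP_B = 1.0 / (3.0 * math.sqrt(3.0))

# Roots closer than this are considered degenerate (saddle-node collision).
_MERGE_TOL = 1e-8
# |f'(r)| below this is labeled marginal rather than guessed stable/unstable.
_MARGINAL_TOL = 1e-8


@dataclass(frozen=True)
class KineticParams:
    """Nondimensional kinetic parameters plus the diffusion coefficient.

    Parameters
    ----------
    a : float
        Normalized maximum production rate (strength of positive feedback).
    b : float
        Normalized basal secretion rate.
    n : int
        Hill coefficient of the cooperativity (default 2).
    d : float
        Normalized diffusion coefficient (0 for well-mixed kinetics).
    """

    a: float
    b: float
    n: int = 2
    d: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if self.b < 0:
            raise ValueError(f"b must be non-negative, got {self.b}")
        if self.d < 0:
            raise ValueError(f"d must be non-negative, got {self.d}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1, got {self.n}")


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional kinetic parameters of the mediator balance equation.

    ``alpha`` (concentration/time) is the maximum production rate, ``beta``
    (concentration/time) the basal secretion rate, ``gamma`` (1/time) the
    degradation rate, ``K_M`` (concentration) the production threshold,
    ``D`` (length^2/time) the diffusion coefficient and ``L`` (length) a
    reference length used only for spatial scaling (any positive choice is
    internally consistent; default 1).
    """

    alpha: float
    beta: float
    gamma: float
    K_M: float
    D: float = 0.0
    n: int = 2
    L: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "K_M", "L"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1, got {self.n}")


@dataclass(frozen=True)
class SteadyStateSet:
    """Ordered steady states of the well-mixed kinetics with stability labels.

    ``roots`` are sorted ascending; in the bistable case there are exactly
    three with stabilities (stable, unstable, stable), aliased as the
    noninflamed state ``S_NI``, threshold ``S_T`` and inflamed state ``S_I``.
    """

    roots: tuple[float, ...]
    stabilities: tuple[str, ...]
    bistable: bool
    params: KineticParams = field(repr=False, default=None)  # type: ignore[assignment]

    def _require_bistable(self) -> None:
        if not self.bistable:
            raise ValueError(
                "steady-state aliases S_NI/S_T/S_I require bistable kinetics; "
                f"got {len(self.roots)} root(s)"
            )

    @property
    def S_NI(self) -> float:
        """Noninflamed (lower stable) state."""
        self._require_bistable()
        return self.roots[0]

    @property
    def S_T(self) -> float:
        """Unstable threshold state."""
        self._require_bistable()
        return self.roots[1]

    @property
    def S_I(self) -> float:
        """Inflamed (upper stable) state."""
        self._require_bistable()
        return self.roots[2]


@dataclass(frozen=True)
class BoundaryCurve:
    """Saddle-node locus bounding the bistable region in the (a, b) plane.

    ``samples`` is an array of (q, a, b) triples along the locus, ordered by
    the parametrizing root ``q``; ``cusp`` is the apex (a, b) beyond which
    no bistability exists for any ``a``.
    """

    samples: np.ndarray
    cusp: tuple[float, float]

    def contains(self, a: float, b: float, n: int = 2) -> bool:
        """True if (a, b) lies inside the bistable region (three roots)."""
        return steady_states(KineticParams(a=a, b=b, n=n)).bistable


def _as_checked_array(q):
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("concentration q must be non-negative")
    return q


def reaction_rate(q, p: KineticParams):
    """Net production rate a*q^n/(q^n+1) + b - q.

    Accepts scalars or arrays; negative concentrations are a domain error.
    """
    q = _as_checked_array(q)
    qn = q**p.n
    out = p.a * qn / (qn + 1.0) + p.b - q
    return float(out) if out.ndim == 0 else out


def reaction_derivative(q, p: KineticParams):
    """d/dq of :func:`reaction_rate`: n*a*q^(n-1)/(q^n+1)^2 - 1."""
    q = _as_checked_array(q)
    qn = q**p.n
    out = p.n * p.a * q ** (p.n - 1) / (qn + 1.0) ** 2 - 1.0
    return float(out) if out.ndim == 0 else out


def _polish_root(r: float, p: KineticParams) -> float:
    """Newton-polish a root of the reaction rate (guarding tangencies)."""
    for _ in range(6):
        fr = reaction_rate(r, p)
        if abs(fr) < 1e-14:
            break
        dfr = reaction_derivative(r, p)
        if abs(dfr) < 1e-6:
            break
        r_new = r - fr / dfr
        if r_new < 0:
            break
        r = r_new
    return r


def _roots_cubic(p: KineticParams) -> list[float]:
    # For n=2 the steady states are the non-negative real roots of
    # q^3 - (a+b) q^2 + q - b = 0 (denominator of the Hill term cleared).
    coeffs = [1.0, -(p.a + p.b), 1.0, -p.b]
    raw = np.roots(coeffs)
    roots = [float(r.real) for r in raw if abs(r.imag) < 1e-10]
    return [r for r in roots if r > -1e-12]


def _roots_scan(p: KineticParams) -> list[float]:
    # Generic n: dense scan for sign changes of f on [0, a+b], plus
    # tangency detection at critical points of f.
    ub = p.a + p.b + 1e-9
    qs = np.linspace(0.0, ub, 4001)
    vals = reaction_rate(qs, p)
    roots: list[float] = []
    for i in range(len(qs) - 1):
        if vals[i] == 0.0:
            roots.append(float(qs[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(
                brentq(lambda q: reaction_rate(q, p), qs[i], qs[i + 1], xtol=1e-14)
            )
    # double roots: f' changes sign and |f| is tiny there
    dvals = reaction_derivative(qs, p)
    for i in range(len(qs) - 1):
        if dvals[i] * dvals[i + 1] < 0:
            qc = brentq(
                lambda q: reaction_derivative(q, p), qs[i], qs[i + 1], xtol=1e-14
            )
            if abs(reaction_rate(qc, p)) < _MERGE_TOL:
                roots.append(qc)
    return roots


def steady_states(p: KineticParams) -> SteadyStateSet:
    """All non-negative steady states of the well-mixed kinetics.

    Roots are polished to |f(r)| < 1e-10, merged when closer than 1e-8
    (saddle-node degeneracy) and classified by the sign of f'(r):
    negative -> stable, positive -> unstable, |f'| < 1e-8 -> marginal.
    ``bistable`` is True iff exactly three distinct roots exist.
    """
    raw = _roots_cubic(p) if p.n == 2 else _roots_scan(p)
    polished = sorted(max(0.0, _polish_root(r, p)) for r in raw)
    merged: list[float] = []
    for r in polished:
        if merged and abs(r - merged[-1]) < _MERGE_TOL:
            continue
        merged.append(r)
    stabilities = []
    for r in merged:
        df = reaction_derivative(r, p)
        if abs(df) < _MARGINAL_TOL:
            stabilities.append(MARGINAL)
        else:
            stabilities.append(STABLE if df < 0 else UNSTABLE)
    return SteadyStateSet(
        roots=tuple(merged),
        stabilities=tuple(stabilities),
        bistable=len(merged) == 3,
        params=p,
    )


def _boundary_a(q: float) -> float:
    return (1.0 + q * q) ** 2 / (2.0 * q)


def _boundary_b(q: float) -> float:
    return q * (1.0 - q * q) / 2.0


def bistable_boundary(n: int = 2, n_samples: int = 200) -> BoundaryCurve:
    """Analytic saddle-node locus of the n = 2 kinetics.

    Parametrized by the degenerate root q in (0, 1):

        a(q) = (1 + q^2)^2 / (2 q),    b(q) = q (1 - q^2) / 2.

    The two branches meet at the cusp q = 1/sqrt(3), i.e.
    (a, b) = (8*sqrt(3)/9, 1/(3*sqrt(3))) ~ (1.5396, 0.19245); above the
    cusp's b the kinetics are monostable for every a.
    """
    if n != 2:
        raise NotImplementedError("analytic bistability boundary requires n = 2")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    qs = np.linspace(1e-3, 1.0 - 1e-6, n_samples)
    samples = np.column_stack(
        [qs, [(1 + q * q) ** 2 / (2 * q) for q in qs], [q * (1 - q * q) / 2 for q in qs]]
    )
    return BoundaryCurve(samples=samples, cusp=(CUSP_A, CUSP_B))


def bistable_interval(b: float, n: int = 2) -> tuple[float, float]:
    """(a_lo, a_hi) bracketing bistability at fixed b, for n = 2.

    Solves b(q) = q(1-q^2)/2 = b on both branches of the saddle-node locus
    and evaluates a(q) there.  Raises ``ValueError`` when b is outside
    (0, b_cusp], i.e. when no bistable interval exists.
    """
    if n != 2:
        raise NotImplementedError("analytic bistable interval requires n = 2")
    if not 0 < b <= CUSP_B:
        raise ValueError(
            f"no bistable a-interval for b={b}: requires 0 < b <= {CUSP_B:.6f}"
        )
    if b == CUSP_B:
        return (CUSP_A, CUSP_A)
    q1 = brentq(lambda q: _boundary_b(q) - b, 1e-12, CUSP_Q, xtol=1e-15)
    q2 = brentq(lambda q: _boundary_b(q) - b, CUSP_Q, 1.0 - 1e-12, xtol=1e-15)
    a1, a2 = _boundary_a(q1), _boundary_a(q2)
    return (min(a1, a2), max(a1, a2))


def nondimensionalize(dp: DimensionalParams) -> KineticParams:
    """Map dimensional parameters to the nondimensional set (a, b, n, d).

    Uses q = p/K_M, t = gamma*T, x -> x/L, giving a = alpha/(gamma*K_M),
    b = beta/(gamma*K_M), d = D/(gamma*L^2); n is unchanged.
    """
    return KineticParams(
        a=dp.alpha / (dp.gamma * dp.K_M),
        b=dp.beta / (dp.gamma * dp.K_M),
        n=dp.n,
        d=dp.D / (dp.gamma * dp.L**2),
    )


def dimensionalize(
    p: KineticParams, gamma: float, K_M: float, L: float = 1.0
) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` given the scale factors."""
    if gamma <= 0 or K_M <= 0 or L <= 0:
        raise ValueError("gamma, K_M and L must be strictly positive")
    return DimensionalParams(
        alpha=p.a * gamma * K_M,
        beta=p.b * gamma * K_M,
        gamma=gamma,
        K_M=K_M,
        D=p.d * gamma * L**2,
        n=p.n,
        L=L,
    )
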