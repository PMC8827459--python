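"""Initial conditions: Gaussian stimulation spots on a resting background.

Emulates the onset of erythema: the tissue sits at the noninflamed steady
state S_NI and one or a few small stimulated areas carry mediator
concentration above the threshold S_T (a suprathreshold stimulus), given by
two-dimensional Gaussian bumps.  Distances are taken with the periodic
minimal-image convention so spots behave identically anywhere on the torus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import SteadyStateSet
from .solver import Field, GridSpec

__all__ = ["StimulusSpec", "make_initial_field", "threshold_disc_radius"]


@dataclass(frozen=True)
class StimulusSpec:
    """One or more Gaussian stimulation spots.

    ``centers`` are (x, y) positions in grid-index units, taken modulo the
    periodic domain; ``amplitude`` is the peak concentration added above the
    background and ``sigma`` the Gaussian width in cells.  ``background``
    defaults to the noninflamed state S_NI of the supplied kinetics.
    """

    centers: tuple[tuple[float, float], ...] = ((0.0, 0.0),)
    amplitude: float = 1.0
    sigma: float = 3.0
    background: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.background is not None and self.background < 0:
            raise ValueError("background must be non-negative")


def _resolve_background(ss: SteadyStateSet | float | None, spec: StimulusSpec) -> float:
    if spec.background is not None:
        return spec.background
    if isinstance(ss, SteadyStateSet):
        return ss.roots[0]
    if ss is None:
        raise ValueError("background unspecified and no steady states supplied")
    return float(ss)


def make_initial_field(
    g: GridSpec, ss: SteadyStateSet | float | None, spec: StimulusSpec
) -> Field:
    """Background plus additive Gaussian spots, periodic minimal image.

    q(x, y) = background + amplitude * sum_c exp(-(dx^2 + dy^2) / (2 sigma^2))

    with dx, dy the minimal-image offsets from center c.  When the kinetics
    are bistable, each spot whose peak falls below the threshold S_T triggers
    a warning (subthreshold stimuli are legitimate controls, not errors).
    """
    background = _resolve_background(ss, spec)
    x = np.arange(g.nx, dtype=float)
    y = np.arange(g.ny, dtype=float)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    q = np.full(g.shape, background)
    for cx, cy in spec.centers:
        if not (np.isfinite(cx) and np.isfinite(cy)):
            raise ValueError(f"stimulus center ({cx}, {cy}) is not finite")
        # the domain is a torus: centers are taken modulo the period
        cx, cy = cx % g.nx, cy % g.ny
        ddx = (xx - cx + g.nx / 2.0) % g.nx - g.nx / 2.0
        ddy = (yy - cy + g.ny / 2.0) % g.ny - g.ny / 2.0 if g.ny > 1 else 0.0
        q += spec.amplitude * np.exp(-(ddx**2 + ddy**2) / (2.0 * spec.sigma**2))
    if isinstance(ss, SteadyStateSet) and ss.bistable and spec.amplitude > 0:
        peak = background + spec.amplitude
        if peak <= ss.S_T:
            warnings.warn(
                f"stimulus peak {peak:.4g} does not exceed the threshold "
                f"S_T={ss.S_T:.4g}; the spot is subthreshold",
                stacklevel=2,
            )
    return Field(q=q, grid=g, t=0.0)


def threshold_disc_radius(
    amplitude: float, background: float, sigma: float, threshold: float
) -> float:
    """Radius (in cells) of the disc where a single spot exceeds ``threshold``.

    Inverts the Gaussian analytically:
    r = sigma * sqrt(2 ln(amplitude / (threshold - background))).
    Returns 0 when the peak does not reach the threshold.
    """
    if threshold <= background:
        raise ValueError("threshold must exceed the background level")
    if amplitude <= threshold - background:
        return 0.0
    return sigma * math.sqrt(2.0 * math.log(amplitude / (threshold - background)))
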