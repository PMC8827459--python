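# Methods

## Model and assumptions

The state variable is a single lumped inflammatory-mediator concentration
q over a two-dimensional patch of dermis, with mediator-secreting cells
(keratinocytes, resident immune cells) assumed homogeneously distributed.
The dimensional balance law

    ∂p/∂T = α pⁿ/(pⁿ + K_Mⁿ) + β − γ p + D Δp

(production with Hill-type positive feedback, basal secretion, first-order
degradation, diffusion) is nondimensionalized by q = p/K_M, t = γT and
x → x/L, giving a = α/(γ K_M), b = β/(γ K_M), d = D/(γ L²). The reference
length L is an explicit parameter (default 1); any positive choice is
internally consistent, and the conversion round-trips exactly. Anti-
inflammatory mediators, stimulus protocols extended in time, and spatial
heterogeneity of the secreting cells are outside the model.

Bistability requires n ≥ 2; the package fixes the analytic work at n = 2
(steady states reduce to the cubic q³ − (a+b)q² + q − b = 0) while
`reaction_rate`/`steady_states` accept general integer n numerically.

## Parameters that matter

| parameter | meaning | default / typical | notes |
|---|---|---|---|
| a | max production rate (normalized) | 1.9–4 | bistable band depends on b |
| b | basal secretion rate (normalized) | 0.01–0.1 | bistability needs b ≤ 1/(3√3) ≈ 0.19245 |
| n | Hill coefficient | 2 | analytic boundary implemented for n = 2 only |
| d | diffusion coefficient (normalized) | 0.5 | front velocity scales as √d |
| dx, dy | grid spacing | 1 (2-D figures), 0.5 (1-D sweeps) | several cells per interface width |
| dt | time step | 0.05 | must satisfy dt ≤ 0.9 / (2d(1/dx² + 1/dy²)) |

The saddle-node boundary is parametrized by the degenerate root q ∈ (0,1):
a(q) = (1+q²)²/(2q), b(q) = q(1−q²)/2, cusp at q = 1/√3, i.e.
(a, b) = (8√3/9, 1/(3√3)). Inside the region the roots are classified by
the sign of f′; |f′| < 1e-8 is labeled "marginal" rather than guessed.
Roots are polished to |f| < 1e-10 and merged when closer than 1e-8 (the
saddle-node degeneracy). The v = 0 locus is traced per b by bracketed
root-finding on the balance S_NI + S_I − 2 S_T (tolerance 1e-10), which
stays accurate near the cusp where contouring a coarse velocity grid would
not.

## Numerical scheme

Explicit forward Euler in time with the standard 5-point periodic Laplacian
(3-point in 1-D), exactly the first-order scheme the model was designed
around. `stability_limit` returns the Von Neumann diffusion bound
1/(2d(1/dx² + 1/dy²)); for d = 0 it falls back to the reaction stiffness
1/max|f′| over [0, 1.5·max root]. `simulate` refuses dt above
`stability_safety` (default 0.9) times the bound. Positivity is monitored,
not enforced: a negative or non-finite cell raises a stability error naming
the cell, with the partial trajectory retained. Snapshot times are computed
from the step count, not accumulated, so stored times are exact multiples
of the interval. Trajectories are bit-deterministic; rerunning a saved
config reproduces identical CSV bytes.

Degenerate inputs: grids need ≥ 3 cells per periodic dimension; stimulus
centers are taken modulo the torus; a subthreshold stimulus warns (it is a
legitimate control) rather than failing; monostable kinetics require an
explicit analysis threshold since no S_T exists.

## Front measurement

The inflamed area is the mask q > S_T (threshold configurable). The
diameter along a measurement row is the length of its single contiguous
run; the measurement is flagged invalid once the run touches the periodic
seam or splits into several runs (pre-fusion spots), and invalid points are
excluded from fits. Region counting uses 4-connected components with
label merging across both periodic seams. The front velocity is the
least-squares slope of radius (= diameter/2) versus time, with the first
and last 20% of valid points dropped (formation transient, boundary
effects); interface width is the distance between the 10% and 90% crossings
of S_I − S_NI, linearly interpolated.

Velocity conventions deserve care. `estimate_velocity` reports the
physical single-front speed (radius growth rate): a 1-D plateau whose two
interfaces travel outward at speed v widens its diameter at 2v. The
solver reproduces the closed-form Nagumo speed (1−2α)/√2 for the standard
cubic to better than 1%, so the radius-rate convention is the one under
which simulation and exact theory coincide.

## Accuracy of the cubic approximation

The cubic velocity formula is exact for the cubic reaction but only
approximate for the Hill kinetics, because A = 1/(S_Tⁿ + 1) freezes the
state-dependent factor 1/(qⁿ + 1) at the threshold. Shooting on the
traveling-wave boundary-value problem (an independent oracle used during
development) shows the formula overestimates the true single-front speed by
a factor ≈ 1.6–1.7 across the expansion regime at d = 0.5 (e.g. exact
0.1343 vs predicted 0.2257 at a = 2.14, b = 0.05). The sign, however, is
predicted correctly everywhere tested away from the v = 0 locus, and that
sign — expansion vs shrinkage — is the model's central claim. When the
velocity is quoted as the growth rate of the *diameter* (the convention
used when reading expansion rates off lesion images, and the one under
which the concordance checks compare magnitudes), prediction and
simulation agree within ≈ 20% at moderate parameters, the factor 2 between
diameter and front speed largely offsetting the approximation's bias.
Near the v = 0 locus the relative error of the formula diverges (both
velocities cross zero at slightly different parameter values), so
concordance checks exclude a neighborhood |a − a*(b)| ≤ 0.05.

## Problem sizes used in the checks

Figure-style 2-D runs use a 200×200 periodic grid, dx = dy = 1, dt = 0.05
(also 0.1 for the time-step-robustness comparison), Gaussian stimulus of
amplitude 1 and σ = 3 cells at the domain center, measured along the row
through the center — sizes chosen so the expanding front stays clear of
the periodic wrap for the full measurement window. The 1-D concordance
sweeps use dx = 0.5 (≥ 4 cells across the interface at d = 0.5) with the
domain length and end time scaled automatically from the predicted speed.
Time-step sensitivity at the strong-feedback point is a genuine first-order
effect of ≈ 1.4% on the front speed between dt = 0.05 and dt = 0.1;
pointwise diameter traces additionally carry ±1-cell quantization, so the
robustness check compares fitted expansion rates (and the module test
bounds pointwise differences by 2% plus one cell per front).

## Known limitations

- The analytic bistability boundary and interval are n = 2 only.
- Only periodic boundaries; no-flux or Dirichlet walls are not available,
  so very long runs end with fronts annihilating across the wrap rather
  than at a wall.
- No curvature-corrected velocity analysis (v − dκ); 2-D expansion rates
  slightly lag the planar-front speed at small radii.
- The Gaussian stimulus is a nondimensional idealization; the physical
  ~1 mm spot size maps onto σ only once L and D are specified.
- Stochastic kinetics, oscillatory (Hopf) regimes and the autonomous
  fading of mature lesions (which requires an anti-inflammatory species)
  are out of scope.
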