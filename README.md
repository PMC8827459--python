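# erythemawave

Bistable reaction–diffusion modeling of skin erythema: why a circular red
lesion expands at constant velocity from a purely local stimulus, and what
it takes to make it shrink instead.

## The model

Erythema — the circular red lesion of eczema, urticaria, psoriasis and many
infections — reflects dilated dermal blood vessels downstream of
inflammatory mediators (TNF-α, IL-1β, histamine). These mediators induce
their own production (positive feedback through NF-κB signaling), are
secreted at a basal rate, degrade, and diffuse through the dermis. In
nondimensional form the mediator concentration q(x, y, t) obeys

    ∂q/∂t = a qⁿ/(qⁿ + 1) + b − q + d Δq

with a the maximum production rate, b the basal secretion rate, d the
diffusion coefficient and n the Hill coefficient (n = 2 throughout, the
simplest cooperativity that yields bistability). For suitable (a, b) the
well-mixed kinetics have three steady states

    S_NI < S_T < S_I

— a stable noninflamed state, an unstable threshold, and a stable inflamed
state. A local suprathreshold stimulus flips a small area to S_I; diffusion
then converts neighboring tissue across the threshold, and the inflamed
area spreads (or recedes) as a traveling front. Approximating the kinetics
by a cubic with the same roots, g(q) = A (q − S_NI)(S_T − q)(q − S_I) with
A = 1/(S_Tⁿ + 1), gives the classical front velocity

    v = √(A d / 2) · (S_NI + S_I − 2 S_T).

The sign of v is set by the balance of the stable states about the
threshold: expansion when S_T is closer to S_NI, shrinkage when it is
closer to S_I, and a stationary front on the balance locus
S_NI + S_I = 2 S_T.

The package provides:

- **kinetics** — steady states with stability labels, the analytic
  saddle-node boundary of the bistable region (cusp at
  a = 8√3/9 ≈ 1.5396, b = 1/(3√3) ≈ 0.19245), and
  dimensional ↔ nondimensional conversion;
- **cubic_theory** — the cubic approximation, the velocity formula, the
  v = 0 locus, and (a, b) regime phase diagrams;
- **solver** — explicit Euler finite differences with a periodic 5-point
  Laplacian and Von Neumann stability checking;
- **stimulation** — Gaussian stimulation-spot initial conditions;
- **front_analysis** — inflamed-area masks, diameter/area traces, fusion
  counting, front profiles, velocity fits and outcome classification;
- **sweeps** — 1-D front-velocity measurement and theory-vs-simulation
  concordance sweeps;
- **config / cli** — JSON-configured, fully reproducible simulation runs.

## Worked example

Steady states at strong feedback (a = 4, b = 0.01):

```console
$ erythemawave steady-states --a 4 --b 0.01
0.01043555587   stable
0.2559741438    unstable
3.7435903       stable
bistable: True
S_NI=0.0104356 S_T=0.255974 S_I=3.74359
```

The middle root is the threshold concentration S_T ≈ 0.26 above which an
area appears inflamed. The front-velocity prediction at moderate and weak
feedback (b = 0.05, d = 0.5):

```console
$ erythemawave velocity --a 2.14 --b 0.05 --d 0.5
v=0.2257011462
regime: expansion

$ erythemawave velocity --a 1.96 --b 0.05 --d 0.5
v=-0.06529316768
regime: shrinkage
```

Lowering the production rate from 2.14 to 1.96 moves the threshold S_T from
0.56 to 0.72 — closer to the inflamed state than to the noninflamed one —
and the front reverses: the same lesion now shrinks and heals. The
stationary boundary for b = 0.05 sits at a\* ≈ 1.99
(`erythemawave` exposes it as `v_zero_locus(0.05)`).

A full 2-D simulation (expanding spot on a 200×200 periodic grid, measured
along the row through the stimulation site) runs from a JSON config:

```sh
erythemawave simulate --config examples/expansion.json
```

writing snapshots (TSV), the diameter/area trace (CSV), the fitted front
velocity and the outcome label (`expansion`, `shrinkage`, `stationary` or
`extinct`) into the run directory.

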