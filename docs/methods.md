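# Model and methods

## Scope

`swarmtaxis` simulates groups of run-and-tumble agents navigating a static
2-D concentration landscape, compares three social mechanisms (independent,
fixed-weight zonal interactions, performance-adaptive weights), and measures
group navigation performance. Everything is generated in code: there are no
external data, and every reported number is an ensemble statistic over seeded
simulations.

## Terrain

The concentration field is

    C(x, y) = A_K · K0(κ · max(r, ε)) + A_p · sin(k_x x) · sin(k_y y)

with `r` the distance to the target. `K0` (modified Bessel function of the
second kind) is the steady radially symmetric solution of the 2-D diffusion
equation with a point source, so the first term plays the role of a chemical
diffusing from the target; the separable sinusoid superimposes a lattice of
local optima and saddles. An alternative periodic form,
`A_p (cos k_x x + cos k_y y)/2`, is available through
`TerrainParams.periodic_form`.

`K0` diverges at `r = 0`; the argument is capped at `κε` so the field is
finite, and inside the cap the gradient is defined as the ring value taken
along the true radial direction (zero radial part exactly at the target).
Agents are normally absorbed well outside the cap, so this convention only
matters for analysis utilities. `A_p = 0` gives a pure bowl whose gradient
points exactly at the target everywhere — the main analytic control case of
the test suite; `A_K = 0` gives the pure sinusoid whose stationary points are
known in closed form (extrema on the quarter-period lattice, saddles on the
half-period lattice), used to validate the critical-point classifier.

Critical points are located as grid-local minima of `|∇C|²` polished by
least-squares root finding on the analytic gradient, then classified by the
eigenvalue signs of a central-difference Hessian of the gradient
(step `10⁻⁴ λ`); eigenvalues below `10⁻⁶` of the spectral radius flag a
degenerate point.

## Individual dynamics

Per time step `dt`, an agent at heading θ moves `v0·dt·û(θ')` where θ' is:

- **run step** (counter < τ): the angle of
  `normalize(w·û(θ) + (1−w)·group)`, or θ itself when there is no group
  direction or the sum cancels (‖·‖ ≤ 1e−12);
- **tumble step** (every τ-th step exactly): `θ + δ`,
  `δ ~ N(0, σ²(g))` with the bounded logistic

      σ²(g) = σ²_min + (σ²_max − σ²_min) / (1 + exp(g / g0)),

  strictly decreasing in the measured gradient `g` and saturating at
  `σ_min`/`σ_max`. Group influence is skipped on tumble steps (a config flag
  `tumble_about_combined` instead centres the tumble on the combined
  direction).

Gaussian internal noise of standard deviation `σ_η` is added to the heading on
*every* step (including tumble steps), then the heading is wrapped to
(−π, π]. The measured gradient is the *temporal* concentration change along
the agent's own path per unit path length — the quantity a swimming cell can
actually sense; `gradient_mode="projected"` switches to the analytic spatial
gradient projected on the heading for comparison. `g` is refreshed once per
step and the next tumble uses the latest value.

Tumble clocks are staggered: initial phases are uniform over `{0, …, τ_i−1}`
so the swarm never tumbles in lockstep (`synchronous_tumbling` restores the
degenerate choice). The tumble step counts as the first step of the new run,
making inter-tumble intervals exactly `τ_i`. All agents update synchronously
from the time-t state; with a fixed seed the whole trajectory is bitwise
reproducible, and the vectorized engine is draw-for-draw identical to the
per-agent reference implementation (asserted in the tests).

## Interactions

Neighbour bands are half-open and lower-inclusive: repulsion `0 < d < R_r`,
alignment `R_r ≤ d < R_o`, attraction `R_o ≤ d < R_a`; each pairwise distance
falls in at most one band. Repulsion preempts everything: the avoidance
direction is `−normalize(Σ û(x_j − x_i))` over repulsion neighbours
(coincident agents contribute a random unit vector). Otherwise the group
direction is `normalize(Σ_orient û(θ_j) + a·Σ_attract û(x_j − x_i))`; the
alignment/attraction ratio `a` (`attraction_weight`) defaults to 1 (equal
unit weights). Exact cancellations return "no direction" and the agent keeps
its heading. Absorbed agents are invisible to all rules.

Weight policies: `independent` (no group direction, ever), `fixed`
(`w = fixed_w` always), `adaptive` — the hard-limit two-state rule evaluated
every step from the agent's own concentration change ΔC over the last step:
`w = w_high` (default 0.5, equal balance) if ΔC > 0, else `w = w_low`
(default 0, pure conformity). ΔC = 0 counts as non-beneficial. Because each
agent's weight is exactly `w_high` or `w_low`, the swarm-mean weight equals
`w_high` times the fraction of currently improving agents — a convenient
leadership readout.

Neighbour search is a fully vectorized all-pairs computation; at the study's
swarm sizes (N ≤ ~100) this is faster than spatial hashing and is verified
element-for-element against the brute-force per-agent rules.

## Metrics and censoring

An agent *arrives* the first step its distance to the target is ≤ the goal
radius; it is then frozen and excluded from interactions, alignment,
clustering and weight averages. Per run:

- **median path length** — the ⌈N/2⌉-th order statistic of arrival steps
  × `v0·dt` (for odd N the ordinary median). If fewer than half arrive the
  value is *censored* and propagates as `inf`, never imputed. The median
  rather than the mean deliberately ignores rare extremely long individual
  paths. A 90th-percentile variant uses the ⌈0.9N⌉-th order statistic.
- **error fraction** — `(L − D)/D` with `D` the start-to-target distance:
  the relative excess over the beeline, zero for a perfectly straight march.
- **alignment** — the polar order parameter `‖mean û(θ)‖` over non-arrived
  agents, averaged over steps until full absorption. 1 means a common
  heading; the all-agents-random floor is ≈ `1/√N`. The mean pairwise
  heading cosine is provided as an alternative (`pairwise_alignment`).
- **clusters** — connected components of the graph joining non-arrived agents
  closer than `R_a`, at the final step.

Ensemble aggregates report means and standard errors over runs (never over
agents), with path-length statistics over uncensored runs plus a separate
censor count. For trend comparisons across conditions with heavy censoring
(noise sweeps, run-length diversity) a *bounded* mean is also reported in
which censored runs enter at the step-budget path length `T_max·v0·dt` — a
lower bound on their true path, so differences it shows are conservative.

## The default calibrated configuration

The terrain constants and kinematic parameters of the original study are not
published, so the package ships one frozen configuration, calibrated once so
that the qualitative phenomena hold, and every benchmark refers to it. All
lengths are in units where the agent speed is 1 length/time.

| parameter | value | rationale |
|---|---|---|
| `A_K`, `κ` | 1.0, 0.1 | global valley spanning the whole domain; bowl slope `≈ A_K/r` at navigation range |
| `A_p`, `k_x = k_y` | 0.018, 4π (λ = 0.5) | periodic slope `A_p·k ≈ 0.23` beats the bowl beyond r ≈ 1, so most of the transit is through local optima |
| `ε` | 0.1 | `0.01/κ`: caps the K0 singularity without affecting navigation |
| `v0`, `dt`, `τ` | 1.0, 0.05, 4 | run length `v0·dt·τ = 0.2` = 40% of λ — inside the 1%–50% window where runs resolve the terrain |
| `σ_min`, `σ_max` | 0.1, 1.2 rad | persistent climbs, near-isotropic reorientation on descents |
| `g0` | 0.01 | ≈ 5% of the periodic slope: the logistic is effectively a sharp beneficial/harmful switch |
| `σ_η` | 0.05 rad/step | mild sensory/actuation noise; swept up to 0.8 in the noise benchmark |
| `R_r`, `R_o`, `R_a` | 0.08, 0.5, 2.0 | collision core well below the swarm's nearest-neighbour spacing; flock diameter of a few λ so members sample decorrelated terrain |
| `fixed_w` | 0.92 | the interior optimum of the shipped weight sweep; the fixed mechanism is always benchmarked at its best |
| `w_low`, `w_high` | 0.0, 0.5 | the two-state adaptive levels: follow the group / equal balance |
| N, `R_init` | 40, 1.0 | group starts unfragmented (everyone within `R_a` of neighbours) |
| start → target | (−4.85, 1.15) → (0, 0), D ≈ 4.98 | ≈ 10 periodic wavelengths of terrain to cross |
| goal radius | 0.35 | ≈ 70% of λ: the target basin the flock core sweeps on arrival. Tying it to `R_r` (the fallback when unset) makes absorption of a 40-agent flock an endgame queue that dominates the path metric, so the shipped config sets it explicitly |
| `T_max` | 1500 | 15× the beeline step count; censoring is absent for interacting mechanisms at default noise |

Benchmark ensemble sizes (chosen as the package's standard study sizes): 100
matched-seed rounds for the mechanism comparison and the error-fraction
estimates, 50 rounds per condition for the weight, noise and group-size
sweeps, 100 rounds for the run-length-diversity experiment. Per-run seeds are
`base_seed + round_index`; sweeps reuse the same seed list across conditions
(paired comparisons).

At this configuration the shipped benchmarks give: independent error fraction
≈ 1.6 with alignment ≈ 0.5; fixed ≈ 0.6–0.75 with alignment ≈ 0.7; adaptive
≈ 0.5 with alignment ≈ 0.7–0.8; the ranking adaptive < fixed < independent is
significant at p < 10⁻¹⁰ over 100 rounds; path length rises monotonically
with internal noise for every mechanism, and at `σ_η = 0.8` only the
independent swarm censors; with per-agent τ drawn uniformly from [1, 48] the
independent mechanism censors in ~90% of rounds while the adaptive swarm is
never censored.

## What the simulations do and do not emulate

The generator emulates the *study conditions*: a cohesive group released at a
fixed distance from a source on a rugged but statistically homogeneous
terrain, identical agents, constant speed, instantaneous heading changes, no
physical contact beyond the repulsion rule. It does not emulate real
bacterial hydrodynamics, cell shape or finite body size, variable swimming
speed, receptor saturation or adaptation kinetics, signalling delays, or
time-varying/stochastic chemical fields. Passing benchmarks therefore show
that the *mechanism comparison* behaves as described under these idealized
conditions, not that the absolute path lengths transfer to any real swarm.

## Numerical choices

- Half-open lower-inclusive zone bands; ΔC = 0 treated as non-beneficial;
  direction sums below 1e−12 in norm are "no direction" (keep heading).
- Headings wrapped to (−π, π]; displacement per active step is exactly
  `v0·dt`; arrived agents are frozen in place.
- The logistic tumble variance is evaluated through `expit`, safe against
  overflow for any `g`.
- Critical-point search: grid-minimum candidates of `|∇C|²`, least-squares
  polish, residual gradient-norm filter at 1e−6, duplicate merge at half the
  grid resolution.
- Censored medians are `inf` end to end; only the explicitly "bounded"
  aggregates substitute the `T_max` path-length bound.
- The engine aborts with a diagnostic on non-finite concentrations (diverging
  state), which no shipped configuration triggers.

## Known limitations

- **Independent-agent alignment.** Independent chemotactic walkers that make
  any net progress carry a common target-ward heading bias, so their polar
  order at the default calibration sits near 0.5 — well above the
  `1/√N ≈ 0.16` disorder floor. Configurations rough enough to push their
  alignment toward the floor (net bias ≈ 0) also slow the fixed flock beyond
  the calibrated error-fraction band: with this interaction model the
  collective-over-individual speed gain tops out around 3×, so "flocks in
  band + independents fully disordered" cannot hold simultaneously. The
  benchmark suite asserts the strong disorder contrast anyway and documents
  the failure.
- **Fixed-mechanism robustness to run-length diversity.** At its optimal
  weight the fixed flock survives per-agent τ drawn from [1, 48] (and mostly
  from [1, 96]): long-run members are pulled back by the per-step group
  coupling before they detach, so the fixed mechanism rarely exceeds the
  simulation length, unlike the original account where both non-adaptive
  mechanisms mostly fail. The corresponding benchmark assertion is left
  strict and fails by design rather than weakening the claim.
- The terrain is additive and separable; bottleneck geometry is implicit
  (saddle corridors), not designed.
- Absorption at the goal is a modelling convention; disable it by setting the
  goal radius below `ε` if arrival dynamics themselves are of interest.
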