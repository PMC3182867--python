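# swarmtaxis

Agent-based simulation of collective chemotactic navigation: groups of
bacteria-inspired run-and-tumble agents climbing a noisy chemical landscape,
with zonal social interactions whose strength can adapt to each agent's own
recent performance.

The package is for researchers in collective behaviour, chemotaxis modelling
and swarm robotics who want a small, fully reproducible test bed for one
question: **when does listening to your neighbours beat trusting your own
sensor, and how much better is switching between the two on the fly?**

## The model

**Terrain.** A static concentration map
`C(x, y) = A_K·K0(κ·max(r, ε)) + A_p·sin(k_x x)·sin(k_y y)`,
where `r` is the distance to the target. The modified Bessel function `K0` is
the steady radial solution of 2-D diffusion from a point source, so the first
term is a smooth global valley with the target (the concentration maximum) at
its bottom; the sinusoidal term overlays periodic mountains, valleys and
saddles that create local optima and bottlenecks. Height is `−C`.

**Individual motion.** Each agent moves at constant speed `v0` and carries a
heading θ. Every `τ` steps it *tumbles*: θ ← θ + δ with
`δ ~ N(0, σ²(g))`, where `g` is the concentration change the agent measured
along its own path (per unit path length) and

```
σ²(g) = σ²_min + (σ²_max − σ²_min) / (1 + exp(g / g0))
```

so runs that climb the gradient persist (small deflection) and runs that
descend are abandoned (near-isotropic reorientation) — chemotaxis through the
tumble angle at constant tumble rate. Gaussian internal noise `η ~ N(0, σ²_η)`
perturbs the heading every step.

**Interactions.** Neighbours are classified into three distance bands:
repulsion (`d < R_r`), velocity alignment (`R_r ≤ d < R_o`) and attraction
(`R_o ≤ d < R_a`). Anyone inside `R_r` triggers pure collision avoidance;
otherwise the group direction is the normalized sum of the aligners' unit
headings and the unit vectors toward attractors. On non-tumble steps the
agent steers along

```
d_i = normalize( w·û(θ_i) + (1 − w)·ĝroup_i )
```

with mixing weight `w ∈ [0, 1]`. Three mechanisms are compared:

- **independent** — neighbours ignored (`w = 1` effectively),
- **fixed** — constant `w`,
- **adaptive** — the two-state performance rule: `w = 0.5` after a step in
  which the agent's measured concentration increased (trust yourself), `w = 0`
  otherwise (follow the group).

**Metrics.** Agents are absorbed on reaching the goal radius around the
target. A run is summarized by the *median path length* (arrival time of the
half-way agent × speed, robust to stragglers; censored if fewer than half
arrive), the *error fraction* `(L − D)/D` against the straight-line distance
`D`, the time-averaged polar order parameter of non-arrived headings
(*alignment*), the number of connected components of the `R_a`-contact graph
(*clusters*), and the mean interaction weight.

## Worked example

```python
from swarmtaxis import default_config, mechanism_comparison

cfg = default_config()                      # the frozen calibrated setup
cmp = mechanism_comparison(cfg, n_rounds=20, base_seed=1)
```

prints, per mechanism (matched seeds, 40 agents, start-to-target distance
`D = 4.98`, i.e. ten terrain wavelengths):

```
independent: error fraction 1.56, alignment 0.54, censored 0/20
      fixed: error fraction 0.62, alignment 0.66, censored 0/20
   adaptive: error fraction 0.50, alignment 0.69, censored 0/20
adaptive<fixed: rank-sum p = 1.15e-03
fixed<independent: rank-sum p = 3.38e-08
adaptive<independent: rank-sum p = 3.19e-08
```

Read: a lone chemotactic walker travels 2.6× the beeline to reach the target
on this terrain; a statically coupled flock cuts the excess to 62%; letting
each agent modulate its conformity by its own last measurement cuts it to
50% — and the ordering is significant already at 20 rounds. `mean_weight` of
the adaptive swarm equals `0.5 × (fraction of agents whose last step improved
their concentration)`, so it doubles as a live measure of how many agents are
currently "leading".

## Command line

```bash
swarmtaxis init-config --out cfg.json            # dump the default config
swarmtaxis run --config cfg.json --seed 3 --out out/
swarmtaxis sweep --param fixed_w --values 0,0.25,0.5,0.75,1 --rounds 50 --out sweep.csv
swarmtaxis compare --rounds 100 --seed 0 --out cmp/
swarmtaxis validate --config cfg.json            # kinematics vs terrain check
swarmtaxis terrain --grid 0.05 --critical-points --out terrain/
```

Configurations are JSON with five sections (`terrain`, `motion`, `zones`,
`policy`, `run`); unknown keys are rejected. All outputs are CSV/JSON;
ensembles derive per-run seeds as `base_seed + round` so partial ensembles
extend reproducibly and sweeps reuse matched seeds across conditions.

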