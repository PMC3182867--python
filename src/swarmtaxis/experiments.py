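"""Configuration, the swarm engine, ensembles, and the study's parameter sweeps.

A run places ``n_agents`` agents uniformly in a disc of radius ``init_radius``
around the start position, headings uniform over all directions, and iterates
the synchronous loop: every agent's group direction is computed from the
time-t state, then every agent advances one run-and-tumble step (see
:mod:`swarmtaxis.dynamics` and :mod:`swarmtaxis.interactions`).  Agents are
absorbed on reaching the goal radius around the target.  The engine is fully
vectorized over agents but reproduces the per-agent rules draw for draw.

Ensembles derive per-run seeds as ``base_seed + round_index`` so partial
ensembles extend reproducibly; sweeps reuse the same seed list for every
swept value (matched seeds, a variance-reduction device for the paired
mechanism and parameter comparisons).

The shipped :func:`default_config` is the frozen calibrated configuration all
benchmark comparisons refer to: a rugged terrain whose start-to-target line
spans ~10 periodic wavelengths, with run length 20% of the wavelength.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .dynamics import AgentState, MotionParams, tumble_sd, unit, wrap_angle
from .interactions import InteractionZones, WeightPolicy, group_directions_all
from .metrics import SummaryStats, Trajectory, summarize
from .terrain import (
    ConfigurationError,
    TerrainParams,
    concentration,
    concentration_gradient,
)

__all__ = [
    "SimulationConfig",
    "EnsembleResult",
    "ComparisonResult",
    "default_config",
    "init_swarm",
    "run_simulation",
    "run_ensemble",
    "sweep",
    "mechanism_comparison",
    "validate_config",
    "load_config",
    "save_config",
]

MECHANISMS = ("independent", "fixed", "adaptive")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete specification of one run (terrain, motion, zones, policy, run)."""

    terrain: TerrainParams = field(default_factory=TerrainParams)
    motion: MotionParams = field(default_factory=MotionParams)
    zones: InteractionZones = field(default_factory=InteractionZones)
    policy: WeightPolicy = field(default_factory=WeightPolicy)
    n_agents: int = 40
    start_position: tuple[float, float] = (-4.85, 1.15)
    init_radius: float = 1.0
    max_steps: int = 1500
    goal_radius: Optional[float] = 0.35
    tau_range: Optional[tuple[int, int]] = None  # per-agent heterogeneous runs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ConfigurationError("n_agents must be >= 1")
        if not (self.init_radius > 0):
            raise ConfigurationError("init_radius must be > 0")
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be >= 1")
        d = np.linalg.norm(
            np.asarray(self.start_position) - np.asarray(self.terrain.target_position)
        )
        if not d > self.init_radius:
            raise ConfigurationError(
                "start-to-target distance must exceed init_radius"
            )
        if self.goal_radius is not None and not self.goal_radius > 0:
            raise ConfigurationError("goal_radius must be > 0")
        if self.tau_range is not None:
            lo, hi = self.tau_range
            if not (1 <= lo <= hi):
                raise ConfigurationError("tau_range must satisfy 1 <= lo <= hi")

    @property
    def resolved_goal_radius(self) -> float:
        return self.goal_radius if self.goal_radius is not None else self.zones.repulsion

    @property
    def straight_line_distance(self) -> float:
        return float(
            np.linalg.norm(
                np.asarray(self.start_position) - np.asarray(self.terrain.target_position)
            )
        )


def default_config() -> SimulationConfig:
    """The frozen calibrated default configuration (see docs/methods.md)."""
    return SimulationConfig()


# ---------------------------------------------------------------------------
# configuration (de)serialization — strict, unknown keys rejected
# ---------------------------------------------------------------------------

_SECTIONS = {
    "terrain": TerrainParams,
    "motion": MotionParams,
    "zones": InteractionZones,
    "policy": WeightPolicy,
}
_TUPLE_FIELDS = {
    "target_position",
    "wavenumbers",
    "domain_bounds",
    "start_position",
    "tau_range",
}


def _build_section(cls, data: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown keys in {cls.__name__} section: {sorted(unknown)}"
        )
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and v is not None else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data.pop(name))
    run = data.pop("run", {})
    if data:
        raise ConfigurationError(f"unknown config sections: {sorted(data)}")
    run_fields = {
        f.name for f in fields(SimulationConfig) if f.name not in _SECTIONS
    }
    unknown = set(run) - run_fields
    if unknown:
        raise ConfigurationError(f"unknown keys in run section: {sorted(unknown)}")
    kwargs.update(
        {
            k: tuple(v) if k in _TUPLE_FIELDS and v is not None else v
            for k, v in run.items()
        }
    )
    return SimulationConfig(**kwargs)


def config_to_dict(config: SimulationConfig) -> dict:
    run = {
        f.name: getattr(config, f.name)
        for f in fields(SimulationConfig)
        if f.name not in _SECTIONS
    }
    out = {name: asdict(getattr(config, name)) for name in _SECTIONS}
    out["run"] = run
    return json.loads(json.dumps(out))  # tuples -> lists, plain JSON types


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


@dataclass
class _Swarm:
    """Vectorized swarm state (one array per AgentState field)."""

    positions: np.ndarray  # (N, 2)
    headings: np.ndarray  # (N,)
    weights: np.ndarray  # (N,)
    since_tumble: np.ndarray  # (N,) int
    tau: np.ndarray  # (N,) int
    last_concentration: np.ndarray  # (N,)
    last_gradient: np.ndarray  # (N,)
    arrived: np.ndarray  # (N,) bool


def _init_swarm_arrays(config: SimulationConfig, rng: np.random.Generator) -> _Swarm:
    n = config.n_agents
    if config.tau_range is not None:
        lo, hi = config.tau_range
        tau = rng.integers(lo, hi + 1, size=n)
    else:
        tau = np.full(n, config.motion.run_length, dtype=int)
    # area-uniform disc
    r = config.init_radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    phi = rng.uniform(-np.pi, np.pi, size=n)
    pos = np.asarray(config.start_position, dtype=float) + r[:, None] * np.stack(
        [np.cos(phi), np.sin(phi)], axis=1
    )
    headings = wrap_angle(rng.uniform(-np.pi, np.pi, size=n))
    if config.motion.synchronous_tumbling:
        phase = np.zeros(n, dtype=int)
    else:
        phase = rng.integers(0, tau)  # staggered tumble clocks
    c0 = np.atleast_1d(concentration(pos, config.terrain))
    goal = config.resolved_goal_radius
    d0 = np.linalg.norm(pos - np.asarray(config.terrain.target_position), axis=1)
    return _Swarm(
        positions=pos,
        headings=np.atleast_1d(headings).astype(float),
        weights=np.full(n, config.policy.resolve_initial_w(), dtype=float),
        since_tumble=phase.astype(int),
        tau=tau.astype(int),
        last_concentration=c0,
        last_gradient=np.zeros(n),
        arrived=d0 <= goal,
    )


def init_swarm(config: SimulationConfig, rng: np.random.Generator) -> list[AgentState]:
    """Initial swarm as a list of per-agent states (same draws as the engine)."""
    s = _init_swarm_arrays(config, rng)
    return [
        AgentState(
            position=s.positions[i].copy(),
            heading=float(s.headings[i]),
            weight=float(s.weights[i]),
            steps_since_tumble=int(s.since_tumble[i]),
            run_length=int(s.tau[i]),
            last_concentration=float(s.last_concentration[i]),
            last_gradient=0.0,
            arrived=bool(s.arrived[i]),
        )
        for i in range(config.n_agents)
    ]


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------


def run_simulation(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Trajectory:
    """Run one simulation to ``max_steps`` or full absorption.

    Synchronous update: all group directions are computed from the time-t
    state, then all agents advance.  Adaptive weights are refreshed every
    step from each agent's per-step concentration change.  Fully determined
    by (config, seed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    terrain = config.terrain
    motion = config.motion
    zones = config.zones
    policy = config.policy
    n = config.n_agents
    goal = config.resolved_goal_radius
    target = np.asarray(terrain.target_position, dtype=float)
    step_len = motion.step_length
    interacting = policy.mode != "independent"
    adaptive = policy.mode == "adaptive"

    s = _init_swarm_arrays(config, rng)
    t_max = config.max_steps
    rec_pos = np.empty((t_max + 1, n, 2))
    rec_theta = np.empty((t_max + 1, n))
    rec_w = np.empty((t_max + 1, n))
    rec_arr = np.empty((t_max + 1, n), dtype=bool)
    rec_pos[0] = s.positions
    rec_theta[0] = s.headings
    rec_w[0] = s.weights
    rec_arr[0] = s.arrived

    cos_t = np.cos(s.headings)
    sin_t = np.sin(s.headings)

    t_end = t_max
    for t in range(1, t_max + 1):
        active = ~s.arrived
        if not active.any():
            t_end = t - 1
            break

        if interacting:
            gd, has_gd = group_directions_all(
                s.positions, s.headings, active, zones, rng
            )
        due = active & (s.since_tumble >= s.tau)
        new_theta = s.headings.copy()

        if interacting:
            steer = active & ~due & has_gd
            if steer.any():
                w = s.weights
                vx = w * cos_t + (1.0 - w) * gd[:, 0]
                vy = w * sin_t + (1.0 - w) * gd[:, 1]
                ok = steer & (np.hypot(vx, vy) > 1e-12)
                new_theta[ok] = np.arctan2(vy[ok], vx[ok])

        idx_due = np.nonzero(due)[0]
        if len(idx_due):
            if motion.tumble_about_combined and interacting:
                base = new_theta[idx_due]
                hg = has_gd[idx_due]
                if hg.any():
                    w = s.weights[idx_due]
                    vx = w * cos_t[idx_due] + (1.0 - w) * gd[idx_due, 0]
                    vy = w * sin_t[idx_due] + (1.0 - w) * gd[idx_due, 1]
                    ok = hg & (np.hypot(vx, vy) > 1e-12)
                    base = np.where(ok, np.arctan2(vy, vx), base)
            else:
                base = s.headings[idx_due]
            sd = tumble_sd(s.last_gradient[idx_due], motion)
            new_theta[idx_due] = base + rng.standard_normal(len(idx_due)) * sd
            s.since_tumble[idx_due] = 0

        if motion.internal_noise_sd > 0:
            new_theta[active] = (
                new_theta[active]
                + rng.standard_normal(int(active.sum())) * motion.internal_noise_sd
            )
        new_theta = wrap_angle(new_theta)

        s.headings[active] = new_theta[active]
        cos_t = np.cos(s.headings)
        sin_t = np.sin(s.headings)
        s.positions[active, 0] += step_len * cos_t[active]
        s.positions[active, 1] += step_len * sin_t[active]

        new_c = concentration(s.positions[active], terrain)
        if not np.all(np.isfinite(new_c)):
            raise FloatingPointError(
                f"non-finite concentration at step {t}; diverging state"
            )
        dc = new_c - s.last_concentration[active]
        if motion.gradient_mode == "temporal":
            s.last_gradient[active] = dc / step_len
        else:
            grad = concentration_gradient(s.positions[active], terrain)
            s.last_gradient[active] = (
                grad[:, 0] * cos_t[active] + grad[:, 1] * sin_t[active]
            )
        s.last_concentration[active] = new_c
        if adaptive:
            s.weights[active] = np.where(dc > 0, policy.w_high, policy.w_low)
        s.since_tumble[active] += 1

        d_target = np.linalg.norm(s.positions[active] - target, axis=1)
        newly = np.nonzero(active)[0][d_target <= goal]
        if len(newly):
            s.arrived[newly] = True

        rec_pos[t] = s.positions
        rec_theta[t] = s.headings
        rec_w[t] = s.weights
        rec_arr[t] = s.arrived

    return Trajectory(
        positions=rec_pos[: t_end + 1],
        headings=rec_theta[: t_end + 1],
        weights=rec_w[: t_end + 1],
        arrived=rec_arr[: t_end + 1],
        dt=motion.dt,
        speed=motion.speed,
        start_position=np.asarray(config.start_position, dtype=float),
        target_position=target,
        goal_radius=goal,
        max_steps=t_max,
    )


# ---------------------------------------------------------------------------
# ensembles, sweeps, comparisons
# ---------------------------------------------------------------------------


@dataclass
class EnsembleResult:
    """Per-run records plus aggregates for one condition."""

    records: pd.DataFrame
    config: SimulationConfig
    base_seed: int

    def aggregate(self) -> dict:
        """Means / SEs over runs (path-length stats over uncensored runs)."""
        df = self.records
        unc = df[~df["censored"]]
        n_unc = len(unc)
        out = {
            "n_rounds": len(df),
            "n_censored": int(df["censored"].sum()),
            "mean_alignment": float(df["alignment"].mean()),
            "mean_n_clusters": float(df["n_clusters"].mean()),
            "mean_weight": float(df["mean_weight"].mean()),
        }
        for col in ("median_path_length", "error_fraction", "p90_path_length"):
            vals = unc[col].to_numpy(dtype=float)
            # p90 can be censored even when the median is not
            vals = vals[np.isfinite(vals)]
            out[f"mean_{col}"] = float(vals.mean()) if len(vals) else np.nan
            out[f"se_{col}"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        # censoring-robust summary: censored runs enter at the step-budget path
        # length (a lower bound on their true path), so means stay finite and
        # monotone under conditions that drive runs past the budget
        cap = self.config.max_steps * self.config.motion.speed * self.config.motion.dt
        bounded = df["median_path_length"].to_numpy(dtype=float).copy()
        bounded[~np.isfinite(bounded)] = cap
        out["mean_median_path_length_bounded"] = float(bounded.mean())
        out["se_median_path_length_bounded"] = (
            float(bounded.std(ddof=1) / np.sqrt(len(bounded)))
            if len(bounded) > 1
            else np.nan
        )
        out["censor_rate"] = out["n_censored"] / len(df)
        return out


def _run_seeds(base_seed: int, n_rounds: int) -> list[int]:
    # base_seed + index: documented derivation so partial ensembles extend
    return [int(base_seed) + i for i in range(n_rounds)]


def run_ensemble(
    config: SimulationConfig, n_rounds: int, base_seed: int
) -> EnsembleResult:
    """``n_rounds`` independent runs with per-run seeds ``base_seed + i``."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rows = []
    for seed in _run_seeds(base_seed, n_rounds):
        traj = run_simulation(replace(config, seed=seed))
        stats = summarize(traj, config.policy.mode, seed, config.zones.attraction)
        rows.append(stats.as_dict())
    return EnsembleResult(pd.DataFrame(rows), config, base_seed)


_SWEEPABLE = ("fixed_w", "n_agents", "internal_noise_sd", "radii", "tau_range")


def _apply_sweep_value(config: SimulationConfig, name: str, value):
    if name == "fixed_w":
        return replace(config, policy=replace(config.policy, fixed_w=float(value)))
    if name == "n_agents":
        return replace(config, n_agents=int(value))
    if name == "internal_noise_sd":
        return replace(
            config, motion=replace(config.motion, internal_noise_sd=float(value))
        )
    if name == "radii":
        r_o, r_a = value
        return replace(
            config,
            zones=replace(config.zones, orientation=float(r_o), attraction=float(r_a)),
        )
    if name == "tau_range":
        lo, hi = value
        return replace(config, tau_range=(int(lo), int(hi)))
    raise ValueError(
        f"unknown sweep parameter {name!r}; sweepable: {', '.join(_SWEEPABLE)}"
    )


def sweep(
    config: SimulationConfig,
    parameter_name: str,
    values: Sequence,
    n_rounds: int,
    base_seed: int,
) -> pd.DataFrame:
    """Ensemble per value, matched seeds across values; long-format table."""
    frames = []
    for value in values:
        cfg = _apply_sweep_value(config, parameter_name, value)
        res = run_ensemble(cfg, n_rounds, base_seed)
        df = res.records.copy()
        df.insert(0, "parameter", parameter_name)
        df.insert(1, "value", [value] * len(df))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class ComparisonResult:
    records: pd.DataFrame
    rank_tests: dict

    def path_lengths(self, mechanism: str) -> np.ndarray:
        df = self.records[self.records["mechanism"] == mechanism]
        return df["median_path_length"].to_numpy(dtype=float)


def mechanism_comparison(
    config: SimulationConfig, n_rounds: int, base_seed: int
) -> ComparisonResult:
    """Run all three mechanisms on matched seeds and rank their path lengths.

    Censored runs enter the rank-sum tests as +inf (worst rank).  The tests
    are one-sided Mann-Whitney U for the orderings adaptive < fixed and
    fixed < independent.
    """
    frames = {}
    for mode in MECHANISMS:
        cfg = replace(config, policy=replace(config.policy, mode=mode))
        frames[mode] = run_ensemble(cfg, n_rounds, base_seed).records
    records = pd.concat(frames.values(), ignore_index=True)
    tests = {}
    for a, b in (("adaptive", "fixed"), ("fixed", "independent"), ("adaptive", "independent")):
        xa = frames[a]["median_path_length"].to_numpy(dtype=float)
        xb = frames[b]["median_path_length"].to_numpy(dtype=float)
        stat, p = mannwhitneyu(xa, xb, alternative="less")
        tests[f"{a}<{b}"] = {"U": float(stat), "p": float(p)}
    return ComparisonResult(records, tests)


# ---------------------------------------------------------------------------
# configuration diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ConfigDiagnostics:
    warnings: list[str]
    terrain_wavelength: float
    terrain_slope: float
    run_length_fraction: float

    @property
    def ok(self) -> bool:
        return not self.warnings


def validate_config(config: SimulationConfig) -> ConfigDiagnostics:
    """Soft diagnostics matching kinematics to the terrain's characteristic
    sizes (hard invariant violations raise at construction instead).

    A run (``v0*dt*run_length``) far below the periodic wavelength means the
    agent cannot resolve concentration changes; a run far above it makes
    motion large independent leaps on an irregular terrain.  A repulsion
    radius beyond half the wavelength makes groups aggregate at the terrain
    scale and sample near-identical concentrations.
    """
    lam = config.terrain.wavelength
    run_len = config.motion.step_length * config.motion.run_length
    frac = run_len / lam
    warnings = []
    if frac < 0.01:
        warnings.append(
            f"runs too short for terrain: run length {run_len:.3g} is "
            f"{frac:.2%} of the wavelength {lam:.3g} (< 1%)"
        )
    if frac > 0.5:
        warnings.append(
            f"runs too long for terrain: run length {run_len:.3g} is "
            f"{frac:.2%} of the wavelength {lam:.3g} (> 50%)"
        )
    if config.zones.repulsion > 0.5 * lam:
        warnings.append(
            f"repulsion radius {config.zones.repulsion:.3g} exceeds half the "
            f"terrain wavelength {lam:.3g}; groups will sample near-identical "
            "concentrations"
        )
    return ConfigDiagnostics(
        warnings=warnings,
        terrain_wavelength=lam,
        terrain_slope=config.terrain.characteristic_slope,
        run_length_fraction=frac,
    )
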