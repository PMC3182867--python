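"""Single-agent run-and-tumble kinematics.

Agents move at constant speed ``v0`` and reorient in two ways: every ``tau``
steps they *tumble* — a Gaussian deflection whose standard deviation shrinks
as the concentration measured along their own path rises, so that successful
directions persist (classic chemotactic bias, implemented through the tumble
angle rather than the tumble rate); on all other ("run") steps they steer
toward a weighted combination of their own heading and the group-derived
direction.  Small Gaussian internal noise perturbs the heading on every step.

Like swimming bacteria, agents are assumed too small to sense a spatial
gradient instantaneously: the "gradient" entering the tumble statistics is by
default the temporal concentration change along the agent's own path per unit
path length (``gradient_mode="temporal"``).  A ``"projected"`` mode that
projects the analytic field gradient onto the heading is available for
comparison.

The functions here define the per-agent semantics; the ensemble engine in
:mod:`swarmtaxis.experiments` vectorizes exactly these rules over the swarm
(and the test-suite checks trajectory equality between the two routes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .terrain import ConfigurationError, TerrainParams, concentration, concentration_gradient

__all__ = [
    "MotionParams",
    "AgentState",
    "measured_gradient",
    "tumble_sd",
    "tumble",
    "combine_directions",
    "advance",
    "wrap_angle",
    "unit",
]


def wrap_angle(theta):
    """Wrap angle(s) to the principal range (-pi, pi]."""
    wrapped = np.mod(-np.asarray(theta) + np.pi, 2.0 * np.pi)
    return np.pi - wrapped


def unit(theta):
    """Unit vector(s) for heading angle(s); output shape ``theta.shape + (2,)``."""
    theta = np.asarray(theta, dtype=float)
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


@dataclass(frozen=True)
class MotionParams:
    """Kinematic parameters of a single agent.

    speed ``v0`` (length/time) and time step ``dt`` (time) set the per-step
    displacement ``v0*dt``; ``run_length`` is the number of steps between
    tumbles; ``internal_noise_sd`` (radians) is applied to the heading every
    step; the tumble deflection is Gaussian with standard deviation between
    ``tumble_sd_min`` and ``tumble_sd_max`` (radians), interpolated by a
    logistic in the measured gradient with scale ``gradient_scale``
    (concentration/length).
    """

    speed: float = 1.0
    dt: float = 0.05
    run_length: int = 4
    internal_noise_sd: float = 0.05
    tumble_sd_min: float = 0.1
    tumble_sd_max: float = 1.2
    gradient_scale: float = 0.01
    gradient_mode: Literal["temporal", "projected"] = "temporal"
    tumble_about_combined: bool = False
    synchronous_tumbling: bool = False

    def __post_init__(self) -> None:
        if not (self.speed > 0 and self.dt > 0):
            raise ConfigurationError("speed and dt must be > 0")
        if not (self.run_length >= 1):
            raise ConfigurationError("run_length must be >= 1")
        if self.internal_noise_sd < 0:
            raise ConfigurationError("internal_noise_sd must be >= 0")
        if not (0 < self.tumble_sd_min <= self.tumble_sd_max):
            raise ConfigurationError("need 0 < tumble_sd_min <= tumble_sd_max")
        if not (self.gradient_scale > 0):
            raise ConfigurationError("gradient_scale must be > 0")
        if self.gradient_mode not in ("temporal", "projected"):
            raise ConfigurationError(f"unknown gradient_mode {self.gradient_mode!r}")

    @property
    def step_length(self) -> float:
        return self.speed * self.dt


@dataclass
class AgentState:
    """Mutable per-agent state.

    ``steps_since_tumble`` counts moves since the last tumble (the tumble
    step itself counts as the first move of the new run, so tumbles recur
    every ``run_length`` steps exactly).
    """

    position: np.ndarray
    heading: float
    weight: float = 1.0
    steps_since_tumble: int = 0
    run_length: int = 4
    last_concentration: float = 0.0
    last_gradient: float = 0.0
    arrived: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.heading = float(wrap_angle(self.heading))
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigurationError("weight must lie in [0, 1]")


def measured_gradient(
    last_concentration: float, new_concentration: float, path_increment: float
) -> float:
    """Concentration change per unit path length along the agent's own track.

    This is the agent's (signed) estimate of the directional derivative along
    its heading, obtained by temporal sampling while swimming.
    """
    if path_increment <= 0:
        raise ValueError("path_increment must be > 0")
    return (new_concentration - last_concentration) / path_increment


def tumble_sd(g, params: MotionParams):
    """Tumble-angle standard deviation as a function of the measured gradient.

    sigma^2(g) = sd_min^2 + (sd_max^2 - sd_min^2) / (1 + exp(g / g0)):
    a bounded logistic, strictly decreasing in g, saturating at sd_min for
    strong up-gradient motion and sd_max for strong down-gradient motion.
    """
    g = np.asarray(g, dtype=float)
    lo = params.tumble_sd_min**2
    hi = params.tumble_sd_max**2
    # expit(-z) = 1/(1+e^z), overflow-safe
    from scipy.special import expit

    var = lo + (hi - lo) * expit(-g / params.gradient_scale)
    return np.sqrt(var)


def tumble(heading: float, g: float, params: MotionParams, rng: np.random.Generator) -> float:
    """Draw a tumble: Gaussian deflection with gradient-dependent spread."""
    delta = rng.standard_normal() * float(tumble_sd(g, params))
    return float(wrap_angle(heading + delta))


def combine_directions(
    heading: float, group_direction: Optional[np.ndarray], weight: float
) -> np.ndarray:
    """Mix the agent's own heading with the group-derived direction.

    d = normalize(w * u(heading) + (1 - w) * group_direction); with no
    neighbors (``group_direction is None``) or an exactly cancelling sum the
    agent keeps its previous heading.
    """
    if not (0.0 <= weight <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    u_self = unit(heading)
    if group_direction is None:
        return u_self
    v = weight * u_self + (1.0 - weight) * np.asarray(group_direction, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        return u_self
    return v / n


def advance(
    agent: AgentState,
    group_direction: Optional[np.ndarray],
    terrain: TerrainParams,
    params: MotionParams,
    rng: np.random.Generator,
) -> AgentState:
    """One synchronous time step of a single agent (in place; returns agent).

    Run step: steer to the self/group combination, else keep heading.  Tumble
    step (due when ``steps_since_tumble >= run_length``): Gaussian deflection
    about the current heading; group influence is skipped that step (or about
    the combined direction when ``tumble_about_combined``).  Internal noise is
    added every step, then the agent moves ``v0*dt`` along the new heading and
    refreshes its concentration measurement and measured gradient.

    RNG draw order (tumble deflection first if due, then internal noise)
    matches the vectorized swarm engine so that an N=1 interacting-free swarm
    reproduces this walk draw for draw.
    """
    if agent.arrived:
        return agent
    if not (np.all(np.isfinite(agent.position)) and np.isfinite(agent.heading)):
        raise ValueError("non-finite agent state")

    def steer_angle() -> float:
        # the heading is carried unchanged unless a group pull actually turns
        # it, so an isolated walk never drifts through angle round-trips
        if group_direction is None:
            return agent.heading
        v = agent.weight * unit(agent.heading) + (1.0 - agent.weight) * np.asarray(
            group_direction, dtype=float
        )
        if np.hypot(v[0], v[1]) <= 1e-12:
            return agent.heading
        return float(np.arctan2(v[1], v[0]))

    due = agent.steps_since_tumble >= agent.run_length
    if due:
        base = steer_angle() if params.tumble_about_combined else agent.heading
        delta = rng.standard_normal() * float(tumble_sd(agent.last_gradient, params))
        new_angle = base + delta
        agent.steps_since_tumble = 0
    else:
        new_angle = steer_angle()

    if params.internal_noise_sd > 0:
        new_angle += rng.standard_normal() * params.internal_noise_sd
    agent.heading = float(wrap_angle(new_angle))
    agent.position = agent.position + params.step_length * unit(agent.heading)

    new_c = float(concentration(agent.position, terrain))
    if params.gradient_mode == "temporal":
        agent.last_gradient = measured_gradient(
            agent.last_concentration, new_c, params.step_length
        )
    else:
        grad = concentration_gradient(agent.position, terrain)
        agent.last_gradient = float(np.dot(grad, unit(agent.heading)))
    agent.last_concentration = new_c
    agent.steps_since_tumble += 1
    return agent
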