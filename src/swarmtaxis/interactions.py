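"""Zonal neighbor rules and interaction-weight policies.

Each agent partitions its neighbors into three concentric distance bands
(the zonal model of collective motion): repulsion for ``0 < d < R_r``,
velocity alignment for ``R_r <= d < R_o`` and attraction for
``R_o <= d < R_a`` (half-open, lower-inclusive bands; the boundary
convention is a model choice, fixed here once).  Repulsion strictly
preempts the other zones: an agent with anyone inside ``R_r`` only avoids
collision.  Arrived (absorbed) agents are invisible to every rule.

Weight policies set the mixing coefficient ``w`` between self-direction and
the group direction: ``independent`` ignores neighbors entirely, ``fixed``
uses a constant ``w``, and ``adaptive`` is the performance-dependent
two-state rule — after a step that increased the measured concentration the
agent trusts itself more (``w_high``, default 0.5, an equal balance),
otherwise it defers to the group (``w_low``, default 0, pure conformity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .dynamics import unit
from .terrain import ConfigurationError

__all__ = [
    "InteractionZones",
    "WeightPolicy",
    "neighbor_sets",
    "repulsion_direction",
    "align_attract_direction",
    "group_direction",
    "group_directions_all",
    "update_weight",
]


@dataclass(frozen=True)
class InteractionZones:
    """Radii of the repulsion / orientation / attraction bands, 0 < R_r < R_o < R_a."""

    repulsion: float = 0.08
    orientation: float = 0.5
    attraction: float = 2.0
    attraction_weight: float = 1.0  # weight of the attraction term relative to alignment

    def __post_init__(self) -> None:
        if not (0 < self.repulsion < self.orientation < self.attraction):
            raise ConfigurationError("zone radii must satisfy 0 < R_r < R_o < R_a")
        if not (self.attraction_weight > 0):
            raise ConfigurationError("attraction_weight must be > 0")


@dataclass(frozen=True)
class WeightPolicy:
    """Interaction-weight rule.

    ``mode="independent"`` forces the group direction to none (w is
    effectively 1); ``"fixed"`` keeps ``fixed_w`` forever; ``"adaptive"``
    switches between ``w_high`` (concentration increased last step) and
    ``w_low`` (otherwise).  ``initial_w`` defaults to the mode's natural
    starting weight.
    """

    mode: Literal["independent", "fixed", "adaptive"] = "fixed"
    fixed_w: float = 0.92
    w_low: float = 0.0
    w_high: float = 0.5
    initial_w: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("independent", "fixed", "adaptive"):
            raise ConfigurationError(f"unknown weight-policy mode {self.mode!r}")
        if not (0.0 <= self.fixed_w <= 1.0):
            raise ConfigurationError("fixed_w must lie in [0, 1]")
        if not (0.0 <= self.w_low < self.w_high <= 1.0):
            raise ConfigurationError("need 0 <= w_low < w_high <= 1")
        if self.initial_w is not None and not (0.0 <= self.initial_w <= 1.0):
            raise ConfigurationError("initial_w must lie in [0, 1]")

    def resolve_initial_w(self) -> float:
        if self.initial_w is not None:
            return self.initial_w
        if self.mode == "independent":
            return 1.0
        if self.mode == "fixed":
            return self.fixed_w
        return self.w_high


def neighbor_sets(
    positions: np.ndarray,
    i: int,
    zones: InteractionZones,
    arrived: Optional[np.ndarray] = None,
) -> tuple[list[int], list[int], list[int]]:
    """Classify neighbors of agent ``i`` into (repulsion, orientation, attraction).

    Coincident neighbors (d == 0) join the repulsion set; arrived agents are
    excluded from all sets.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if not (0 <= i < n):
        raise IndexError(f"agent index {i} out of range for {n} agents")
    d = np.linalg.norm(positions - positions[i], axis=1)
    alive = np.ones(n, dtype=bool) if arrived is None else ~np.asarray(arrived, bool)
    alive[i] = False
    rep = np.nonzero(alive & (d < zones.repulsion))[0]
    ori = np.nonzero(alive & (d >= zones.repulsion) & (d < zones.orientation))[0]
    att = np.nonzero(alive & (d >= zones.orientation) & (d < zones.attraction))[0]
    return list(rep), list(ori), list(att)


def _random_unit(rng: Optional[np.random.Generator]) -> np.ndarray:
    if rng is None:
        raise ValueError("coincident agents require an rng for the repulsion direction")
    phi = rng.uniform(-np.pi, np.pi)
    return np.array([np.cos(phi), np.sin(phi)])


def repulsion_direction(
    i: int,
    positions: np.ndarray,
    repulsion_set: Sequence[int],
    rng: Optional[np.random.Generator] = None,
) -> Optional[np.ndarray]:
    """Collision-avoidance direction: minus the normalized sum of unit vectors
    toward repulsion-zone neighbors; ``None`` on exact cancellation.

    A coincident neighbor (zero distance) contributes a random unit vector.
    """
    positions = np.asarray(positions, dtype=float)
    acc = np.zeros(2)
    for j in repulsion_set:
        dv = positions[j] - positions[i]
        d = np.linalg.norm(dv)
        acc += _random_unit(rng) if d == 0 else dv / d
    n = np.linalg.norm(acc)
    if n < 1e-12:
        return None
    return -acc / n


def align_attract_direction(
    i: int,
    positions: np.ndarray,
    headings: np.ndarray,
    orientation_set: Sequence[int],
    attraction_set: Sequence[int],
    attraction_weight: float = 1.0,
) -> Optional[np.ndarray]:
    """Alignment + attraction direction when the repulsion zone is empty.

    Normalized sum of the orientation-zone neighbors' unit headings and the
    unit vectors toward attraction-zone neighbors (equal unit weights);
    ``None`` if both sets are empty or the sum cancels.
    """
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    acc = np.zeros(2)
    for j in orientation_set:
        acc += unit(headings[j])
    for j in attraction_set:
        dv = positions[j] - positions[i]
        acc += attraction_weight * dv / np.linalg.norm(dv)
    n = np.linalg.norm(acc)
    if n < 1e-12:
        return None
    return acc / n


def group_direction(
    i: int,
    positions: np.ndarray,
    headings: np.ndarray,
    zones: InteractionZones,
    arrived: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> Optional[np.ndarray]:
    """Full zonal rule for one agent: repulsion preempts alignment/attraction."""
    rep, ori, att = neighbor_sets(positions, i, zones, arrived)
    if rep:
        return repulsion_direction(i, positions, rep, rng)
    return align_attract_direction(
        i, positions, headings, ori, att, zones.attraction_weight
    )


def group_directions_all(
    positions: np.ndarray,
    headings: np.ndarray,
    active: np.ndarray,
    zones: InteractionZones,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized zonal rule for every active agent simultaneously.

    Returns ``(directions, has_direction)`` with shapes ``(N, 2)`` and
    ``(N,)``; rows with ``has_direction`` False are zero.  Identical, agent
    for agent, to composing :func:`neighbor_sets` with the two direction
    rules (the O(N^2) reference route checked in the tests); inactive
    (arrived) agents are invisible and get no direction.
    """
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    active = np.asarray(active, dtype=bool)
    n = len(positions)
    diff = positions[None, :, :] - positions[:, None, :]  # diff[i, j] = x_j - x_i
    dist = np.linalg.norm(diff, axis=-1)
    visible = active[None, :] & active[:, None]
    np.fill_diagonal(visible, False)

    coincident = visible & (dist == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = diff / np.where(dist > 0, dist, 1.0)[:, :, None]
    if coincident.any():
        # random repulsion direction per coincident ordered pair
        idx = np.argwhere(coincident)
        phi = rng.uniform(-np.pi, np.pi, size=len(idx)) if rng is not None else None
        if phi is None:
            raise ValueError("coincident agents require an rng")
        u[idx[:, 0], idx[:, 1], 0] = np.cos(phi)
        u[idx[:, 0], idx[:, 1], 1] = np.sin(phi)

    rep_mask = visible & (dist < zones.repulsion)
    ori_mask = visible & (dist >= zones.repulsion) & (dist < zones.orientation)
    att_mask = visible & (dist >= zones.orientation) & (dist < zones.attraction)

    rep_sum = -np.einsum("ij,ijk->ik", rep_mask.astype(float), u)
    ori_sum = ori_mask.astype(float) @ unit(headings)
    att_sum = zones.attraction_weight * np.einsum(
        "ij,ijk->ik", att_mask.astype(float), u
    )

    has_rep = rep_mask.any(axis=1)
    has_soc = ori_mask.any(axis=1) | att_mask.any(axis=1)
    vec = np.where(has_rep[:, None], rep_sum, ori_sum + att_sum)
    norm = np.linalg.norm(vec, axis=1)
    has_dir = active & (has_rep | has_soc) & (norm > 1e-12)
    out = np.zeros_like(vec)
    np.divide(vec, norm[:, None], out=out, where=has_dir[:, None])
    return out, has_dir


def update_weight(delta_c: float, policy: WeightPolicy, current: float) -> float:
    """Per-step weight update.

    Adaptive mode: ``w_high`` after a beneficial step (concentration change
    > 0), ``w_low`` otherwise (zero change counts as non-beneficial).  Fixed
    and independent modes return their constants unchanged.
    """
    if policy.mode == "fixed":
        return policy.fixed_w
    if policy.mode == "independent":
        return current
    return policy.w_high if delta_c > 0 else policy.w_low
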