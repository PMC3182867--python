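"""Group movement characteristics of a finished run.

Path length is measured through arrival times: an agent "arrives" the first
time it comes within the goal radius of the target, after which it is frozen
(absorbed) and excluded from interactions, alignment, and clustering.  The
group-level path length is the *median* path length — the navigation time of
the half-way arriving agent times the speed — which is robust against the
rare, extremely long individual paths this kind of stochastic search
produces.  A run where fewer than half the agents arrive within the step
budget is *censored* (the median path length exceeds the simulation length);
censored values propagate as ``inf`` and are never imputed.

The error fraction is the relative excess of the median path length over the
straight-line start-to-target distance, (L - D) / D: 0 means the group went
straight, 1 means it travelled twice the beeline.

Group alignment is the polar order parameter — the norm of the mean unit
heading over non-arrived agents — averaged over the trajectory; 1 is perfect
common heading, 0 no net direction.  Cohesion is summarized by the number of
connected components of the contact graph whose edges join agents closer
than the attraction radius, at the final step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dynamics import unit

__all__ = [
    "Trajectory",
    "SummaryStats",
    "arrival_times",
    "median_path_length",
    "percentile_path_length",
    "error_fraction",
    "group_alignment",
    "pairwise_alignment",
    "count_clusters",
    "mean_weight",
    "summarize",
]

CENSORED = np.inf


@dataclass
class Trajectory:
    """Full per-step record of a run.

    Arrays are time-aligned with shape ``(T+1, N, ...)``; index 0 is the
    initial state.  ``arrived`` flags are monotone non-decreasing per agent.
    """

    positions: np.ndarray  # (T+1, N, 2)
    headings: np.ndarray  # (T+1, N)
    weights: np.ndarray  # (T+1, N)
    arrived: np.ndarray  # (T+1, N) bool
    dt: float
    speed: float
    start_position: np.ndarray
    target_position: np.ndarray
    goal_radius: float
    max_steps: int

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0] - 1

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    @property
    def straight_line_distance(self) -> float:
        return float(np.linalg.norm(np.asarray(self.target_position) - np.asarray(self.start_position)))


def arrival_times(traj: Trajectory) -> np.ndarray:
    """First step index at which each agent is within the goal radius.

    Censored agents (never within ``goal_radius`` up to the last recorded
    step) get ``inf``.  Agents starting inside the goal get 0.
    """
    if traj.goal_radius <= 0:
        raise ValueError("goal_radius must be > 0")
    arr = traj.arrived
    first = np.argmax(arr, axis=0).astype(float)
    never = ~arr.any(axis=0)
    first[never] = CENSORED
    return first


def _order_stat(values: np.ndarray, k: int) -> float:
    """k-th smallest (1-based) with inf-aware partition."""
    v = np.sort(np.asarray(values, dtype=float))
    return float(v[k - 1])


def median_path_length(arrival_steps: np.ndarray, speed: float, dt: float) -> float:
    """Median path length: the time for half the group to arrive, times v0.

    Defined through the ceil(N/2)-th order statistic of the arrival steps
    (for odd N this is the ordinary median), so the value is censored (inf)
    exactly when fewer than half the agents arrived.
    """
    arrival_steps = np.asarray(arrival_steps, dtype=float)
    n = len(arrival_steps)
    if n < 1:
        raise ValueError("need at least one agent")
    k = (n + 1) // 2
    t = _order_stat(arrival_steps, k)
    return t * speed * dt


def percentile_path_length(arrival_steps: np.ndarray, q: float, speed: float, dt: float) -> float:
    """Path length of the q-th percentile arriver (order statistic, inf-aware)."""
    arrival_steps = np.asarray(arrival_steps, dtype=float)
    n = len(arrival_steps)
    k = min(max(int(np.ceil(q / 100.0 * n)), 1), n)
    return _order_stat(arrival_steps, k) * speed * dt


def error_fraction(median_length: float, straight_distance: float) -> float:
    """Relative excess of the median path over the straight line, (L - D)/D."""
    if straight_distance <= 0:
        raise ValueError("straight-line distance must be > 0")
    if not np.isfinite(median_length):
        return CENSORED
    return (median_length - straight_distance) / straight_distance


def _polar_order(headings: np.ndarray, active: np.ndarray) -> float:
    u = unit(headings[active])
    return float(np.linalg.norm(u.mean(axis=0)))


def group_alignment(traj: Trajectory) -> float:
    """Time-averaged polar order parameter over non-arrived agents.

    Steps after full absorption contribute nothing (the average runs over
    steps with at least one active agent).
    """
    active = ~traj.arrived
    counts = active.sum(axis=1)
    n_live = int(np.argmax(counts == 0)) if (counts == 0).any() else len(counts)
    if n_live == 0:
        return np.nan
    a = active[:n_live]
    c = (np.cos(traj.headings[:n_live]) * a).sum(axis=1)
    s = (np.sin(traj.headings[:n_live]) * a).sum(axis=1)
    order = np.hypot(c, s) / counts[:n_live]
    return float(order.mean())


def pairwise_alignment(traj: Trajectory) -> float:
    """Alternative alignment metric: mean pairwise heading cosine, time-averaged.

    For a step with m active agents this equals (|sum u|^2 - m) / (m (m - 1));
    steps with fewer than two active agents are skipped.
    """
    vals = []
    for t in range(traj.positions.shape[0]):
        active = ~traj.arrived[t]
        m = int(active.sum())
        if m < 2:
            continue
        s = unit(traj.headings[t][active]).sum(axis=0)
        vals.append((float(s @ s) - m) / (m * (m - 1)))
    return float(np.mean(vals)) if vals else np.nan


def count_clusters(positions: np.ndarray, attraction_radius: float) -> int:
    """Connected components of the graph joining agents closer than R_a."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n == 0:
        return 0
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adj = (d < attraction_radius)
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return int(n_comp)


def mean_weight(traj: Trajectory) -> float:
    """Time- and agent-averaged interaction weight over non-arrived agents."""
    active = ~traj.arrived
    if not active.any():
        return float(np.mean(traj.weights[0]))
    return float(traj.weights[active].mean())


@dataclass
class SummaryStats:
    """One row of the run-records table."""

    mechanism: str
    seed: int
    n_agents: int
    median_path_length: float
    censored: bool
    error_fraction: float
    alignment: float
    n_clusters: int
    mean_weight: float
    p90_path_length: float
    n_arrived: int

    def as_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "seed": self.seed,
            "n_agents": self.n_agents,
            "median_path_length": self.median_path_length,
            "censored": self.censored,
            "error_fraction": self.error_fraction,
            "alignment": self.alignment,
            "n_clusters": self.n_clusters,
            "mean_weight": self.mean_weight,
            "p90_path_length": self.p90_path_length,
            "n_arrived": self.n_arrived,
        }


def summarize(
    traj: Trajectory,
    mechanism: str,
    seed: int,
    attraction_radius: float,
) -> SummaryStats:
    """Compute the full per-run summary from a trajectory."""
    steps = arrival_times(traj)
    med = median_path_length(steps, traj.speed, traj.dt)
    d = traj.straight_line_distance
    final_active = ~traj.arrived[-1]
    n_clusters = count_clusters(traj.positions[-1][final_active], attraction_radius)
    return SummaryStats(
        mechanism=mechanism,
        seed=seed,
        n_agents=traj.n_agents,
        median_path_length=med,
        censored=not np.isfinite(med),
        error_fraction=error_fraction(med, d),
        alignment=group_alignment(traj),
        n_clusters=n_clusters,
        mean_weight=mean_weight(traj),
        p90_path_length=percentile_path_length(steps, 90.0, traj.speed, traj.dt),
        n_arrived=int(np.isfinite(steps).sum()),
    )
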