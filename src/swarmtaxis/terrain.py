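"""Static concentration terrain: a diffusion-like Bessel bowl with periodic obstacles.

The chemoattractant field is modelled as

    C(x, y) = A_K * K0(kappa * max(r, eps)) + periodic(x, y)

where ``r`` is the distance to the target and ``K0`` is the modified Bessel
function of the second kind — the radially symmetric steady solution of the 2-D
diffusion equation with a point source, so the global term mimics a chemical
diffusing from the target.  The periodic perturbation (by default a product of
sines, ``A_p * sin(k_x x) * sin(k_y y)``) superimposes a lattice of mountains and
valleys that creates local maxima, minima and saddles away from the target:
"height" is negated concentration, so the target is the lowest point of the
landscape and the global concentration maximum.

``K0`` diverges at the origin; the field is capped on a ring of radius ``eps``
around the target so the maximum is finite.  Inside the cap the gradient is
evaluated on the ring along the radial direction (a documented convention —
agents are absorbed at the target long before the cap matters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.special import k0, k1

__all__ = [
    "TerrainParams",
    "CriticalPoint",
    "concentration",
    "concentration_gradient",
    "height_profile",
    "find_critical_points",
    "terrain_grid",
]


class ConfigurationError(ValueError):
    """Raised when parameters violate a model invariant."""


PeriodicForm = Literal["product_sines", "sum_cosines"]


@dataclass(frozen=True)
class TerrainParams:
    """Parameters of the static concentration map.

    Attributes
    ----------
    target_position:
        Location of the chemical source (global concentration maximum).
    bessel_amplitude:
        ``A_K`` — amplitude of the diffusive K0 bowl, concentration units,
        >= 0 (zero gives a purely periodic field, useful for analysis).
    bessel_decay:
        ``kappa`` — inverse decay length of the bowl, 1/length, > 0.
    periodic_amplitude:
        ``A_p`` — amplitude of the periodic mountains/valleys, >= 0.
    wavenumbers:
        ``(k_x, k_y)`` of the periodic term, 1/length, > 0.  The terrain's
        characteristic length (peak-to-peak distance) is ``2*pi/k``.
    singularity_radius:
        ``eps`` — cap radius around the target where C is held at its ring
        value; must satisfy ``eps < 1/kappa``.
    domain_bounds:
        ``(xmin, xmax, ymin, ymax)`` rectangle containing the experiment.
    periodic_form:
        ``"product_sines"`` (default) uses ``A_p sin(kx x) sin(ky y)``;
        ``"sum_cosines"`` uses ``A_p (cos(kx x) + cos(ky y)) / 2``.
    """

    target_position: tuple[float, float] = (0.0, 0.0)
    bessel_amplitude: float = 1.0
    bessel_decay: float = 0.1
    periodic_amplitude: float = 0.018
    wavenumbers: tuple[float, float] = (4.0 * np.pi, 4.0 * np.pi)
    singularity_radius: float = 0.1
    domain_bounds: tuple[float, float, float, float] = (-10.0, 10.0, -10.0, 10.0)
    periodic_form: PeriodicForm = "product_sines"

    def __post_init__(self) -> None:
        if self.bessel_amplitude < 0:
            raise ConfigurationError("bessel_amplitude must be >= 0")
        if not (self.bessel_decay > 0):
            raise ConfigurationError("bessel_decay must be > 0")
        if self.periodic_amplitude < 0:
            raise ConfigurationError("periodic_amplitude must be >= 0")
        kx, ky = self.wavenumbers
        if not (kx > 0 and ky > 0):
            raise ConfigurationError("wavenumbers must be > 0")
        if not (0 < self.singularity_radius < 1.0 / self.bessel_decay):
            raise ConfigurationError(
                "singularity_radius must satisfy 0 < eps < 1/kappa"
            )
        xmin, xmax, ymin, ymax = self.domain_bounds
        tx, ty = self.target_position
        if not (xmin < tx < xmax and ymin < ty < ymax):
            raise ConfigurationError("target_position must lie inside domain_bounds")
        if self.periodic_form not in ("product_sines", "sum_cosines"):
            raise ConfigurationError(f"unknown periodic_form {self.periodic_form!r}")

    @property
    def wavelength(self) -> float:
        """Characteristic terrain length: the longer of the two periods."""
        kx, ky = self.wavenumbers
        return 2.0 * np.pi / min(kx, ky)

    @property
    def characteristic_slope(self) -> float:
        """Peak gradient magnitude of the periodic term (A_p * max k)."""
        return self.periodic_amplitude * max(self.wavenumbers)


def _check_finite(p: np.ndarray) -> None:
    if not np.all(np.isfinite(p)):
        raise ValueError("position contains non-finite components")


def _periodic(x: np.ndarray, y: np.ndarray, params: TerrainParams) -> np.ndarray:
    kx, ky = params.wavenumbers
    if params.periodic_form == "product_sines":
        return params.periodic_amplitude * np.sin(kx * x) * np.sin(ky * y)
    return 0.5 * params.periodic_amplitude * (np.cos(kx * x) + np.cos(ky * y))


def _periodic_gradient(
    x: np.ndarray, y: np.ndarray, params: TerrainParams
) -> tuple[np.ndarray, np.ndarray]:
    kx, ky = params.wavenumbers
    a = params.periodic_amplitude
    if params.periodic_form == "product_sines":
        gx = a * kx * np.cos(kx * x) * np.sin(ky * y)
        gy = a * ky * np.sin(kx * x) * np.cos(ky * y)
    else:
        gx = -0.5 * a * kx * np.sin(kx * x)
        gy = -0.5 * a * ky * np.sin(ky * y)
    return gx, gy


def concentration(p, params: TerrainParams) -> np.ndarray:
    """Concentration C at point(s) ``p`` (shape ``(2,)`` or ``(..., 2)``).

    The K0 argument is capped at ``kappa * eps`` so C stays finite at the
    target; the periodic term is never capped.
    """
    p = np.asarray(p, dtype=float)
    _check_finite(p)
    x = p[..., 0]
    y = p[..., 1]
    tx, ty = params.target_position
    r = np.hypot(x - tx, y - ty)
    r_capped = np.maximum(r, params.singularity_radius)
    bowl = params.bessel_amplitude * k0(params.bessel_decay * r_capped)
    return bowl + _periodic(x, y, params)


def concentration_gradient(p, params: TerrainParams) -> np.ndarray:
    """Analytic gradient of C (uses dK0/dz = -K1(z)).

    Inside the singularity cap the radial part is evaluated on the eps-ring
    along the radial direction of ``p`` (zero radial part exactly at the
    target, where the direction is undefined).
    """
    p = np.asarray(p, dtype=float)
    _check_finite(p)
    x = p[..., 0]
    y = p[..., 1]
    tx, ty = params.target_position
    dx = x - tx
    dy = y - ty
    r = np.hypot(dx, dy)
    r_capped = np.maximum(r, params.singularity_radius)
    # dC/dr on the (possibly capped) ring; direction is the true radial unit.
    dcdr = -params.bessel_amplitude * params.bessel_decay * k1(
        params.bessel_decay * r_capped
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / np.where(r > 0, r, 1.0), 0.0)
        uy = np.where(r > 0, dy / np.where(r > 0, r, 1.0), 0.0)
    gx, gy = _periodic_gradient(x, y, params)
    out = np.empty(np.broadcast(x, y).shape + (2,), dtype=float)
    out[..., 0] = dcdr * ux + gx
    out[..., 1] = dcdr * uy + gy
    return out


def height_profile(start, end, n_samples: int, params: TerrainParams) -> np.ndarray:
    """Terrain height (= -C) at ``n_samples`` evenly spaced points on [start, end].

    A degenerate segment (start == end) yields ``n_samples`` copies of the
    single height.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    pts = start[None, :] * (1.0 - t) + end[None, :] * t
    return -concentration(pts, params)


@dataclass(frozen=True)
class CriticalPoint:
    position: tuple[float, float]
    kind: Literal["maximum", "minimum", "saddle"]
    degenerate: bool = False


def _hessian_fd(p: np.ndarray, params: TerrainParams, h: float) -> np.ndarray:
    """Finite-difference Hessian from the analytic gradient (central stencil)."""
    H = np.empty((2, 2))
    for k in range(2):
        dp = np.zeros(2)
        dp[k] = h
        H[:, k] = (
            concentration_gradient(p + dp, params)
            - concentration_gradient(p - dp, params)
        ) / (2.0 * h)
    return 0.5 * (H + H.T)


def find_critical_points(
    params: TerrainParams,
    grid_resolution: float,
    *,
    degenerate_tol: float = 1e-6,
) -> list[CriticalPoint]:
    """Locate and classify stationary points of C inside the domain.

    Candidate points are grid-local minima of ``|grad C|^2`` refined by
    least-squares root polishing of the analytic gradient; each converged root
    is classified by the eigenvalue signs of a finite-difference Hessian.
    Eigenvalues below ``degenerate_tol`` (relative to the largest) flag the
    point degenerate.  The singularity cap is excluded (C is not smooth
    there); the capped peak at the target is reported as a maximum whenever
    the target dominates its periodic surroundings.
    """
    xmin, xmax, ymin, ymax = params.domain_bounds
    if grid_resolution >= 0.5 * params.wavelength:
        raise ValueError("grid_resolution must be below half the periodic wavelength")
    nx = max(int(np.ceil((xmax - xmin) / grid_resolution)) + 1, 4)
    ny = max(int(np.ceil((ymax - ymin) / grid_resolution)) + 1, 4)
    xs = np.linspace(xmin, xmax, nx)
    ys = np.linspace(ymin, ymax, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X, Y], axis=-1)
    g = concentration_gradient(pts, params)
    gn = np.einsum("...k,...k->...", g, g)

    # interior grid-local minima of |grad|^2 (8-neighborhood)
    core = gn[1:-1, 1:-1]
    is_min = np.ones_like(core, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_min &= core <= gn[1 + di : nx - 1 + di, 1 + dj : ny - 1 + dj]
    ii, jj = np.nonzero(is_min)
    candidates = pts[1:-1, 1:-1][ii, jj]

    tx, ty = params.target_position
    eps = params.singularity_radius
    h = 1e-4 * params.wavelength
    found: list[tuple[np.ndarray, str, bool]] = []
    for c in candidates:
        sol = least_squares(
            lambda q: concentration_gradient(q, params),
            c,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        root = sol.x
        if np.linalg.norm(concentration_gradient(root, params)) > 1e-6:
            continue
        if not (xmin <= root[0] <= xmax and ymin <= root[1] <= ymax):
            continue
        if params.bessel_amplitude > 0 and np.hypot(root[0] - tx, root[1] - ty) < 2.0 * eps:
            continue  # cap region (C not smooth there); handled separately
        H = _hessian_fd(root, params, h)
        ev = np.linalg.eigvalsh(H)
        scale = max(np.abs(ev).max(), 1e-300)
        degenerate = bool(np.min(np.abs(ev)) < degenerate_tol * scale)
        if ev[0] > 0 and ev[1] > 0:
            kind = "minimum"
        elif ev[0] < 0 and ev[1] < 0:
            kind = "maximum"
        else:
            kind = "saddle"
        if not any(np.linalg.norm(root - f[0]) < 0.5 * grid_resolution for f in found):
            found.append((root, kind, degenerate))

    out = [
        CriticalPoint((float(p[0]), float(p[1])), kind, degenerate)
        for p, kind, degenerate in found
    ]
    # The capped target peak: a maximum provided the bowl dominates the local
    # periodic range, which the TerrainParams invariants make the common case.
    ring_c = params.bessel_amplitude * k0(params.bessel_decay * eps)
    if ring_c > 2.0 * params.periodic_amplitude:
        out.append(CriticalPoint((float(tx), float(ty)), "maximum", False))
    return out


def terrain_grid(params: TerrainParams, resolution: float) -> "np.ndarray":
    """Regular grid sample of the field as an ``(M, 3)`` array (x, y, C)."""
    xmin, xmax, ymin, ymax = params.domain_bounds
    xs = np.arange(xmin, xmax + 0.5 * resolution, resolution)
    ys = np.arange(ymin, ymax + 0.5 * resolution, resolution)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X, Y], axis=-1)
    C = concentration(pts, params)
    return np.column_stack([X.ravel(), Y.ravel(), C.ravel()])
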