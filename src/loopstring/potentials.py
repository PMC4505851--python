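"""Analytic 2D multi-well potentials with locatable critical points.

These landscapes validate the string method: minima and saddles are found
independently by a grid scan plus Newton refinement, so a refined path can be
checked against the true saddle and the true barrier height.
Energies are in kcal/mol; positions are dimensionless "angstrom-like" units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

__all__ = [
    "GaussianTerm",
    "ToyPotential2D",
    "CriticalPoint",
    "make_two_well_potential",
    "make_three_well_potential",
    "locate_critical_points",
    "HarmonicWell",
    "FlatModel",
]


@dataclass(frozen=True)
class GaussianTerm:
    """amplitude * exp(-1/2 (x-c)^T P (x-c)); negative amplitude is a well."""

    amplitude: float
    center: tuple[float, float]
    invcov: tuple[tuple[float, float], tuple[float, float]]


@dataclass
class ToyPotential2D:
    """Sum of Gaussian terms plus an optional quadratic confinement."""

    gaussians: list[GaussianTerm]
    confinement_k: float = 0.0
    confinement_center: tuple[float, float] = (0.0, 0.0)
    offset: float = 0.0  # additive constant (gauge); free energies ignore it

    def _terms(self):
        for g in self.gaussians:
            yield (
                float(g.amplitude),
                np.asarray(g.center, dtype=float),
                np.asarray(g.invcov, dtype=float),
            )

    def energy(self, x) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x)
        e = np.full(len(pts), self.offset)
        for a, c, p in self._terms():
            d = pts - c
            e += a * np.exp(-0.5 * np.einsum("ni,ij,nj->n", d, p, d))
        if self.confinement_k:
            d = pts - np.asarray(self.confinement_center)
            e += 0.5 * self.confinement_k * np.sum(d**2, axis=1)
        return float(e[0]) if single else e

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x)
        g = np.zeros_like(pts)
        for a, c, p in self._terms():
            d = pts - c
            ex = a * np.exp(-0.5 * np.einsum("ni,ij,nj->n", d, p, d))
            g += -ex[:, None] * (d @ p.T)
        if self.confinement_k:
            g += self.confinement_k * (pts - np.asarray(self.confinement_center))
        return g[0] if single else g

    def hessian(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(2)
        h = np.zeros((2, 2))
        for a, c, p in self._terms():
            d = x - c
            ex = a * np.exp(-0.5 * d @ p @ d)
            pd = p @ d
            h += ex * (np.outer(pd, pd) - p)
        if self.confinement_k:
            h += self.confinement_k * np.eye(2)
        return h

    # Model protocol used by the dynamics engine: one site in 2 dimensions.
    @property
    def n_sites(self) -> int:
        return 1

    @property
    def dim(self) -> int:
        return 2

    @property
    def masses(self) -> np.ndarray:
        return np.array([1.0])

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float).reshape(2)
        return float(self.energy(x)), -self.gradient(x).reshape(1, 2)


@dataclass(frozen=True)
class CriticalPoint:
    position: np.ndarray
    value: float
    kind: str  # "minimum" | "saddle" | "maximum"


def make_two_well_potential(
    barrier_height: float, well_separation: float = 3.0, seed: int | None = None
) -> ToyPotential2D:
    """Two Gaussian wells of depth ``barrier_height`` on the x axis.

    The saddle sits near the origin by symmetry; the realised barrier
    (saddle minus minimum) is close to, but not exactly, ``barrier_height``
    because the wells overlap — use :func:`locate_critical_points` for the
    exact analytic gap.  ``seed`` adds a reproducible +-2% depth asymmetry.
    """
    if barrier_height <= 0:
        raise ValueError("barrier_height must be positive")
    if well_separation <= 0:
        raise ValueError("well_separation must be positive")
    d = well_separation / 2.0
    sigma = 0.8
    p = ((1.0 / sigma**2, 0.0), (0.0, 1.0 / sigma**2))
    depth_a = depth_b = barrier_height
    if seed is not None:
        rng = np.random.default_rng(seed)
        depth_a *= 1.0 + 0.02 * rng.uniform(-1, 1)
        depth_b *= 1.0 + 0.02 * rng.uniform(-1, 1)
    return ToyPotential2D(
        gaussians=[
            GaussianTerm(-depth_a, (-d, 0.0), p),
            GaussianTerm(-depth_b, (+d, 0.0), p),
        ],
        confinement_k=0.5,
    )


def make_three_well_potential(
    barrier_height: float, well_separation: float = 3.0
) -> ToyPotential2D:
    """Three collinear wells: middle one shallower, giving one metastable
    intermediate between the outer states."""
    if barrier_height <= 0:
        raise ValueError("barrier_height must be positive")
    d = well_separation
    sigma = 0.7
    p = ((1.0 / sigma**2, 0.0), (0.0, 1.0 / sigma**2))
    return ToyPotential2D(
        gaussians=[
            GaussianTerm(-barrier_height, (-d, 0.0), p),
            GaussianTerm(-0.6 * barrier_height, (0.0, 0.0), p),
            GaussianTerm(-barrier_height, (+d, 0.0), p),
        ],
        confinement_k=0.3,
    )


def locate_critical_points(
    pot: ToyPotential2D,
    grid_resolution: float = 0.2,
    bounds: tuple[float, float, float, float] | None = None,
) -> list[CriticalPoint]:
    """Brute-force critical-point oracle.

    Newton refinement (root of the gradient, with the analytic Hessian as
    Jacobian) is started from every grid node; converged roots are
    de-duplicated and classified by the Hessian eigenvalues.
    """
    if bounds is None:
        cs = np.array([g.center for g in pot.gaussians]) if pot.gaussians else np.zeros((1, 2))
        lo = cs.min(axis=0) - 2.5
        hi = cs.max(axis=0) + 2.5
        bounds = (lo[0], hi[0], lo[1], hi[1])
    x0, x1, y0, y1 = bounds
    xs = np.arange(x0, x1 + grid_resolution / 2, grid_resolution)
    ys = np.arange(y0, y1 + grid_resolution / 2, grid_resolution)
    found: list[CriticalPoint] = []
    for gx in xs:
        for gy in ys:
            sol = root(
                pot.gradient,
                np.array([gx, gy]),
                jac=pot.hessian,
                method="hybr",
                tol=1e-12,
            )
            if not sol.success:
                continue
            p = sol.x
            if not (x0 - 0.5 <= p[0] <= x1 + 0.5 and y0 - 0.5 <= p[1] <= y1 + 0.5):
                continue
            if np.linalg.norm(pot.gradient(p)) > 1e-8:
                continue
            if any(np.linalg.norm(p - c.position) < 1e-4 for c in found):
                continue
            ev = np.linalg.eigvalsh(pot.hessian(p))
            if np.all(ev > 1e-10):
                kind = "minimum"
            elif np.all(ev < -1e-10):
                kind = "maximum"
            elif ev[0] < -1e-10 < 1e-10 < ev[1]:
                kind = "saddle"
            else:
                continue  # degenerate; not classified
            found.append(CriticalPoint(p.copy(), float(pot.energy(p)), kind))
    found.sort(key=lambda c: (c.kind, c.value))
    return found


@dataclass
class HarmonicWell:
    """Isotropic harmonic well (1/2) kappa |x|^2 for one site in any dim."""

    kappa: float
    dim: int = 1
    mass: float = 1.0
    temperature: float = 300.0

    @property
    def n_sites(self) -> int:
        return 1

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass])

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float).reshape(1, self.dim)
        return float(0.5 * self.kappa * np.sum(x * x)), -self.kappa * x


@dataclass
class FlatModel:
    """Zero potential; with a large mass the dynamics is effectively frozen."""

    n_sites: int = 1
    dim: int = 1
    mass: float = 1.0
    temperature: float = 300.0

    @property
    def masses(self) -> np.ndarray:
        return np.full(self.n_sites, self.mass)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float)
        return 0.0, np.zeros_like(x)
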