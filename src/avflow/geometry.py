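"""Centreline utilities: arclength resampling, discrete curvature, the
Dean-number screen for secondary flow, and section-averaged radius profiles
(the vessel-lofting input)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "Centreline",
    "AnastomosisSpec",
    "resample_centreline",
    "curvature",
    "dean_number",
    "section_average_radii",
    "section_radius_interpolator",
]


@dataclass(frozen=True)
class Centreline:
    """Ordered centreline points with per-point maximum-inscribed-sphere
    radii, both in metres."""

    points: np.ndarray  # (n, 3)
    radius: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        r = np.asarray(self.radius, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 4:
            raise ValueError("need at least 4 centreline points of shape (n, 3)")
        if r.shape != (p.shape[0],) or np.any(r <= 0):
            raise ValueError("radii must be positive, one per point")
        if np.any(np.linalg.norm(np.diff(p, axis=0), axis=1) == 0):
            raise ValueError("consecutive centreline points must be distinct")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "radius", r)

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arclength, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class AnastomosisSpec:
    """Vein-on-artery connection parameters."""

    angle: float = 35.0
    vein_to_artery_diameter_ratio: float = 1.0
    side: str = "inner"

    def __post_init__(self) -> None:
        if not (0 < self.angle < 90):
            raise ValueError("angle must lie in (0, 90) degrees")
        if self.vein_to_artery_diameter_ratio <= 0:
            raise ValueError("diameter ratio must be positive")
        if self.side not in ("inner", "outer"):
            raise ValueError("side must be 'inner' or 'outer'")


def resample_centreline(c: Centreline, n: int) -> Centreline:
    """Arclength-uniform resampling with linear interpolation of points and
    radii; total arclength of a polyline is preserved exactly."""
    if n < 4:
        raise ValueError("n must be >= 4")
    s = c.arclength
    if s[-1] <= 0:
        raise ValueError("degenerate centreline")
    su = np.linspace(0.0, s[-1], n)
    pts = np.column_stack([np.interp(su, s, c.points[:, i]) for i in range(3)])
    rad = np.interp(su, s, c.radius)
    return Centreline(points=pts, radius=rad)


def curvature(c: Centreline) -> np.ndarray:
    """Discrete Frenet curvature |dT/ds| from finite differences of unit
    tangents; nonnegative, invariant to rigid motions."""
    p = c.points
    s = c.arclength
    tang = np.gradient(p, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    dT = np.gradient(tang, s, axis=0)
    return np.linalg.norm(dT, axis=1)


def dean_number(Re: float, kappa_A: float, D_A: float) -> float:
    """De = Re * sqrt(kappa_A * D_A / 2)."""
    if Re < 0 or kappa_A < 0 or D_A < 0:
        raise ValueError("inputs must be nonnegative")
    return Re * math.sqrt(kappa_A * D_A / 2.0)


def _section_edges(total: float, n_sections: int) -> np.ndarray:
    return np.linspace(0.0, total, n_sections + 1)


def section_average_radii(c: Centreline, n_sections: int = 5) -> Centreline:
    """Replace each point's radius with the mean radius of its equisized
    arclength section (trapezoidal mean of the piecewise-linear radius
    profile over the section)."""
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    s = c.arclength
    edges = _section_edges(s[-1], n_sections)
    means = _section_means(s, c.radius, edges)
    which = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_sections - 1)
    return Centreline(points=c.points.copy(), radius=means[which])


def _section_means(s: np.ndarray, r: np.ndarray, edges: np.ndarray) -> np.ndarray:
    means = np.empty(edges.size - 1)
    # dense grid keeps the trapezoid mean exact for piecewise-linear profiles
    grid = np.unique(np.concatenate([s, edges]))
    rg = np.interp(grid, s, r)
    for i in range(edges.size - 1):
        mask = (grid >= edges[i]) & (grid <= edges[i + 1])
        gs, gr = grid[mask], rg[mask]
        means[i] = np.trapezoid(gr, gs) / (gs[-1] - gs[0])
    return means


def section_radius_interpolator(c: Centreline, n_sections: int = 5):
    """Monotone cubic through the section-mean radii at section midpoints —
    the smooth profile a lofting step would sweep.  Returns a callable of
    arclength; constant extrapolation beyond the end midpoints."""
    s = c.arclength
    edges = _section_edges(s[-1], n_sections)
    means = _section_means(s, c.radius, edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    if mids.size == 1:
        return lambda x: np.full_like(np.asarray(x, dtype=float), means[0])
    interp = PchipInterpolator(mids, means, extrapolate=False)

    def profile(x):
        x = np.asarray(x, dtype=float)
        y = interp(np.clip(x, mids[0], mids[-1]))
        return y

    return profile
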