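"""Time-averaged pathology mapping: Henry's-law concentrations,
lumen-to-wall normal oxygen flux, threshold classification of the wall into
quad-colour pathology maps, per-region area statistics, and volumetric
shear-rate exposure fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .wall_analysis import SpaceTimeVectorField, SurfaceMesh

__all__ = [
    "TransportProperties",
    "WallMapThresholds",
    "QuadMap",
    "ExposureReport",
    "henry_concentration",
    "hypoxia_flux_threshold",
    "lwnof",
    "time_average_field",
    "classify_wall",
    "percentage_areas",
    "shear_rate_exposure",
    "OXYGEN",
]


@dataclass(frozen=True)
class TransportProperties:
    """Oxygen transport constants: plasma diffusivity (m^2/s) and Henry's
    law constant (mol m^-3 mmHg^-1)."""

    diffusivity: float = 1.2e-9
    henry_constant: float = 1.74e-3

    def __post_init__(self) -> None:
        if self.diffusivity <= 0 or self.henry_constant <= 0:
            raise ValueError("transport properties must be positive")


OXYGEN = TransportProperties()


@dataclass(frozen=True)
class WallMapThresholds:
    """Pathology thresholds: low/high time-averaged WSS magnitude (Pa) and
    low time-averaged lumen-to-wall oxygen flux (mol m^-2 s^-1)."""

    wss_low: float = 0.5
    wss_high: float = 30.0
    flux_low: float = 4.275e-7

    def __post_init__(self) -> None:
        if not (0 < self.wss_low < self.wss_high):
            raise ValueError("require 0 < wss_low < wss_high")
        if self.flux_low <= 0:
            raise ValueError("flux_low must be positive")


#: Display precedence for the quad-colour map.
_LABEL_PRECEDENCE = ("yellow", "blue", "red", "green")


@dataclass
class QuadMap:
    """Per-face pathology masks and a display label per face.

    yellow = low-WSS AND low-flux overlap, blue = low WSS, red = high WSS,
    green = low flux; 'none' where no mask applies.  Precedence
    yellow > blue > red > green.
    """

    wss_low: np.ndarray
    wss_high: np.ndarray
    flux_low: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.wss_low, self.wss_high, self.flux_low):
            if m.shape != self.wss_low.shape or m.dtype != bool:
                raise ValueError("masks must be aligned boolean arrays")
        if np.any(self.wss_low & self.wss_high):
            raise ValueError("a face cannot be both low- and high-WSS")

    @property
    def overlap(self) -> np.ndarray:
        return self.wss_low & self.flux_low

    @property
    def labels(self) -> np.ndarray:
        lab = np.full(self.wss_low.shape, "none", dtype=object)
        lab[self.flux_low] = "green"
        lab[self.wss_high] = "red"
        lab[self.wss_low] = "blue"
        lab[self.overlap] = "yellow"
        return lab

    def mask(self, name: str) -> np.ndarray:
        masks = {
            "wss_low": self.wss_low,
            "wss_high": self.wss_high,
            "flux_low": self.flux_low,
            "overlap": self.overlap,
        }
        return masks[name]


@dataclass
class ExposureReport:
    """Percentage areas of each pathology mask per mesh region."""

    percentages: dict  # region -> {mask name -> percent of region area}

    def __getitem__(self, region: str) -> dict:
        return self.percentages[region]


def henry_concentration(pO2: float, props: TransportProperties = OXYGEN) -> float:
    """Dissolved oxygen concentration C = H * pO2 (mol/m^3)."""
    if pO2 < 0:
        raise ValueError("partial pressure must be nonnegative")
    return props.henry_constant * pO2


def hypoxia_flux_threshold(consumption_rate: float, wall_thickness: float) -> float:
    """Minimum areal oxygen flux that keeps a wall layer of the given
    thickness supplied at the given volumetric consumption rate."""
    if consumption_rate <= 0 or wall_thickness <= 0:
        raise ValueError("inputs must be positive")
    return consumption_rate * wall_thickness


def lwnof(wall_normal_gradient, props: TransportProperties = OXYGEN):
    """Lumen-to-wall normal oxygen flux J = -2*kappa*(n . grad C).

    ``wall_normal_gradient`` is n . grad C with n the outward wall normal;
    the factor of two accounts for haemoglobin-augmented transport.
    Positive J means oxygen delivered from lumen to wall.
    """
    g = np.asarray(wall_normal_gradient, dtype=float)
    out = -2.0 * props.diffusivity * g
    return float(out) if out.ndim == 0 else out


def time_average_field(field: SpaceTimeVectorField | tuple) -> np.ndarray:
    """Per-face trapezoidal time average.

    For vector fields the magnitude is taken *before* averaging, yielding
    the time-averaged WSS magnitude.  A ``(times, values)`` tuple of a
    scalar per-face series is averaged as-is.  Non-uniform sampling is
    handled by the trapezoid weights.
    """
    if isinstance(field, SpaceTimeVectorField):
        times = field.times
        values = np.linalg.norm(field.vectors, axis=2)  # (n_t, n_f)
    else:
        times, values = field
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.shape[0] != times.size:
            raise ValueError("values must have time as the leading axis")
    if times.size < 2:
        raise ValueError("need at least 2 snapshots")
    span = times[-1] - times[0]
    return np.trapezoid(values, times, axis=0) / span


def classify_wall(
    avg_wss: np.ndarray,
    avg_flux: np.ndarray,
    thr: WallMapThresholds = WallMapThresholds(),
) -> QuadMap:
    """Threshold the averaged fields into the quad-colour pathology masks.

    Strict inequalities are used; faces exactly at a threshold fall in no
    mask (measure-zero in practice).
    """
    avg_wss = np.asarray(avg_wss, dtype=float)
    avg_flux = np.asarray(avg_flux, dtype=float)
    if avg_wss.shape != avg_flux.shape:
        raise ValueError("avg_wss and avg_flux must be aligned")
    return QuadMap(
        wss_low=avg_wss < thr.wss_low,
        wss_high=avg_wss > thr.wss_high,
        flux_low=avg_flux < thr.flux_low,
    )


def percentage_areas(
    qmap: QuadMap, mesh: SurfaceMesh, regions: Sequence[str] = ("artery", "vein")
) -> ExposureReport:
    """Area-weighted percentage of each mask within each mesh region."""
    areas = mesh.face_areas
    report: dict[str, dict[str, float]] = {}
    for region in regions:
        idx = mesh.region_faces(region)  # raises on empty region
        total = areas[idx].sum()
        report[region] = {
            name: 100.0 * areas[idx][qmap.mask(name)[idx]].sum() / total
            for name in ("wss_low", "wss_high", "flux_low", "overlap")
        }
    return ExposureReport(report)


def shear_rate_exposure(
    cell_volumes: np.ndarray,
    shear_series: np.ndarray,
    thresholds: Sequence[float] = (10.0, 100.0, 250.0),
) -> np.ndarray:
    """Volume fraction exposed to shear rate above each threshold at some
    point in the pulse.

    ``shear_series`` is (n_cells, n_t); a cell counts toward a threshold if
    its maximum over time exceeds it.  Fractions are nonincreasing along an
    ascending threshold list.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be positive and ascending")
    vol = np.asarray(cell_volumes, dtype=float)
    shear = np.asarray(shear_series, dtype=float)
    if shear.shape[0] != vol.size:
        raise ValueError("shear_series rows must match cell_volumes")
    peak = shear.max(axis=1)
    total = vol.sum()
    return np.array([vol[peak > thr].sum() / total for thr in thresholds])
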