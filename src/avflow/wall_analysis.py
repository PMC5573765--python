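"""Unsteadiness analysis of wall shear stress fields: ring-averaged
magnitude series, windowed power spectral density, and snapshot proper
orthogonal decomposition under an area-weighted inner product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal

from .inflow import SampledWaveform
from .lumped import AnalysisWindow

__all__ = [
    "SurfaceMesh",
    "SpaceTimeVectorField",
    "SpectralDensity",
    "PODResult",
    "ring_average_magnitude",
    "compute_psd",
    "snapshot_pod",
    "modes_for_energy",
]

REGION_LABELS = ("artery", "vein", "other")

#: Eigenvalues below this fraction of the largest are truncated to zero so
#: that mode counts are stable against round-off.
_EIG_TRUNCATION = 1e-12


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface with per-face region labels and optional
    named rings (closed transverse bands of faces)."""

    vertices: np.ndarray  # (n_v, 3), metres
    faces: np.ndarray     # (n_f, 3) vertex indices
    region: np.ndarray    # (n_f,) strings from REGION_LABELS
    rings: dict = field(default_factory=dict)  # name -> face-index array

    _face_areas: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.region = np.asarray(self.region)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be triangles (n, 3)")
        if self.region.shape != (self.n_faces,):
            raise ValueError("region must label every face")
        unknown = set(np.unique(self.region)) - set(REGION_LABELS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
        self.rings = {k: np.asarray(v, dtype=np.int64) for k, v in self.rings.items()}
        for name, idx in self.rings.items():
            if idx.size == 0:
                raise ValueError(f"ring {name!r} is empty")
        if np.any(self.face_areas <= 0):
            raise ValueError("degenerate (zero-area) faces present")

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    @property
    def face_areas(self) -> np.ndarray:
        if self._face_areas is None:
            v = self.vertices
            a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
            b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
            self._face_areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        return self._face_areas

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def region_faces(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.region == label)
        if idx.size == 0:
            raise ValueError(f"region {label!r} is empty")
        return idx


@dataclass
class SpaceTimeVectorField:
    """Per-face wall vector snapshots over time (e.g. WSS in Pa)."""

    mesh: SurfaceMesh
    times: np.ndarray       # (n_t,)
    vectors: np.ndarray     # (n_t, n_f, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.times.size < 2:
            raise ValueError("need at least 2 snapshots")
        if self.vectors.shape != (self.times.size, self.mesh.n_faces, 3):
            raise ValueError("vectors must be (n_t, n_faces, 3)")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.times)
        return bool(np.max(np.abs(d - d.mean())) <= 1e-9 * d.mean())

    def window_slice(self, window: AnalysisWindow) -> np.ndarray:
        mask = (self.times >= window.start - 1e-12) & (
            self.times <= window.end + 1e-12
        )
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class SpectralDensity:
    frequencies: np.ndarray
    power: np.ndarray        # one-sided, Pa^2/Hz
    window_label: str

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.power, self.frequencies))

    @property
    def peak_frequency(self) -> float:
        return float(self.frequencies[np.argmax(self.power)])


@dataclass
class PODResult:
    eigenvalues: np.ndarray      # nonincreasing, >= 0
    energy_fraction: np.ndarray  # cumulative, ends at 1
    spatial_modes: np.ndarray    # (n_modes, n_faces_region, 3)
    temporal_coeffs: np.ndarray  # (n_modes, n_t)
    snapshot_count: int
    face_indices: np.ndarray     # region faces the modes live on
    degenerate: bool = False     # zero-variance input


def ring_average_magnitude(
    field: SpaceTimeVectorField, ring: str
) -> SampledWaveform:
    """Area-weighted mean of |vector| over a named ring, per snapshot."""
    if ring not in field.mesh.rings:
        raise ValueError(f"unknown ring {ring!r}")
    idx = field.mesh.rings[ring]
    w = field.mesh.face_areas[idx]
    mag = np.linalg.norm(field.vectors[:, idx, :], axis=2)
    series = mag @ w / w.sum()
    return SampledWaveform(field.times, series, units="Pa")


def compute_psd(series: SampledWaveform, window: AnalysisWindow) -> SpectralDensity:
    """One-sided PSD of the mean-removed, Hann-tapered window segment.

    Single-segment periodogram; the frequency resolution is the reciprocal
    of the window length.
    """
    t, v = series.times, series.values
    dt = float(np.mean(np.diff(t)))
    if np.max(np.abs(np.diff(t) - dt)) > 1e-9 * dt:
        raise ValueError("PSD requires uniform sampling")
    mask = (t >= window.start - 1e-12) & (t <= window.end + 1e-12)
    seg = v[mask]
    if seg.size < 8:
        raise ValueError("fewer than 8 samples in window")
    # symmetric Hann keeps the estimate invariant under time reversal
    freqs, power = signal.periodogram(
        seg, fs=1.0 / dt, window=np.hanning(seg.size), detrend="constant",
        scaling="density",
    )
    return SpectralDensity(freqs, power, window.label)


def snapshot_pod(
    field: SpaceTimeVectorField,
    region: str = "artery",
    window: AnalysisWindow | None = None,
) -> PODResult:
    """Snapshot POD of the temporal fluctuation field over a mesh region.

    The temporal mean field (over the analysis window) is subtracted, the
    snapshot correlation matrix is formed under the area-weighted inner
    product summed over the three vector components, and its
    eigendecomposition yields energies (eigenvalues), area-orthonormal
    spatial modes, and temporal coefficients.  The eigenvalues equal the
    squared singular values of the weighted, mean-centred snapshot matrix.
    """
    faces = field.mesh.region_faces(region)
    if window is None:
        snap = np.arange(field.times.size)
    else:
        snap = field.window_slice(window)
        if snap.size < 2:
            raise ValueError("need at least 2 snapshots in window")

    w = field.mesh.face_areas[faces]
    x = field.vectors[np.ix_(snap, faces)]          # (n_t, n_f, 3)
    n_t = snap.size
    x = x - x.mean(axis=0, keepdims=True)
    xm = x.reshape(n_t, -1)                          # flatten (face, comp)
    sw = np.sqrt(np.repeat(w, 3))
    y = xm * sw                                      # weighted snapshots

    corr = y @ y.T
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    if evals[0] <= 0.0:
        # zero-variance field: a single zero-energy mode, flagged
        zero_mode = np.zeros((1, faces.size, 3))
        return PODResult(
            eigenvalues=np.zeros(1),
            energy_fraction=np.ones(1),
            spatial_modes=zero_mode,
            temporal_coeffs=np.zeros((1, n_t)),
            snapshot_count=n_t,
            face_indices=faces,
            degenerate=True,
        )

    keep = evals > _EIG_TRUNCATION * evals[0]
    evals = evals[keep]
    evecs = evecs[:, keep]
    s = np.sqrt(evals)

    # spatial modes, orthonormal under the area-weighted inner product
    v = (y.T @ evecs) / s            # Euclidean-orthonormal in weighted space
    modes = (v / sw[:, None]).T.reshape(-1, faces.size, 3)
    coeffs = (evecs * s).T           # a_i(t); x(t) = sum_i a_i(t) phi_i

    total = evals.sum()
    return PODResult(
        eigenvalues=evals,
        energy_fraction=np.cumsum(evals) / total,
        spatial_modes=modes,
        temporal_coeffs=coeffs,
        snapshot_count=n_t,
        face_indices=faces,
    )


def modes_for_energy(pod: PODResult, threshold: float) -> int:
    """Smallest mode count whose cumulative energy reaches ``threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if pod.degenerate:
        return 0
    idx = np.searchsorted(pod.energy_fraction, threshold - 1e-12)
    return int(min(idx + 1, pod.energy_fraction.size))
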