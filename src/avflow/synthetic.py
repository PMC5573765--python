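"""Seeded generators for every input the pipeline consumes, with recorded
ground truth so downstream stages are tested by recovery.

Each generator is a pure function of its :class:`GeneratorConfig`; the same
seed yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .inflow import (
    BLOOD,
    FluidProperties,
    FourierWaveform,
    SampledWaveform,
    fourier_fit,
    scale_to_peak_reynolds,
)
from .lumped import (
    InternalElements,
    NetworkSolution,
    WindkesselSet,
    WindkesselTerminal,
    simulate_network,
)
from .calibration import CalibrationRefs
from .transport_maps import WallMapThresholds
from .wall_analysis import SpaceTimeVectorField, SurfaceMesh

__all__ = [
    "GeneratorConfig",
    "TruthNetwork",
    "gen_inflow_waveform",
    "gen_cylinder_mesh",
    "gen_wss_field",
    "gen_oxygen_walldata",
    "gen_truth_network",
    "gen_shear_volume",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic generators; defaults mirror the physical
    setting the analyses assume (1 s period, 15 harmonics, peak Re 1300,
    time-averaged-to-peak Re ratio ~750/1300)."""

    seed: int = 0
    # inflow
    n_modes: int = 15
    period: float = 1.0
    peak_Re: float = 1300.0
    mean_to_peak: float = 750.0 / 1300.0
    diameter: float = 5e-3
    fluid: FluidProperties = BLOOD
    harmonic_jitter: float = 0.03
    # mesh
    tube_radius: float = 2.5e-3
    tube_length: float = 6e-2
    n_axial: int = 24
    n_circ: int = 24
    ring_stations: tuple = (0.25, 0.4)
    ring_width: int = 1  # axial rows per ring
    # wss field
    field_rank: int = 3
    field_region: str = "artery"  # faces carrying the fluctuation patterns
    axial_bias: float = 1.0  # streamwise alignment of fluctuation patterns
    noise: float = 0.0
    mean_wss: float = 2.0
    fluct_scale: float = 0.5
    window_start: float = 1.0
    n_snapshots: int = 1000
    snapshot_dt: float = 0.001
    temporal_harmonics: tuple = ()
    mode_energies: tuple = ()
    # oxygen
    low_flux_fraction: float = 0.25
    thresholds: WallMapThresholds = WallMapThresholds()
    # network
    internal_scale: float = 1.0
    dt_0d: float = 1e-3
    surrogate_perturbation: float = 0.0
    # shear exposure
    n_cells: int = 500
    exposure_fractions: tuple = (1.0, 0.99, 0.93)
    exposure_thresholds: tuple = (10.0, 100.0, 250.0)


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed, stream))


def _harmonic_max(period: float, harmonics) -> float:
    """Maximum of the zero-mean harmonic sum over one period."""
    wf = FourierWaveform(period=period, mean_flow=0.0, harmonics=harmonics)
    tg = np.linspace(0.0, period, 4096, endpoint=False)
    v = wf.evaluate(tg)
    i = int(np.argmax(v))
    dt = period / 4096
    res = minimize_scalar(
        lambda t: -float(wf.evaluate(t)),
        bounds=(tg[i] - dt, tg[i] + dt),
        method="bounded",
        options={"xatol": 1e-14},
    )
    return max(float(v[i]), -float(res.fun))


def gen_inflow_waveform(cfg: GeneratorConfig) -> FourierWaveform:
    """Smooth positive pulsatile inflow (m^3/s): a band-limited raised-cosine
    systolic bump with seeded harmonic jitter, pinned to the configured
    time-averaged-to-peak ratio, then scaled to the target peak Reynolds
    number."""
    rng = _rng(cfg, 0)
    n = 1024
    t = np.arange(n) * (cfg.period / n)
    width = 0.35 * cfg.period
    bump = np.where(t < width, 0.5 * (1.0 - np.cos(2.0 * math.pi * t / width)), 0.0)
    base = fourier_fit(SampledWaveform(t, bump), cfg.n_modes, period=cfg.period)

    jitter = cfg.harmonic_jitter
    for _ in range(8):
        pert = 1.0 + jitter * (
            rng.standard_normal(cfg.n_modes) + 1j * rng.standard_normal(cfg.n_modes)
        )
        harmonics = tuple(c * p for c, p in zip(base.harmonics, pert))
        smax = _harmonic_max(cfg.period, harmonics)
        beta = (1.0 / cfg.mean_to_peak - 1.0) / smax
        shape = FourierWaveform(
            period=cfg.period,
            mean_flow=1.0,
            harmonics=tuple(beta * c for c in harmonics),
        )
        if shape.evaluate(np.linspace(0, cfg.period, 4096, endpoint=False)).min() > 0.02:
            break
        jitter *= 0.5  # retry gentler jitter if positivity failed
    else:  # pragma: no cover
        raise RuntimeError("could not build a positive waveform")
    return scale_to_peak_reynolds(shape, cfg.peak_Re, cfg.diameter, cfg.fluid)


def gen_cylinder_mesh(cfg: GeneratorConfig) -> SurfaceMesh:
    """Open tube along z, triangulated, artery/vein halves, with closed
    transverse ring bands at the configured axial stations."""
    a, L = cfg.tube_radius, cfg.tube_length
    na, nc = cfg.n_axial, cfg.n_circ
    if a <= 0 or L <= 0 or na < 2 or nc < 3:
        raise ValueError("degenerate tube dimensions")
    z = np.linspace(0.0, L, na + 1)
    theta = np.arange(nc) * (2.0 * math.pi / nc)
    verts = np.array(
        [
            [a * math.cos(th), a * math.sin(th), zz]
            for zz in z
            for th in theta
        ]
    )
    faces = []
    row_of_face = []
    for i in range(na):
        for j in range(nc):
            v00 = i * nc + j
            v01 = i * nc + (j + 1) % nc
            v10 = (i + 1) * nc + j
            v11 = (i + 1) * nc + (j + 1) % nc
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
            row_of_face += [i, i]
    faces = np.array(faces, dtype=np.int64)
    row_of_face = np.array(row_of_face)

    centroids_z = verts[faces].mean(axis=1)[:, 2]
    region = np.where(centroids_z < L / 2.0, "artery", "vein").astype(object)

    rings = {}
    for k, frac in enumerate(cfg.ring_stations):
        row0 = int(frac * na)
        rows = range(row0, min(row0 + cfg.ring_width, na))
        idx = np.flatnonzero(np.isin(row_of_face, list(rows)))
        rings[f"ring{k}"] = idx
    return SurfaceMesh(vertices=verts, faces=faces, region=region, rings=rings)


def _orthonormal_patterns(
    rng: np.random.Generator, weights: np.ndarray, k: int, axial_bias: float = 0.0
) -> np.ndarray:
    """k random patterns, orthonormal under the diagonal weight vector."""
    dim = weights.size
    if k > dim:
        raise ValueError("rank exceeds degrees of freedom")
    raw = rng.standard_normal((k, dim))
    raw[:, 2::3] += axial_bias  # favour the streamwise (z) component
    out = np.empty_like(raw)
    for i in range(k):
        v = raw[i]
        for j in range(i):
            v = v - np.dot(v * weights, out[j]) * out[j]
        v /= math.sqrt(np.dot(v * weights, v))
        out[i] = v
    return out


def gen_wss_field(mesh: SurfaceMesh, cfg: GeneratorConfig) -> SpaceTimeVectorField:
    """Space-time WSS field of controlled spatial rank and spectral content.

    A steady axial mean field of magnitude ``mean_wss`` is superposed with
    ``field_rank`` spatial patterns, supported on the faces of
    ``field_region`` and orthonormal there under the area weighting, driven
    by zero-mean sinusoids at integer harmonics of the sampling window,
    plus optional white noise.  With zero noise the fluctuation field over
    that region has rank exactly ``field_rank``.
    """
    rng = _rng(cfg, 1)
    k = cfg.field_rank
    n_t = cfg.n_snapshots
    dt = cfg.snapshot_dt
    times = cfg.window_start + np.arange(n_t) * dt
    T = n_t * dt

    region_faces = mesh.region_faces(cfg.field_region)
    w = np.repeat(mesh.face_areas[region_faces], 3)
    patterns_region = _orthonormal_patterns(rng, w, k, cfg.axial_bias)
    patterns = np.zeros((k, 3 * mesh.n_faces))
    cols = (3 * region_faces[:, None] + np.arange(3)).ravel()
    patterns[:, cols] = patterns_region

    harmonics = cfg.temporal_harmonics or tuple(range(1, k + 1))
    if len(harmonics) != k:
        raise ValueError("temporal_harmonics must have one entry per mode")
    energies = cfg.mode_energies or tuple(
        cfg.fluct_scale**2 * 2.0 ** (-i) for i in range(k)
    )
    if len(energies) != k:
        raise ValueError("mode_energies must have one entry per mode")

    tau = (times - cfg.window_start) / T
    signals = np.stack(
        [
            math.sqrt(2.0 * e) * np.sin(2.0 * math.pi * m * tau)
            for m, e in zip(harmonics, energies)
        ]
    )  # (k, n_t), rows orthogonal and zero-mean on the uniform grid

    fluct = signals.T @ patterns  # (n_t, 3*n_f)
    vectors = fluct.reshape(n_t, mesh.n_faces, 3)
    vectors = vectors + np.array([0.0, 0.0, cfg.mean_wss])  # axial mean field
    if cfg.noise > 0:
        vectors = vectors + cfg.noise * rng.standard_normal(vectors.shape)
    return SpaceTimeVectorField(mesh=mesh, times=times, vectors=vectors)


def gen_oxygen_walldata(mesh: SurfaceMesh, cfg: GeneratorConfig):
    """Per-face wall-normal concentration gradients (n . grad C) with a
    chosen area fraction below the hypoxia flux threshold.

    Returns ``(gradients, truth)`` where ``truth`` records the low-flux
    face mask and the achieved area fraction.
    """
    rng = _rng(cfg, 2)
    kappa = 1.2e-9
    thr = cfg.thresholds.flux_low
    areas = mesh.face_areas
    order = rng.permutation(mesh.n_faces)
    cum = np.cumsum(areas[order]) / areas.sum()
    n_low = int(np.searchsorted(cum, cfg.low_flux_fraction)) if cfg.low_flux_fraction > 0 else 0
    low_mask = np.zeros(mesh.n_faces, dtype=bool)
    low_mask[order[:n_low]] = True

    flux = np.where(
        low_mask,
        thr * rng.uniform(0.2, 0.8, mesh.n_faces),
        thr * rng.uniform(1.5, 4.0, mesh.n_faces),
    )
    gradients = -flux / (2.0 * kappa)
    truth = {
        "low_mask": low_mask,
        "area_fraction_low": float(areas[low_mask].sum() / areas.sum()),
    }
    return gradients, truth


@dataclass
class TruthNetwork:
    """A self-consistent synthetic calibration problem."""

    windkessel: WindkesselSet
    internal: InternalElements
    refs: CalibrationRefs
    surrogate: Callable[[WindkesselSet], NetworkSolution]
    inflow: FourierWaveform  # mL/s
    solution: NetworkSolution


_BASE_FREE_PARAMS = np.array([6.88, 59.80, 0.010, 7.00, 10.30, 10.50])
# inductances sized as rho*l/A for centimetre-scale vessels, quadratic
# resistances giving sub-mmHg drops at physiological flows
_BASE_INTERNAL = InternalElements(
    L1A=1e-2, L2A=1.5e-2, L1V=2e-2, R1A=5e-4, R2A=1e-3, R1V=8e-4
)


def gen_truth_network(cfg: GeneratorConfig) -> TruthNetwork:
    """Draw truth Windkessel parameters within +/-50% of the packaged
    P1-IN values, run the 0D network to periodic state, and derive
    self-consistent calibration references from the truth traces."""
    rng = _rng(cfg, 3)
    free = _BASE_FREE_PARAMS * rng.uniform(0.5, 1.5, 6)
    wk = WindkesselSet.from_free_parameters(free)
    internal = InternalElements(
        *(_BASE_INTERNAL.as_array() * cfg.internal_scale * rng.uniform(0.8, 1.2, 6))
    )
    inflow_si = gen_inflow_waveform(cfg)
    inflow = inflow_si.scaled(1e6)  # m^3/s -> mL/s

    sol = simulate_network(
        inflow, wk, internal, dt=cfg.dt_0d, max_cycles=30, P_init="dc"
    )
    p_bai = sol.node_pressures["P_BAI"]
    refs = CalibrationRefs(
        P_RS=float(p_bai.max()),
        P_RD=float(p_bai.min()),
        Q_R=sol.flow("Q_VO"),
    )

    pert = 1.0 + cfg.surrogate_perturbation
    surr_internal = InternalElements(*(internal.as_array() * pert))

    def surrogate(wkx: WindkesselSet) -> NetworkSolution:
        return simulate_network(
            inflow, wkx, surr_internal, dt=cfg.dt_0d, max_cycles=30, P_init="dc"
        )

    return TruthNetwork(
        windkessel=wk,
        internal=internal,
        refs=refs,
        surrogate=surrogate,
        inflow=inflow,
        solution=sol,
    )


def gen_shear_volume(cfg: GeneratorConfig):
    """Equal-volume cells with pulsatile shear-rate histories whose peak
    values realise the configured exposure fractions.

    Returns ``(volumes, shear_series, truth)`` with the achieved fractions
    recorded in ``truth``.
    """
    rng = _rng(cfg, 4)
    n = cfg.n_cells
    thrs = np.asarray(cfg.exposure_thresholds, dtype=float)
    fracs = np.asarray(cfg.exposure_fractions, dtype=float)
    if np.any(np.diff(fracs) > 0):
        raise ValueError("exposure fractions must be nonincreasing")

    counts = np.round(fracs * n).astype(int)  # cells above each threshold
    peaks = np.empty(n)
    start = 0
    # top band: above the highest threshold
    peaks[: counts[-1]] = rng.uniform(1.2 * thrs[-1], 4.0 * thrs[-1], counts[-1])
    start = counts[-1]
    # interior bands, highest first: peaks strictly between adjacent thresholds
    for b in range(len(thrs) - 2, -1, -1):
        m = counts[b] - counts[b + 1]
        peaks[start : start + m] = rng.uniform(
            1.05 * thrs[b], 0.95 * thrs[b + 1], m
        )
        start += m
    peaks[start:] = rng.uniform(0.1 * thrs[0], 0.9 * thrs[0], n - start)
    peaks = rng.permutation(peaks)

    n_t = 51
    profile = 0.5 * (1.0 - np.cos(2.0 * math.pi * np.linspace(0, 1, n_t)))
    profile[n_t // 2] = 1.0  # pin the exact peak
    shear = peaks[:, None] * profile[None, :]
    volumes = np.full(n, 1.0 / n)
    truth = {
        "fractions": np.array([(peaks > t).mean() for t in thrs]),
        "peaks": peaks,
    }
    return volumes, shear, truth
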