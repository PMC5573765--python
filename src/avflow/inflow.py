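"""Pulsatile inlet boundary condition: Fourier waveforms, Reynolds scaling,
and the Womersley spatial velocity profile.

All quantities are SI (m, s, Pa, m^3/s) unless noted otherwise.  Clinical
units (mL/s, mmHg) are confined to I/O layers; see :mod:`avflow.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special
from scipy.optimize import minimize_scalar

__all__ = [
    "FluidProperties",
    "FourierWaveform",
    "SampledWaveform",
    "WomersleyField",
    "fourier_fit",
    "reynolds_number",
    "scale_to_peak_reynolds",
    "womersley_number",
    "womersley_velocity",
    "BLOOD",
]

#: Womersley number below which a harmonic profile is evaluated in its
#: quasi-steady (parabolic) limit to avoid catastrophic cancellation in the
#: Bessel-function quotient.
_ALPHA_PARABOLIC = 0.1


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Attributes
    ----------
    viscosity:
        Dynamic viscosity in Pa s.
    density:
        Mass density in kg/m^3.
    """

    viscosity: float
    density: float

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


#: Blood treated as a Newtonian fluid.
BLOOD = FluidProperties(viscosity=3.5e-3, density=1060.0)


@dataclass(frozen=True)
class FourierWaveform:
    """Periodic waveform as a mean plus complex harmonics of one fundamental.

    ``value(t) = mean_flow + sum_k Re[harmonics[k-1] * exp(i*k*omega*t)]``
    with ``omega = 2*pi/period``.
    """

    period: float
    mean_flow: float
    harmonics: tuple = ()

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "harmonics", tuple(complex(h) for h in self.harmonics))

    @property
    def omega(self) -> float:
        """Fundamental angular frequency, rad/s."""
        return 2.0 * math.pi / self.period

    @property
    def n_modes(self) -> int:
        return len(self.harmonics)

    def __call__(self, t):
        return self.evaluate(t)

    def evaluate(self, t):
        """Evaluate the waveform at time(s) ``t`` (scalar or array)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.mean_flow, dtype=float)
        for k, c in enumerate(self.harmonics, start=1):
            out += (c * np.exp(1j * k * self.omega * t)).real
        return out if out.shape else float(out)

    def derivative(self, t):
        """dQ/dt at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=float)
        for k, c in enumerate(self.harmonics, start=1):
            out += (1j * k * self.omega * c * np.exp(1j * k * self.omega * t)).real
        return out if out.shape else float(out)

    def scaled(self, factor: float) -> "FourierWaveform":
        """Return the waveform multiplied by a real scalar."""
        return replace(
            self,
            mean_flow=self.mean_flow * factor,
            harmonics=tuple(c * factor for c in self.harmonics),
        )

    def peak(self, n_grid: int = 8192) -> float:
        """Maximum of |Q(t)| over one period.

        Coarse grid search refined with a bounded scalar maximisation so the
        result is accurate to machine precision for band-limited signals.
        """
        tg = np.linspace(0.0, self.period, n_grid, endpoint=False)
        q = np.abs(self.evaluate(tg))
        i = int(np.argmax(q))
        dt = self.period / n_grid
        lo, hi = tg[i] - dt, tg[i] + dt
        res = minimize_scalar(
            lambda t: -abs(float(self.evaluate(t))),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-14},
        )
        return max(float(q[i]), -float(res.fun))


@dataclass(frozen=True)
class SampledWaveform:
    """Discrete time series carrier (flow, pressure, ...).

    ``units`` is metadata only and takes no part in arithmetic.
    """

    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


def _uniform_dt(times: np.ndarray, rtol: float = 1e-6) -> float | None:
    """Return the common spacing if ``times`` is uniform, else None."""
    d = np.diff(times)
    if d.size == 0:
        return None
    dt = float(np.mean(d))
    if np.max(np.abs(d - dt)) > rtol * dt:
        return None
    return dt


def fourier_fit(
    samples: SampledWaveform,
    n_modes: int,
    period: float | None = None,
    resample: bool = False,
) -> FourierWaveform:
    """Fit mean plus the first ``n_modes`` harmonics to one period of samples.

    Parameters
    ----------
    samples:
        One full period of a periodic signal.  A duplicated endpoint
        (``t[-1] - t[0] == period`` with matching values) is tolerated and
        dropped.
    n_modes:
        Number of harmonics of the fundamental ``2*pi/period`` to keep.
    period:
        Signal period.  Defaults to the sample span (endpoint-inclusive
        grid) or span + dt (endpoint-exclusive uniform grid).
    resample:
        If True, non-uniform samples are linearly interpolated onto a
        uniform grid before the DFT; otherwise non-uniform input is an
        error.

    The mean of the samples is preserved exactly and the returned harmonics
    reproduce the discrete Fourier content of the input.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    t = samples.times
    v = samples.values
    if t.size < 4:
        raise ValueError("need at least 4 samples")

    dt = _uniform_dt(t)
    if period is None:
        if dt is None:
            raise ValueError("period must be given for non-uniform samples")
        period = samples.span + dt  # assume endpoint-exclusive grid

    # drop a duplicated endpoint covering exactly one period
    if abs(samples.span - period) <= 1e-9 * period:
        t, v = t[:-1], v[:-1]
        dt = _uniform_dt(t)
    elif samples.span > period * (1 + 1e-9):
        raise ValueError("samples span more than one period; trim first")

    if dt is None:
        if not resample:
            raise ValueError(
                "non-uniform sampling: pass resample=True to interpolate"
            )
        n = t.size
        tu = t[0] + np.arange(n) * (period / n)
        # periodic linear interpolation
        tp = np.concatenate([t, [t[0] + period]])
        vp = np.concatenate([v, [v[0]]])
        v = np.interp(tu, tp, vp)
        t = tu
        dt = period / n

    n = t.size
    if n_modes > (n - 1) // 2:
        raise ValueError(
            f"n_modes={n_modes} exceeds the Nyquist limit {(n - 1) // 2} "
            f"for {n} samples"
        )

    spec = np.fft.rfft(v)
    mean = float(spec[0].real) / n
    omega = 2.0 * math.pi / period
    harmonics = []
    for k in range(1, n_modes + 1):
        c = 2.0 * spec[k] / n
        c *= np.exp(-1j * k * omega * t[0])  # refer phases to t = 0
        harmonics.append(complex(c))
    return FourierWaveform(period=period, mean_flow=mean, harmonics=tuple(harmonics))


def reynolds_number(flow: float, diameter: float, fluid: FluidProperties) -> float:
    """Pipe Reynolds number, mean-velocity convention: 4*rho*|Q|/(pi*mu*D)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return 4.0 * fluid.density * abs(flow) / (math.pi * fluid.viscosity * diameter)


def scale_to_peak_reynolds(
    waveform: FourierWaveform,
    target_Re: float,
    diameter: float,
    fluid: FluidProperties,
) -> FourierWaveform:
    """Rescale a waveform so its peak Reynolds number equals ``target_Re``.

    The whole signal is multiplied by a single positive scalar, so the
    waveform shape (and the ratio of time-averaged to peak Re) is preserved.
    """
    peak_q = waveform.peak()
    if peak_q <= 0:
        raise ValueError("waveform is identically zero; cannot scale")
    peak_re = reynolds_number(peak_q, diameter, fluid)
    return waveform.scaled(target_Re / peak_re)


def womersley_number(
    diameter: float, angular_frequency: float, fluid: FluidProperties
) -> float:
    """alpha = (D/2) * sqrt(omega * rho / mu)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if angular_frequency < 0:
        raise ValueError("angular frequency must be nonnegative")
    return (diameter / 2.0) * math.sqrt(
        angular_frequency * fluid.density / fluid.viscosity
    )


@dataclass(frozen=True)
class WomersleyField:
    """Axial velocity field of fully developed pulsatile pipe flow.

    Each harmonic of the driving flow waveform is given the classical
    oscillatory-pipe-flow radial profile, normalised so that the
    cross-sectional integral of each harmonic equals that harmonic's flow;
    the mean flow carries a parabolic (Poiseuille) profile.
    """

    radius: float
    waveform: FourierWaveform
    fluid: FluidProperties

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def alpha(self, k: int = 1) -> float:
        """Womersley number of harmonic ``k``."""
        return womersley_number(2.0 * self.radius, k * self.waveform.omega, self.fluid)

    def _harmonic_profile(self, k: int, r: np.ndarray) -> np.ndarray:
        """Complex radial profile of harmonic k, unit flow normalisation."""
        R = self.radius
        a = self.alpha(k)
        area = math.pi * R * R
        if a < _ALPHA_PARABOLIC:
            return 2.0 / area * (1.0 - (r / R) ** 2) + 0j
        lam = 1j ** 1.5 * a
        j0l = special.jv(0, lam)
        num = 1.0 - special.jv(0, lam * r / R) / j0l
        den = 1.0 - 2.0 * special.jv(1, lam) / (lam * j0l)
        return num / den / area

    def velocity(self, r, t: float):
        """Axial velocity at radial position(s) ``r`` and time ``t``, m/s."""
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        if np.any(r < 0) or np.any(r > self.radius * (1 + 1e-12)):
            raise ValueError("r must lie in [0, radius]")
        R = self.radius
        wf = self.waveform
        u = 2.0 * wf.mean_flow / (math.pi * R * R) * (1.0 - (r / R) ** 2)
        for k, c in enumerate(wf.harmonics, start=1):
            prof = self._harmonic_profile(k, r)
            u = u + (c * prof * np.exp(1j * k * wf.omega * t)).real
        return float(u[0]) if scalar else u


def womersley_velocity(field: WomersleyField, r, t: float):
    """Functional wrapper around :meth:`WomersleyField.velocity`."""
    return field.velocity(r, t)
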