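import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avflow.inflow import (
    BLOOD,
    FluidProperties,
    FourierWaveform,
    SampledWaveform,
    WomersleyField,
    fourier_fit,
    reynolds_number,
    scale_to_peak_reynolds,
    womersley_number,
    womersley_velocity,
)


def _sampled(period, fn, n=256):
    t = np.arange(n) * (period / n)
    return SampledWaveform(t, fn(t))


class TestFourierFit:
    def test_pure_sinusoid_identity(self):
        # Re[c e^{i w t}] with c = 2 - 3j
        c = 2.0 - 3.0j
        w = 2 * math.pi
        s = _sampled(1.0, lambda t: (c * np.exp(1j * w * t)).real)
        wf = fourier_fit(s, n_modes=1)
        assert wf.mean_flow == pytest.approx(0.0, abs=1e-12)
        assert wf.harmonics[0] == pytest.approx(c, abs=1e-12)

    def test_constant_signal(self):
        s = _sampled(1.0, lambda t: np.full_like(t, 3.7))
        wf = fourier_fit(s, n_modes=5)
        assert wf.mean_flow == pytest.approx(3.7, abs=1e-14)
        assert all(abs(c) < 1e-12 for c in wf.harmonics)

    def test_three_harmonics_recovered(self):
        # construct-then-recover oracle
        truth = FourierWaveform(
            period=1.0,
            mean_flow=5.0,
            harmonics=(1.0 + 0.5j, 0.0, -0.25 + 2.0j),
        )
        s = _sampled(1.0, truth.evaluate, n=512)
        wf = fourier_fit(s, n_modes=15)
        assert wf.mean_flow == pytest.approx(5.0, abs=1e-10)
        for got, want in zip(wf.harmonics[:3], truth.harmonics):
            assert got == pytest.approx(want, abs=1e-10)
        for got in wf.harmonics[3:]:
            assert abs(got) < 1e-10

    def test_nonuniform_without_resampling_errors(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 1, 64))
        s = SampledWaveform(t, np.sin(2 * math.pi * t))
        with pytest.raises(ValueError, match="resample"):
            fourier_fit(s, 1, period=1.0)

    def test_nonuniform_with_resampling(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 0.999, 4096))
        s = SampledWaveform(t, 1.0 + np.sin(2 * math.pi * t))
        wf = fourier_fit(s, 1, period=1.0, resample=True)
        assert abs(wf.harmonics[0] - (-1j)) < 1e-2

    def test_nyquist_error(self):
        s = _sampled(1.0, np.sin, n=16)
        with pytest.raises(ValueError, match="Nyquist"):
            fourier_fit(s, n_modes=8)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_fit_evaluate_roundtrip(self, seed):
        # identity on band-limited signals
        rng = np.random.default_rng(seed)
        n_modes = int(rng.integers(1, 8))
        truth = FourierWaveform(
            period=1.0,
            mean_flow=float(rng.normal()),
            harmonics=tuple(rng.normal(size=n_modes) + 1j * rng.normal(size=n_modes)),
        )
        wf = fourier_fit(_sampled(1.0, truth.evaluate), n_modes=n_modes)
        tt = rng.uniform(0, 1, 32)
        np.testing.assert_allclose(wf.evaluate(tt), truth.evaluate(tt), atol=1e-10)


class TestReynolds:
    def test_zero_flow(self):
        assert reynolds_number(0.0, 5e-3, BLOOD) == 0.0

    def test_arithmetic(self):
        want = 4 * 1060 * 1e-5 / (math.pi * 3.5e-3 * 5e-3)
        assert reynolds_number(1e-5, 5e-3, BLOOD) == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(771.3, rel=1e-3)

    def test_linearity(self):
        a = reynolds_number(1e-5, 5e-3, BLOOD)
        b = reynolds_number(2e-5, 5e-3, BLOOD)
        assert b == pytest.approx(2 * a, rel=1e-14)

    def test_zero_diameter_errors(self):
        with pytest.raises(ValueError):
            reynolds_number(1e-5, 0.0, BLOOD)


class TestScaleToPeakReynolds:
    def _waveform(self):
        return FourierWaveform(1.0, 1e-5, harmonics=(5e-6 + 1e-6j, 1e-6))

    def test_peak_re_hits_target(self):
        wf = scale_to_peak_reynolds(self._waveform(), 1300.0, 5e-3, BLOOD)
        got = reynolds_number(wf.peak(), 5e-3, BLOOD)
        assert got == pytest.approx(1300.0, rel=1e-6)

    def test_already_at_target_is_identity(self):
        wf = scale_to_peak_reynolds(self._waveform(), 1300.0, 5e-3, BLOOD)
        wf2 = scale_to_peak_reynolds(wf, 1300.0, 5e-3, BLOOD)
        assert wf2.mean_flow == pytest.approx(wf.mean_flow, rel=1e-12)

    def test_linearity_in_target(self):
        wf1 = scale_to_peak_reynolds(self._waveform(), 1300.0, 5e-3, BLOOD)
        wf2 = scale_to_peak_reynolds(self._waveform(), 2600.0, 5e-3, BLOOD)
        assert wf2.mean_flow == pytest.approx(2 * wf1.mean_flow, rel=1e-12)
        for a, b in zip(wf1.harmonics, wf2.harmonics):
            assert b == pytest.approx(2 * a, rel=1e-12)

    def test_zero_waveform_errors(self):
        with pytest.raises(ValueError):
            scale_to_peak_reynolds(FourierWaveform(1.0, 0.0), 1300.0, 5e-3, BLOOD)


class TestWomersleyNumber:
    def test_zero_frequency(self):
        assert womersley_number(5e-3, 0.0, BLOOD) == 0.0

    def test_arithmetic(self):
        want = 2.5e-3 * math.sqrt(2 * math.pi * 1060 / 3.5e-3)
        assert womersley_number(5e-3, 2 * math.pi, BLOOD) == pytest.approx(
            want, rel=1e-12
        )
        assert want == pytest.approx(3.45, rel=1e-2)

    def test_sqrt_scaling(self):
        a = womersley_number(5e-3, 1.0, BLOOD)
        b = womersley_number(5e-3, 4.0, BLOOD)
        assert b == pytest.approx(2 * a, rel=1e-14)


def _flow_integral(field, t, n_quad=80):
    """Gauss-Legendre integral of u(r,t)*2*pi*r over the cross-section."""
    x, w = np.polynomial.legendre.leggauss(n_quad)
    r = 0.5 * field.radius * (x + 1.0)
    u = field.velocity(r, t)
    return float(np.sum(w * u * 2 * math.pi * r) * 0.5 * field.radius)


class TestWomersleyVelocity:
    R = 2.5e-3

    def _steady(self, q=1e-5):
        return WomersleyField(self.R, FourierWaveform(1.0, q), BLOOD)

    def test_steady_centreline_poiseuille(self):
        f = self._steady()
        want = 2 * 1e-5 / (math.pi * self.R**2)
        assert f.velocity(0.0, 0.3) == pytest.approx(want, rel=1e-12)

    def test_steady_half_centreline_at_r_over_sqrt2(self):
        f = self._steady()
        u0 = f.velocity(0.0, 0.0)
        assert f.velocity(self.R / math.sqrt(2), 0.0) == pytest.approx(
            u0 / 2, rel=1e-12
        )

    def test_no_slip(self):
        wf = FourierWaveform(1.0, 1e-5, harmonics=(3e-6 + 1e-6j, 1e-6 - 2e-6j))
        f = WomersleyField(self.R, wf, BLOOD)
        for t in (0.0, 0.17, 0.5, 0.93):
            assert abs(f.velocity(self.R, t)) < 1e-12

    def test_r_out_of_range_errors(self):
        f = self._steady()
        with pytest.raises(ValueError):
            f.velocity(-1e-6, 0.0)
        with pytest.raises(ValueError):
            f.velocity(self.R * 1.01, 0.0)

    def test_flow_consistency_random_waveforms(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            wf = FourierWaveform(
                1.0,
                1e-5,
                harmonics=tuple(
                    1e-6 * (rng.normal(size=5) + 1j * rng.normal(size=5))
                ),
            )
            f = WomersleyField(self.R, wf, BLOOD)
            for t in rng.uniform(0, 1, 100):
                q = _flow_integral(f, t)
                assert q == pytest.approx(float(wf.evaluate(t)), rel=1e-6)

    def test_single_harmonic_matches_fd_bvp_oracle(self):
        # independent finite-difference solve of the oscillatory pipe-flow
        # equation, Richardson-extrapolated, unit-flow normalised
        R = self.R
        mu, rho = BLOOD.viscosity, BLOOD.density
        alpha = 10.0
        omega = (alpha / R) ** 2 * mu / rho

        def fd_profile(n):
            h = R / n
            r = np.arange(n + 1) * h
            A = np.zeros((n + 1, n + 1), dtype=complex)
            b = np.ones(n + 1, dtype=complex)  # unit pressure-gradient drive
            A[0, 0] = 1j * omega * rho + 4 * mu / h**2
            A[0, 1] = -4 * mu / h**2
            for j in range(1, n):
                A[j, j] = 1j * omega * rho + 2 * mu / h**2
                A[j, j - 1] = -mu / h**2 + mu / (2 * r[j] * h)
                A[j, j + 1] = -mu / h**2 - mu / (2 * r[j] * h)
            A[n, n] = 1.0
            b[n] = 0.0
            u = np.linalg.solve(A, b)
            flow = np.trapezoid(u * 2 * math.pi * r, r)
            return r, u / flow

        r1, u1 = fd_profile(1000)
        r2, u2 = fd_profile(2000)
        u_extrap = (4 * u2[::2] - u1) / 3  # h^2 -> h^4 Richardson

        wf = FourierWaveform(period=2 * math.pi / omega, mean_flow=0.0,
                             harmonics=(1.0 + 0j,))
        f = WomersleyField(R, wf, BLOOD)
        got = f._harmonic_profile(1, r1)
        scale = np.max(np.abs(u_extrap))
        assert np.max(np.abs(got - u_extrap)) / scale < 1e-6

    def test_low_alpha_limit_is_parabolic(self):
        # alpha = 0.05 -> profile within 1e-3 of parabola (centreline units)
        R = self.R
        mu, rho = BLOOD.viscosity, BLOOD.density
        alpha = 0.05
        omega = (alpha / R) ** 2 * mu / rho
        wf = FourierWaveform(2 * math.pi / omega, 0.0, harmonics=(1e-6,))
        f = WomersleyField(R, wf, BLOOD)
        r = np.linspace(0, R, 50)
        # exact (non-series) evaluation just above the switch threshold,
        # compared against the parabolic limit
        alpha2 = 0.11
        omega2 = (alpha2 / R) ** 2 * mu / rho
        wf2 = FourierWaveform(2 * math.pi / omega2, 0.0, harmonics=(1e-6,))
        f2 = WomersleyField(R, wf2, BLOOD)
        exact = f2._harmonic_profile(1, r)
        para = 2 / (math.pi * R**2) * (1 - (r / R) ** 2)
        assert np.max(np.abs(exact - para)) / para.max() < 1e-3

    def test_wrapper_function(self):
        f = self._steady()
        assert womersley_velocity(f, 0.0, 0.0) == f.velocity(0.0, 0.0)


class TestFluidProperties:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            FluidProperties(viscosity=-1.0, density=1000.0)
        with pytest.raises(ValueError):
            FluidProperties(viscosity=1e-3, density=0.0)

    def test_periodicity_of_waveform(self):
        wf = FourierWaveform(0.8, 2.0, harmonics=(1 + 1j, 0.5))
        t = np.linspace(0, 0.8, 13)
        np.testing.assert_allclose(wf.evaluate(t), wf.evaluate(t + 0.8), atol=1e-12)
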