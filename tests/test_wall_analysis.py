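import math

import numpy as np
import pytest

from avflow.inflow import SampledWaveform
from avflow.lumped import AnalysisWindow
from avflow.wall_analysis import (
    PODResult,
    SpaceTimeVectorField,
    compute_psd,
    modes_for_energy,
    ring_average_magnitude,
    snapshot_pod,
)


def _field(mesh, vectors, t0=0.0, dt=0.01):
    n_t = vectors.shape[0]
    times = t0 + np.arange(n_t) * dt
    return SpaceTimeVectorField(mesh=mesh, times=times, vectors=vectors)


def _window(field):
    return AnalysisWindow("W", float(field.times[0]), float(field.times[-1]))


class TestRingAverage:
    def test_uniform_field(self, small_mesh):
        v = np.zeros((5, small_mesh.n_faces, 3))
        v[..., 0] = 2.0
        series = ring_average_magnitude(_field(small_mesh, v), "ring0")
        np.testing.assert_allclose(series.values, 2.0, rtol=1e-14)

    def test_two_equal_faces(self, two_face_mesh):
        v = np.zeros((3, 2, 3))
        v[:, 0, 0] = 1.0
        v[:, 1, 1] = 3.0
        series = ring_average_magnitude(_field(two_face_mesh, v), "band")
        np.testing.assert_allclose(series.values, 2.0, rtol=1e-14)

    def test_matches_bruteforce(self, small_mesh, rng):
        v = rng.standard_normal((4, small_mesh.n_faces, 3))
        series = ring_average_magnitude(_field(small_mesh, v), "ring1")
        idx = small_mesh.rings["ring1"]
        w = small_mesh.face_areas[idx]
        for i in range(4):
            want = sum(
                wi * np.linalg.norm(v[i, j]) for wi, j in zip(w, idx)
            ) / w.sum()
            assert series.values[i] == pytest.approx(want, rel=1e-12)

    def test_unknown_ring(self, small_mesh):
        v = np.zeros((2, small_mesh.n_faces, 3))
        with pytest.raises(ValueError, match="ring"):
            ring_average_magnitude(_field(small_mesh, v), "nope")


class TestPSD:
    def test_sinusoid_peak_bin(self):
        dt = 1e-3
        t = np.arange(1000) * dt
        s = SampledWaveform(t, np.sin(2 * math.pi * 25 * t))
        psd = compute_psd(s, AnalysisWindow("WT", 0.0, 1.0))
        assert psd.peak_frequency == pytest.approx(25.0, abs=1.01)

    def test_constant_series_no_power(self):
        t = np.arange(256) * 1e-3
        psd = compute_psd(SampledWaveform(t, np.full(256, 7.0)),
                          AnalysisWindow("W", 0.0, 0.256))
        assert np.all(psd.power < 1e-20)

    def test_parseval_white_noise(self, rng):
        dt = 1e-3
        n = 4096
        t = np.arange(n) * dt
        x = rng.standard_normal(n)
        psd = compute_psd(SampledWaveform(t, x), AnalysisWindow("W", 0.0, t[-1]))
        integrated = np.trapezoid(psd.power, psd.frequencies)
        assert integrated == pytest.approx(np.var(x), rel=0.05)

    def test_too_few_samples(self):
        t = np.arange(100) * 1e-3
        s = SampledWaveform(t, np.sin(t))
        with pytest.raises(ValueError, match="8 samples"):
            compute_psd(s, AnalysisWindow("W", 0.0, 0.005))

    def test_time_reverse_symmetry(self, rng):
        dt = 1e-3
        n = 512
        t = np.arange(n) * dt
        x = rng.standard_normal(n)
        w = AnalysisWindow("W", 0.0, t[-1])
        a = compute_psd(SampledWaveform(t, x), w)
        b = compute_psd(SampledWaveform(t, x[::-1].copy()), w)
        np.testing.assert_allclose(a.power, b.power, rtol=1e-9, atol=1e-18)

    def test_frequency_resolution(self):
        dt = 2e-4
        t = np.arange(1500) * dt
        s = SampledWaveform(t, np.sin(2 * math.pi * 40 * t))
        psd = compute_psd(s, AnalysisWindow("WS", 0.0, t[-1]))
        df = psd.frequencies[1] - psd.frequencies[0]
        assert df == pytest.approx(1.0 / (1500 * dt), rel=1e-6)


def _weighted_svd_eigs(field, region, window):
    """Independent oracle: full SVD of the weighted mean-centred matrix."""
    faces = field.mesh.region_faces(region)
    snap = field.window_slice(window)
    x = field.vectors[np.ix_(snap, faces)].reshape(snap.size, -1)
    x = x - x.mean(axis=0, keepdims=True)
    sw = np.sqrt(np.repeat(field.mesh.face_areas[faces], 3))
    s = np.linalg.svd(x * sw, compute_uv=False)
    return s**2


class TestSnapshotPOD:
    def test_rank_one(self, small_mesh, rng):
        pattern = rng.standard_normal((small_mesh.n_faces, 3))
        t = np.arange(50) * 0.01
        v = np.sin(2 * math.pi * t)[:, None, None] * pattern[None]
        field = _field(small_mesh, v)
        pod = snapshot_pod(field, "artery", _window(field))
        assert pod.eigenvalues.size == 1
        assert pod.energy_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_equal_energy_modes(self, small_mesh):
        from avflow.synthetic import GeneratorConfig, gen_wss_field

        k = 4
        cfg = GeneratorConfig(
            seed=5, field_rank=k, n_snapshots=200, snapshot_dt=0.001,
            mode_energies=(1.0,) * k, noise=0.0,
        )
        field = gen_wss_field(small_mesh, cfg)
        pod = snapshot_pod(field, "artery", _window(field))
        assert pod.eigenvalues.size == k
        np.testing.assert_allclose(
            pod.eigenvalues / pod.eigenvalues[0], 1.0, rtol=1e-8
        )
        for m, lam in enumerate(pod.eigenvalues):
            assert pod.energy_fraction[m] == pytest.approx((m + 1) / k, rel=1e-10)

    def test_svd_oracle(self, small_mesh, rng):
        v = rng.standard_normal((30, small_mesh.n_faces, 3))
        field = _field(small_mesh, v)
        w = _window(field)
        pod = snapshot_pod(field, "artery", w)
        want = _weighted_svd_eigs(field, "artery", w)
        want = want[want > 1e-12 * want[0]]
        np.testing.assert_allclose(pod.eigenvalues, want, rtol=1e-8)

    def test_reconstruction(self, small_mesh, rng):
        v = rng.standard_normal((20, small_mesh.n_faces, 3))
        field = _field(small_mesh, v)
        w = _window(field)
        pod = snapshot_pod(field, "artery", w)
        faces = pod.face_indices
        x = v[:, faces, :] - v[:, faces, :].mean(axis=0, keepdims=True)
        recon = np.einsum("mt,mfc->tfc", pod.temporal_coeffs, pod.spatial_modes)
        np.testing.assert_allclose(
            recon, x, atol=1e-8 * np.abs(x).max()
        )

    def test_energy_conservation(self, small_mesh, rng):
        v = rng.standard_normal((25, small_mesh.n_faces, 3))
        field = _field(small_mesh, v)
        pod = snapshot_pod(field, "artery", _window(field))
        faces = pod.face_indices
        x = v[:, faces, :] - v[:, faces, :].mean(axis=0, keepdims=True)
        w = small_mesh.face_areas[faces]
        total = np.sum(x**2 * w[None, :, None])
        assert pod.eigenvalues.sum() == pytest.approx(total, rel=1e-10)

    def test_mode_orthonormality(self, small_mesh, rng):
        v = rng.standard_normal((15, small_mesh.n_faces, 3))
        field = _field(small_mesh, v)
        pod = snapshot_pod(field, "artery", _window(field))
        w = small_mesh.face_areas[pod.face_indices]
        flat = pod.spatial_modes.reshape(pod.eigenvalues.size, -1)
        gram = flat @ (flat * np.repeat(w, 3)).T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_rotation_invariance(self, small_mesh, rng):
        from scipy.spatial.transform import Rotation

        v = rng.standard_normal((12, small_mesh.n_faces, 3))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        f1 = _field(small_mesh, v)
        f2 = _field(small_mesh, v @ rot.T)
        e1 = snapshot_pod(f1, "artery", _window(f1)).eigenvalues
        e2 = snapshot_pod(f2, "artery", _window(f2)).eigenvalues
        np.testing.assert_allclose(e1, e2, rtol=1e-9)

    def test_face_reorder_invariance(self, rng):
        from avflow.wall_analysis import SurfaceMesh
        from avflow.synthetic import GeneratorConfig, gen_cylinder_mesh

        mesh = gen_cylinder_mesh(GeneratorConfig(seed=0, n_axial=6, n_circ=8))
        v = rng.standard_normal((10, mesh.n_faces, 3))
        perm = rng.permutation(mesh.n_faces)
        mesh2 = SurfaceMesh(
            vertices=mesh.vertices.copy(),
            faces=mesh.faces[perm],
            region=mesh.region[perm],
        )
        f1 = _field(mesh, v)
        f2 = _field(mesh2, v[:, perm, :])
        e1 = snapshot_pod(f1, "artery", _window(f1)).eigenvalues
        e2 = snapshot_pod(f2, "artery", _window(f2)).eigenvalues
        np.testing.assert_allclose(e1, e2, rtol=1e-9)

    def test_zero_variance_flagged(self, small_mesh):
        v = np.ones((5, small_mesh.n_faces, 3))
        field = _field(small_mesh, v)
        pod = snapshot_pod(field, "artery", _window(field))
        assert pod.degenerate
        assert pod.eigenvalues.size == 1
        assert pod.eigenvalues[0] == 0.0


class TestModesForEnergy:
    def _pod(self, eigenvalues):
        lam = np.asarray(eigenvalues, dtype=float)
        return PODResult(
            eigenvalues=lam,
            energy_fraction=np.cumsum(lam) / lam.sum(),
            spatial_modes=np.zeros((lam.size, 1, 3)),
            temporal_coeffs=np.zeros((lam.size, 2)),
            snapshot_count=2,
            face_indices=np.array([0]),
        )

    def test_rank_one(self):
        assert modes_for_energy(self._pod([1.0]), 0.96) == 1

    def test_ten_equal(self):
        assert modes_for_energy(self._pod([1.0] * 10), 0.96) == 10

    def test_threshold_one(self):
        assert modes_for_energy(self._pod([3.0, 1.0, 0.5]), 1.0) == 3

    def test_exact_boundary(self):
        assert modes_for_energy(self._pod([1.0] * 10), 0.9) == 9

    def test_monotone_in_threshold(self):
        pod = self._pod([8.0, 4.0, 2.0, 1.0, 0.5])
        counts = [modes_for_energy(pod, th) for th in (0.5, 0.8, 0.96, 1.0)]
        assert counts == sorted(counts)
        assert counts[-1] <= pod.snapshot_count + 3  # <= number of modes

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            modes_for_energy(self._pod([1.0]), 0.0)
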