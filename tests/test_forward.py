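"""Forward model: the N-shaped pulse closed form and channel restriction."""

import numpy as np
import pytest

from zsa2a import (Phantom, make_spherical_array, restrict_channels,
                   sample_subset, simulate_channels)
from zsa2a.forward import load_channels, save_channels

C = 1500.0  # m/s


def n_pulse_oracle(t, detector, center, a, amplitude, c=C):
    """Independent scalar evaluation of the uniform-sphere pulse."""
    d = float(np.linalg.norm(np.asarray(detector) - np.asarray(center)))
    cm = c * 1e3  # mm/s
    out = np.zeros_like(t)
    for k, tk in enumerate(t):
        u = d - cm * tk
        if abs(u) <= a:
            out[k] = amplitude * u / (2.0 * d)
    return out


class TestSimulate:
    def test_empty_phantom_all_zero(self, small_array, box):
        ph = Phantom(np.empty((0, 5)), box)
        data = simulate_channels(ph, small_array)
        assert np.all(data.samples == 0)

    def test_matches_scalar_oracle(self, box):
        arr = make_spherical_array(8, 60.0)
        ph = Phantom(np.array([[2.0, 1.0, -3.0, 1.0, 0.7]]), box)
        data = simulate_channels(ph, arr)
        t = data.times
        for i in range(arr.n_detectors):
            expected = n_pulse_oracle(t, arr.positions[i], [2.0, 1.0, -3.0], 1.0, 0.7)
            assert np.allclose(data.samples[i], expected, rtol=0, atol=1e-15)

    def test_pulse_shape_properties(self):
        # one 1 mm sphere 50 mm from a detector: support, zero crossing, edges
        arr = make_spherical_array(1, 50.0)
        det = arr.positions[0]
        ph = Phantom(np.array([[0.0, 0.0, 0.0, 1.0, 1.0]]),
                     np.array([[-2.0, -2, -2], [2.0, 2, 2]]))
        data = simulate_channels(ph, arr, dt=5e-9)
        t = data.times
        p = data.samples[0]
        cm = C * 1e3
        d = 50.0
        nz = np.nonzero(p)[0]
        assert t[nz[0]] >= (d - 1.0) / cm - 5e-9
        assert t[nz[-1]] <= (d + 1.0) / cm + 5e-9
        # sign change at t = d/c
        assert np.all(p[t < (d - 1.0) / cm] == 0)
        before = p[(t > (d - 1.0) / cm) & (t < d / cm - 5e-9)]
        after = p[(t > d / cm + 5e-9) & (t < (d + 1.0) / cm)]
        assert np.all(before > 0) and np.all(after < 0)
        # max |p| at the support edges
        edge = np.abs(p).max()
        assert np.isclose(edge, 1.0 / (2 * d), rtol=0.01)
        assert np.abs(p[np.argmin(np.abs(t - d / cm))]) < 0.1 * edge

    def test_superposition_exact(self, small_array, box):
        a1 = np.array([[3.0, -2.0, 1.0, 0.8, 1.0]])
        a2 = np.array([[-4.0, 5.0, -2.0, 1.2, 0.5]])
        both = Phantom(np.vstack([a1, a2]), box)
        t0, dt, n_t = 2.0e-5, 25e-9, 2500
        kw = dict(t0=t0, dt=dt, n_t=n_t)
        s_both = simulate_channels(both, small_array, **kw).samples
        s1 = simulate_channels(Phantom(a1, box), small_array, **kw).samples
        s2 = simulate_channels(Phantom(a2, box), small_array, **kw).samples
        assert np.allclose(s_both, s1 + s2, rtol=1e-12, atol=1e-300)

    def test_amplitude_scaling(self, small_array, single_sphere):
        s1 = simulate_channels(single_sphere, small_array).samples
        # power-of-two factor: scaling commutes bitwise with the simulation
        s2 = simulate_channels(single_sphere.scaled(2.0), small_array).samples
        assert np.array_equal(s2, 2.0 * s1)
        # general factor: exact up to one rounding
        s3 = simulate_channels(single_sphere.scaled(3.0), small_array).samples
        assert np.allclose(s3, 3.0 * s1, rtol=1e-15, atol=0)

    def test_radial_shift_moves_pulse(self, box):
        # translating an absorber radially away from a detector by delta
        # shifts its pulse by delta / c (to within one sample)
        arr = make_spherical_array(1, 60.0)
        det = arr.positions[0]
        u = det / np.linalg.norm(det)
        c0 = 2.0 * u  # on the detector axis
        delta = 1.0  # mm toward the origin = away from the detector
        kw = dict(t0=3.0e-5, dt=25e-9, n_t=2200)
        pa = simulate_channels(Phantom(np.array([[*c0, 0.5, 1.0]]), box), arr, **kw)
        pb = simulate_channels(Phantom(np.array([[*(c0 - delta * u), 0.5, 1.0]]),
                                       box), arr, **kw)
        shift = np.argmax(np.correlate(pb.samples[0], pa.samples[0], "full")) \
            - (pa.n_t - 1)
        expected = delta / (C * 1e3) / 25e-9
        assert abs(shift - expected) <= 1

    def test_window_too_short_names_pair(self, small_array, single_sphere):
        with pytest.raises(ValueError, match="absorber 0 at detector"):
            simulate_channels(single_sphere, small_array, t0=0.0, n_t=10)

    def test_noise_is_seeded(self, small_array, single_sphere):
        a = simulate_channels(single_sphere, small_array, noise_std=0.01,
                              noise_seed=5)
        b = simulate_channels(single_sphere, small_array, noise_std=0.01,
                              noise_seed=5)
        assert np.array_equal(a.samples, b.samples)


class TestRestrict:
    def test_identity(self, small_array, single_sphere):
        data = simulate_channels(single_sphere, small_array)
        out = restrict_channels(data, np.arange(data.n_detectors))
        assert np.array_equal(out.samples, data.samples)

    def test_single_row(self, small_array, single_sphere):
        data = simulate_channels(single_sphere, small_array)
        out = restrict_channels(data, [0])
        assert out.samples.shape == (1, data.n_t)
        assert np.array_equal(out.samples[0], data.samples[0])

    def test_subset_shape(self, single_sphere):
        arr = make_spherical_array(512, 60.0)
        data = simulate_channels(single_sphere, arr)
        sub = sample_subset(512, 400, seed=1)
        out = restrict_channels(data, sub)
        assert out.samples.shape == (400, data.n_t)

    def test_composition(self, small_array, single_sphere):
        data = simulate_channels(single_sphere, small_array)
        outer = np.array([3, 7, 11, 20, 40, 41])
        inner = np.array([0, 2, 5])
        once = restrict_channels(data, outer[inner])
        twice = restrict_channels(restrict_channels(data, outer), inner)
        assert np.array_equal(once.samples, twice.samples)

    def test_out_of_range(self, small_array, single_sphere):
        data = simulate_channels(single_sphere, small_array)
        with pytest.raises(ValueError):
            restrict_channels(data, [data.n_detectors])


def test_hdf5_roundtrip(tmp_path, small_array, single_sphere):
    data = simulate_channels(single_sphere, small_array)
    save_channels(data, tmp_path / "sino.h5", small_array)
    back, arr = load_channels(tmp_path / "sino.h5")
    assert np.array_equal(back.samples, data.samples)
    assert back.t0 == data.t0 and back.dt == data.dt
    assert np.array_equal(arr.positions, small_array.positions)
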