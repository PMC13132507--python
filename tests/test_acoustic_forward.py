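"""Ring-array forward projection, chirp coding and channel noise."""

import numpy as np
import pytest
from scipy.signal import fftconvolve, stft

from tamon.acoustic_forward import (DetectorArray, RingProjector, add_noise,
                                    chirp_forward, impulse_forward)
from tamon.reconstruction import ImageGrid, backproject_raw
from tamon.waveforms import ChirpSpec, expected_response

VS = 1540.0


class TestDetectorArray:
    def test_default_geometry(self):
        arr = DetectorArray()
        assert arr.n_elements == 512
        assert arr.ring_diameter == pytest.approx(0.6)
        assert arr.fs == pytest.approx(5e6)
        radii = np.hypot(*arr.element_positions.T)
        assert np.allclose(radii, 0.3)
        # even angular spacing
        ang = np.unwrap(np.arctan2(arr.element_positions[:, 1],
                                   arr.element_positions[:, 0]))
        assert np.allclose(np.diff(ang), 2 * np.pi / 512)

    def test_position_override_shape_checked(self):
        with pytest.raises(ValueError):
            DetectorArray(n_elements=4, element_positions=np.zeros((3, 2)))


class TestImpulseForward:
    def test_point_source_arrival_times(self, medium_grid, medium_array):
        """The bipolar feature arrives at distance/vs on every element."""
        n = medium_grid.n_pixels
        src = np.zeros((n, n))
        iy, ix = 40, 20
        src[iy, ix] = 1.0
        traces = impulse_forward(src, medium_array, medium_grid, VS)
        point = np.array([medium_grid.axis(0)[ix], medium_grid.axis(1)[iy]])
        for e in range(medium_array.n_elements):
            dist = np.linalg.norm(medium_array.element_positions[e] - point)
            expected = dist / VS * medium_array.fs
            # bipolar feature: strongest samples straddle the arrival
            peak = np.argmax(np.abs(traces[e]))
            assert abs(peak - expected) <= 1.5

    def test_superposition(self, small_grid, small_array):
        a = np.zeros((32, 32)); a[10, 12] = 1.0
        b = np.zeros((32, 32)); b[20, 7] = 2.0
        f = lambda img: impulse_forward(img, small_array, small_grid, VS)
        assert np.max(np.abs(f(a + b) - f(a) - f(b))) <= 1e-9

    def test_center_source_symmetric(self, small_array):
        # odd grid so one pixel sits exactly at the ring centre
        grid = ImageGrid(n_pixels=33, pixel_size=1e-3)
        src = np.zeros((33, 33))
        src[16, 16] = 1.0
        traces = impulse_forward(src, small_array, grid, VS)
        assert np.allclose(traces, traces[0], atol=1e-12 +
                           1e-9 * np.abs(traces[0]).max())

    def test_source_beyond_trace_length_rejected(self, small_grid,
                                                 small_array):
        src = np.ones((32, 32))
        with pytest.raises(ValueError):
            impulse_forward(src, small_array, small_grid, VS, n_samples=100)


class TestAdjointConsistency:
    def test_forward_adjoint_inner_products(self, small_grid, small_array,
                                            rng):
        """<F x, y> == <x, F* y> validates the operator pair."""
        proj = RingProjector(small_array, small_grid, VS)
        for _ in range(3):
            x = rng.normal(size=(32, 32))
            y = rng.normal(size=(16, proj.n_samples))
            lhs = float(np.sum(proj.forward(x) * y))
            rhs = float(np.sum(x * proj.adjoint(y)))
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_backproject_raw_is_adjoint(self, small_grid, small_array, rng):
        proj = RingProjector(small_array, small_grid, VS)
        x = rng.normal(size=(32, 32))
        y = rng.normal(size=(16, proj.n_samples))
        lhs = float(np.sum(proj.forward(x) * y))
        rhs = float(np.sum(x * backproject_raw(y, small_array, small_grid,
                                               VS)))
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestChirpForward:
    def test_linear_in_beta(self, small_grid, small_array, chirp_spec):
        src = np.zeros((32, 32)); src[10, 12] = 1.0
        t1 = chirp_forward(src, small_array, small_grid, chirp_spec,
                           beta=3e-4, cp=3500.0, speed_of_sound=VS)
        t2 = chirp_forward(src, small_array, small_grid, chirp_spec,
                           beta=6e-4, cp=3500.0, speed_of_sound=VS)
        assert np.allclose(t2, 2.0 * t1)

    def test_matches_fft_convolution_oracle(self, small_grid, small_array,
                                            chirp_spec):
        src = np.zeros((32, 32)); src[10, 12] = 1.0
        imp = impulse_forward(src, small_array, small_grid, VS)
        profile = -np.pi * (3e-4 / 3500.0) * expected_response(chirp_spec)
        # independent oracle: frequency-domain product at full length
        n = imp.shape[1] + profile.size - 1
        oracle = np.fft.irfft(np.fft.rfft(imp, n, axis=1)
                              * np.fft.rfft(profile, n), n, axis=1)
        out = chirp_forward(src, small_array, small_grid, chirp_spec,
                            beta=3e-4, cp=3500.0, speed_of_sound=VS)
        scale = np.abs(oracle).max()
        assert np.max(np.abs(out - oracle)) <= 1e-7 * scale

    def test_spectrogram_ridge_spans_doubled_band(self, medium_grid,
                                                  medium_array, chirp_spec):
        """Recorded chirp sweeps ~0.1-2.0 MHz as a rising ridge."""
        src = np.zeros((64, 64)); src[40, 20] = 1.0
        out = chirp_forward(src, medium_array, medium_grid, chirp_spec,
                            beta=3e-4, cp=3500.0, speed_of_sound=VS)
        f, t, z = stft(out[0], fs=medium_array.fs, nperseg=128)
        power = np.abs(z)
        # the ramp weighting de-emphasises the low band edge, so activity
        # is gated loosely
        active = power.max(axis=0) > 0.02 * power.max()
        ridge = f[np.argmax(power, axis=0)][active]
        assert ridge.min() <= 0.35e6
        assert ridge.max() >= 1.8e6
        # ridge rises with time overall
        assert np.polyfit(np.arange(ridge.size), ridge, 1)[0] > 0


class TestAddNoise:
    def test_infinite_snr_identity(self, rng):
        traces = rng.normal(size=(4, 500))
        assert np.array_equal(add_noise(traces, np.inf, 0), traces)

    def test_seed_reproducibility(self, rng):
        traces = rng.normal(size=(4, 500))
        assert np.array_equal(add_noise(traces, 20.0, 42),
                              add_noise(traces, 20.0, 42))
        assert not np.array_equal(add_noise(traces, 20.0, 42),
                                  add_noise(traces, 20.0, 43))

    def test_empirical_snr_matches_request(self, rng):
        traces = rng.normal(size=(8, 4000))
        noisy = add_noise(traces, 20.0, 7)
        p_sig = np.mean(traces**2)
        p_noise = np.mean((noisy - traces) ** 2)
        snr_db = 10 * np.log10(p_sig / p_noise)
        assert snr_db == pytest.approx(20.0, abs=0.25)

    def test_zero_traces_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros((2, 100)), 20.0, 0)


def test_pulse_compression_snr_gain(chirp_spec):
    """Matched filtering of a unit-amplitude chirp improves output SNR over
    a unit-amplitude pulse of duration 1/bandwidth by roughly the square
    root of the time-bandwidth product (~19.5 for 400 us x 0.95 MHz).

    Monte-Carlo: matched-filter each waveform in white noise and compare
    the clean correlation peak with the empirical noise level at the
    filter output.
    """
    from tamon.waveforms import doubled_chirp

    bandwidth = chirp_spec.f1 - chirp_spec.f0
    chirp = doubled_chirp(chirp_spec)
    n_pulse = int(round(chirp_spec.fs / bandwidth))
    pulse = np.ones(n_pulse)
    sigma = 1.0

    def matched_snr(wave, seed):
        peak = float(np.sum(wave * wave))  # zero-lag autocorrelation
        noise = np.random.default_rng(seed).normal(0, sigma, 20000)
        out = np.correlate(noise, wave, mode="valid")
        return peak / np.std(out)

    gains = [matched_snr(chirp, s) / matched_snr(pulse, 100 + s)
             for s in range(5)]
    expected = np.sqrt(chirp_spec.tc * bandwidth)
    assert expected == pytest.approx(19.5, abs=0.1)
    mean_gain = float(np.mean(gains))
    assert expected / 1.5 <= mean_gain <= expected * 1.5
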