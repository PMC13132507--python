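"""Chirp waveform generation: phases, frequencies, frame assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import cumulative_trapezoid
from scipy.signal import stft

from tamon.waveforms import (ChirpSpec, ModulationFrame, build_modulation_frame,
                             doubled_chirp, expected_response,
                             heating_envelope, instantaneous_frequency,
                             modulating_chirp)


class TestChirpSpec:
    def test_defaults_and_rate(self, chirp_spec):
        assert chirp_spec.fr == pytest.approx((1.0e6 - 0.05e6) / 400e-6)

    @pytest.mark.parametrize("kwargs", [
        dict(f0=2e6, f1=1e6),              # inverted band
        dict(f0=-1.0, f1=1e6),             # negative lower edge
        dict(fs=2e6),                      # below Nyquist for doubled chirp
        dict(taper_fraction=0.6),          # over-long taper
        dict(tc=0.0),                      # empty chirp
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ChirpSpec(**kwargs)

    def test_nonuniform_grid_rejected(self, chirp_spec):
        t = chirp_spec.time_grid()
        t[5] += 3e-8
        with pytest.raises(ValueError):
            modulating_chirp(chirp_spec, t)

    def test_out_of_range_grid_rejected(self, chirp_spec):
        t = chirp_spec.time_grid() + 2 * chirp_spec.tc
        with pytest.raises(ValueError):
            doubled_chirp(chirp_spec, t)


class TestModulatingChirp:
    def test_zero_at_origin(self, chirp_spec):
        assert modulating_chirp(chirp_spec)[0] == 0.0

    def test_upper_band_edge_frequency(self, chirp_spec):
        """Instantaneous frequency reaches f1 = 1.0 MHz at t = tc."""
        x = modulating_chirp(chirp_spec, taper=False)
        f = instantaneous_frequency(x, chirp_spec.fs, chirp_spec.tc)
        assert f == pytest.approx(1.0e6, rel=1e-3)

    def test_phase_integration_oracle(self, chirp_spec):
        """The waveform equals sin of the integral of 2*pi*fm(t)."""
        t = chirp_spec.time_grid()
        fm = chirp_spec.fr * t + chirp_spec.f0
        phase = 2.0 * np.pi * cumulative_trapezoid(fm, t, initial=0.0)
        x = modulating_chirp(chirp_spec, t, taper=False)
        # trapezoid phase error is O(dt^2 * fr); bound evaluated analytically
        assert np.max(np.abs(x - np.sin(phase))) < 1e-4
        # against the exact closed-form phase the match is tight
        exact = np.sin(2 * np.pi * (0.5 * chirp_spec.fr * t**2
                                    + chirp_spec.f0 * t))
        assert np.max(np.abs(modulating_chirp(chirp_spec, t, taper=False)
                             - exact)) <= 1e-9

    def test_taper_attenuates_edges_only(self, chirp_spec):
        x_t = modulating_chirp(chirp_spec, taper=True)
        x_u = modulating_chirp(chirp_spec, taper=False)
        n = x_t.size
        n_tap = int(round(chirp_spec.taper_fraction * n))
        mid = slice(n_tap, n - n_tap)
        assert np.allclose(x_t[mid], x_u[mid])
        assert np.all(np.abs(x_t[:n_tap]) <= np.abs(x_u[:n_tap]) + 1e-12)


class TestHeatingEnvelope:
    def test_zero_at_origin(self, chirp_spec):
        assert heating_envelope(chirp_spec)[0] == 0.0

    def test_squared_chirp_identity(self, chirp_spec):
        """g(t) == 2 x(t)^2 for the untapered chirp (trig identity)."""
        t = chirp_spec.time_grid()
        g = heating_envelope(chirp_spec, t)
        x = modulating_chirp(chirp_spec, t, taper=False)
        assert np.max(np.abs(g - 2.0 * x**2)) <= 1e-12

    def test_unit_time_average(self, chirp_spec):
        g = heating_envelope(chirp_spec)
        assert np.mean(g) == pytest.approx(1.0, rel=0.01)


class TestDoubledChirp:
    def test_band_edges(self, chirp_spec):
        """x2f sweeps 0.1 to 2.0 MHz (twice the modulation band)."""
        x2 = doubled_chirp(chirp_spec)
        f_lo = instantaneous_frequency(x2, chirp_spec.fs, 0.0)
        f_hi = instantaneous_frequency(x2, chirp_spec.fs, chirp_spec.tc)
        assert f_lo == pytest.approx(0.1e6, rel=5e-3)
        assert f_hi == pytest.approx(2.0e6, rel=5e-3)

    @pytest.mark.parametrize("f0,f1,tc", [
        (0.05e6, 1.0e6, 400e-6),
        (0.1e6, 0.8e6, 300e-6),
        (0.2e6, 1.2e6, 500e-6),
    ])
    def test_stft_ridge_doubling(self, f0, f1, tc):
        """The spectrogram ridge of x2f is twice the ridge of x, bin-wise."""
        spec = ChirpSpec(f0=f0, f1=f1, tc=tc, fs=10e6)
        t = spec.time_grid()
        x = modulating_chirp(spec, t, taper=False)
        x2 = doubled_chirp(spec, t)
        nper = 256
        f_axis, t_axis, zx = stft(x, fs=spec.fs, nperseg=nper)
        _, _, z2 = stft(x2, fs=spec.fs, nperseg=nper)
        df = f_axis[1] - f_axis[0]
        interior = (t_axis > 0.1 * tc) & (t_axis < 0.9 * tc)
        ridge_x = f_axis[np.argmax(np.abs(zx), axis=0)][interior]
        ridge_2 = f_axis[np.argmax(np.abs(z2), axis=0)][interior]
        assert np.all(np.abs(ridge_2 - 2.0 * ridge_x) <= 2 * df + 1e-9)


class TestExpectedResponse:
    def test_zero_at_origin(self, chirp_spec):
        assert expected_response(chirp_spec)[0] == 0.0

    def test_ramp_weight_at_extrema(self, chirp_spec):
        """r(t)/x2f(t) equals the ramp fm(t) wherever x2f is at an extremum."""
        t = chirp_spec.time_grid()
        x2 = doubled_chirp(chirp_spec, t)
        r = expected_response(chirp_spec, t)
        extrema = np.abs(np.abs(x2) - 1.0) < 1e-3
        assert extrema.sum() > 10
        ratio = r[extrema] / x2[extrema]
        fm = chirp_spec.fr * t[extrema] + chirp_spec.f0
        assert np.max(np.abs(ratio - fm) / fm) <= 1e-9

    def test_envelope_ramp_is_increasing(self, chirp_spec):
        t = chirp_spec.time_grid()
        r = expected_response(chirp_spec, t)
        x2 = doubled_chirp(chirp_spec, t)
        extrema = np.abs(np.abs(x2) - 1.0) < 1e-6
        peaks = np.abs(r[extrema])
        assert np.all(np.diff(peaks) > 0)


class TestModulationFrame:
    def test_zero_hold_returns_chirp_alone(self, chirp_spec):
        frame = ModulationFrame(hold_duration=0.0, period=chirp_spec.tc)
        out = build_modulation_frame(chirp_spec, frame)
        n_chirp = int(round(chirp_spec.tc * chirp_spec.fs))
        t = np.arange(n_chirp) / chirp_spec.fs
        assert np.allclose(out, modulating_chirp(chirp_spec, t))

    def test_hold_power_is_half_chirp_power(self, chirp_spec):
        out = build_modulation_frame(chirp_spec)
        n_chirp = int(round(chirp_spec.tc * chirp_spec.fs))
        n_hold = int(round(9.5e-3 * chirp_spec.fs))
        hold = out[n_chirp:n_chirp + n_hold]
        t = np.arange(n_chirp) / chirp_spec.fs
        chirp_u = modulating_chirp(chirp_spec, t, taper=False)
        ratio = np.mean(hold**2) / np.mean(chirp_u**2)
        assert ratio == pytest.approx(0.5, abs=1e-3)

    def test_frame_sample_count(self, chirp_spec):
        assert build_modulation_frame(chirp_spec).size == 50_000

    def test_period_shorter_than_segments_rejected(self, chirp_spec):
        with pytest.raises(ValueError):
            build_modulation_frame(
                chirp_spec, ModulationFrame(hold_duration=9.5e-3,
                                            period=5e-3))


@settings(deadline=None, max_examples=10, derandomize=True)
@given(f0=st.floats(0.02e6, 0.3e6), bw=st.floats(0.3e6, 1.2e6),
       tc=st.floats(200e-6, 600e-6))
def test_phase_continuity_and_band(f0, bw, tc):
    """Analytic phase of x is smooth and its derivative spans [f0, f1]."""
    spec = ChirpSpec(f0=f0, f1=f0 + bw, tc=tc, fs=12e6)
    x = modulating_chirp(spec, taper=False)
    f_mid = instantaneous_frequency(x, spec.fs, 0.5 * tc)
    assert f_mid == pytest.approx(f0 + 0.5 * bw, rel=2e-2)


def test_waveform_generators_deterministic(chirp_spec):
    assert np.array_equal(modulating_chirp(chirp_spec),
                          modulating_chirp(chirp_spec))
    assert np.array_equal(expected_response(chirp_spec),
                          expected_response(chirp_spec))


def test_export_waveform_roundtrip(tmp_path, chirp_spec):
    x = modulating_chirp(chirp_spec)
    path = tmp_path / "chirp.txt"
    from tamon.waveforms import export_waveform
    export_waveform(path, x, chirp_spec)
    header = path.read_text().splitlines()[:4]
    assert header[0].startswith("# fs=")
    assert np.allclose(np.loadtxt(path), x)
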