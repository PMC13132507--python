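"""Universal back-projection, envelope combination and probe masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tamon.acoustic_forward import DetectorArray, RingProjector, impulse_forward
from tamon.reconstruction import (Backprojector, ImageGrid, apply_probe_mask,
                                  backproject, envelope_combine,
                                  reconstruct_frame)

VS = 1540.0


class TestImageGrid:
    def test_extent_identity(self):
        g = ImageGrid()
        assert g.n_pixels == 512
        assert g.pixel_size == pytest.approx(0.25e-3)
        assert g.extent == pytest.approx(0.128)

    def test_index_round_trip(self):
        g = ImageGrid(n_pixels=64, pixel_size=1e-3)
        point = (g.axis(0)[40], g.axis(1)[12])
        row, col = g.index_of(point)
        assert (row, col) == (12, 40)
        # a nearby off-centre point snaps to the same pixel
        row2, col2 = g.index_of((point[0] + 0.4e-3, point[1] - 0.4e-3))
        assert (row2, col2) == (12, 40)

    def test_off_grid_point_rejected(self):
        g = ImageGrid(n_pixels=64, pixel_size=1e-3)
        with pytest.raises(ValueError):
            g.index_of((1.0, 0.0))


class TestBackproject:
    def test_point_source_localization(self, medium_grid, medium_array):
        """Envelope reconstruction peaks within one 0.25 mm pixel of the
        true source position."""
        n = medium_grid.n_pixels
        for iy, ix in [(40, 20), (12, 50), (32, 32)]:
            src = np.zeros((n, n))
            src[iy, ix] = 1.0
            traces = impulse_forward(src, medium_array, medium_grid, VS)
            env = reconstruct_frame(traces, medium_array, medium_grid, VS)
            jy, jx = np.unravel_index(np.argmax(env), env.shape)
            assert abs(jy - iy) <= 1 and abs(jx - ix) <= 1

    def test_all_zero_traces_give_zero_image(self, small_grid, small_array):
        proj = RingProjector(small_array, small_grid, VS)
        img = backproject(np.zeros((16, proj.n_samples)), small_array,
                          small_grid, VS)
        assert np.all(img == 0.0)

    def test_linearity(self, small_grid, small_array, rng):
        proj = RingProjector(small_array, small_grid, VS)
        a = rng.normal(size=(16, proj.n_samples))
        b = rng.normal(size=(16, proj.n_samples))
        img = backproject(3.0 * a - b, small_array, small_grid, VS)
        parts = 3.0 * backproject(a, small_array, small_grid, VS) \
            - backproject(b, small_array, small_grid, VS)
        assert np.allclose(img, parts)

    def test_two_equal_sources_equal_amplitude(self, medium_grid,
                                               medium_array):
        n = medium_grid.n_pixels
        src = np.zeros((n, n))
        src[32, 16] = 1.0
        src[32, 48] = 1.0  # mirror position
        traces = impulse_forward(src, medium_array, medium_grid, VS)
        env = reconstruct_frame(traces, medium_array, medium_grid, VS)
        a = env[30:35, 14:19].max()
        b = env[30:35, 46:51].max()
        assert a == pytest.approx(b, rel=0.05)

    def test_short_traces_rejected(self, small_grid, small_array):
        with pytest.raises(ValueError):
            backproject(np.zeros((16, 64)), small_array, small_grid, VS)

    def test_matches_brute_force_delay_and_sum(self, small_grid,
                                               small_array, rng):
        """Vectorised UBP equals a per-pixel delay-and-sum oracle."""
        proj = RingProjector(small_array, small_grid, VS)
        traces = rng.normal(size=(16, proj.n_samples))
        img = backproject(traces, small_array, small_grid, VS)
        fs = small_array.fs
        t = np.arange(traces.shape[1]) / fs
        dtr = np.zeros_like(traces)
        dtr[:, 1:-1] = (traces[:, 2:] - traces[:, :-2]) * fs / 2.0
        b = 2.0 * traces - 2.0 * t * dtr
        oracle = np.zeros((32, 32))
        xs = small_grid.axis(0)
        ys = small_grid.axis(1)
        for iy in range(32):
            for ix in range(32):
                acc = 0.0
                for e in range(16):
                    d = np.hypot(small_array.element_positions[e, 0] - xs[ix],
                                 small_array.element_positions[e, 1] - ys[iy])
                    s = d * fs / VS
                    i0 = int(np.floor(s))
                    frac = s - i0
                    acc += (1 - frac) * b[e, i0] + frac * b[e, i0 + 1]
                oracle[iy, ix] = acc / 16
        assert np.max(np.abs(img - oracle)) <= 1e-6 * np.abs(oracle).max()

    def test_resolution_near_diffraction_limit(self, medium_array):
        """FWHM of a reconstructed point is within twice the diffraction
        limit at the 2 MHz band edge."""
        from tamon.deconvolution import DeconvolutionConfig, wiener_deconvolve
        from tamon.acoustic_forward import chirp_forward
        from tamon.waveforms import ChirpSpec, expected_response

        spec = ChirpSpec()
        grid = ImageGrid(n_pixels=64, pixel_size=0.25e-3)
        src = np.zeros((64, 64))
        src[32, 32] = 1.0
        coded = chirp_forward(src, medium_array, grid, spec, 3e-4, 3500.0, VS)
        chi = wiener_deconvolve(coded, DeconvolutionConfig(
            reference=expected_response(spec)))
        env = reconstruct_frame(chi, medium_array, grid, VS)
        row = env[32]
        half = row.max() / 2
        above = np.nonzero(row >= half)[0]
        fwhm_m = (above[-1] - above[0] + 1) * grid.pixel_size
        diffraction = VS / 2e6 / 2  # half-wavelength at the upper band edge
        assert fwhm_m <= 2 * diffraction


class TestEnvelopeCombine:
    def test_zero_quadrature_gives_magnitude(self, rng):
        re = rng.normal(size=(8, 8))
        assert np.allclose(envelope_combine(re, np.zeros_like(re)),
                           np.abs(re))

    def test_dominates_both_components(self, rng):
        re = rng.normal(size=(8, 8))
        im = rng.normal(size=(8, 8))
        env = envelope_combine(re, im)
        assert np.all(env >= np.abs(re) - 1e-15)
        assert np.all(env >= np.abs(im) - 1e-15)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(phi=st.floats(0.0, 2 * np.pi))
    def test_analytic_phase_rotation_invariance(self, phi):
        rng = np.random.default_rng(5)
        re = rng.normal(size=(6, 6))
        im = rng.normal(size=(6, 6))
        re2 = np.cos(phi) * re - np.sin(phi) * im
        im2 = np.sin(phi) * re + np.cos(phi) * im
        assert np.allclose(envelope_combine(re, im),
                           envelope_combine(re2, im2), atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            envelope_combine(np.zeros((4, 4)), np.zeros((5, 5)))


class TestProbeMask:
    def test_disk_pixel_count(self):
        """A 5 cm mask on the 0.25 mm grid keeps the disk's pixel count
        to within one boundary ring."""
        g = ImageGrid(n_pixels=512, pixel_size=0.25e-3)
        masked = apply_probe_mask(np.ones((512, 512)), g, (0.0, 0.0), 0.05)
        count = int(masked.sum())
        r_px = 0.025 / 0.25e-3
        expected = np.pi * r_px**2
        ring = 2 * np.pi * r_px
        assert abs(count - expected) <= ring

    def test_huge_mask_keeps_image(self, small_grid, rng):
        img = rng.normal(size=(32, 32))
        out = apply_probe_mask(img, small_grid, (0.0, 0.0),
                               10 * small_grid.extent)
        assert np.array_equal(out, img)

    def test_outside_radius_exactly_zero(self):
        g = ImageGrid(n_pixels=256, pixel_size=0.5e-3)
        out = apply_probe_mask(np.ones((256, 256)), g, (0.0, 0.0), 0.05)
        xx, yy = g.mesh()
        outside = np.hypot(xx, yy) > 0.025 + 1e-9
        assert np.all(out[outside] == 0.0)

    def test_off_grid_center_rejected(self, small_grid):
        with pytest.raises(ValueError):
            apply_probe_mask(np.ones((32, 32)), small_grid, (1.0, 1.0), 0.05)
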