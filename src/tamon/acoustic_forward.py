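"""Forward projection of heating maps into ring-array channel data.

Under thermal confinement the thermoacoustic pressure obeys a wave
equation whose source is the time derivative of the heating rate.  For
delta-like heating the solution at a detector is the shell integral of
the source at radius ``vs*t``, time-differentiated: this module
discretises that operator on the 2-D ring plane (the reconstruction
plane), with spherical-spreading amplitude weighting and a
central-difference time derivative.  Chirp-coded excitation is obtained
by convolving the impulse traces with the source time profile
``-pi * (beta/Cp) * fm(t) * x2f(t)``.

The forward operator and its exact adjoint share one set of delay tables
so the forward/reconstruction pair can be validated by inner-product
(adjoint-consistency) tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .reconstruction import ImageGrid
from .waveforms import ChirpSpec, expected_response

__all__ = [
    "DetectorArray",
    "ChannelFrameSeries",
    "RingProjector",
    "impulse_forward",
    "chirp_forward",
    "add_noise",
]


def _ring_positions(n_elements: int, ring_diameter: float) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(n_elements) / n_elements
    r = ring_diameter / 2.0
    return np.column_stack([r * np.cos(angles), r * np.sin(angles)])


@dataclass(frozen=True)
class DetectorArray:
    """Ring receiver array geometry and sampling.

    Defaults: 512 elements evenly spaced on a 60 cm diameter ring, 1 MHz
    centre frequency (metadata; element bandwidth is not modelled), 5 MSPS
    parallel digitisation.  ``element_positions`` may be overridden for
    non-uniform layouts.
    """

    n_elements: int = 512
    ring_diameter: float = 0.6
    center_frequency: float = 1e6
    fs: float = 5e6
    element_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_elements < 1 or self.ring_diameter <= 0 or self.fs <= 0:
            raise ValueError("invalid array definition")
        if self.element_positions is None:
            object.__setattr__(
                self, "element_positions",
                _ring_positions(self.n_elements, self.ring_diameter))
        else:
            pos = np.asarray(self.element_positions, dtype=float)
            if pos.shape != (self.n_elements, 2):
                raise ValueError("element_positions must be (n_elements, 2)")
            object.__setattr__(self, "element_positions", pos)


@dataclass
class ChannelFrameSeries:
    """Per-second frames of multi-channel fast-time pressure traces."""

    taus: np.ndarray            # (n_frames,) slow-time stamps, s
    traces: np.ndarray          # (n_frames, n_elements, n_samples)
    array: DetectorArray
    speed_of_sound: float = 1540.0

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 3:
            raise ValueError("traces must be (n_frames, n_elements, n_samples)")
        if self.traces.shape[0] != self.taus.size:
            raise ValueError("frame count does not match tau stamps")
        if self.traces.shape[1] != self.array.n_elements:
            raise ValueError("channel count does not match array")
        if np.any(np.diff(self.taus) <= 0):
            raise ValueError("tau must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]


class RingProjector:
    """Discrete shell-integral forward operator and its exact adjoint.

    Precomputes, for every (element, pixel) pair, the arrival sample
    ``|x - x_e| * fs / vs`` split into integer part and linear-interpolation
    fraction, plus the spherical-spreading amplitude weight
    ``pixel_area / (2*pi*distance)``.  ``forward`` bins pixel amplitudes
    into time samples and applies a central-difference time derivative;
    ``adjoint`` is the exact transpose.
    """

    def __init__(self, array: DetectorArray, grid: ImageGrid,
                 speed_of_sound: float, n_samples: int | None = None):
        if speed_of_sound <= 0.0:
            raise ValueError("speed of sound must be positive")
        self.array = array
        self.grid = grid
        self.vs = speed_of_sound
        pix = grid.pixel_coords()
        pos = array.element_positions
        # per-element delay/weight tables in compact dtypes (the tables
        # dominate memory at full array/grid scale)
        n_el = array.n_elements
        n_pix = pix.shape[0]
        self._i0 = np.empty((n_el, n_pix), dtype=np.int32)
        self._frac = np.empty((n_el, n_pix), dtype=np.float32)
        self._weight = np.empty((n_el, n_pix), dtype=np.float32)
        max_s = 0.0
        for e in range(n_el):
            dist = np.hypot(pos[e, 0] - pix[:, 0], pos[e, 1] - pix[:, 1])
            s = dist * array.fs / speed_of_sound
            max_s = max(max_s, float(s.max()))
            i0 = np.floor(s)
            self._i0[e] = i0.astype(np.int32)
            self._frac[e] = (s - i0).astype(np.float32)
            self._weight[e] = (grid.pixel_size**2
                               / (2.0 * np.pi * dist)).astype(np.float32)
        need = int(np.ceil(max_s)) + 3
        if n_samples is None:
            n_samples = need
        elif n_samples < need:
            raise ValueError(
                f"trace length {n_samples} cannot record sources at the "
                f"grid edge (need >= {need} samples)")
        self.n_samples = int(n_samples)

    def _derivative(self, m: np.ndarray) -> np.ndarray:
        d = np.zeros_like(m)
        d[..., 1:-1] = (m[..., 2:] - m[..., :-2]) * (self.array.fs / 2.0)
        return d

    def forward(self, amplitude_image: np.ndarray) -> np.ndarray:
        """Project a source amplitude image to (n_elements, n_samples)."""
        amp = np.asarray(amplitude_image, dtype=float).ravel()
        if amp.size != self.grid.n_pixels**2:
            raise ValueError("image does not match the projector grid")
        n_el = self.array.n_elements
        shells = np.zeros((n_el, self.n_samples))
        for e in range(n_el):
            v = amp * self._weight[e]
            shells[e] = (np.bincount(self._i0[e], v * (1.0 - self._frac[e]),
                                     minlength=self.n_samples)
                         + np.bincount(self._i0[e] + 1, v * self._frac[e],
                                       minlength=self.n_samples))
        return self._derivative(shells)

    def adjoint(self, traces: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`forward`."""
        traces = np.asarray(traces, dtype=float)
        if traces.shape != (self.array.n_elements, self.n_samples):
            raise ValueError("traces do not match the projector shape")
        # transpose of the central difference: -D with endpoint rows removed
        z = traces.copy()
        z[..., 0] = 0.0
        z[..., -1] = 0.0
        b = -self._derivative(z)
        img = np.zeros(self.grid.n_pixels**2)
        for e in range(self.array.n_elements):
            i0 = self._i0[e]
            frac = self._frac[e]
            img += self._weight[e] * ((1.0 - frac) * b[e, i0]
                                      + frac * b[e, i0 + 1])
        return img.reshape(self.grid.n_pixels, self.grid.n_pixels)


def impulse_forward(amplitude_image, array: DetectorArray, grid: ImageGrid,
                    speed_of_sound: float, n_samples: int | None = None,
                    projector: RingProjector | None = None) -> np.ndarray:
    """Per-channel delta-heating (impulse) traces of a source image."""
    if projector is None:
        projector = RingProjector(array, grid, speed_of_sound, n_samples)
    return projector.forward(amplitude_image)


def chirp_forward(amplitude_image, array: DetectorArray, grid: ImageGrid,
                  spec: ChirpSpec, beta: float, cp: float,
                  speed_of_sound: float,
                  projector: RingProjector | None = None) -> np.ndarray:
    """Chirp-coded channel traces of a heating map.

    Convolves the impulse traces with the thermoacoustic source time
    profile ``-pi*(beta/Cp)*fm(t)*x2f(t)``.  Output amplitude is linear in
    the heating map and in beta/Cp.  ``beta`` in 1/C, ``cp`` in J/(kg C)
    (only the ratio matters for the trace scale).
    """
    impulse = impulse_forward(amplitude_image, array, grid, speed_of_sound,
                              projector=projector)
    profile = -np.pi * (beta / cp) * expected_response(spec)
    return fftconvolve(impulse, profile[None, :], mode="full", axes=1)


def add_noise(traces: np.ndarray, snr_db: float, seed) -> np.ndarray:
    """Add white Gaussian channel noise at a requested SNR.

    The SNR (dB) is defined against the mean square of the chirp-coded
    trace block, i.e. ``snr_db = 10*log10(mean(traces**2) / sigma**2)``.
    ``snr_db = inf`` returns the traces unchanged; the noise is fully
    determined by ``seed``.
    """
    traces = np.asarray(traces, dtype=float)
    if np.isinf(snr_db):
        return traces.copy()
    p_signal = float(np.mean(traces**2))
    if p_signal <= 0.0:
        raise ValueError("cannot set an SNR on all-zero traces")
    sigma = np.sqrt(p_signal * 10.0 ** (-snr_db / 10.0))
    rng = np.random.default_rng(seed)
    return traces + rng.normal(0.0, sigma, size=traces.shape)
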