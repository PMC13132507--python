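"""Wiener deconvolution of chirp-coded channel recordings.

Each recorded channel is the convolution of a pulse-like tissue response
with the known ramp-weighted doubled chirp ``r(t)``.  The response is
recovered by regularised inverse filtering,

    chi(t) = IFFT[ conj(R) * X / (|R|**2 + lambda) ],

which compresses the chirp while damping noise amplification.  The
reference spectrum is normalised to unit peak power before the
regulariser is applied, so ``lambda`` (default 0.1) is a scale-free
noise-to-signal parameter regardless of the amplitude units of the
recordings.  The FFT length is the next power of two >= twice the trace
length, making the deconvolution linear rather than circular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DeconvolutionConfig", "wiener_deconvolve"]


@dataclass
class DeconvolutionConfig:
    """Wiener regulariser and expected-response reference.

    ``reference`` is the sampled expected response r(t) (see
    :func:`tamon.waveforms.expected_response`); ``fs`` optionally records
    its sample rate so mismatched trace rates can be rejected.
    """

    reference: np.ndarray
    lambda_reg: float = 0.1
    fs: float | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.lambda_reg <= 0.0:
            raise ValueError("lambda_reg must be positive")
        if self.reference.ndim != 1 or not np.any(self.reference != 0.0):
            raise ValueError("reference must be a nonzero 1-D waveform")


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def wiener_deconvolve(traces, config: DeconvolutionConfig,
                      fs: float | None = None) -> np.ndarray:
    """Recover pulse-like responses from chirp-coded traces.

    Parameters
    ----------
    traces : ndarray
        Trace(s) with time on the last axis (1-D or (n_channels, n)).
    config : DeconvolutionConfig
        Reference waveform and regulariser.
    fs : float, optional
        Sample rate of the traces; rejected if it disagrees with the
        reference's recorded rate.

    Returns
    -------
    ndarray
        Same shape as the input; lag 0 corresponds to the emission time,
        so an input delayed by d samples yields a peak at index d.
    """
    traces = np.asarray(traces, dtype=float)
    if fs is not None and config.fs is not None and \
            not np.isclose(fs, config.fs, rtol=1e-9):
        raise ValueError("trace and reference sampling rates differ")
    n = traces.shape[-1]
    nfft = _next_pow2(2 * max(n, config.reference.size))
    ref_spec = np.fft.rfft(config.reference, nfft)
    power = np.abs(ref_spec) ** 2
    peak = power.max()
    if peak <= 0.0:
        raise ValueError("reference has an empty spectrum")
    ref_spec = ref_spec / np.sqrt(peak)
    power = power / peak
    filt = np.conj(ref_spec) / (power + config.lambda_reg)
    spec = np.fft.rfft(traces, nfft, axis=-1)
    out = np.fft.irfft(spec * filt, nfft, axis=-1)
    return out[..., :n]
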