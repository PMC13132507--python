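"""Chirp-modulated excitation waveforms for thermoacoustic signal generation.

A continuous-wave microwave carrier (metadata only; never synthesized here)
is amplitude-modulated with a linear chirp ``x(t)`` so that tissue heating,
which is proportional to the squared electric field, oscillates at acoustic
frequencies.  Squaring a unit chirp doubles its instantaneous frequency, so
the thermoacoustic source term rides on the frequency-doubled chirp
``x2f(t)`` weighted by the instantaneous modulation frequency
``fm(t) = fr*t + f0``.  This module generates:

* the modulating chirp ``x(t) = sin(2*pi*(fr/2*t**2 + f0*t))`` with Hamming
  edge tapers,
* the heating envelope ``g(t) = 1 - cos(4*pi*(fr/2*t**2 + f0*t))``,
* the doubled chirp ``x2f(t) = sin(2*pi*fr*t**2 + 4*pi*f0*t)``,
* the ramp-weighted deconvolution reference ``r(t) = fm(t)*x2f(t)``,
* the full modulation frame (chirp followed by a single-tone hold segment
  that keeps the delivered average power at the clinical level).

All generators are deterministic functions of a :class:`ChirpSpec` on a
uniform, sample-centred time grid starting at ``t = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "ChirpSpec",
    "ModulationFrame",
    "modulating_chirp",
    "heating_envelope",
    "doubled_chirp",
    "expected_response",
    "build_modulation_frame",
    "instantaneous_frequency",
    "export_waveform",
]


@dataclass(frozen=True)
class ChirpSpec:
    """Linear-chirp modulation parameters.

    Parameters
    ----------
    f0, f1 : float
        Lower and upper modulation frequency in Hz.  Defaults 0.05 MHz and
        1.0 MHz; the thermoacoustic band is twice this (0.1--2.0 MHz).
    tc : float
        Chirp duration in seconds (default 400 us).
    fs : float
        Sample rate in Hz.  Must resolve the frequency-doubled chirp, i.e.
        ``fs >= 4*f1``.
    taper_fraction : float
        Fraction of the chirp length Hamming-tapered at each edge to reduce
        deconvolution sidelobes.  The taper length is not dictated by the
        physics; 0.1 is a reasonable default.
    """

    f0: float = 0.05e6
    f1: float = 1.0e6
    tc: float = 400e-6
    fs: float = 5e6
    taper_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (self.f1 > self.f0 > 0.0):
            raise ValueError("require f1 > f0 > 0")
        if self.tc <= 0.0:
            raise ValueError("chirp duration tc must be positive")
        if self.fs < 2.0 * (2.0 * self.f1):
            raise ValueError(
                "fs must satisfy Nyquist for the frequency-doubled chirp "
                f"(fs >= {4.0 * self.f1:g} Hz)"
            )
        if not 0.0 <= self.taper_fraction < 0.5:
            raise ValueError("taper_fraction must lie in [0, 0.5)")

    @property
    def fr(self) -> float:
        """Linear chirp rate (f1 - f0)/tc in Hz/s."""
        return (self.f1 - self.f0) / self.tc

    def time_grid(self, include_end: bool = True) -> np.ndarray:
        """Uniform time grid over [0, tc] at the spec's sample rate."""
        n = int(round(self.tc * self.fs))
        return np.arange(n + 1 if include_end else n) / self.fs


@dataclass(frozen=True)
class ModulationFrame:
    """One repetition period of the modulating waveform.

    After the chirp, a single-tone hold segment maintains microwave energy
    deposition; its mean modulating power is ``hold_power_ratio`` times the
    (untapered) chirp's.  Defaults: 9.5 ms hold at half power within a 10 ms
    period (100 Hz repetition rate).
    """

    hold_duration: float = 9.5e-3
    hold_power_ratio: float = 0.5
    period: float = 10e-3

    def __post_init__(self) -> None:
        if self.hold_duration < 0.0:
            raise ValueError("hold_duration must be non-negative")
        if not 0.0 <= self.hold_power_ratio:
            raise ValueError("hold_power_ratio must be non-negative")
        if self.period <= 0.0:
            raise ValueError("period must be positive")


def _check_grid(spec: ChirpSpec, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be a 1-D array with >= 2 samples")
    dt = np.diff(t)
    step = 1.0 / spec.fs
    if not np.allclose(dt, step, rtol=1e-6, atol=step * 1e-6):
        raise ValueError("time grid must be uniform at spacing 1/fs")
    tol = 0.5 * step
    if t[0] < -tol or t[-1] > spec.tc + tol:
        raise ValueError("time grid must lie within [0, tc]")
    return t


def _phase(spec: ChirpSpec, t: np.ndarray) -> np.ndarray:
    """Modulating-chirp phase 2*pi*(fr/2*t**2 + f0*t)."""
    return 2.0 * np.pi * (0.5 * spec.fr * t**2 + spec.f0 * t)


def _edge_taper(n: int, fraction: float) -> np.ndarray:
    """Unit window with half-Hamming ramps over ``fraction`` of each edge."""
    w = np.ones(n)
    n_tap = int(round(fraction * n))
    if n_tap > 0:
        ham = np.hamming(2 * n_tap + 1)
        w[:n_tap] = ham[:n_tap]
        w[n - n_tap:] = ham[n_tap + 1:]
    return w


def modulating_chirp(spec: ChirpSpec, t: np.ndarray | None = None,
                     taper: bool = True) -> np.ndarray:
    """Sampled modulating chirp x(t) with Hamming edge tapers.

    ``x(t) = sin(2*pi*(fr/2*t**2 + f0*t))`` for 0 <= t <= tc; the
    instantaneous frequency sweeps linearly from f0 to f1.
    """
    if t is None:
        t = spec.time_grid()
    t = _check_grid(spec, t)
    x = np.sin(_phase(spec, t))
    if taper and spec.taper_fraction > 0.0:
        x = x * _edge_taper(t.size, spec.taper_fraction)
    return x


def heating_envelope(spec: ChirpSpec, t: np.ndarray | None = None) -> np.ndarray:
    """Sampled heating envelope g(t) = 1 - cos(4*pi*(fr/2*t**2 + f0*t)).

    The heating rate is proportional to the squared electric field, so the
    envelope equals ``2*x(t)**2`` (untapered) and oscillates at twice the
    modulation frequency.  Carrier-scale (GHz) terms are outside the
    acoustic detection band and are omitted by contract.
    """
    if t is None:
        t = spec.time_grid()
    t = _check_grid(spec, t)
    return 1.0 - np.cos(2.0 * _phase(spec, t))


def doubled_chirp(spec: ChirpSpec, t: np.ndarray | None = None) -> np.ndarray:
    """Frequency-doubled chirp x2f(t) = sin(2*pi*fr*t**2 + 4*pi*f0*t).

    Instantaneous frequency is ``2*fr*t + 2*f0``, spanning 2*f0 to 2*f1
    (0.1--2.0 MHz with the default spec).
    """
    if t is None:
        t = spec.time_grid()
    t = _check_grid(spec, t)
    return np.sin(2.0 * np.pi * spec.fr * t**2 + 4.0 * np.pi * spec.f0 * t)


def expected_response(spec: ChirpSpec, t: np.ndarray | None = None) -> np.ndarray:
    """Ramp-weighted doubled chirp r(t) = (fr*t + f0) * x2f(t).

    This is the expected pulse-compression reference for Wiener
    deconvolution of recorded thermoacoustic channel data: the source term
    carries the instantaneous modulation frequency ``fm(t) = fr*t + f0`` as
    an amplitude ramp on the doubled chirp.
    """
    if t is None:
        t = spec.time_grid()
    t = _check_grid(spec, t)
    return (spec.fr * t + spec.f0) * doubled_chirp(spec, t)


def build_modulation_frame(spec: ChirpSpec,
                           frame: ModulationFrame | None = None) -> np.ndarray:
    """Sampled full-period modulating waveform: tapered chirp + hold tone.

    The hold segment is a single tone at ``f1`` continuing the chirp's end
    phase, scaled so its mean squared value is ``hold_power_ratio`` times
    that of the untapered chirp.  The remainder of the period (if any) is
    zero-padded.  Returns ``round(period*fs)`` samples.
    """
    if frame is None:
        frame = ModulationFrame()
    if frame.period + 0.5 / spec.fs < spec.tc + frame.hold_duration:
        raise ValueError("period shorter than chirp + hold segments")
    n_period = int(round(frame.period * spec.fs))
    n_chirp = int(round(spec.tc * spec.fs))
    n_hold = int(round(frame.hold_duration * spec.fs))
    t_chirp = np.arange(n_chirp) / spec.fs
    out = np.zeros(n_period)
    out[:n_chirp] = modulating_chirp(spec, t_chirp)
    if n_hold > 0:
        mean_sq = np.mean(np.sin(_phase(spec, t_chirp)) ** 2)
        amp = np.sqrt(2.0 * frame.hold_power_ratio * mean_sq)
        phase_end = _phase(spec, np.array([spec.tc]))[0]
        t_rel = (np.arange(n_hold) + (n_chirp - spec.tc * spec.fs)) / spec.fs
        out[n_chirp:n_chirp + n_hold] = amp * np.sin(
            phase_end + 2.0 * np.pi * spec.f1 * t_rel)
    return out


def instantaneous_frequency(x: np.ndarray, fs: float, t_eval: float,
                            edge_guard: int = 64,
                            fit_halfwidth: int | None = None) -> float:
    """Instantaneous frequency of a sampled waveform at time ``t_eval``.

    Numerically differentiates the unwrapped analytic-signal phase.  A local
    quadratic is fitted to the phase over a window near ``t_eval`` (staying
    ``edge_guard`` samples away from the record edges, where the Hilbert
    transform is unreliable) and differentiated analytically; for linear
    chirps the quadratic model is exact, so evaluation at the very edge of
    the record is an exact extrapolation.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 * edge_guard:
        raise ValueError("record too short for the requested edge guard")
    phase = np.unwrap(np.angle(hilbert(x)))
    if fit_halfwidth is None:
        fit_halfwidth = max(4 * edge_guard, n // 8)
    i_eval = t_eval * fs
    lo = int(max(edge_guard, min(i_eval - fit_halfwidth, n - 1 - edge_guard - 8)))
    hi = int(min(n - 1 - edge_guard, max(i_eval + fit_halfwidth, lo + 8)))
    idx = np.arange(lo, hi + 1)
    tau = idx / fs - t_eval
    coeffs = np.polyfit(tau, phase[idx], deg=2)
    return coeffs[1] / (2.0 * np.pi)


def export_waveform(path, x: np.ndarray, spec: ChirpSpec) -> None:
    """Write a waveform as single-column text with a small header.

    The header records fs, tc, f0 and f1 so the file can be cross-checked
    against (or loaded into) laboratory AWG programs.
    """
    header = (f"fs={spec.fs:.9g} Hz\ntc={spec.tc:.9g} s\n"
              f"f0={spec.f0:.9g} Hz\nf1={spec.f1:.9g} Hz")
    np.savetxt(path, np.asarray(x), header=header)
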