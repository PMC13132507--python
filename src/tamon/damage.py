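"""Arrhenius thermal damage accumulation and ablation-zone extraction.

Thermal cell death is modelled as a first-order rate process: the damage
integral

    Omega(r, tau) = A * integral_0^tau exp(-Ea / (R * T_K(r, tau'))) dtau'

accumulates over the absolute-temperature history.  ``Omega > 1``
corresponds to a surviving cell fraction of exp(-1), i.e. roughly 63 % of
cells killed, and defines the ablation zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .thermal import TemperatureSeries

__all__ = [
    "DamageModelConfig",
    "DamageMap",
    "DamageSeries",
    "arrhenius_integrate",
    "ablation_mask",
    "survival_fraction_pct",
    "time_to_threshold",
    "export_contour",
]

GAS_CONSTANT = 8.314  # J / (mol K)


@dataclass(frozen=True)
class DamageModelConfig:
    """Arrhenius kinetics parameters (typical liver values).

    ``frequency_factor`` A in 1/s, ``activation_energy`` Ea in J/mol,
    ``gas_constant`` R in J/(mol K), and the Omega ``threshold`` defining
    ablation.
    """

    frequency_factor: float = 7.39e39
    activation_energy: float = 2.577e5
    gas_constant: float = GAS_CONSTANT
    threshold: float = 1.0

    def rate(self, kelvin):
        """Instantaneous damage rate A*exp(-Ea/(R*T_K)) in 1/s."""
        kelvin = np.asarray(kelvin, dtype=float)
        if np.any(kelvin <= 0.0):
            raise ValueError("absolute temperature must be positive")
        return self.frequency_factor * np.exp(
            -self.activation_energy / (self.gas_constant * kelvin))


@dataclass(frozen=True)
class DamageMap:
    """Damage integral map at one slow-time instant."""

    omega: np.ndarray
    tau: float
    threshold: float = 1.0

    @property
    def ablated(self) -> np.ndarray:
        return self.omega > self.threshold


@dataclass(frozen=True)
class DamageSeries:
    """Cumulative damage maps along slow time."""

    times: np.ndarray           # (n_t,)
    omega: np.ndarray           # (n_t, ...)
    config: DamageModelConfig = field(default_factory=DamageModelConfig)

    def map_at(self, i: int) -> DamageMap:
        return DamageMap(self.omega[i], float(self.times[i]),
                         self.config.threshold)

    @property
    def final(self) -> DamageMap:
        return self.map_at(len(self.times) - 1)


def arrhenius_integrate(temperature_series, config: DamageModelConfig | None = None,
                        dt: float | None = None) -> DamageSeries:
    """Accumulate the damage integral over a temperature history.

    Parameters
    ----------
    temperature_series : TemperatureSeries or ndarray
        Either a :class:`~tamon.thermal.TemperatureSeries` (degrees C, its
        Kelvin accessor is used) or a raw Kelvin stack ``(n_t, ...)``; for
        a raw stack ``dt`` gives the uniform sample spacing in seconds.
    config : DamageModelConfig, optional
        Kinetics parameters; defaults to typical liver values.

    Returns
    -------
    DamageSeries
        Trapezoidal cumulative integral, Omega(tau=0) = 0.
    """
    if config is None:
        config = DamageModelConfig()
    if isinstance(temperature_series, TemperatureSeries):
        kelvin = temperature_series.kelvin
        times = np.asarray(temperature_series.times, dtype=float)
    else:
        kelvin = np.asarray(temperature_series, dtype=float)
        if dt is None:
            raise ValueError("dt is required for a raw Kelvin stack")
        times = np.arange(kelvin.shape[0]) * dt
    rate = config.rate(kelvin)
    omega = cumulative_trapezoid(rate, times, axis=0, initial=0.0)
    return DamageSeries(times=times, omega=omega, config=config)


def ablation_mask(damage, threshold: float | None = None) -> np.ndarray:
    """Boolean ablation mask Omega > threshold.

    Accepts a :class:`DamageMap`, a :class:`DamageSeries` (final map), or a
    raw Omega array.  The resulting mask is also what flips the
    ablated-tissue branch of the thermal-expansion model consumed by the
    calibration.
    """
    if isinstance(damage, DamageSeries):
        omega = damage.final.omega
        default_thr = damage.config.threshold
    elif isinstance(damage, DamageMap):
        omega = damage.omega
        default_thr = damage.threshold
    else:
        omega = np.asarray(damage, dtype=float)
        default_thr = 1.0
    thr = default_thr if threshold is None else threshold
    return omega > thr


def survival_fraction_pct(omega) -> np.ndarray | float:
    """Percentage of cells killed at damage level Omega: 100*(1 - e^-Omega)."""
    return 100.0 * (1.0 - np.exp(-np.asarray(omega, dtype=float)))


def time_to_threshold(kelvin: float, config: DamageModelConfig | None = None) -> float:
    """Exposure time at constant absolute temperature to reach Omega = threshold."""
    if config is None:
        config = DamageModelConfig()
    return config.threshold / float(config.rate(kelvin))


def export_contour(path, mask: np.ndarray, pixel_size: float,
                   origin: tuple[float, float] = (0.0, 0.0)) -> None:
    """Write the ablation-zone outline as plain-text (x, y) coordinates in m.

    Uses marching squares at level 0.5 on the binary mask; each contour is
    separated by a blank line, suitable for overlay plotting.
    """
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    ny, nx = mask.shape
    with open(path, "w") as fh:
        fh.write("# x_m y_m\n")
        for contour in contours:
            for row, col in contour:
                x = (col - (nx - 1) / 2.0) * pixel_size + origin[0]
                y = (row - (ny - 1) / 2.0) * pixel_size + origin[1]
                fh.write(f"{x:.6g} {y:.6g}\n")
            fh.write("\n")
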