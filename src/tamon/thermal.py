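"""Nonlinear heat diffusion with temperature-dependent tissue properties.

The slow-time temperature field ``T(r, tau)`` evolves as

    dT/dtau = div( alpha(T) grad T ) + Q0(r, tau) / (rho*Cp(T)),

where ``alpha`` is the thermal diffusivity and ``rho*Cp`` the volumetric
heat capacity, both strongly temperature dependent in liver tissue.  The
heating function ``Q0`` (W/m^3) is piecewise constant over each slow-time
frame.  The solver is an explicit finite-difference scheme with
face-averaged diffusivity, supporting insulated (Neumann) or fixed-ambient
(Dirichlet) boundaries, an optional cool-down period after the last frame,
and arbitrary dimensionality (the monitoring pipeline runs 2-D slices; 3-D
is supported for axial-weighting studies).

Property correlations (T in degrees Celsius):

    rho*Cp(T) ~ 3.542 + 1.79e-4 * exp(0.233*T)   [MJ m^-3 C^-1]
    alpha(T)  ~ 1.55e-7 + 4.95e-16 * exp(0.201*T) [m^2/s]
    beta(T)   ~ 3.5e-4 + 3e-6 * (T - 37)          [1/C], ablated: 3e-4

The exponentials blow up with temperature, so property evaluation is
clamped at ``t_clamp`` (default 100 C); phase change is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThermalProperties",
    "ConstantThermalProperties",
    "TemperatureField",
    "TemperatureSeries",
    "z_weighting",
    "solve_heat",
    "export_probe_series",
]

CELSIUS_TO_KELVIN = 273.15


@dataclass(frozen=True)
class ThermalProperties:
    """Temperature-dependent liver tissue properties.

    ``rho_cp`` returns MJ m^-3 C^-1 (the solver converts to SI), ``alpha``
    m^2/s and ``beta`` 1/C.  ``beta`` switches to the constant
    ``beta_ablated`` wherever an ``ablated`` mask is set, reflecting the
    loss of the temperature dependence once protein coagulation has
    destroyed the tissue microstructure.  Mass density is assumed constant;
    only the volumetric product rho*Cp is ever used.
    """

    beta_ablated: float = 3e-4
    t_clamp: float = 100.0

    def _clamped(self, temperature):
        return np.minimum(np.asarray(temperature, dtype=float), self.t_clamp)

    def rho_cp(self, temperature):
        """Volumetric heat capacity in MJ m^-3 C^-1."""
        t = self._clamped(temperature)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite temperature input")
        return 3.542 + 1.79e-4 * np.exp(0.233 * t)

    def alpha(self, temperature):
        """Thermal diffusivity in m^2/s."""
        t = self._clamped(temperature)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite temperature input")
        return 1.55e-7 + 4.95e-16 * np.exp(0.201 * t)

    def beta(self, temperature, ablated=None):
        """Coefficient of thermal expansion in 1/C.

        Linear in temperature (anchored at 37 C, similar to water);
        replaced by ``beta_ablated`` where ``ablated`` is True.
        """
        t = self._clamped(temperature)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite temperature input")
        b = 3.5e-4 + 3e-6 * (t - 37.0)
        if ablated is not None:
            b = np.where(ablated, self.beta_ablated, b)
        return b


@dataclass(frozen=True)
class ConstantThermalProperties:
    """Constant-property variant used for analytic solver checks."""

    alpha_value: float = 1.55e-7
    rho_cp_value: float = 3.542  # MJ m^-3 C^-1
    beta_ablated: float = 3e-4
    t_clamp: float = np.inf

    def rho_cp(self, temperature):
        return np.full_like(np.asarray(temperature, dtype=float),
                            self.rho_cp_value)

    def alpha(self, temperature):
        return np.full_like(np.asarray(temperature, dtype=float),
                            self.alpha_value)

    def beta(self, temperature, ablated=None):
        t = np.asarray(temperature, dtype=float)
        b = 3.5e-4 + 3e-6 * (t - 37.0)
        if ablated is not None:
            b = np.where(ablated, self.beta_ablated, b)
        return b


@dataclass(frozen=True)
class TemperatureField:
    """Temperature map (degrees C) at one slow-time instant."""

    temperature: np.ndarray
    tau: float

    @property
    def kelvin(self) -> np.ndarray:
        return self.temperature + CELSIUS_TO_KELVIN


@dataclass(frozen=True)
class TemperatureSeries:
    """Stack of temperature maps sampled along slow time."""

    times: np.ndarray          # (n_t,) seconds
    maps: np.ndarray           # (n_t, ...) degrees C

    @property
    def kelvin(self) -> np.ndarray:
        return self.maps + CELSIUS_TO_KELVIN

    def field(self, i: int) -> TemperatureField:
        return TemperatureField(self.maps[i], float(self.times[i]))

    def at(self, tau: float) -> TemperatureField:
        i = int(np.argmin(np.abs(self.times - tau)))
        return self.field(i)


def z_weighting(z, rprobe: float = 0.01, normalized: bool = True):
    """Axial weighting of the probe's radiating segment.

    ``w(z) = sqrt(rprobe**2 - z**2)`` for |z| < rprobe (the circular
    cross-section of a radiating segment of half-length ``rprobe``), zero
    outside.  With ``normalized=True`` the weight integrates to one over z,
    so a 2-D slice heating map scaled by ``w`` becomes a 3-D volumetric
    density without changing the total deposited power.
    """
    if rprobe <= 0.0:
        raise ValueError("rprobe must be positive")
    z = np.asarray(z, dtype=float)
    inside = np.abs(z) < rprobe
    w = np.where(inside, np.sqrt(np.maximum(rprobe**2 - z**2, 0.0)), 0.0)
    if normalized:
        w = w / (0.5 * np.pi * rprobe**2)
    if w.ndim == 0:
        return float(w)
    return w


def _divergence_term(t_map: np.ndarray, a_map: np.ndarray, dx: float,
                     bc: str, t_ambient: float) -> np.ndarray:
    """div(alpha grad T) with face-averaged diffusivity."""
    div = np.zeros_like(t_map)
    for axis in range(t_map.ndim):
        if bc == "insulated":
            tp = np.concatenate(
                [np.take(t_map, [0], axis=axis), t_map,
                 np.take(t_map, [-1], axis=axis)], axis=axis)
        else:  # dirichlet at ambient
            pad_shape = list(t_map.shape)
            pad_shape[axis] = 1
            amb = np.full(pad_shape, t_ambient)
            tp = np.concatenate([amb, t_map, amb], axis=axis)
        ap = np.concatenate(
            [np.take(a_map, [0], axis=axis), a_map,
             np.take(a_map, [-1], axis=axis)], axis=axis)

        def sl(lo, hi):
            s = [slice(None)] * t_map.ndim
            s[axis] = slice(lo, hi)
            return tuple(s)

        centre = tp[sl(1, -1)]
        upper = tp[sl(2, None)]
        lower = tp[sl(0, -2)]
        a_centre = ap[sl(1, -1)]
        face_hi = 0.5 * (a_centre + ap[sl(2, None)])
        face_lo = 0.5 * (a_centre + ap[sl(0, -2)])
        div += (face_hi * (upper - centre) - face_lo * (centre - lower)) / dx**2
    return div


def solve_heat(q_series, props, t_init, dx: float, dt: float,
               frame_duration: float = 1.0, cooldown: float = 0.0,
               sample_dt: float = 1.0, bc: str = "dirichlet",
               t_ambient: float | None = None, sample_slice=None,
               return_final: bool = False):
    """Integrate the bioheat equation driven by per-frame heating maps.

    Parameters
    ----------
    q_series : ndarray
        Stack ``(n_frames, *field_shape)`` of heating maps in W/m^3, each
        applied for ``frame_duration`` seconds.  For a constant exposure
        pass ``q[None]`` with ``frame_duration`` set to the exposure time.
    props : ThermalProperties-like
        Object providing ``alpha(T)``, ``rho_cp(T)`` (MJ m^-3 C^-1) and a
        ``t_clamp`` attribute for property evaluation.
    t_init : float or ndarray
        Initial temperature in degrees C (uniform scalar or full map).
    dx, dt : float
        Grid spacing (m) and time step (s).  ``dt`` must satisfy the
        explicit stability bound ``max(alpha)*dt/dx**2 <= 1/(2*ndim)``.
    cooldown : float
        Extra integration time with zero source after the last frame.
    sample_dt : float
        Interval at which temperature maps are recorded (must be a
        multiple of ``dt``).
    bc : {"dirichlet", "insulated"}
        Outer boundary condition; "dirichlet" holds the boundary at
        ``t_ambient`` (default: the initial temperature), reflecting a
        water-immersed sample.

    sample_slice : tuple of slices/ints, optional
        Record only this view of the field at each sample time (e.g. the
        mid-plane of a 3-D volume) -- keeps long 3-D runs in memory.
    return_final : bool
        Also return the final full-resolution field.

    Returns
    -------
    TemperatureSeries or (TemperatureSeries, ndarray)
        Maps (or sampled views) recorded at t = 0, sample_dt, ...
        including the cool-down period; with ``return_final`` also the
        final full field.
    """
    frames = np.asarray(q_series, dtype=float)
    if frames.ndim < 2:
        raise ValueError(
            "q_series must be a stack of heating maps (n_frames, *shape)")
    if bc not in ("dirichlet", "insulated"):
        raise ValueError(f"unknown boundary condition {bc!r}")

    field_shape = frames.shape[1:]
    t_map = np.asarray(t_init, dtype=float)
    if t_map.ndim == 0:
        t_map = np.full(field_shape, float(t_map))
    if t_map.shape != field_shape:
        raise ValueError("t_init shape does not match heating maps")
    ndim = t_map.ndim

    clamp = getattr(props, "t_clamp", np.inf)
    probe_t = min(clamp, 150.0) if np.isfinite(clamp) else 150.0
    alpha_max = float(np.max(props.alpha(np.array([probe_t]))))
    if alpha_max * dt / dx**2 > 1.0 / (2.0 * ndim) + 1e-12:
        raise ValueError(
            "explicit stability bound violated: max(alpha)*dt/dx**2 = "
            f"{alpha_max * dt / dx**2:.3g} > 1/(2*ndim)")

    if t_ambient is None:
        t_ambient = float(np.mean(t_map))

    steps_per_frame = max(1, int(round(frame_duration / dt)))
    sample_every = max(1, int(round(sample_dt / dt)))
    n_frames = frames.shape[0]
    cool_steps = int(round(cooldown / dt))

    t_map = t_map.copy()

    def grab(field):
        return field.copy() if sample_slice is None \
            else field[sample_slice].copy()

    samples = [grab(t_map)]
    sample_times = [0.0]
    zero_q = np.zeros(field_shape)
    step = 0
    for global_frame in range(n_frames + (1 if cool_steps else 0)):
        if global_frame < n_frames:
            q = frames[global_frame]
            n_steps = steps_per_frame
        else:
            q = zero_q
            n_steps = cool_steps
        for _ in range(n_steps):
            t_eval = np.minimum(t_map, clamp)
            a_map = props.alpha(t_eval)
            rho_cp = props.rho_cp(t_eval) * 1e6  # MJ -> J
            div = _divergence_term(t_map, a_map, dx, bc, t_ambient)
            t_map = t_map + dt * (div + q / rho_cp)
            if bc == "dirichlet":
                for axis in range(ndim):
                    idx = [slice(None)] * ndim
                    idx[axis] = 0
                    t_map[tuple(idx)] = t_ambient
                    idx[axis] = -1
                    t_map[tuple(idx)] = t_ambient
            step += 1
            if step % sample_every == 0:
                if not np.all(np.isfinite(t_map)):
                    raise FloatingPointError(
                        f"temperature field became non-finite at step {step} "
                        f"(t = {step * dt:.3f} s)")
                samples.append(grab(t_map))
                sample_times.append(step * dt)
    if not np.all(np.isfinite(t_map)):
        raise FloatingPointError("temperature field became non-finite")
    series = TemperatureSeries(times=np.asarray(sample_times),
                               maps=np.asarray(samples))
    if return_final:
        return series, t_map
    return series


def export_probe_series(path, series: TemperatureSeries, index) -> None:
    """Write a single-point temperature time series as CSV.

    Emulates the fibre-optic thermometer log: one row per sample with slow
    time (s) and temperature (C) at the given grid index.
    """
    vals = series.maps[(slice(None),) + tuple(index)]
    with open(path, "w") as fh:
        fh.write("tau_s,temperature_C\n")
        for t, v in zip(series.times, vals):
            fh.write(f"{t:.6g},{v:.6g}\n")
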