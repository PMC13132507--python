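"""Absolute calibration of thermoacoustic images to a heating function.

Thermoacoustic images are proportional to the heating function only up to
an unknown system scale (detector sensitivity, acoustic attenuation,
amplifier gains).  During the first seconds of an ablation the tissue
heats rapidly but is not yet ablated, so the image amplitude near the
probe tip rises in proportion to the temperature-dependent thermal
expansion coefficient beta(T).  Matching that observed rise against the
rise predicted by the bioheat model driven by a candidate scaling K gives
an absolute calibration:

    K_hat = argmin_K  sum_{tau=0..5 s}  ( I_n(tau) - beta_n(tau; K) )**2,

where both the tip-averaged image amplitude I_n and the tip-averaged
modelled beta are normalised to their tau = 0 values and tau is sampled
in one-second increments.  The heating function over the fit window is
held at its tau = 0 estimate ``K * w(z) * I_TA``; because rising beta
would otherwise inflate the inferred power, later frames are divided by
``beta(T)/beta(T0)`` when converted to heating maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .reconstruction import ImageGrid, TAImageSeries
from .thermal import ThermalProperties, solve_heat, z_weighting

__all__ = [
    "TipRegion",
    "CalibrationResult",
    "tip_average",
    "ta_to_heating",
    "estimate_K",
    "true_scale",
]


@dataclass(frozen=True)
class TipRegion:
    """Disk around the probe tip used for amplitude averaging (5 mm)."""

    center: tuple[float, float]
    diameter: float = 5e-3

    def __post_init__(self) -> None:
        if self.diameter <= 0.0:
            raise ValueError("diameter must be positive")


@dataclass
class CalibrationResult:
    """Estimated image-to-heating scaling and fit diagnostics.

    ``k_hat`` converts image units to W/m^3 (together with the axial
    weight); ``residual`` is the final sum-of-squares objective;
    ``degenerate`` flags series with no usable amplitude rise, for which
    ``k_hat`` collapses to the search bound and must not be trusted.
    """

    k_hat: float
    tip_region: TipRegion
    fit_times: np.ndarray
    residual: float
    ta_norm: np.ndarray = field(default_factory=lambda: np.array([]))
    beta_norm: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate: bool = False

    def to_text(self) -> str:
        lines = [
            f"k_hat: {self.k_hat:.8g}",
            f"tip_center_x: {self.tip_region.center[0]:.8g}",
            f"tip_center_y: {self.tip_region.center[1]:.8g}",
            f"tip_diameter: {self.tip_region.diameter:.8g}",
            f"fit_window_s: {self.fit_times[-1]:.8g}",
            f"residual: {self.residual:.8g}",
            f"degenerate: {self.degenerate}",
        ]
        return "\n".join(lines) + "\n"


def tip_average(image: np.ndarray, grid: ImageGrid,
                region: TipRegion) -> float:
    """Mean image value over the tip disk."""
    if not grid.contains(region.center):
        raise ValueError("tip region lies outside the grid")
    mask = grid.disk_mask(region.center, region.diameter)
    if not mask.any():
        raise ValueError("tip region contains no pixels")
    return float(np.mean(np.asarray(image)[mask]))


def ta_to_heating(image: np.ndarray, grid: ImageGrid,
                  temperature: np.ndarray | float,
                  props: ThermalProperties, k: float, t0: float,
                  z: float = 0.0, rprobe: float = 0.01,
                  ablated: np.ndarray | None = None):
    """Convert a thermoacoustic image to a heating map (W/m^3).

    ``Q0 = K * w(z) * I_TA / (beta(T)/beta(T0))``: the beta ratio divides
    the image so that the amplitude growth caused by rising beta does not
    inflate the inferred deposited power.  Where ``ablated`` is set the
    constant ablated-tissue beta replaces the linear model.
    """
    from .phantom import HeatingMap

    if k <= 0.0:
        raise ValueError("K must be positive")
    beta0 = float(props.beta(np.asarray(t0, dtype=float)))
    if beta0 == 0.0:
        raise ValueError("beta(T0) vanishes; cannot normalize")
    ratio = props.beta(temperature, ablated=ablated) / beta0
    w = z_weighting(z, rprobe)
    q0 = k * w * np.asarray(image, dtype=float) / ratio
    return HeatingMap(Q0=np.maximum(q0, 0.0), grid=grid)


def _modeled_beta_norm(k: float, base_field: np.ndarray, grid: ImageGrid,
                       props: ThermalProperties, t0: float,
                       tip_mask: np.ndarray, n_seconds: int,
                       dt: float, bc: str) -> np.ndarray:
    """Normalised tip-averaged (mid-plane) beta rise for trial scaling k.

    ``base_field`` is the axially weighted tau = 0 image: 2-D for a
    slice model, or a w(z)-inflated 3-D stack whose mid-plane is tracked.
    """
    q0 = k * base_field
    sample_slice = None if base_field.ndim == 2 \
        else (base_field.shape[0] // 2,)
    temps = solve_heat(q0[None], props, t0, dx=grid.pixel_size, dt=dt,
                       frame_duration=float(n_seconds), sample_dt=1.0,
                       bc=bc, sample_slice=sample_slice)
    beta_avg = np.array([
        np.mean(props.beta(temps.maps[i])[tip_mask])
        for i in range(len(temps.times))
    ])
    return beta_avg / beta_avg[0]


def estimate_K(ta_series: TAImageSeries, props: ThermalProperties,
               t0: float, tip_region: TipRegion | None = None,
               rprobe: float = 0.01, n_seconds: int = 5,
               thermal_dt: float = 0.05, bc: str = "dirichlet",
               search_decades: float = 3.0, dimension: int = 2,
               nz: int = 49) -> CalibrationResult:
    """Estimate the image-to-heating scaling from the early amplitude rise.

    Requires frames at tau = 0..n_seconds (1-s spacing).  For each trial
    K the bioheat model is driven by the tau = 0 heating estimate held
    constant, and the modelled normalised beta rise at the tip is compared
    with the normalised image rise; the squared difference is minimised by
    a bounded scalar search over log10 K spanning ``2*search_decades``
    decades around a slope-matched initial guess.

    With ``dimension=3`` each trial solves the bioheat equation on an
    ``nz``-plane stack with the image inflated along z by the normalized
    axial weight w(z), and the tip average is taken on the mid-plane.
    """
    grid = ta_series.grid
    if tip_region is None:
        if ta_series.probe_center is None:
            raise ValueError("no tip region and no probe center recorded")
        tip_region = TipRegion(center=ta_series.probe_center)
    taus = ta_series.taus
    wanted = np.arange(n_seconds + 1, dtype=float)
    idx = []
    for w_t in wanted:
        j = int(np.argmin(np.abs(taus - w_t)))
        if abs(taus[j] - w_t) > 0.25:
            raise ValueError(
                f"fit window requires a frame near tau = {w_t:g} s")
        idx.append(j)
    frames = ta_series.images[idx]

    tip_mask = grid.disk_mask(tip_region.center, tip_region.diameter)
    i_avg = np.array([float(np.mean(f[tip_mask])) for f in frames])
    if i_avg[0] <= 0.0:
        raise ValueError("zero tip amplitude at tau = 0; degenerate series")
    i_norm = i_avg / i_avg[0]

    w0 = z_weighting(0.0, rprobe)
    if dimension == 3:
        if nz % 2 == 0:
            raise ValueError("nz must be odd so the mid-plane is exact")
        z = (np.arange(nz) - nz // 2) * grid.pixel_size
        wz = z_weighting(z, rprobe)
        base_field = wz[:, None, None] * frames[0][None, :, :]
    elif dimension == 2:
        base_field = w0 * frames[0]
    else:
        raise ValueError("dimension must be 2 or 3")

    # slope-matched initial guess: d(beta_n)/dtau ~ beta' * qdot / (rho cp)
    beta0 = float(props.beta(np.asarray(t0, dtype=float)))
    rho_cp0 = float(props.rho_cp(np.asarray(t0, dtype=float))) * 1e6
    slope = (i_norm[-1] - i_norm[0]) / float(n_seconds)
    beta_slope = 3e-6  # d(beta)/dT of the linear tissue model
    base_mid = base_field if base_field.ndim == 2 \
        else base_field[base_field.shape[0] // 2]
    tip_base = float(np.mean(base_mid[tip_mask]))
    degenerate = slope <= 0.0 or tip_base <= 0.0
    if degenerate:
        k_guess = 1.0
    else:
        k_guess = slope * beta0 * rho_cp0 / (beta_slope * tip_base)

    def objective(log_k: float) -> float:
        beta_n = _modeled_beta_norm(10.0**log_k, base_field, grid, props,
                                    t0, tip_mask, n_seconds, thermal_dt, bc)
        return float(np.sum((i_norm - beta_n) ** 2))

    lo = np.log10(k_guess) - search_decades
    hi = np.log10(k_guess) + search_decades
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    k_hat = float(10.0**res.x)
    beta_n = _modeled_beta_norm(k_hat, base_field, grid, props, t0,
                                tip_mask, n_seconds, thermal_dt, bc)
    at_bound = res.x - lo < 1e-2 or hi - res.x < 1e-2
    return CalibrationResult(k_hat=k_hat, tip_region=tip_region,
                             fit_times=wanted, residual=float(res.fun),
                             ta_norm=i_norm, beta_norm=beta_n,
                             degenerate=bool(degenerate or at_bound))


def true_scale(q0_true, ta_frame0: np.ndarray, grid: ImageGrid,
               tip_region: TipRegion, rprobe: float = 0.01) -> float:
    """Ground-truth scaling K_true implied by a synthetic experiment.

    Defined as the ratio of the tip-averaged true heating function to the
    tip-averaged (axially weighted) tau = 0 image, i.e. the K for which
    ``K * w(0) * I_TA`` reproduces the true tip heating.  Used to score
    parameter recovery of :func:`estimate_K` on synthetic data.
    """
    q0_map = q0_true.Q0 if hasattr(q0_true, "Q0") else np.asarray(q0_true)
    tip_q = tip_average(q0_map, grid, tip_region)
    tip_i = tip_average(np.asarray(ta_frame0), grid, tip_region)
    if tip_i <= 0.0:
        raise ValueError("zero tip image amplitude")
    return tip_q / (z_weighting(0.0, rprobe) * tip_i)
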