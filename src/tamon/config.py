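"""Run configuration: every pipeline default in one round-trippable record.

Defaults reproduce the reference acquisition and model settings: a
0.05--1.0 MHz, 400 us chirp at 5 MSPS; a 512-element, 60 cm ring array;
a 128 mm / 0.25 mm reconstruction grid with a 5 cm probe mask; liver
thermal properties with 0.25 mm / 10 ms solver resolution and a 60 s
cool-down; Arrhenius kinetics A = 7.39e39 1/s, Ea = 2.577e5 J/mol; a
five-second, one-hertz calibration window with a 5 mm tip region; and a
100 W phantom.  Desk-scale runs override the grid and array sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """A configuration file is malformed or inconsistent."""


@dataclass
class ChirpConfig:
    f0: float = 0.05e6
    f1: float = 1.0e6
    tc: float = 400e-6
    fs: float = 5e6
    taper_fraction: float = 0.1
    hold_duration: float = 9.5e-3
    hold_power_ratio: float = 0.5
    period: float = 10e-3


@dataclass
class ArrayConfig:
    n_elements: int = 512
    ring_diameter: float = 0.6
    center_frequency: float = 1e6
    fs: float = 5e6


@dataclass
class ReconstructionConfig:
    n_pixels: int = 512
    pixel_size: float = 0.25e-3
    speed_of_sound: float = 1540.0
    mask_diameter: float = 0.05
    lambda_reg: float = 0.1


@dataclass
class PhantomConfig:
    total_power: float = 100.0
    sigma_lateral: float = 4e-3
    sigma_axial: float = 8e-3
    probe_x: float = 0.0
    probe_y: float = 0.0
    probe_radius: float = 0.01
    t_init: float = 18.0
    sigma_eff: float = 2.0


@dataclass
class ThermalConfig:
    dx: float = 0.25e-3
    dt: float = 0.01
    cooldown: float = 60.0
    bc: str = "dirichlet"
    t_clamp: float = 100.0
    beta_ablated: float = 3e-4
    dimension: int = 2      # 2: mid-plane slice; 3: w(z)-inflated stack
    nz: int = 49            # z planes for dimension 3 (odd)


@dataclass
class DamageConfig:
    frequency_factor: float = 7.39e39
    activation_energy: float = 2.577e5
    gas_constant: float = 8.314
    threshold: float = 1.0


@dataclass
class CalibrationConfig:
    window_seconds: int = 5
    tip_diameter: float = 5e-3


@dataclass
class RunSection:
    duration: float = 60.0
    frame_rate: float = 1.0
    noise_snr_db: float = float("inf")
    seed: int = 0


@dataclass
class RunConfig:
    chirp: ChirpConfig = field(default_factory=ChirpConfig)
    array: ArrayConfig = field(default_factory=ArrayConfig)
    reconstruction: ReconstructionConfig = field(
        default_factory=ReconstructionConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    damage: DamageConfig = field(default_factory=DamageConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    run: RunSection = field(default_factory=RunSection)

    def validate(self) -> None:
        c = self.chirp
        if not (c.f1 > c.f0 > 0):
            raise ConfigError("chirp: require f1 > f0 > 0")
        if c.fs < 4 * c.f1:
            raise ConfigError("chirp: fs below Nyquist for the doubled chirp")
        if self.array.n_elements < 1:
            raise ConfigError("array: n_elements must be >= 1")
        if self.reconstruction.pixel_size <= 0:
            raise ConfigError("reconstruction: pixel_size must be positive")
        if self.phantom.total_power <= 0:
            raise ConfigError("phantom: total_power must be positive")
        if self.thermal.bc not in ("dirichlet", "insulated"):
            raise ConfigError("thermal: bc must be dirichlet or insulated")
        if self.thermal.dt <= 0 or self.thermal.dx <= 0:
            raise ConfigError("thermal: dx and dt must be positive")
        if self.thermal.dimension not in (2, 3):
            raise ConfigError("thermal: dimension must be 2 or 3")
        if self.thermal.dimension == 3 and (
                self.thermal.nz < 3 or self.thermal.nz % 2 == 0):
            raise ConfigError("thermal: nz must be an odd count >= 3")
        if self.damage.threshold <= 0:
            raise ConfigError("damage: threshold must be positive")
        if self.calibration.window_seconds < 1:
            raise ConfigError("calibration: window must cover >= 1 s")
        if self.run.frame_rate <= 0:
            raise ConfigError("run: frame_rate must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if np.isinf(self.run.noise_snr_db):
            d["run"]["noise_snr_db"] = "inf"
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        sections = {f.name: f.type for f in dataclasses.fields(cls)}
        for section, values in (data or {}).items():
            if section not in sections:
                raise ConfigError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            valid = {f.name for f in dataclasses.fields(target)}
            for key, value in (values or {}).items():
                if key not in valid:
                    raise ConfigError(
                        f"unknown key {key!r} in section {section!r}")
                if key == "noise_snr_db" and value in ("inf", ".inf"):
                    value = float("inf")
                setattr(target, key, type(getattr(target, key))(value)
                        if not isinstance(value, bool) else value)
        cfg.validate()
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path!s}: {exc}") from exc
    return RunConfig.from_dict(data or {})


def save_config(path, config: RunConfig) -> None:
    config.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
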