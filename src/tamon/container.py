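"""HDF5 run container for channel data and derived products.

One file per run with a fixed group layout:

    /frames/<k>/traces        raw channel traces (n_elements, n_samples)
    /frames/<k>/tau           slow-time stamp (s)
    /frames/<k>/deconvolved   pulse-like responses (written by monitoring)
    /array/positions          element coordinates (n_elements, 2)
    /meta/fs, /meta/vs        sampling rate and speed of sound
    /ta_images/<k>            envelope images with grid metadata
    /temperature/<k>          temperature maps with tau stamps
    /damage/<k>               damage-integral maps with tau stamps
    /calibration              scaling-factor record
"""

from __future__ import annotations

import numpy as np

import h5py

from .acoustic_forward import ChannelFrameSeries, DetectorArray
from .calibration import CalibrationResult, TipRegion
from .reconstruction import ImageGrid, TAImageSeries
from .thermal import TemperatureSeries

__all__ = [
    "write_frame",
    "write_acquisition_meta",
    "load_acquisition_meta",
    "iter_frames",
    "save_channel_frames",
    "load_channel_frames",
    "save_deconvolved",
    "load_deconvolved",
    "save_ta_images",
    "load_ta_images",
    "save_temperature",
    "load_temperature",
    "save_damage",
    "load_damage",
    "save_calibration",
    "load_calibration",
]


def write_frame(handle: h5py.File, k: int, tau: float,
                traces: np.ndarray) -> None:
    """Write one frame into an open container (streaming writer)."""
    g = handle.require_group("frames").require_group(str(k))
    for name in ("traces", "tau"):
        if name in g:
            del g[name]
    g.create_dataset("traces", data=np.asarray(traces, dtype=np.float32))
    g.create_dataset("tau", data=float(tau))


def write_acquisition_meta(handle: h5py.File, array: DetectorArray,
                           speed_of_sound: float) -> None:
    arr = handle.require_group("array")
    if "positions" in arr:
        del arr["positions"]
    arr.create_dataset("positions", data=array.element_positions)
    arr.attrs["n_elements"] = array.n_elements
    arr.attrs["ring_diameter"] = array.ring_diameter
    arr.attrs["center_frequency"] = array.center_frequency
    meta = handle.require_group("meta")
    meta.attrs["fs"] = array.fs
    meta.attrs["vs"] = speed_of_sound


def save_channel_frames(path, series: ChannelFrameSeries,
                        mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        for k in range(series.n_frames):
            write_frame(f, k, float(series.taus[k]), series.traces[k])
        write_acquisition_meta(f, series.array, series.speed_of_sound)


def load_acquisition_meta(path) -> tuple[DetectorArray, float, list[str]]:
    """Array geometry, speed of sound and ordered frame keys of a container."""
    with h5py.File(path, "r") as f:
        if "frames" not in f or len(f["frames"]) == 0:
            raise ValueError(f"container {path!s} holds no frames")
        keys = _sorted_frame_keys(f["frames"])
        arr = f["array"]
        array = DetectorArray(
            n_elements=int(arr.attrs["n_elements"]),
            ring_diameter=float(arr.attrs["ring_diameter"]),
            center_frequency=float(arr.attrs["center_frequency"]),
            fs=float(f["meta"].attrs["fs"]),
            element_positions=arr["positions"][()],
        )
        vs = float(f["meta"].attrs["vs"])
    return array, vs, keys


def iter_frames(path):
    """Yield (k, tau, traces) frame by frame without loading the stack.

    The file is opened per frame so callers may interleave writes to the
    same container between frames.
    """
    with h5py.File(path, "r") as f:
        keys = _sorted_frame_keys(f["frames"])
    for k in keys:
        with h5py.File(path, "r") as f:
            g = f["frames"][k]
            yield int(k), float(g["tau"][()]), g["traces"][()].astype(float)


def _sorted_frame_keys(group) -> list[str]:
    return sorted(group.keys(), key=int)


def load_channel_frames(path) -> ChannelFrameSeries:
    array, vs, keys = load_acquisition_meta(path)
    with h5py.File(path, "r") as f:
        taus = np.array([float(f["frames"][k]["tau"][()]) for k in keys])
        traces = np.stack([f["frames"][k]["traces"][()].astype(float)
                           for k in keys])
    return ChannelFrameSeries(taus=taus, traces=traces, array=array,
                              speed_of_sound=vs)


def save_deconvolved(path, frame_index: int, deconvolved: np.ndarray) -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group("frames").require_group(str(frame_index))
        if "deconvolved" in g:
            del g["deconvolved"]
        g.create_dataset("deconvolved", data=np.asarray(deconvolved))


def load_deconvolved(path, frame_index: int) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["frames"][str(frame_index)]["deconvolved"][()]


def _write_grid_attrs(group, grid: ImageGrid) -> None:
    group.attrs["n_pixels"] = grid.n_pixels
    group.attrs["pixel_size"] = grid.pixel_size
    group.attrs["center_x"] = grid.center[0]
    group.attrs["center_y"] = grid.center[1]


def _read_grid_attrs(group) -> ImageGrid:
    return ImageGrid(n_pixels=int(group.attrs["n_pixels"]),
                     pixel_size=float(group.attrs["pixel_size"]),
                     center=(float(group.attrs["center_x"]),
                             float(group.attrs["center_y"])))


def save_ta_images(path, series: TAImageSeries, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "ta_images" in f:
            del f["ta_images"]
        g = f.create_group("ta_images")
        _write_grid_attrs(g, series.grid)
        g.attrs["mask_applied"] = series.mask_applied
        if series.probe_center is not None:
            g.attrs["probe_center"] = list(series.probe_center)
        for k in range(series.images.shape[0]):
            d = g.create_dataset(str(k), data=series.images[k])
            d.attrs["tau"] = float(series.taus[k])


def load_ta_images(path) -> TAImageSeries:
    with h5py.File(path, "r") as f:
        g = f["ta_images"]
        grid = _read_grid_attrs(g)
        keys = _sorted_frame_keys(g)
        taus = np.array([float(g[k].attrs["tau"]) for k in keys])
        images = np.stack([g[k][()] for k in keys])
        probe_center = None
        if "probe_center" in g.attrs:
            pc = g.attrs["probe_center"]
            probe_center = (float(pc[0]), float(pc[1]))
        return TAImageSeries(taus=taus, images=images, grid=grid,
                             mask_applied=bool(g.attrs["mask_applied"]),
                             probe_center=probe_center)


def _save_stack(path, group_name: str, times, maps) -> None:
    with h5py.File(path, "a") as f:
        if group_name in f:
            del f[group_name]
        g = f.create_group(group_name)
        for k in range(len(times)):
            d = g.create_dataset(str(k), data=maps[k])
            d.attrs["tau"] = float(times[k])


def _load_stack(path, group_name: str):
    with h5py.File(path, "r") as f:
        g = f[group_name]
        keys = _sorted_frame_keys(g)
        times = np.array([float(g[k].attrs["tau"]) for k in keys])
        maps = np.stack([g[k][()] for k in keys])
    return times, maps


def save_temperature(path, series: TemperatureSeries) -> None:
    _save_stack(path, "temperature", series.times, series.maps)


def load_temperature(path) -> TemperatureSeries:
    times, maps = _load_stack(path, "temperature")
    return TemperatureSeries(times=times, maps=maps)


def save_damage(path, times, omega) -> None:
    _save_stack(path, "damage", times, omega)


def load_damage(path):
    return _load_stack(path, "damage")


def save_calibration(path, result: CalibrationResult) -> None:
    with h5py.File(path, "a") as f:
        if "calibration" in f:
            del f["calibration"]
        g = f.create_group("calibration")
        g.attrs["k_hat"] = result.k_hat
        g.attrs["residual"] = result.residual
        g.attrs["degenerate"] = result.degenerate
        g.attrs["tip_center"] = list(result.tip_region.center)
        g.attrs["tip_diameter"] = result.tip_region.diameter
        g.create_dataset("fit_times", data=result.fit_times)
        g.create_dataset("ta_norm", data=result.ta_norm)
        g.create_dataset("beta_norm", data=result.beta_norm)


def load_calibration(path) -> CalibrationResult:
    with h5py.File(path, "r") as f:
        g = f["calibration"]
        tip = TipRegion(center=(float(g.attrs["tip_center"][0]),
                                float(g.attrs["tip_center"][1])),
                        diameter=float(g.attrs["tip_diameter"]))
        return CalibrationResult(
            k_hat=float(g.attrs["k_hat"]), tip_region=tip,
            fit_times=g["fit_times"][()], residual=float(g.attrs["residual"]),
            ta_norm=g["ta_norm"][()], beta_norm=g["beta_norm"][()],
            degenerate=bool(g.attrs["degenerate"]))
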