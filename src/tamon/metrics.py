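"""Ablation-extent metrics and cross-modality error statistics.

The ablation zone is summarised by the inertia-equivalent ellipse of its
binary mask; the reported width is the geometric mean of the ellipse's
major and minor axes.  Paired per-sample percentage errors against a
reference modality are aggregated as signed mean and RMS.  Also included
are the arrival-displacement error caused by reconstructing with a fixed
speed of sound while the true speed has risen with temperature, and the
corresponding coherence-limit wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "AblationSummary",
    "ErrorTable",
    "fit_ellipse",
    "error_stats",
    "summarize_errors",
    "sos_displacement_error",
    "incoherence_wavelength",
    "export_error_table",
]


@dataclass(frozen=True)
class AblationSummary:
    """Ellipse-fit summary of a segmented ablation zone (axes in mm)."""

    major_axis: float
    minor_axis: float
    diameter_gm: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.major_axis >= self.minor_axis > 0.0:
            raise ValueError("require major_axis >= minor_axis > 0")


@dataclass(frozen=True)
class ErrorTable:
    """Per-sample percentage errors with signed mean and RMS."""

    per_sample_error: np.ndarray
    mean_error: float
    rms_error: float


def fit_ellipse(mask: np.ndarray, pixel_size: float,
                source_label: str = "") -> AblationSummary:
    """Second-moment (inertia-equivalent) ellipse fit of a binary mask.

    If the mask has several connected components the largest is used.
    Axis lengths are returned in mm via the grid spacing (m); the
    geometric-mean diameter is sqrt(major*minor).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    region = max(props, key=lambda r: r.area)
    major = region.axis_major_length * pixel_size * 1e3
    minor = region.axis_minor_length * pixel_size * 1e3
    if minor <= 0.0:
        # degenerate (line-like) region: fall back to one pixel width
        minor = pixel_size * 1e3
    return AblationSummary(major_axis=major, minor_axis=minor,
                           diameter_gm=float(np.sqrt(major * minor)),
                           source_label=source_label)


def error_stats(estimates, reference) -> ErrorTable:
    """Signed percentage errors of paired width estimates.

    ``error_i = 100 * (estimate_i - reference_i) / reference_i``; the mean
    is the arithmetic mean of the signed errors and the RMS the root mean
    square of the signed errors.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and reference must be paired")
    if np.any(ref == 0.0):
        raise ValueError("reference widths must be nonzero")
    err = 100.0 * (est - ref) / ref
    return ErrorTable(per_sample_error=err,
                      mean_error=float(np.mean(err)),
                      rms_error=float(np.sqrt(np.mean(err**2))))


def summarize_errors(per_sample_error) -> ErrorTable:
    """Aggregate already-computed signed percentage errors."""
    err = np.asarray(per_sample_error, dtype=float)
    return ErrorTable(per_sample_error=err,
                      mean_error=float(np.mean(err)),
                      rms_error=float(np.sqrt(np.mean(err**2))))


def sos_displacement_error(path_length: float, v_baseline: float,
                           v_elevated: float) -> float:
    """Arrival-displacement error (mm) of a fixed-speed reconstruction.

    If the true speed of sound has risen from ``v_baseline`` to
    ``v_elevated`` (e.g. ~1540 -> ~1560 m/s between 37 C and 60 C) but the
    reconstruction assumes the baseline value, arrivals over ``path_length``
    (m) are displaced by ``path_length * |dv| / v_elevated``.
    """
    if v_baseline <= 0.0 or v_elevated <= 0.0:
        raise ValueError("speeds must be positive")
    return path_length * abs(v_elevated - v_baseline) / v_elevated * 1e3


def incoherence_wavelength(displacement_error_mm: float) -> float:
    """Wavelength (mm) below which summation becomes incoherent.

    A half-wavelength path error destroys coherence, so signals with
    wavelengths shorter than twice the displacement error are degraded.
    """
    if displacement_error_mm < 0.0:
        raise ValueError("displacement error must be non-negative")
    return 2.0 * displacement_error_mm


def export_error_table(path, rows, modality_labels, reference_label="photo") -> None:
    """Write a per-sample width/error CSV.

    ``rows`` is a sequence of dicts with a reference width (mm) under
    ``reference_label`` and estimate widths under each modality label;
    percentage-error columns are appended per modality.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = [reference_label] + list(modality_labels) + [
            f"{m}_error_pct" for m in modality_labels]
        writer.writerow(header)
        for row in rows:
            ref = row[reference_label]
            vals = [row[m] for m in modality_labels]
            errs = [100.0 * (v - ref) / ref for v in vals]
            writer.writerow([ref] + vals + [f"{e:.1f}" for e in errs])
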