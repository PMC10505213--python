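"""Pseudo-color rendering of dynamics maps and slice extraction.

A dynamics image is composed in HSV space: the hue encodes the dynamics
metric (red = low, green = high by default), the value encodes the
time-averaged OCT intensity in dB, and the saturation is fixed at 1 for
every pixel.  Dark pixels therefore mark weak backscatter regardless of
their dynamics, which suppresses the background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .metrics import DynamicsMaps

#: Default hue window for LIV, dB^2 (red 0 deg -> green 120 deg).
DEFAULT_LIV_RANGE = (0.0, 10.0)
#: Default hue window for OCDS_l, 1/ms.
DEFAULT_OCDSL_RANGE = (0.0, 6e-4)


@dataclass(frozen=True)
class ColorMapSpec:
    """Mapping of metric and intensity values onto HSV channels.

    ``metric_range`` clips the dynamics metric before linear mapping onto
    ``hue_range_deg``; ``intensity_range_db`` clips the dB intensity before
    linear mapping onto the value channel [0, 1].  Saturation is fixed at 1
    and is deliberately not a parameter.
    """

    metric_range: tuple[float, float]
    intensity_range_db: tuple[float, float]
    hue_range_deg: tuple[float, float] = (0.0, 120.0)

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (*self.metric_range, "metric_range"),
            (*self.intensity_range_db, "intensity_range_db"),
        ):
            if not lo < hi:
                raise ValueError(f"{name} must satisfy lo < hi, got ({lo}, {hi})")
        for h in self.hue_range_deg:
            if not 0.0 <= h < 360.0:
                raise ValueError("hues must lie in [0, 360) degrees")


def default_intensity_range(mean_intensity_db: np.ndarray) -> tuple[float, float]:
    """Per-volume value-channel window: [min + 5 dB, 99.9th percentile]."""
    lo = float(mean_intensity_db.min()) + 5.0
    hi = float(np.percentile(mean_intensity_db, 99.9))
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def render_pseudo_color(
    metric_slice: np.ndarray,
    intensity_slice_db: np.ndarray,
    spec: ColorMapSpec,
) -> np.ndarray:
    """Compose an RGB image from co-registered metric and intensity slices.

    Returns a float array shaped ``(*slice.shape, 3)`` with values in
    [0, 1].  Pure function: identical inputs give bit-identical output.
    """
    metric_slice = np.asarray(metric_slice, dtype=float)
    intensity_slice_db = np.asarray(intensity_slice_db, dtype=float)
    if metric_slice.shape != intensity_slice_db.shape:
        raise ValueError(
            f"metric slice {metric_slice.shape} and intensity slice "
            f"{intensity_slice_db.shape} must be co-registered (same shape)"
        )
    m_lo, m_hi = spec.metric_range
    h_lo, h_hi = spec.hue_range_deg
    i_lo, i_hi = spec.intensity_range_db
    frac = (np.clip(metric_slice, m_lo, m_hi) - m_lo) / (m_hi - m_lo)
    hue = (h_lo + frac * (h_hi - h_lo)) / 360.0
    value = (np.clip(intensity_slice_db, i_lo, i_hi) - i_lo) / (i_hi - i_lo)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)


def extract_slice(
    maps: DynamicsMaps,
    metric: Literal["liv", "ocds_l", "ocds_e"],
    plane: Literal["en_face", "b_scan"],
    index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract co-registered (metric, intensity) 2D slices from map volumes.

    ``en_face`` slices at constant depth z (shape (y, x)); ``b_scan``
    slices at constant location y (shape (z, x)).  Single-voxel planes —
    no depth projection.
    """
    metric_vol = getattr(maps, metric)
    if metric_vol is None:
        raise ValueError(f"metric {metric!r} was not computed for these maps")
    ny, nz, nx = maps.shape
    if plane == "en_face":
        if not 0 <= index < nz:
            raise IndexError(f"en_face index {index} out of range [0, {nz})")
        return metric_vol[:, index, :], maps.mean_intensity_db[:, index, :]
    if plane == "b_scan":
        if not 0 <= index < ny:
            raise IndexError(f"b_scan index {index} out of range [0, {ny})")
        return metric_vol[index], maps.mean_intensity_db[index]
    raise ValueError(f"unknown plane {plane!r}; use 'en_face' or 'b_scan'")
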