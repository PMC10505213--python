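"""Repeated raster scan protocol: geometry, timing and derived quantities.

The acquisition protocol divides the lateral (slow-scan) field into
``n_regions`` regions of ``locations_per_region`` B-scan locations each.
Every region is raster-scanned ``n_repeats`` times, so each B-scan location
is revisited once per ``frame_repeat_time_ms``.  The default parameters
(8 regions x 16 locations, 32 repeats, 204.8 ms frame repetition time)
describe a 128-location volume captured in ~52.4 s with a per-location
observation window of ~6.35 s.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition geometry and timing of a repeated raster scan.

    Parameters
    ----------
    n_regions : int
        Number of lateral sub-regions scanned sequentially.
    locations_per_region : int
        B-scan (y) locations per region.
    n_repeats : int
        Repeated frames N acquired at each location.
    frame_repeat_time_ms : float
        Interval dt between successive frames at the same location, ms.
    pixel_size_x_mm, pixel_size_y_mm, pixel_size_z_mm : float
        Voxel dimensions.  Defaults spread a 1 x 1 x 2.91 mm^3 field over a
        512 (x) x 128 (y) x 1024 (z) grid.
    """

    n_regions: int = 8
    locations_per_region: int = 16
    n_repeats: int = 32
    frame_repeat_time_ms: float = 204.8
    pixel_size_x_mm: float = 1.0 / 512
    pixel_size_y_mm: float = 1.0 / 128
    pixel_size_z_mm: float = 2.91 / 1024

    def __post_init__(self) -> None:
        for name in ("n_regions", "locations_per_region", "n_repeats"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if self.frame_repeat_time_ms <= 0:
            raise ValueError("frame_repeat_time_ms must be > 0")
        for name in ("pixel_size_x_mm", "pixel_size_y_mm", "pixel_size_z_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_locations(self) -> int:
        """Total B-scan locations in a volume."""
        return self.n_regions * self.locations_per_region

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_size_x_mm * self.pixel_size_y_mm * self.pixel_size_z_mm

    def timestamps_ms(self):
        """Frame acquisition times t_i = i * dt for i = 0..N-1 (ms)."""
        import numpy as np

        return np.arange(self.n_repeats) * self.frame_repeat_time_ms


# Ready-made protocol of the high-temporal-density single-location scan
# (350 repeats of one B-scan at 12.8 ms) used for the early decay metric.
HIGH_DENSITY_PROTOCOL = ScanProtocol(
    n_regions=1,
    locations_per_region=1,
    n_repeats=350,
    frame_repeat_time_ms=12.8,
)


@dataclass(frozen=True)
class TimingSummary:
    """Derived timing quantities of a scan protocol."""

    volume_acquisition_time_s: float
    time_window_s: float
    nyquist_hz: float
    frames_per_volume: int

    def __post_init__(self) -> None:
        if not (
            self.volume_acquisition_time_s > 0
            and self.time_window_s > 0
            and self.nyquist_hz > 0
            and self.frames_per_volume > 0
        ):
            raise ValueError("all TimingSummary fields must be positive")

    def __str__(self) -> str:  # 4 significant digits, full precision kept in fields
        return (
            f"volume acquisition time: {self.volume_acquisition_time_s:.4g} s\n"
            f"observation time window: {self.time_window_s:.4g} s\n"
            f"Nyquist frequency:       {self.nyquist_hz:.4g} Hz\n"
            f"frames per volume:       {self.frames_per_volume}"
        )


def protocol_timing(protocol: ScanProtocol) -> TimingSummary:
    """Compute acquisition time, observation window and Nyquist frequency.

    One raster pass over a region's B-scan locations takes one frame
    repetition time, so a volume completes in
    ``n_regions * n_repeats * frame_repeat_time_ms`` (no inter-region
    flyback is modeled).  The observation window at a single location spans
    first to last repeat, ``(n_repeats - 1) * frame_repeat_time_ms``.
    """
    dt_s = protocol.frame_repeat_time_ms / 1000.0
    return TimingSummary(
        volume_acquisition_time_s=protocol.n_regions * protocol.n_repeats * dt_s,
        time_window_s=(protocol.n_repeats - 1) * dt_s,
        nyquist_hz=1.0 / (2.0 * dt_s),
        frames_per_volume=protocol.n_locations * protocol.n_repeats,
    )
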