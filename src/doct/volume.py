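"""Time-sequential OCT intensity volumes and dB scaling.

Axis convention (enforced throughout the package): ``(y, t, z, x)`` —
slow-scan B-scan location, repeat index, depth (increasing downward),
fast-scan lateral position.  Dynamics metrics operate along the ``t`` axis
of the dB-scaled data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .protocol import ScanProtocol

Scale = Literal["linear", "dB"]

#: Default dB floor, as a fraction of the volume's full scale (its maximum).
DEFAULT_DB_FLOOR_FRACTION = 1e-7


@dataclass
class TimeSequenceVolume:
    """4D OCT intensity indexed ``(y, t, z, x)`` with acquisition metadata.

    ``timestamps_ms`` are per-repeat acquisition times (frame granularity;
    within-frame pixel timing jitter is ignored).  ``scale`` records whether
    ``data`` holds linear or dB-scaled intensity.
    """

    data: np.ndarray
    protocol: ScanProtocol
    timestamps_ms: Optional[np.ndarray] = None
    scale: Scale = "linear"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (y, t, z, x), got shape {self.data.shape}")
        if self.timestamps_ms is None:
            self.timestamps_ms = self.protocol.timestamps_ms()
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if self.data.shape[1] != self.protocol.n_repeats:
            raise ValueError(
                f"t axis length {self.data.shape[1]} != protocol.n_repeats "
                f"{self.protocol.n_repeats}"
            )
        if self.timestamps_ms.shape != (self.data.shape[1],):
            raise ValueError("timestamps length must equal the t axis length")
        if np.any(np.diff(self.timestamps_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.scale == "dB" and not np.all(np.isfinite(self.data)):
            raise ValueError("dB-scaled data must be finite (apply a floor before scaling)")

    @property
    def n_locations(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(z, x) shape of one B-scan frame."""
        return self.data.shape[2], self.data.shape[3]

    @property
    def dt_ms(self) -> float:
        return self.protocol.frame_repeat_time_ms


def to_db(volume: TimeSequenceVolume, floor: Optional[float] = None) -> TimeSequenceVolume:
    """Convert a linear-intensity volume to dB scale: ``10*log10(max(I, floor))``.

    Parameters
    ----------
    volume : TimeSequenceVolume
        Linear-scale volume with non-negative intensities.
    floor : float, optional
        Absolute intensity floor (> 0) clamping zeros so logs stay finite.
        Defaults to ``DEFAULT_DB_FLOOR_FRACTION`` of the volume's maximum.

    Returns
    -------
    TimeSequenceVolume
        New volume with ``scale='dB'``; shape, timestamps and protocol unchanged.
    """
    if volume.scale == "dB":
        warnings.warn("volume is already dB-scaled; returning it unchanged", stacklevel=2)
        return volume
    data = np.asarray(volume.data, dtype=float)
    if np.any(data < 0):
        raise ValueError("linear intensities must be non-negative")
    if not np.all(np.isfinite(data)):
        raise ValueError("linear intensities must be finite")
    if floor is None:
        full_scale = float(data.max())
        floor = DEFAULT_DB_FLOOR_FRACTION * full_scale if full_scale > 0 else 1e-30
    if floor <= 0:
        raise ValueError("floor must be > 0")
    db = 10.0 * np.log10(np.maximum(data, floor))
    return TimeSequenceVolume(
        data=db,
        protocol=volume.protocol,
        timestamps_ms=volume.timestamps_ms.copy(),
        scale="dB",
    )


def db_scale(values: np.ndarray, floor: float) -> np.ndarray:
    """Array-level dB conversion ``10*log10(max(v, floor))`` for convenience."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("linear intensities must be non-negative")
    return 10.0 * np.log10(np.maximum(values, floor))
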