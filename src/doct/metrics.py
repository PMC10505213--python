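"""Dynamics metrics: LIV, temporal autocorrelation and OCDS.

LIV (logarithmic intensity variance, dB^2) is the per-pixel temporal
variance of the dB-scaled OCT intensity over the N repeated frames, with
divisor N:

    LIV(x,z) = (1/N) * sum_i [I_dB(x,z,t_i) - <I_dB(x,z)>_t]^2

OCDS (OCT correlation decay speed, 1/ms) is the negated slope of an
ordinary-least-squares line fitted to the temporal autocorrelation
rho(tau_i) of the dB intensity over a delay window:

  * late variant (OCDS_l):  tau in [204.8, 1228.8] ms on the 204.8 ms grid
    (6 points) — sensitive to slow, second-scale dynamics;
  * early variant (OCDS_e): tau in [12.8, 64] ms on the 12.8 ms grid
    (5 points, high-density single-location protocol) — sensitive to fast
    dynamics that alias in the late window.

The autocorrelation at integer lag i is the Pearson correlation between the
two overlapping subsequences offset by i frames, each demeaned and scaled by
its own standard deviation, so rho(0) = 1 and any affine transform of the
sequence leaves the curve unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .volume import TimeSequenceVolume

#: Delay window of the late correlation decay speed, ms.
OCDSL_WINDOW_MS: tuple[float, float] = (204.8, 1228.8)
#: Delay window of the early correlation decay speed, ms.
OCDSE_WINDOW_MS: tuple[float, float] = (12.8, 64.0)

_GRID_TOL_MS = 1e-9


class InsufficientDataError(ValueError):
    pass


@dataclass
class AutocorrelationCurve:
    """Temporal autocorrelation rho(tau_i) on the delay grid tau_i = i*dt.

    ``valid[i]`` is False where either overlapping subsequence at lag i has
    zero variance (rho undefined there; stored as 0).
    """

    delays_ms: np.ndarray
    rho: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.delays_ms.shape == self.rho.shape == self.valid.shape):
            raise ValueError("delays_ms, rho and valid must share one shape")


@dataclass
class OcdsFit:
    """Result of an OCDS window fit: decay speed (1/ms) and validity flag."""

    speed: float
    valid: bool

    def __float__(self) -> float:
        return float(self.speed)


def compute_liv(sequence: np.ndarray, n_frames: Optional[int] = None) -> float:
    """Temporal variance (divisor N) of a dB intensity sequence, in dB^2."""
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 1:
        raise ValueError("sequence must be 1D")
    if n_frames is not None and len(seq) != n_frames:
        raise ValueError(f"sequence length {len(seq)} != n_frames {n_frames}")
    if len(seq) < 2:
        raise InsufficientDataError("LIV needs at least 2 frames")
    if not np.all(np.isfinite(seq)):
        raise ValueError("sequence must be finite")
    return float(np.mean((seq - seq.mean()) ** 2))


def compute_acf(sequence: np.ndarray, dt_ms: float = 1.0) -> AutocorrelationCurve:
    """Per-lag Pearson autocorrelation of a dB intensity sequence.

    At lag i the leading ``seq[:-i]`` and trailing ``seq[i:]`` subsequences
    are correlated using their own means and variances (local Pearson
    estimator, robust for short N).  A constant sequence yields
    ``valid=False`` at every positive lag rather than an exception.
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 1 or len(seq) < 2:
        raise InsufficientDataError("autocorrelation needs a 1D sequence of length >= 2")
    if not np.all(np.isfinite(seq)):
        raise ValueError("sequence must be finite")
    n = len(seq)
    rho = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    var0 = np.var(seq)
    rho[0] = 1.0
    valid[0] = var0 > 0
    for lag in range(1, n):
        a = seq[: n - lag]
        b = seq[lag:]
        va = np.var(a)
        vb = np.var(b)
        if va > 0 and vb > 0 and len(a) >= 2:
            cov = np.mean((a - a.mean()) * (b - b.mean()))
            rho[lag] = cov / np.sqrt(va * vb)
            valid[lag] = True
    return AutocorrelationCurve(np.arange(n) * dt_ms, rho, valid)


def _window_indices(delays_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = window_ms
    if not lo < hi:
        raise ValueError(f"delay window must satisfy lo < hi, got {window_ms}")
    idx = np.flatnonzero((delays_ms >= lo - _GRID_TOL_MS) & (delays_ms <= hi + _GRID_TOL_MS))
    if len(idx) < 2:
        raise ValueError(
            f"delay window {window_ms} ms covers {len(idx)} grid delays; "
            "at least 2 are required"
        )
    return idx


def fit_ocds(curve: AutocorrelationCurve, delay_window_ms: tuple[float, float]) -> OcdsFit:
    """Negated OLS slope of rho(tau) over the grid delays inside a window.

    Positive values mean decaying correlation ("decay speed"); a rising
    curve yields a negative value, which is retained.  If any in-window
    point is invalid (zero-variance subsequence) the fit returns 0 with
    ``valid=False``.
    """
    idx = _window_indices(curve.delays_ms, delay_window_ms)
    if not np.all(curve.valid[idx]):
        return OcdsFit(0.0, False)
    tau = curve.delays_ms[idx]
    rho = curve.rho[idx]
    tau_c = tau - tau.mean()
    slope = float(np.dot(tau_c, rho - rho.mean()) / np.dot(tau_c, tau_c))
    return OcdsFit(-slope, True)


@dataclass
class DynamicsMaps:
    """Co-registered dynamics volumes, all shaped ``(y, z, x)``.

    ``liv`` in dB^2, ``ocds_l``/``ocds_e`` in 1/ms (0 where flagged invalid
    in the matching ``*_valid`` mask), ``mean_intensity_db`` the
    time-averaged dB intensity.  ``provenance`` records the protocol and
    computation parameters.
    """

    liv: np.ndarray
    ocds_l: np.ndarray
    mean_intensity_db: np.ndarray
    ocds_l_valid: np.ndarray
    ocds_e: Optional[np.ndarray] = None
    ocds_e_valid: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.liv.shape == self.ocds_l.shape == self.mean_intensity_db.shape):
            raise ValueError("all maps must share one shape")
        if np.any(self.liv < 0):
            raise ValueError("LIV must be non-negative everywhere")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.liv.shape


def _acf_lagset(flat_db: np.ndarray, lags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-lag Pearson ACF over many pixels.

    Parameters: ``flat_db`` shaped (n_pixels, N).  Returns ``rho`` and
    ``valid`` shaped (n_pixels, len(lags)).
    """
    npix, n = flat_db.shape
    rho = np.zeros((npix, len(lags)))
    valid = np.zeros((npix, len(lags)), dtype=bool)
    for j, lag in enumerate(lags):
        a = flat_db[:, : n - lag]
        b = flat_db[:, lag:]
        ma = a.mean(axis=1)
        mb = b.mean(axis=1)
        va = a.var(axis=1)
        vb = b.var(axis=1)
        cov = (a * b).mean(axis=1) - ma * mb
        ok = (va > 0) & (vb > 0)
        denom = np.sqrt(va * vb, where=ok, out=np.ones_like(va))
        rho[:, j] = np.where(ok, cov / denom, 0.0)
        valid[:, j] = ok
    return rho, valid


def _ocds_from_lagset(
    rho: np.ndarray, valid: np.ndarray, tau_ms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized -OLS slope over the window lags; invalid pixels -> 0."""
    ok = valid.all(axis=1)
    tau_c = tau_ms - tau_ms.mean()
    sxx = np.dot(tau_c, tau_c)
    slope = (rho - rho.mean(axis=1, keepdims=True)) @ tau_c / sxx
    return np.where(ok, -slope, 0.0), ok


def _window_lags(window_ms: tuple[float, float], dt_ms: float, n: int, name: str) -> np.ndarray:
    delays = np.arange(n) * dt_ms
    try:
        idx = _window_indices(delays, window_ms)
    except ValueError as err:
        raise ValueError(
            f"{name} window {window_ms} ms does not fit the delay grid "
            f"(dt = {dt_ms} ms, N = {n}): {err}"
        ) from err
    return idx


def compute_dynamics_volume(
    volume: TimeSequenceVolume,
    ocdsl_window_ms: tuple[float, float] = OCDSL_WINDOW_MS,
    compute_ocds_e: bool = False,
    ocdse_window_ms: tuple[float, float] = OCDSE_WINDOW_MS,
) -> DynamicsMaps:
    """Apply LIV and OCDS estimators at every voxel of a dB volume.

    The input must be dB-scaled; the LIV, OCDS and time-averaged intensity
    maps are computed independently per (y, z, x) voxel along the t axis.
    Requesting the early decay speed requires the high-density delay grid
    (the window must cover >= 2 grid delays below N*dt).
    """
    if volume.scale != "dB":
        raise ValueError("compute_dynamics_volume requires a dB-scaled volume (use to_db)")
    ny, n, nz, nx = volume.data.shape
    dt = volume.dt_ms
    lags_l = _window_lags(ocdsl_window_ms, dt, n, "OCDS_l")
    lags_e = _window_lags(ocdse_window_ms, dt, n, "OCDS_e") if compute_ocds_e else None

    flat = np.moveaxis(volume.data, 1, -1).reshape(-1, n)  # (y*z*x, N)
    mean = flat.mean(axis=1)
    liv = ((flat - mean[:, None]) ** 2).mean(axis=1)

    rho_l, valid_l = _acf_lagset(flat, lags_l)
    ocds_l, ok_l = _ocds_from_lagset(rho_l, valid_l, lags_l * dt)

    out_shape = (ny, nz, nx)
    maps = DynamicsMaps(
        liv=liv.reshape(out_shape),
        ocds_l=ocds_l.reshape(out_shape),
        mean_intensity_db=mean.reshape(out_shape),
        ocds_l_valid=ok_l.reshape(out_shape),
        provenance={
            "protocol": volume.protocol,
            "ocdsl_window_ms": tuple(ocdsl_window_ms),
        },
    )
    if compute_ocds_e:
        rho_e, valid_e = _acf_lagset(flat, lags_e)
        ocds_e, ok_e = _ocds_from_lagset(rho_e, valid_e, lags_e * dt)
        maps.ocds_e = ocds_e.reshape(out_shape)
        maps.ocds_e_valid = ok_e.reshape(out_shape)
        maps.provenance["ocdse_window_ms"] = tuple(ocdse_window_ms)
    return maps
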