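"""Synthetic dynamic-speckle spheroid phantoms with known ground truth.

A phantom is a nested-ball spheroid (necrotic core, viable rim, optional
peripheral drug-affected shell) over a noise-floor background, optionally
sitting above a bright well-plate slab.  Every voxel carries a
time-sequential speckle intensity generated by a phasor-sum engine:

    field(t) = static phasor (power 1 - f)
             + sum over K dynamic phasors (total power f)

where ``f`` is the region's ``dynamic_fraction``.  Each dynamic phasor is
a circular complex Gaussian Ornstein-Uhlenbeck process whose field
autocorrelation is exactly ``exp(-delta/tau_c)`` across a frame interval
``delta``, so the region parameter ``decorrelation_time_ms`` maps directly
onto the correlation-decay axis probed by OCDS.  Intensity is |field|^2
scaled to the region's mean backscatter level, plus an additive
constant-variance intensity noise floor.

With ``f = 1`` and ``tau_c`` much shorter than the frame interval the
intensity is fully developed speckle: exponentially distributed with unit
coefficient of variation, decorrelated between frames.  With ``f = 0``
the sequence is constant up to noise.

Phantom parameters are synthetic: they emulate the qualitative core/rim
dynamics contrast of tumor spheroids, not any measured biological
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .protocol import ScanProtocol
from .volume import TimeSequenceVolume

#: Integer codes of the ground-truth label volume.
LABELS = {
    "background": 0,
    "necrotic_core": 1,
    "viable_rim": 2,
    "drug_shell": 3,
    "plate": 4,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
_NOISE_STREAM_KEY = 0x6E6F6973  # distinct sub-stream for the noise field


@dataclass(frozen=True)
class RegionDynamics:
    """Dynamics and backscatter of one phantom region.

    ``dynamic_fraction`` is the fraction of scatterer power that
    fluctuates; ``decorrelation_time_ms`` the correlation time tau_c of the
    dynamic field component; ``mean_intensity_db`` the target mean
    backscatter (``-inf`` for a signal-free region).
    """

    label: str
    dynamic_fraction: float
    decorrelation_time_ms: float
    mean_intensity_db: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if not 0.0 <= self.dynamic_fraction <= 1.0:
            raise ValueError("dynamic_fraction must lie in [0, 1]")
        if self.decorrelation_time_ms <= 0:
            raise ValueError("decorrelation_time_ms must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, per-region dynamics and reproducibility seed of a phantom.

    The grid is ``(y, z, x)`` with per-axis voxel sizes in mm; the spheroid
    is a ball of ``rim_radius_mm`` around ``center_mm`` containing a
    concentric core of ``core_radius_mm``, optionally wrapped in a shell of
    ``shell_thickness_mm``.  ``plate_thickness_vox`` > 0 adds a full-field
    slab at the deepest z.
    """

    grid_shape: tuple[int, int, int] = (32, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (0.02, 0.02, 0.02)
    center_mm: Optional[tuple[float, float, float]] = None  # (y, z, x); default mid-field
    core_radius_mm: float = 0.17
    rim_radius_mm: float = 0.28
    shell_thickness_mm: float = 0.0
    regions: tuple[RegionDynamics, ...] = ()
    plate_thickness_vox: int = 0
    noise_floor_db: Optional[float] = -25.0
    scatterers_per_voxel: int = 10
    protocol: ScanProtocol = field(
        default_factory=lambda: ScanProtocol(
            n_regions=2,
            locations_per_region=16,
            pixel_size_x_mm=0.02,
            pixel_size_y_mm=0.02,
            pixel_size_z_mm=0.02,
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_radius_mm > self.rim_radius_mm:
            raise ValueError("region radii must be nested: core_radius <= rim_radius")
        if self.shell_thickness_mm < 0:
            raise ValueError("shell_thickness_mm must be >= 0")
        if self.scatterers_per_voxel < 1:
            raise ValueError("scatterers_per_voxel must be >= 1")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate region labels in spec")

    @property
    def center(self) -> tuple[float, float, float]:
        if self.center_mm is not None:
            return self.center_mm
        ny, nz, nx = self.grid_shape
        vy, vz, vx = self.voxel_size_mm
        # z-center placed above mid-depth so an optional plate slab fits below
        return (ny / 2 * vy, nz * 0.42 * vz, nx / 2 * vx)

    def region(self, label: str) -> RegionDynamics:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(f"spec has no region {label!r}")

    def outer_radius_mm(self) -> float:
        return self.rim_radius_mm + self.shell_thickness_mm


def region_labels(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth label volume (y, z, x) from the phantom geometry.

    Raises if the spheroid (including its shell) would overlap the plate
    slab — regions must tile the grid without overlap.
    """
    ny, nz, nx = spec.grid_shape
    vy, vz, vx = spec.voxel_size_mm
    cy, cz, cx = spec.center
    yy = (np.arange(ny) + 0.5) * vy - cy
    zz = (np.arange(nz) + 0.5) * vz - cz
    xx = (np.arange(nx) + 0.5) * vx - cx
    r = np.sqrt(
        yy[:, None, None] ** 2 + zz[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    outer = spec.outer_radius_mm()
    if spec.shell_thickness_mm > 0:
        labels[r <= outer] = LABELS["drug_shell"]
    labels[r <= spec.rim_radius_mm] = LABELS["viable_rim"]
    labels[r <= spec.core_radius_mm] = LABELS["necrotic_core"]
    if spec.plate_thickness_vox > 0:
        z_plate = nz - spec.plate_thickness_vox
        if np.any(labels[:, z_plate:, :] != LABELS["background"]):
            raise ValueError("invalid spec: spheroid overlaps the plate slab")
        labels[:, z_plate:, :] = LABELS["plate"]
    return labels


def ground_truth_core_fraction(labels: np.ndarray) -> float:
    """Necrotic-core voxel fraction of the whole spheroid (core+rim+shell)."""
    core = np.count_nonzero(labels == LABELS["necrotic_core"])
    spheroid = np.count_nonzero(
        np.isin(labels, [LABELS["necrotic_core"], LABELS["viable_rim"], LABELS["drug_shell"]])
    )
    return core / spheroid if spheroid else 0.0


def _simulate_block(
    dyn: RegionDynamics,
    n_frames: int,
    dt_ms: float,
    K: int,
    n_pixels: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Linear intensity time series for a block of like-dynamics voxels.

    Returns shape (n_pixels, n_frames).  The dynamic field is the sum of K
    independent complex-Gaussian OU phasors with lag-1 autoregression
    coefficient exp(-dt/tau_c); the static component is a fixed
    random-phase phasor per pixel.
    """
    f = dyn.dynamic_fraction
    mean_lin = 10.0 ** (dyn.mean_intensity_db / 10.0) if np.isfinite(dyn.mean_intensity_db) else 0.0
    if mean_lin == 0.0:
        return np.zeros((n_pixels, n_frames))
    static = np.sqrt(1.0 - f) * np.exp(1j * rng.uniform(0.0, 2 * np.pi, size=n_pixels))
    field_t = np.empty((n_pixels, n_frames), dtype=complex)
    if f == 0.0:
        field_t[:] = static[:, None]
    else:
        r = np.exp(-dt_ms / dyn.decorrelation_time_ms)
        innov = np.sqrt(1.0 - r * r)
        amp = np.sqrt(f / K)

        def cn(shape):
            return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)

        d = cn((n_pixels, K))
        field_t[:, 0] = static + amp * d.sum(axis=1)
        for t in range(1, n_frames):
            d = r * d + innov * cn((n_pixels, K))
            field_t[:, t] = static + amp * d.sum(axis=1)
    return np.abs(field_t) ** 2 * mean_lin


def _intensity_noise(
    shape: tuple[int, ...], noise_floor_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive constant-variance intensity noise around the floor level."""
    mu = 10.0 ** (noise_floor_db / 10.0)
    return np.clip(rng.normal(mu, mu / 5.0, size=shape), 0.0, None)


def simulate_pixel_sequence(
    dyn: RegionDynamics,
    protocol: ScanProtocol,
    K: int = 10,
    seed: int = 0,
    n_pixels: int = 1,
    noise_floor_db: Optional[float] = None,
) -> np.ndarray:
    """Simulate linear intensity time series for independent pixels.

    Returns shape (n_pixels, N); fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = _simulate_block(
        dyn, protocol.n_repeats, protocol.frame_repeat_time_ms, K, n_pixels, rng
    )
    if noise_floor_db is not None:
        out = out + _intensity_noise(out.shape, noise_floor_db, rng)
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[TimeSequenceVolume, np.ndarray]:
    """Assemble a 4D linear-intensity phantom volume and its label volume.

    Per-region voxel blocks are generated from independent sub-streams of
    the master seed (one per region label, voxels in fixed C order), so the
    volume is bit-reproducible for a fixed spec regardless of how regions
    are iterated.  Convert with :func:`doct.volume.to_db` downstream.
    """
    labels = region_labels(spec)
    ny, nz, nx = spec.grid_shape
    n = spec.protocol.n_repeats
    data = np.zeros((ny, n, nz, nx))
    for name, code in LABELS.items():
        ys, zs, xs = np.nonzero(labels == code)
        if len(ys) == 0:
            continue
        if name == "background":
            continue  # background carries noise only
        dyn = spec.region(name)
        rng = np.random.default_rng([spec.seed, code])
        block = _simulate_block(
            dyn, n, spec.protocol.frame_repeat_time_ms, spec.scatterers_per_voxel,
            len(ys), rng,
        )
        data[ys, :, zs, xs] = block
    if spec.noise_floor_db is not None:
        noise_rng = np.random.default_rng([spec.seed, _NOISE_STREAM_KEY])
        data += _intensity_noise(data.shape, spec.noise_floor_db, noise_rng)
    volume = TimeSequenceVolume(data=data, protocol=spec.protocol, scale="linear")
    return volume, labels


# --- ready-made scenarios -------------------------------------------------

def _core(f=0.05, tau=30.0, db=0.0):
    return RegionDynamics("necrotic_core", f, tau, db)


def _rim(f=0.9, tau=1000.0, db=0.0):
    return RegionDynamics("viable_rim", f, tau, db)


def _shell(f=0.5, tau=30.0, db=0.0):
    return RegionDynamics("drug_shell", f, tau, db)


_PLATE = RegionDynamics("plate", 0.0, 1000.0, 5.0)

#: Virtual treatment days of the growth series and their core/rim radius ratios.
GROWTH_SERIES_DAYS = {1: 0.4, 3: 0.6, 6: 0.8}


def scenario_library(
    name: str, seed: int = 0
) -> Union[PhantomSpec, dict[int, PhantomSpec]]:
    """Ready-made phantom specs emulating the study's qualitative patterns.

    ``growth_series`` returns a mapping of virtual treatment day to spec
    (necrotic core fraction growing over days); every other name returns a
    single spec.  Parameterizations are synthetic and purely qualitative:

    * ``mcf7_control`` — low-dynamics slow core, high-dynamics rim;
    * ``mcf7_taxol_1um`` — concentric low / high / low decay-speed shells;
    * ``ht29_control`` — fast high-magnitude core (short tau_c, aliased in
      the late window) under a slower rim;
    * ``ht29_sn38`` — like the control plus a thin low-decay-speed
      peripheral shell (drug-affected periphery).
    """
    base = dict(plate_thickness_vox=4, seed=seed)
    if name == "mcf7_control":
        return PhantomSpec(regions=(_core(), _rim(), _PLATE), **base)
    if name == "mcf7_taxol_1um":
        return PhantomSpec(
            core_radius_mm=0.14,
            rim_radius_mm=0.22,
            shell_thickness_mm=0.06,
            regions=(_core(), _rim(), _shell(), _PLATE),
            **base,
        )
    if name == "ht29_control":
        return PhantomSpec(
            regions=(_core(f=0.9, tau=50.0), _rim(f=0.7, tau=900.0), _PLATE), **base
        )
    if name == "ht29_sn38":
        return PhantomSpec(
            core_radius_mm=0.15,
            rim_radius_mm=0.24,
            shell_thickness_mm=0.04,
            regions=(_core(f=0.9, tau=50.0), _rim(f=0.7, tau=900.0), _shell(), _PLATE),
            **base,
        )
    if name == "growth_series":
        rim = 0.28
        return {
            day: PhantomSpec(
                core_radius_mm=ratio * rim,
                rim_radius_mm=rim,
                regions=(_core(), _rim(), _PLATE),
                plate_thickness_vox=4,
                seed=int(np.random.SeedSequence([seed, day]).generate_state(1)[0] % (2**31)),
            )
            for day, ratio in GROWTH_SERIES_DAYS.items()
        }
    raise KeyError(
        f"unknown scenario {name!r}; known: mcf7_control, mcf7_taxol_1um, "
        "ht29_control, ht29_sn38, growth_series"
    )
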