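"""Spheroid segmentation and volumetric quantification.

The spheroid is segmented from the time-averaged intensity volume by an
intensity threshold followed by connected-component analysis
(6-connectivity by default).  The bright well-plate bottom, which also
exceeds the threshold, is removed either by an automatic geometric rule
(near-bottom slab with a large lateral footprint) or by an explicit
user-supplied z-exclusion range; the largest remaining component is the
spheroid.

Quantification over the mask yields the spheroid volume, the mean LIV and
mean OCDS_l, and the necrotic cell ratio: the fraction of spheroid voxels
whose dynamics metric falls strictly below a cutoff (defaults 3 dB^2 for
LIV, 2e-4 1/ms for OCDS_l).  Boundary voxels exactly at a cutoff count as
viable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import measure

from .metrics import DynamicsMaps

#: Dynamics cutoffs below which a voxel counts as necrotic.
DEFAULT_LIV_CUTOFF_DB2 = 3.0
DEFAULT_OCDSL_CUTOFF_MS_INV = 2e-4


class EmptySegmentationError(ValueError):
    pass


@dataclass
class SpheroidMask:
    """Boolean spheroid mask aligned to a DynamicsMaps volume (y, z, x)."""

    mask: np.ndarray
    voxel_volume_mm3: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (y, z, x)")
        if not self.mask.any():
            raise EmptySegmentationError("segmentation produced an empty mask")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be > 0")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SpheroidQuant:
    """Scalar read-outs of one segmented spheroid."""

    volume_mm3: float
    mean_liv_db2: float
    mean_ocdsl_ms_inv: float
    necrotic_ratio_liv: float
    necrotic_ratio_ocdsl: float
    cutoffs: tuple[float, float] = (DEFAULT_LIV_CUTOFF_DB2, DEFAULT_OCDSL_CUTOFF_MS_INV)

    def __post_init__(self) -> None:
        for r in (self.necrotic_ratio_liv, self.necrotic_ratio_ocdsl):
            if not 0.0 <= r <= 1.0:
                raise ValueError("necrotic ratios must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "volume_mm3": self.volume_mm3,
            "mean_liv_db2": self.mean_liv_db2,
            "mean_ocdsl_ms_inv": self.mean_ocdsl_ms_inv,
            "necrotic_ratio_liv": self.necrotic_ratio_liv,
            "necrotic_ratio_ocdsl": self.necrotic_ratio_ocdsl,
        }


def _component_is_plate(
    labeled: np.ndarray,
    label: int,
    footprint_fraction: float,
    max_thickness_vox: int,
    near_bottom_vox: int,
) -> bool:
    ys, zs, xs = np.nonzero(labeled == label)
    ny, nz, nx = labeled.shape
    footprint = len(np.unique(ys * nx + xs)) / (ny * nx)
    z_extent = int(zs.max() - zs.min() + 1)
    return (
        footprint >= footprint_fraction
        and z_extent <= max_thickness_vox
        and zs.min() >= nz - near_bottom_vox
    )


def remove_plate(
    labeled: np.ndarray,
    footprint_fraction: float = 0.8,
    max_thickness_vox: int = 6,
    near_bottom_vox: Optional[int] = None,
) -> np.ndarray:
    """Zero out components classified as the well-plate bottom.

    A component is a plate when its lateral (y, x) footprint covers at least
    ``footprint_fraction`` of the field AND it is a thin slab
    (z extent <= ``max_thickness_vox``) lying near the deepest z (within
    ``near_bottom_vox`` of the bottom; default twice the slab thickness).
    Raises if the rule removes every component.
    """
    if near_bottom_vox is None:
        near_bottom_vox = 2 * max_thickness_vox
    labeled = labeled.copy()
    labels = [l for l in np.unique(labeled) if l != 0]
    if not labels:
        raise EmptySegmentationError("no components to classify")
    kept = 0
    for label in labels:
        if _component_is_plate(
            labeled, label, footprint_fraction, max_thickness_vox, near_bottom_vox
        ):
            labeled[labeled == label] = 0
        else:
            kept += 1
    if kept == 0:
        raise EmptySegmentationError("plate-removal rule removed all components")
    return labeled


def segment_spheroid(
    intensity_db: np.ndarray,
    threshold_db: float,
    connectivity: int = 1,
    voxel_volume_mm3: float = 1.0,
    z_exclude: Optional[tuple[int, int]] = None,
    plate_footprint_fraction: float = 0.8,
    plate_max_thickness_vox: int = 6,
) -> SpheroidMask:
    """Threshold + connected-component segmentation of the spheroid.

    Voxels strictly above ``threshold_db`` are labeled into connected
    components (``connectivity=1`` is 6-connectivity).  The well-plate
    bottom is removed automatically (see :func:`remove_plate`) unless a
    manual ``z_exclude=(z_lo, z_hi)`` half-open depth range is given, in
    which case those planes are excluded before labeling instead.  The
    spheroid is the largest remaining component.
    """
    intensity_db = np.asarray(intensity_db, dtype=float)
    if intensity_db.ndim != 3:
        raise ValueError("intensity volume must be 3D (y, z, x)")
    if not np.all(np.isfinite(intensity_db)):
        raise ValueError("intensity volume must be finite")
    if not intensity_db.min() <= threshold_db <= intensity_db.max():
        warnings.warn(
            f"threshold {threshold_db} dB lies outside the data range "
            f"[{intensity_db.min():.2f}, {intensity_db.max():.2f}] dB",
            stacklevel=2,
        )
    binary = intensity_db > threshold_db
    if z_exclude is not None:
        z_lo, z_hi = z_exclude
        binary[:, z_lo:z_hi, :] = False
    if not binary.any():
        raise EmptySegmentationError("no voxel above the intensity threshold")
    labeled = measure.label(binary, connectivity=connectivity)
    if z_exclude is None:
        labeled = remove_plate(
            labeled,
            footprint_fraction=plate_footprint_fraction,
            max_thickness_vox=plate_max_thickness_vox,
        )
    labels, counts = np.unique(labeled[labeled > 0], return_counts=True)
    spheroid_label = labels[np.argmax(counts)]
    return SpheroidMask(
        mask=labeled == spheroid_label,
        voxel_volume_mm3=voxel_volume_mm3,
        provenance={
            "threshold_db": threshold_db,
            "connectivity": connectivity,
            "z_exclude": z_exclude,
            "plate_footprint_fraction": plate_footprint_fraction,
            "plate_max_thickness_vox": plate_max_thickness_vox,
        },
    )


def quantify_spheroid(
    mask: SpheroidMask,
    maps: DynamicsMaps,
    liv_cutoff: float = DEFAULT_LIV_CUTOFF_DB2,
    ocdsl_cutoff: float = DEFAULT_OCDSL_CUTOFF_MS_INV,
) -> SpheroidQuant:
    """Volume, mean dynamics and necrotic cell ratios over the mask.

    Necrotic ratio = (voxels with metric strictly below the cutoff) /
    (all spheroid voxels), separately for LIV and OCDS_l.
    """
    if liv_cutoff <= 0 or ocdsl_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    if mask.mask.shape != maps.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match maps shape {maps.shape}"
        )
    m = mask.mask
    n = mask.n_voxels
    liv = maps.liv[m]
    ocdsl = maps.ocds_l[m]
    return SpheroidQuant(
        volume_mm3=n * mask.voxel_volume_mm3,
        mean_liv_db2=float(liv.mean()),
        mean_ocdsl_ms_inv=float(ocdsl.mean()),
        necrotic_ratio_liv=float(np.count_nonzero(liv < liv_cutoff)) / n,
        necrotic_ratio_ocdsl=float(np.count_nonzero(ocdsl < ocdsl_cutoff)) / n,
        cutoffs=(liv_cutoff, ocdsl_cutoff),
    )
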