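"""Reading and writing time-sequential OCT volumes.

Two on-disk dialects are supported and auto-detected by :func:`read_volume`:

* a single HDF5 file with datasets ``/intensity`` (y, t, z, x) and
  ``/timestamps`` (ms), optional ``/labels`` (y, z, x), and the scan
  protocol stored as root attributes;
* a directory of multi-page TIFF stacks, one stack per B-scan location
  (``loc0000.tif`` ... pages = repeats, each page one (z, x) frame), with a
  ``metadata.yaml`` sidecar holding the protocol, scale and timestamps.

Round-trips preserve the data bit-exactly and the metadata fields exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import tifffile
import yaml

from .metrics import DynamicsMaps
from .protocol import ScanProtocol
from .volume import TimeSequenceVolume

_PROTOCOL_FIELDS = [f.name for f in dataclasses.fields(ScanProtocol)]


def write_volume_h5(
    path: str | Path,
    volume: TimeSequenceVolume,
    labels: Optional[np.ndarray] = None,
) -> None:
    """Write a volume (and optional ground-truth label volume) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=volume.data)
        f.create_dataset("timestamps", data=volume.timestamps_ms)
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels))
        f.attrs["scale"] = volume.scale
        for name in _PROTOCOL_FIELDS:
            f.attrs[name] = getattr(volume.protocol, name)


def read_volume_h5(path: str | Path, with_labels: bool = False):
    with h5py.File(path, "r") as f:
        protocol = ScanProtocol(
            **{
                name: (int(f.attrs[name]) if isinstance(f.attrs[name], (int, np.integer)) else float(f.attrs[name]))
                for name in _PROTOCOL_FIELDS
            }
        )
        volume = TimeSequenceVolume(
            data=f["intensity"][()],
            protocol=protocol,
            timestamps_ms=f["timestamps"][()],
            scale=str(f.attrs["scale"]),
        )
        labels = f["labels"][()] if with_labels and "labels" in f else None
    return (volume, labels) if with_labels else volume


def write_volume_tiff(dirpath: str | Path, volume: TimeSequenceVolume) -> None:
    """Write one multi-page TIFF per B-scan location plus a YAML sidecar."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    for y in range(volume.n_locations):
        tifffile.imwrite(dirpath / f"loc{y:04d}.tif", volume.data[y], photometric="minisblack")
    meta = {
        "scale": volume.scale,
        "timestamps_ms": [float(t) for t in volume.timestamps_ms],
        "protocol": {name: getattr(volume.protocol, name) for name in _PROTOCOL_FIELDS},
    }
    (dirpath / "metadata.yaml").write_text(yaml.safe_dump(meta))


def read_volume_tiff(dirpath: str | Path) -> TimeSequenceVolume:
    dirpath = Path(dirpath)
    meta = yaml.safe_load((dirpath / "metadata.yaml").read_text())
    stacks = sorted(dirpath.glob("loc*.tif"))
    if not stacks:
        raise FileNotFoundError(f"no loc*.tif stacks found in {dirpath}")
    data = np.stack([tifffile.imread(p) for p in stacks])
    return TimeSequenceVolume(
        data=data,
        protocol=ScanProtocol(**meta["protocol"]),
        timestamps_ms=np.asarray(meta["timestamps_ms"], dtype=float),
        scale=meta["scale"],
    )


def read_volume(path: str | Path, with_labels: bool = False):
    """Auto-detect the dialect: a directory reads as TIFF, a file as HDF5."""
    path = Path(path)
    if path.is_dir():
        vol = read_volume_tiff(path)
        return (vol, None) if with_labels else vol
    return read_volume_h5(path, with_labels=with_labels)


def write_dynamics_maps(path: str | Path, maps: DynamicsMaps) -> None:
    """Persist a DynamicsMaps container to HDF5 with provenance attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("liv", data=maps.liv)
        f.create_dataset("ocds_l", data=maps.ocds_l)
        f.create_dataset("ocds_l_valid", data=maps.ocds_l_valid)
        f.create_dataset("mean_intensity_db", data=maps.mean_intensity_db)
        if maps.ocds_e is not None:
            f.create_dataset("ocds_e", data=maps.ocds_e)
            f.create_dataset("ocds_e_valid", data=maps.ocds_e_valid)
        prov = dict(maps.provenance)
        protocol = prov.pop("protocol", None)
        if protocol is not None:
            for name in _PROTOCOL_FIELDS:
                f.attrs[name] = getattr(protocol, name)
        for key, value in prov.items():
            f.attrs[key] = value


def read_dynamics_maps(path: str | Path) -> DynamicsMaps:
    with h5py.File(path, "r") as f:
        protocol = None
        if all(name in f.attrs for name in _PROTOCOL_FIELDS):
            protocol = ScanProtocol(
                **{
                    name: (int(f.attrs[name]) if isinstance(f.attrs[name], (int, np.integer)) else float(f.attrs[name]))
                    for name in _PROTOCOL_FIELDS
                }
            )
        prov = {
            key: tuple(v) if isinstance(v := f.attrs[key], np.ndarray) else v
            for key in f.attrs
            if key not in _PROTOCOL_FIELDS
        }
        if protocol is not None:
            prov["protocol"] = protocol
        return DynamicsMaps(
            liv=f["liv"][()],
            ocds_l=f["ocds_l"][()],
            ocds_l_valid=f["ocds_l_valid"][()],
            mean_intensity_db=f["mean_intensity_db"][()],
            ocds_e=f["ocds_e"][()] if "ocds_e" in f else None,
            ocds_e_valid=f["ocds_e_valid"][()] if "ocds_e_valid" in f else None,
            provenance=prov,
        )
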