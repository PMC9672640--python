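"""Readers and writers: NIfTI / DICOM-series volumes, manifests, bag caches.

Volume I/O goes through SimpleITK, which handles both `.nii`/`.nii.gz` files
and DICOM series directories. Arrays are reordered to this package's
``(x, y, z)`` axis convention (SimpleITK arrays arrive as ``(z, y, x)``).

Bags are cached as ``.npz`` containers with a JSON sidecar recording the
window, target size and normalization used to build them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .preprocess import CTVolume, TumorBag, TumorCuboid

MANIFEST_COLUMNS = ["bag_id", "path", "center_x", "center_y", "center_z", "label"]

__all__ = [
    "read_volume",
    "write_volume",
    "write_cuboid",
    "read_manifest",
    "write_manifest",
    "save_bag",
    "load_bag",
    "MANIFEST_COLUMNS",
]


def read_volume(path: str | Path, id: str | None = None) -> CTVolume:
    """Read a NIfTI file or a DICOM series directory into a CTVolume."""
    path = Path(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise ValueError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        image = reader.Execute()
    else:
        image = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(image).transpose(2, 1, 0)  # (z,y,x)->(x,y,z)
    spacing = tuple(float(s) for s in image.GetSpacing())
    return CTVolume(voxels.astype(float), spacing, id=id or path.stem)


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a CTVolume as NIfTI."""
    image = sitk.GetImageFromArray(volume.voxels.transpose(2, 1, 0))
    image.SetSpacing(volume.spacing)
    sitk.WriteImage(image, str(path))


def write_cuboid(cuboid: TumorCuboid, path: str | Path) -> None:
    """Persist a standardized cuboid as NIfTI (1 mm isotropic)."""
    write_volume(CTVolume(cuboid.voxels, (1.0, 1.0, 1.0), cuboid.source_id), path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the bag manifest CSV and check its schema.

    Columns: ``bag_id, path, center_x, center_y, center_z, label`` with
    centers as 0-based voxel coordinates in the 1 mm resampled grid.
    """
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["bag_id"].duplicated().any():
        raise ValueError("manifest contains duplicate bag_id values")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def save_bag(bag: TumorBag, path: str | Path) -> None:
    """Save a bag as ``.npz`` plus a JSON sidecar describing its provenance."""
    path = Path(path)
    np.savez_compressed(
        path,
        instances=bag.instances,
        label=np.array(-1 if bag.label is None else int(bag.label)),
    )
    sidecar = {"bag_id": bag.bag_id, **{k: _jsonable(v) for k, v in bag.meta.items()}}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_bag(path: str | Path) -> TumorBag:
    path = Path(path)
    with np.load(path) as data:
        instances = data["instances"]
        label = int(data["label"])
    meta = {}
    bag_id = path.stem
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        bag_id = meta.pop("bag_id", bag_id)
    return TumorBag(
        instances, label=None if label < 0 else label, bag_id=bag_id, meta=meta
    )


def _jsonable(value):
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    if isinstance(value, (tuple, list)):
        return [_jsonable(v) for v in value]
    return value
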