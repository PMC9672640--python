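"""CT preprocessing: isotropic resampling, tumor-cuboid cropping, bag building.

The pipeline standardizes heterogeneous clinical CT (varying slice thickness
and pixel size) into a fixed-geometry tumor cuboid and then into a bag of
per-slice instances for multiple-instance learning:

1. :func:`resample_isotropic` — trilinear resampling to 1x1x1 mm voxels.
2. :func:`crop_tumor_cuboid` — a 64x64x32-voxel cuboid centred on the tumor,
   padded with air (-1000 HU) where it overhangs the scan.
3. :func:`build_bag` — each of the 32 axial slices is intensity-windowed,
   mapped to [0, 1], bilinearly resized to the backbone's input size,
   replicated to 3 channels and standardized with the backbone's
   natural-image channel statistics.

Axes are ordered ``(x, y, z)``; axial slices are constant-``z`` planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

CUBOID_SHAPE = (64, 64, 32)
DEFAULT_WINDOW = (-1000.0, 400.0)  # lung-mass window: air through soft tissue
PAD_HU = -1000.0
# conventional channel statistics of ImageNet-pretrained backbones
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

__all__ = [
    "CTVolume",
    "TumorCuboid",
    "TumorBag",
    "resample_isotropic",
    "crop_tumor_cuboid",
    "build_bag",
    "CUBOID_SHAPE",
    "DEFAULT_WINDOW",
    "PAD_HU",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]


@dataclass
class CTVolume:
    """A 3-D scalar field in Hounsfield units with per-axis voxel spacing."""

    voxels: np.ndarray  # (nx, ny, nz), HU
    spacing: tuple[float, float, float]  # mm per voxel along (x, y, z)
    id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def is_isotropic(self, spacing: float = 1.0, tol: float = 1e-6) -> bool:
        return all(abs(s - spacing) <= tol for s in self.spacing)


@dataclass
class TumorCuboid:
    """A standardized 64x64x32 HU cuboid cropped around a tumor center."""

    voxels: np.ndarray  # (64, 64, 32), HU
    source_id: str = ""
    center: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.shape != CUBOID_SHAPE:
            raise ValueError(f"cuboid shape must be {CUBOID_SHAPE}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("cuboid values must be finite")


@dataclass
class TumorBag:
    """A bag of K per-slice instances ready for the backbone.

    ``instances`` has shape ``(K, S, S, 3)``; the three channels are
    replicates of the same windowed slice, standardized per channel. ``label``
    is 1 for response, 0 for nonresponse, ``None`` when unknown.
    """

    instances: np.ndarray
    label: int | None = None
    bag_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=float)
        if self.instances.ndim != 4 or self.instances.shape[-1] != 3:
            raise ValueError("instances must have shape (K, S, S, 3)")
        if self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance")
        if not np.all(np.isfinite(self.instances)):
            raise ValueError("instance values must be finite")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]


def resample_isotropic(volume: CTVolume, target_spacing: float = 1.0) -> CTVolume:
    """Resample to isotropic voxels by trilinear interpolation.

    The output grid has ``round(dim * spacing / target)`` voxels per axis
    (at least 1). Output voxel ``i`` sits at physical coordinate
    ``i * target_spacing`` measured from the first input voxel; values come
    from trilinear interpolation in physical coordinates, clamped at the
    volume border.
    """
    if not np.isfinite(target_spacing) or target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    in_shape = volume.shape
    in_spacing = volume.spacing
    out_shape = tuple(
        max(1, int(round(d * s / target_spacing)))
        for d, s in zip(in_shape, in_spacing)
    )
    if out_shape == in_shape and volume.is_isotropic(target_spacing):
        return CTVolume(volume.voxels.copy(), (target_spacing,) * 3, volume.id)
    axes = [
        np.arange(n) * target_spacing / sp for n, sp in zip(out_shape, in_spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        volume.voxels, np.stack(coords), order=1, mode="nearest"
    )
    return CTVolume(out, (target_spacing,) * 3, volume.id)


def crop_tumor_cuboid(
    volume: CTVolume,
    center: tuple[int, int, int],
    pad_value: float = PAD_HU,
) -> TumorCuboid:
    """Crop a 64x64x32 cuboid centred on ``center`` from a 1 mm volume.

    With even extents the center voxel occupies index ``extent // 2`` on each
    axis (i.e. the low side takes ``extent // 2`` voxels, the high side the
    remaining ``extent - extent // 2 - 1``). Out-of-grid positions are filled
    with ``pad_value`` (air by default).
    """
    if not volume.is_isotropic(1.0):
        raise ValueError("crop requires a volume resampled to 1 mm isotropic")
    center = tuple(int(c) for c in center)
    if len(center) != 3:
        raise ValueError("center must be a 3-vector of voxel indices")
    for c, n in zip(center, volume.shape):
        if not (0 <= c < n):
            raise ValueError(f"center {center} outside volume of shape {volume.shape}")
    out = np.full(CUBOID_SHAPE, float(pad_value))
    los = [c - e // 2 for c, e in zip(center, CUBOID_SHAPE)]
    src, dst = [], []
    for lo, e, n in zip(los, CUBOID_SHAPE, volume.shape):
        s0, s1 = max(lo, 0), min(lo + e, n)
        src.append(slice(s0, s1))
        dst.append(slice(s0 - lo, s1 - lo))
    out[tuple(dst)] = volume.voxels[tuple(src)]
    return TumorCuboid(out, source_id=volume.id, center=center)


def _resize_bilinear(image: np.ndarray, size: int) -> np.ndarray:
    """Resize a 2-D image with bilinear interpolation.

    Pixel centres align under the area convention: output pixel ``i`` samples
    input coordinate ``(i + 0.5) * n_in / n_out - 0.5``, clamped at borders.
    """
    h, w = image.shape
    if (h, w) == (size, size):
        return image.copy()
    ys = (np.arange(size) + 0.5) * h / size - 0.5
    xs = (np.arange(size) + 0.5) * w / size - 0.5
    grid = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(image, np.stack(grid), order=1, mode="nearest")


def build_bag(
    cuboid: TumorCuboid,
    window: tuple[float, float] = DEFAULT_WINDOW,
    target_size: int = 224,
    label: int | None = None,
    bag_id: str = "",
    channel_mean: tuple[float, float, float] = IMAGENET_MEAN,
    channel_std: tuple[float, float, float] = IMAGENET_STD,
    standardize: bool = True,
) -> TumorBag:
    """Turn a cuboid into a bag of 32 three-channel instances.

    Each axial slice (in z order) is clipped to ``window``, mapped linearly to
    [0, 1], bilinearly resized to ``target_size`` square, replicated into
    three identical channels and, when ``standardize``, shifted/scaled by the
    backbone's per-channel natural-image statistics.
    """
    lo, hi = float(window[0]), float(window[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError("window must be a finite interval with lower < upper")
    if target_size < 8:
        raise ValueError("target_size must be at least 8 pixels")
    k = cuboid.voxels.shape[2]
    instances = np.empty((k, target_size, target_size, 3))
    mean = np.asarray(channel_mean, dtype=float)
    std = np.asarray(channel_std, dtype=float)
    if np.any(std <= 0):
        raise ValueError("channel_std must be positive")
    for z in range(k):
        sl = np.clip(cuboid.voxels[:, :, z], lo, hi)
        sl = (sl - lo) / (hi - lo)
        sl = _resize_bilinear(sl, target_size)
        rgb = np.repeat(sl[:, :, None], 3, axis=2)
        if standardize:
            rgb = (rgb - mean) / std
        instances[z] = rgb
    return TumorBag(
        instances,
        label=label,
        bag_id=bag_id or cuboid.source_id,
        meta={
            "window": (lo, hi),
            "target_size": int(target_size),
            "channel_mean": tuple(mean),
            "channel_std": tuple(std),
            "standardized": bool(standardize),
            "source_id": cuboid.source_id,
            "center": tuple(cuboid.center),
        },
    )
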