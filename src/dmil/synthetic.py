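"""Seeded synthetic cohorts with the MIL structure the model assumes.

Two generators emulate the study's response/nonresponse bags without any
clinical data:

* :func:`generate_image_cohort` — CT-like volumes: lung-density Gaussian
  background (mean -700 HU), an ellipsoidal soft-tissue tumor (mean +30 HU)
  at a recorded center, and — in positive bags only — an additive textured
  signal on a random subset of the tumor's axial slices. That per-slice
  injection is the standard MIL assumption: a positive bag contains at least
  one positive instance, a negative bag contains none, and the ground-truth
  signal slices give attention weights a localization target.
* :func:`generate_embedding_cohort` — the same bag structure directly in
  embedding space (unit-variance Gaussian instances, signal instances shifted
  by ``signal_effect`` standard deviations along a fixed random direction),
  bypassing imaging for fast pooling/training tests.

Everything is fully determined by ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .preprocess import CTVolume, CUBOID_SHAPE
from .training import LabeledBag

__all__ = [
    "SyntheticConfig",
    "ImageCohort",
    "EmbeddingCohort",
    "generate_image_cohort",
    "generate_embedding_cohort",
]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort generator.

    ``signal_effect`` is in HU for image cohorts and in instance-noise
    standard deviations for embedding cohorts. ``signal_fraction`` is the
    fraction of the bag's 32 slices carrying signal in positive bags (at
    least one slice is always signalled).
    """

    n_bags: int = 200
    prevalence: float = 0.5
    volume_shape: tuple[int, int, int] = (80, 80, 40)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius: tuple[float, float] = (8.0, 14.0)  # semi-axis range, mm
    signal_effect: float = 150.0  # 5 x noise_sd
    signal_fraction: float = 1.0
    noise_sd: float = 30.0
    background_hu: float = -700.0
    tumor_hu: float = 30.0
    n_instances: int = 32
    embedding_dim: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bags < 2:
            raise ValueError("n_bags must be at least 2")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if not 0 < self.signal_fraction <= 1:
            raise ValueError("signal_fraction must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.signal_effect < 0:
            raise ValueError("signal_effect must be non-negative")
        if self.tumor_radius[0] <= 0 or self.tumor_radius[0] > self.tumor_radius[1]:
            raise ValueError("tumor_radius must be a positive (low, high) range")
        if self.n_instances < 1 or self.embedding_dim < 1:
            raise ValueError("n_instances and embedding_dim must be positive")
        if any(int(s) < 2 for s in self.volume_shape):
            raise ValueError("volume_shape axes must be at least 2 voxels")

    @property
    def n_signal_instances(self) -> int:
        return max(1, int(np.floor(self.signal_fraction * self.n_instances + 0.5)))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImageCohort:
    """Synthetic CT-like volumes with tumor centers, labels and ground truth."""

    volumes: list[CTVolume]
    centers: np.ndarray  # (n, 3) voxel coordinates
    labels: np.ndarray  # (n,)
    signal_slices: list[list[int]]  # cuboid-relative z indices, [] for negatives
    bag_ids: list[str]
    config: SyntheticConfig

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bag_id": self.bag_ids,
                "path": ["" for _ in self.bag_ids],
                "center_x": self.centers[:, 0],
                "center_y": self.centers[:, 1],
                "center_z": self.centers[:, 2],
                "label": self.labels,
            }
        )


@dataclass
class EmbeddingCohort:
    """Embedding-level bags plus per-instance ground-truth signal masks."""

    bags: list[LabeledBag]
    signal_masks: list[np.ndarray]  # boolean (K,) per bag
    config: SyntheticConfig = field(default=None)  # type: ignore[assignment]

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags])


def _balanced_labels(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(np.floor(config.prevalence * config.n_bags + 0.5))
    n_pos = min(max(n_pos, 1), config.n_bags - 1)
    labels = np.zeros(config.n_bags, dtype=int)
    labels[:n_pos] = 1
    return labels[rng.permutation(config.n_bags)]


def generate_image_cohort(config: SyntheticConfig) -> ImageCohort:
    """Generate CT-like volumes with an ellipsoidal tumor and slice-level signal.

    Positive bags receive an additive textured signal of mean magnitude
    ``signal_effect`` HU inside the tumor cross-section on
    ``max(1, round(signal_fraction * 32))`` randomly chosen tumor slices
    (capped at the number of slices the tumor spans inside the cuboid's
    z-range). Negative bags receive none.
    """
    rng = derive_rng(config.seed, "image-cohort")
    shape = tuple(int(s) for s in config.volume_shape)
    labels = _balanced_labels(config, rng)
    half_z = CUBOID_SHAPE[2] // 2
    volumes, centers, signal_slices, bag_ids = [], [], [], []
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    )
    for i, label in enumerate(labels):
        vox = rng.normal(config.background_hu, config.noise_sd, shape)
        center = np.array(
            [s // 2 + rng.integers(-3, 4) for s in shape], dtype=int
        )
        semi = rng.uniform(config.tumor_radius[0], config.tumor_radius[1], 3)
        semi = np.minimum(semi, np.array(shape) / 2.0 - 1.0)
        inside = (
            np.sum(((grid - center[:, None, None, None]) / semi[:, None, None, None]) ** 2, axis=0)
            <= 1.0
        )
        vox[inside] = rng.normal(config.tumor_hu, config.noise_sd, int(inside.sum()))
        chosen: list[int] = []
        if label == 1:
            z_lo = max(int(np.ceil(center[2] - semi[2])), center[2] - half_z, 0)
            z_hi = min(
                int(np.floor(center[2] + semi[2])),
                center[2] + half_z - 1,
                shape[2] - 1,
            )
            eligible = np.arange(z_lo, z_hi + 1)
            m = min(config.n_signal_instances, len(eligible))
            picked = np.sort(rng.choice(eligible, size=m, replace=False))
            for z in picked:
                mask = inside[:, :, z]
                texture = rng.uniform(0.5, 1.5, int(mask.sum()))
                vox[:, :, z][mask] += config.signal_effect * texture
            chosen = [int(z - (center[2] - half_z)) for z in picked]
        volumes.append(CTVolume(vox, config.spacing, id=f"synth-{i:04d}"))
        centers.append(center)
        signal_slices.append(chosen)
        bag_ids.append(f"synth-{i:04d}")
    return ImageCohort(
        volumes=volumes,
        centers=np.array(centers),
        labels=labels,
        signal_slices=signal_slices,
        bag_ids=bag_ids,
        config=config,
    )


def generate_embedding_cohort(config: SyntheticConfig) -> EmbeddingCohort:
    """Generate embedding-level bags with the MIL signal structure.

    Negative-bag instances are standard-normal around a zero mean; in positive
    bags, ``max(1, round(signal_fraction * K))`` instances are shifted by
    ``signal_effect`` (in noise standard deviations) along a fixed random unit
    direction drawn once per cohort.
    """
    rng = derive_rng(config.seed, "embedding-cohort")
    k, d = config.n_instances, config.embedding_dim
    labels = _balanced_labels(config, rng)
    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)
    bags, masks = [], []
    for i, label in enumerate(labels):
        E = rng.normal(size=(k, d))
        mask = np.zeros(k, dtype=bool)
        if label == 1:
            m = config.n_signal_instances
            idx = rng.choice(k, size=m, replace=False)
            mask[idx] = True
            E[idx] += config.signal_effect * direction
        bags.append(LabeledBag(f"embed-{i:04d}", E, int(label)))
        masks.append(mask)
    return EmbeddingCohort(bags=bags, signal_masks=masks, config=config)
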