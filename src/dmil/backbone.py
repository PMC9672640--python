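"""Shared-weight convolutional backbones and per-instance feature extraction.

Every instance (slice) of a bag passes through the *same* convolutional
feature extractor — weight sharing across instances is what makes the model a
MIL architecture rather than K independent classifiers. The extractor ends at
its last convolutional feature maps; global average pooling then reduces the
``(K, D, h, w)`` maps to a ``(K, D)`` embedding matrix, one D-vector per
slice.

Two backbones are defined in-repo:

* ``vgg16`` — the standard 13-convolution VGG16 feature stack (3x3 convs,
  2x2 max pools); on 224x224 inputs it produces 512-channel 7x7 maps, so a
  32-instance bag yields a 32 x 512 x 7 x 7 tensor. Randomly initialized by
  default; pretrained weights can be loaded from a checkpoint.
* ``tiny_test`` — two stride-2 conv blocks (16 then 8 channels) on 32x32
  inputs, giving (K, 8, 8, 8) maps; it keeps the full pipeline CPU-testable
  in seconds.

Further architectures plug in through :func:`register_backbone`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from . import nn
from .preprocess import TumorBag

__all__ = [
    "BackboneSpec",
    "Backbone",
    "register_backbone",
    "build_backbone",
    "available_backbones",
    "extract_instance_features",
    "global_average_pool",
    "save_backbone",
    "load_backbone",
]

# VGG16 feature-stack configuration: channel widths, "M" = 2x2 max pool
_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M")


@dataclass
class BackboneSpec:
    """Declarative description of a backbone: name, input size, feature dim."""

    name: str = "vgg16"
    input_size: int = 224
    feature_dim: int = 512
    pretrained: bool = False
    trainable_depth: str = "all"  # all | head_only

    def __post_init__(self) -> None:
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        if self.input_size < 8:
            raise ValueError("input_size must be at least 8")
        if self.trainable_depth not in ("all", "head_only"):
            raise ValueError("trainable_depth must be 'all' or 'head_only'")


class Backbone:
    """A built feature extractor: spec + layer stack."""

    def __init__(self, spec: BackboneSpec, net: nn.Sequential) -> None:
        self.spec = spec
        self.net = net

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def parameters(self) -> list[nn.Parameter]:
        return self.net.parameters()


def _build_vgg16(spec: BackboneSpec, rng: np.random.Generator) -> Backbone:
    layers: list[nn.Module] = []
    cin = 3
    for item in _VGG16_CFG:
        if item == "M":
            layers.append(nn.MaxPool2d())
        else:
            layers.append(
                nn.Conv2d(cin, int(item), 3, stride=1, padding=1, rng=rng,
                          dtype=np.float32)
            )
            layers.append(nn.ReLU())
            cin = int(item)
    return Backbone(spec, nn.Sequential(*layers))


def _build_tiny(spec: BackboneSpec, rng: np.random.Generator) -> Backbone:
    net = nn.Sequential(
        nn.Conv2d(3, 16, 3, stride=2, padding=1, rng=rng),
        nn.ReLU(),
        nn.Conv2d(16, 8, 3, stride=2, padding=1, rng=rng),
        nn.ReLU(),
    )
    return Backbone(spec, net)


def _unavailable(name: str) -> Callable:
    def build(spec: BackboneSpec, rng: np.random.Generator) -> Backbone:
        raise NotImplementedError(
            f"backbone {name!r} has no in-repo definition; register a builder "
            "with dmil.backbone.register_backbone"
        )

    return build


_REGISTRY: dict[str, Callable[[BackboneSpec, np.random.Generator], Backbone]] = {
    "vgg16": _build_vgg16,
    "tiny_test": _build_tiny,
    "alexnet": _unavailable("alexnet"),
    "resnet34": _unavailable("resnet34"),
    "densenet": _unavailable("densenet"),
    "mobilenet_v2": _unavailable("mobilenet_v2"),
}

_DEFAULT_SPECS = {
    "vgg16": dict(input_size=224, feature_dim=512),
    "tiny_test": dict(input_size=32, feature_dim=8),
}


def register_backbone(
    name: str,
    builder: Callable[[BackboneSpec, np.random.Generator], Backbone],
) -> None:
    """Add (or replace) a backbone builder in the registry."""
    _REGISTRY[name] = builder


def available_backbones() -> list[str]:
    return sorted(_REGISTRY)


def default_spec(name: str, **overrides) -> BackboneSpec:
    """Spec with the registry's conventional input size / feature dim."""
    base = dict(_DEFAULT_SPECS.get(name, {}))
    base.update(overrides)
    return BackboneSpec(name=name, **base)


def build_backbone(
    spec: BackboneSpec | str, rng: np.random.Generator | None = None
) -> Backbone:
    """Instantiate a backbone from its spec (or name), seeded by ``rng``."""
    if isinstance(spec, str):
        spec = default_spec(spec)
    if spec.name not in _REGISTRY:
        raise ValueError(
            f"unknown backbone {spec.name!r}; available: {available_backbones()}"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    return _REGISTRY[spec.name](spec, rng)


def extract_instance_features(
    bag: TumorBag | np.ndarray,
    backbone: Backbone,
    train: bool = False,
    batch_size: int | None = None,
) -> np.ndarray:
    """Run every instance through the shared-weight backbone.

    Returns per-instance feature maps of shape ``(K, D, h, w)``. The same
    parameters are applied to every instance; ``batch_size`` only controls how
    many instances share one forward call and does not affect the result.
    """
    instances = bag.instances if isinstance(bag, TumorBag) else np.asarray(bag)
    k, s1, s2, c = instances.shape
    if c != 3:
        raise ValueError("instances must have 3 channels")
    if (s1, s2) != (backbone.spec.input_size,) * 2:
        raise ValueError(
            f"instances are {s1}x{s2} but backbone expects "
            f"{backbone.spec.input_size}x{backbone.spec.input_size}"
        )
    x = instances.transpose(0, 3, 1, 2)
    first_dtype = backbone.parameters()[0].value.dtype
    x = x.astype(first_dtype)
    if batch_size is None or batch_size >= k:
        return np.asarray(backbone.forward(x, train=train))
    if train:
        raise ValueError("chunked extraction is inference-only")
    chunks = [
        backbone.forward(x[i : i + batch_size], train=False)
        for i in range(0, k, batch_size)
    ]
    return np.concatenate(chunks, axis=0)


def global_average_pool(maps: np.ndarray) -> np.ndarray:
    """Average each feature map over its spatial grid: (K, D, h, w) -> (K, D)."""
    maps = np.asarray(maps)
    if maps.ndim != 4:
        raise ValueError("expected feature maps of shape (K, D, h, w)")
    if not np.all(np.isfinite(maps)):
        raise ValueError("feature maps must be finite")
    return maps.mean(axis=(2, 3))


def save_backbone(backbone: Backbone, path: str | Path) -> None:
    """Save parameters as ``.npz`` with a JSON metadata sidecar."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(backbone.parameters())}
    np.savez(path, **arrays)
    meta = asdict(backbone.spec)
    meta["n_params"] = len(arrays)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_backbone(path: str | Path) -> Backbone:
    """Rebuild a backbone from an ``.npz`` checkpoint and its JSON sidecar."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    meta.pop("n_params", None)
    spec = BackboneSpec(**meta)
    backbone = build_backbone(spec, np.random.default_rng(0))
    with np.load(path) as data:
        for i, p in enumerate(backbone.parameters()):
            loaded = data[f"p{i}"]
            if loaded.shape != p.value.shape:
                raise ValueError("checkpoint does not match architecture")
            p.value[...] = loaded
    return backbone
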