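"""Stratified splitting, supervised training of the MIL model, bag scoring.

The sample unit is the *bag* (one patient's 32-slice tumor cuboid): batches
are batches of bags, and every instance of a bag travels with it through the
shared-weight backbone, the pooling head and the classifier. Training
minimizes binary cross-entropy between the sigmoid bag score and the bag
label with Adam at the configured learning rate (default 1e-5, batch of 32
bags, 50 epochs), and returns the parameters of the epoch with the best
validation AUC.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from ._rng import derive_rng
from .backbone import Backbone, global_average_pool
from .evaluation import ScoredCohort, roc_auc
from .mil_pooling import BagClassifier, make_pooling_head
from .preprocess import TumorBag

__all__ = [
    "TrainConfig",
    "SplitManifest",
    "LabeledBag",
    "MILModel",
    "TrainedModel",
    "split_stratified",
    "train_dmil",
    "predict_bags",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: lr 1e-5, 32 bags/batch, 50 epochs)."""

    learning_rate: float = 1e-5
    epochs: int = 50
    batch_bags: int = 32
    loss: str = "bce"
    seed: int = 0
    optimizer: str = "adam"
    checkpoint_criterion: str = "best_val_auc"  # or "last_epoch"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epochs < 1 or self.batch_bags < 1:
            raise ValueError("epochs and batch_bags must be at least 1")
        if self.loss != "bce":
            raise ValueError("only binary cross-entropy loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.checkpoint_criterion not in ("best_val_auc", "last_epoch"):
            raise ValueError("unknown checkpoint_criterion")


@dataclass
class SplitManifest:
    """Disjoint train/validation/test bag-id lists from a stratified split."""

    train: list[str]
    validation: list[str]
    test: list[str]
    ratios: tuple[float, float, float]
    seed: int

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class LabeledBag:
    """A training item: instance images (K,S,S,3) or embeddings (K,D) + label."""

    bag_id: str
    data: np.ndarray
    label: int | None = None

    @classmethod
    def from_tumor_bag(cls, bag: TumorBag) -> "LabeledBag":
        return cls(bag.bag_id, bag.instances, bag.label)


def _largest_remainder(total: int, ratios: np.ndarray) -> np.ndarray:
    """Apportion ``total`` items to ratios: floors, then remainders largest
    first (ties toward the earlier split)."""
    quotas = total * ratios
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    # stable sort descending by fractional part -> earlier split wins ties
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def split_stratified(
    manifest: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> SplitManifest:
    """Randomly split bags into train/validation/test, stratified by label.

    Sizes follow a stratified largest-remainder rule: per-class quotas
    ``ratio * n_class`` are rounded by largest remainder, then reconciled so
    the split totals equal the largest-remainder apportionment of the whole
    cohort. Assignment within a class is a seeded permutation; the result is
    invariant to manifest row order.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    if not {"bag_id", "label"} <= set(manifest.columns):
        raise ValueError("manifest needs bag_id and label columns")
    labels = manifest["label"]
    if labels.isna().any():
        raise ValueError("every bag must be labelled for a stratified split")
    if manifest["bag_id"].duplicated().any():
        raise ValueError("duplicate bag_id in manifest")

    rvec = np.asarray(ratios)
    by_class = {
        c: sorted(str(b) for b in manifest.loc[labels == c, "bag_id"])
        for c in sorted(labels.unique())
    }
    for c, ids in by_class.items():
        if len(ids) < len(ratios):
            raise ValueError(f"class {c} has fewer bags than splits")

    global_sizes = _largest_remainder(len(manifest), rvec)
    per_class = {c: _largest_remainder(len(ids), rvec) for c, ids in by_class.items()}

    # reconcile per-class sums against the global apportionment by moving one
    # bag at a time from a surplus split to a deficit split, choosing the
    # class whose fractional quota most favors the deficit split
    def totals() -> np.ndarray:
        return np.sum(list(per_class.values()), axis=0)

    guard = 0
    while not np.array_equal(totals(), global_sizes):
        guard += 1
        if guard > 10 * len(manifest):  # pragma: no cover - safety net
            raise RuntimeError("split reconciliation failed to converge")
        diff = totals() - global_sizes
        s_from = int(np.argmax(diff))
        s_to = int(np.argmin(diff))
        best_c, best_key = None, None
        for c, counts in per_class.items():
            if counts[s_from] == 0:
                continue
            frac = len(by_class[c]) * rvec[s_to] - counts[s_to]
            key = (frac, counts[s_from])
            if best_key is None or key > best_key:  # ties: earlier class wins
                best_c, best_key = c, key
        per_class[best_c][s_from] -= 1
        per_class[best_c][s_to] += 1

    rng = derive_rng(seed, "split")
    parts: tuple[list[str], list[str], list[str]] = ([], [], [])
    for c, ids in by_class.items():
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        n_tr, n_va, _ = per_class[c]
        parts[0].extend(shuffled[:n_tr])
        parts[1].extend(shuffled[n_tr : n_tr + n_va])
        parts[2].extend(shuffled[n_tr + n_va :])
    return SplitManifest(
        train=parts[0], validation=parts[1], test=parts[2],
        ratios=ratios, seed=int(seed),
    )


class MILModel:
    """Backbone (optional) + pooling head + bag classifier.

    With ``backbone=None`` the model consumes precomputed instance embeddings
    directly — useful for fast experiments on embedding-level bags.
    """

    def __init__(
        self,
        pooling: str,
        feature_dim: int,
        bag_size: int = 32,
        attention_dim: int = 128,
        backbone: Backbone | None = None,
        seed: int = 0,
    ) -> None:
        rng = derive_rng(seed, "model-init")
        self.backbone = backbone
        self.pooling_name = pooling
        self.pooling = make_pooling_head(
            pooling, feature_dim, bag_size=bag_size, attention_dim=attention_dim,
            rng=rng,
        )
        self.head = BagClassifier(feature_dim)
        self.feature_dim = feature_dim
        self._maps_shape = None

    @property
    def train_backbone(self) -> bool:
        return (
            self.backbone is not None
            and self.backbone.spec.trainable_depth == "all"
        )

    def trainable_parameters(self) -> list[nn.Parameter]:
        params = self.pooling.parameters() + self.head.parameters()
        if self.train_backbone:
            params = self.backbone.parameters() + params
        return params

    def all_parameters(self) -> list[nn.Parameter]:
        params = self.pooling.parameters() + self.head.parameters()
        if self.backbone is not None:
            params = self.backbone.parameters() + params
        return params

    def forward_bag(self, data: np.ndarray, train: bool = False) -> float:
        """Return the bag logit; caches intermediates when ``train``."""
        data = np.asarray(data)
        if self.backbone is not None:
            if data.ndim != 4:
                raise ValueError("backbone model expects (K, S, S, 3) instances")
            x = data.transpose(0, 3, 1, 2).astype(
                self.backbone.parameters()[0].value.dtype
            )
            maps = self.backbone.forward(x, train=train and self.train_backbone)
            self._maps_shape = maps.shape
            E = global_average_pool(maps)
        else:
            if data.ndim != 2:
                raise ValueError("embedding model expects a (K, D) matrix")
            E = data.astype(float)
        if E.shape[1] != self.feature_dim:
            raise ValueError(
                f"model built for D={self.feature_dim}, got D={E.shape[1]}"
            )
        z = self.pooling.forward(E, train=train)
        return self.head.forward(z, train=train)

    def backward_bag(self, dlogit: float) -> None:
        dz = self.head.backward(dlogit)
        dE = self.pooling.backward(dz)
        if self.train_backbone:
            k, d, h, w = self._maps_shape
            dmaps = np.broadcast_to(
                (dE / (h * w))[:, :, None, None], (k, d, h, w)
            ).astype(self.backbone.parameters()[0].value.dtype)
            self.backbone.backward(dmaps)

    def score_bag(self, data: np.ndarray) -> float:
        return float(nn.sigmoid(self.forward_bag(data, train=False)))

    def attention_weights(self, data: np.ndarray) -> np.ndarray | None:
        """Per-instance attention weights of the last scored bag, if any."""
        self.forward_bag(data, train=False)
        return getattr(self.pooling, "last_weights", None)

    def snapshot(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.all_parameters()]

    def restore(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.all_parameters(), values):
            p.value[...] = v


@dataclass
class TrainedModel:
    """A trained MIL model plus its config and per-epoch history."""

    model: MILModel
    config: TrainConfig
    history: pd.DataFrame
    best_epoch: int
    split: SplitManifest | None = None
    extras: dict = field(default_factory=dict)


def _cohort_from_scores(bags: list[LabeledBag], model: MILModel) -> ScoredCohort:
    return ScoredCohort(
        [b.bag_id for b in bags],
        np.array([model.score_bag(b.data) for b in bags]),
        np.array([int(b.label) for b in bags]),
    )


def train_dmil(
    train_bags: list[LabeledBag],
    val_bags: list[LabeledBag],
    model: MILModel,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train backbone + pooling + head on labelled bags.

    Runs ``config.epochs`` passes over seeded-shuffled mini-batches of
    ``config.batch_bags`` bags, minimizing mean binary cross-entropy between
    the sigmoid bag score and the bag label. Records per-epoch training loss
    and validation AUC, and finishes on the checkpoint selected by
    ``config.checkpoint_criterion`` (best validation AUC by default, last
    epoch when there is no validation set).
    """
    config = config or TrainConfig()
    if not train_bags:
        raise ValueError("training set is empty")
    labels = {int(b.label) for b in train_bags if b.label is not None}
    if len(labels) < 2:
        raise ValueError("training set must contain both classes")
    rng = derive_rng(config.seed, "train-shuffle")
    opt = nn.Adam(model.trainable_parameters(), lr=config.learning_rate)
    use_val = bool(val_bags) and config.checkpoint_criterion == "best_val_auc"
    best_metric, best_state, best_epoch = -np.inf, None, -1
    rows = []
    n = len(train_bags)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_bags):
            batch = order[start : start + config.batch_bags]
            opt.zero_grad()
            for i in batch:
                bag = train_bags[i]
                logit = model.forward_bag(bag.data, train=True)
                loss, dlogit = nn.bce_with_logits(
                    np.array([logit]), np.array([float(bag.label)])
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, bag {bag.bag_id}"
                    )
                model.backward_bag(float(dlogit[0]) / len(batch))
                epoch_losses.append(loss)
            opt.step()
        val_auc = np.nan
        if use_val:
            val_auc = roc_auc(_cohort_from_scores(val_bags, model)).auc
            if val_auc > best_metric:
                best_metric = val_auc
                best_state = model.snapshot()
                best_epoch = epoch
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_auc": float(val_auc),
            }
        )
    if use_val and best_state is not None:
        model.restore(best_state)
    else:
        best_epoch = config.epochs - 1
    return TrainedModel(
        model=model,
        config=copy.deepcopy(config),
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
    )


def predict_bags(
    model: TrainedModel | MILModel, bags: list[LabeledBag]
) -> list[tuple[str, float]]:
    """Score bags with a trained model; deterministic, evaluation mode."""
    mil = model.model if isinstance(model, TrainedModel) else model
    return [(b.bag_id, mil.score_bag(b.data)) for b in bags]
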