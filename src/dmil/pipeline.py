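"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

A single YAML-style config dict drives the run; the schema is validated up
front (unknown keys are rejected) and every output lands in one run
directory with enough provenance — config snapshot, seed, package version,
split manifest — to reproduce the run exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .backbone import Backbone, build_backbone, default_spec
from ._rng import derive_rng
from .evaluation import ScoredCohort, decision_curve, evaluate_cohort, roc_auc
from .mil_pooling import export_attention_csv, AttentionPoolHead
from .preprocess import build_bag, crop_tumor_cuboid, resample_isotropic
from .synthetic import SyntheticConfig, generate_image_cohort
from .training import (
    LabeledBag,
    MILModel,
    TrainConfig,
    predict_bags,
    split_stratified,
    train_dmil,
)

__all__ = ["validate_config", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("dmil")

_SCHEMA: dict[str, set[str] | None] = {
    "seed": None,
    "simulate": {
        "n_bags", "prevalence", "volume_shape", "spacing", "tumor_radius",
        "signal_effect", "signal_fraction", "noise_sd", "background_hu",
        "tumor_hu", "n_instances", "embedding_dim",
    },
    "input": {"manifest"},
    "preprocess": {"window", "size"},
    "model": {"backbone", "pooling", "attention_dim", "trainable_depth"},
    "train": {
        "learning_rate", "epochs", "batch_bags", "loss", "optimizer",
        "checkpoint_criterion",
    },
    "split": {"ratios"},
    "evaluate": {"cutoff", "ci_level", "ci_method"},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},
    "preprocess": {"window": [-1000, 400], "size": 32},
    "model": {"backbone": "tiny_test", "pooling": "attention"},
    "train": {},
    "split": {"ratios": [0.70, 0.10, 0.20]},
    "evaluate": {"cutoff": "youden", "ci_level": 0.95},
}


def validate_config(config: dict) -> dict:
    """Schema-check a run config; returns it with defaults filled in.

    Unknown keys at any level are rejected; ``model.pooling`` is required, as
    is exactly one bag source (``simulate`` or ``input``).
    """
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    unknown = set(config) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, allowed in _SCHEMA.items():
        if key in config and allowed is not None:
            section = config[key]
            if not isinstance(section, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            bad = set(section) - allowed
            if bad:
                raise ValueError(f"unknown keys in {key!r}: {sorted(bad)}")
    if "model" not in config or "pooling" not in config["model"]:
        raise ValueError("config must set model.pooling (max | conv | attention)")
    if ("simulate" in config) == ("input" in config):
        raise ValueError("config needs exactly one of 'simulate' or 'input'")
    merged = {
        "seed": int(config.get("seed", 0)),
        "preprocess": {**DEFAULT_CONFIG["preprocess"], **config.get("preprocess", {})},
        "model": {"backbone": "tiny_test", **config["model"]},
        "train": dict(config.get("train", {})),
        "split": {**DEFAULT_CONFIG["split"], **config.get("split", {})},
        "evaluate": {**DEFAULT_CONFIG["evaluate"], **config.get("evaluate", {})},
    }
    if "simulate" in config:
        merged["simulate"] = dict(config["simulate"])
    else:
        merged["input"] = dict(config["input"])
    return merged


def _load_bags_from_manifest(
    manifest: pd.DataFrame, pre_cfg: dict, root: Path
) -> list[LabeledBag]:
    bags = []
    window = tuple(pre_cfg["window"])
    size = int(pre_cfg["size"])
    for row in manifest.itertuples(index=False):
        volume = io.read_volume(root / str(row.path), id=str(row.bag_id))
        volume = resample_isotropic(volume, 1.0)
        cuboid = crop_tumor_cuboid(
            volume, (int(row.center_x), int(row.center_y), int(row.center_z))
        )
        bag = build_bag(
            cuboid, window=window, target_size=size,
            label=int(row.label), bag_id=str(row.bag_id),
        )
        bags.append(LabeledBag.from_tumor_bag(bag))
    return bags


def _bags_from_cohort(cohort, pre_cfg: dict) -> list[LabeledBag]:
    bags = []
    window = tuple(pre_cfg["window"])
    size = int(pre_cfg["size"])
    for vol, center, label, bag_id in zip(
        cohort.volumes, cohort.centers, cohort.labels, cohort.bag_ids
    ):
        volume = resample_isotropic(vol, 1.0)
        cuboid = crop_tumor_cuboid(volume, tuple(center))
        bag = build_bag(
            cuboid, window=window, target_size=size,
            label=int(label), bag_id=bag_id,
        )
        bags.append(LabeledBag.from_tumor_bag(bag))
    return bags


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the configured stages and write all artifacts to ``out_dir``."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        snapshot = {"config": cfg, "package_version": __version__}
        (out / "config.yaml").write_text(yaml.safe_dump(snapshot, sort_keys=False))
        seed = cfg["seed"]

        # --- bags -----------------------------------------------------------
        if "simulate" in cfg:
            sim = SyntheticConfig(**cfg["simulate"], seed=seed)
            cohort = generate_image_cohort(sim)
            log.info("simulated %d volumes", len(cohort.volumes))
            io.write_manifest(cohort.manifest(), out / "manifest.csv")
            (out / "signal_slices.json").write_text(
                json.dumps(dict(zip(cohort.bag_ids, cohort.signal_slices)))
            )
            bags = _bags_from_cohort(cohort, cfg["preprocess"])
        else:
            manifest_path = Path(cfg["input"]["manifest"])
            manifest = io.read_manifest(manifest_path)
            bags = _load_bags_from_manifest(
                manifest, cfg["preprocess"], manifest_path.parent
            )
        log.info("preprocessed %d bags", len(bags))
        by_id = {b.bag_id: b for b in bags}
        labels_df = pd.DataFrame(
            {"bag_id": [b.bag_id for b in bags], "label": [b.label for b in bags]}
        )

        # --- split / train ---------------------------------------------------
        split = split_stratified(
            labels_df, ratios=tuple(cfg["split"]["ratios"]), seed=seed
        )
        split.to_json(out / "split.json")
        model_cfg = cfg["model"]
        spec = default_spec(
            model_cfg["backbone"],
            trainable_depth=model_cfg.get("trainable_depth", "all"),
        )
        backbone: Backbone = build_backbone(spec, derive_rng(seed, "backbone-init"))
        model = MILModel(
            pooling=model_cfg["pooling"],
            feature_dim=spec.feature_dim,
            bag_size=bags[0].data.shape[0],
            attention_dim=int(model_cfg.get("attention_dim", 128)),
            backbone=backbone,
            seed=seed,
        )
        train_cfg = TrainConfig(**cfg["train"], seed=seed)
        trained = train_dmil(
            [by_id[b] for b in split.train],
            [by_id[b] for b in split.validation],
            model,
            train_cfg,
        )
        trained.history.to_csv(out / "history.csv", index=False)
        np.savez(
            out / "checkpoint.npz",
            **{f"p{i}": p.value for i, p in enumerate(model.all_parameters())},
        )
        log.info("trained %d epochs (best %d)", train_cfg.epochs, trained.best_epoch)

        # --- evaluate --------------------------------------------------------
        test_bags = [by_id[b] for b in split.test]
        scores = predict_bags(trained, test_bags)
        scores_df = pd.DataFrame(
            {
                "bag_id": [s[0] for s in scores],
                "score": [s[1] for s in scores],
                "label": [b.label for b in test_bags],
            }
        )
        scores_df.to_csv(out / "scores.csv", index=False)
        cohort_scored = ScoredCohort(
            scores_df["bag_id"].tolist(),
            scores_df["score"].to_numpy(),
            scores_df["label"].to_numpy(),
        )
        report = evaluate_cohort(
            cohort_scored,
            cutoff=cfg["evaluate"]["cutoff"],
            ci_level=float(cfg["evaluate"]["ci_level"]),
            ci_method=cfg["evaluate"].get("ci_method", "delong"),
        )
        report.to_json(out / "report.json")
        roc_auc(cohort_scored).to_frame().to_csv(out / "roc.csv", index=False)
        decision_curve(cohort_scored).to_frame().to_csv(out / "dca.csv", index=False)
        if isinstance(model.pooling, AttentionPoolHead):
            export_attention_csv(
                (
                    (b.bag_id, model.attention_weights(b.data))
                    for b in test_bags
                ),
                out / "attention.csv",
            )
        log.info("evaluation: AUC %.3f accuracy %.3f", report.auc, report.accuracy)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
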