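"""Training, evaluation, cross-validation and prediction loops.

Training iterates whole-cloud batches — every cloud is processed at its
full resolution, never down-sampled — with Adam and the composite two-head
loss.  Per-cloud geometry (voxel grids, coarsened assignments, rulebooks)
is precomputed once and reused across epochs, since point coordinates never
change during training.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, use_dtype
from .io import DatasetBundle, LabeledPointCloud, export_ply, write_points_txt
from .losses import (
    SegmentationReport,
    class_weights,
    evaluate,
    total_loss,
)
from .model import (
    FFNet,
    ModelConfig,
    Preprocessed,
    load_checkpoint,
    predict_labels,
    save_checkpoint,
)
from .voxelgrid import majority_labels

__all__ = [
    "RunConfig",
    "TrainLog",
    "train",
    "evaluate_bundle",
    "cross_validate",
    "predict_cloud",
    "predict_to_file",
]


@dataclass
class RunConfig:
    """Everything one training run needs."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train_data: str | None = None
    test_data: str | None = None
    seed: int = 0
    out_dir: str = "runs/default"
    clip_norm: float = 10.0

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        model_d = dict(d.get("model", {}))
        if "stage_widths" in model_d:
            model_d["stage_widths"] = tuple(model_d["stage_widths"])
        return RunConfig(
            model=ModelConfig(**model_d),
            train_data=d.get("train_data"),
            test_data=d.get("test_data"),
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "runs/default")),
            clip_norm=float(d.get("clip_norm", 10.0)),
        )


@dataclass
class TrainLog:
    """Per-epoch history plus the retained best checkpoint."""

    epochs: list[dict] = field(default_factory=list)
    best_miou: float = -1.0
    best_epoch: int = -1
    checkpoint_path: str = ""


def _prepare(model: FFNet, bundle: DatasetBundle):
    pres: list[Preprocessed] = []
    vlabels: list[np.ndarray] = []
    for cloud in bundle.clouds:
        if cloud.labels is None:
            raise ValueError(
                f"cloud {cloud.plant_id!r} day {cloud.day} has no labels"
            )
        pre = model.preprocess(cloud)
        pres.append(pre)
        vlabels.append(
            majority_labels(cloud.labels, pre.assignment,
                            model.config.num_classes)
        )
    return pres, vlabels


def train(
    bundle: DatasetBundle,
    config: RunConfig | ModelConfig | None = None,
    max_steps: int | None = None,
    log_fn=print,
) -> tuple[FFNet, TrainLog]:
    """Train a fresh network on a labeled bundle.

    ``max_steps`` caps the number of optimizer steps regardless of the
    epoch budget (handy for fixed-step harnesses).  The best-train-mIoU
    checkpoint is written under ``out_dir``.
    """
    if isinstance(config, ModelConfig):
        config = RunConfig(model=config)
    elif config is None:
        config = RunConfig()
    if len(bundle) == 0:
        raise ValueError("empty training bundle")
    model = FFNet(config.model)
    model.train_mode(True)
    pres, vlabels = _prepare(model, bundle)
    all_labels = np.concatenate([c.labels for c in bundle.clouds])
    weights = class_weights(all_labels, config.model.num_classes)
    opt = Adam(model.parameters(), lr=config.model.learning_rate,
               clip_norm=config.clip_norm)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    os.makedirs(config.out_dir, exist_ok=True)
    log = TrainLog(checkpoint_path=os.path.join(config.out_dir, "best.npz"))
    metrics_path = os.path.join(config.out_dir, "metrics.jsonl")
    metrics_fh = open(metrics_path, "w")
    try:
        _run_epochs(model, config, pres, vlabels, weights, opt,
                    shuffle_rng, log, metrics_fh, max_steps, log_fn)
    finally:
        metrics_fh.close()
    return model, log


def _run_epochs(model, config, pres, vlabels, weights, opt, shuffle_rng,
                log, metrics_fh, max_steps, log_fn):
    bs = config.model.batch_size
    steps = 0
    with use_dtype(config.model.precision):
        for epoch in range(config.model.epochs):
            order = shuffle_rng.permutation(len(pres))
            ep_loss = ep_lv = ep_lp = 0.0
            n_batches = 0
            confusion_pred: list[np.ndarray] = []
            confusion_true: list[np.ndarray] = []
            for start in range(0, len(order), bs):
                idx = order[start:start + bs]
                opt.zero_grad()
                batch_loss = batch_lv = batch_lp = 0.0
                for i in idx:
                    pre, vl = pres[i], vlabels[i]
                    p_logits, v_logits, _ = model.forward(pre)
                    loss, lv, lp = total_loss(
                        v_logits, vl, p_logits, pre.cloud.labels, weights
                    )
                    if not math.isfinite(loss.item()):
                        raise RuntimeError(
                            f"non-finite loss at epoch {epoch}, "
                            f"cloud {pre.cloud.plant_id!r}: {loss.item()}"
                        )
                    (loss * (1.0 / len(idx))).backward()
                    batch_loss += loss.item() / len(idx)
                    batch_lv += lv.item() / len(idx)
                    batch_lp += lp.item() / len(idx)
                    confusion_pred.append(predict_labels(p_logits))
                    confusion_true.append(pre.cloud.labels)
                opt.step()
                steps += 1
                ep_loss += batch_loss
                ep_lv += batch_lv
                ep_lp += batch_lp
                n_batches += 1
                if max_steps is not None and steps >= max_steps:
                    break
            report = evaluate(
                np.concatenate(confusion_pred),
                np.concatenate(confusion_true),
                config.model.num_classes,
            )
            entry = {
                "epoch": epoch,
                "loss": ep_loss / n_batches,
                "loss_v": ep_lv / n_batches,
                "loss_p": ep_lp / n_batches,
                "train_miou": report.miou,
                "steps": steps,
            }
            log.epochs.append(entry)
            metrics_fh.write(json.dumps(entry) + "\n")
            metrics_fh.flush()
            if log_fn is not None:
                log_fn(
                    f"epoch {epoch:3d}  loss {entry['loss']:.4f}  "
                    f"loss_v {entry['loss_v']:.4f}  "
                    f"loss_p {entry['loss_p']:.4f}  "
                    f"train mIoU {report.miou:.4f}"
                )
            if report.miou > log.best_miou:
                log.best_miou = report.miou
                log.best_epoch = epoch
                save_checkpoint(model, log.checkpoint_path)
            if max_steps is not None and steps >= max_steps:
                break


def evaluate_bundle(
    model: FFNet | str, bundle: DatasetBundle
) -> SegmentationReport:
    """Pooled confusion over every cloud in the bundle."""
    if isinstance(model, str):
        model = load_checkpoint(model)
    if len(bundle) == 0:
        raise ValueError("empty evaluation bundle")
    k = model.config.num_classes
    names = None
    confusion = np.zeros((k, k), dtype=np.int64)
    model.train_mode(False)
    try:
        for cloud in bundle.clouds:
            if cloud.labels is None:
                raise ValueError(
                    f"cloud {cloud.plant_id!r} has no labels to evaluate"
                )
            if cloud.class_names and len(cloud.class_names) != k:
                raise ValueError(
                    f"class count mismatch: model has {k}, cloud has "
                    f"{len(cloud.class_names)}"
                )
            names = cloud.class_names or names
            p_logits, _, _ = model.forward(cloud)
            rep = evaluate(predict_labels(p_logits), cloud.labels, k)
            confusion += rep.confusion
    finally:
        model.train_mode(True)
    tp = np.diag(confusion).astype(np.float64)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    denom = tp + fn + fp
    iou = np.where(denom > 0, tp / np.maximum(denom, 1), 1.0)
    return SegmentationReport(
        confusion=confusion,
        per_class_iou=iou,
        miou=float(iou.mean()),
        class_names=names,
    )


def cross_validate(
    model: FFNet | str,
    bundle: DatasetBundle,
    source_name: str = "train-domain",
    target_name: str = "test-domain",
) -> SegmentationReport:
    """Evaluate a model on a bundle from a different domain (e.g. trained
    on maize-like plants, tested on tomato-like plants)."""
    if isinstance(model, str):
        model = load_checkpoint(model)
    k = model.config.num_classes
    for cloud in bundle.clouds:
        if cloud.class_names and len(cloud.class_names) != k:
            raise ValueError("class sets differ between model and bundle")
    report = evaluate_bundle(model, bundle)
    report.source = source_name
    report.target = target_name
    return report


def predict_cloud(model: FFNet, cloud: LabeledPointCloud) -> np.ndarray:
    model.train_mode(False)
    try:
        p_logits, _, _ = model.forward(cloud)
    finally:
        model.train_mode(True)
    return predict_labels(p_logits)


def predict_to_file(model: FFNet | str, cloud: LabeledPointCloud,
                    out_path: str) -> None:
    """Write coordinates + predicted labels, point order preserved;
    the extension picks the format (.ply or text)."""
    if isinstance(model, str):
        model = load_checkpoint(model)
    labels = predict_cloud(model, cloud)
    out = LabeledPointCloud(
        coords=cloud.coords,
        labels=labels,
        class_names=["ground", "stem", "leaf"][: model.config.num_classes],
        plant_id=cloud.plant_id,
        day=cloud.day,
        source=cloud.source,
    )
    if str(out_path).lower().endswith(".ply"):
        export_ply(out, out_path)
    else:
        write_points_txt(out, out_path)
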