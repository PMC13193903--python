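"""Linear-probing (LP) and LP + fine-tuning (LP-FT) training regimes.

The transfer-learning protocol trains the classifier head first with the
backbone frozen (linear probing), optionally followed by end-to-end
fine-tuning at a reduced learning rate. Validation accuracy is monitored
every epoch; the best checkpoint is kept and early stopping halts
stagnating runs. Cross-entropy loss, AdamW optimizer, batch size 64,
learning rates 1e-3 (LP) and 1e-4 (FT) by default.

The reference backbone is the CPU-trainable :class:`~ifcmorph.nn.CompactCNN`,
whose "frozen backbone" is its seed-fixed random-feature extractor (there
are no pretrained weights at desk scale). The four large ImageNet backbone
identifiers are accepted in configuration for deployments that provide an
external deep-learning runtime and weights, and raise a clear error here.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import CLASS_ORDER, MorphClass
from .data import as_stem_and_labels
from .nn import AdamW, CompactCNN, cross_entropy, linear_backward

#: backbone ids recognized in configuration; only compact-cnn is bundled
KNOWN_BACKBONES = (
    "compact-cnn",
    "mobilenet-v3-large",
    "efficientnet-v2-s",
    "resnet-50",
    "convnext-tiny",
)


@dataclass(frozen=True)
class TrainConfig:
    regime: str = "LP_FT"  # "LP" or "LP_FT"
    backbone_id: str = "compact-cnn"
    batch_size: int = 64
    lr_lp: float = 1e-3
    lr_ft: float = 1e-4
    max_epochs_lp: int = 30
    max_epochs_ft: int = 30
    patience: int = 5
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("LP", "LP_FT"):
            raise ValueError("regime must be 'LP' or 'LP_FT'")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.backbone_id not in KNOWN_BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone_id!r}; known: {KNOWN_BACKBONES}"
            )


@dataclass
class TrainedClassifier:
    """A frozen predictor: backbone + head snapshot with its training log."""

    backbone_id: str
    net: CompactCNN
    classes: tuple[MorphClass, ...]
    log: pd.DataFrame
    best_epoch: int
    config: TrainConfig

    @property
    def best_val_accuracy(self) -> float:
        return float(self.log["val_acc"].max())


def _build_backbone(cfg: TrainConfig, n_classes: int) -> CompactCNN:
    if cfg.backbone_id != "compact-cnn":
        raise RuntimeError(
            f"backbone {cfg.backbone_id!r} requires an external deep-learning "
            "runtime and ImageNet-pretrained weights; this build bundles only "
            "the CPU-trainable 'compact-cnn' reference backbone"
        )
    return CompactCNN(n_classes=n_classes, seed=cfg.seed)


def _accuracy(net: CompactCNN, stems: np.ndarray, y: np.ndarray) -> float:
    if len(y) == 0:
        return float("nan")
    preds = []
    for start in range(0, len(y), 512):
        probs = net.predict_proba_from_stem(stems[start : start + 512])
        preds.append(probs.argmax(axis=1))
    return float((np.concatenate(preds) == y).mean())


def _train_loop(
    net: CompactCNN,
    s_train: np.ndarray,
    y_train: np.ndarray,
    s_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    phase: str,
    head_only: bool,
    max_epochs: int,
    lr: float,
    log_rows: list[dict],
    include_initial: bool,
) -> int:
    """Epoch loop with best-checkpoint tracking and early stopping.

    Mutates ``net`` to the best-validation-accuracy parameters seen; ties
    break toward the earliest epoch. Returns the best epoch number.
    """
    trainable = net.head_keys if head_only else net.trainable_keys
    opt = AdamW(
        {k: net.params[k] for k in trainable},
        lr=lr,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 29]))
    # features of the frozen backbone never change during LP: compute once
    feat_train = net.features(s_train) if head_only else None
    feat_val = net.features(s_val) if head_only else None

    best_acc, best_epoch, best_snap = -np.inf, -1, None
    if include_initial:
        acc0 = _accuracy(net, s_val, y_val)
        log_rows.append(
            {
                "phase": phase, "epoch": 0, "train_loss": np.nan,
                "train_acc": np.nan, "val_acc": acc0,
            }
        )
        best_acc, best_epoch, best_snap = acc0, 0, net.snapshot()
    stall = 0
    n = len(y_train)
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            yb = y_train[idx]
            if head_only:
                feats = feat_train[idx]
                fcache = None
            else:
                feats, fcache = net.features(s_train[idx], with_cache=True)
            logits, lcache = net.logits_from_features(feats, with_cache=True)
            loss, dlog = cross_entropy(logits, yb)
            dfeats, dhw, dhb = linear_backward(dlog, lcache)
            grads = {"head.w": dhw, "head.b": dhb}
            if not head_only:
                grads.update(net.features_backward(dfeats, fcache))
            opt.step(grads)
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == yb).sum())
        if head_only:
            val_logits = net.logits_from_features(feat_val)
            val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        else:
            val_acc = _accuracy(net, s_val, y_val)
        log_rows.append(
            {
                "phase": phase,
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_acc": hits / n,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc, best_epoch, best_snap = val_acc, epoch, net.snapshot()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    if best_snap is not None:
        net.load(best_snap)
    return best_epoch


def linear_probe(data, cfg: TrainConfig) -> TrainedClassifier:
    """Train only the classifier head on frozen backbone features.

    ``data`` is a (train, val) pair; each part is an
    :class:`~ifcmorph.data.ImageDataset` or an (inputs, labels) tuple.
    Backbone parameters are untouched (verifiable by checksum).
    """
    (s_train, y_train), (s_val, y_val) = (
        as_stem_and_labels(data[0]),
        as_stem_and_labels(data[1]),
    )
    if len(y_train) == 0:
        raise ValueError("empty training split")
    net = _build_backbone(cfg, n_classes=len(CLASS_ORDER))
    net.set_feature_norm(s_train)
    log_rows: list[dict] = []
    best = _train_loop(
        net, s_train, y_train, s_val, y_val, cfg,
        phase="lp", head_only=True, max_epochs=cfg.max_epochs_lp,
        lr=cfg.lr_lp, log_rows=log_rows, include_initial=False,
    )
    return TrainedClassifier(
        backbone_id=cfg.backbone_id,
        net=net,
        classes=CLASS_ORDER,
        log=pd.DataFrame(log_rows),
        best_epoch=best,
        config=cfg,
    )


def fine_tune(model: TrainedClassifier, data, cfg: TrainConfig) -> TrainedClassifier:
    """End-to-end fine-tuning at the reduced learning rate.

    All parameters become trainable. The validation-best checkpoint over the
    fine-tuning phase (including its LP starting point, logged as epoch 0)
    is returned; the training log is appended to the model's. With
    ``max_epochs_ft == 0`` the model is returned unchanged.
    """
    if cfg.max_epochs_ft == 0:
        return model
    if cfg.lr_ft >= cfg.lr_lp:
        warnings.warn(
            f"fine-tuning lr ({cfg.lr_ft}) is not below the probing lr "
            f"({cfg.lr_lp}); fine-tuning is meant to run at a reduced rate",
            stacklevel=2,
        )
    (s_train, y_train), (s_val, y_val) = (
        as_stem_and_labels(data[0]),
        as_stem_and_labels(data[1]),
    )
    if len(y_train) == 0:
        raise ValueError("empty training split")
    net = copy.deepcopy(model.net)
    log_rows: list[dict] = []
    best = _train_loop(
        net, s_train, y_train, s_val, y_val, cfg,
        phase="ft", head_only=False, max_epochs=cfg.max_epochs_ft,
        lr=cfg.lr_ft, log_rows=log_rows, include_initial=True,
    )
    return TrainedClassifier(
        backbone_id=model.backbone_id,
        net=net,
        classes=model.classes,
        log=pd.concat(
            [model.log, pd.DataFrame(log_rows)], ignore_index=True
        ),
        best_epoch=best,
        config=cfg,
    )


def train(data, cfg: TrainConfig) -> TrainedClassifier:
    """Run the configured regime: LP, or LP followed by fine-tuning."""
    model = linear_probe(data, cfg)
    if cfg.regime == "LP_FT":
        model = fine_tune(model, data, cfg)
    return model


def predict(
    model: TrainedClassifier, inputs, batch_size: int = 256
) -> tuple[list[str], np.ndarray]:
    """Predict labels and class probabilities for a batch of model inputs.

    ``inputs`` is an (N, 224, 224, 3) array or an ImageDataset. Outputs are
    deterministic and batch-size independent (up to float round-off).
    """
    from .data import ImageDataset

    if isinstance(inputs, ImageDataset):
        stems = inputs.stem_array()
    else:
        x = np.asarray(inputs)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != (224, 224, 3):
            raise ValueError(
                f"inputs must be (N, 224, 224, 3) model inputs, got {x.shape}"
            )
        stems = CompactCNN.stem(x)
    probs = np.concatenate(
        [
            model.net.predict_proba_from_stem(stems[i : i + batch_size])
            for i in range(0, len(stems), batch_size)
        ]
    )
    labels = [model.classes[k].value for k in probs.argmax(axis=1)]
    return labels, probs


# ---------------------------------------------------------------------------
# persistence


def save_classifier(model: TrainedClassifier, path) -> None:
    """Save parameters (.npz) with a JSON sidecar (config, log, best epoch)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.net.params)
    sidecar = {
        "backbone_id": model.backbone_id,
        "classes": [c.value for c in model.classes],
        "best_epoch": model.best_epoch,
        "config": dataclass_to_dict(model.config),
        "log": model.log.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_classifier(path) -> TrainedClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = TrainConfig(**sidecar["config"])
    net = _build_backbone(cfg, n_classes=len(sidecar["classes"]))
    with np.load(path.with_suffix(".npz")) as arrs:
        net.load({k: arrs[k] for k in arrs.files})
    return TrainedClassifier(
        backbone_id=sidecar["backbone_id"],
        net=net,
        classes=tuple(MorphClass(c) for c in sidecar["classes"]),
        log=pd.DataFrame(sidecar["log"]),
        best_epoch=int(sidecar["best_epoch"]),
        config=cfg,
    )


def dataclass_to_dict(cfg) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def with_seed(cfg: TrainConfig, seed: int) -> TrainConfig:
    return replace(cfg, seed=seed)
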