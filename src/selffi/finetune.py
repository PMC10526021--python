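"""Supervised multi-label fine-tuning of a (pre-trained) encoder.

The projection head used during contrastive pre-training is discarded; the
encoder is topped with dropout and a single affine layer producing one logit
per disease class, trained with independent per-class binary cross-entropy on
sigmoid outputs — the standard choice for a multi-label task where an image
may carry any subset of the six diseases.  Splits are patient-disjoint by
construction (train/validation/test fractions default to roughly 80:15:5) and
the best-validation model is kept.  Passing ``checkpoint=None`` trains from
random initialization — the no-pre-train baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentPolicy, augment_view, load_image
from .manifest import ImageRecord, LABEL_COLUMNS, read_manifest
from . import nn
from .pretrain import EncoderSpec, preprocess


@dataclass
class FinetuneConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 0.001
    weight_decay: float = 0.001
    dropout: float = 0.5
    image_size: int = 512
    n_classes: int = 6
    freeze_encoder: bool = False
    threshold: float = 0.5
    modality: str = "UFI"
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    split_fractions: tuple[float, float, float] = (0.8, 0.15, 0.05)
    augment_train: Optional[AugmentPolicy] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def desk_finetune_config(**overrides) -> FinetuneConfig:
    """CPU-scale profile: 64-pixel images, tiny encoder, short schedule."""
    base = dict(
        epochs=6, batch_size=16, image_size=64, learning_rate=0.003,
        encoder=EncoderSpec("tiny_cnn"),
        augment_train=AugmentPolicy(
            output_size=64, rotation_max_degrees=20.0, crop_scale=(0.8, 1.0),
            color_jitter=False, grayscale_prob=0.0, blur=False,
        ),
        split_fractions=(0.6, 0.2, 0.2),
    )
    base.update(overrides)
    return FinetuneConfig(**base)


def split_by_patient(
    records: Sequence[ImageRecord],
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[ImageRecord], list[ImageRecord], list[ImageRecord]]:
    """Partition records into patient-disjoint train/val/test lists."""
    patients = sorted({r.patient_id for r in records})
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n = len(order)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - 2) if n >= 3 else n_train
    n_val = min(n_val, n - n_train - 1) if n - n_train >= 2 else n_val
    groups = (set(order[:n_train]), set(order[n_train:n_train + n_val]),
              set(order[n_train + n_val:]))
    validate_patient_disjoint(*groups)
    return tuple(  # type: ignore[return-value]
        [r for r in records if r.patient_id in g] for g in groups
    )


def validate_patient_disjoint(*groups: set[str]) -> None:
    """Hard error if any patient appears in more than one split."""
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            overlap = groups[i] & groups[j]
            if overlap:
                raise ValueError(
                    f"patients shared between splits {i} and {j}: {sorted(overlap)[:5]}"
                )


def _load_resized(record: ImageRecord, size: int, cache: dict) -> np.ndarray:
    key = (record.path, size)
    if key not in cache:
        img = load_image(record.path)
        cache[key] = augment_view(
            img, AugmentPolicy.identity(size), np.random.default_rng(0)
        )
    return cache[key]


def _bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-class binary cross-entropy and its gradient wrt logits."""
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    grad = (p - y) / logits.size
    return float(loss), grad


def _init_model(config: FinetuneConfig, checkpoint: Optional[str | Path],
                rng: np.random.Generator) -> tuple[nn.Sequential, nn.Sequential, int]:
    encoder, feature_dim = nn.build_encoder(config.encoder.architecture, rng)
    if checkpoint is not None:
        weights, buffers, meta = nn.load_checkpoint(checkpoint)
        if meta["architecture"] != config.encoder.architecture:
            raise ValueError(
                f"checkpoint encoder {meta['architecture']!r} does not match "
                f"requested {config.encoder.architecture!r}"
            )
        n_enc = len(encoder.params())
        n_buf = len(encoder.buffers())
        nn.restore_module(encoder, weights["model"][:n_enc],
                          buffers.get("model", [])[:n_buf])
    head = nn.Sequential([nn.Dropout(config.dropout),
                          nn.Linear(feature_dim, config.n_classes, rng)])
    return encoder, head, feature_dim


def finetune_run(
    manifest: str | Path,
    checkpoint: Optional[str | Path],
    config: FinetuneConfig,
    out_dir: str | Path,
    splits: Optional[tuple[Sequence[str], Sequence[str], Sequence[str]]] = None,
) -> dict:
    """Fine-tune on labeled images; returns checkpoint path and score table.

    ``splits``, when given, lists explicit patient ids per partition
    (validated for disjointness); otherwise patients are partitioned by
    ``config.split_fractions``.  The returned score table holds one row per
    (test image, class) with the predicted probability and true label.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = [r for r in read_manifest(manifest)
               if r.modality == config.modality and r.labels is not None]
    if not records:
        raise ValueError("no labeled records of the requested modality in manifest")
    if splits is not None:
        groups = tuple(set(map(str, g)) for g in splits)
        validate_patient_disjoint(*groups)
        train, val, test = (
            [r for r in records if r.patient_id in g] for g in groups
        )
    else:
        train, val, test = split_by_patient(records, config.split_fractions, config.seed)
    if not train or not val or not test:
        raise ValueError("each split must contain at least one labeled image")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    encoder, head, feature_dim = _init_model(config, checkpoint, rng)
    trainable = head.params() if config.freeze_encoder else encoder.params() + head.params()
    opt = nn.AdamW(trainable, lr=config.learning_rate, weight_decay=config.weight_decay)

    cache: dict = {}
    y_of = {r.image_id: np.asarray(r.labels[: config.n_classes], dtype=np.float64)
            for r in records}
    meta = {
        "architecture": config.encoder.architecture,
        "feature_dim": feature_dim,
        "n_classes": config.n_classes,
        "image_size": config.image_size,
        "dropout": config.dropout,
        "stage": "finetune",
    }
    best_val = math.inf
    history = []
    ckpt_path = out_dir / "finetune_best.npz"
    for epoch in range(1, config.epochs + 1):
        epoch_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 100 + epoch]))
        order = epoch_rng.permutation(len(train))
        epoch_loss = []
        for start in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[start:start + config.batch_size]]
            if config.augment_train is not None:
                imgs = [augment_view(load_image(r.path), config.augment_train, epoch_rng)
                        for r in batch]
            else:
                imgs = [_load_resized(r, config.image_size, cache) for r in batch]
            x = preprocess(imgs)
            y = np.stack([y_of[r.image_id] for r in batch])
            opt.zero_grad()
            # a frozen encoder is a fixed feature extractor: run it in eval
            # mode so the head trains on the same features it is scored on
            feats = encoder.forward(x, train=not config.freeze_encoder,
                                    rng=epoch_rng)
            logits = head.forward(feats, train=True, rng=epoch_rng)
            loss, glogits = _bce_with_logits(logits, y)
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            gfeats = head.backward(glogits.astype(np.float32))
            if not config.freeze_encoder:
                encoder.backward(gfeats)
            opt.step()
            epoch_loss.append(loss)
        val_loss = _eval_loss(encoder, head, val, config, y_of, cache)
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_loss)),
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            nn.save_checkpoint(ckpt_path, {"encoder": encoder, "head": head}, meta)

    scores = _score_table(ckpt_path, test, config, cache)
    scores_path = out_dir / "scores.csv"
    scores.to_csv(scores_path, index=False)
    return {
        "checkpoint": str(ckpt_path),
        "scores": str(scores_path),
        "score_table": scores,
        "history": history,
        "splits": {
            "train": sorted({r.patient_id for r in train}),
            "val": sorted({r.patient_id for r in val}),
            "test": sorted({r.patient_id for r in test}),
        },
    }


def _forward_probs(encoder: nn.Sequential, head: nn.Sequential,
                   x: np.ndarray) -> np.ndarray:
    logits = head.forward(encoder.forward(x))
    return 1.0 / (1.0 + np.exp(-logits))


def _eval_loss(encoder, head, records, config, y_of, cache) -> float:
    imgs = [_load_resized(r, config.image_size, cache) for r in records]
    y = np.stack([y_of[r.image_id] for r in records])
    logits = head.forward(encoder.forward(preprocess(imgs)))
    loss, _ = _bce_with_logits(logits, y)
    return loss


def _score_table(checkpoint: Path, records: Sequence[ImageRecord],
                 config: FinetuneConfig, cache: dict) -> pd.DataFrame:
    imgs = [_load_resized(r, config.image_size, cache) for r in records]
    probs = predict(checkpoint, imgs)
    rows = []
    for r, p in zip(records, probs):
        for k in range(config.n_classes):
            rows.append({
                "image_id": r.image_id,
                "class": LABEL_COLUMNS[k],
                "probability": float(p[k]),
                "label": int(r.labels[k]),
            })
    return pd.DataFrame(rows)


def load_finetuned(checkpoint: str | Path) -> tuple[nn.Sequential, nn.Sequential, dict]:
    weights, buffers, meta = nn.load_checkpoint(checkpoint)
    rng = np.random.default_rng(0)
    encoder, feature_dim = nn.build_encoder(meta["architecture"], rng)
    head = nn.Sequential([nn.Dropout(meta.get("dropout", 0.0)),
                          nn.Linear(feature_dim, meta["n_classes"], rng)])
    nn.restore_module(encoder, weights["encoder"], buffers.get("encoder"))
    nn.restore_module(head, weights["head"], buffers.get("head"))
    return encoder, head, meta


def predict(checkpoint: str | Path, images: Sequence[np.ndarray]) -> np.ndarray:
    """Per-class sigmoid probabilities, one row of length n_classes per image."""
    encoder, head, meta = load_finetuned(checkpoint)
    if len(images) == 0:
        return np.zeros((0, meta["n_classes"]))
    for im in images:
        if im.shape[0] != meta["image_size"] or im.shape[1] != meta["image_size"]:
            raise ValueError(
                f"image size {im.shape[:2]} does not match checkpoint "
                f"({meta['image_size']})"
            )
    return _forward_probs(encoder, head, preprocess(images))
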