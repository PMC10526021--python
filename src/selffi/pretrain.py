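"""Self-supervised pre-training: encoder + projection head on the three
contrastive objectives.

Training draws positive pairs per enabled objective (pair-instance,
bi-lateral, multi-modality), augments each member into a view, embeds the
views through encoder f and projection head g, and minimizes the
temperature-scaled contrastive loss with in-batch negatives.  Objectives are
scheduled round-robin by default — each optimization step carries one
objective's batch, keeping that loss's negative pool homogeneous — or
jointly, where every step sums all enabled objectives' losses over their own
batches.  Optimization uses AdamW; an 80:20 patient-level split provides a
per-epoch validation loss, and both the best-validation and the last model
are checkpointed.

The clinical-scale protocol (ResNet34, 224-pixel views, 3000 epochs at batch
128, lr 5e-5, weight decay 1e-4, temperature 0.07) is encoded in the config
defaults; desk-scale runs override the encoder, image size and epoch count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .augment import AugmentPolicy, make_views
from .losses import EmbeddingBatch, batch_contrastive_loss_and_grad, total_loss
from .manifest import ImageRecord, ManifestError, PairExample, build_pairs, read_manifest
from . import nn

OBJECTIVES = ("pair_instance", "bilateral", "multimodal")


@dataclass
class EncoderSpec:
    architecture: str = "tiny_cnn"
    pretrained_init: bool = False


@dataclass
class ProjectionHeadSpec:
    hidden_dim: int = 64
    out_dim: int = 128


@dataclass
class PretrainConfig:
    objectives: tuple[str, ...] = OBJECTIVES
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    epochs: int = 3000
    batch_size: int = 128
    learning_rate: float = 0.00005
    weight_decay: float = 0.0001
    temperature: float = 0.07
    train_split: float = 0.8
    schedule: str = "roundrobin"   # or "joint"
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    head: ProjectionHeadSpec = field(default_factory=ProjectionHeadSpec)
    augment: AugmentPolicy = field(default_factory=lambda: AugmentPolicy(output_size=224))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.objectives:
            raise ValueError("at least one objective is required")
        for obj in self.objectives:
            if obj not in OBJECTIVES:
                raise ValueError(f"unknown objective {obj!r}")
        if not 0.0 < self.train_split < 1.0:
            raise ValueError("train_split must lie in (0, 1)")
        if self.schedule not in ("roundrobin", "joint"):
            raise ValueError("schedule must be 'roundrobin' or 'joint'")


def desk_pretrain_config(**overrides) -> PretrainConfig:
    """CPU-scale profile: tiny encoder, 64-pixel views, short schedule."""
    base = dict(
        epochs=5, batch_size=16, learning_rate=0.001, temperature=0.2,
        encoder=EncoderSpec("tiny_cnn"),
        head=ProjectionHeadSpec(hidden_dim=64, out_dim=32),
        augment=AugmentPolicy(output_size=64, rotation_max_degrees=30.0,
                              crop_scale=(0.7, 1.0), blur_prob=0.2,
                              brightness=0.1, contrast=0.1, saturation=0.1,
                              hue=0.02, grayscale_prob=0.05),
    )
    base.update(overrides)
    return PretrainConfig(**base)


def preprocess(images: Sequence[np.ndarray]) -> np.ndarray:
    """uint8 HxWx3 views -> NCHW float32 in [-0.5, 0.5]."""
    x = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return (x / 255.0 - 0.5).transpose(0, 3, 1, 2)


def split_patients(
    records: Sequence[ImageRecord], train_fraction: float, seed: int
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Deterministic patient-level split; every patient lands wholly on one side."""
    patients = sorted({r.patient_id for r in records})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = max(1, int(round(train_fraction * len(patients))))
    n_train = min(n_train, len(patients))
    train_ids = {patients[i] for i in order[:n_train]}
    train = [r for r in records if r.patient_id in train_ids]
    val = [r for r in records if r.patient_id not in train_ids]
    return train, val


def _build_model(config: PretrainConfig, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    encoder, feature_dim = nn.build_encoder(config.encoder.architecture, rng)
    head = nn.build_projection_head(feature_dim, config.head.hidden_dim,
                                    config.head.out_dim, rng)
    return nn.Sequential([encoder, head]), feature_dim


def _objective_pairs(records: Sequence[ImageRecord], objectives: Sequence[str],
                     seed: int, where: str) -> dict[str, list[PairExample]]:
    pools: dict[str, list[PairExample]] = {}
    for obj in objectives:
        try:
            pools[obj] = build_pairs(records, obj, seed=seed)
        except ManifestError as exc:
            raise ManifestError(f"objective {obj!r} on the {where} split: {exc}") from exc
    return pools


def _embed_pairs(model: nn.Sequential, pairs: Sequence[PairExample],
                 policy: AugmentPolicy, rng: np.random.Generator,
                 cache: dict, temperature: float) -> EmbeddingBatch:
    views = []
    links = []
    for i, pair in enumerate(pairs):
        va, vb = make_views(pair, policy, rng, image_cache=cache)
        views += [va, vb]
        links.append((2 * i, 2 * i + 1))
    z = model.forward(preprocess(views), train=True, rng=rng)
    return EmbeddingBatch(z=z, pair_links=links, temperature=temperature)


def pretrain_run(manifest: str | Path, config: PretrainConfig,
                 out_dir: str | Path) -> dict:
    """Run the self-supervised stage; returns paths and the training log.

    Writes ``best.npz`` (lowest validation loss), ``last.npz`` and a
    line-delimited JSON log into ``out_dir``.  Fully deterministic given
    ``config.seed`` on one device.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_manifest(manifest)
    train_recs, val_recs = split_patients(records, config.train_split, config.seed)
    train_pools = _objective_pairs(train_recs, config.objectives, config.seed, "train")
    val_pools: dict[str, list[PairExample]] = {}
    if val_recs:
        for obj in config.objectives:
            try:
                val_pools[obj] = build_pairs(val_recs, obj, seed=config.seed)
            except ManifestError:
                pass  # a small validation split may lack some linkage

    init_rng = np.random.default_rng(config.seed)
    model, feature_dim = _build_model(config, init_rng)
    opt = nn.AdamW(model.params(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    weight_of = dict(zip(OBJECTIVES, config.loss_weights))
    cache: dict[str, np.ndarray] = {}
    log_path = out_dir / "pretrain_log.jsonl"
    best_val = math.inf
    history: list[dict] = []
    meta = {
        "architecture": config.encoder.architecture,
        "feature_dim": feature_dim,
        "hidden_dim": config.head.hidden_dim,
        "out_dim": config.head.out_dim,
        "image_size": config.augment.output_size,
        "stage": "pretrain",
    }

    with open(log_path, "w") as log_fh:
        for epoch in range(1, config.epochs + 1):
            epoch_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, epoch])
            )
            epoch_losses: dict[str, list[float]] = {o: [] for o in config.objectives}
            batches = {
                obj: _batched(pairs, config.batch_size, epoch_rng)
                for obj, pairs in train_pools.items()
            }
            n_rounds = max(len(b) for b in batches.values())
            for step in range(n_rounds):
                step_parts: dict[str, float] = {}
                if config.schedule == "joint":
                    grads_done = False
                    opt.zero_grad()
                    for obj in config.objectives:
                        chunk = batches[obj][step % len(batches[obj])]
                        eb = _embed_pairs(model, chunk, config.augment, epoch_rng,
                                          cache, config.temperature)
                        loss, gz = batch_contrastive_loss_and_grad(eb)
                        _check_finite(loss, epoch, obj)
                        model.backward((weight_of[obj] * gz).astype(np.float32))
                        step_parts[obj] = loss
                        grads_done = True
                    if grads_done:
                        opt.step()
                else:  # roundrobin: one objective per optimization step
                    for obj in config.objectives:
                        if step >= len(batches[obj]):
                            continue
                        chunk = batches[obj][step]
                        opt.zero_grad()
                        eb = _embed_pairs(model, chunk, config.augment, epoch_rng,
                                          cache, config.temperature)
                        loss, gz = batch_contrastive_loss_and_grad(eb)
                        _check_finite(loss, epoch, obj)
                        model.backward((weight_of[obj] * gz).astype(np.float32))
                        opt.step()
                        step_parts[obj] = loss
                for obj, val in step_parts.items():
                    epoch_losses[obj].append(val)

            mean_losses = {
                obj: (float(np.mean(vals)) if vals else None)
                for obj, vals in epoch_losses.items()
            }
            breakdown = total_loss(
                mean_losses.get("pair_instance"),
                mean_losses.get("bilateral"),
                mean_losses.get("multimodal"),
                config.loss_weights,
            )
            val_loss = _validation_loss(model, val_pools, config, cache)
            entry = {
                "epoch": epoch,
                "objective_losses": mean_losses,
                "total_loss": breakdown.total,
                "val_loss": val_loss,
            }
            history.append(entry)
            log_fh.write(json.dumps(entry) + "\n")
            nn.save_checkpoint(out_dir / "last.npz", {"model": model}, meta)
            crit = val_loss if val_loss is not None else breakdown.total
            if crit < best_val:
                best_val = crit
                nn.save_checkpoint(out_dir / "best.npz", {"model": model}, meta)

    return {
        "checkpoint": str(out_dir / "best.npz"),
        "last_checkpoint": str(out_dir / "last.npz"),
        "log": str(log_path),
        "history": history,
    }


def _check_finite(loss: float, epoch: int, obj: str) -> None:
    if not math.isfinite(loss):
        raise RuntimeError(
            f"non-finite {obj} loss at epoch {epoch}; "
            "reduce the learning rate or inspect the input images"
        )


def _batched(pairs: Sequence[PairExample], batch_size: int,
             rng: np.random.Generator) -> list[list[PairExample]]:
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    out = [shuffled[i:i + batch_size] for i in range(0, len(shuffled), batch_size)]
    # a single positive pair has no in-batch negatives; fold it into its neighbor
    if len(out) > 1 and len(out[-1]) < 2:
        out[-2].extend(out.pop())
    return [b for b in out if len(b) >= 2]


def _validation_loss(model: nn.Sequential, val_pools: dict, config: PretrainConfig,
                     cache: dict) -> Optional[float]:
    if not val_pools:
        return None
    losses = []
    for obj, pairs in val_pools.items():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4711]))
        chunk = pairs[: config.batch_size]
        if len(chunk) < 2:
            continue
        eb = _embed_pairs(model, chunk, config.augment, rng, cache, config.temperature)
        loss, _ = batch_contrastive_loss_and_grad(eb, want_grad=False)
        losses.append(loss)
    return float(np.mean(losses)) if losses else None


def load_model(checkpoint: str | Path) -> tuple[nn.Sequential, dict]:
    """Rebuild the pre-training model (encoder + head) from a checkpoint."""
    weights, buffers, meta = nn.load_checkpoint(checkpoint)
    rng = np.random.default_rng(0)
    encoder, feature_dim = nn.build_encoder(meta["architecture"], rng)
    head = nn.build_projection_head(feature_dim, meta["hidden_dim"],
                                    meta["out_dim"], rng)
    model = nn.Sequential([encoder, head])
    nn.restore_module(model, weights["model"], buffers.get("model"))
    return model, meta


def embed(checkpoint: str | Path, images: Sequence[np.ndarray],
          space: str = "projection") -> np.ndarray:
    """Embed images with a pre-trained checkpoint.

    ``space='projection'`` returns projection-head outputs z = g(f(u));
    ``space='encoder'`` returns the encoder features f(u) (linear probing).
    """
    model, meta = load_model(checkpoint)
    encoder = model.layers[0]
    width = meta["out_dim"] if space == "projection" else meta["feature_dim"]
    if len(images) == 0:
        return np.zeros((0, width))
    for im in images:
        if im.shape[0] != meta["image_size"] or im.shape[1] != meta["image_size"]:
            raise ValueError(
                f"image size {im.shape[:2]} does not match checkpoint "
                f"({meta['image_size']})"
            )
    x = preprocess(images)
    if space == "projection":
        return model.forward(x)
    if space == "encoder":
        return encoder.forward(x)
    raise ValueError("space must be 'projection' or 'encoder'")
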