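"""Run configuration (YAML) and end-to-end pipeline orchestration.

A :class:`RunConfig` nests the per-stage configurations — synthetic-data
generation, augmentation, contrastive pre-training, fine-tuning, evaluation —
under a single seed.  Defaults encode the clinical-scale training protocol
(ResNet-class encoder, 3000 pre-training epochs at batch 128, lr 5e-5,
weight decay 1e-4, temperature 0.07; fine-tuning 100 epochs at batch 64,
lr 1e-3, weight decay 1e-3, dropout 0.5, 512-pixel images); the ``desk``
profile swaps in a tiny CNN, 64-pixel images and short schedules so the full
pipeline runs on one CPU in minutes.

``run_pipeline`` executes an ordered, contiguous subset of the stages
simulate → pretrain → finetune → evaluate → contribute into a run directory,
records a config-hash per completed stage so re-runs can skip finished work,
and fails with a pointer to the missing stage when an upstream artifact is
absent.  The contribute stage trains every combination of the three
objectives (plus the no-pre-train baseline) at desk scale and decomposes the
resulting metric table into individual / additional / total contributions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd
import yaml

from .augment import AugmentPolicy
from .contribution import ResultsTable, contribution_table
from .finetune import FinetuneConfig, desk_finetune_config, finetune_run
from .metrics import report
from .pretrain import (EncoderSpec, PretrainConfig, ProjectionHeadSpec,
                       desk_pretrain_config, pretrain_run)
from .synthetic import SyntheticConfig, generate_dataset

STAGES = ("simulate", "pretrain", "finetune", "evaluate", "contribute")


@dataclass
class DataConfig:
    manifest: Optional[str] = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/selffi"
    data: DataConfig = field(default_factory=DataConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    evaluate_threshold: float = 0.5


def desk_run_config(seed: int = 0, n_patients: int = 20, **synthetic_overrides) -> RunConfig:
    """CPU-scale profile used by tests and worked examples."""
    synth = SyntheticConfig(n_patients=n_patients, seed=seed, **synthetic_overrides)
    return RunConfig(
        seed=seed,
        data=DataConfig(synthetic=synth),
        pretrain=desk_pretrain_config(seed=seed, epochs=2),
        finetune=desk_finetune_config(seed=seed, epochs=3),
    )


def paper_run_config(seed: int = 0) -> RunConfig:
    """Clinical-scale protocol; needs GPU-scale compute and real data."""
    warnings.warn(
        "the paper-faithful profile specifies a ResNet34 encoder and "
        "3000-epoch pre-training; it is not runnable in this CPU-only build"
    )
    cfg = RunConfig(seed=seed)
    cfg.pretrain.encoder = EncoderSpec("resnet34")
    cfg.finetune.encoder = EncoderSpec("resnet34")
    return cfg


# --- YAML (de)serialization with unknown-key rejection ---------------------

def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _from_plain(cls: type, data: Any) -> Any:
    if not is_dataclass(cls):
        return data
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {cls.__name__}")
    kwargs = {}
    for name, value in data.items():
        target = _NESTED.get((cls.__name__, name))
        if target is not None and value is not None:
            kwargs[name] = _from_plain(target, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    ("RunConfig", "data"): DataConfig,
    ("RunConfig", "pretrain"): PretrainConfig,
    ("RunConfig", "finetune"): FinetuneConfig,
    ("DataConfig", "synthetic"): SyntheticConfig,
    ("PretrainConfig", "encoder"): EncoderSpec,
    ("PretrainConfig", "head"): ProjectionHeadSpec,
    ("PretrainConfig", "augment"): AugmentPolicy,
    ("FinetuneConfig", "encoder"): EncoderSpec,
    ("FinetuneConfig", "augment_train"): AugmentPolicy,
}


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _from_plain(RunConfig, data)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(_to_plain(config), sort_keys=True).encode()
    ).hexdigest()[:16]


# --- pipeline --------------------------------------------------------------

def _stage_done(run_dir: Path, stage: str, digest: str) -> bool:
    marker = run_dir / f".{stage}.done"
    if marker.exists():
        try:
            return json.loads(marker.read_text()).get("hash") == digest
        except json.JSONDecodeError:
            return False
    return False


def _mark_done(run_dir: Path, stage: str, digest: str, artifacts: dict) -> None:
    (run_dir / f".{stage}.done").write_text(
        json.dumps({"hash": digest, "artifacts": artifacts})
    )


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} needs {path.name} — run the {stage!r} stage first"
        )
    return path


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES,
                 run_dir: Optional[str | Path] = None) -> Path:
    """Execute the requested contiguous stages into a run directory."""
    idx = [STAGES.index(s) for s in stages]
    if sorted(idx) != idx or any(b - a != 1 for a, b in zip(idx, idx[1:])):
        raise ValueError(f"stages must be a contiguous ordered subset of {STAGES}")
    run_dir = Path(run_dir if run_dir is not None else config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, run_dir / "config.yaml")
    digest = config_hash(config)

    manifest = (Path(config.data.manifest) if config.data.manifest
                else run_dir / "data" / "manifest.csv")

    for stage in stages:
        if _stage_done(run_dir, stage, digest):
            continue
        if stage == "simulate":
            manifest, _ = generate_dataset(config.data.synthetic, run_dir / "data")
            _mark_done(run_dir, stage, digest, {"manifest": str(manifest)})
        elif stage == "pretrain":
            _require(manifest, "simulate", stage)
            result = pretrain_run(manifest, config.pretrain, run_dir / "pretrain")
            _mark_done(run_dir, stage, digest, {"checkpoint": result["checkpoint"]})
        elif stage == "finetune":
            _require(manifest, "simulate", stage)
            ckpt = _require(run_dir / "pretrain" / "best.npz", "pretrain", stage)
            result = finetune_run(manifest, ckpt, config.finetune, run_dir / "finetune")
            _mark_done(run_dir, stage, digest, {"scores": result["scores"]})
        elif stage == "evaluate":
            scores_path = _require(run_dir / "finetune" / "scores.csv", "finetune", stage)
            rep = report(pd.read_csv(scores_path), config.evaluate_threshold)
            payload = rep.to_dict()
            payload["macro_percent"] = {k: 100.0 * v for k, v in rep.macro.items()}
            with open(run_dir / "metrics.json", "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            _mark_done(run_dir, stage, digest, {"metrics": str(run_dir / "metrics.json")})
        elif stage == "contribute":
            _require(manifest, "simulate", stage)
            results_csv, contrib_csv = ablation_run(manifest, config, run_dir / "ablation")
            _mark_done(run_dir, stage, digest, {"contribution": str(contrib_csv)})
    return run_dir


_COMBOS: tuple[tuple[str, ...], ...] = (
    (), ("pair_instance",), ("bilateral",), ("multimodal",),
    ("pair_instance", "bilateral"), ("pair_instance", "multimodal"),
    ("bilateral", "multimodal"),
    ("pair_instance", "bilateral", "multimodal"),
)


def ablation_run(manifest: str | Path, config: RunConfig,
                 out_dir: str | Path) -> tuple[Path, Path]:
    """Train every objective combination plus the baseline and decompose.

    Writes ``results.csv`` (macro metrics ×100 per combination, mirroring the
    clinical results-table layout) and ``contribution.csv`` (the I/A/C
    decomposition) into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    table = ResultsTable()
    for combo in _COMBOS:
        tag = "+".join(combo) if combo else "none"
        if combo:
            pre_cfg = dataclasses.replace(config.pretrain, objectives=combo)
            pre = pretrain_run(manifest, pre_cfg, out_dir / f"pretrain_{tag}")
            ckpt = pre["checkpoint"]
        else:
            ckpt = None
        fin = finetune_run(manifest, ckpt, config.finetune, out_dir / f"finetune_{tag}")
        rep = report(fin["score_table"], config.evaluate_threshold)
        metrics = {k: 100.0 * v for k, v in rep.macro.items()}
        table.add(combo, metrics)
        rows.append({"methods": tag, **metrics})
    results_csv = out_dir / "results.csv"
    pd.DataFrame(rows).to_csv(results_csv, index=False)
    contrib = contribution_table(table)
    contrib_csv = out_dir / "contribution.csv"
    contrib.to_csv(contrib_csv, index=False)
    return results_csv, contrib_csv
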