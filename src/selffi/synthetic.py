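"""Procedural paired fundus-image generator.

Real cohorts of ultra-wide-field (UFI) and conventional (CFI) fundus
photographs carry two correlations that contrastive pre-training can exploit:
a patient's left and right eyes share patient-level appearance (bi-lateral
pairs), and the UFI and CFI of one eye show the same retina at different
fields of view (multi-modality pairs).  This module renders small synthetic
images with exactly that structure so every downstream stage — pairing,
augmentation, contrastive losses, fine-tuning, metrics — can be exercised
end-to-end with no external data.

The renderer is deliberately schematic: a circular fundus disk, a vessel tree
grown by a deterministic random walk from the optic disc, and per-disease
motifs (e.g. a central blob for macular degeneration, a peripheral blob for a
retinal break, an enlarged cup for glaucoma suspect) whose strength is set by
``lesion_contrast``.  Each scene is a pure function of the patient latent
vector; the right eye is the horizontally mirrored geometry, and the CFI is
the central 40% of the field re-rendered at full resolution with finer vessel
detail.  Independent per-view Gaussian noise (``view_noise_sd``) models
acquisition variability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy.special import ndtr

from .manifest import ImageRecord, write_manifest

#: fraction of the UFI field of view covered by the conventional image
CFI_FIELD_FRACTION = 0.4

_DEFAULT_PREVALENCE = (0.30, 0.20, 0.15, 0.20, 0.15, 0.10)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort.

    ``disease_prevalence`` orders the six classes as (DM retinopathy,
    epiretinal membrane, glaucoma suspect, macular degeneration, retinal
    break, retinal vein occlusion).  ``lesion_contrast`` in (0, 1] scales all
    disease motifs; ``view_noise_sd`` is per-pixel Gaussian noise on the
    0–255 scale, drawn independently for every rendered view.
    """

    n_patients: int = 20
    image_size: int = 64
    disease_prevalence: tuple[float, ...] = _DEFAULT_PREVALENCE
    patient_latent_dim: int = 8
    view_noise_sd: float = 2.0
    lesion_contrast: float = 0.8
    seed: int = 0
    per_eye_labels: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if len(self.disease_prevalence) != 6:
            raise ValueError("disease_prevalence must have six entries")
        if any(not 0.0 <= p <= 1.0 for p in self.disease_prevalence):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.patient_latent_dim < 6:
            raise ValueError("patient_latent_dim must be >= 6 (one axis per disease)")
        if not 0.0 < self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must lie in (0, 1]")
        if self.view_noise_sd < 0:
            raise ValueError("view_noise_sd must be nonnegative")


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth for one synthetic patient."""

    patient_id: str
    latent: tuple[float, ...]
    labels: tuple[int, ...]


def labels_from_latent(latent: np.ndarray, config: SyntheticConfig) -> tuple[int, ...]:
    """Deterministic multi-label assignment: disease k is active when the
    standard-normal CDF of latent axis k falls below its prevalence."""
    u = ndtr(np.asarray(latent[:6], dtype=float))
    return tuple(int(u[k] < config.disease_prevalence[k]) for k in range(6))


def _symmetric_grid(size: int, half_width: float) -> tuple[np.ndarray, np.ndarray]:
    # pixel centers exactly symmetric under negation so mirrored geometry
    # rasterizes to the bitwise-mirrored image
    step = 2.0 * half_width / (size - 1)
    coords = (np.arange(size) - (size - 1) / 2.0) * step
    return np.meshgrid(coords, coords)  # X, Y with Y increasing down rows


def _latent_rng(latent: np.ndarray) -> np.random.Generator:
    digest = hashlib.sha256(np.asarray(latent, dtype=np.float64).tobytes()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _vessel_tree(latent: np.ndarray, detail: int) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Grow polyline branches from the optic disc; returns (points_x, points_y, width)."""
    rng = _latent_rng(latent)
    branches = []
    n_branches = 6
    n_steps = 14 * detail
    step = 0.11 / detail
    for b in range(n_branches):
        # fan out from the disc, biased toward the temporal (negative-x) side
        angle = np.pi + (b - (n_branches - 1) / 2.0) * 0.55 + 0.15 * rng.standard_normal()
        x, y = 0.45, 0.02 * rng.standard_normal()
        xs, ys = [x], [y]
        for _ in range(n_steps):
            angle += 0.5 * rng.standard_normal() / np.sqrt(detail)
            # gentle pull back toward the horizontal arcades
            angle += 0.08 * np.sign(-np.sin(angle)) * abs(y) / np.sqrt(detail)
            x += step * np.cos(angle)
            y += step * np.sin(angle)
            if x * x + y * y > 0.92:
                break
            xs.append(x)
            ys.append(y)
        width = 0.020 - 0.0012 * b
        branches.append((np.asarray(xs), np.asarray(ys), width))
    return branches


def _paint_segments(
    mask: np.ndarray, X: np.ndarray, Y: np.ndarray,
    xs: np.ndarray, ys: np.ndarray, width: float,
) -> None:
    """Accumulate a soft vessel mask from one polyline (distance-to-segment)."""
    for i in range(len(xs) - 1):
        px, py, qx, qy = xs[i], ys[i], xs[i + 1], ys[i + 1]
        dx, dy = qx - px, qy - py
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            continue
        t = np.clip(((X - px) * dx + (Y - py) * dy) / seg2, 0.0, 1.0)
        d2 = (X - px - t * dx) ** 2 + (Y - py - t * dy) ** 2
        np.maximum(mask, np.exp(-d2 / (2.0 * width * width)), out=mask)


def _gaussian_blob(X: np.ndarray, Y: np.ndarray, cx: float, cy: float, sigma: float) -> np.ndarray:
    return np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * sigma * sigma)))


def render_eye(
    latent: np.ndarray,
    side: str,
    modality: str,
    labels: Sequence[int],
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one eye as an ``image_size × image_size × 3`` uint8 array.

    With ``view_noise_sd == 0`` (or ``rng=None``) the output is a pure
    function of ``(latent, side, modality, labels)``; the right eye is the
    exact horizontal mirror of the left.
    """
    latent = np.asarray(latent, dtype=np.float64)
    if latent.shape != (config.patient_latent_dim,):
        raise ValueError(
            f"latent has shape {latent.shape}, expected ({config.patient_latent_dim},)"
        )
    size = config.image_size
    if modality == "CFI":
        half_width, detail = CFI_FIELD_FRACTION, 2
    elif modality == "UFI":
        half_width, detail = 1.0, 1
    else:
        raise ValueError(f"unknown modality {modality!r}")
    X, Y = _symmetric_grid(size, half_width)
    c = float(config.lesion_contrast)
    lab = tuple(int(v) for v in labels)

    fundus = X * X + Y * Y < 0.97  # circular field on dark background
    # fundus pigmentation varies markedly between patients; tie the base tint
    # and a broad pigment gradient to the latent so patient identity is a
    # salient image property, as it is in real cohorts
    tint = 0.08 * np.tanh(latent[[5, 6, 7]])
    grad = 0.08 * np.tanh(latent[4]) * Y
    base = np.stack(
        [
            (0.72 + tint[0]) + grad,
            (0.34 + tint[1]) + 0.5 * grad,
            (0.14 + tint[2]) + 0.04 * _gaussian_blob(X, Y, 0.0, 0.0, 0.6),
        ],
        axis=-1,
    )

    vessel = np.zeros_like(X)
    caliber = 0.8 + 0.4 / (1.0 + np.exp(-latent[3]))  # patient vessel caliber
    for xs, ys, width in _vessel_tree(latent, detail):
        _paint_segments(vessel, X, Y, xs, ys, caliber * width)

    # optic disc, nasal side, patient-specific height; glaucoma suspect
    # enlarges the pale cup
    disc_y = 0.12 * np.tanh(latent[2])
    disc_r = 0.10
    cup_r = disc_r * (0.45 + 0.40 * c * lab[2])
    disc = _gaussian_blob(X, Y, 0.45, disc_y, disc_r)
    cup = _gaussian_blob(X, Y, 0.45, disc_y, cup_r)

    img = base.copy()
    img += disc[..., None] * np.array([0.20, 0.35, 0.30])
    img += cup[..., None] * np.array([0.15, 0.25, 0.25])
    img -= vessel[..., None] * np.array([0.30, 0.26, 0.08])

    if lab[0]:  # DM retinopathy: scattered dark microaneurysm-like dots
        dot_rng = _latent_rng(latent + 17.0)
        for _ in range(12):
            r = 0.15 + 0.55 * dot_rng.random()
            th = 2 * np.pi * dot_rng.random()
            blob = _gaussian_blob(X, Y, r * np.cos(th), r * np.sin(th), 0.022)
            img -= c * blob[..., None] * np.array([0.45, 0.30, 0.10])
    if lab[1]:  # epiretinal membrane: grayish sheen over the macula
        sheen = _gaussian_blob(X, Y, -0.25, 0.0, 0.20)
        img += c * sheen[..., None] * np.array([0.18, 0.22, 0.26])
    if lab[3]:  # macular degeneration: bright central blob
        blob = _gaussian_blob(X, Y, -0.25, 0.0, 0.12)
        img += c * blob[..., None] * np.array([0.25, 0.28, 0.10])
    if lab[4]:  # retinal break: pale blob in the far periphery
        blob = _gaussian_blob(X, Y, -0.55, 0.58, 0.10)
        img += c * blob[..., None] * np.array([0.30, 0.30, 0.28])
    if lab[5]:  # retinal vein occlusion: wedge-shaped darkening off the disc
        theta = np.arctan2(Y - disc_y, X - 0.45)
        wedge = np.exp(-((theta - 2.4) ** 2) / (2 * 0.35**2)) * (
            1 - _gaussian_blob(X, Y, 0.45, disc_y, 0.18)
        )
        img -= c * wedge[..., None] * np.array([0.25, 0.18, 0.05])

    img *= fundus[..., None]
    if side == "right":
        img = img[:, ::-1, :]
    elif side != "left":
        raise ValueError(f"unknown side {side!r}")

    img = np.clip(img, 0.0, 1.0) * 255.0
    if rng is not None and config.view_noise_sd > 0:
        img = img + rng.normal(0.0, config.view_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, list[PatientTruth]]:
    """Render the full cohort: four images per patient (left/right × UFI/CFI),
    a manifest CSV, and a JSON truth file for test oracles.

    Fully deterministic given ``config.seed``: re-running with the same
    configuration reproduces byte-identical manifests and images.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    records: list[ImageRecord] = []
    truths: list[PatientTruth] = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        latent = rng.standard_normal(config.patient_latent_dim)
        labels = labels_from_latent(latent, config)
        for side in ("left", "right"):
            eye_labels = labels
            if config.per_eye_labels and side == "right":
                eye_labels = labels_from_latent(latent[::-1].copy(), config)
            for modality in ("UFI", "CFI"):
                noise_rng = np.random.default_rng(rng.integers(0, 2**31))
                img = render_eye(latent, side, modality, eye_labels, config, noise_rng)
                image_id = f"{pid}_{side}_{modality}"
                rel = f"images/{image_id}.png"
                Image.fromarray(img).save(img_dir / f"{image_id}.png")
                records.append(
                    ImageRecord(
                        image_id=image_id,
                        patient_id=pid,
                        eye_side=side,
                        modality=modality,
                        path=str(out_dir / rel),
                        labels=eye_labels,
                    )
                )
        truths.append(PatientTruth(pid, tuple(latent.tolist()), labels))
    manifest_path = write_manifest(records, out_dir / "manifest.csv")
    truth_payload = {
        t.patient_id: {"latent": list(t.latent), "labels": list(t.labels)} for t in truths
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)
    return manifest_path, truths
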