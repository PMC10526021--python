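"""Stochastic image augmentation for contrastive view construction.

The pre-training objectives need correlated-but-distinct views: two
independent augmentations of one image (pair-instance) or one augmentation of
each member of a bi-lateral / multi-modal pair.  The policy mirrors common
contrastive practice — random resized crop, horizontal/vertical flips,
rotation up to 180°, color jitter (brightness/contrast/saturation/hue),
random grayscale and Gaussian blur — applied geometric-first.

Every transform consumes its random draws from the supplied generator in a
fixed order whether or not it is enabled, so disabling a transform is
behaviorally identical to setting its probability/strength to zero, and a
given generator state always maps to the same output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage

from .manifest import PairExample

_MIN_CROPPABLE = 8
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class AugmentPolicy:
    """Enable flags and parameter ranges for each transform."""

    output_size: int = 64
    crop: bool = True
    crop_scale: tuple[float, float] = (0.6, 1.0)   # area fraction range
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation: bool = True
    rotation_max_degrees: float = 180.0
    color_jitter: bool = True
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.05          # fraction of a full hue revolution
    grayscale_prob: float = 0.2
    blur: bool = True
    blur_prob: float = 0.5
    blur_sigma: tuple[float, float] = (0.1, 1.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rotation_max_degrees <= 180.0:
            raise ValueError("rotation_max_degrees must lie in [0, 180]")
        if self.output_size <= 0:
            raise ValueError("output_size must be positive")
        lo, hi = self.crop_scale
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("crop_scale must satisfy 0 < lo <= hi <= 1")
        if not 0.0 <= self.grayscale_prob <= 1.0:
            raise ValueError("grayscale_prob must lie in [0, 1]")

    @staticmethod
    def identity(output_size: int = 64) -> "AugmentPolicy":
        """A policy with every stochastic transform disabled (resize only)."""
        return AugmentPolicy(
            output_size=output_size, crop=False, horizontal_flip=False,
            vertical_flip=False, rotation=False, color_jitter=False,
            grayscale_prob=0.0, blur=False,
        )


def load_image(path: str) -> np.ndarray:
    """Read a raster image as an HxWx3 uint8 array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except (OSError, FileNotFoundError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[0] == size and img.shape[1] == size:
        return img
    pil = Image.fromarray(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return np.asarray(pil.resize((size, size), Image.BILINEAR))


def _hue_rotation_matrix(theta: float) -> np.ndarray:
    # rotation of RGB space about the achromatic axis
    c, s = np.cos(theta), np.sin(theta)
    m = np.full((3, 3), (1.0 - c) / 3.0)
    m += np.eye(3) * c
    k = s / np.sqrt(3.0)
    m += k * np.array([[0, -1, 1], [1, 0, -1], [-1, 1, 0]], dtype=float)
    return m


def augment_view(img: np.ndarray, policy: AugmentPolicy,
                 rng: np.random.Generator) -> np.ndarray:
    """Apply one stochastic policy sample; returns output_size² uint8 RGB."""
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    h, w = img.shape[:2]
    if h < _MIN_CROPPABLE or w < _MIN_CROPPABLE:
        raise ValueError(
            f"image {h}x{w} smaller than minimum croppable size {_MIN_CROPPABLE}"
        )
    out = img.astype(np.float64)

    # crop (random area fraction, random position), then resize
    scale = rng.uniform(*policy.crop_scale)
    uy, ux = rng.random(), rng.random()
    if policy.crop:
        side = np.sqrt(scale)
        ch, cw = max(_MIN_CROPPABLE, int(round(h * side))), max(_MIN_CROPPABLE, int(round(w * side)))
        ch, cw = min(ch, h), min(cw, w)
        y0 = int(round(uy * (h - ch)))
        x0 = int(round(ux * (w - cw)))
        out = out[y0:y0 + ch, x0:x0 + cw]
    out = _resize(out, policy.output_size).astype(np.float64)

    u_h, u_v = rng.random(), rng.random()
    if policy.horizontal_flip and u_h < 0.5:
        out = out[:, ::-1]
    if policy.vertical_flip and u_v < 0.5:
        out = out[::-1]

    angle = rng.uniform(-policy.rotation_max_degrees, policy.rotation_max_degrees)
    if policy.rotation and angle != 0.0:
        out = ndimage.rotate(out, angle, axes=(1, 0), reshape=False, order=1,
                             mode="constant", cval=0.0)

    fb = 1.0 + rng.uniform(-policy.brightness, policy.brightness)
    fc = 1.0 + rng.uniform(-policy.contrast, policy.contrast)
    fs = 1.0 + rng.uniform(-policy.saturation, policy.saturation)
    fh = rng.uniform(-policy.hue, policy.hue)
    if policy.color_jitter:
        out = out * fb
        mean = out.mean()
        out = (out - mean) * fc + mean
        gray = out @ _LUMA
        out = gray[..., None] + (out - gray[..., None]) * fs
        if fh != 0.0:
            out = out @ _hue_rotation_matrix(2.0 * np.pi * fh).T

    if rng.random() < policy.grayscale_prob:
        out = np.repeat((out @ _LUMA)[..., None], 3, axis=2)

    u_blur = rng.random()
    sigma = rng.uniform(*policy.blur_sigma)
    if policy.blur and u_blur < policy.blur_prob:
        out = ndimage.gaussian_filter(out, sigma=(sigma, sigma, 0.0))

    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def make_views(
    pair: PairExample,
    policy: AugmentPolicy,
    rng: np.random.Generator,
    image_cache: Optional[dict[str, np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce the two contrastive views of a positive pair.

    ``pair_instance`` pairs yield two independent augmentations of the same
    image; bi-lateral and multi-modal pairs yield one augmentation of each
    member.  ``image_cache`` (path -> array) avoids repeated disk reads.
    """
    def fetch(path: str) -> np.ndarray:
        if image_cache is not None:
            if path not in image_cache:
                image_cache[path] = load_image(path)
            return image_cache[path]
        return load_image(path)

    img_a = fetch(pair.record_a.path)
    if pair.pair_type == "pair_instance":
        return augment_view(img_a, policy, rng), augment_view(img_a, policy, rng)
    img_b = fetch(pair.record_b.path)
    return augment_view(img_a, policy, rng), augment_view(img_b, policy, rng)
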