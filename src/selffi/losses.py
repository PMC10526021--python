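"""Temperature-scaled contrastive (InfoNCE / NT-Xent) losses.

The three pre-training objectives — pair-instance (two augmentations of one
image), bi-lateral (a patient's left and right eye) and multi-modality (the
UFI and CFI of one eye) — all share the same loss form: for an anchor
embedding z_a with positive z_p and negatives {z_k},

    L = −log  exp(sim(z_a, z_p)/τ) / Σ exp(sim(z_a, ·)/τ)

with sim the cosine similarity and τ a temperature.  Two denominator
conventions exist: the NT-Xent form includes the positive term in the sum
(loss is then nonnegative) while the bare form sums over the K negatives
only.  ``include_positive_in_denominator`` selects between them; the
NT-Xent form is the default.

``batch_contrastive_loss`` applies the loss with in-batch negatives — for
each anchor every embedding that is neither the anchor nor its linked
positive — symmetrized over both directions of every pair.  The combined
objective is the (weighted) sum of the three per-strategy losses.

Everything here is plain NumPy; ``batch_contrastive_loss_and_grad`` also
returns the analytic gradient with respect to the raw (unnormalized)
embeddings, which the training loops consume directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp


@dataclass
class EmbeddingBatch:
    """A batch of projected representations with its positive-pair links.

    ``z`` is N×D; ``pair_links`` lists (anchor, positive) index tuples;
    ``temperature`` is the τ of the loss (paper-scale default 0.07).
    """

    z: np.ndarray
    pair_links: list[tuple[int, int]]
    temperature: float = 0.07

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 2 or self.z.shape[0] < 2:
            raise ValueError("z must be an N x D matrix with N >= 2")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        n = self.z.shape[0]
        for a, p in self.pair_links:
            if not (0 <= a < n and 0 <= p < n):
                raise ValueError(f"pair link ({a}, {p}) out of range for N={n}")
            if a == p:
                raise ValueError(f"pair link ({a}, {p}) joins an index with itself")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-objective losses and their weighted total."""

    pair_instance: Optional[float]
    bilateral: Optional[float]
    multimodality: Optional[float]
    total: float


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def info_nce(
    anchor: np.ndarray,
    positive: np.ndarray,
    negatives: Sequence[np.ndarray],
    temperature: float = 0.07,
    include_positive_in_denominator: bool = True,
) -> float:
    """Single-anchor InfoNCE loss against K explicit negatives."""
    if len(negatives) == 0:
        raise ValueError("at least one negative sample is required")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s_pos = cosine_similarity(anchor, positive) / temperature
    s_neg = np.array([cosine_similarity(anchor, n) for n in negatives]) / temperature
    pool = np.append(s_neg, s_pos) if include_positive_in_denominator else s_neg
    return float(logsumexp(pool) - s_pos)


def _normalize_rows(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding row")
    return z / norms, norms


def _anchor_list(pair_links: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    # symmetrize: each pair contributes both directions
    return [(a, p) for a, p in pair_links] + [(p, a) for a, p in pair_links]


def batch_contrastive_loss(
    batch: EmbeddingBatch,
    include_positive_in_denominator: bool = True,
) -> float:
    """Mean symmetrized InfoNCE over a batch with in-batch negatives.

    For each anchor the negatives are every other row of ``batch.z`` except
    the anchor itself and its linked positive.
    """
    loss, _ = batch_contrastive_loss_and_grad(
        batch, include_positive_in_denominator, want_grad=False
    )
    return loss


def batch_contrastive_loss_and_grad(
    batch: EmbeddingBatch,
    include_positive_in_denominator: bool = True,
    want_grad: bool = True,
) -> tuple[float, Optional[np.ndarray]]:
    """Loss of :func:`batch_contrastive_loss` plus dL/dz (N×D)."""
    if not batch.pair_links:
        raise ValueError("pair_links must be nonempty")
    zn, norms = _normalize_rows(batch.z)
    n = zn.shape[0]
    tau = batch.temperature
    sims = (zn @ zn.T) / tau
    anchors = _anchor_list(batch.pair_links)
    m = len(anchors)
    total = 0.0
    g_sims = np.zeros_like(sims) if want_grad else None
    for a, p in anchors:
        row = sims[a]
        mask = np.ones(n, dtype=bool)
        mask[a] = False
        if not include_positive_in_denominator:
            mask[p] = False
            if not mask.any():
                raise ValueError("no negatives available for anchor")
            lse = logsumexp(row[mask])
            total += lse - row[p]
            if want_grad:
                soft = np.zeros(n)
                soft[mask] = np.exp(row[mask] - lse)
                soft[p] -= 1.0
                g_sims[a] += soft / m
        else:
            lse = logsumexp(row[mask])
            total += lse - row[p]
            if want_grad:
                soft = np.zeros(n)
                soft[mask] = np.exp(row[mask] - lse)
                soft[p] -= 1.0
                g_sims[a] += soft / m
    loss = total / m
    if not want_grad:
        return loss, None
    # sims = zn @ zn.T / tau  (diagonal never used: grad there is zero)
    g_zn = (g_sims @ zn + g_sims.T @ zn) / tau
    # back through row normalization zn_i = z_i / ||z_i||
    g_z = (g_zn - zn * np.sum(g_zn * zn, axis=1, keepdims=True)) / norms
    return loss, g_z


def total_loss(
    pair_instance: Optional[float],
    bilateral: Optional[float],
    multimodality: Optional[float],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LossBreakdown:
    """Combine the per-objective losses into the overall training objective.

    ``None`` marks an objective absent from the step; absent terms contribute
    nothing.  The breakdown stores the unweighted components and the weighted
    total (which equals their plain sum under unit weights).
    """
    comps = (pair_instance, bilateral, multimodality)
    tot = sum(w * c for w, c in zip(weights, comps) if c is not None)
    return LossBreakdown(pair_instance, bilateral, multimodality, float(tot))
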