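# Methods

## The model

`selffi` implements contrastive pre-training for paired retinal fundus
photography followed by supervised multi-label fine-tuning.  An encoder
f(·) maps an image to a feature vector and a projection head g(·) — exactly
Linear → ReLU → Linear — maps features to the embedding z = g(f(u)) on which
the contrastive losses act.  Similarity is the cosine

    sim(z_i, z_j) = z_i · z_j / (‖z_i‖₂ ‖z_j‖₂)

and each objective is a temperature-scaled InfoNCE loss: for an anchor with
one positive and K negatives,

    L = −log [ exp(sim(a, p)/τ) / Σ_k exp(sim(a, k)/τ) ].

Three positive-pair constructions are used:

* **pair-instance** — two stochastic augmentations of one image (the SimCLR
  scheme);
* **bi-lateral** — the left- and right-eye ultra-wide-field images (UFI) of
  one patient;
* **multi-modality** — the UFI and the conventional fundus image (CFI) of
  the same patient, matched per eye by default (the per-patient fallback is
  a flag on the pairing index, since clinical exports do not always record
  laterality for both modalities).

The combined objective is the weighted sum
L_total = w₁·L_pair-instance + w₂·L_bi-lateral + w₃·L_multi-modality with
default weights (1, 1, 1).

### Denominator convention

Two InfoNCE variants circulate: the NT-Xent form, whose denominator includes
the positive term (loss ≥ 0 always), and the bare form summing over the K
negatives only (loss can be negative).  The default here is the NT-Xent
form, standard for SimCLR-style training; the bare form is available via
`include_positive_in_denominator=False`.  Both satisfy the analytic limits
ln(K+1) and ln K respectively on uniform-similarity pools, which the tests
pin down.

### Negatives and symmetrization

`batch_contrastive_loss` uses in-batch negatives: for each anchor, every
embedding in the batch that is neither the anchor nor its linked positive.
Negatives therefore span other patients, which is what drives the
representation toward patient-level identity.  The loss is symmetrized —
averaged over both directions of every pair — so left/right and UFI/CFI
anchors are treated evenly.  K is induced by batch composition (K = N − 2
per anchor).

### Objective scheduling

The three pair pools have different sizes, and nothing forces their batches
to align.  The default schedule is round-robin: within an epoch each enabled
objective contributes its own optimization steps over its own batches, so
each loss's negative pool stays homogeneous in view type.  A `joint`
schedule (sum of all enabled losses per step, one batch each) is
config-selectable.

## Training protocol

Defaults encode the clinical-scale protocol: ResNet34 encoder, 128-d
embedding, AdamW with learning rate 5e-5, weight decay 1e-4, temperature
0.07, 3000 epochs at batch 128, 224-px pre-training views, 80:20
patient-level train/validation split; fine-tuning replaces the projection
head with dropout (0.5) plus a single affine layer to six logits, trained
100 epochs at batch 64, learning rate 1e-3, weight decay 1e-3, 512-px
images.  Fine-tuning uses independent per-class binary cross-entropy on
sigmoid outputs — the task is multi-label, so per-class Bernoulli likelihood
is the standard choice.  Splits are patient-disjoint by construction and
validated before training.

This build is CPU-only NumPy: layers (strided convolution via im2col,
batch normalization, ReLU, global average pooling, affine, inverted
dropout), backpropagation, and AdamW are implemented in `selffi.nn`.  A
ResNet34 cannot be trained without a GPU framework, so the **desk profile**
substitutes a four-block Conv–BatchNorm–ReLU encoder (`tiny_cnn`, 64-d
features), 64-px images, 32-d embeddings, learning rate 1e-3 and temperature
0.2.  The softer desk temperature and larger step size are numerical
choices for tiny batches and a tiny encoder; τ = 0.07 at batch 128 remains
the documented clinical-scale setting.  Batch normalization matters here:
without it the tiny all-ReLU encoder starts with near-collinear embeddings
and the contrastive loss sits at its uniform plateau ln(N−1).

## Evaluation

The ROC curve is computed at every distinct score threshold in descending
order (ties collapse to one threshold) and the AUC is its trapezoidal area
½ Σ (x_{i+1} − x_i)(y_i + y_{i+1}); this equals the Mann–Whitney rank
statistic with ties counted ½, which the tests verify on 1000 random sets.
Accuracy, precision, recall and F1 are confusion-count ratios at a fixed
threshold (default 0.5; AUC itself is threshold-free).  For the six-class
multi-label task the summary "accuracy" is the mean of per-class binary
accuracies, not subset accuracy — per-class accuracy under imbalance is the
only aggregation consistent with high accuracy coexisting with a low F1 —
and all macro numbers are unweighted means over classes.  Classes whose AUC
is undefined on a given evaluation set (one label value only) are excluded
from the macro AUC with a warning.  Zero-denominator ratios are reported as
0 with a warning, never an exception.

The contribution decomposition over a results table M indexed by method
subsets is

    I_m  = M_m − M_∅            (individual improvement)
    A_mp = M_{m+p} − M_p        (additional improvement with partner p)
    C_m  = I_m + (1/n) Σ_p A_mp (total contribution)

with n the number of partners for which both required entries exist (2 in
the full design; partial tables degrade gracefully, down to C = I with a
warning when no pairwise entry exists).  The module is pure arithmetic and
accepts any results table, including the published clinical one that ships
as a fixture in `selffi.experiments.PUBLISHED_RESULTS`.

## The synthetic cohort

The generator emits, per patient, four 64-px images — left/right eye ×
UFI/CFI — driven by an 8-d standard-normal patient latent:

* a circular fundus field with patient-specific pigmentation (tint ±0.08
  per channel, a vertical pigment gradient) tied to the latent;
* a vessel tree grown by a deterministic random walk from the optic disc,
  with patient-specific caliber and disc height;
* the right eye is the exact horizontal mirror of the left-eye geometry;
* the CFI re-renders the central 40% of the field at full resolution with
  finer vessel detail (crop fraction chosen to caricature a 30–50° field
  inside a ~200° one);
* six disease motifs, scaled by `lesion_contrast` ∈ (0, 1]: scattered dark
  dots (DM retinopathy), a grayish macular sheen (epiretinal membrane), an
  enlarged pale cup (glaucoma suspect), a bright central blob (macular
  degeneration), a pale peripheral blob (retinal break), and a dark wedge
  off the disc (retinal vein occlusion).

Labels derive deterministically from the latent: class k is active when
Φ(latent_k) < prevalence_k, so both eyes (and both modalities) of a patient
share labels, and truth is reproducible from the seed.  Per-view Gaussian
noise (`view_noise_sd`, default 2 gray levels) models acquisition
variability.  Default prevalences (0.30, 0.20, 0.15, 0.20, 0.15, 0.10)
give small cohorts a realistic mix of common and rarer findings.

The pigmentation amplitude is deliberately moderate.  If color alone
identifies a patient, the contrastive objectives solve themselves through
that shortcut and discard the spatial features that matter downstream; at
±0.08 the encoder must also use disc geometry, vessel structure and motifs,
which is the regime the method assumes in real data.

**What passing desk-scale tests does and does not show.**  The generator
reproduces the *correlation structure* the method exploits (shared patient
content across eyes and modalities) but none of the photometric complexity
of real fundus photography — no optics, no media opacity, no acquisition
artifacts, no longitudinal change, and lesions are parametric stamps rather
than pathology.  Passing tests demonstrate that the machinery (pairing,
losses, optimization, evaluation) behaves as specified and that pre-training
recovers planted structure; they say nothing about clinical performance.

## Desk-scale experiments

* **Alignment recovery** — 30 patients, all three objectives, 40 epochs
  (≈120 steps per objective at batch 16).  On held-out patients the mean
  positive-minus-negative cosine gap per objective rises from ≈0.03 at
  initialization to ≈0.5–0.7 after training (3-seed means).
* **Pre-training benefit** — separate unlabeled (30 patients) and labeled
  (40 patients) cohorts; disease signal on the two classes whose latent
  axes also shape stable patient appearance (macular degeneration ↔ vessel
  caliber, vein occlusion ↔ fundus tint) at prevalence 0.4/0.4 and lesion
  contrast 0.9 — diseases co-varying with global fundus appearance are the
  regime where patient-level representations transfer.  Both arms train an
  identical head on a frozen encoder at matched budgets (150 epochs,
  learning rate 3e-3, dropout 0.2, 12 labeled training patients, 30:20:50
  split so the test AUC is stable); only the encoder weights differ:
  contrastively pre-trained versus random.  This frozen-encoder (linear
  evaluation) protocol is the standard measure of representation quality;
  at desk scale, *full* fine-tuning re-learns the task from scratch within
  its budget in both arms, so initialization effects wash out and the
  comparison would measure optimization noise rather than representation
  quality.  Reported as mean test macro-AUC over 5 seeds; a directional
  check with a margin of a few AUC points.
* **End-to-end pipeline** — 20 patients on the desk profile through
  simulate → pretrain → finetune → evaluate → contribute, including the
  8-combination ablation; bit-reproducible under a fixed seed.

## Numerical choices and edge cases

* Augmentation order is geometric first (crop → flips → rotation) then
  photometric (jitter → grayscale → blur), the usual contrastive
  convention.  Every transform consumes its random draws whether or not it
  is enabled, so disabling a transform is exactly equivalent to zeroing its
  probability, and outputs are a pure function of the generator state.
* Jitter strengths and the crop-scale range are config-exposed; defaults
  (strength 0.2, hue 0.05, crop area 0.6–1.0) follow common contrastive
  practice, with softer values in the desk profile.
* A trailing batch with fewer than two pairs is folded into its neighbor
  (a single pair has no in-batch negative).
* Patients with several images in one (eye, modality) slot resolve to the
  lexicographically smallest image id — deterministic without a date field.
* Records with unknown laterality are excluded from bi-lateral pairing and
  retained for pair-instance.
* Checkpoints (npz) carry weights, batch-norm running statistics and a JSON
  config snapshot; save → load → embed is bitwise reproducible on one
  device.
* Zero-norm embeddings, single-class label vectors, empty score tables and
  zero-pair objectives raise informative errors at the boundary rather than
  propagating NaNs.

## Known limitations

* No GPU path and no ResNet34; clinical-scale configurations are encoded
  but not runnable here.
* The printed one-directional loss form is implemented but training always
  uses the symmetrized variant.
* Loss weights beyond (1, 1, 1) are exposed but no tuning harness is
  provided.
* The benefit experiment's margin is small at desk scale; it orders the
  means, it does not estimate an effect size.
* Crop-based augmentation invariance measurably suppresses peripheral
  information in the learned embedding (probes for the peripheral
  retinal-break motif score worse on contrastive features than on random
  features).  This is an expected property of the pretext task, and a
  caution for wide-field imagery where the periphery carries diagnostic
  signal: crop scales should be chosen with the downstream anatomy in
  mind.
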