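# Methods

This note documents the models, numerical choices and known limitations of
`parotidseg`, in the order data flows through the pipeline.

## Synthetic phantoms

No public multi-sequence parotid-tumor MR dataset exists, so every stage is
exercised on procedurally generated phantoms (`parotidseg.phantoms`).

A phantom is a three-channel scalar volume on a grid of (slices, height,
width) voxels with anisotropic spacing — default 5.0 mm slice thickness
versus 0.8 mm in-plane pixels, the regime of clinical head-and-neck
protocols, where slices are 5–10x thicker than pixels. The anatomy is
deliberately minimal: two parotid-like ellipsoids placed mirror-symmetrically
about the midline column, each optionally containing a smaller tumor
ellipsoid. Ellipsoids were chosen over more organic shapes because their
smooth closed surfaces make surface-distance metrics (HD95/AHD) well-defined
and oracle-checkable. Laterality follows radiological display convention: the
anatomical-left gland occupies high column indices (image right); the cohort
manifest records this so nothing downstream has to guess.

Geometry is jittered per case (radii ±10%, small center offsets). Tumor
placement uses a conservative containment bound — the per-axis offset plus
tumor radius, summed in quadrature against the parotid radii, stays below
0.95 — so tumor ⊆ parotid holds voxel-exactly by construction (and is
asserted anyway during rendering).

Intensities are generated directly on the normalized [0, 1] scale, one mean
per (sequence, tissue): by default the gland is brightest on T1w (fatty
tissue), the tumor is bright on T2w and brightest on T1wC (contrast
enhancement) while *darker* than the gland on plain T1w. These defaults are
package choices — no per-tissue intensity statistics were available — and are
fully configurable per spec. Gaussian noise (default sd 0.02) is added after
region assembly; with noise disabled the region intensities equal the
contrast profile exactly, which the tests rely on.

Cohort generation samples tumor laterality as left/right/both with
proportions 44.6/49.1/6.3%, the case mix of a unilateral-dominated tumor
cohort, and derives per-case seeds deterministically from the cohort seed.

What the phantoms do **not** emulate: bias fields, k-space/motion artifacts,
inter-sequence registration error, anatomic neighbors (mandible, vessels),
irregular tumor margins, or intensity heterogeneity within tissues. Passing
tests therefore demonstrate the *mechanics* of the pipeline (shapes, losses,
metrics, bookkeeping, trainability), not clinical-grade accuracy.

## Preprocessing

Sequences are kept in the canonical order T1w, T2w, T1wC wherever channels
are stacked. Intensity normalization is one min–max map per volume per
sequence onto [0, 1], placing the intensity midpoint at 0.5; a constant
volume maps to all 0.5. Normalization is per volume rather than per slice so
intensities remain comparable across a patient's slices. An alternative
reading — shifting the *mean* to 0.5 — was considered and rejected because it
does not by itself bound the output to [0, 1]; min–max satisfies both
requirements simultaneously.

Volumes are never resampled through the slice direction; the anisotropic
native spacing is preserved and carried into the distance metrics. In-plane,
slices are center-cropped or symmetrically zero-padded to the model's square
input size; the transform is recorded and inverted to place predictions back
on the native grid. All slices enter training, including background-only
ones — there is no slice-selection heuristic, and empty slices teach the
network the null output.

## Augmentation

Three training-time augmentations, applied on the fly in the order
affine → mirror → gray:

* **Gray disturbance** — one multiplicative factor from [0.9, 1.1] and one
  additive shift from [−0.1, 0.1] per sample (a single scalar pair, not per
  pixel), applied to the normalized image and clipped back to [0, 1]. The
  clip keeps inputs on the scale the network expects; labels are untouched.
* **Affine disturbance** — one in-plane rotation (default ±10°), isotropic
  scale ([0.95, 1.05]) and translation (±5% of the frame) about the image
  center, applied identically to image (bilinear) and label (nearest
  neighbor, re-binarized); out-of-frame regions are zero-filled. The
  magnitudes are defaults exposed in `AffineParams`, chosen as mild,
  anatomy-preserving perturbations.
* **Mirroring with label swap** — with probability 0.5 the laterality
  (column) axis is flipped *and* the left/right label channels are swapped
  (left↔right parotid, left↔right tumor), keeping the anatomy consistent.
  The operation is an involution and conserves per-channel foreground counts
  up to the permutation; both properties are tested.

## Network

A 2D U-Net (`ModelConfig` defaults: input 512x512, 4 pooling stages, base 64
filters doubling per level to 1024 at the bottleneck). The encoder comprises
12 convolution blocks — 3x3 convolution, batch normalization, ReLU —
allocated [2, 2, 2, 3, 3] across the five resolution levels (bottleneck
last); any allocation summing over levels is accepted via configuration,
since only the total (12) and pooling count (4) are fixed design points. The
decoder uses bilinear 2x upsampling followed by convolution blocks (2 per
level by default).

Each skip connection carries an additive attention gate. The gating signal is
the bottleneck feature map: both skip and gate are projected to an
intermediate width (half the skip channels) by 1x1 convolutions, summed,
rectified, reduced to one channel and passed through a sigmoid; the resulting
[0, 1] mask multiplies the skip features. Gate parameters are separate per
level. One implementation detail matters for memory: the gate projection is
applied at the bottleneck's native (coarse) resolution and the *projected*
map is bilinearly resampled to the skip resolution. Because a 1x1 convolution
commutes exactly with bilinear interpolation, this is mathematically
identical to resampling first, but avoids materializing a 1024-channel map at
512x512. The conventional attention U-Net wiring — gating each skip from the
adjacent coarser decoder feature — is available as
`gate_source="adjacent_decoder"` and registered in the model registry as a
comparison slot.

Outputs are independent per-channel sigmoids. This is essential here: tumors
lie inside parotids, so the four ROI channels are not mutually exclusive and
a softmax would be wrong.

The network, its gradients and RMSprop are implemented directly on numpy
(`autodiff.py`, `layers.py`): a small reverse-mode tape with im2col
convolution, 2x2 max pooling, bilinear resampling and composite batch
normalization. All gradients are verified against central finite differences
in the test suite, and forward operations against independent references
(scipy correlation, block-reduce pooling, adjoint dot-product tests). Being
pure numpy, runs are bit-reproducible under fixed seeds.

## Training

Loss: `1 − soft Dice` with smoothing constant s = 1.0 in numerator and
denominator — the plain ratio is undefined on background-only channels, so a
stabilizer is required; s is configurable. One Dice is computed per output
channel and averaged uniformly (no channel weighting).

The reduction over the batch deserves a note. Computing one smoothed Dice per
(sample, channel) and averaging rewards all-empty predictions on
background-only slices (their smoothed Dice is exactly 1), and on small
structures this creates a genuine failure mode: for some initializations the
tumor channels collapse to exactly zero output (saturated sigmoid, dead
gradient) while the overall loss still falls. The default therefore pools the
intersection and volume sums over the whole batch before forming the per-
channel Dice — an all-empty tumor prediction then scores near zero on any
batch containing tumor voxels, and the collapse disappears. The per-sample
form remains available (`TrainConfig.loss_reduction="per_sample"`).

Optimizer: RMSprop (uncentered, alpha 0.99), learning rate 1e-4, 200 epochs,
batch size 8 by default. No learning-rate schedule and no early stopping; a
best-validation-checkpoint option exists but is off by default, so the final
epoch is what is evaluated. Per-fold seeds are `seed + fold_index`.

Cross-validation is at the patient level: a seeded permutation of patient ids
split into k near-equal folds (sizes differ by at most one; 285 patients and
10 folds give validation folds of 28 or 29). Every patient is evaluated
exactly once, by the model that never saw it.

### Scaled-down problem sizes

The full-scale configuration (512x512, base 64, 200 epochs, 285 patients) is
what the defaults describe; the shipped tests and the acceptance script
exercise the same code paths at miniature sizes chosen as the package's test
conditions: 64x64 phantoms with a depth-3 / base-16 network for the overfit
check (4 cases, 30 epochs, augmentation off) and a 6-case, 2-fold, 25-epoch
cross-validation for the end-to-end run. At ~120 optimizer steps the paper-
scale learning rate 1e-4 cannot move RMSprop-normalized weights appreciably,
so the scaled-down runs use 1e-2 — the top of the stated 1e-2/1e-3/1e-4
tuning grid; the pipeline default remains 1e-4.

## Evaluation metrics

DICE and JACCARD are exact voxel-count ratios; the identity
J = D / (2 − D) holds to rational-arithmetic precision and is asserted.

Distance metrics are computed in 3D on the stacked native grid in
millimetres, honoring anisotropic spacing — one value per ROI per patient, as
cohort reporting requires (a 2D per-slice mode is exposed as an option for
sensitivity checks). Surfaces are foreground voxels with at least one
background 6-neighbor, the grid border counting as background; distances are
Euclidean between voxel centers (no surface meshing — simpler, and exactly
reproducible by a brute-force oracle). HD95 takes the 95th percentile (linear
interpolation) of the *pooled* union of the two directed surface-distance
sets; the max-of-directed-percentiles variant found elsewhere in the
literature is selectable (`pooling="max_directed"`). AHD is the mean of the
two directed average surface distances.

Degenerate cases are deterministic and flagged rather than exceptional: both
masks empty → overlap 1; exactly one empty → overlap 0; HD95/AHD undefined
(NaN) unless both masks are nonempty, with undefined counts carried into the
cohort report.

Cohort aggregation reports per-ROI means and a 95% range, computed by default
as the empirical 2.5th–97.5th percentile across patients; a bootstrap CI of
the mean is the alternative (`interval="bootstrap"`), since published "95%
CI" columns can mean either.

## Sequence ablation and registry

The ablation plan enumerates the seven channel combinations — each sequence
alone, each pair, and all three — and runs one cross-validation per
combination with the input channel count following the subset size. Fold
splits are shared across combinations (same seed), so rows are comparable and
results are invariant to the order combinations are listed. Comparison
architectures are registry slots (`register_model`); only the two attention
U-Net wirings are built in.

## Known limitations

* Phantom realism, as above: results on phantoms bound what the pipeline can
  show about clinical data.
* The numpy engine is single-threaded BLAS-bound; a full-resolution forward
  pass takes tens of seconds, so full-scale 200-epoch training is out of
  reach here — the defaults document the configuration rather than promise
  desk-scale runtime.
* Inputs are assumed co-registered; no registration, bias-field correction or
  DICOM handling is provided.
* Batch normalization statistics come from small batches at the miniature
  scales; eval-mode running statistics can lag train-mode behavior early in
  training.
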