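# Methods

## The problem

Vision-transformer pipelines for volumetric medical images tokenize a fixed
array shape, so heterogeneous acquisitions (different voxel spacing, matrix
size, origin, field of view) are conventionally resampled or resized to a
common grid first. Resampling costs spatial resolution; random cropping
avoids that cost but leaves the network with no way to know *where in the
scanner* a voxel was acquired, because patch-wise positional embeddings
encode array position only. `geoppe` implements the alternative: a
pixel-wise embedding of each voxel's *physical* position, computed from
image metadata, added to the intensities before tokenization.

## The embedding

Every tomographic header carries the affine that places voxel indices in
the scanner's mm frame: the origin (physical center of voxel `(0,0,0)`),
the per-axis spacing, and a 3×3 orthonormal direction matrix. The physical
center of voxel `(i,j,k)` is

    p = origin + direction @ (spacing * (i, j, k)).

The embedding is a radial sinusoid of that position,

    PPE(p) = sin(ω · ‖p‖) / S,

with two hyperparameters: the angular frequency ω (rad/mm), which sets the
radial period, and the scaling factor S, which bounds the amplitude to 1/S
so the positional signal cannot dominate the (unit-variance, normalized)
intensity signal. Defaults are ω = 1 and S = 100, the best-performing
cells of the reference ablations over ω ∈ {0.1, 1} and
S ∈ {1, 10, 100, 1000, 10000}.

Three structural properties follow directly and are what the test suite
pins down:

* **Resolution/FOV invariance** — the field's value at a physical point is
  independent of the grid sampling it. Two acquisitions that share voxel
  centers agree there to float precision; an array-index embedding does not
  (the suite carries this negative control).
* **Rotation invariance** — only ‖p‖ enters, so any orthogonal transform of
  the frame about the device origin leaves the field unchanged. This also
  makes the embedding indifferent to RAS-vs-LPS header conventions, which
  differ by axis signs about the same origin; the package stores whatever
  frame the header provides and does not convert.
* **Crop equivariance** — cropping updates the origin to the start voxel's
  physical center, so the field of a cropped geometry is the corresponding
  sub-block of the full field.

Because sin is periodic, the embedding is ambiguous across radial shells;
it is intended to complement, not replace, the regular patch-wise embedding
(macro patch position), and the benchmark includes the ablation arm that
drops the regular embedding.

## Tokenization

A `(C, H, W, D)` volume is split into non-overlapping `P³` patches
(`N = HWD/P³` of them), each flattened to length `P³·C`; tokens are
`Patches @ W + PE_patch` with `W` a learned `(P³·C) × K` projection. The
patch scan order is row-major over the `(H/P, W/P, D/P)` block grid —
arbitrary but frozen, since a learnable patch embedding is only meaningful
under a fixed order. Non-divisible shapes are rejected rather than padded:
silent padding would decouple array content from the geometry used to
compute the embedding. The regular patch embedding supports `learnable`
(truncated-normal, trainable), `sinusoidal` (fixed interleaved sin/cos
bands over patch index), and `none` (the ablation arm).

## Preprocessing arms

Order of operations: per-channel standardization → (random crop | resample
to shape) → add PPE (crop arms that include it) → random per-axis flips →
patchify → tokens. Choices the order encodes:

* Normalization first, so the 1/S amplitude bound is meaningful against
  unit-variance intensities.
* PPE on the *post-crop* geometry (equal to cropping the full-image field,
  by crop equivariance).
* PPE before flips: a flip is intensity augmentation — it permutes voxels
  without changing their acquisition-time physical positions — so image and
  embedding must flip jointly to preserve the voxel↔embedding pairing. The
  flipped volume keeps its geometry for the same reason.
* Labels get the identical spatial transforms, nearest-neighbour under
  resampling, and never receive normalization or the embedding.
* Crop starts are uniform over valid positions (no lesion-biased sampling);
  one explicit seed per sample drives all randomness.

The resample arm interpolates trilinearly in physical space onto the
FOV-preserving grid (`new_spacing = spacing·size/new_size`, origin shifted
half a voxel so FOV edges coincide).

## The phantom generator

The generator reproduces the statistical structure the embedding exploits,
with every case on its own grid:

| parameter | default | meaning |
|---|---|---|
| spacing | U(1, 4) mm, one isotropic draw per case | acquisition resolution heterogeneity |
| matrix size | {32³, 48³, 64³} | sequence-length heterogeneity |
| FOV center | U(−12, 12) mm per axis | origin jitter |
| lesion center | N(0, 5 mm), clipped ±10 mm | target anchored near device origin |
| lesion radius | U(5, 10) mm | target scale |
| decoys | 2–3 spheres, centers ≥ 30 mm from origin | same appearance, unlabeled |
| texture | smoothed white noise, σ = 8 mm, unit SD | background structure, resolution-independent scale |
| contrast | 3.0 | conspicuous hyperintensity, as in diffusion imaging |
| edge softening | σ = 0.7 voxel | partial-volume effect at the lesion rim |
| noise | SD 0.1 | white acquisition noise |

The label is exactly binary (voxel = 1 iff its physical center lies in a
drawn *target* sphere); only the *image* uses the softened indicator.
Spacing is isotropic per case by default (per-axis draws are available) so
that voxel aspect is not a nuisance factor a small training set must
marginalize. The *decoys* carry the identical intensity signature but sit
far from the origin-anchored target prior: intensity alone cannot separate
target from decoy, physical position can, and array indices cannot (the
grid varies per case). Small fields of view geometrically exclude the
periphery and may contain fewer or no decoys. Contrast is high enough that
detection itself is tractable at desk scale — the benchmark's intended
difficulty is *where*, not *whether*. With spacing up to 4 mm and ω = 1,
the sinusoid is aliased on the coarsest grids (ω·spacing > π); the field's
values remain exact at voxel centers and a documented warning is emitted.

What the phantoms do **not** emulate: anatomy-dependent intensity priors,
multi-contrast channels with differing appearance, scanner bias fields,
anisotropic partial-volume blurring, oblique direction matrices in the
training data, or targets whose position correlates with array index.
Passing benchmarks here therefore show that the embedding restores
physical-space awareness under geometric heterogeneity — not that it
improves any particular clinical task.

## Evaluation stack

* **Dice**: `2|P∩G|/(|P|+|G|)`; both-empty returns 1 by convention.
* **HD95**: surfaces are mask voxels removed by a 6-connectivity erosion
  (array-edge voxels count as surface); distances between surface-voxel
  centers in mm via spacing; statistic is the 95th percentile (linear
  interpolation) of nearest distances pooled from both directions. Tested
  against an O(n²) all-pairs oracle.
* **True-positive-component HD95**: predicted 26-connected components with
  ≥ 1 overlapping voxel are kept before HD95 — appropriate for multi-focal
  targets where distant false positives would otherwise dominate. No
  overlapping component → undefined (NaN, never an exception); undefined
  cases are excluded from means and counted.
* **Wilcoxon signed-rank**, two-sided, zero differences dropped: for ≤ 15
  non-zero pairs the null is enumerated exactly over all 2ⁿ sign
  assignments on average ranks (handles ties); larger samples use the
  tie-corrected normal approximation. Bonferroni correction multiplies by
  the comparison count and caps at 1.

## The demo segmenter

A small CPU transformer in numpy with explicit forward/backward passes:
patch projection + patch-wise embedding, two pre-LayerNorm encoder blocks
(4-head self-attention, GELU MLP at ratio 2), final LayerNorm, and a
per-token linear head emitting P³ voxel logits, scattered back to the
volume and refined by one pass of a fixed separable trilinear kernel
(0.25, 0.5, 0.25; zero-padded, hence self-adjoint, which keeps the
backward pass exact). The head additionally receives the raw patch through
an elementwise skip (a per-voxel gain on the input): without an input-level
skip the K-dimensional token bottleneck cannot represent voxel-level
intensity rules at all, and the segmenter underperformed plain intensity
thresholding. Loss is soft-Dice + binary cross-entropy; optimizer is Adam.
Gradients are verified against central finite differences in the test
suite. Parameters default to float32 (float64 available; the gradient
check uses it).

Desk-scale defaults: 32³ ROI, P = 8 (64 tokens), K = 64, depth 2, learning
rate 3e-3, batch 4, 1000 Adam steps, best-validation-Dice checkpointing
over a fixed set of seeded validation views — sized so that the full
benchmark (4 arms × 3 seeds, each 48 train / 8 validation / 16 test cases)
runs on one CPU in roughly ten minutes. These are the package's own
choices for a model ~10⁴× smaller than the GPU-scale architectures the
embedding was originally evaluated with; they are not a reproduction of
that protocol (300 epochs, batch 1, lr 1e-4).

Comparisons are paired end to end: arms trained with the same seed share
the model initialization, batch order, crop positions and flips (the
training stream is deliberately arm-independent), and evaluation
preparation is deterministic (centered crop, no flips), so per-case scores
feed paired Wilcoxon tests. The benchmark reports mean test Dice per arm.
The reference ordering at clinical scale is crop+PPE > crop ≥ resample and
regular+PPE ≥ PPE-only; at this package's scale the crop-vs-resample gap
reproduces robustly, while the embedding-vs-no-embedding margins sit at
training-noise level (see Known limitations). Magnitudes are phantom- and
scale-specific and are not comparable to clinical numbers.

## Numerical notes

* Radii are accumulated in float64 before the sine; the field is cast to
  the image dtype only on addition.
* "Exact" equalities that involve re-associated float additions (crop
  origin shift, add-then-subtract round trips) hold to < 1e−12 absolute,
  not bit-for-bit; tests assert accordingly.
* Constant channels normalize to zeros behind an ε-guard (std < 1e−8) with
  a warning.
* Voxelized sphere volumes fluctuate by far more than one voxel volume
  (3D lattice-point counting error grows ~ r^1.4 in lattice units); phantom
  volume checks therefore use a surface-layer half-voxel-diagonal bound,
  the scale at which binary voxelization can actually agree.
* Degenerate Wilcoxon input (all differences zero) returns p = 1 with a
  warning; fewer than 5 non-zero pairs is an error.

## Known limitations

* Oblique (sheared) affines are rejected; only orthonormal direction
  matrices are supported. 2D and 4D-time geometries are out of scope.
* The embedding is a single scalar field shared by all channels; channels
  on different sampling grids are rejected rather than resampled.
* The demo segmenter fixes its token count at build time (one ROI shape);
  sliding-window inference and multi-scale decoders are out of scope.
* **The embedding's Dice benefit is not resolvable at desk scale.** The
  method is documented at its source as suited primarily to large
  datasets, and its advantage vanished even at clinical scale when
  acquisitions were homogeneous. Here, with 48 training cases and 1000 CPU
  Adam steps, the crop+PPE vs crop margin is of the same order as
  run-to-run training noise (per-seed deltas within roughly ±0.1,
  configuration means within ±0.02 of zero across an ω/S/architecture
  exploration). Per-case diagnostics show the mechanism acting in
  individual runs — reduced decoy false positives at coarse spacing —
  without surviving averaging. The benchmark therefore demonstrates the
  geometric properties (field invariances, pipeline correctness, paired
  evaluation machinery) and the crop-vs-resample resolution effect
  robustly, while the embedding-vs-none ordering should be read as a
  scale-limited, noise-level comparison. The regular-PE vs none ablation
  is equally noise-level here: under random cropping, patch index carries
  almost no task information.
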