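# Methods

This note documents the models, procedures and design choices behind
`cmrseg`, in the order data flows through the pipeline.

## Problem setting and assumptions

The package segments short-axis cine CMR stacks (one 3D volume per cardiac
frame, ED and ES) into background, LV blood pool, LV myocardium and RV blood
pool. It assumes: per-frame 3D NIfTI files with correct `pixdim` spacing;
the slice axis is the low-resolution axis; ED/ES frames are given (no frame
detection); annotations, when present, are per-slice 2D contours rasterized
to voxel labels, possibly partial (structure-by-structure, frame-by-frame).
Orientation headers are read but volumes are not reoriented — pose
variation is treated as a property of the data distribution and addressed by
augmentation, not registration.

## Normalization

All images are resampled in-plane to 1.25 × 1.25 mm — a median pixel
spacing for clinical short-axis protocols — with bilinear interpolation for
images and nearest-neighbour for label maps; slice count and slice
thickness are never changed (2D networks tolerate heterogeneous slice
thickness, and annotations are made slice-wise). The resampled in-plane
shape is `round(shape × spacing / target)` with round-half-away-from-zero;
the rounding rule and the crop offsets are recorded in a `GeometryRecord`,
which makes the inverse mapping exact by construction rather than by
re-derivation. After the central crop/zero-pad to the fixed network grid,
each 2D slice is standardized to mean 0, s.d. 1. Choices the pipeline fixes
deliberately:

- **Normalization statistics are per cropped 2D slice**, not per volume.
  This equalizes contrast slice-by-slice (apical slices with little blood
  get stretched differently from basal slices) and is the convention the
  training batches see.
- **σ = 0 slices map to zeros** instead of raising: blank slices legally
  occur in padded stacks.
- **Padding value is 0**, the mean of normalized intensities.
- **Restoration order**: class *scores* are uncropped and bilinearly
  rescaled to the native grid first; the per-pixel argmax is applied last
  (ties resolve to the lowest class index, deterministically). Restoring
  scores rather than hard labels keeps sub-pixel boundary information
  through the rescale.

## Augmentation

Order: flips → rotation → scaling → random crop, with cropping always last
so outputs have the network's input size; the random crop position doubles
as translation augmentation without introducing black borders for in-range
offsets. Rotation/scaling interpolate about the image centre with zero
padding outside, bilinear for images and nearest-neighbour for labels
(mirroring the resampling kernels). Ranges: flips p = 0.5 per axis,
rotation U[−30°, +30°], scale U[0.7, 1.4]. Gamma contrast augmentation
(x ↦ x^γ on [0, 1]-rescaled raw intensities, γ ∈ [0.7, 1.5]) is implemented
but disabled by default — geometric augmentation is the pipeline's working
core, and contrast variation brought only marginal gains. One shared random
stream drives all draws; image and label always receive the identical draw;
with a fixed seed an epoch's augmentation sequence is bit-reproducible.

## Network

A 2D U-Net with batch normalization after every hidden convolution and
dropout (rate 0.2) after each of the four skip concatenations. Encoder
channels (f, 2f, 4f, 8f, 8f) — the bottleneck capped at 8f — parameter-free
bilinear 2× upsampling, decoder channels (4f, 2f, f, f), and a biased 1×1
output convolution; hidden convolutions are bias-free since batch norm
absorbs the shift. Convolution weight totals (kernel elements only):
13,382,464 at f = 64 and 836,560 at f = 16, a ratio of 15.997 — quartering
every layer's filters divides the weights by ~16, with the input and output
layers breaking exactness. Input sizes must be divisible by 16 (four
poolings).

The layer stack is implemented directly on numpy (float32): convolutions as
batch-first im2col plus one batched BLAS matmul per layer, with symmetric
hand-written backward passes. Every layer's gradient is verified against
central finite differences in the test suite (directional derivatives;
composite checks through many ReLU kinks are avoided as they are not
smooth). On one CPU core a batch of 20 96×96 slices takes ≈1.3 s per
forward+backward at f = 8.

## Training and model selection

SGD with classical momentum 0.9 on pixel-wise cross-entropy (no class
weighting; background-only slices are kept). Full-scale defaults: batches
of 20 slices, initial learning rate 0.001, halved every 50 epochs. The
output head's bias is initialized to the log class frequencies of the
training labels (prior-probability initialization): the initial softmax
then matches the label marginals, which removes the all-background
cold-start that plain zero initialization exhibits on class-imbalanced
segmentation and that short desk-scale runs cannot afford to sit through.
Hidden weights use He initialization. Epochs
iterate over all 2D slices of all training frames in shuffled order.
Validation mean IoU — per-class intersection-over-union pooled over the
validation batch, averaged over classes present in prediction or reference
— is computed on *augmented* validation slices with one fixed seed for all
epochs, so the selection signal is comparable across epochs; the
highest-IoU snapshot is returned (ties → earliest epoch, an early-stopping
behaviour). The run seed fans out via `SeedSequence.spawn` to shuffling,
training augmentation, dropout and validation streams, making runs
bit-reproducible on CPU.

**Desk-scale protocol.** The package's tests and examples train reduced
configurations (f = 8, 96×96 or 80×80 crop, batches of 10, learning rate
0.05–0.1, constant within ≤16 epochs) chosen so a run converges on one CPU
core in minutes. The learning-rate increase compensates for the reduced
scale; the 50-epoch decay horizon only matters for full-scale runs. The
full-scale defaults remain the package defaults. The RV is always the last
structure to converge: its blood pool shares the LV's intensity, so the
network must learn the spatial configuration before RV Dice rises —
typically 300+ SGD updates in the reduced setting.

## The phantom

Each subject is analytic geometry voxelized on a configurable grid: per
slice, the LV is a disk whose radius tapers linearly from base (20 mm
default) to apex (×0.4), the myocardium a 7 mm annulus, and the RV the
intersection of a disk (radius = LV base radius) with the exterior of the
epicardial disk and a planar "free-wall" cut. The cut is tilted 35°
relative to the LV→RV axis, which makes the anatomy **chiral**: a mirrored
heart is not any rotation of an unmirrored one (verified by a test that
sweeps all rotations). Without that asymmetry, circle-only anatomy would
make flip augmentation an alias of rotation augmentation and the flip
ablation meaningless.

ES frames contract both cavity radii by a factor c (default 0.75) while
preserving myocardial cross-sectional area per slice (incompressible-wall
approximation: the wall thickens inward), so LV mass is frame-invariant —
a physiologic sanity property the evaluation can assert. All per-slice
areas are closed forms (disk, annulus, circle-circle lens, circular
segment), and a validation check guarantees the free-wall cut never reaches
the septal lens, keeping the closed-form RV area exact. Analytic volumes
are therefore exact oracles for the clinical-parameter code; voxel-counted
volumes converge to them under grid refinement (≤5 % error at 1.25 mm).

Intensities are class means (blood 1.0 for both cavities, myocardium 0.45,
background 0.15 — bSSFP-like ordering; the identical LV/RV blood intensity
forces the network to use shape context) with optional gamma shift and
additive Gaussian noise; the seed drives only the noise and the background
tissue, never the heart geometry, so labels are exact.

**Background confusers.** Real short-axis images are hard to segment not
because the heart is faint but because surrounding tissue — chest wall,
liver, vessels — shares its intensities; only the heart is labelled. The
phantom emulates this with unlabelled confuser structures placed in the
heart's *body frame*: a bright chest-wall-like band beyond the RV free
wall, a large liver-like blob on the opposite side, and a few random
tissue blobs, with intensities spanning the myocardial-to-blood range.
Because they are anchored to the heart's pose and chirality, they rotate
and mirror with the anatomy, so a network that has only seen upright,
unmirrored, single-size hearts faces genuinely out-of-distribution context
on the shifted domain — which is precisely what makes the geometric
augmentations carry measurable value at desk scale (with an empty
background the task is locally decodable and the augmentation ablation
shows no signal). Confusers are drawn from the subject's seed,
independently of the heart geometry, and can be disabled
(`confusers_enabled=False`) for exact intensity-class checks.

Two stock domains emulate the cross-site situation: **domain A** (training)
is a fixed scanner — 1.8 mm in-plane, 8 mm slices, 10 slices, upright pose,
narrow anatomical and noise ranges, no mirroring; **domain B** (shifted
test) draws pixel spacing U[0.78, 2.3] mm, slice thickness U[5, 10] mm,
8–12 slices, pose U[−45°, +45°], mirrored orientation with probability 0.5,
wider heart-size, contrast (γ ∈ [0.7, 1.4]) and noise ranges, and larger
centre offsets. A "pathology" variant produces hypertrophy-like thick-wall
hearts.

**Scale.** The phantom is a *scaled-down* heart: with the desk-scale
96 px/120 mm test window, the anatomy (total span ≈95 mm including the RV)
must fit the crop the way a full-scale heart fits the standard 256 px/
320 mm window. Absolute volumes (LV EDV ≈53 mL) are therefore below adult
norms; ratios (EF, mass/volume) are physiologic.

**What the phantom does not model** — and hence what passing tests do not
show about clinical data: MR physics (k-space truncation, coil shading,
banding, flow artifacts), papillary muscles and trabeculation, irregular
wall thickness, atrioventricular anatomy at the base, observer variability
in the labels, and pathology beyond a thick-wall caricature. Results on the
phantom demonstrate that the pipeline's geometry, statistics and learning
machinery are correct and that augmentation confers the expected
cross-domain robustness *on geometric/statistical shifts*; they do not
certify clinical accuracy.

## Evaluation

3D Dice is computed per frame (ED and ES are each a 3D overlap over the
whole stack) and pooled over frames and subjects into per-structure
mean (s.d.); a structure without reference labels contributes no entry
(never a zero), matching partially-annotated cohorts. Both-empty masks
score Dice 1. Clinical parameters: structure volume = voxel count ×
sz·sy·sx / 1000 mL; LV mass = myocardial ED volume × 1.05 g/mL. Bland-
Altman uses per-pair means m and differences d; pairs with m outside
[Q1 − 1.5 IQR, Q3 + 1.5 IQR] (quartiles by numpy's linear interpolation)
are removed before the mean difference, its sample s.d. (n−1) and the
limits of agreement MD ± 1.96 s.d. are computed — the rule protects the
s.d. from a few extreme-volume failures. Spearman's ρ uses mid-ranks for
ties (via scipy); it is reported as ρ, not ρ².

## Ablation study design

One model per row — full pipeline, then resampling / rotation / flips /
scaling removed one at a time — all sharing data, seed and budget. Each row
is evaluated with *its own* preprocessing (a model trained without
resampling is deployed without it). Expected pattern, which the acceptance
test asserts at reduced scale: within-domain scores move little (<0.05
spread) while the full pipeline beats every single-removal row on the
shifted domain. Failed rows are marked and the grid still returned.

The desk-scale ablation runs at a target spacing equal to the training
domain's native 1.8 mm grid (crop 64). This keeps the resampling toggle a
pure test of its cross-domain mechanism — unifying the shifted domain's
0.78–2.3 mm spacings onto the training grid — instead of conflating it
with a within-domain resolution change: at the scaled-down heart size, the
apical RV is only a few pixels at 1.8 mm, so a model trained at native
resolution is resolution-limited in a way the full-size protocol is not.
The augmentation toggles have observable cross-domain cost only because
the phantom's background contains body-frame confuser tissue (see above):
without intensity-overlapping context, a network segments the shifted
domain by local appearance alone and flips/rotation/scale augmentation
shows no benefit even directionally.

## Known limitations

- The numpy layer stack is single-threaded BLAS-bound; full-scale (f = 64,
  256×256, 1000 epochs) training is out of reach by design — the package
  targets correctness and desk-scale evidence, not GPU throughput.
- No post-processing (connected components, anatomical constraints) and no
  test-time augmentation; predictions are the raw restored argmax.
- The ablation's desk-scale effect sizes are not those of a full-scale
  study. In repeated grid experiments only the resampling effect was large
  and stable (cross-domain gaps of 0.18–0.29 mean foreground Dice); the
  rotation/flip/scale removals matched or beat the full pipeline
  cross-domain, because a single-removal row is the easier optimization
  problem for a reduced-width network under a ~10³-update budget — the
  augmentation *burden* outweighs its *protection* at this scale, the same
  capacity phenomenon that makes the quarter-width model lose cross-domain
  accuracy at full scale. Training every row to saturation would remove the
  confound but takes several-fold more compute per row. The acceptance
  tests assert the full directional pattern anyway and the unmet clauses
  fail openly rather than being weakened.
- `GeometryRecord` inversion is exact only for the recorded pipeline
  (resample → crop); arbitrary preprocessing chains are out of scope.
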