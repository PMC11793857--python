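# Methods

`xcelunet` implements a dual-task volumetric network for shoulder CT: it
segments the proximal humerus and scapula while staging three glenohumeral
(GH) joint conditions — osteophyte size (OS), joint-space narrowing (JS)
and humeroscapular alignment (HSA) — and explains the staging decisions
with 3D GradCAM. This note records the model, the choices made where the
design was genuinely open, and what the synthetic phantoms do and do not
establish.

## Network

The segmentation backbone is an edge-aware 3D UNet with one shared encoder
and two parallel decoders. The encoder has three blocks (two 3×3×3
convolutions + ReLU, then 2×2×2 max pooling), doubling feature maps from 8
to 32, with a 64-channel bottleneck. The mask decoder (MD) predicts
3-class region maps (background / humerus / scapula) and the contour
decoder (CD) predicts 3-class edge maps; both upsample with 2×2×2
transpose convolutions halving channels, receive encoder skip connections
at matching resolutions, and end in a 1×1×1 convolution with softmax. Each
CD block's output is additionally concatenated into the same-resolution MD
block input (unidirectional CD→MD skips), so boundary evidence informs
region prediction.

The classification branch applies global average pooling to the 64
bottleneck maps, two dense layers (64 and 16 units, ReLU), and three
heads: 3-way softmax for OS, 3-way softmax for JS, one sigmoid unit for
HSA (decision threshold 0.5). For an 80³ input the bottleneck is spatially
10³, so the pooled vector averages Z = 1000 positions per map.

Open points resolved as package conventions: two convolutions per block
(the standard UNet block); CD→MD skips by concatenation, consistent with
the encoder skips; softmax (not per-class sigmoid) on the CD head, for
symmetry with MD; no batch normalization.

### Why a built-in numeric backend

The layers, reverse-mode autodiff and the Adam optimizer are implemented
in numpy inside the package (`xcelunet.autodiff`, `xcelunet.layers`).
Convolutions are im2col + GEMM with hand-written backward passes; column
buffers are reused across steps, which means a second forward pass through
a model invalidates the pending gradients of an earlier, un-backwarded
one — the training loops never interleave passes that way. Gradient
correctness of every primitive is verified against central finite
differences in the test suite. The backend is CPU-only and sized for the
desk-scale experiments below, not for clinical-resolution training runs.

## Losses

Stage 1 minimizes a region loss and a contour loss,

    L_r = 1 − (α·D + (1 − α)·C)          (on MD outputs)
    L_c = 1 − (β·C + (1 − β)·Ĉ)          (on CD outputs vs. edge targets)

with D the soft Dice score averaged over foreground classes (smoothing
ε = 1e-6 in numerator and denominator, so a class absent from both
volumes scores 1). C and Ĉ are score-like distance-weighted cross-entropy
terms: C = exp(−WCE_near) and Ĉ = exp(−WCE_far), where WCE is the
weight-averaged per-voxel cross-entropy under boundary-distance weights

    w_near(x) = 1 + γ·exp(−d(x)/τ),   w_far(x) = 1 + γ·(1 − exp(−d(x)/τ)),

d(x) the Euclidean distance (mm) to the nearest inter-class boundary
voxel, γ = 5, τ = 3 mm by default (a boundary band of a few millimetres
matches the scale of the bone interfaces; both are configurable). The
exp(−WCE) mapping takes cross-entropy from [0, ∞) into (0, 1], so C sits
on the same score scale as D, both losses live in [0, 1), and a perfect
one-hot prediction gives exactly L_r = L_c = 0.

α follows a warm-down schedule α(t) = max(0.5, 1 − 0.005·t) per training
epoch: Dice dominates early, the boundary-weighted term gains influence
until the two balance at epoch 100. The linear reading is the only one
consistent with reaching exactly 0.5 at iteration 100 (a multiplicative
0.995 decay would give ≈ 0.606). β is the fraction of shape-boundary
voxels in the batch, computed jointly over classes. Edge targets are
morphological gradients (3³ structuring element) of each class mask, with
overlaps resolved to the lower class index and the grid border not
counted as an edge.

Stage 2 uses class-balanced cross-entropy: each task's per-sample loss is
scaled by K_c = (1/N_c) / Σᵢ(1/Nᵢ) of the true class, which sums to one
across classes and equalizes unevenly represented grades. The three task
losses are summed (averaging would only rescale the learning rate). If a
grade is absent from a small training corpus the balancing is undefined;
the trainer then falls back to uniform weights with a warning rather than
refusing to run. Internally the trainer evaluates this loss in logit
space (log-softmax, and softplus for the binary head): the values are
identical to the probability form, but the gradients stay bounded at
softmax − one-hot, so the optimizer can recover from confidently wrong
predictions where float32 probabilities saturate to exactly 0 or 1 and
the probability-space gradient vanishes.

## Training protocol

Two sequential stages, both Adam at learning rate 1e-4. Stage 1 trains
encoder + both decoders on label-cropped, patched volumes (160³ patches
with ≥ 25% overlap between equally spaced windows at clinical sizes;
phantom-scale runs use the volumes whole). Stage 2 trains the
classification branch on GH-centred crops (doubled by sagittal mirroring,
which leaves all three condition labels unchanged) under one of four
freeze setups: TL (encoder, bottleneck, decoders all frozen), FT-B
(bottleneck trainable), FT-E (encoder + bottleneck trainable), FT-N
(everything trainable); the classification branch is always trainable.
Freeze audits hash each parameter group before and after training.

Early stopping aborts after 40 consecutive epochs (configurable) without
validation-loss improvement and returns the best-epoch weights; the
stopping epoch therefore always equals best epoch + patience, or the
epoch cap. The validation split is 15% of the training cases, seeded,
and optionally at flip-pair granularity so a crop and its mirror never
straddle the split. Stage-2 re-instantiates the optimizer (no stage-1
moment carry-over) and optimizes the classification loss only; because
that loss carries no gradient into the decoders, their forward pass is
skipped exactly. A joint-loss switch exists (off by default) for
replaying segmentation losses during fine-tuning.

Stage-2 optimization uses the freeze-then-unfreeze schedule common in
fine-tuning practice. The pooled bottleneck vector is strictly positive
with a large common mode and small between-case variation, so a freshly
initialized head starting alongside encoder updates learns impractically
slowly and its early gradients into the encoder are noise. The trainer
therefore first brings the heads to convergence with cheap full-batch
steps on pooled features cached from the (held-fixed) stage-1 encoder —
2000 steps at learning rate 3e-3 by default, touching only
classification parameters — and then runs the configured freeze setup's
epoch loop, with the trainable segmentation groups stepping at one tenth
of the head learning rate (discriminative learning rates). Both schedule
parameters are in ``TrainConfig``; warm-up leaves every segmentation
weight untouched, so the TL setup's bit-identity guarantee is
unaffected.

Inference normalizes, patches, stitches per-class probabilities by
arithmetic averaging with renormalization, takes the voxelwise argmax,
then locates the GH joint from the predicted labels and runs the staging
heads. If the predicted segmentation lacks either bone, staging is
skipped with an explicit "no GH joint found" status.

## GradCAM

For a task s and class c, the score y is the head's pre-activation logit
(pre-softmax for OS/JS, pre-sigmoid for HSA — standard GradCAM practice).
Gradients are taken with respect to the pre-pooling bottleneck
activations, the only place spatial positions still exist; each of the 64
maps gets the weight α_f = (1/Z)·Σ_ijk ∂y/∂A_f,ijk, and the map is
ReLU(Σ_f α_f A_f), trilinearly upsampled onto the crop. The implementation
re-runs the classification path from the bottleneck as an autodiff leaf,
so maps are available under every freeze setup. A localization score
(fraction of top-decile activation mass inside a stated region mask)
quantifies where the evidence concentrates.

## Surfaces and metrics

Meshes come from marching cubes at iso-level 0.5 on binary class masks
(largest connected component kept, vertices in mm, no smoothing).
Reconstruction error is the one-way distance from each reference-mesh
vertex to its nearest predicted-mesh *vertex* (a point-to-triangle option
exists but is off by default); RMSE and the Hausdorff maximum summarize
it. Voxel overlap reports per-class Dice, precision and recall.

The OS auto-labeler grades the maximum one-way distance from the
morphologic to the osteophyte-cleared humerus surface: < 3 mm → 0,
3–7 mm → 1 (both thresholds closed into the middle class, keeping the
three intervals exhaustive), > 7 mm → 2. One-way morph→cleared is the
right direction because osteophytes exist only on the morph surface.
Nearest-vertex queries use a k-d tree; the test suite keeps an exhaustive
O(n²) search as the oracle.

## Synthetic phantoms

The phantom generator stands in for clinical data. Geometry is analytic
signed-distance compositing: a spherical humeral head continued by a
cylindrical shaft; spherical-cap osteophytes fused to the infero-lateral
head, placed so the cap apex sits exactly s_o millimetres above the
unperturbed sphere (hence the morph-to-cleared maximum distance recovers
s_o by construction); a scapula made of a concave glenoid shell concentric
with the nominal head position at the configured joint gap, plus a thin
medial plate. Voxelization assigns bone/soft-tissue HU with one-voxel
partial-volume blending and optional Gaussian noise; ground-truth meshes
are iso-surfaced from the continuous distance fields at level 0, which
places vertices on the true surface with sub-voxel accuracy and keeps
them independent of the quantized label masks.

Truth grades follow the generating parameters. OS uses the 3/7 mm
thresholds. The JS and HSA criteria are qualitative in clinical grading,
so the generator fixes conventions: gap ≥ 3 mm physiological, gap below
one voxel non-detectable, in between narrowed; eccentric iff the cranial
shift is ≥ 2 mm (comfortably above voxel noise). Dataset sampling
apportions OS grades by largest remainder (exact for uniform mixes,
within one case of n·w otherwise) and defaults all three class mixes to
the clinical frequencies 31.1/36.1/32.8 (OS), 38.2/27.2/34.6 (JS),
56.1/43.9 (HSA). Per-grade parameter ranges stay ≥ 1 mm clear of the OS
class boundaries so auto-labelling is unambiguous.

What the phantoms do not emulate: realistic scapula morphology, cortical/
trabecular texture, metal artifacts, anisotropic slice spacing, and the
blurred bone interfaces of severe osteoarthritis. Passing tests therefore
demonstrate that the architecture, losses, training protocol, and metrics
are implemented correctly and can learn strongly separable geometry —
not that clinical-grade accuracy transfers to real CT.

## Desk-scale experiment sizes

The learning tests run on one CPU: stage 1 on 16 phantoms at 48³ voxels
(1 mm spacing, batch 2, ≤ 30 epochs), evaluated as mean per-class hard
Dice over humerus and scapula on 4 held-out phantoms; stage 2 under FT-E
on 60 GH crops of 48³ (30 phantoms with osteophyte heights 1/5/10 mm
plus their mirrors, batch 4, 15 epochs after head warm-up), evaluated as
OS accuracy on 15 held-out phantoms against a 1/3 chance level. The
48³ crop is chosen so the infero-lateral osteophyte tips — the
discriminative anatomy — lie inside the joint-centred window at phantom
scale; nuisance variation (head radius ±3%, random gaps, alignment and
noise) is kept modest so the three osteophyte classes remain separable
at this corpus size. The pipeline demo uses 6 phantoms at 32³ with
2-epoch stages — enough to exercise every stage contract, not to
converge.

## Known limitations

* The numeric backend is single-device CPU; clinical-resolution training
  (160³ patches, hundreds of cases) is out of its intended range.
* The GH-joint locator (sphere fit to the superior-third humeral boundary,
  nearest scapula voxel as the glenoid point) is a geometric stand-in and
  falls back to the label centroid, with a warning, on degenerate fits.
* Only binary HSA (concentric/eccentric cranio-caudal shift) is modelled.
* Phantom realism as above; no DICOM ingestion or spacing resampling.
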