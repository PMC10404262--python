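# Methods

## Model and procedure

The framework transfers tissue labels (background, CSF, GM, WM) from one
labeled *source* domain to a chain of unlabeled *target* domains whose
intensity statistics drift away from the source. It has four moving parts.

**Segmentation backbone.** A 3D dense-block encoder–decoder. Seven dense
blocks sit along a contracting path (full, 1/2, 1/4 resolution), a
bottleneck (1/8), and an expanding path (1/4, 1/2, full) with skip
connections; each block stacks three BN–ReLU–Conv(3³)–Dropout units whose
inputs are the concatenation of everything earlier in the block. Each
convolution has `16 * size_scale` kernels with dropout 0.1; 1³
"compression" convolutions reduce each block's output to the growth width
before 2× average-pool downsampling or nearest-neighbor upsampling. The
head is a 1³ convolution with per-voxel softmax over C = 4 classes.
Training minimizes the voxel-mean cross-entropy
`-Σ_i Y_i ln X_i` on randomly extracted two-channel patches, with Xavier
initialization and SGD (lr 0.005, ×0.1 after each epoch).

**Confidence model.** A two-level 3D U-Net that maps the one-hot automated
segmentation concatenated with its four probability maps (8 input channels)
to a per-voxel reliability score in (0, 1) via a logistic head. Targets are
binary agreement maps (1 where automated = manual) obtained by K = 2 fold
self-testing: each fold is segmented by a model trained on the other fold,
so the error statistics match those the confidence model will face on
unseen data. The loss is `-(Y ln X + a (1-Y) ln(1-X))` with a = 0.1: the
complement term of the (far more numerous) correct voxels is down-weighted
to counter the volume imbalance between correct and misclassified voxels.
The two models are optimized strictly separately — the confidence model is
trained only after its segmentation model is done. One confidence model,
trained on the source domain, is reused for every target domain.

A consequence worth stating: for local error probability q the
loss-optimal confidence is `q / (q + a(1-q))`, which falls below the 0.5
gate only when q > 1/(1+a) ≈ 0.91. The gate therefore zeroes only voxels
that are almost surely wrong — gross anomalies such as topological defects —
while ordinary boundary uncertainty is retained with mildly reduced weight.
The adaptation gains flow mostly from confidence-*weighted* self-training
rather than from hard exclusion.

**Confidence-gated self-training.** For a target domain, the current model
produces pseudo-labels (arg-max of its fused probability maps) and the
confidence model produces `M_cp`; weights are
`w(x) = M_cp(x)` where `M_cp(x) >= 0.5`, else 0 (threshold inclusive). A
new model, warm-started from the current one, is trained with the
spatially-weighted cross-entropy `-w Σ_i Y_i ln X_i`, normalized by the
count of positively weighted voxels so the effective step size does not
shrink as the gate tightens; all-masked patches contribute zero and are
skipped. Background participates like any other class.

**Gradual label propagation.** Domains are traversed in order
(24m → 18m → 12m → 9m → 6m → 0–3m analogs). At step k the step-k−1 model
pseudo-labels domain k, and every previously traversed domain is
re-designated as source: the labeled source subjects (weight 1) and each
earlier domain's self-segmented volumes (with their gate weights)
accumulate into a replay bank that contributes patches alongside the new
domain's. Adaptation patch centers cycle over CSF / GM / WM /
any-foreground voxels of the (pseudo-)labels. Both choices address the same
failure mode, which we observed directly at desk scale: WM occupies ~1 % of
the volume, and under uniform sampling without replay, each step's
pseudo-label noise erodes WM recall multiplicatively until the class
vanishes from the chain. Warm-starting from the previous model (rather
than retraining from scratch) is what makes a two-epoch desk-scale
adaptation meaningful; it is switchable (`warm_start=False`) for ablation.

**Inference.** Whole volumes are segmented by sliding-window patch
inference on a regular grid with 50 % overlap; per-voxel class
probabilities are averaged over covering patches and renormalized to the
simplex; the label is the per-voxel arg-max with ties broken toward the
lowest class code. Inputs are z-scored per channel over an Otsu foreground
mask, so training and inference are insensitive to global intensity scale.

## The phantom

The generator emulates the structural and statistical challenges of the
real task at desk scale:

* **Geometry.** WM is a recursively branched tree (trunk radius 3 voxels,
  children shrinking in length by 0.65 and radius by 1 per level, with a
  meandering direction walk), guaranteeing a single 26-connected WM
  component. GM is the Euclidean shell of configurable thickness (default
  2 voxels) around WM; CSF a further 2-voxel shell; the rest background.
  Any GM voxel entirely surrounded by GM (a pocket between branches) is
  relabeled CSF so GM is a true shell.
* **Domain series.** Channel 0 is T1w-like (CSF dark < GM < WM bright),
  channel 1 T2w-like (inverted CSF/WM ordering). Along the age-descending
  series the GM–WM mean gap decays geometrically, `|gap| = g0 (1-d)^k`
  with d = 0.3 per step, and at the final domain it flips sign on both
  channels — emulating the isointense-to-inverted myelination contrast of
  the youngest infant scans (unmyelinated WM reads darker than GM on T1w
  and brighter on T2w). CSF, being water, keeps its contrast at every age.
  Additive Gaussian noise grows by 10 % per step (a Rician option exists).
  Rendering draws per-voxel tissue intensities, applies a Gaussian
  partial-volume blur (σ = 0.8 voxels), then adds noise.
* **Defects.** "Holes" (interior WM balls relabeled GM) and "handles"
  (spurious WM bridges grown from the WM surface) can be injected with a
  returned change mask, kept ≥ 8 voxels apart so each defect is one
  connected mask component.

Calibration principle: every domain in the default series remains in the
supervised-learnable regime — a model trained *in* the youngest domain with
true labels reaches WM Dice ≈ 0.88 — mirroring the real setting, where
even neonatal scans are segmentable by a fully supervised system. The
series' difficulty is in the *transfer*, not in the domain itself.

What the phantom does not emulate: anatomically realistic lobule geometry,
bias fields, motion artifacts, inter-subject anatomical variability beyond
the seeded tree, or multi-site protocol differences other than the
intensity/noise schedule. Passing tests therefore demonstrate that the
mechanism works under controlled contrast collapse and inversion — not
clinical-grade accuracy on real MRI.

## Desk-scale study conditions

All seeded protocol runs (tests and `scripts/acceptance.py`) use: 48³
phantoms at nominal 0.8 mm spacing, branch depth 3, GM thickness 2;
`size_scale = 0.25` (4 kernels per convolution); patch size 16; four
labeled source subjects (128 patches each for the source model, 64 for the
K-fold models), two unlabeled volumes per target domain (96 patches each),
96 confidence patches per subject with centers alternating between
foreground and disagreement voxels; 2 epochs, batch 4, SGD lr 0.005 ×0.1
per epoch with momentum 0.9. Adaptation quality is evaluated per domain as
the mean Dice over that domain's two testing subjects (self-trained on
without labels, mirroring the transductive evaluation of the real
protocol) plus one fully held-out subject. The momentum value is a package
default: the optimizer family and learning-rate schedule are as stated
above, and plain momentum-free SGD cannot move a freshly initialized
network in the small step counts these conditions allow. The reference
configuration (`size_scale = 1.0`, 32³ patches, 1000 patches per subject)
is the documented full-scale setting; it is not exercised by the test
suite.

## Numerical choices

* Probabilities are clamped to [1e-7, 1] (confidence values to
  [1e-7, 1-1e-7]) before logs, so all losses are finite at saturation.
* The engine computes in float32, channels-last; 3D convolutions are one
  BLAS matmul per kernel offset ("same" zero padding), the fastest
  pure-numpy formulation at these patch sizes; gradients are verified
  against central differences in the test suite.
* Batch normalization uses batch statistics in training (running-estimate
  momentum 0.1) and running estimates at inference.
* HD95: surface voxels are mask voxels with a face-adjacent (6-connected)
  neighbor outside the mask, with out-of-bounds counting as outside;
  directed nearest-surface distances are scaled by voxel spacing; the
  95th percentiles use linear interpolation; HD95 is the max of the two
  directed percentiles (symmetric under argument swap). Classes absent
  from a volume yield NaN ("undefined") rather than a score.
* Patch sampling draws corners uniformly over positions whose window
  intersects the foreground; fixed patch sets per training run (no
  per-epoch resampling). All generators and trainers are pure functions of
  their arguments and seeds; single-threaded runs are bit-reproducible.
* Resampling to isotropic spacing uses linear interpolation for
  intensities and nearest-neighbor for labels; a volume already at target
  spacing is returned unchanged.

## Known limitations

* The dense-block backbone follows the published block counts and block
  contents; the exact inter-block wiring (compression widths, pool/upsample
  operators, skip placement) is fixed here and recorded in
  `SegModelConfig`, since no full layer table is published for the
  reference architecture.
* With a = 0.1 the confidence gate rarely fires outside gross anomalies
  (see above); retained-voxel fractions near 1.0 are expected, not a bug.
* The desk-scale conditions are small enough that single-voxel effects
  matter: Dice comparisons across seeds have a spread of a few points, and
  the acceptance properties are asserted over three seeded runs rather
  than point estimates.
* The confidence model consumes whole-volume (post-fusion) probability
  maps; patchwise pre-fusion probabilities are not exposed.
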