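# Methods

`fedct` simulates, end to end, a two-stage semi-supervised federated
learning workflow for partially labeled 3D cardiac CT: per-task
convolutional teachers trained with federated averaging, pseudo-labeling of
each site's unlabeled data, distillation of all tasks into one multi-head
attention-based student, and head-only finetuning on the human labels.
Everything runs against a synthetic aortic-root phantom federation so that
every stage can be scored against known ground truth on one CPU.

## The phantom federation

The phantom is deliberately stylised: a contrast-filled cylinder (blood
pool, default 300 HU) whose axis is the annulus normal, embedded in a
background of −50 HU; three hinge points (RCC, LCC, NCC) on a ring of
radius 12 mm at nominally 0°/120°/240° with configurable angular jitter
(default ±5°); two coronary ostia 8 mm above the annulus plane at 0.8× ring
radius; two membranous-septum points below the RCC–NCC midpoint (MS1 upper,
MS2 lower, 4 mm apart); and 1–3 calcific spheres of 1.5–3 mm radius at
~900 HU near the ring.  Additive Gaussian noise (25 HU) and a per-sample
translation of the annulus center (uniform ±3 mm per axis) provide
inter-patient variability.  The heart mask is a dilated cylinder covering
every foreground structure.

What the phantom reproduces faithfully is the *label structure* of a
multi-centre federation, which is what the method is about: skewed
per-client label availability, large unlabeled fractions, per-annotator
systematic bias (a fixed 3-vector per annotator, drawn with ~1 mm scale)
plus isotropic scatter (default 1.5 mm), and occasional MS1/MS2 id swaps.
What it does not reproduce: CT physics (beam hardening, motion, contrast
timing), anatomical shape variability, anisotropic fields of view, or
inter-scanner intensity differences.  Passing tests therefore demonstrate
the *mechanics* of the pipeline — label routing, aggregation, distillation,
provenance, QC — and directional learning behaviour, not clinical-grade
accuracy.

Two federation presets exist.  `tiny` (the test preset) has 4 clients × 12
volumes at 32³ voxels (2 mm spacing), with skewed labeled counts
(HCO 5/5/4/4, MS 4/0/4/3, CALC 0/5/4/4) and client D held out for every
task.  `consortium` reproduces the 8-location count structure of a real TAVI
federation
(8104 volumes; 251 HCO labels over 7 locations; 116 MS over 3; 118 CALC
over 3; locations 6+7, 7, and 6 held out respectively).  Only the
row/column totals, the extreme location sizes (3001 and 20), and the
held-out sets of that structure are fixed by the scenario; the remaining per-location
counts are a fixed choice consistent with all of them.  The preset is
validated and plannable (topology, aggregation weights, splits) on any
machine; materializing all 8104 volumes is a batch-scale run, not part of
the test suite.

Random streams are split hierarchically: federation seed → client seed
(derived via a CRC of the client id, so adding a client never changes
another client's data) → per-sample seed.  All generation is a pure
function of (spec, config, seed).

## Preprocessing

CT volumes are normalized with fixed reference constants: clip to
[−1024, 696] HU (the reference 5th/95th percentiles), subtract μ = −438.61,
divide by max(σ, 1e−8) with σ = 520.98.  The constants are part of the
contract — every federation client applies the identical mapping; nothing
is recomputed per dataset.  Heart-ROI cropping takes the tight bounding box
of the (supplied or phantom) heart mask plus a world-mm margin and updates
the origin so world coordinates are preserved; resampling maps voxel
centers with linear (images) or nearest (masks) interpolation, keeping the
first voxel center fixed.  Landmarks live in world mm everywhere; the voxel
grid appears only inside the label codec, which makes every metric
invariant to crop/resample round-trips.

## Label codec

Point annotations become per-channel Gaussian heatmaps evaluated at voxel
centers, exp(−‖x − p‖²/2σ²) with σ = 3 mm (≈1.5 voxels at the default
spacing) — wide enough that the half-maximum support spans several voxels
for sub-voxel decoding, narrow enough that neighbouring landmarks (the MS
pair, 4 mm apart) remain separable.  Decoding takes the intensity-weighted
centroid over voxels ≥ 0.5× the channel maximum; exact ties in the maximum
resolve to the lowest linear index, and a channel with non-positive maximum
decodes to an *absent* landmark with a warning flag rather than an
arbitrary position (an argmax mode exists as a fallback).  The round-trip
error bound, checked over 100 random phantoms, is half the voxel diagonal.
Whether the original workflow regressed heatmaps or segmented small spheres
is not recorded anywhere we could rely on; the codec is isolated in one
module precisely so it can be swapped.

## Networks and loss

Both architectures are size-parameterized; tests run tiny configurations,
full-scale ones are constructible.  The implementation is a compact
reverse-mode autodiff on numpy (same-padding 3D convolution, 2× pooling and
nearest upsampling, instance/layer norm, windowed or global self-attention,
CE/Dice losses), every operator gradient-checked against central
differences.

**Teacher** — a residual 3D U-Net per task: residual conv blocks with
instance normalization, average-pool downsampling, nearest upsampling with
1×1×1 projections and additive skips, and a 1×1×1 output conv per
resolution level for deep supervision.  Default tiny scale: 8 base filters
(4 for the calcification task, see below), 2 levels; the full-scale
configuration (32 base filters, 5 levels) is constructible.  Input is
2-channel: normalized CT concatenated with the heart mask (conditioning by
concatenation; the mechanism is a design choice — the source describes
feeding the heart segmentation as a condition without specifying how).

**Student** — a patch-attention encoder–decoder with three heads: 8³-voxel
patches are linearly embedded (learned positional embedding), processed by
pre-norm transformer blocks whose self-attention runs within local windows
of the token grid (the default "windowed" variant) or globally ("plain"),
then decoded back to full resolution by conv+instance-norm upsampling,
fused with a full-resolution conv stem.  Three 1×1×1 convolution heads —
HCO (5 channels), MS (2), CALC (1) — share the entire backbone.  This is a
desk-scale stand-in for the full-scale windowed-attention architecture, not
a reproduction of its layer structure.

Output-head biases initialize at −4 (foreground prior ≈ 2%), the standard
trick for extremely sparse targets; without it the early Dice gradient is
swamped.

**Loss** — per supervision level, binary cross-entropy plus soft Dice
(ε = 1e−5 in numerator and denominator), summed with weights ∝ 2^−l
normalized to 1 (the deepest levels contribute least; the practice is
standard, the exact weights are our choice).  Heatmap channels are treated
as independent soft-target binary problems: landmark Gaussians overlap
spatially, so a cross-channel softmax would be wrong.  Targets are
downsampled per level by block averaging (soft heatmaps) or nearest
striding (hard masks).  Multi-task samples take the *mean* of per-task
losses over present tasks only; heads of absent tasks are never part of
the graph, so their gradient is exactly zero — this is the partial-label
routing the whole design turns on.

**Optimization** — AdamW (decoupled weight decay 1e−4), batch size 1
(samples are whole volumes), constant learning rate.  The teacher uses
lr = 0.01 of the full-scale configuration.  The full-scale student lr of 1e−4 is calibrated to
full-scale training with ~10⁴–10⁵ steps; AdamW's per-step displacement is
bounded by the learning rate, so at the tiny preset's ~360 steps that
setting cannot move the network appreciably.  `StudentConfig` keeps 1e−4 as
the default; the tiny preset overrides it (current preset value: see
`fedct.pipeline.tiny_config`), a scale-regime choice, not a tuned constant.
Teacher capacity is matched per task in the tiny preset: the point tasks
need enough width to disambiguate ring azimuth (8 base filters), while the
bright-blob segmentation trains fastest small (4).

## Federation simulation

Clients train sequentially in-process with isolated random streams — the
parallel hub-and-spoke topology produces the same result, so sequential
execution buys bit-reproducibility on one machine.  Each round: broadcast
server state → `epochs` local epochs per client → weighted parameter mean.
Default weights are per-client labeled training counts ("a popular FedAvg
variant" is all the provenance there is, so the weighting is pluggable:
`sample-count` or `uniform`).  Before averaging, (state, weight) pairs are
sorted by (weight, state checksum); floating-point addition is not
associative, so this canonical order is what makes the aggregate exactly
invariant to client permutation.  A federation of one client with one round
is bitwise identical to plain local training.  Optimizer state is local to
each client round (the server exchanges parameters only).  There is no
networking, TLS, or authentication — trust is simulated.

Schedules: the full-scale schedule is 20 rounds × 10 local epochs; the tiny
preset uses 5 × 2.  Local test splits reserve 20% per client (25% in the
tiny preset, i.e. 3 of 12); held-out clients' *entire* shards form the
"other" split.

## Distillation stages

*Pseudo-labels (1B)*: each trained teacher predicts on every sample lacking
a human label for its task; predictions are decoded to *hard* labels
(point sets / binarized masks) — format-identical to human labels except
for provenance flags.  Human labels are never overwritten.  A point channel
whose peak probability stays below 0.25 is degenerate: the pseudo-label is
stored but flagged and excluded from training (excluding teacher failure
modes rather than imputing them).  Soft-label distillation is deliberately
not the default; the workflow distills from hard pseudo-labels.

*Distillation (2A)*: the student trains federated over **all** clients on
their training samples, pseudo- and human-labeled together (whether the
original mixed them is unrecorded; both modes are supported, mixing is the
default since the human labels are finetuned on afterwards anyway), with
routed loss.

*Head finetuning (2B)*: per task, federated over that task's training
clients, human labels only, updating only that head's parameters.  After
each aggregation the frozen partition is restored bitwise from the
broadcast state (the floating-point mean of identical values is not bitwise
identical).  A runtime assertion verifies the backbone checksum is
unchanged.  Federated (rather than per-site) finetuning mirrors the stage-1
topology; the alternative is one flag away.

*Transfer*: a fresh 1×1×1 output conv is trained on a new single-target
segmentation task (the phantom's blood-pool tube) over frozen backbone
features, probing feature quality exactly as a last-layer-only probe.

## Evaluation

Landmark tasks score per-landmark Euclidean distance in world mm against
the generator's ground truth (never visible to training); absent predicted
landmarks are reported and counted but excluded from means.  Segmentation
scores Dice, with both-empty = 1.0 by convention (logged).  Tables pool
per-sample values within each (task, model, split) cell — pooling over
samples, not over client means; the alternative is available and the two
agree to 1e−12 when client sizes are equal.  "Training" pools training
clients' local test sets; "other" pools held-out clients' samples.

Inter-observer variability: per (sample, landmark), each annotator's
distance from the across-annotator mean point, pooled.  For k annotators
with isotropic σ the expectation is σ·2√(2/π)·√((k−1)/k); the simulation
reproduces it within 5% at 10⁴ draws.

## Geometry QC

Operates on coordinates only — privacy by construction.  Each annotation is
registered to its own annulus frame: plane through the three hinge points,
centroid at the origin, normal oriented toward the ostia (fallback MS1),
in-plane rotation minimizing Σ wrap(θᵢ − idealᵢ − φ)² with the
landmark-to-ideal assignment fixed *by name* so id mix-ups surface as large
residuals instead of being hidden.  The rotation search uses a coarse grid
(0.25°) to pick the wrap configuration followed by the exact closed-form
minimum (mean of wrapped deviations); sum of squares was chosen over
absolute deviations (the objective is configurable in principle — the
original inspection is visual and records no objective).  MS points are
additionally expressible in a similarity frame of the RCC–NCC segment
(origin at the midpoint, scale-normalized by the segment length).

Anomaly rules: an id-swap is flagged when MS1 (the upper point by
definition) registers below MS2 along the annulus normal; an outlier when a
registered coordinate deviates from the per-landmark federation median by
more than 3× the MAD (median distance from the median point) *and* more
than 0.5 mm — the MAD rule alone is scale-free, so without an absolute
floor arbitrarily tight clusters could still be flagged.  Both thresholds
are configuration.

## Numerical choices and degenerate inputs

- float64 throughout the autodiff; numerically stable sigmoid/log1p forms
  in the losses; ε = 1e−5 Dice smoothing keeps all-zero/all-one
  predictions finite.
- Collinear hinge points, empty crop masks, coincident RCC/NCC, samples
  with no usable labels, channel-count and grid mismatches: explicit
  errors naming the offending quantity.
- All-zero prediction channels degrade to absent-with-flag, not errors.
- Checkpoints embed a config hash; loading into a mismatched configuration
  is refused.

## Problem sizes

The default test suite and the acceptance script run the tiny preset: 48
volumes at 32³, teachers of ~10⁵ parameters, 5 rounds × 2 epochs, one
seeded run — chosen so the full chain (three teachers, pseudo-labeling,
distillation, finetuning, evaluation, QC) completes in minutes on one CPU
while still exhibiting the qualitative behaviour the full-scale method
claims: federated teachers that localize on held-out clients, a student
that gains its teachers' skills on unlabeled data, heads that finetune
without touching the backbone, and distilled features that transfer better
than random ones.

## Known limitations

- The phantom's geometric regularity makes localization easier than real
  anatomy; absolute errors are not comparable to clinical numbers.
- Attention at 4³–6³ token grids cannot show the large-data advantages of
  full-scale transformers; directional claims only.
- Batch size 1 and no augmentation (unrecorded in the source; conservative
  defaults).
- The FedAvg variant is the plain weighted mean; momentum-style server
  optimizers are out of scope.
- Instance-norm statistics are per-sample, so there is no train/eval mode
  distinction; this differs from batch-norm-based U-Nets.
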