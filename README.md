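# fedct

Semi-supervised **fed**erated knowledge distillation for partially labeled
3D cardiac **CT** — with a synthetic phantom federation so the whole
pipeline runs, and is tested, on one CPU without clinical data.

## The problem

Multi-centre imaging collaborations rarely share one label set: in a
TAVI-planning consortium, every site may annotate the aortic-valve hinge
points and coronary ostia (HCO: RCC, LCC, NCC, RCO, LCO), but only a few
annotate the membranous septum (MS1/MS2) or segment aortic-root
calcification, and most volumes carry no labels at all.  Privacy rules
keep the images at each site, so neither the labels nor the unlabeled data
can be pooled centrally.

`fedct` implements a two-stage answer:

1. **Stage 1** — one convolutional teacher per label type (a residual 3D
   U-Net) is trained with federated averaging across the sites that own
   that label: clients train locally, a server averages parameters
   (weighted by labeled sample count) each round.
2. **Stage 1B** — the trained teachers predict on every unlabeled volume at
   every site, producing *hard pseudo-labels* (decoded point sets, binarized
   masks) that are format-identical to human labels.
3. **Stage 2A** — a single attention-based student with one output head per
   task distills all three teachers at once, training federated over all
   sites on pseudo- and human labels with *task-routed loss*: a sample
   lacking a task contributes exactly zero gradient to that head.
4. **Stage 2B** — each head is finetuned on human labels only, with the
   shared backbone frozen bitwise.

Around the training core: fixed-constant CT normalization
(clip to [−1024, 696] HU, then (x − μ)/σ with μ = −438.61, σ = 520.98),
heart-ROI cropping, NIfTI and MITK point-set I/O, per-landmark mm /
Dice evaluation split into "training" vs "other" (held-out) clients,
inter-observer variability analysis, and a privacy-preserving label-QC
module that registers landmark sets to a canonical annulus frame (plane of
the three hinge points, rotation minimizing deviation from the ideal
0°/120°/240° directions) to flag MS1/MS2 id swaps and outliers from
coordinates alone.

Every stage is exercised on a synthetic aortic-root phantom: a stylised
blood-pool cylinder with hinge points on the annulus ring, ostia above the
plane, MS points below, bright calcific blobs, simulated annotators
(bias + scatter + occasional id swaps), and a skewed partial-label
federation.  Ground truth is known, so held-out accuracy, routing
correctness, and QC recall are all measurable.

## Worked example

```bash
python examples/03_federated_teachers.py
```

trains the membranous-septum teacher for 5 federated rounds × 2 local
epochs on the 4-client tiny federation and evaluates on the held-out
client:

```
per-round mean training loss:
  round 0: 1.002 (client weights [3.0, 2.0])
  round 1: 0.958 (client weights [3.0, 2.0])
  round 2: 0.909 (client weights [3.0, 2.0])
  round 3: 0.914 (client weights [3.0, 2.0])
  round 4: 0.823 (client weights [3.0, 2.0])

held-out client D: mean MS landmark error 1.98 mm over 12 samples
```

The loss is the deep-supervised CE+Dice objective; the error is the mean
Euclidean distance of the decoded MS1/MS2 points from the generator's
ground truth on a client whose data never entered training — i.e. the
generalization the federated approach is for.  For scale: the annulus ring
radius is 12 mm and the simulated annotators scatter by 1.5 mm, so ~2 mm is
close to the label noise floor.

The full chain (teachers → pseudo-labels → distilled multi-head student →
head finetuning → result table) is one call:

```bash
fedct all --config tiny --out runs/demo --seed 1      # CLI
python examples/04_distillation_pipeline.py            # same, from Python
```

which writes `results_table.csv` with mean ± sd per (task, model,
training/other split), the federation manifest, per-stage logs and
checkpoints, and a run manifest with seeds and checksums.  Other examples:
`01` phantom + federation anatomy, `02` preprocessing and file round-trips,
`05` privacy-preserving geometry QC, `06` inter-observer variability vs its
closed form.

## Layout

| | |
|---|---|
| `fedct.phantom` | synthetic volumes, annotators, federations (+ `consortium` preset with the 8-site label-count structure of a real TAVI federation) |
| `fedct.preprocess` | normalization, crop, resample, NIfTI / MITK `.mps` I/O |
| `fedct.labelcodec` | point ↔ heatmap codec, mask binarization |
| `fedct.models` | teacher / student networks, CE+Dice deep supervision, routed loss, AdamW (on an internal numpy autodiff) |
| `fedct.federation` | FedAvg, local training, stage-1 orchestration |
| `fedct.distill` | pseudo-labels, stage-2 distillation, head finetuning, last-layer transfer |
| `fedct.evaluation` | mm / Dice metrics, result tables, inter-observer |
| `fedct.geometry_qc` | annulus-frame registration, swap/outlier flags, QC reports |
| `fedct.pipeline`, `fedct.cli` | configured, logged, resumable runs; `fedct` CLI |

Design and modelling details are in [`docs/methods.md`](docs/methods.md).
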