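# roiprog

**ROI-based deep-learning Progressive Index for conversion prediction from
structural brain MRI.**

Predicting which cognitively normal older adults will progress to mild
cognitive impairment (MCI) requires detecting subtle, spatially localized
structural change years before symptoms. `roiprog` implements a two-step,
atlas-driven convolutional framework for this problem:

1. **Screening (SRNet).** For every region of interest (ROI) in a label
   atlas (e.g. the 116-parcel AAL), a small 3D CNN is trained on the cubic
   patch extracted at that ROI's centroid, and the region's discriminative
   capability is recorded as its held-out AUC. Regions are ranked and the
   top K = 10 selected.
2. **Scoring (MRNet).** A multi-ROI network stacks K = 10 parallel branches
   that **share one backbone parameter set**, concatenates their features
   (10 × 64 = 640) into a single fully-connected softmax head, and is
   trained on the progressive-vs-stable contrast. The positive-class
   probability of a subject's scan is their **Progressive Index (PI)** — a
   continuous score in [0, 1] read as the propensity to progress.

The shared backbone is five 3×3×3 convolutional layers (ReLU; channels
16, 32, 64, 64, 64) with stride-2 max-pooling after the first four layers and
global average pooling after the fifth: a 32³ patch maps through
32 → 16 → 8 → 4 → 2 → 1 to a 64-dimensional feature vector. Training
minimizes the binary cross-entropy
`L = −[y log F(M) + (1 − y) log(1 − F(M))]`.

The package also provides the evaluation layer such a score needs
(mean-threshold sensitivity/specificity, rank-sum AUC and bootstrap ROC CIs,
covariate-adjusted group contrasts and logistic odds ratios, age-adjusted
partial correlation) and a **synthetic phantom-cohort generator** that plants
a configurable atrophy-like signal in chosen ROIs, so the entire pipeline is
buildable, testable and benchmarkable without access to any restricted
neuroimaging dataset. The networks and their training loop are implemented
directly in numpy with hand-written backpropagation (verified against finite
differences in the test suite); everything is seeded and exactly
reproducible. See `docs/methods.md` for the full model description.

Intended users: neuroimaging methods researchers who want a transparent,
dependency-light reference implementation of ROI-screening + multi-ROI
scoring, and anyone needing a controlled phantom benchmark for patch-based
3D classifiers.

## Worked example

A complete run on a small synthetic cohort (45 subjects: 20 stable, 20
progressive, 5 with unknown outcome; 12 spherical ROIs of which 1–3 carry
the planted effect):

```yaml
# run.yaml
out_dir: demo_run
master_seed: 7
channels: [4, 8, 16, 16, 16]   # reduced backbone for 16^3 patches
patch_size: 16
epochs: 4
batch_size: 8
learning_rate: 0.002
shape: [48, 48, 48]
n_rois: 12
roi_radius: 4
informative_labels: [1, 2, 3]
intensity_shift: 0.5
erosion_fraction: 0.1
noise_sd: 0.2
n_per_group: {sNC: 20, pNC: 20, rNC: 5}
k: 4
n_boot: 500
```

```sh
roiprog all -c run.yaml
```

This simulates the cohort, screens all 12 ROIs, trains the multi-ROI model
on the top 4, scores every subject and writes the statistics. Key outputs:

`demo_run/auc_table.csv` — per-ROI screening AUCs; the three planted ROIs
are found immediately:

```
label_id,name,auc,n_train,n_val
1,roi_1,1.0,32,8
2,roi_2,1.0,32,8
3,roi_3,1.0,32,8
4,roi_4,0.5625,32,8
5,roi_5,0.5,32,8
```

`demo_run/ranking.json` — `selected: [1, 2, 3, 11]` (the planted regions
plus one noise region to fill k = 4).

`demo_run/metrics.json` — mean-threshold classification of the scored
cohort (threshold = mean PI over all 45 subjects, including the 5 with
unknown outcome; counts over the 40 labeled):

```json
{"threshold": 0.5467, "sensitivity": 1.0, "specificity": 1.0, "auc": 1.0,
 "counts": {"TP": 20, "FP": 0, "TN": 20, "FN": 0}}
```

`demo_run/stats.json` — the progressive-vs-stable group contrast on PI
(t = 38.5, p ≈ 5e-32) and the unadjusted logistic model of outcome on PI
(OR 1.94 per point of PI × 100; flagged non-converged here because the
planted effect separates the classes perfectly).

At this effect size (intensity shift 0.5 against noise SD 0.2) the phantom
task is easy by design — the run demonstrates the mechanics end to end.
Weaker shifts give intermediate AUCs and PI gaps; a null cohort gives
chance-level screening AUCs (that is what the acceptance study below
measures).

Every stage can also be run separately (`roiprog simulate|screen|train|
score|metrics|stats -c run.yaml`); stages are restartable from their
declared artifacts, and two runs with the same `master_seed` produce
byte-identical PI tables.

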