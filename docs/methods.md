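# Methods

## The model

`roiprog` implements a two-step, region-of-interest (ROI) based convolutional
framework that maps a skull-stripped, spatially normalized 3D structural brain
image `M` and an integer ROI label atlas to a continuous **Progressive Index
(PI)** in [0, 1].

**Backbone.** Both steps share one feature-extractor architecture: five
3×3×3 convolutional layers with ReLU activations and channels
(16, 32, 64, 64, 64); a stride-2 max-pool follows each of the first four
layers and a global average pool follows the fifth. A 32³ input patch
traverses the spatial chain 32 → 16 → 8 → 4 → 2 → 1, so the output is a
64-dimensional feature vector. Convolutions use same-padding with stride 1 —
the only padding convention under which this chain closes without cropping.
The head is a single fully-connected layer to 2 logits with softmax; the
positive-class probability is the network's score. Training minimizes the
binary cross-entropy `L = −[y log F(M) + (1 − y) log(1 − F(M))]` in its
equivalent two-logit softmax form (probabilities are clipped to
[1e−7, 1 − 1e−7] before logs for numerical safety).

**Step 1 — screening (SRNet).** For each candidate ROI, one single-backbone
network is trained on the cubic patch extracted at that ROI's centroid, and
its AUC on a held-out stratified validation split is recorded. ROIs are
ranked by descending AUC (ties broken by ascending label id — the tie rule is
a package decision) and the top K (default 10) are selected. The screening
AUC is deliberately computed on held-out data, not the training split, since
an over-parameterized network's training AUC is uninformative. By default
screening uses the same progressive-vs-stable composite contrast as training;
`screen_contrast="ad_vs_nc"` restricts to AD/NC-tagged rows when the cohort
vocabulary permits.

**Step 2 — multi-ROI scoring (MRNet).** K parallel branches evaluate **one
shared backbone parameter set** on the K selected ROI patches (branch order =
ranking order, serialized in the checkpoint because the FC head is
order-sensitive); the concatenated K×64 feature vector feeds a single FC
layer to 2 logits. The PI of a subject is the trained MRNet's positive-class
probability. The K=1 case is exactly an SRNet.

**Evaluation layer.** Mean-threshold classification (threshold = mean PI over
*all* scored subjects, unknown-outcome subjects included; PI ≥ threshold
calls positive; sensitivity/specificity/AUC over known-label rows only),
rank-sum (Mann–Whitney) AUC with ties credited 0.5, ROC curves with a
stratified percentile-bootstrap 95% CI (default 2000 resamples, seeded),
per-group PI summaries with a linear-model progressive-vs-stable contrast
(unadjusted it reduces exactly to the pooled two-sample t test), nested
covariate-adjusted logistic regressions with Wald odds ratios and 95% CIs
(complete-case per model, dropped rows counted), and an age-adjusted partial
Pearson correlation (residualize both variables on [1, covariate]; p from the
t transform with n−3 degrees of freedom).

## Numerical and implementation choices

- The networks, backpropagation and the Adam training loop are implemented
  directly in numpy (im2col convolutions; the input-gradient of a same-padded
  convolution is computed as a same-padded convolution with the spatially
  flipped, channel-transposed kernel; max-pool subgradients split evenly
  across tied maxima). Gradients are verified against central finite
  differences in the test suite. Training runs in float32; every stochastic
  choice (initialization, stratified split, epoch shuffling) consumes a named
  sub-seed derived by SHA-256 from one master seed, so runs are exactly
  reproducible and screening results are independent of execution order.
- Weight initialization is He-normal (fan-in of the 3³ kernel); biases start
  at zero. Defaults: Adam at learning rate 1e-3, batch size 8, stratified
  validation fraction 0.2. The optimizer, rates and epoch counts are
  engineering choices exposed in `TrainConfig`, not claims about how any
  reference model was trained.
- Patch extraction uses 0-based voxel indices and the half-open window
  `[c − size//2, c + ceil(size/2))`, so an even patch size (32) has a
  well-defined centre voxel; out-of-bounds voxels are zero-filled, so border
  ROIs still yield full-size patches. ROI centroids are per-axis means of
  voxel indices rounded half-to-even, computed in the atlas voxel grid (no
  world-coordinate transforms; images are assumed co-registered).
- Per-patch intensity standardization (z-scoring; constant patches map to
  zeros) is applied just before the network input and is on by default. A
  uniform intensity shift of a whole patch therefore carries no signal; class
  contrasts must appear as *structure within* the patch, which is exactly
  what the ROI-localized phantom effect produces.
- The shipped AAL-116 lookup table is the standard public 116-parcel naming
  (90 cerebral + 26 cerebellar/vermis regions) numbered 1..116 in atlas
  order. It is documentation for readable outputs; the user supplies the
  actual label volume, and no registration resources ship with the package.

## The synthetic phantom cohort

The generator emulates the statistical structure the classifier assumes, not
MRI realism: a parcellation of non-overlapping random spheres; background
intensity 0.2 and ROI tissue 1.0 (fixed, so effect sizes are interpretable);
for progressive subjects (label 1) the informative ROIs are darkened by
`intensity_shift` and the outermost `erosion_fraction` of their voxels —
ordered by distance from the centroid, ties broken deterministically — reset
to background (an atrophy proxy); i.i.d. Gaussian noise of SD `noise_sd` is
added everywhere. Subjects with unknown follow-up (`r*` group tags) are drawn
from the stable process and carry a missing label. Group tags reuse the
longitudinal-cohort vocabulary (sNC/pNC/rNC, sSCD/pSCD/rSCD, AD/pMCI/sMCI) so
the evaluation code paths are exercised with realistic cohort structure.

What it does **not** model: MRI texture, bias fields, partial-volume effects,
deformation-based atrophy, registration error, longitudinal trajectories.
Passing tests on phantoms therefore demonstrate that the pipeline recovers
planted, ROI-localized class differences under additive noise — not that it
attains any particular accuracy on real neuroimaging data.

### Benchmark study conditions

The fixed benchmark (`roiprog.benchmark`) uses 48³ volumes, 30 spherical ROIs
of radius 4, ROIs {1, 2, 3} informative, intensity shift 0.5, erosion 0.1,
noise SD 0.2, 100 subjects per class, and the **reduced backbone** (channels
4-8-16-16-16) on 16³ patches — the same five-layer structure with the
spatial chain 16 → 8 → 4 → 2 → 1 at a fraction of the full 32³ compute, which
keeps a 30-ROI × 10-replicate screening study at desk scale. Screening nets
train for 2 epochs of Adam at lr 2e-3, batch 16 (the planted contrast is
strong, and identical settings are used for signal and null cohorts); the
multi-ROI stage trains 6 epochs at lr 1e-3.

Because a 16³ patch window is wider than a radius-4 sphere, a patch centred
on a *non-informative* ROI that neighbours an informative one can see part of
the planted signal — the same spillover a real atlas patch has over adjacent
parcels. In a signal cohort, uninformative regions are therefore not expected
to sit exactly at chance; recovery is judged by the planted ROIs reaching the
top of the ranking. In a *null* cohort (no planted signal anywhere) every ROI
is expected at chance, and the screening validation AUC of a single replicate
scatters around 0.5 with SD ≈ 0.09 at a 20+20 validation split — so the null
check averages each ROI's AUC across the 10 seeded replicate cohorts (SD of
the mean ≈ 0.03) before asserting proximity to chance; asserting the band per
replicate across 30 ROIs would reject a correct implementation almost surely.

## Known limitations

- CPU-only; the numpy training loop is adequate for patch-scale networks and
  simulation studies, not for full-resolution production training runs.
- Perfectly separated logistic models are reported as non-converged fits
  (with a lightly ridge-regularized fallback for diagnostics) rather than
  implementing exact/Firth logistic regression.
- The combined PI+clinical model's ROC is in-sample (apparent) by design,
  matching single-cohort reporting practice; no cross-validated variant is
  run by default.
- Odds ratios are reported per unit of PI×100 by default (`pi_scale=100`),
  since per-unit ORs on a 0–1 score are unreadable; the scale is recorded in
  the term name of every output.
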