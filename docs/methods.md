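# Methods

## Problem setting

Response assessment in pediatric Hodgkin lymphoma hinges on comparing a
baseline FDG PET/CT scan (PET1) with an interim scan after two
chemotherapy cycles (PET2).  Baseline disease is bulky and hot (lesion
SUVmax typically above 10 g/mL); residual interim disease is faint
(SUVmax around 2 g/mL) and easily confused with physiologic uptake, so
readers grade it against two reference regions — mediastinal blood pool
and liver — on the 5-point Deauville scale.  `longipet` implements a
dual-time-point segmentation network plus the full quantification and
evaluation stack around it, exercisable end-to-end on synthetic
phantoms with known ground truth.

## Network

The segmenter is a UNet-shaped encoder-decoder: a 3-D shifted-window
transformer encoder (patch embedding of stride 2, per-stage windowed
multi-head self-attention with alternating regular/shifted 7^3 windows,
patch merging between stages) and a convolutional decoder whose blocks
are two (3x3x3 conv, instance norm, leaky ReLU) units with a residual
connection.  Two mechanisms couple the time points, both strictly
one-way (baseline to interim):

* **Longitudinally-aware window attention (LAWA).**  At the end of each
  encoder stage, a window-based multi-head cross-attention layer takes
  queries from the interim features and keys/values from the baseline
  features; `softmax(QK^T/sqrt(d))V` is computed inside non-overlapping
  windows and added residually to the interim stream.  Cross-attention
  uses the regular (unshifted) window partition.
* **Longitudinally-aware attention gates (LAAG).**  Each decoder skip
  connection passes through a shared additive attention gate.  The
  interim branch's pre-sigmoid coefficient logits are refined by a
  learnable 7^3 convolution over the concatenated baseline and interim
  logits before the sigmoid is applied.  Operating on pre-sigmoid
  logits makes the "passthrough" configuration exact: a kernel that
  selects the interim channel reduces the gate to the standard
  attention gate, which both a unit test and the zero-cross-equivalence
  property rely on.

Weight sharing is by construction: there is one backbone and it is
applied to both scans; only the LAWA cross layers and the LAAG
refinement kernels are branch-specific.  Consequently the parameter
count of the dual-branch model is exactly the single-branch count plus
the cross modules, and the baseline output is bit-for-bit independent
of the interim input.

Positional information inside windows uses a learnable per-position-pair
bias table of shape (heads, T, T) with T = window volume.  For a fixed
window size this spans the same function class as a relative-position
table indexed by offsets; it was chosen for implementation simplicity.

Defaults follow the published scale (embed dim 48, depths 2/2/2/2,
heads 3/6/12/24, 112^3 patches, 7^3 windows).  A reduced profile (embed
dim 12, two stages, 4^3 windows, 24^3-32^3 patches) is the default for
CPU work; it is the same code path at smaller tensor sizes.

The network runs on a self-contained reverse-mode autodiff engine over
numpy (`longipet.nn`): tape-based tensors, fused adjoints for the
expensive kernels (3-D convolution, instance/layer norm, softmax), and
AdamW with cosine decay.  Convolution picks its algorithm by kernel
volume — an offset-accumulation loop for kernels up to 3^3 (contiguous
BLAS calls, no buffer), an im2col view plus one `tensordot` for larger
kernels such as the 7^3 LAAG refinement.  Every gradient has a
finite-difference test.

## Training

Both branches are optimized jointly with a compound loss: per branch,
cross-entropy plus soft Dice (smoothing eps 1e-5), summed with equal
branch weights.  The cross-entropy term weights lesion voxels by a
factor of 4 (configurable): lesions occupy a tiny fraction of any
patch — residual interim disease especially — and without the class
weight "predict nothing" persists as a stable optimum of the interim
branch.  Patches are sampled at the same spatial location of both
co-registered scans, with two of every three patches centered on a
lesion voxel (union over time points); an option exists to bias
lesion-centered patches toward interim-positive voxels, off by default
because residual-heavy sampling starves the model of organ and
background negatives.

Intensity normalization: PET is clipped to [0, 30] SUV and
log-compressed, log1p(SUV)/log1p(30).  On a linear scale residual
uptake (SUV ~2) is nearly indistinguishable from body background once
the range is set by baseline lesions (SUV ~13); the log scale keeps
both regimes salient.  CT is z-scored per volume.

The longitudinal cross modules start as an exact no-op (zeroed W-MCA
output projections, passthrough LAAG refinement) and draw their weights
from a random stream separate from the backbone's, so the interim
branch begins as the clean weight-shared single-branch network — with
identical backbone initialisation whether or not the baseline branch is
built — and the cross pathway grows from zero during training.  This is
the usual zero-init practice for residual adapter paths and markedly
stabilises joint optimization at small scale.

Voxels belonging to reference lesions flagged *equivocal* (uptake the
annotator could not attribute to lymphoma) are excluded from the loss
by default; a gradient probe asserts they receive exactly zero
gradient.  Treating them as foreground or background is available by
configuration, since only their exclusion from *evaluation* is settled
practice and their training handling is a genuinely open choice.

Cross-validation scaffolding partitions patients (both their scans
together) into k near-equal folds deterministically.

`LASNetSegmenter` wraps configuration, training and sliding-window
inference behind the scikit-learn estimator protocol (fit/predict,
`get_params`/`set_params`), so the model composes with sklearn tooling;
the functional `training.train` remains the underlying entry point.

## Whole-volume inference

Overlapping patches are blended with Gaussian importance weights and
the per-voxel foreground probability is thresholded at 0.5 (argmax of
two classes).  Volumes smaller than the patch are zero-padded and
cropped back.

## Post-processing: MPDR

Mask propagation through deformable registration: the baseline
prediction is mapped onto the interim grid (nearest-neighbour, so masks
stay binary) and every interim connected component with zero voxel
overlap against the propagated mask is removed.  The filter never adds
voxels and is idempotent.  Registration is a pluggable contract —
identity and rigid transforms for testing, a Demons backend (SimpleITK)
for deformable use; a failed registration raises, never silently falls
back to identity.  The documented cost: genuinely new interim lesions
are removed too.

## Quantification

Connected components use 26-connectivity (the common convention for
PET lesions).  Metrics, all computed from components on the native
grid:

* MTV (mL): total segmented volume.  TLG: voxelwise SUV integral,
  identical to the sum of per-lesion MTV x SUVmean.
* SUVmax; SUVpeak as the greedy hottest-connected-cluster mean of 4
  voxels (lesions smaller than 4 voxels use all their voxels).
* Dmax (mm): largest centroid-to-centroid distance; 0 with at most one
  lesion.  Dspleen (mm): maximum over lesions of centroid distance to
  the nearest spleen-surface voxel; centroids inside the spleen score 0.
* dSUVmax (%): 100 x (SUVmax2 - SUVmax1)/SUVmax1; -100 when nothing
  residual is segmented; missing when SUVmax1 is not positive.
* qPET: hottest residual lesion SUVpeak divided by mean liver SUV;
  without residual lesions it is reported as 0 with an explicit
  no-lesion flag.

qPET maps onto Deauville bands with half-open cuts 0.95 / 1.3 / 2.0
(below 0.95 -> band "<=2"; the boundary value falls in the upper band).
The patient-level score is alternatively the maximum lesion-level
score, with "<=2" for lesion-free patients.  These no-lesion
conventions are explicit package conventions.

The two response routes (qPET-derived band versus maximum lesion score)
agree one-sidedly by construction on phantoms: a qPET at or above the
DS3 cut requires a residual lesion, and every contoured residual
carries a lesion score of at least 3.  Exact two-sided agreement cannot
hold because the qPET cuts act on a peak-to-liver ratio while lesion
scores are assigned per lesion; borderline low-uptake residuals can be
score-3 yet qPET-negative.  The tests therefore assert the one-sided
implication and the exact equivalence between score-route positivity
and the presence of contoured residual disease.

## Detection and segmentation scoring

Overlap criterion: a predicted component touching any non-equivocal
reference lesion (at least one shared voxel) is a true positive; one
touching only equivocal lesions is excluded from the counts entirely; a
non-equivocal reference lesion with no overlapping prediction is a
false negative.  The strict criterion additionally requires the
predicted component's SUVmax to equal the matched lesion's (exact by
default — both read the same grid); a failed pair contributes one false
positive and one false negative, so strict F1 never exceeds overlap F1.
One prediction may match several truths and vice versa; classification
is prediction-sided for TP/FP and truth-sided for FN, and the distinct
matched-truth count is reported alongside.

Cohort detection scores pool lesion counts across patients before
forming precision/recall/F1 (micro-averaging); patient-level bootstrap
sits on top.  Segmentation quality per patient: Dice, false-positive
volume and false-negative volume in mL, with Dice of two empty masks
defined as 1.

Agreement of predicted and reference Deauville classifications is
scored at the two clinically used splits (scores 3-5 positive; scores
4-5 positive) with F1 and Cohen's kappa.

## Statistics

Nonparametric patient-level bootstrap, default 10,000 trials, 2.5/97.5
percentile CI.  Statistics may aggregate lesion-level counts; the
resampling unit is always the patient.  Paired comparisons resample
both arms jointly; a difference is significant at the 0.05 level when
one arm strictly exceeds the other in at least 95% of trials (ties
never count as wins).  Spearman correlations use average ranks for
ties; degenerate (zero-variance) inputs are flagged, not silently
scored.

## Synthetic phantoms

Each phantom patient is a 96^3 voxel, 4 mm isotropic dual-time-point
study (a 32^3 / 6 mm compact profile exists for CPU-bound work): a body
ellipsoid containing liver (mean SUV 2.2), mediastinal blood pool (1.6)
and spleen (1.8) over a 0.7 background, with smoothed Gaussian texture;
the CT channel is a smoothed density map with no claim to CT realism.
Baseline lesions are ellipsoids with Gaussian-softened edges (so
SUVpeak differs from SUVmax), lognormal SUVmax with median 13 g/mL, and
sizes calibrated so total baseline MTV has a median of a few hundred
mL.  At interim, each lesion independently resolves (probability 0.75)
or persists shrunken (factor 0.55) with lognormal residual uptake;
occasional new lesions appear (probability 0.05) and about one in five
annotated residuals is flagged equivocal.

Lesion-level Deauville scores are assigned from the simulated peak
against the reference-region means (above mediastinum -> 3, above liver
-> 4, above twice liver -> 5) with a small multiplicative reader jitter
(sd 0.15 in log space) standing in for visual-grading variability.
Only lesions scoring 3 or higher are contoured, mirroring reader
practice; because that cut truncates the uptake distribution, the raw
residual draw median is set to 0.75 of the target so the *contoured*
lesions land at the target median of 2 g/mL.  Residuals graded below 3
remain visible in the image but carry no contour.

Inter-time-point misalignment is a smooth random displacement field
(coarse Gaussian-filtered grid, linearly upsampled, clamped to the
configured magnitude, default 4 mm) plus a small rigid shift, applied
jointly to the interim image and masks.  All randomness flows through
one seeded generator with per-patient substreams; identical seed and
spec reproduce studies bit-identically.

What the phantoms do not model: scanner point-spread and reconstruction
artifacts, attenuation, respiratory motion, realistic CT anatomy, and
any intensity signature for the equivocal flag (it is a pure label).
Passing tests therefore demonstrate correctness of the machinery and
qualitative directionality (e.g. the value of the baseline branch), not
clinical-grade performance.

## Problem sizes and numerical choices

CPU budgets drive the default experiment sizes: the overfit check
trains the reduced profile on 4 compact phantoms for at most 300 steps
(stopping early once training Dice clears 0.8 with margin); the
longitudinal-awareness comparison trains the full and ablated models on
12 compact phantoms for 300 steps each and compares interim detection
F1 on 12 held-out patients under a 2,000-trial paired bootstrap.  That
comparison cohort carries 2-4 baseline lesions per patient of which
most persist (resolution probability 0.2) with moderate shrinkage
(factor 0.8) — residual uptake stays subtle (median ~2 g/mL, inside the
reference-region range) but the residuals are large enough (~25 voxels
at 6 mm) that the task is learnable at this training length; with the
default heavy-shrinkage response model the residuals are a handful of
voxels and neither arm learns anything, which demonstrates nothing.
Metric-oracle checks run on small random volumes where brute-force
loops are exact and fast.  Dice smoothing eps is 1e-5; binarization
threshold 0.5; component ordering is by descending volume with
lexicographic centroid tie-break, making labelling deterministic.

## Known limitations

The engine is CPU-only and single-threaded BLAS-bound; published-scale
training (112^3 patches, four stages) is configurationally supported
but not a practical CPU workload.  The phantom response model draws
lesion-wise residual uptake independently of baseline uptake, which is
a simplification.  MPDR's deformable backend uses modest Demons
settings and is not tuned for clinical registration quality.
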