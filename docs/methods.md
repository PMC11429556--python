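# Methods

This note documents the models and procedures implemented in `ran_mvpa`,
the parameter defaults and why they are what they are, the statistical
structure of the synthetic cohort generator, and the numerical and design
choices made where the underlying analysis description left the choice
open.

## Task model and contrast

The RAN block design is represented explicitly: a lead-in (default 10 s),
`n_cycles` (3) repetitions of the condition cycle NULL → COLOR → NUMBER →
LETTER (20 s per block), and a tail (20 s), sampled at TR = 2 s. With the
defaults this is 270 s and exactly 135 volumes; construction fails loudly
if the total duration is not an integer multiple of the TR. Blocks are
half-open intervals `[onset, offset)` and volume indices are 0-based, with
volume *i* assigned to the block covering its acquisition onset `i·TR`.

The Letter > Color contrast is a plain temporal average: per voxel, the
mean over letter-block volumes minus the mean over color-block volumes.
There is no HRF convolution and no GLM — the contrast definition *is* block
averaging, and a GLM is deliberately out of scope. One free choice is the
hemodynamic delay: block averaging can be applied to the nominal block
windows or to windows shifted forward to account for the BOLD lag. Both
are exposed through `hrf_shift_volumes`; the default is 2 volumes (4 s),
a conventional lag for 20 s blocks, and 0 gives the unshifted windows.
Shifted indices that cross into the next block are kept (no within-run
clipping); indices past the final volume are dropped. NULL and NUMBER
blocks are carried in the data model but unused by the default contrast.

## Parcellation and features

A parcellation is an integer label volume (0 = background) plus a region
table (label, name, hemisphere, contralateral homolog). Validation
enforces that every label present in the volume is in the table, that
homolog links are symmetric, and that homolog pairs lie in opposite
hemispheres. Two feature granularities are derived from the contrast
maps:

* region means (the Fisher filter's input): the arithmetic mean over each
  region's voxels. An empty region yields a *missing* value, never a
  silent zero — a zero would masquerade as a measured null signal.
* voxel features (the SVM's input): raw voxel values in the union of a
  region set, with a fixed lexicographic (i, j, k) column ordering so that
  weight maps are bit-for-bit reproducible across runs and machines.

All labeled regions participate in region averaging; no gray-matter or
other mask is applied (the masked variant would be a preprocessing
concern, upstream of this package).

## Fisher-score selection

Each region is scored per visit with the two-class Fisher criterion
F = (μ₁−μ₂)²/(σ₁²+σ₂²) using unbiased variances. No formula variant is
canonical in the literature, so the class-size-weighted denominator
((n₁σ₁²+n₂σ₂²)/(n₁+n₂)) is available behind a flag; the unweighted form is
the default. Degenerate inputs: zero pooled variance scores +inf when the
means differ (perfect separation) and 0 when they agree.

A region survives a threshold if its score meets it at **any** of the
visits. The threshold is swept over the grid 0.16–0.26 in steps of 0.02
(six values); each threshold's surviving set is evaluated by mean LOO SVM
accuracy across visits, and the best mean wins. Ties are resolved to the
*largest* tied threshold — the most parsimonious region set — and logged;
thresholds whose surviving set is empty are skipped.

Selection deliberately runs on the full sample at each visit, before and
outside the cross-validation loop, reproducing the original analysis
order. This is a known circularity (selection sees the labels that CV
later predicts) and inflates absolute accuracies; the package reproduces
it faithfully as the default because fidelity to the published procedure
is the point. The evaluation callback abstraction keeps a nested
(within-fold) selection implementable by the user without touching the
sweep machinery.

## Classification and permutation inference

The classifier is a linear SVM with C = 1 throughout; no other kernel or
hyperparameter search is in scope. Features are **not** standardized by
default: the weight-map stage thresholds raw |w| at 0.02, which is only
meaningful on the original feature scale. Per-training-fold z-scoring is
available as a config option.

Leave-one-out CV holds out each sample once; metrics come from the n
held-out predictions. Sensitivity is the recall of the stated positive
class (survivors; "high" performers), specificity the recall of the
negative class, balanced accuracy their arithmetic mean. Zero-denominator
metrics are reported missing, with a warning. Degenerate folds whose
training set collapses to one class predict that class and are logged; an
exactly-zero SVM decision value resolves to the first class in sorted
order and is logged.

The permutation test shuffles the whole label vector (class sizes are
preserved by construction) B times (default 1000) with an explicit seed,
recomputes the LOO accuracy each time, and reports p = k/B where k counts
shuffles at or above the observed accuracy. The identity labeling is not
added to the count; the bias-corrected (k+1)/(B+1) estimator is reported
alongside.

Two properties of LOO worth knowing when reading results:

* **Pessimistic null bias.** With balanced classes, removing the held-out
  sample leaves the training fold imbalanced *against* that sample's
  class, so under pure noise the expected LOO accuracy sits slightly
  below 0.5 (≈0.45 at n = 40 in our simulations), not on it. Tests
  therefore check that null accuracy does not *exceed* chance rather than
  that it equals 0.5. The permutation p-value is unaffected — observed
  and shuffled statistics share the bias.
* **Implementation note.** The LOO/permutation inner loop calls the
  libsvm training routine directly rather than constructing a new
  scikit-learn estimator per fold; the solver is identical and the test
  suite asserts prediction-level equivalence with the `SVC` path, which
  remains as a fallback.

## Weight maps and clusters

A full-sample linear SVM (per visit) gives one signed weight per voxel
feature; weights are placed at their (i, j, k) coordinates, zero
elsewhere, oriented so positive weights vote for the positive (survivor)
class. Clusters are connected components of |w| ≥ 0.02 with ≥ 50 voxels.
Two choices were open:

* **Connectivity.** Unstated in the original description; the default is
  26-connectivity (the most inclusive, and common for voxel clusters),
  configurable to 6 or 18.
* **Sign handling.** Components are formed on the magnitude image, so a
  cluster may mix signs; its dominant sign is reported. A
  `sign_separated` flag clusters positive and negative weights
  independently instead.

On the synthetic cohort the default thresholds typically yield *no*
surviving cluster, and this is expected: SVM weight norms scale inversely
with the margin, so the better the groups separate, the *smaller* the
weights — the absolute 0.02 cutoff is calibrated to the original data's
feature scale, not to an arbitrary simulation's. The cluster stage is
therefore validated on constructed weight maps with known component
structure, and the group-statistics stage uses the selected-region voxel
union as its cluster, which is also how the original analysis defined the
cluster it averaged.

## Group statistics and performer stratification

Cluster-averaged contrasts (one scalar per subject) are compared between
groups per visit with Welch's two-sided t-test; the original description
does not name its test, and Welch is the safer default under unequal
variances (pooled-variance t is a config option). The contralateral
analysis maps the selected regions through their homolog links and runs
the *identical* code path on the mirrored voxel set.

Performer stratification pools all survivor visits, treating each
subject-visit as one sample — matching the published sample sizes, which
exceed the subject count (e.g. 28+61 = 89 > 50). The resulting
within-subject dependence across pooled visits is a deliberate
fidelity-over-purity choice and should be kept in mind when interpreting
the per-test permutation p-values. A score of exactly 100 is a *high*
performer (the cutoff is inclusive); samples missing a test's score are
dropped for that test only. Features for performer classification are the
same selected-region voxel features as the survivor/control analysis —
the feature provenance is not stated in the original description, and
reusing the selected set is the natural reading of its narrative order.

## Synthetic cohort generator

The generator exists so that every stage has a testable input with known
ground truth. It emulates:

* **Design.** Two groups with nested attrition 50/50 → 36/36 → 21/21
  across three visits; attrition keeps the first-enrolled subjects, so
  later visits are strict subsets.
* **Geometry.** A 32×32×32 grid with 15 mirror-symmetric left/right
  region pairs (rectangular 6×8×5 boxes, 240 voxels each, separated by
  background gutters). Four right-hemisphere regions are the planted set,
  mirroring the lateralized occipital role in the analysis.
* **Signal.** Each subject-visit contrast map is
  `subject_offset + is_survivor · δ_visit · [voxel ∈ planted] + N(0, σ²)`
  with σ = 1, subject offsets N(0, 0.4²) fixed across visits, and
  δ = (0, 0.4, 0.8) noise-SDs per visit. The zero first-visit effect and
  the growth to 0.8 SD are calibration choices that make the simulated
  accuracy trajectory (chance → ≈0.55–0.6 → ≈0.8+) qualitatively mirror
  the published 57 % → 75 % → 79 % divergence; they are configuration, not
  claims about the real cohort. The subject-offset SD of 0.4 keeps
  between-subject variation comparable to, but smaller than, voxel noise,
  as regional averages of real contrast maps behave.
* **Scores.** Seven standardized scores per subject-visit:
  `100 + 15·(ρ·z + √(1−ρ²)·ε)` where z is the subject-visit
  planted-region mean signal standardized across the cohort. Three tests
  (sound awareness, reading fluency, word attack) have ρ = 0.5; the other
  four ρ = 0 — reproducing the published pattern of which tests were
  predictable from the imaging. 5 % of scores are removed completely at
  random.
* An optional series mode emits full 135-volume 4D series whose
  Letter > Color contrast recovers the planted maps, so the contrast stage
  is exercised end to end; its per-volume noise SD defaults to the value
  that gives the temporal-average contrast unit noise variance.

All randomness flows from one master seed through a single generator;
identical seeds give byte-identical datasets.

What the generator does **not** emulate: spatial autocorrelation,
physiological drift and motion residuals, lesion/resection geometry,
age/sex structure, and site effects. Passing tests on this cohort
demonstrates that the pipeline recovers the statistical structure it
assumes — planted regions, effect timing, score coupling — not that it
would achieve any particular accuracy on real clinical data.

## Problem sizes used in validation

The test suite and the acceptance script run the full default design
(50/50 → 36/36 → 21/21, 30 regions, 32³ grid). The simulation panel spans
20 fixed seeds; permutation tests in the acceptance script use B = 199
shuffles and the calibration study uses B = 99 with 200 repetitions —
Monte-Carlo sizes chosen to keep each study at desk scale while leaving
the binomial error on the reported rates small relative to the bands
being checked. The published-table arithmetic uses the printed group
sizes as-is.

## Known limitations

* Full-sample feature selection before CV (faithful to the source
  procedure) inflates absolute accuracy estimates; use the evaluation
  callback with nested selection for unbiased numbers.
* Pooling survivor visits ignores within-subject correlation.
* The absolute weight-map thresholds (|w| ≥ 0.02, 50 voxels) do not
  transfer across feature scales; rescaled data needs rescaled cutoffs.
* Region means weight every voxel equally (no partial-volume handling),
  and the parcellation is voxel-based; surface parcellations are out of
  scope.
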