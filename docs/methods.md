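# Methods

## Problem and data model

A structure set is one patient's collection of named ROIs; each ROI is a
set of closed planar polygons indexed by axial slice on a fixed pixel grid
(default 512×512 clinically, 128×128 here) with uniform 2.5 mm slice
spacing. The package's task is to recover each structure's TG-263 identity
from geometry alone, under the assumption that input labels are
unreliable — which is why raw labels are preserved verbatim and play no
role in classification.

Conventions fixed by this package (the interchange formats and trained
checkpoints depend on them):

* pixel (row *r*, col *c*) has its center at continuous coordinates
  (*x* = *c*, *y* = *r*);
* slice indices are 0-based and increase toward the patient's superior;
* +x is patient left, +y posterior (DICOM-style HFS reading).

## Rasterization

A pixel belongs to a contour iff its **center** is inside the polygon.
The inside test is even-odd ray crossing; a center within 10⁻⁹ px of an
edge counts as inside (the boundary-inclusive completion makes the test
total and mirror-symmetric). No sub-pixel supersampling is applied.
Multiple polygons of one ROI on one slice are unioned into one mask, so
each (structure, slice) has a single center of mass; overlap *within* one
self-intersecting polygon flips parity, which is the even-odd rule's
documented behavior rather than a guess at clinical intent. A winding-rule
variant was considered and rejected: nothing downstream distinguishes the
two on simple clinical contours, and even-odd has the simpler oracle.

The center of mass is computed on the mask (mean of one-pixel column and
row indices), not on polygon vertices — vertex-based CoM is deliberately
not offered, since the mask is what the image classifiers see.

## Coordinate frames

All frames are affine per axis and never clamp: structures inferior to the
brain (esophagus, spinal cord) legitimately map below the nominal output
range.

* `UNNORM` — raw pixel/slice values.
* `NONANAT` — grid range [0, n−1] → [−1, 1] on x and y; z anchored to the
  brain's inferior/superior slices → [0, 1]. The asymmetric z range is
  kept deliberately; "harmonizing" it would silently change trained
  models' input distribution.
* `ANAT_BRAIN` — extremes of the rasterized brain (union over slices) →
  ±1 on all three axes. Extremes come from masks, not vertices, for
  consistency with the mask-based CoM.
* `ANAT_EYES_BSTEM` — lateral extremes from the union of the two eyes;
  cranial-caudal extremes from eyes ∪ brainstem. The anterior-posterior
  reference is genuinely underdetermined (no single natural choice);
  this package uses the union of all three reference ROIs with the same
  orientation as the brain frame, and records the resolved anchors in the
  frame object so a trained model is unambiguous about what it expects.

Axis orientation on the normalized axes: the minimum pixel/slice
coordinate of the reference maps to the lower end of the output range, so
normalized x/y/z always increase with column/row/slice index.

No head-posture or rotation correction is applied.

## Classifiers

Input unit: a `SliceSample` — a 3-channel mask stack (green = the slice to
classify; red/blue = the structure's preceding/succeeding slice masks,
zeros where absent), the green channel's normalized CoM, and the parent
structure's slice count.

* **Position-only**: (x, y) or (x, y, z) → optional 32-node hidden layer →
  17 outputs.
* **Segment-only**: backbone → 64-node hidden layer → 17 outputs
  (single-slice variant zeroes red/blue).
* **Combined**: backbone features ⧺ (x, y, z, n) → dropout 0.6 → hidden 64
  → dropout 0.2 → 17 outputs.

The probability transform is softmax (the standard choice; nothing else is
implied by the output contract).

**Backbone.** The contract is any map from a 3-channel stack to a
fixed-length feature vector, so a pretrained large backbone can be plugged
in. The built-in desk-scale backbone — a fixed average-pool of the input
to ≤ 32 px, four 3×3 stride-2 convolution blocks (8/16/32/64 channels),
and **global moment pooling** — is trained from scratch and grid-size
agnostic. Moment pooling (per-channel mean activation plus its first
spatial moments along x and y) replaces a plain global average because a
purely translation-invariant backbone cannot represent laterality at all:
it would be structurally unable to tell a left eye from a right eye,
whereas deep full-frame backbones retain absolute position through border
effects. The moments restore that coarse frame position in closed form at
a third of the channel count.

**Hyperparameters** (defaults, from the tuned clinical configuration):
batch 12, SGD with learning rate 0.1 multiplied by 0.5 after each epoch
(the decay is stated without a schedule anywhere authoritative; per-epoch
is the simplest consistent reading and is recorded in the run history),
weight decay 0, dropouts 0.6/0.2, hidden width 64, class weights 10 for
Cochlea_L/R and Pituitary and 1 otherwise, 5 epochs for the
position/segment ablations. The optimizer is plain SGD — the minimal
reading of a specification that gives only lr/decay/weight-decay.
The two dropouts are defined positionally (features → hidden,
hidden → output); segment heads contain the same junctions and therefore
receive the same dropouts.

**Numerical conditioning.** The slice-count feature is fed through a fixed
1/32 scaling before the combined head. The feature's semantics are
unchanged (still linear in ROI length); without the scaling its dynamic
range (2–60) dominates the O(1) normalized coordinates and destabilizes
SGD at lr 0.1, which in practice collapses the small-organ classes onto
the weight-boosted pituitary. Loss reduction is the batch mean of
per-sample weighted terms, so doubling a class weight exactly doubles that
class's contribution. Weight init is He-normal, biases zero; all
randomness (init, dropout, shuffling, splits) derives from explicit seeded
generators, so training is bit-reproducible on a given platform.

The train/validation split is at **patient** level (80/20, seeded): no
patient contributes slices to both groups.

## Voting

Each classified slice casts one hard argmax vote; the structure receives
the label with the strictly largest count. A shared maximum is `TIE`,
reported as such and counted as a misclassification in every metric —
breaking ties (e.g. by probability mass) would silently change the
metric's meaning. Ranked or probability-weighted ballots are out of scope.

Predictions are per-sample and unconstrained across a slice: two
structures on the same slice may legitimately receive the same class.

## Evaluation

* Total accuracy; mean accuracy per class (unweighted mean of per-class
  recall over classes with support > 0 — zero-support classes are excluded
  rather than counted as 0, so the metric stays defined on small cohorts).
* Confusion matrices with columns = true class; column-normalizing makes
  each column a per-class recall profile. TIEs sit outside the 17×17 grid
  in a side count (the matrix has no tie row).
* Failure histograms binned by structure slice count.
* Guess baselines: uniform 1/k, and proportional Σᵢ (nᵢ/N)² evaluated on
  the same distribution; the bundled clinical per-class slice counts
  (446-patient head-and-neck training cohort) give 13.18 % → printed 13.1.
  Published percentages mix truncation and rounding conventions, so both
  one-decimal formatters are provided; the library itself always reports
  full precision.
* The voting-vs-slice comparison is made on **mean accuracy per class**,
  which is how the clinical result states its improvement (92.0 → 97.6 and
  93.3 → 97.9); total slice accuracy is dominated by thick structures and
  is not the quantity voting is designed to improve.

**Robustness harness.** Each organ class is sampled exactly twice
(structures with ≥ 2 slices); one seeded-random slice is deleted and the
structure re-voted, with zero channels standing in for the missing
neighbour data and the slice-count feature decremented accordingly. At the
pure vote level, removing one vote from a unanimous tally of n ≥ 2 can be
*proved* to preserve the winner (max of n−1 votes is unique); at the
pipeline level the property is only empirical, because deleting a slice
also changes the neighbouring samples' channels and count feature.

## The phantom generator

Each of the 17 OARs is a geometric primitive (ellipsoid or elliptic tube)
with a fixed template: center in fractional head coordinates, in-plane
semi-axes, axial extent. A patient is a jittered realization: a global
head transform (scale 1 ± 0.05 about the grid center, in-plane shift
± 4 px, axial shift ± 2 slices) plus per-organ jitter (center ± 1 px,
scale 1 ± 0.08, axial shift ± 1 slice), per-slice contour jitter
(center ± 0.6 px, scale 1 ± 0.08 — hand-drawn contours vary slice to
slice), and a slow sinusoidal axial drift (≤ 2 px) for tubular organs.
All jitter is uniform with the stated bounds so organs provably stay
inside the grid; Gaussian alternatives were rejected for exactly that
reason. Per-organ jitter is deliberately small relative to the global
transform: adjacent organs move together in real anatomy, and it is the
*relative* geometry of close organ pairs (chiasm–pituitary,
esophagus–cord) that carries class information.

Template axial extents reproduce the clinical slice-count ordering
(brain > spinal cord > esophagus > brainstem; cochleae smallest at 2
slices), paired organs are exact mirror templates (so zero jitter gives
exact mirror symmetry, a property the tests exploit), and every generated
polygon is guaranteed to rasterize to a nonempty mask via a 1.2 px minimum
in-plane radius. Default grid is 128×128 so end-to-end CPU training runs
in minutes; the rasterizer and frames are grid-agnostic and 512×512
remains available.

**What the phantom does not emulate:** CT intensities, true organ shapes
(no atlas or deformable anatomy), contouring errors and missing organs,
inter-observer variability structure, and the real ~150:1 class imbalance
of clinical slice counts (the phantom's is ~16:1). Consequently, passing
phantom tests demonstrates that the pipeline's machinery — features,
normalization, training, voting — behaves as designed, not that clinical
accuracy transfers. Two knock-on effects are worth naming: geometric
primitives make *position* relatively more informative (and shape less)
than clinical contours, so the single-slice segment net and the strongest
position net land close together rather than far apart; and identical
organs (lens vs pituitary) become distinguishable only by position, which
makes the weight-10 pituitary the phantom's characteristic failure
attractor, playing the role the cochlea plays clinically.

## Reference study conditions

The acceptance tests and `scripts/acceptance.py` run: 60 phantom patients
at 128×128 (seeded), 48/12 patient split, combined brain-normalized
network (CAS-B) trained 5 epochs with the default hyperparameters, with
segment-only (SS/SM) and position-only (PU/PN) ablations at equal seed and
epochs, followed by voting evaluation and the robustness harness
(17 × 2 = 34 structures). These sizes keep a full run around three
minutes on one CPU while leaving the qualitative comparisons stable:
typical results are 92–98 % structure-level voting accuracy, voting ≥
slice accuracy on mean-per-class, SM ahead of SS by ~5 points, normalized
ahead of unnormalized position nets, and a thin-structure-dominated
failure histogram. Across seeds the voting accuracy varies by a few
points; the trends above were stable in every seed examined except that
voting's mean-per-class edge over slices can invert when slice accuracy
itself approaches 99 %.

## Known limitations

* No pretrained backbone ships with the package; the backbone contract
  accepts one, but all published numbers here use the desk-scale net.
* The 17-class vocabulary is fixed; other anatomical sites require new
  reference anatomy for the frames (any large, consistently contoured
  structure would do).
* DICOM RTSTRUCT import handles axial CLOSED_PLANAR contours only and
  requires the caller to supply grid geometry; there is no DICOM export.
* TIE reporting means a two-slice structure with split votes is always
  "wrong" — by design, since silently breaking ties would overstate
  accuracy on exactly the thin structures where the method is weakest.
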