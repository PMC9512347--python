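# contourclass

Slice-wise classification of head-and-neck organ-at-risk (OAR) contours
into TG-263-compliant nomenclature.

Radiotherapy structure sets accumulated before (or outside) the AAPM TG-263
standard carry inconsistent ROI names ("Left Parotid", "Parotidl",
"PAROTID_LT", ...), which blocks large-scale data mining. This package
identifies a contoured structure from its **geometry alone**: each axial
contour is rasterized to a binary mask, classified slice by slice, and the
per-slice predictions are aggregated into a single structure label by
plurality voting. No CT intensity data are used.

It is aimed at medical-physics and ML researchers who need to relabel or
QA legacy structure databases, and at anyone studying how positional
normalization and vote aggregation affect shape classification.

## Method

For a structure $S$ with contours on slices $z_1 < \dots < z_n$:

1. **Rasterization.** Each polygon is converted to a binary mask on the
   512×512 (or scaled) pixel grid: pixel $(r, c)$ is 1 iff its center
   $(x{=}c,\ y{=}r)$ lies inside the contour (even-odd rule, boundary
   inclusive, no supersampling).
2. **Features.** The mask's center of mass
   $(\bar x, \bar y)$ and slice index $z$ are mapped through a
   patient-specific affine frame: either a non-anatomical scaling of the
   pixel grid to $[-1,1]$ (with $z$ anchored to the brain's slice span on
   $[0,1]$), or an anatomical frame in which the lateral /
   anterior-posterior / cranial-caudal extremes of reference anatomy (the
   brain, or the eyes + brainstem) map to $\pm 1$. The structure's total
   slice count $n$ is a further feature (slice spacing is uniform 2.5 mm,
   so $n$ is proportional to ROI length).
3. **Slice classifiers.** Three families: position-only dense networks
   $(x,y[,z]) \mapsto p \in \Delta^{16}$; segment-only convolutional
   networks over a 3-channel stack (green = slice to classify, red/blue =
   preceding/succeeding slice masks, zeros where absent); and the combined
   network, which concatenates the convolutional features with
   $(x, y, z, n)$ ahead of a 64-node hidden layer with dropout
   (0.6 / 0.2). Training is plain SGD (lr 0.1, halved each epoch, batch 12)
   with class-weighted cross-entropy (cochleae and pituitary weighted 10).
4. **Voting.** Each slice's argmax is one vote; the structure receives the
   plurality label. A tied maximum is reported as `TIE` and counted as a
   misclassification — never broken.

Reported metrics: **total accuracy** (fraction of items correct) and
**mean accuracy per class** (unweighted mean of per-class recall),
plus column-normalized confusion matrices and failure histograms by
structure thickness.

Because no public clinical structure-set corpus accompanies the method,
the package includes a seeded synthetic phantom generator: 17 OARs as
jittered geometric primitives with realistic relative positions, mirror
symmetry for paired organs, and clinically ordered slice counts. All
training and evaluation in the test suite runs on phantoms.

## Worked example

```sh
python examples/03_train_and_vote.py
```

trains the combined brain-normalized classifier (CAS-B) on 16 phantom
patients for 5 epochs and votes on 4 held-out patients:

```
 epoch      lr  train_total_acc  val_total_acc
     0 0.10000         0.385073       0.761905
     1 0.05000         0.749542       0.855159
     2 0.02500         0.831044       0.849206
     3 0.01250         0.853938       0.888889
     4 0.00625         0.875916       0.886905

held-out voting: total accuracy 80.9%, mean accuracy per class 80.9%, 13 errors (of which 0 ties) in 68 structures
```

The history shows slice-level accuracy climbing as the learning rate
decays; the voting summary counts whole structures. At this deliberately
small training size most residual errors are 3-slice structures (lenses,
chiasm) captured by the weight-boosted pituitary class; the 60-patient
reference study reaches ≥ 90% structure-level voting accuracy. The other
examples demonstrate phantom generation, rasterization + frames, and the
missing-slice robustness probe.

A thin CLI wraps the same pipeline:

```sh
contourclass generate --n-patients 10 --seed 1 --out-dir cohort/
contourclass train --cohort-dir cohort/ --network CAS-B --seed 1 --out model.npz
contourclass classify --checkpoint model.npz --structure-set cohort/P0000.json --out decisions.csv
contourclass evaluate --decisions decisions.csv --truth cohort/truth.csv --report-dir report/
```

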