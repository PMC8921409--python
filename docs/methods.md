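# Methods

`spinealign` measures twelve sagittal spinal-alignment parameters on lateral
whole-spine radiographs by localizing eleven anatomical key points with a
decentralized (coarse-to-fine, three-order) convolutional cascade, then
applying plane geometry to the recovered points.  This note documents the
model, its assumptions, the synthetic phantom that stands in for clinical
radiographs, and the numerical and design choices a maintainer would want to
know.

## Alignment geometry

The key points are the anterior/posterior corner pairs of five endplates —
C2 inferior, C7 inferior, T1 superior, L1 superior and the sacral (S1)
superior endplate — plus the femoral-head centre F.  All computation uses the
image frame: x right, y down; "horizontal" and "vertical" are the image axes,
and radiographs are assumed upright (no gravity-vector correction).

Internally every angle is signed:

* **slope(plate)** = angle of the endplate against horizontal, positive when
  the posterior corner is inferior; a vertical plate folds to +90 deg.
* **PT** (pelvic tilt) = angle of the line from F to the sacral-plate
  midpoint against vertical, positive when the midpoint lies posterior to F.
  The posterior direction is read off the sacral corner labels, so the same
  formulae serve left- and right-facing radiographs.
* **incidence(target)** := PT + slope(target).  With the sacral plate as its
  own target this is the pelvic incidence, giving the defining identity
  PI = PT + SS; L1I, T1I and C2I are the same construction for higher
  endplates.  Geometrically this is the signed angle between the F-to-sacral-
  midpoint line and the *anterior-leaning* unit perpendicular of the target
  plate (the test suite verifies this against an explicit cross/dot-product
  construction).
* **Cobb-type angles** LL, TK, C27L = slope(lower plate) − slope(upper
  plate), giving LL = SS − L1S and TK = L1S − T1S.

The public report is unsigned magnitudes in degrees (Cobb angles folded to
[0, 90]), matching clinical convention; `signed=True` exposes the internal
representation on which the identity suite holds to 1e-9 deg.

Two consequences of this algebra are worth stating explicitly.  All twelve
parameters are invariant under translation, uniform scaling, and horizontal
mirroring (with anterior/posterior labels following the anatomy).  Under a
global rotation by phi, slopes and PT shift by exactly phi, Cobb-type angles
are unchanged, and incidence-type angles — being the *sum* of two co-rotating
signed angles — shift by exactly 2·phi.  A rotation-invariant incidence would
require the difference PT − slope instead, which contradicts the defining
identity PI = PT + SS; we keep the identity.

Degenerate inputs (zero-length endplates, F coinciding with the sacral
midpoint) raise errors naming the offending landmark: a missing corner
invalidates the clinical measurement and must not be silently skipped.

## Cascade architectures

Three detection orders, each a VGG-flavoured stack of five valid (unpadded)
convolutions interleaved with non-overlapping max pooling, then dropout
(rate 0.5), one ReLU, two fully connected layers (256, then 128 for the
first order / 90 for the others) and a linear coordinate head:

| order  | input     | regresses                                   | outputs |
|--------|-----------|---------------------------------------------|---------|
| first  | 1620x540  | one region centre (cervical, lumbar, femoral: one model instance each) | 2 |
| second | 500x250   | minor-ROI centres (cervical: C1, C2-C3, C7-T1; lumbar: T12-L1, L5-S1)  | 6 / 4 |
| third  | 150x150   | key-point coordinates per minor ROI          | 4 (C1, L1), 8 (C2, T1, S1), 2 (femoral) |

Shape propagation uses the valid-convolution rule h' = h − k + 1 and floor
division for pooling, with one deliberate exception: the second-order model's
first 3x3 pool divides 242 → 81, i.e. rounds *up*; that layer carries an
explicit ceiling flag so the declared architecture reproduces its published
shape table cell for cell.  The second-order Conv4 uses 32 filters, as its
output shape column requires.

The printed output count of 2 for the first order cannot locate three
regions with one head, so the package instantiates three first-order models
sharing the architecture, one per region — the only reading consistent with
a 2-output table and three first-order ROIs.  The optional C1 model (4
outputs) detects points used by no parameter; it can be trained and run but
is excluded from measurement by default.

Eight-output third-order models cover two endplates each: the C2 model also
regresses the C3 superior plate, the T1 model covers C7 inferior + T1
superior, and the S1 model covers L5 inferior + S1 superior.  The extra
plates give the models an unambiguous geometric anchor and supply C7's
corners; only the named measurement plates feed the geometry.

Coordinates are regressed normalized to [0, 1] within the model's input
frame (scale-free MSE) and denormalized through the recorded crop
transforms.  Every ROI transform (resize or crop) is an exact affine map;
crop/uncrop round-trips are exact, and a cascade whose predictors are
ground-truth lookups is the exact identity on landmarks — this oracle mode
isolates coordinate-transform bugs from model error and is part of the test
suite.

### Desk-scale profile

The full-resolution architectures cannot run on quarter-scale phantoms (the
feature maps go non-positive), and training them on a single CPU would be
prohibitive.  The default *desk profile* therefore works at 810x270 (quarter
native), with:

* first-order input 162x54 (image / 5; the native pipeline's whole-image
  downsample is likewise configurable),
* second-order crops 155x79 and third-order crops 42x42: the native
  500x250 / 150x150 scaled by image height / 3240, plus margins — 4 px on
  the third-order window so the steepest sacral endplates stay fully
  inside, and ~30/16 px on the second-order window so first-order centre
  error cannot push a spinal section outside its crop.  The femoral branch
  skips the second order, so its minor-ROI window is enlarged to 63x63 for
  the same reason,
* the same five-conv layer patterns refitted by `scaled_arch`: kernels
  halved (rounded to odd), pooling skipped where a map axis would collapse,
  and a ReLU after every convolution.  At reduced resolution the published
  pattern — whose only nonlinearities are the max pools and a single ReLU —
  underfits coordinate regression measurably; the per-conv ReLU variant is
  used for desk-scale work only, while the native `ArchSpec`s remain exactly
  as published.

Initialization is seeded: gain-1 (Xavier) normal for linear conv stacks,
He gain where a conv feeds a ReLU, and a zero-initialized output head so
training starts from the label-mean regime (a zero image maps to the head
bias).

## Training

Mean squared error L = (1/n) Σ (A_j − Y_j)² over all outputs, optimized by
Adadelta (rho 0.9, eps 1e-6, step scale 1.0 — the optimizer's standard
hyperparameters; only the optimizer itself is prescribed by the protocol).
Defaults follow the study protocol: dropout 50% (owned by `TrainingConfig`
and applied to the dropout layers at fit time), 50 epochs, batch size 32,
five-fold cross-validation with seeded 8:2 splits.

Augmentation: horizontal flips transform image and labels together and swap
anterior/posterior corner pairs (lateral radiographs occur facing either
way); rotation (default ±15 deg) and scaling (0.9–1.1) about the crop centre
are reserved for the third-order models, reflecting vertebral pose and size
variation.  Augmented samples whose labels leave [−0.1, 1.1] are rejected
with a log entry.

Per-order training is independent: second/third-order training crops are
taken at *ground-truth* ROI centres with Gaussian centre jitter sized to
the measured prediction error of the preceding stage (12 px for
second-order crops, 6 px for third-order, 10 px for the femoral branch at
desk scale); inference chains the predictions.  Third-order crops alternate
between full and 0.3x jitter, so the models are robust to upstream error
yet precise on well-centred windows.  Inference exploits that with a
refinement pass: each third-order window is re-centred on the centroid of
the first prediction (minus the mean label offset recorded at training
time) and predicted again.  Later orders are trained on several
independently jittered crops per phantom (defaults: 6 second-order and 8
third-order crops, and 6 shift/flip variants of the whole image for the
first order).  This crop multiplication mirrors the way the later orders of
such cascades are trained on far more crops than there are radiographs, and
matters doubly here because Adadelta ramps its effective step size over the
first few hundred updates.

The desk-scale recovery protocol used by the acceptance suite: 230 phantoms
(200 train / 30 test, fixed seed), 16 epochs, desk profile.  On the held-out
phantoms the trained cascade must keep the mean landmark error below 2% of
the image height and the pelvic-tilt MAE below 2 deg.  These sizes keep the
whole protocol at roughly ten minutes on one CPU core.

## Synthetic phantoms

The phantom generator emulates the *structure* of a clinical whole-spine
lateral dataset — not radiograph physics.  Vertebral bodies are bright
rotated quadrilaterals whose corners are the landmark ground truth, each
with a posterior spinous-process tab (real vertebrae are posteriorly
asymmetric; without this cue the anterior/posterior corner identity is
unlearnable from a small local crop), femoral heads are two near-superimposed
discs whose centroid is F, plus endplate emphasis lines, Gaussian blur
(sigma 1 px), additive Gaussian noise (sigma 5 grey levels), and an optional
occlusion band over the cervicothoracic junction mimicking shoulder-girdle
overlap.

Pose synthesis is exact: the twelve parameters are linear in six underlying
signed angles (PT, SS, L1S, T1S, C2S and the C7 slope), so pinned target
angles are imposed by least-squares projection onto the consistent subspace;
mutually inconsistent pins (e.g. PI, PT, SS with PI ≠ PT + SS) are detected
from the projection residual.  Free angles are drawn per morphology class —
good posture (SS 28–45, L1S −12..10, T1S −38..−15 deg), increased lumbar
lordosis (steeper SS with more negative L1S), thoracic kyphosis (more
negative T1S) — with flexion/extension adding a pelvic and upper-spine lean
of 4–12 deg.  Ranges are package defaults chosen to span typical adult
sagittal alignment with the pathological classes shifted as named; they are
configurable and make no claim about any particular study population.
Vertical positions place C2 near 13% and the sacral plate near 74% of image
height so the cervical (C1–T1) and lumbar (T12–S1) sections each fit a
second-order crop.

Dataset generation stratifies morphology 283:101:116 and posture
150:200:150 (largest-remainder apportionment, so the counts are exact at
n = 500), pairs the two stratifications by seeded shuffle, and randomizes
facing side.  Everything is deterministic per (spec, seed): identical seeds
give bitwise-identical images and labels.

What passing on phantoms does *not* show: robustness to soft tissue,
exposure variation, spine instrumentation, anatomical variants, or the
genuinely blurry cervicothoracic junction of real films.  The phantom
isolates the cascade's localization and coordinate plumbing, which is what
the package can verify without clinical data.

## Agreement statistics

`agreement` reports Pearson r on raw pairs, R² = r² (consistent with the
paired correlation/R² columns of clinical validation tables), MAE, the
sample (n−1) standard deviation of absolute errors (configurable via
`ddof`), and Bland–Altman limits mean ± 1.96 SD of signed differences.
Zero-variance series leave the correlation undefined and *flagged*, never a
silent NaN.  Detection-rate curves use a strict inequality (error < τ), so
the rate at τ = 0 is 0.  The expert table flattens case × parameter grids
and compares method and experts in all four pairings, with the expert mean
as the standard reference; `min_expert_error` takes the per-angle minimum
against either expert.  Plot helpers (Bland–Altman panels, detection-rate
curves, scatterplots) are conveniences; no statistic depends on plotting.

## Known limitations

* The CNN engine is a minimal numpy implementation (exact gradients,
  seeded, single-threaded); it is sized for desk-scale experiments, not for
  training on thousands of native-resolution radiographs.
* Desk-scale accuracy is bounded by phantom rendering (1 px at 810x270 is
  4 px native); slope-type parameters amplify corner error by roughly
  1/(plate length), so slopes of short cervical plates are the noisiest —
  consistent with the cascade's general difficulty around T1 on real films.
* The femoral branch routes directly from first to third order (the
  published second-order heads cover only cervical and lumbar sections), so
  femoral localization leans on first-order accuracy.
* Left/right facing is handled by the data mix; an explicit orientation
  override mirrors input and un-mirrors outputs for single-sided bundles.
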