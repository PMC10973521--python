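# Methods

## Coordinate frame and angle conventions

All computation runs in image coordinates: x is the column, y the row,
origin top-left, y increasing downward (toward the ankle in a correctly
oriented standing AP radiograph). Pixel centres sit at integer
coordinates. Directed angles rotate one line's direction onto another's,
positive counter-clockwise in this frame, wrapped to (−180°, 180°].

Angles are evaluated in a side-normalised frame with the lateral side at
+x: for a right leg in a standard AP image (medial = larger x) the x axis
is mirrored first. With femoral/tibial mechanical directions f, t taken
distally and articular directions c, p taken medial→lateral,

    mLDFA       = angle(−f → c)      (lateral side of the knee)
    MPTA        = angle(t → −p)      (medial side)
    JLCA_signed = angle(c → p)       (positive = lateral joint-line opening)
    mTFA        = mLDFA + JLCA_signed + (180° − MPTA)
                = 180° + angle(f → t)   (mod 360°, by angle additivity)

so the composition identity is exact by construction (tested to 1e-9° on
random axis sets), and all four values are invariant under translation,
uniform scaling, and left/right mirroring with the side flag flipped.

The mTFA sign convention is a genuine ambiguity in the field: population
means near 181.8° in varus-risk cohorts imply varus > 180°, while the
"hip-knee-ankle < 177° means varus" convention is the complement. The
package defaults to varus > 180° (`varus_gt_180`) and exposes
`varus_lt_180` as a configuration switch; JLCA is reported as a magnitude
with the signed value retained for the identity.

## Landmark rules and their declared conventions

The five rule-based procedures operate on the outline of the largest
8-connected component of each mask (Moore neighbour tracing, clockwise,
closed loop; outlines enclosing no area are rejected). Conventions the
source rules leave open were fixed as follows:

* **Circle fit** (femoral head): algebraic least squares (Kåsa) —
  closed-form, deterministic, exact on noiseless circular data, adequate at
  mask resolution. A flattened inferior arc (acetabular overlap) biases
  the fit because the chord pixels participate; the bias is ≈ 1 px at 10%
  flattening of the radius and grows roughly linearly, a known limitation.
* **Peaks** (tibial spines): local y-minima along the outline with
  prominence ≥ 5% of the outline's bounding-box height; the two most
  prominent are kept, left one first. The spine-centre search is
  restricted to the outline arc between the two peaks.
* **Distal femur**: the two condyle points are the per-half (split at the
  centroid column) outline points closest to the bounding-box bottom line;
  the notch is the highest point of the inter-condylar arc strictly
  between them and below the centroid, and must rise above both condyle
  tips (otherwise "no prominence" failure, e.g. a convex lower border).
* **Plateau / talus corners**: convex-hull points above the centroid
  nearest the two upper bounding-box corners.
* **Ankle centre**: restricted to the distal-tibia outline arc below its
  centroid.
* **Tie-breaks** are deterministic and mirror-consistent: geometric
  searches break ties toward the smaller outline index; condyle picks take
  the middle of a tied flat raster run; corner-candidate distance ties
  break toward smaller y then smaller x. (A blanket smallest-x rule would
  break mirror equivariance by the width of the tied run.)
* **Medial/lateral labels** come from the patient side: right leg medial =
  larger x in a standard AP image, left leg the reverse. Both-leg images
  are split at the vertical midline (patient right on image left).

## The phantom generator

The generator defines the study conditions for every test. Ground truth is
analytic: the tibial mechanical axis is placed vertically, the plateau
line rotated to the MPTA target about the tibial spine centre, the
condylar line rotated from it by the signed JLCA, the femoral mechanical
axis rotated to the mLDFA target about the intercondylar notch; mTFA
follows from the identity. Stylised silhouettes are then rasterised around
the truth points: head = disk (optional inferior flattening); distal femur
= shaft + two condylar lobes tangent to the condylar line with a carved
intercondylar wedge whose apex is the notch; proximal tibia = plateau slab
with two triangular spines flanking the spine centre; distal tibia = shaft
with a flat plafond through the ankle centre; talus = dome beneath it.

Default geometry (pixels): 448×1376 canvas, femur 600, tibia 540, head
radius 60, condyle radius 26 and separation 100, plateau half-width 80,
spine height 22 and separation 44, joint gap 18 — roughly 0.7 mm/px for an
adult limb. Two rasterisation choices matter for accuracy: condylar lobes
are superellipses (exponent 1.3) rather than circles, because a circle's
raster bottom is a ~10 px flat run whose endpoints wander with joint-line
tilt, while the pointier profile keeps the most-distal point sub-pixel
stable; and the plateau slab drops vertically below its corners so the
rasterised corner is near-right-angled (an acute corner loses its tip
pixels). Rendering is 8-bit: bone 200, soft-tissue halo 120 (8-px
dilation), background 30, a vertical illumination gradient, optional
Gaussian noise (σ = 4 by default); these are conventions, not X-ray
physics.

Populations draw (mLDFA, MPTA, JLCA_signed) i.i.d. from Gaussian marginals
matching an automated-measurement clinical cohort — mLDFA 87.73 ± 1.86,
MPTA 86.99 ± 3.29, JLCA 1.67 ± 1.41 (degrees) — truncated to [78°, 102°]
(joint-line angles), [−10°, 10°] (JLCA) and to an implied mechanical-axis
deviation |mTFA − 180°| ≤ 12° so the limb stays on the canvas; the
truncations act beyond 3.4 SD and are negligible for the moments. The
three generative marginals are primary; the implied mTFA distribution
(≈ 182.4 ± 4.0) is close to, but not exactly, the cohort's printed mTFA
row, because four separately reported marginals cannot all be consistent
with the exact identity.

What the phantom does **not** emulate: anatomical shape variation,
osteophytes and joint-space narrowing, rotation/flexion malpositioning,
X-ray projection physics, overlapping anatomy (beyond the optional head
flattening) and implants. Passing tests therefore demonstrate correctness
of the geometry and rules under clean segmentations with realistic angular
variation, not clinical robustness.

## Segmentation

The network is a symmetric encoder–decoder: the encoder of the `full`
variant is the 13 convolutional layers of VGG16, mirrored by a 13-layer
decoder that upsamples by scattering values at the max-pooling indices
saved by the corresponding encoder pool, followed by a 3×3 classifier
convolution and per-pixel softmax. The `desk` variant keeps the topology
at 4 encoder/decoder blocks with 8/16/32/32 channels (~31k parameters,
< 0.1% of full), for CPU training. Everything is float32 NumPy; 3×3
convolutions are one BLAS GEMM over im2col patches per layer, with
analytic backward passes (verified against finite differences).

Two-step layout: step 1 resizes the whole image to 311×932 (desk: 64×192,
the same 1:3 aspect) and scales intensities to [0, 1]; per-bone ROIs are
the margin-padded (default 10%) bounding boxes of the largest predicted
component per class, mapped back through the resize transform. Step 2
crops each ROI and resizes to the bone's working size (470×470, 740×540,
720×470, 470×430, 370×220; desk: 48×48, 80×64, 80×48, 48×48, 48×32 —
multiples of 16 so four pools fit), segments, and maps the mask back with
the recorded affine transform (bilinear for images, nearest for masks).
Prediction post-processing keeps the largest component and fills interior
holes.

Training is SGD with momentum 0.9, learning rate 1e-2, mini-batches of 4,
up to 120 epochs (desk experiments use 10 — the phantom contrast is strong
and held-out Dice saturates early), per-pixel cross-entropy, best
validation parameters restored. Two optimisation aids address extreme
class imbalance: the classifier bias can be initialised to the log class
priors, and `train` accepts per-class weights (median-frequency
balancing), used only for the multi-class step-1 locator where the distal
bones are a sub-percent pixel fraction; per-bone step-2 training is
unweighted.

**Known limitation** — desk-scale step-1 quality: at 64×192 with ≤ 32
channels the locator finds the joints but confuses bone identities along
the shaft segments (locally identical vertical bars; the receptive field
cannot always disambiguate which joint it is near), so ROI boxes from a
CPU-budget-trained step-1 do not reliably contain the full bone. The
ROI-location geometry is therefore validated with an oracle step-1 that
emits ground-truth class probabilities, and the headline segmentation
experiment trains and evaluates the per-bone networks on reference-ROI
crops (the bone's bounding box + 10% margin), scoring held-out predictions
against the full-resolution reference masks after mapping back to raw
coordinates. The full-size two-step configuration is architecturally
supported but not claimed to be validated here.

## Evaluation statistics

Overlap metrics are computed from the per-class confusion tally: global
accuracy, mean per-class recall, mean and frequency-weighted IoU, and mean
Dice over foreground classes only (a background Dice would inflate
scores). A Dice of two empty masks is defined as 1 (vacuous agreement).
A DSC ≥ 0.7 is banded "excellent agreement".

The ICC defaults to ICC(2,1) — two-way random effects, absolute agreement,
single measurement — the standard model when an algorithm is compared with
human raters on absolute values; ICC(3,1) is selectable. Point estimate,
95% CI and p-value come from the two-way ANOVA mean squares (via
pingouin); the independent test oracle is a hand-coded McGraw & Wong
closed form. Reliability bands follow the Altman cut-points (≥ 0.81 very
good, 0.61–0.80 good, 0.41–0.60 moderate, below fair-or-poor). Zero
between-subject variance leaves the ICC undefined and is flagged rather
than guessed.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script use: a 63-case angle-recovery
grid (joint-line angles 84–92°, JLCA 0–6°, tolerance 1°); 1000 random axis
sets for the identity; 100 random instances per brute-force geometry
oracle; n = 500 two-way tables for ICC recovery (tolerance 0.05); and a
200-phantom population split 80/10/10 for the segmentation experiment
(10 epochs per bone, minutes on one CPU, held-out mean Dice per bone
compared against the 0.7 threshold). Boundary-noise robustness uses
Bernoulli jitter p = 0.1 with a 2° angle tolerance.
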