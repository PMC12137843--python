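# Methods

## Scope and model

`cellstiff` evaluates single-cell stiffness from phase-contrast images
in three coupled steps: (i) a compact CNN classifies cells as soft or
stiff and its stiff-class softmax probability p (the "stiffness range")
acts as a continuous stiffness score; (ii) p is calibrated against
reference Young's moduli E with a one-phase-decay curve and inverted to
predict moduli in pascals; (iii) Grad-CAM — standard for the
classifier, a modified form for the regressor — localizes the image
evidence. Reference computations (Hertz fitting of AFM force curves, DC
transit times) provide the measured moduli the calibration consumes.

The central modeling assumption is that stiffness leaves two visible
signatures in phase contrast: soft, rounded, weakly adherent cells show
a bright peripheral halo, and stiff cells show heterogeneous
intracellular texture. Everything downstream (phantom design, the
monotone p–E relationship, the saliency expectations) follows from it.

## Phantom generator

The generator renders exactly those two cues, controlled by one
dimensionless stiffness parameter s ∈ [0, 1]:

* geometry: an ellipse whose eccentricity (up to 12%) and radial
  sinusoidal boundary perturbation (modes 3/5/7, amplitude
  `boundary_irregularity`·s) both scale with s, so soft phantoms are
  near-circular and stiff ones irregular;
* halo: a Gaussian radial band centered at 0.9 R with σ = 0.075 R and
  amplitude `halo_gain`·(1 − s) — by construction the band-mean halo
  contrast at s = 0 is ≈ 0.86·`halo_gain`;
* texture: low-pass-filtered (σ = 1.5 px) Gaussian speckle inside the
  cell rescaled to standard deviation `texture_gain`·s;
* background noise sd `noise_sd`, 8-bit quantization, optional
  replication to three identical channels (the imaging content is
  monochrome even when stored as RGB).

s maps to ground-truth modulus log-linearly over 200 Pa–3 kPa — the
range typical of cultured mesenchymal stromal cells — via
E(s) = 200·15^s Pa, a strictly increasing bijection with an exact
inverse. Labels use a threshold at s = 0.5; training sets draw s from
well-separated intervals ([0, 0.2] soft, [0.8, 1] stiff) to mimic
chemically softened/stiffened subpopulations, and `generate_phantom_spectrum`
draws s uniformly over [0, 1] to play the role of untreated,
intermediate-stiffness cells.

Defaults (crop 100 px, radius 30 px, halo gain 70, texture gain 45,
noise sd 4) were chosen once so that the two cues are strong relative
to noise but neither saturates 8-bit range. The magnitudes of the real
halo/texture contrasts are not documented anywhere we could anchor to,
so these are free parameters of the phantom, not claims about
microscopy. What passing tests show is therefore that the *pipeline*
(training, calibration, inversion, explanation, reference fits) is
correct and internally consistent — not that the classifier would reach
the same accuracy on real phase-contrast images, which carry optics,
debris, focus and confluency effects the phantom deliberately omits.

## Networks and training

No deep-learning framework is part of the dependency set; the networks
are built on a small numpy engine (`cellstiff.nn`) with im2col
convolutions, 2×2 max pooling, dense layers, softmax cross-entropy and
MSE losses, and Adam. Backprop is verified against central finite
differences in the test suite. Training is single-threaded numpy and
bit-reproducible for a fixed seed.

* Classifier: conv 16 → pool → conv 32 → pool → dense 64 → dense 2,
  ReLU hidden, softmax output, categorical cross-entropy, Adam lr 10⁻⁵,
  batch 32. The conv widths are a deliberate minimal choice — the
  published architecture diagram for this family of models is not
  available — sized so the phantom task trains in minutes on one CPU.
* Regressor: fixed census of one 3×3 convolution (8 filters), two 2×2
  poolings, two dense layers (32, 1), linear output, MSE loss, Adam
  lr 10⁻⁵.

**Internal regression target.** The regressor trains on standardized
log₁₀(modulus) and exposes predictions in Pa. With Adam, each parameter
moves at most lr per step, so a raw-Pa output head (targets of order
10²–10³) cannot be reached at lr 10⁻⁵ in any desk-scale step budget;
standardizing the target (and taking logs, since 200–3000 Pa spans an
order of magnitude) makes the output head reachable while the loss
remains MSE. The transform is affine and stored on the model, so it is
inverted exactly at prediction time. Raw-Pa training remains available
via `RegressorSpec(log_target=False)`.

**Problem sizes.** Desk-scale runs use 2,000 training phantoms and 6
epochs for the classifier (the well-separated phantom task reaches
validation accuracy 1.0 within 2–3 epochs; 6 adds margin) and 12–15
epochs for the regressor on 800 phantoms. Early stopping (patience 10,
best-weights restore) is on by default. These sizes are the package's
own defaults for synthetic experiments; nothing prevents longer runs.

## Calibration

p is fitted as a saturating function of E,
p(E) = plateau + (p₀ − plateau)·e^(−kE), by `scipy.optimize.curve_fit`
with the parameter-free initialization p₀ ← p at the smallest observed
E, plateau ← p at the largest, k ← 1/median(E), and k bounded positive.
This orientation (rather than fitting E against p) gives a
single-valued analytic inverse for converting ranges to moduli. The
"one-phase decay" name follows the convention of common curve-fitting
software; with plateau > p₀ the same formula is a rising saturation
curve, which is the shape an increasing p–E relation produces. Fit
requirements: ≥ 4 distinct E values, non-constant p; the fit reports
RSS over its own inputs.

Inversion clips p into the open interval between p₀ and plateau by
ε = 10⁻⁶ (with a warning) and caps predictions at E_max = 10 kPa near
the asymptote, where the inverse diverges. APE = 100·|pred − true|/true
and CV = 100·sd/mean (sample sd) summarize agreement.

## Grad-CAM

Channel weights are spatial averages of output gradients over a chosen
convolutional feature layer (default: the last one, standard practice).
For classification the target is the pre-softmax class score and the
displayed map is the ReLU-rectified weighted activation sum, normalized
to [0, 1]. For regression the target is d = 1/|x − x′|; since
∂d/∂x = −1/(x − x′)² < 0 exactly when x > x′, the sign of the incoming
gradient encodes whether highlighted regions would decrease
(overestimate) or increase (underestimate) the prediction, and the mode
is recorded with the map. Whether the regression map should be
rectified before display is a convention choice; the signed map is kept
and |map| offered, so both readings are available. Gradients flow
through the internal target transform by the chain rule
(∂x/∂raw = ln10·scale·x for the log target). All α weights are verified
against finite differences (relative error well below 10⁻³).

## Reference measurements

**Hertz/AFM.** The indenter model is a conical Sneddon form,
F = (2/π)·tanθ·E/(1−ν²)·δ², with default half-angle 18° and ν = 0.5 —
the standard approximation for pyramidal AFM tips; the probe geometry
is configurable since real calibrations differ. Given the contact
point, E is a closed-form linear least-squares solution (exact on
noiseless curves). An unknown contact point is located by a two-segment
change-point search (flat baseline + quadratic regime, minimal total
RSS), which recovers synthetic contact points to within the sampling
step. Per-cell moduli average repeated fits and warn when the count is
not the conventional three.

**Deformability cytometry.** Frames (default 128×256 px at 250 fps) are
thresholded; the single cell's intensity centroid defines entry (first
frame with centroid x ≥ x_start) and exit (first with centroid
x ≥ x_end) of the constriction, and transit time is the frame
difference over fps. The synthetic generator records ground truth from
the same rendered-centroid definition, so noiseless extraction matches
exactly; sequences with more than one detected blob are rejected.
Diameters come from the equivalent-circle area before entry, and
records are summarized in half-open diameter bins (default width 1 px)
by median/IQR transit time, because transit time confounds size with
stiffness.

## Statistics

`compare_groups` mirrors the field's convention: Shapiro–Wilk on every
group at α = 0.05 gates parametric tests (two-sample t-test, or one-way
ANOVA with Tukey's HSD post hoc for > 2 groups) versus rank tests
(Mann–Whitney U, Kruskal–Wallis). Shapiro–Wilk is our choice of
normality test; any gate of this kind is approximate, and the type-I
error of the combined procedure is verified by simulation (≈ 0.05 under
a three-group Gaussian null). Gaussian distribution summaries use the
ML normal fit and reject zero-variance samples. The two-group test is
the independent-sample form, appropriate for the unpaired synthetic
groups generated here.

## Degenerate inputs and numerical conventions

Splits floor the validation/test counts and give the remainder to
train; stratification partitions each class separately with a seeded
shuffle. Hard classification labels use p ≥ 0.5 (ties to stiff,
argmax-of-softmax convention). Resizing is bilinear with anti-aliasing
on downscale; normalization is exactly affine and invertible on the
continuous scale. Max-pool routes gradients to the argmax element only.
All generators, splits, and training runs take explicit integer seeds
and derive child seeds from `numpy.random.default_rng`, so any artifact
is reproducible from config + seed.

## Known limitations

* The phantom is a two-cue caricature; results do not transfer claims
  to real microscopy (see above).
* The classifier architecture and training epochs are package defaults,
  not a reconstruction of any published network.
* The modulus-threshold labeling rule for "2 ± 1 kPa or above"-style
  definitions is ambiguous at the band edge; both readings (≥ 1 kPa
  default, ≥ 2 kPa strict) are supported via `ModulusLabelRule`.
* Viscoelastic indentation models, cantilever spring-constant
  calibration, and multi-cell DC scenes are out of scope.
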