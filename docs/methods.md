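# Methods

This document describes the model and the numerical choices behind `veus`:
the conditional adversarial translator, the color codec and its exactness
guarantees, the quantification metrics, the clinical-evaluation statistics,
and the synthetic phantom — including what the phantom can and cannot stand
in for.

## 1. Problem setting

Strain elastography overlays a pseudo-color stiffness map on the B-mode
image: soft tissue renders blue, stiff tissue red, with a continuous color
bar in between. Readers quantify a lesion by its strain ratio (SR) — the
mean elasticity level inside the tumor region of interest (ROI) divided by
the mean level in a same-depth reference region of normal tissue — and by
the Tsukuba elasticity score, a 1–5 visual grade used to adjust the BI-RADS
category. `veus` learns the mapping from the B-mode image to the composite
pseudo-color elastogram, then runs the identical quantification on real and
synthesized images so the two can be compared like for like.

## 2. Color codec (`veus.codec`)

Elasticity is represented as integer levels 1…256 mapped through a
`ColorBar` of 256 RGB entries running blue → cyan → green → yellow → red
(endpoints (0, 0, 240) and (252, 0, 0)). The composite image is

```
composite = floor(bus · (1 − w)) + w · bar[level]
```

with overlay opacity `w = 0.5` by default. Two deliberate integer-
arithmetic choices make this overlay *lossless* at `w = 0.5`:

- every channel of every bar entry is a multiple of 4, so `w · bar[level]`
  is integer-exact and the halved bar remains injective (all 256 scaled
  entries stay distinct);
- the B-mode layer is floor-scaled into `[0, (1 − w) · 255]`, so the sum
  never clips.

Subtracting the stored B-mode layer therefore recovers the pure color
exactly, and decoding — nearest bar entry by squared Euclidean RGB
distance, computed in integer arithmetic with ties broken toward the
smaller level — returns the original level for every pixel. The test suite
asserts this round trip exactly for all 256 levels and for random maps.
For synthesized images the same nearest-color decoder acts as a robust
quantizer: outputs need not lie on the bar, and each pixel maps to the
closest legal color.

## 3. Translator (`veus.gan`)

### Generator

A U-Net takes the 1-channel B-mode image (scaled to [−1, 1]) and outputs a
3-channel composite through Tanh. The full-scale plan has encoder output
channels (64, 128, 256, 512, 512, 512, 512) — seven stride-2 4×4
convolutions, so a 256×256 input reaches a 2×2×512 bottleneck — and decoder
input channels (512, 1024, 1024, 1024, 512, 256, 128), the doubling caused
by skip concatenation. Each block is ordered activation → convolution →
batch normalization; decoder blocks use transposed convolutions (stride-2
4×4), the exact adjoint of the encoder convolution. Decoder output widths
are derived from the skip plan (`decoder_in[j+1] − encoder[m−2−j]`) and
validated at construction.

### Discriminators

Two PatchGAN discriminators view the 4-channel concatenation of the B-mode
image and an elastogram:

- a **global** discriminator on the whole image (channels 64, 128, 256,
  512, 512, 1; strides 2, 2, 2, 1, 1, 1), emitting a patch map of
  real/fake probabilities rather than a single scalar, which constrains
  local texture statistics;
- a **tumor** discriminator on the ROI crop (resized to 128×128 by nearest
  neighbor), which concentrates capacity on lesion rendering.

### Losses

With `x` the B-mode image, `y` the real and `y_v` the synthesized
elastogram, and CE the cross-entropy on probabilities:

```
L_G = λ · Σ γ(y) |y − y_v| / N  +  CE(1, D(x, y_v))  +  CE(1, D_t(x_t, y_v^t))
L_D = ½ [CE(1, D(x, y)) + CE(0, D(x, y_v))]          (and likewise for D_t)
```

with λ = 100. The L1 term is weighted per pixel by a color-rebalancing
factor γ so that rare colors (typically the stiff red end, since most
tissue is soft) are not washed out by the abundant blues:

```
γ_p = ( α · P̃(p) + (1 − α) / Q )^(−1),   α = 0.8
```

where `P̃` is the empirical color distribution of the training elastograms
over a Lab a/b-plane grid of bin width 10 and `Q` is the number of occupied
bins. Closed forms used as test oracles: a uniform distribution gives
γ = Q; α = 0 gives γ = Q for every bin; α = 1 with P̃ = ½ gives γ = 2. Raw
γ has magnitude ≈ Q, which multiplied by λ = 100 would dwarf the
adversarial terms, so by default γ is rescaled to unit expectation under
P̃ (the raw behavior is available with `rebalance_normalize=False`).
Weights are looked up from the *real* target pixel's bin so they do not
depend on the generator's moving output.

A configuration flag `literal_printed_loss` switches the global
discriminator's fake term to be evaluated on the real pair; that variant
makes the global discriminator independent of the generator and exists only
for comparison experiments — it is off by default.

### Optimization

Adam with learning rate 2·10⁻⁴, β₁ = 0.5, β₂ = 0.999; the rate is constant
for the first half of training (epochs 1–100 of 200 at full scale) and then
decays linearly to zero. Weights are initialized from N(0, 0.02²). Random
horizontal flips augment training pairs (ROI columns are mirrored
accordingly); an optional differentiable augmentation (brightness jitter ±
0.2 and translation up to ⅛ of the image, applied identically to both
discriminator inputs with exact gradients) is available but off by default.
Cross-entropies are computed on probabilities clamped away from {0, 1}
(10⁻⁷) in closed-form evaluations and via numerically stabilized
softplus-on-logits inside training.

### Desk-scale configuration

All tests and examples run a reduced configuration chosen so the full
adversarial loop trains in minutes on one CPU: 64×64 images with 0.6 mm
pixels (the same 38.4 mm field of view as 256×256 at 0.15 mm), generator
channels (16, 32, 64, 128) — four downsamplings to a 4×4 bottleneck —
discriminators (16, 32, 64, 1) with strides (2, 2, 2, 1), batch size 8, 30
epochs with decay from epoch 15, tumor crops at 24×24. This is a surrogate
scale: it demonstrates that the architecture and objective recover the
stiffness contrast, not that they match any clinical operating point.

### Numerical implementation

The layer library (`veus.nn`) is pure NumPy: convolutions via
`im2col`/`col2im`, transposed convolutions as the exact adjoint of the
corresponding convolution, batch normalization with running statistics for
inference, and Adam. Every layer's backward pass is verified against
central finite differences (agreement to ~10⁻⁷ absolute) in the test
suite, so training dynamics are not hostage to a silent gradient bug.
Inference resizes inputs to the nearest multiple of the total stride and
back by nearest neighbor, and uses running batch statistics, so
`synthesize` is deterministic.

## 4. Quantification (`veus.quantify`)

- **Strain ratio**: mean decoded level in the tumor ROI over the mean level
  in a reference box. The reference is auto-placed at the same depth
  (row-centered on the ROI), flush against whichever lateral margin is
  wider, with ties going left; placement is validated never to intersect
  the ROI, and overlapping boxes are rejected.
- **SSIM**: the global (single-window) structural similarity with K₁ =
  0.01, K₂ = 0.03, L = 255, averaged over channels. A hand-computed 4-pixel
  oracle is frozen in the tests.
- **MAPE**: mean of |v − v̂| / v over paired positive measurements.
- **CHC**: color-histogram correlation. Each image is converted to HSV;
  hue (50 bins) and saturation (60 bins) histograms are compared with the
  Hellinger-based affinity HC = 1 − √(1 − BC), where BC is the
  Bhattacharyya coefficient of the normalized histograms, and the two
  channels are averaged. Identical images give exactly 1, disjoint color
  supports exactly 0.

## 5. Clinical evaluation (`veus.clinical_eval`)

- **AUC with confidence interval**: midrank (tie-aware) AUC with the fast
  DeLong structural-components variance; equals the brute-force pairwise
  statistic exactly, as the tests assert on hundreds of random instances.
- **Paired DeLong test**: two-sided z-test on the AUC difference of two
  score vectors over the same cases, using the paired covariance of the
  structural components. Cross-checked against a 10⁴-resample paired
  bootstrap in the tests.
- **Depth-stratified AUC**: AUC per tumor-depth bin (default edges 0, 10,
  15, 20 mm, ∞), with single-class bins flagged undefined rather than
  reported as numbers.
- **Tsukuba–BI-RADS fusion**: on the ordinal scale 2 < 3 < 4a < 4b < 4c <
  5, a soft lesion (elasticity score 1–3) moves the BI-RADS category one
  step down and a stiff one (4–5) one step up, clipped at the ends.
- **Perceptual score**: in a blind two-image test the reader picks which
  image is the real elastogram; each case scores 1 when the pick is wrong
  and 0 when right, and the mean over cases is the score. A reader who
  cannot tell the images apart scores ½ in expectation; the tests and
  `scripts/acceptance.py` verify this by simulating 10⁴ random-pick trials.

## 6. Synthetic phantom (`veus.phantom`)

Each case is a registered BUS/EUS pair with known stiffness ground truth:

- **Stiffness map**: background level 64 with smooth spatial variation; one
  elliptical lesion (axes 4–12 mm, center depth 8–32 mm by default) whose
  level is drawn from disjoint class ranges — benign 80–140, malignant
  180–245 — so class separation by SR is achievable by construction.
- **B-mode rendering**: multiplicative Rayleigh speckle (σ = 0.35) over a
  smooth echogenicity field, exponential depth attenuation (0.02 per mm),
  and a hypoechoic lesion whose echo intensity decreases monotonically with
  stiffness level. That last coupling is what makes the translation task
  learnable from B-mode alone; it is the phantom's strongest idealization.
- **Elastogram rendering**: the ground-truth level map encoded through the
  color bar and composited on the B-mode layer at opacity 0.5 (losslessly,
  §2).
- **Attenuation artifacts**: lesions whose top edge lies deeper than 20 mm
  acquire, with probability 0.259 (the default mirrors the prevalence of
  posterior shadowing observed in deep clinical lesions), a wide dropout
  band from the lesion's upper half to the bottom of the image repainted
  with soft-end colors uncorrelated with true stiffness. The ground-truth
  map is untouched: attenuation corrupts the measurement, not the tissue.
  This reproduces the mechanism by which real elastography degrades with
  depth while a B-mode-driven synthesis need not.
- **Dataset assembly**: the benign/malignant split is allocated
  deterministically (`round(n · fraction)` malignant, interleaved), BI-RADS
  categories are sampled label-consistently, and identical seeds produce
  byte-identical datasets on disk.

### What the phantom does and does not establish

The phantom supports *mechanism-level* claims: the codec is exact, the
metrics satisfy their identities, the optimization reduces its objective,
and the trained translator transfers the stiffness signal present in the
B-mode texture into decodable elastograms whose strain ratios separate the
classes (held-out mean AUC ≥ 0.8 at desk scale, and better than
artifact-corrupted real elastograms on deep lesions). It does **not**
establish clinical performance: real B-mode texture carries far weaker and
less monotone stiffness information than the phantom's built-in coupling,
real lesions are not ellipses with disjoint class stiffness, speckle is
correlated with anatomy, and reader behavior is not simulated beyond the
chance-level null. Numbers measured on the phantom are properties of the
pipeline, not of breast imaging.

## 7. Limitations

- The generator's realism is bounded by the phantom: it learns the
  phantom's stiffness–echogenicity coupling and will not generalize to
  modalities or anatomies outside it.
- Desk-scale results use 64×64 images and small networks; full-scale
  (256×256) training is implemented and validated for gradient correctness
  but is far slower in pure NumPy than in a GPU framework, and no
  full-scale empirical results are reported here.
- The decoded-SR route assumes the paired B-mode layer is available to
  subtract; for composites from other sources the decoder still returns
  the nearest legal color but exactness guarantees no longer apply.
- DeLong inference assumes independent cases; clustered readings (multiple
  lesions per patient, multiple readers) would need a clustered variance
  estimator.
- The Tsukuba–BI-RADS fusion implements a fixed one-step adjustment rule;
  it does not model reader variability in assigning either input score.
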