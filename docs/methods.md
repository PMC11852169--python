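# Methods

This note documents the models and procedures `funduslab` implements, the
parameters that matter, the synthetic data the tests run on, and the
numerical and design choices that were genuinely open.

## Stage 1: the geometric labeler

### Multiscale contrast shape descriptor

For a pixel *p* and direction θ the directional contrast is the mean of
`d` bilinearly interpolated samples at unit arc-length spacing along the
ray from *p*, minus `I(p)`. The descriptor reduces the profile over
`n_directions = 16` uniformly spaced directions:

* **blob / dark** — `max(0, min_θ c(θ))`: positive only where *every*
  direction sees brighter surroundings, i.e. isotropically dark spots
  (bleeding). The min-over-directions is the vessel killer: along a
  vessel's axis `c ≈ 0`.
* **blob / bright** — `max(0, −max_θ c(θ))`: symmetric for exudates.
* **linear** — `max(0, max_θ c(θ))`: the signed maximum, which is large on
  dark curvilinear structure and, unlike an absolute-value variant, stays
  quiet on the bright flanks of lesion boundaries. This matters: a
  rectified-magnitude linear response would paint a halo around every dark
  lesion and the vessel-adjacency filter would then discard the lesion.

Sixteen directions resolve line orientations at the smallest scale;
angular sampling below ~8 lets diagonal vessels leak into the blob
response.

**Scales.** `d ∈ {3, 5, 10}` px at the 1000×1000 CFP working resolution
(`{5, 8, 15}` for 1500×1500 ultrawide-field). A pixel responds at scale
`d` only if every ray of length `d` exits the lesion with contrast budget
to spare, so the largest scale caps the detectable lesion: a region is
*fully* covered — and therefore ring-scored against true background —
only when its longest chord is ≲ `d_max`·(1 − floor/contrast) ≈ 8–9 px.
Larger blobs respond only in a central core whose outer ring still lies
inside the lesion, collapsing the confidence. This is an inherent
property of the descriptor, not an implementation limit; detecting larger
lesions requires adding larger scales via `mcsd.scales`.

**Merging and flooring.** Per-scale fields are floored at
`contrast_floor = 0.02` (normalized intensity) and merged by pixelwise
maximum, preserving a contrast magnitude for downstream scoring. The
floor is deliberately low: at 0.04 the boundary ring of lesions near the
size cap falls under the floor and the candidate erodes by one ring,
which silently destroys its confidence score (see above). Noise
suppression does not need a high floor because the min-over-directions
statistic is negative almost surely on zero-mean noise; residual specks
are removed by the `min_area = 2` component filter and the LOW confidence
bucket. Candidate components are hole-filled: textured lesions (soft
exudates) respond everywhere except at interior texture dips, and the
dips are part of the lesion.

### Ring confidence and buckets

The signed distance of a region (positive inside, negative outside, zero
on the boundary contour) is the exact Euclidean distance transform with a
0.5 px pixel-center offset; it is everywhere within half a pixel of the
true signed distance, which is the accuracy the band construction needs.
Band width `w = max(1, round(r_max/4))`; the inner band is the interior
shell of depth ≤ w, the outer band the exterior shell of width ≤ w
clipped to the field of view. `confidence = |outer − inner| / inner` is
invariant to multiplicative illumination. Buckets: LOW < 0.15 ≤
INDETERMINATE < 0.35 ≤ HIGH, thresholds passing at equality. LOW regions
are retained (they do not block training windows); INDETERMINATE regions
are quarantined — never labels, always blockers. A dark region whose
outer band overlaps vessel pixels above 0.35 is flagged vessel-excluded
and barred from HIGH: its high contrast is the vessel's, not its own.
Vessel-excluded regions also block training windows.

The ratio form has an asymmetry worth knowing: a bright lesion of
contrast `c` on background `b` scores only `c/(b + c)`, so bright lesions
need roughly `c ≳ 0.54·b` to reach HIGH while dark lesions reach it far
earlier. The synthetic generator's priors respect this (below).

### Typing rules

* Dark, HIGH → microaneurysm iff boundary-covariance eigenvalue ratio
  λ₁/λ₂ ≤ 1.25 *and* area < image_area/200; else hemorrhage. The two
  conditions are conjoined because violating either contradicts the
  microaneurysm phenotype (tiny and round). The raw eigenvalue ratio is
  used (not its square root). Degenerate boundaries (λ₂ ≈ 0) count as
  elongated.
* Bright, HIGH → the lesion is split by its own inner ring into core
  (depth > w) and shell (depth ≤ w); if the fraction of shell pixels
  brighter than the core mean exceeds 15% the profile is uneven → soft
  exudate, else hard exudate. A lesion too small to have a core defaults
  to hard exudate with a warning. Reusing the ring geometry keeps one
  consistent region model across scoring and typing.

## Stage 2: patches and segmentation

### Clean-window mining

Windows grow from 10×10 around a HIGH region's centroid (or a random
background pixel of a lesion-free image) in 5 px side steps while free of
indeterminate pixels, stop at 120, revert to the last clean size on
violation, and are kept when the (border-clipped) extent reaches 60.
Lesion windows carry the union of HIGH-region masks of their target type
as labels; per type, an equal number of background windows is
rejection-sampled (50× the quota attempt budget) so the training set is
exactly balanced. Augmentation draws a seeded subset of translation,
cropping, padding, scaling, flipping, rotation, Gaussian noise and
intensity shift; geometric operations transform image and masks
identically, photometric ones leave masks untouched.

### U-Net harness

A classical four-stage U-Net (filters 32/64/128/256, double 3×3
convolutions, 2×2 max pooling, nearest-upsampling decoder with skip
concatenation, 1×1 sigmoid head) implemented directly in numpy with
im2col convolutions and hand-derived backpropagation, verified against
numerical gradients in the test suite. Training minimizes the Dice loss
`1 − (2Σpt + ε)/(Σp + Σt + ε)`, ε = 1e-6, computed **over the whole
batch**: per-patch Dice is degenerate on the empty-target background
patches (the loss jumps from 0 to ~1 the moment any probability mass
appears) and reliably collapses training to the empty prediction.
Validation performance is the pooled Dice coefficient on a held-out 10%
split; the learning rate halves after 3 epochs without improvement and
training stops after 10 (both schedules are unit-tested against injected
plateaus). The output head's bias starts at −2 so the initial prediction
is near the true foreground prior rather than 0.5.

Two further stabilizers matter at small data scale, both measured rather
than assumed: Adam's second-moment decay is 0.9 (at 0.999 the Dice
gradient spike that appears when the denominator shrinks saturates the
sigmoid and kills roughly one run in three; at 0.9 training was stable on
10/10 seeds), and the desk-scale profile trains at `lr = 1e-4` while the
library default remains the published 1e-3.

**Patch-to-input fitting.** The default follows the full-scale recipe:
windows resized to `input_side = 96`. The desk-scale profile used by the
tests and the acceptance script instead center-crops at native resolution
(`patch_fit = "crop"`, `input_side = 24`): synthetic lesions are only a
few pixels and resizing 60–120 px windows down erases them, while crops
keep lesion scale identical between training patches and the overlapping
sliding-window inference tiles (stride = half a tile, probabilities
averaged, threshold 0.5, 8-connected components as detections).

## Evaluation

Binary-overlap matching: a prediction is a true positive iff it shares at
least one pixel with any truth region; a truth region is detected iff at
least one prediction overlaps it, counted once; everything else is a
false positive, reported per image. An IoU-threshold mode exists behind a
flag but is not the default. Size-binned reporting assigns truths by
their own area and false positives by predicted area to the half-open
bins (0,10), [10,50), [50,100), [100,∞).

## Synthetic scenes

The generator emulates what the labeler assumes about fundus photographs:
a smooth illumination field (mean 0.45, ±0.02 low-frequency variation)
with Gaussian sensor noise (σ = 0.01); dark tapering vessels with
Gaussian cross-sections (contrast 0.15–0.30, half-width 1–2.5 px);
microaneurysms as dark discs (radius 1.2–3, contrast 0.15–0.35);
hemorrhages as warped dark ellipses (semi-major 2.5–3.8, axis ratio
1.5–2.2, contrast 0.20–0.35), optionally planted on a vessel centerline
to exercise the vessel-exclusion rule; hard exudates as bright discs with
a monotone quadratic falloff (radius 2–3.2, contrast 0.30–0.40); soft
exudates as bright discs with scattered intensity dips (radius 2.5–3.5,
30% of pixels at half elevation) — dips rather than positive speckles,
because positive speckles break the all-directions-negative bright-blob
test at non-speckled pixels and fragment the candidate, while dips become
interior holes that hole-filling restores and still leave ~70% of the
shell above the core mean, the soft-exudate signature. Optional faint
dark spots (contrast 0.04–0.10) exercise the LOW/INDETERMINATE buckets.

The priors are deliberately inside the descriptor's detectable band and
above the bright-lesion confidence floor discussed above; the background
mean (0.45) is at the darker end of realistic green-channel values, which
is what makes exudates of contrast ≥ 0.3 reach the HIGH bucket at all.
Placement is rejection-sampled (100 retries, then a generation error)
with lesions kept clear of vessels, each other and the border; everything
derives from a single seeded generator, and identical seeds reproduce
scenes bit for bit.

**What passing on this generator does and does not show.** The scenes
validate the geometry of the method: descriptor selectivity, ring
scoring, the typing rules, patch cleanliness and the learning loop. They
do not model optic disc or fovea, drusen or laser scars, UWF eyelash and
stain artifacts, JPEG texture, or lesions beyond the default scales —
so the measured recovery/sensitivity numbers characterize the
implementation, not clinical performance.

## Problem sizes and tolerances

The reference experiments (in `funduslab.benchmarks`, asserted by the
test suite and reported by `scripts/acceptance.py`) use: 20 random 32×32
images for descriptor/oracle agreement (tolerance 1e-9; measured ~1e-16);
50 line-plus-disc phantoms at 160² for vessel suppression (disc response
≥ 3× line response); a 5×5 grid of uniform radius-4 discs for closed-form
confidence (tolerance 0.05); 200 generated lesions for typing accuracy
(≥ 90%); 20 scenes at 320² plus 5 lesion-free scenes for labeler
recovery (≥ 90% of isolated lesions with contrast ≥ 0.25 HIGH-bucketed,
≤ 2 spurious HIGH per clean scene); and 200 mined patches for the
segmentation experiments (5-epoch smoke decrease; 30-epoch detection
scoring on 3 held-out scenes). Scene counts and canvas sizes were chosen
to keep a full run in the minutes range on one CPU; the experiments scale
up by argument.

## Known limitations

* Lesions wider than the largest descriptor scale are invisible to
  Stage 1 by construction; real deployments should extend `mcsd.scales`
  upward and revisit `contrast_floor` accordingly.
* The numpy U-Net is a correctness-first harness: bit-reproducible on one
  CPU thread but orders of magnitude slower than a framework
  implementation; the desk-scale detection numbers (trained on 200
  patches) are far from what the recipe yields at full data scale, and
  its false-positive rate in particular is an artifact of the tiny
  training set.
* The ultrawide-field profile scales the canonical size and descriptor
  scales but models none of the peripheral distortion or eyelash/stain
  artifacts such images carry.
* Confidence is a hard-thresholded ratio, not a calibrated probability.
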