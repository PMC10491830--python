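# Methods

## Indices

Both indices are per-image area ratios on [0, 100].

* `t = 100 · mycorrhized_area / total_root_area`, where the mycorrhized
  area is the set of pixels strictly darker than a global brightness
  threshold θ (strict `<`, so a pixel exactly at θ is background — this
  matters when porting thresholding macros), intersected with the root
  mask, and the total area is the root section isolated from the slide
  background. Default θ = 100 on the 8-bit scale.
* `ml = 100 · c / (c + n)` with `c` the classifier-labeled colonized area
  and `n` the non-colonized area. The classifier uses three classes
  (colonized / root tissue / background) so that `n` can be restricted to
  root tissue; an `include_background` flag widens the denominator to the
  whole frame for comparison. Identically, `ml(c, n) = t(c, c + n)`.

Degenerate inputs are defined, not fatal: a frame with no detectable root
(or `c = n = 0`) yields index 0 with an `empty` flag.

The Trouvelot class assignment makes the six visual criteria total over
[0, 100] via half-open intervals: 0 → 1; (0, trace] → 2; (trace, 10] → 3;
(10, 50] → 4; (50, 90] → 5; (90, 100] → 6. The trace cutoff separating
"few traces" from "< 10 %" is inherently visual; it defaults to 1 % and
is configurable rather than hard-coded as truth.

## Root isolation and thresholding

The root mask is `pixels < bg_cutoff` (default 240), hole-filled, then
cleaned by discarding 8-connected components below 0.1 % of the frame —
removing stain debris while keeping any plausible root fragment. The
background cutoff is a package choice (how the original macro isolated
the root is not fixed by the method itself) and is logged with every
measurement. Thresholding is deliberately global and *ex ante*: no
per-image adaptation, since that is the method being characterized.

Grayscale conversion defaults to BT.601 luminance (0.299 R + 0.587 G +
0.114 B, rounded half-up). The red channel is offered as an alternative
because a blue stain absorbs red light most strongly, giving the best
fungal contrast; the choice is an explicit `method` option.

## Feature bank

The 25-channel per-pixel description vector partitions as 5 Gaussian +
5 Sobel-of-Gaussian + 12 Gabor + 3 Hessian. Only the partition is fixed
by the method; the parameter values are package defaults:

| family | parameters | default | why |
|---|---|---|---|
| Gaussian | 5 sigmas (px) | 1, 2, 4, 8, 16 | octave-spaced scales spanning hypha widths (~2–10 px at 4× magnification) |
| Sobel of Gaussian | 5 sigmas (px) | 1, 2, 4, 8, 16 | edge strength at the same scales |
| Gabor | 3 frequencies (cyc/px) × 4 orientations | 0.05, 0.12, 0.25 × 0°, 45°, 90°, 135° | oriented texture of filamentous hyphae |
| Hessian | 1 sigma | 2 | λ₁ ≥ λ₂ and det = λ₁λ₂: ridge/blob geometry |

Gabor channels are quadrature-pair magnitudes (phase-invariant, standard
texture practice). All filters use reflective padding. The configuration
is hashed and stored inside every trained model; prediction under a
different configuration is refused with both hashes named.

## Classifier

Default learner: random forest, 100 trees, unlimited depth, fixed seed,
single-threaded (determinism over speed). Training rows are the feature
vectors at annotated pixels; out-of-bag and training accuracy are
recorded in the model metadata. Ties in predicted class probability
break toward the first class in the model's class list, making label
maps stable across runs. Saved models are a single joblib archive
(classifier + feature config + metadata + version tag); loading checks
the version and save→load→predict is bit-identical. The model metadata
has an optional `created` field supplied by the caller rather than an
automatic timestamp, so that identical data + seed produce byte-identical
model files. A training folder (`images/`, `labels/`, `config.yaml`,
paired filenames, label codes 0–3 in 8-bit PNGs) can be exported and
re-imported losslessly for sharing reference annotations between
laboratories.

## Synthetic scenes

The generator emulates what matters for segmentation benchmarks: a
smooth, slightly wavy root band (default 50 % of frame height) in a
light blue tone on a near-white slide, with dark-blue intraradical
structures — hyphae as smoothed random-walk strokes, arbuscules as
dilated branching skeletons confined to elliptical cell-sized patches,
vesicles as filled ellipses — plus optional extraradical strokes outside
the root that darken the image but are excluded from the colonized mask
(only intraradical structures count as colonization). Mean intensity
levels (background 252 > root 205 > fungus 70) are enforced before
Gaussian sensor noise (default SD 4) and a linear illumination ramp
(default ±2 %) are applied, so a noise-free scene has a known ideal
thresholding operating point and noise/illumination act as separate,
opt-in difficulty knobs.

Structures are placed greedily, sized to the remaining area deficit,
until the colonized fraction is within a declared tolerance of 0.02 of
the target (exact targeting is ill-posed under discrete rasterization);
if the placement budget (400 attempts) runs out the achieved fraction is
reported and flagged, and a nonzero target with an all-zero structure
inventory is an explicit placement error. Everything is driven by one
`numpy` PCG64 generator, so a given parameter set is bit-reproducible.

What the scenes do *not* model — and hence what passing tests do not
show about real micrographs: brightness variation between slides and
dyes, out-of-focus blur, bacteria/algae/debris that confound dark-pixel
selection, root overlaps, and pixel-size calibration (scenes are in
pixel units; both indices are scale-free ratios, so this is benign).
Recovery results on synthetic scenes bound algorithm error, not
real-data ambiguity.

## Statistics

Classical (not Welch) one-way ANOVA. From raw groups, the standard
decomposition; from printed summaries, `SS_within = Σ (nᵢ−1)sᵢ²` and
`SS_between = Σ nᵢ(mᵢ − grand)²` with the grand mean pooled by group
size — algebraically identical to the raw route, which the tests verify
to 1e−9 relative on seeded data. Printed SDs are taken as sample SDs
(n−1); reconstructed tables then match published values within the
propagation of their 2-decimal rounding (~1 % relative). `MS_within = 0`
yields F = ∞ (flagged), not a crash.

Bonferroni post hoc: for each of the C(6,2) = 15 pairs,
`tᵢⱼ = (mᵢ − mⱼ) / sqrt(MS_within (1/nᵢ + 1/nⱼ))` on the pooled
within-group df, two-sided p multiplied by 15 and capped at 1,
significant at family-wise α = 0.05.

Polynomial fits (degrees 1–3) regress the visual class score (y) on the
index (x), with `R² = 1 − SS_res/SS_tot`; constant y gives R² = 0 by
convention, constant x is a rank-deficient design and an error. R² is
non-decreasing in degree (nested models), which the tests assert.

## Problem sizes

The classifier experiments in the test suite and acceptance script use
144 × 192 px scenes, 10 training scenes with 800 annotated pixels per
class each, 60-tree forests, and a 12-scene evaluation gradient spanning
true fractions 0–0.6 at noise SD 4 — small enough to run anywhere, large
enough that recovery error (≤ 5 index points) and rank correlation
(≥ 0.9) are meaningful. Library defaults remain 100 trees and
192 × 256 px scenes.

## Known limitations

* The feature bank reproduces the 5/5/12/3 channel partition, not any
  proprietary software's channel values bit-for-bit.
* One Hessian scale (three derived features) rather than multi-scale
  Hessian; per-structure sub-classes (arbuscule vs vesicle vs hypha) are
  left to the type system but not trained in v1.
* Thresholding quality on real images depends on brightness calibration
  between slides, which the global *ex ante* cutoff cannot absorb.
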