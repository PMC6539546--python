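# Methods

## Detection model

The detector is a classical two-stage sliding-window pipeline for red,
quasi-circular fruit on green foliage. Its assumptions: targets are
approximately circular, redder than everything else in the scene, and at
least as large as the scan window in the working-resolution image;
illumination varies smoothly and multiplicatively.

**Preprocessing.** Images are resized to the working resolution (360×202,
bicubic) and illumination-normalized in HSI space: the intensity channel is
log-compressed, `I' = log(1 + 255·I)/log 256`, then equalized with CLAHE;
hue and saturation pass through unchanged and the result is converted back
to RGB. The HSI transform is the arccos/minimum textbook formulation, with
the degenerate conventions S = 0 where I = 0 and H = 0 for achromatic
pixels; its inverse is the standard three-sector reconstruction. Because
only intensity is remapped, hue is preserved exactly for every pixel that
stays inside the RGB gamut; pixels driven to a channel limit by the
brightness remap can shift hue (a gamut effect, not a numerical one).

**Coarse stage.** A Gaussian Naive Bayes classifier over three per-pixel
color transforms — R−G, R−B, and the red chromaticity R/(R+G+B) (defined 0
at black pixels) — labels pixels tomato/background. Class conditionals are
diagonal Gaussians fitted by maximum likelihood with variances floored at
1e-6; priors are class frequencies; per-class samples are sorted into a
canonical order before accumulating sufficient statistics so the model is
bit-identical under permutations of the training data. The binary mask is
cleaned by morphological opening then closing (3×3 square footprint),
components under 25 px² are discarded as noise, and each surviving
component's bounding box, padded by 16 px (one window step) and grown to at
least 64×64 inside the image, becomes a region of interest.

**Fine stage.** An image pyramid downscales by 1.1 per level while the
level stays at least 113×64 (13 levels at 360×202); level k has dimensions
⌊W/1.1ᵏ⌋ × ⌊H/1.1ᵏ⌋ resampled bicubically from the original. A 64×64
window slides on a 16 px grid, restricted to windows overlapping a
(per-level rescaled) ROI by at least one pixel. Each window is converted to
grayscale (Rec. 601 luma; max-channel available as an option) and described
by HOG: centered [-1,0,1] gradients with replicated borders, orientations
folded to [0,180), magnitude-weighted bilinear voting into the two adjacent
of 10 orientation bins (circular wrap), 4 px × 8 px cells, 2×2-cell blocks
at 1-cell stride, each 40-entry block L2-normalized as v/√(‖v‖² + ε²) with
ε = 1e-5, concatenated row-major — 4200 dimensions for a 64×64 window. The
cell geometry, block size, bin count and L2 normalization are the tuned
configuration of the detector; stride, grayscale mode and ε are exposed in
`HogConfig`.

**Classifier.** A soft-margin linear SVM with hinge loss and C = 1, solved
exactly by libsvm's dual solver; in high feature dimension the Gram matrix
is precomputed with BLAS and handed to the solver, which yields the same
optimum far faster than per-entry kernel evaluation. Ties (margin exactly
0) classify as tomato. Confidences for NMS come from a Platt-style logistic
in the margin, P = σ(A·m), fitted by maximum likelihood with Platt's
smoothed targets on a held-out stratified quarter of the training set (the
final separator is then refit on everything). The calibration has no
intercept, pinning confidence 0.5 to the decision boundary and making
confidence strictly monotone in the margin. A hash of the HOG configuration
is stored with the model and checked at scan time, so a model can never be
applied under a different descriptor geometry.

**False Color Removal.** Windows accepted by the SVM are binarized with a
fixed plane in RGB space — w·(R,G,B) + b > 0 with the shipped constants
(0.16, −0.093, −0.037, −11.032) — and kept only when the white-pixel
fraction strictly exceeds 0.3. `fit_color_plane` re-derives such planes
from per-sample mean colors by the same soft-margin objective (slack sum
unweighted, i.e. C = 1). The filter removes two false-positive families:
round-but-off-color objects (unripe fruit), and shape-plausible windows
that only clip a fruit's edge.

**NMS and output.** Accepted windows are mapped to original coordinates
(multiply by 1.1ᵏ; dimensions floor, coordinates round-half-up; clip to the
image). Detections under confidence 0.7 are dropped, then greedy NMS keeps
the highest-confidence box and suppresses boxes overlapping it by IoU
strictly above 0.3 (intersection-over-min-area available as an option).
Ties break by larger area, then top-left lexicographic order, making the
result independent of input order. The confidence filter runs before
suppression. Final boxes carry their inscribed circle (center of box,
radius half the shorter side) as the displayed fruit outline.

**Evaluation.** Detections are matched to ground truth greedily in
decreasing confidence; a detection claims the unclaimed ground-truth box of
highest IoU at or above 0.5 (a center-in-box criterion is available, since
visual judgments of "correctly identified" in field studies are not
IoU-based; the IoU proxy is the default and is stricter). Duplicates on an
already-claimed fruit are false positives. Rates are recall = TP/(TP+FN),
precision = TP/(TP+FP) (0 when no detections), F1 their harmonic mean,
false rate FP/(TP+FP), missed rate FN/(TP+FN), reported as percentages
rounded half-up to two decimals. ROC/AUC uses the tie-aware rank
(Mann–Whitney) formulation.

## Synthetic scenes

The generator emulates the structure of greenhouse photographs at the
working resolution rather than their photometry. A scene is a pure function
of its `SceneSpec` (same seed ⇒ bit-identical output):

- **Background**: a green base with ~50 random elliptical leaf blobs in
  green hues (G > R by construction) and Gaussian pixel noise.
- **Fruit**: discs with radius 28–40 px (the scan window is sized so the
  smallest fruit is never below the window's trained apparent scale — the
  pyramid only downscales), radial shading falling to 70% at the rim, a
  specular highlight, and ±10% per-channel jitter around base RGB
  (200, 45, 40).
- **Conditions**: requested pairwise overlap is met geometrically (the
  center distance solving lens-area/smaller-disc-area = target, by Brent's
  method); occlusion draws a leaf ellipse over the fruit, bisecting its
  offset until pixel-counted coverage hits the requested fraction, and the
  measured fraction is recorded. Labels are exclusive with precedence
  occluded > overlapped > separated; the generator never occludes paired
  fruit, so "overlapped ⇔ boxes intersect" holds exactly.
- **Unripe companions**: with probability 0.25 per fruit, an adjacent
  green-turning fruit (base RGB (110, 150, 80), 0.9× radius) is rendered
  touching a ripe one — the mixed-ripeness truss situation. Companions
  share the ripe fruit's shaded-sphere geometry (HOG, being color-blind and
  gain-normalized, cannot separate them) but their color plane response
  stays below the FCR threshold at any plausible brightness. They are not
  annotated as targets and are excluded from background training crops via
  the fruit mask.
- **Illumination**: multiplicative fields — sunny ≈ 1.07, shaded ≈ 0.65,
  each with a mild lateral ramp, plus a strong 0.45→1.15 ramp option.

**Standard datasets.** Training: 69 scenes × 3 fruit, mixing the three
conditions in proportions 10:40:25 and alternating sunny/shaded → 207
positive patches (ground-truth box plus ~5 px margin per side, each side
jittered ±3 px to emulate manual cropping, resized to 64×64) and 621
background patches (windows of random side 48–96 px with under 20% fruit
coverage), doubled to 1656 by one random-rotation copy per patch
(reflection-padded, so corners leak no label information). Test: 75 scenes
× 2 fruit = 150 fruit — 10 separated / 40 overlapped / 25 occluded scenes
(overlap and occlusion fractions drawn from [0.15, 0.35]), illumination
alternating. These sizes are the package's standard experiment and are what
`scripts/acceptance.py` runs.

**What passing these scenes does not show.** The renderer has no
perspective, no camera noise model, no specular foliage, no stems/strings/
wires, no fruit clusters larger than pairs, and fruit are perfect discs;
color distributions are far cleaner than real imagery. Results on synthetic
scenes demonstrate that the pipeline's machinery is correct and that its
stages interact as designed (e.g. the FCR ablation lowers precision), not
that the quoted rates transfer to field photographs.

## Numerical choices

- CLAHE clip limit 2/256 ≈ 0.0078 in scikit-image's normalized units
  (equivalently: bins capped at 2× the mean histogram height), tiles on an
  8×8 grid. scikit-image's CLAHE min-max rescales its output; brightness is
  therefore not preserved, contrast relations are.
- Bicubic resize without anti-aliasing, clamped to [0, 255]; resizing to
  the current size returns an exact copy.
- SVM solver tolerance 1e-6 for library use, 1e-4 inside the pipeline
  (training sets there are large and well-separated); the two-point and
  brute-force comparisons in the tests use tighter tolerances.
- Degenerate definitions: precision 0 with no detections; F1 0 when
  precision+recall = 0; chromaticity 0 at black pixels; S = 0 at I = 0;
  H = 0 for achromatic pixels; empty masks are an error for white-ratio.
- Rounding: reported percentages round half-up to 2 decimals; pyramid
  dimensions floor; back-mapped coordinates round half-up.

## Design choices on genuinely open points

- "Overlap" in NMS is IoU (intersection-over-min-area selectable);
  suppression and the FCR ratio test are strict inequalities.
- The confidence threshold applies before suppression.
- NMS confidence is a logistic calibration of the SVM margin; any monotone
  map with 0.5 at margin 0 would satisfy the same contract.
- "113×64" minimum pyramid size is read as width 113 × height 64, matching
  the 360:202 working aspect ratio.
- Block stride is 1 cell (overlapping blocks, the classical HOG layout).
- Gradients are computed on a single grayscale channel; a max-channel
  option exists but is not the default.
- Background training crops require under 20% fruit coverage — counting
  fruit of any ripeness, since a human would not crop a tomato as
  "background".

## Known limitations

- Fruit smaller than ~56 px apparent diameter at level 0 cannot be found:
  the pyramid only downscales. A real deployment would add upscaled levels
  or a smaller window.
- Heavily occluded or heavily overlapped fruit (blocked area well above
  50%) are missed, and two fruit whose boxes overlap by more than the NMS
  threshold can merge into one detection.
- The FCR plane is a single global separator in RGB; strongly atypical
  lighting would require refitting it (`fit_color_plane`).
- Scan-time HOG is computed per window on the enhanced level image; the
  one-pixel replicated border at window edges therefore differs slightly
  from a descriptor computed with full-image context. Training and scanning
  use the identical per-window path, so the two are consistent.
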