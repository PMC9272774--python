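# Methods

## Model and assumptions

`tasselrow` treats row guidance as a per-frame geometry problem: a frame
contains exactly two navigable crop rows, one per image half, approximately
straight in image coordinates and near-vertical (tilt well below 45°), and
the tassels along them are the brightest, most saturated structures after a
logarithmic contrast stretch. The pipeline makes no use of temporal
information; every frame is processed independently and deterministically.

Coordinates are 0-based with the origin at the top-left and y increasing
downward. Lines are parameterised as `x = a·y + b`, so `a = tan(angle from
vertical)`; regressing x on y keeps the fit well-conditioned for
near-vertical rows, where the usual y-on-x regression degenerates.

## Pipeline stages and parameters

### Contrast augmentation

The bottom `crop_fraction` (default 3/4) of the frame is kept — the upper
part of the scene is both useless for navigation and the most visually
congested — and resized to `target_size × target_size` (default 600 px,
aspect not preserved; the downstream thresholds are calibrated on this
square frame). Each RGB channel is mapped through
`Out = clip(round(C · log(1 + p)), 0, 255)` with `C = 48` and the natural
logarithm. The base is not fixed by the calibration that produced `C`; we
default to the natural log and expose the base, because `48·ln(1+p)` maps
the darkest ~200 grey levels onto the full output range while clipping only
the top of the range (`48·ln 256 ≈ 266`). Clipping, rather than rescaling,
preserves the meaning of the fixed HSV thresholds downstream.

### Segmentation

The stretched image is converted to HSV on the integer convention
H ∈ [0, 179] (half degrees), S, V ∈ [0, 255] — the convention in which the
calibrated tassel gamut H ∈ [80, 121], S ∈ [250, 255], V ∈ [240, 255] is
stated; a hue interval of [80, 121] only fits a 0–179 scale. Range
endpoints are inclusive. Pixels outside the gamut are zeroed; the masked
image is grayscaled with the classic luma weights (0.299, 0.587, 0.114) and
binarised with Otsu's method.

Otsu is implemented as a vectorised cumulative-moment scan over all 255
splits of the 256-bin histogram; ties break toward the smallest threshold
and foreground is strictly greater than the threshold. A constant image has
no two-class split: it returns the constant as threshold, an empty mask and
a degeneracy flag instead of raising.

Morphological cleaning is one binary dilation with a 3×3 square element
(inflating thin tassel skeletons) followed by a 9×9 median filter
(removing impulse noise); both preserve binarity. The median uses
zero padding, so a frame's outermost ~4 px can erode — irrelevant to row
fitting, which uses interior structure.

### Multi-ROI tracking

The frame is split at `center` (default 260 — the calibrated value for this
camera geometry; `target_size/2` is the symmetric alternative and both are
config-exposed). Per half, eight strips of height `Δh = 20` px are scanned
bottom-up. In the first strip whose maximum column count `M(j)` reaches
`Y = 15`, the qualifying column nearest `center` anchors a
`(L1 + L2) × H = 100 × 20` px box (`L1 = 45` left of the anchor, `L2 = 55`
right; the anchor sits on the box's lower edge). Boxes are clipped at image
borders and their column profiles shorten accordingly.

The anchor is refined to the minimiser of the balance function
`f(x) = |Σ_{v≤x} Z(v)(x−v) − Σ_{v>x} Z(v)(v−x)|`, evaluated for every
candidate column via prefix sums (algebraically identical to the exhaustive
scan; `f` is a piecewise-linear function on a discrete domain, so the
minimum is found by enumeration, not calculus). Ties break toward the
smallest column. The box anchored at the refined column spans
`[anchor − L1, anchor + L2)`.

Sliding: the box moves up `Δh` per level. A level with `T1 < T0 = 20` white
pixels is a sparse crop area and is shifted horizontally by `d = 20` px
toward `center` (rows converge upward) and re-tested, at most
`max_corrections = 3` times — a cap the original procedure leaves implicit;
it prevents livelock when a row is lost. If every probe is sparse the level
is recorded *empty* at the **unshifted** candidate anchor, so subsequent
levels continue along the row trend rather than drifting centreward.
A refined anchor that deviates from the linear extrapolation of the two
previous accepted anchors by more than `deviation_limit = 2d = 40` px is
flagged *deviated* and recorded at the trend anchor: this turns the
qualitative "stray tassel regions are not processed" judgement into an
explicit, testable rule. Deviated and empty levels contribute no feature
points. The chain terminates when the candidate's top edge would leave the
frame, covering the full working frame rather than only the eight search
strips.

### Feature points and lines

Accepted boxes are diced into complete `micro_cell × micro_cell = 10 × 10`
px cells (10 across × 2 down for an unclipped box); a cell with strictly
more than `H0 = 20` white pixels emits its geometric midpoint. A side needs
at least `min_points = 4` points for a confident fit (two-point fits are
exact and meaningless under noise; the threshold is config-exposed). Lines
are ordinary least squares of x on y via `numpy.polyfit`.

The navigation line bisects the **acute** angle at the intersection of the
two row lines: unit direction vectors are taken with positive y-component,
one is flipped if they subtend more than 90°, and their sum is the bisector
direction; an exact right angle ties toward the bisector closer to
vertical. The intersection abscissa is computed as the average of both
lines' evaluations, which makes the bisector exactly symmetric in its
arguments down to floating point. Lines whose slopes differ by less than
`parallel_tol` get the parallel midline instead. The declination θ between
two lines is the acute angle between their directions, in [0°, 90°].

## Synthetic scenes

The generator emulates the statistical structure the detector measures, at
working-frame scale (600×600, so evaluation configs disable the crop step):

* two row lines with bottom anchors in [140, 200] / [400, 460] px and tilts
  up to 15° from vertical, leaning toward the centre (a perspective-style
  convergence), rejection-sampled so the rows stay ≥ 120 px apart at the top
  edge — two non-crossing rows being the regime the tracker is defined for;
* 30 vertically elongated elliptical tassel blobs per row (half-axes 4–8 px
  across, 8–12 px along), jittered σ = 3 px about the line — sizes chosen so
  a blob fills micro-ROI cells past `H0` and a strip column reaches `Y`;
* tassel colours solved backwards from the segmentation gamut: the red
  channel is 0 (pinning post-transform saturation at 255 under any
  illumination scale), blue 232–250 (so V ≥ 240 survives a 0.7× illumination
  dip), green below blue (hue stays in the selected blue-cyan band). A
  forward self-check pushes the rendered blobs through the actual
  log-transform + HSV mask and rejects the scene if less than 95% of blob
  pixels survive;
* soil background with per-pixel texture plus dull-green leaf ellipses, both
  deliberately outside the gamut (any appreciable minimum channel kills the
  S ≥ 250 condition);
* a per-scene illumination scale drawn from [0.7, 1.3] (emulating the two
  light levels a field study spans), salt-and-pepper impulse noise at rate
  1% by default (salt pixels are painted in-gamut so they binarise white),
  and optional stray "deviated" blobs offset 60 px from a row.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real fields: plant morphology (forked tassels,
partial occlusion), wind motion, shadows and specular highlights, weeds,
curved rows, and any colour distribution other than the calibrated gamut.
Ground truth is exact by construction (the navigation line is the acute
bisector of the true row lines), so recovery tests measure the algorithm,
not annotation quality.

Determinism: a scene is a pure function of its parameter set including the
seed; batch evaluation gives scene *i* the seed `base + i`.

## Evaluation

`evaluate_batch` runs the detector on n seeded scenes and reports θ against
each scene's true navigation line: mean/max/min θ, the fraction of frames
with θ below the 5° accuracy criterion (failed detections count as misses),
and informational per-frame wall time. On mask scenes the tracker runs
directly on the rendered binary image, isolating it from segmentation.

A note on noise: the impulse-noise knob degrades detection only marginally
by design — the balance function cancels spatially symmetric noise moments
and the micro-ROI count threshold rejects sparse salt — so θ statistics are
statistically flat across noise rates of 0–5%. The suite therefore asserts
*robustness* (quality preserved under noise on paired seed lists) rather
than a monotone degradation ordering, which at these rates would be decided
by sampling error.

## Known limitations

* Exactly one row pair; fields with visible adjacent rows near the centre
  line will confuse the half-frame split.
* The fixed HSV gamut is camera- and crop-calibrated; other sensors or
  growth stages need re-calibration of `C` and the thresholds.
* No robust fitting: a run of misclassified feature points shifts the least
  squares line (deviated-region exclusion mitigates, not eliminates, this).
* Straight-line row model only; curved or terraced rows violate it.
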