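# Methods

This note documents the models and procedures implemented in `eyeseg`, the
parameters that matter, the numerical choices, what the synthetic generator
does and does not emulate, and the known limitations.

## Pipeline assumptions

The detector assumes a roughly frontal face of medium-to-good quality in
which both irises are at least partly visible, supplied with a face
bounding box. All geometric priors are anthropometric ratios of the face
box: eye width ≈ face_width/5, iris diameter ≈ 0.42 × eye width,
inter-pupillary distance ≈ 0.4 × face width. Coordinates are 0-based pixel
centers, x right, y down; rectangles are half-open `[x, x+w)`.

## Eye region and eyebrow row

The face box is narrowed to 70% of its width to drop hair/background, and
the eye search band defaults to rows `[0.20 h, 0.55 h]` of the face. These
band fractions are not derivable from the detector itself; they are
standard facial-proportion priors and are exposed in `PipelineConfig`.

The eyebrow row is the first top-down valley of the band's per-row
intensity sums. Raw row sums fluctuate with pixel noise, so the projection
is smoothed with a 5-row moving average (nearest-edge padded — zero padding
would fabricate valleys at the band edges) and a valley must have a
prominence of at least 10% of the projection's range to count; shallower
dips are noise, not a facial feature. On plateaus the topmost row wins; if
no qualifying valley exists the global minimum row is returned.

## Fast radial symmetry transform

Gradients are 3×3 Sobel derivatives (border pixels zeroed; the kernel is
applied as a correlation so `gx > 0` where intensity increases with x). A
pixel with non-zero gradient votes at its positively- and
negatively-affected pixels `p± = p ± round(r·g/‖g‖)`; rounding is
half-away-from-zero so votes are placed symmetrically for opposite gradient
signs, and out-of-image votes are discarded rather than clamped so border
cells are never over-weighted. Dark mode (used for the iris) accumulates
only the negative votes: `O_r(p−) −= 1`, `M_r(p−) −= ‖g‖`.

The per-radius response is

    F_r = sign(Õ_r) · |Õ_r|^α · |M̃_r|,

with Õ_r, M̃_r the accumulators divided by their maximum absolute value
over the map (an all-zero map yields a zero response). Carrying the
orientation sign and the magnitude *modulus* guarantees that dark centers
come out negative — which the downstream minimum-intensity scan requires —
and coincides with the signed product `|Õ|^α·M̃` wherever the two
accumulators agree in sign, which is everywhere in a single-polarity mode.
`F_r` is blurred with a unit-sum Gaussian of σ = 0.25 r truncated at 3σ,
and the full transform is the sum over radii. Defaults: α = 2 (the common
radial-strictness choice; small enough to keep responses from thin
eyelash-like edges, large enough to suppress straight edges),
`magnitude_floor = 0` (the weak-gradient floor belongs to the radius stage,
not the transform).

The vectorized implementation is checked for exact (≤1e-6) agreement with a
literal per-pixel loop implementation of the same definitions
(`tests/oracles.py`), and for the analytic properties: zero response on
constant images, invariance to intensity offsets, translation equivariance,
and dark-on-I ≈ −bright-on-(255−I) duality.

## Iris center selection

Minima of the transform are collected per tile of a `2 r_min` sliding grid
and merged when closer than `r_min` (the lower response survives); tiles
whose minimum is not below the image's mean response carry no symmetry
evidence and are dropped. Candidate confidence is
`(−S) · (255 − blur(gray))/255` — circularity gated by pupil darkness —
halved above the eyebrow row (the penalty magnitude is a config choice).
Pairs are chosen by maximizing `score_l · score_r · exp(−(d/w − 0.4)² /
(2·0.1²))` where `d/w` is the candidate IPD normalized by face width, with
the left/right half constraint enforced; an empty half raises a detection
failure for that eye. The winner is refined to the minimum of the blurred
image within a `(r_min/2)`-sized window (ties break toward the unrefined
center), constraining the center to the dark pupil.

## Iris radius

The eye ROI is blurred (Gaussian σ = 2 px — "blurred" left unquantified by
the design, so a small fixed σ is used throughout), differentiated with the
Sobel kernel sensitive to vertical edges, and the absolute response taken:
the iris→sclera transitions on both horizontal sides are vertical edges,
and taking |·| lets the left (dark→bright) and right (bright→dark) sides
sum constructively. Responses below the 20th percentile of the non-zero
magnitudes are zeroed. The projection samples each candidate radius at 1°
steps over θ ∈ [−45°, 45°] on both sides (nearest-pixel lookup;
out-of-image samples contribute zero) and the radius is the argmax, ties
toward the smaller radius. The angular window avoids the eyelid-occluded
top and bottom of the iris.

## Sclera color model

Features per pixel: HSV hue in [0,1) (achromatic pixels get hue 0 by
convention) and the chromatic opponent channels O1, O2. The intensity
channel O3 is excluded by default — the classifier should respond to
chromaticity, not illumination — but can be enabled. Hue is used raw; an
angle-encoded (sin, cos) variant would serve a linear separator better but
is left off to keep the feature space minimal. Features are standardized by
the training mean/variance.

The classifier is a linear SVM (scikit-learn `LinearSVC`, C = 1). Platt
calibration is fitted by Newton iteration with the standard
prior-corrected targets `(N₊+1)/(N₊+2)` and `1/(N₋+2)` and a backtracking
line search, on out-of-fold decision values from a 5-fold stratified split
so the sigmoid is not tuned on resubstitution scores. The calibrated model
is compiled into a 2^24-entry uint8 table (16 MiB + 32-byte header: magic,
version, feature flags; little-endian); quantization bounds the
lookup-vs-direct error by 1/(2·255), verified to 1/255 in tests. Table
compilation is chunked (2^20 colors at a time) to bound memory.

## Eyelid shape

The 12-value control-point vector stores everything except the center
relative to `(c_x, c_y)`, making the model translation-invariant. The top
parabola interpolates `(tl_x, tl_y), (t_x, t_y), (tr_x, tr_y)`; the bottom
parabola shares the outer x-coordinates, with y-offsets `bl_y, br_y`
interpreted as added to `tl_y, tr_y` (the natural reading of "offset"
relative to the top control points; configurable bands would allow the
alternative). Hypotheses are sampled uniformly per coordinate from bounds
proportional to the iris radius R (e.g. `t_y ∈ [−2.2R, −0.8R]`,
`tl_x ∈ [−3R, −1.2R]`); the bounds are eye-anthropometry choices, exposed
in config, and samples violating `tl_x < t_x < tr_x` are rejected and
redrawn.

Scoring uses vertical pixel bands at offsets 1..Δ from each parabola
(Δ = 5 px): offsets along y rather than along the curve normal — simpler
under the `y = f(x)` parametrization and indistinguishable for the shallow
curvature of eyelids. Inner and outer band means of both parabolas are
pooled and combined as `ω = (α·mean₊ − β·mean₋)/(α+β)` with α = β = 0.5;
"Σ over the band" is implemented as a mean so ω is bounded in [−1, 1] and
comparable across hypotheses of different extent. The scoring x-range is
`[c_x − 3R, c_x + 3R]` clipped to the map.

Voting takes the top 30% of N = 200 hypotheses by ω. ω can be negative, so
selected weights are shifted by the minimum selected ω and floored at
ε = 1e-6 before the per-coordinate weighted average; the result is a convex
combination of the selected control points. N = 200 / 30% are the operating
point beyond which more samples stop improving recovery. Corners are the
real intersections of the two parabolas (no two real roots → the caller
falls back to the scoring x-range endpoints); the eye mask is the region
between the parabolas and between the corner x-coordinates.

On a binary ground-truth map the voted shape recovers every control point
to within Δ = 5 px over seeded runs (typically ≤ 4.6 px for the outer
control points, ≤ 1 px for the mid-points); determinism is exact under a
fixed seed, and translation equivariance holds to ~0.1 px (band rows are
integer-rounded, so float noise in the parabola solve can flip a borderline
row).

## Evaluation metrics

Center errors are normalized by the true inter-center distance: `wec`,
`aec`, `bec` take the max, mean, min of the two per-eye distances. Radius
errors are normalized by the mean true radius: `aer = (|Δr_l|+|Δr_r|)/
(r_l+r_r)`, `wer`/`ber` the max/min versions; `aer = (wer+ber)/2` is an
algebraic identity and is tested as such. Mask comparisons report
sensitivity, specificity and accuracy from pixel confusion counts, with
zero denominators raised as errors rather than silently zeroed.
`accuracy_curve` produces the cumulative fraction-below-threshold curve
used for localization benchmarking.

## Synthetic data

The renderer emulates exactly the structure the detector exploits: uniform
skin, an off-white sclera region bounded by the two eyelid parabolas, a
dark iris disk clipped to the eye opening, a darker pupil, dark eyebrow
bands, i.i.d. Gaussian pixel noise (σ = 2 for clean images, 12 for noisy),
and an optional specular disk. Anti-aliasing is off so masks and
annotations are pixel-exact by construction, which makes the
parameter-recovery tests well-posed. Default colors (skin (205,170,140),
sclera (235,230,225), iris (60,80,40), pupil (15,15,15)) approximate the
contrast of real periocular patches. Default face geometry: 320×320 faces,
IPD ratio 0.4, eye row at 0.42 h, iris radius 0.042 × face width (≈13 px,
the scale at which real medium-resolution face images put the iris);
per-image jitter varies IPD and eye row by ±0.02 and the radius by ±10%.
The `occluded` difficulty drops the top-lid mid-point to −0.2 R, covering
the upper pupil as in semi-closed eyes, and measurably degrades center
recovery relative to `clean`.

What the generator does **not** emulate: iris texture, limbic gradients,
eyelashes, glasses and specular clutter, shading, pose, skin-tone
diversity, or sclera yellowing with age. Passing recovery tests therefore
demonstrates correctness of the algorithms under their stated assumptions
— not field performance on photographs, which depends on exactly those
nuisance factors.

## Problem sizes

The test suite and the acceptance script run the recovery studies at
50 rendered eyes (radius), 50 rendered faces (centers), 30 disk trials,
20 eyelid seeds, and 10 random images for the oracle comparison; the whole
acceptance run completes in well under a minute on one CPU.

## Known limitations

- Closed or heavily occluded eyes break the circularity assumption; the
  detector degrades (by design it has no appearance model beyond darkness
  and circularity).
- A parabola cannot represent ptotic or strongly non-parabolic eyelid
  contours.
- The linear color model cannot represent hue circularity; the optional
  (sin, cos) hue encoding mitigates this when enabled.
- The sliding-window minima scan uses non-overlapping tiles with post-merge;
  a minimum sitting exactly on a tile boundary can produce two candidates
  that the `r_min` merge then collapses.
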