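# Methods

## The measurement model

The pipeline treats a cervical epithelium micrograph as a population of
stained nuclei inside a delineated region of interest (ROI) running from the
basal lamina (image bottom, by convention) to the epithelial surface. Its
premise, following Richart's morphology, is that lesion grade is expressed
by how far the crowded, dark, basaloid compartment extends upward: in normal
epithelium nuclei are dense only near the basal lamina, in CIN 3 nearly the
whole thickness is crowded.

Six parameters are measured per image, in pixel units (a calibration scalar
converts to µm²; the default 0.22998 µm²/px derives from a 472×608 frame
imaging 0.066 mm²):

* **A** — ROI pixel count.
* **N** — mean area of segmented nuclei. Segmentation stretches ROI contrast
  (1st/99th percentile → 0/255), thresholds dark pixels (Otsu on ROI values
  by default), fills holes (4-connected background), removes components
  below `min_area` (default 30 px², about a sixth of the smallest reference
  group mean), and suppresses components touching the image frame so only
  whole nuclei are measured. Touching nuclei are *not* split — there is no
  robust automatic cluster splitting, so the validation imagery keeps nuclei
  separable instead.
* **V** — mean zone-of-influence area. Influence zones are the geodesic
  Voronoï partition of the ROI on the nuclei: each ROI pixel joins the
  nucleus at minimum within-ROI chamfer distance (8-neighbour moves weighted
  1 and √2). Equidistant (SKIZ) pixels take the lower nucleus label, which
  makes the partition exact, so V = A / count.
* **D** — differentiated area. The mean Delaunay edge *e* between the
  geodesic centers of the zones, divided by a quarter of the mean nuclear
  radius *r* = round(√(N/π)), gives the dilation/erosion coefficient
  *k* = round(4e/r). Closing the nuclei mask with a disc of radius *k*
  (exact Euclidean disc via distance transforms) merges the crowded
  compartment; the result is hole-filled and only components touching the
  basal band (bottom 5 ROI rows per column) are kept. D is their area. The
  raw closing area is also reported for comparison.
* **Hst, HstU** — chromaticism. The segmented nuclei are superimposed on the
  *original* (unstretched) grey image and inverted, so each nucleus pixel
  carries 255 − grey and everything else 0. Hst is the mean of this
  superimposition over all ROI pixels; HstU the same over the upper
  (non-differentiated) region. This area-integrated normalization — rather
  than a mean over nucleus pixels only — is what reproduces the reference
  magnitudes (normal Hst ≈ 19 although nuclei are far darker than 19 grey
  levels below white) and the collapse of HstU in CIN 3, where the upper
  compartment holds almost no nuclei. The per-nucleus-pixel mean remains
  available as `normalize="nuclei"`.

Three ratios condense these: N/V (nucleo-cytoplasmic), DR = D/A
(differentiation) and HstR = HstU/Hst. The cervical score is affine,

    S = w1·(N/V) + w2·DR + w3·(1 − HstR) + b,

with (w, b) the exact solve of the 4×4 system mapping the four reference
group-mean ratio triples to the published group scores 27/51/78/100.
(1 − HstR) enters because HstR falls with grade. The solved weights are
(62.10, 101.97, −67.81) with offset 48.20: the negative third weight means
that, *conditional on N/V and DR*, a lower upper-chromaticism deficit
slightly tempers the score; across the four reference triples the score is
nonetheless strictly increasing, which is the property asserted in tests. A
non-negativity-constrained fit was rejected because it misses the CIN 3
anchor by ~1.9 score units. The grade is the nearest reference score with
ties to the higher grade — the clinically conservative choice, since the
treatment cut-off itself is left open.

Welch's t-test (unconditional, Welch–Satterthwaite df) compares successive
groups in batch reports; unconditional Welch avoids a data-dependent
equal-variance branch and is strictly more conservative.

## The worked-example scene and closing semantics

The three-disc scene (199-px discs, separations 32 and 60 px) fixes the
closing semantics. Separations are **center-to-center** — the same quantity
the pipeline's mean Delaunay edge measures. This matters: a closing of
radius k merges two discs of radius r at center distance d only when the
dilation bridge survives the matching erosion, i.e. when
(d/2)² ≤ 2kr + r². For border-to-border gaps of 32 the dilated discs at
k = 16 would be merely tangent and the erosion would sever them; with
center distance 32 (gap 16), k = 16 merges the near pair and leaves the far
pair separate — two components, as the worked example requires. By the same
inequality the 60-px pair needs k ≥ 56 on the discrete grid to merge
(effective rasterized radius ≈ 7.5), not k = 30.

The closing is geodesic to the ROI: pixels outside the ROI count as
foreground during the erosion (tissue continues past the delineation), so
basal components stay attached to the ROI border. This variant is extensive
and idempotent within the ROI (asserted as property tests).

## Synthetic epithelium generator

The generator renders what the pipeline measures, with ground truth:

* **Geometry** — a rectangular ROI inset 10 px from the frame, basal lamina
  at the bottom. The dense band occupies the lower `differentiation_fraction`
  of the ROI height, with that fraction set to the reference D/A per group
  (0.142 / 0.355 / 0.578 / 0.858).
* **Counts** — total nuclei = ROI area / reference V (e.g. 153 for Normal,
  601 for CIN 3 at 608×472), split between a dense basal lattice and a
  sparse upper lattice whose pitch (65 / 55 / 55 / 112 px by grade) keeps
  upper nuclei outside merging range of the closing while their count
  reproduces the reference upper chromaticism.
* **Placement** — jittered lattices with an occupancy-grid guard (a 1-px
  moat) that guarantees non-overlap and 8-connectivity separation. Dart
  throwing was rejected: the dense band runs at nucleus/zone packing ≈ 0.5,
  where random sequential adsorption jams (≈ 0.547 for discs) before
  reaching the target count. The first upper lattice row stands off from the
  dense band by more than the closing merge reach estimated from the lattice
  pitches, so the measured D stays the basal block.
* **Shapes** — ellipses with areas from a truncated normal (SD = 0.15·N,
  clipped at ±2 SD), axis ratio 0.7–1.0 (0.85–1.0 in the dense band, where
  elongated outliers cannot fit the pitch), random orientation. On repeated
  collision the placer falls back to a centered circle, shrinking only as a
  last resort (rare; the measured N bias stays ≈ 3%, well inside the 10%
  recovery tolerance).
* **Grey levels** — background 235, additive Gaussian noise σ = 4 (clipped
  to [0, 255]) so thresholding is nontrivial. Nucleus darkness is derived in
  closed form from the reference statistics: upper darkness
  d_u = HstU·s_u²/N and basal darkness
  d_b = (Hst − d_u·N(1−f)/s_u²) / (N/V − N(1−f)/s_u²), which makes the
  area-integrated Hst/HstU measured on generated images land on the
  reference values. All four groups land in d ∈ [160, 236] (grey 19–95 on
  background 235), comfortably segmentable.
* **Determinism** — one `numpy` Generator seeded per image; identical
  (preset, seed, size) reproduce the raster bit for bit.

What the generator does **not** emulate: staining chemistry, koilocytotic
halos, nuclear clusters/overlaps, stromal tissue, folds, uneven
illumination, or irregular basal lamina. Passing recovery tests therefore
show that the measurement chain is correct on separable nuclei in a
rectangular ROI — not that segmentation is robust to clinical artefacts,
which the original workflow handled by manual ROI delineation and which
remains the user's contract here (the ROI mask input).

## Numerical choices and degenerate inputs

* Chamfer (1, √2) path lengths are compared with an absolute tolerance of
  1e-9; distinct chamfer sums below ~10⁵ steps differ by ≳ 1e-5, so ties are
  detected exactly. The geodesic center minimizes the maximum within-zone
  distance exactly, via iteratively tightened eccentricity lower bounds
  (Dijkstra from the current best candidate and from its farthest witness),
  with ties to the smallest (row, column).
* Mean Delaunay edge is averaged over unique edges by default; per-triangle
  multiplicity is exposed as `edge_mode="per_triangle"`. Collinear centers
  fall back to a flagged chain; two centers give the single edge.
* The coefficient uses the mean edge exactly as stated
  (`coefficient_mode="edge"`); a gap-based variant (edge minus 2r) is
  available since crowding can also be parameterized border-to-border.
* Zero nuclei: N is reported missing (never zero), no grade is assigned.
  Empty closing gives D = 0 and upper region = ROI. Constant-grey ROIs pass
  preprocessing unchanged with a warning.
* Pixel calibration: the computed 0.23 µm²/px is the default; the printed
  constant 0.22 of the reference acquisition is exposed alongside because
  its published units are internally inconsistent.

## Problem sizes

Validation cohorts are 10 images per group at the native 608×472 geometry
(the acceptance script uses the Normal and CIN 3 cohorts; the test suite
runs all four). Smoke tests use 304×236 frames, the smallest size holding
≥ 30 nuclei for every preset.

## Known limitations

* The score calibration is anchored to group *means*; per-image scores of
  heterogeneous real material will scatter around the reference anchors, and
  the grade cut-offs (nearest reference) are a pragmatic default, not a
  clinically validated decision rule.
* The chromaticism normalization is an interpretation (area-integrated
  mean); a per-pixel mode ships alongside but yields different absolute
  Hst/HstU scales.
* Square-grid morphology: results can shift by ~1 px at zone and closing
  boundaries relative to hexagonal-grid implementations.
* Overlapping nuclei are measured as single components, inflating N and
  deflating the count in dense clinical material.
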