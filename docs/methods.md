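# Methods

This note documents the models and procedures implemented in `hsirow`, the
choices made where the design was genuinely open, and what the synthetic test
scenes do and do not establish about real field imagery.

## Imaging model and coordinate conventions

A cube is `data[y, x, b]`: `y` the vertical scan-line axis (0 = top), `x` the
horizontal travel axis, `b` the band, with strictly increasing per-band
wavelengths in nm. Column intervals are half-open `[start, end)`. Cubes are
tagged `raw`, `dark_corrected` or `reflectance`; reflectance values are
dimensionless ratios against the white tile and are deliberately **not**
clipped at 1 (specular pixels legitimately exceed the tile). Non-finite
pixels in derived index images (0/0 in a normalised difference) are set to 0,
the "no contrast" value for every index used here.

Dark current is modelled per vertical detector pixel: the reference is a
`(rows × bands)` spectrum subtracted from every column, clamped at zero
(negative intensities are unphysical and destabilise normalised differences;
clamping is this package's choice). VNIR dark correction is off by default —
for the target scanner pair the VNIR dark signal is negligible — but the
operation accepts any cube. The field protocol's manual click-cropping of row
ends is replaced by explicit column indices in the config, for
reproducibility.

## Index images

* "Mean intensity between wavelengths a and b" means the mean over all bands
  whose centre lies in `[a, b]` inclusive; centred windows take the `n`
  nearest band centres (band grids rarely contain the exact nominal
  wavelength).
* NDVI uses red = 650–680 nm, NIR = 710–740 nm. The plant-SWIR contrast is
  the normalised difference of 3-band means centred at 1375 vs 1411 nm (the
  leaf water band); the whiteref-SWIR contrast uses 1620 vs 1537 nm.
* All index images are computed in float regardless of input dtype.

## Seam finding

`min_cost_path` implements the first-order DP recurrence over columns with
moves Δy ∈ {−1, 0, +1}, diagonal moves penalised by `lambda_ver`, off-image
rows at infinite cost, initial column cost `C(0, y)`, and backtracking from
the minimum of the final column. Tie-breaks are fixed: straight beats
up-from-below beats down-from-above, and the final column takes the smallest
row — deterministic output that also favours paths with limited vertical
movement. Correctness is checked against an independent Dijkstra search over
the explicit move DAG.

**Gradient convention.** `vertical_gradient` is the signed central-difference
gradient along y, *downward-positive*, rescaled so the image's maximum
absolute gradient is 1 (making the `1 − g_y` cost scale-invariant to image
brightness). Under this convention the grass-boundary cost
`exp(−I(x))·(1 − g_y)` is cheapest along dark-above/bright-below NDVI edges —
the bottom of the background sheet, with grass beneath. The white tile's
*lower* edge is the opposite polarity (bright above, dark below), so
`detect_whiteref_vnir` runs the edge cost on the negated 455–480 nm mean
image for that seam; the upper edge then uses the non-negated image plus the
distance penalty. One signed convention with one explicit negation keeps both
seams and the algebraic relation `cost_grass_boundary ≡ cost_edge` at zero
column means intact.

**Shape function.** The expected-width prior for the tile's upper edge is a
symmetric per-column V, `d(x, y) = |(bottom_y(x) − w_expected) − y|` — zero
exactly at the expected row, growing linearly. Defaults `lambda_ver = 0.05`
and `lambda_dist = 0.01` are chosen so that a full-strength gradient edge
(cost drop of 1) always dominates a one-pixel vertical move or a one-row
distance-prior violation; both are config-overridable.

## Plant masks

VNIR: `ndvi > 0.3` (a conventional green-vegetation cut-off; recovery on
simulated scenes is insensitive across roughly 0.2–0.5), eroded with a 3×3
cross whose out-of-image neighbours count as false (border pixels need full
support — conservative on mixed edge pixels), then everything below the grass
seam is removed. SWIR: the 1375/1411 contrast thresholded at the Otsu optimum
(256-bin histogram, delegated to scikit-image behind this package's surface,
with a degenerate-input guard), then the bottom 15 % of rows blanked — the
grass strip, which the noisier SWIR data does not support seam-finding on.
Thresholds use strict `>` for determinism.

## White reference

VNIR: lower seam, expected-width-guided upper seam, mask strictly between
them, then per-column occlusion filtering on the 455–480 nm values of each
column's mask pixels: columns with variance above 2× the mean column variance
are invalidated (partial occlusion), then columns with mean intensity below
80 % of the median surviving mean (full occlusion). The 80 %-of-median rule
is this package's operationalisation of "remove the darkest columns": the
median reference makes it robust to global illumination drift. Variance is
computed over the mask rows of the band-mean image; computing it over
wavelengths instead would be the main alternative reading.

SWIR: the tile is the lowest mode of the 1620/1537 index. The 256-bin
histogram is smoothed with a 5-bin moving average and searched outward from
the 10 %-quantile bin, nearest bins first, for a valley bin — defined as ≤
both neighbours and strictly below at least one. (Requiring strictly-below on
both sides fails whenever the valley is an exact-zero plateau, as happens on
clean scenes; the relaxed rule selects the first plateau bin.) Pixels below
the valley value are kept and eroded with the 3×3 cross; column validity
follows mask occupancy. A histogram with no interior valley (monotone) raises
a detection failure.

## Splitting

Peaks of the smoothed per-column plant-pixel profile (moving average of width
0.1× the expected pitch; scipy's `find_peaks` with `distance = 0.8×` pitch,
which is exactly the greedy keep-taller-first rule). Boundaries at midpoints;
peak gaps above 1.5× pitch subdivided into `round(gap/pitch)` equal parts to
cover undetected plants; then while the region count exceeds the known
plants-per-row, the region with the fewest plant pixels merges into its
lower-count neighbour, and while it falls short, the widest region is split
at its interior profile minimum (ties → the median minimising column, which
halves flat regions sensibly). Every internal boundary is finally moved to
the profile minimum within ±0.25× pitch (ties resolved toward the provisional
boundary), clamped so regions never collapse. The 1.5× threshold, the
merge/split selection rules and the ±0.25× window are this package's choices,
symmetric around one plant pitch. Analysis spans shave `round(0.1×width)`
columns per side.

## Reflectance and traits

Sections are consecutive column blocks (default 100 columns); each section's
reference spectrum is the mean over its valid tile columns, and sections with
no valid columns borrow the nearest valid section (tie → left), so a post
occluding a whole section does not break normalisation. A zero reference
value in any band is an error naming the band. Height is the vertical extent
of the mask within the analysis span; metres come from the swath calibration
(1.2 m over 402 VNIR / 378 SWIR rows by default). Density is plant pixels per
column of the analysis span. Missing plants yield empty spectra (flagged in
the run manifest) rather than errors.

## The scene simulator

`generate_scene` renders both scanner cubes from one geometry: cardboard
background, a white tile strip (rows 8–22 % of height), vertical posts
(painted over tile and background), a bottom grass strip (15 % of height,
with a smooth sinusoidal boundary wobble), and plants built as a vertical
cane plus three canopy ellipses per plant, pitched evenly with jittered
centres, entirely between tile and grass. The cube is
`endmember_reflectance × illumination(x) + dark(y, b) + N(0, σ)`, clipped at
zero. Illumination drift is a smooth low-order polynomial over x shared by
all materials — precisely what sectioned normalisation must cancel; dark
current is a smooth random per-row × per-band field (SWIR amplitude 0.02,
VNIR 0 by default); σ defaults to 0.005 against a unit illumination scale.

Endmembers are hand-built piecewise-linear curves: leaf (red ≈ 0.05, NIR ≈
0.55 → NDVI ≈ 0.8; 1375 ≈ 0.38 vs 1411 ≈ 0.16; rising 1537 → 1620 recovery
after the 1450 nm water band), grass = 0.85× leaf, flat cardboard (0.25),
flat tile (0.95, above every other material at every band), and a dull post.
They reproduce the qualitative index structure the pipeline relies on —
including the three-mode whiteref-SWIR histogram with the tile lowest — but
are **not** measured spectra: no BRDF or specular effects, no mixed boundary
pixels, no atmospheric-absorption noise bands, no wind blur, and crisp
single-material pixels. Passing recovery tests therefore demonstrates
algorithmic correctness under the stated scene model, not field-grade
robustness.

## Problem sizes

Defaults follow the scanners (178 bands / 402 rows VNIR, 278 bands / 378 rows
SWIR; 48 plants per trial row; 12 plants per example frame). The horizontal
pitch in pixels is not a scanner constant; the default is 100 px/plant. The
test suite and the acceptance script run the same conditions on reduced grids
chosen so discretisation effects stay small relative to the recovery
tolerances: 180-row/40-band VNIR and 200-row/100-band SWIR frames at 12
plants (100 px pitch), and 48-plant rows at 60 px pitch, 20 seeds per
recovery check. At the full scanner geometry a single-seed check gives the
same or better recovery (e.g. tile IoU ≈ 0.96 SWIR / 0.98 VNIR).

## Known limitations

* The two scanners are processed independently; no VNIR/SWIR registration.
* Splitting assumes one known plant count per row and roughly even pitch;
  intertwined canopies beyond the 10 % margin crop are not resolved.
* The SWIR grass removal is a fixed bottom crop, not a seam.
* Reflectance is relative to the tile (tile reflectance treated as 1).
* Shadows of plants are not removed from the background classes.
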