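# Methods notes

This document records the models, conventions and numerical choices behind
`organelletrack`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic fixtures do and do not
demonstrate.

## Input standardisation

Stacks are normalised to frames × channels × height × width regardless of
the on-disk axis order.  Frames-first (TCYX), channel-first (CTYX) and
interleaved (TYXC) TIFF layouts are accepted; when axis metadata is absent
the smallest non-spatial axis of size ≤ 4 is assumed to be channels and the
assumption is logged.  Only 2-D time series are supported — no z-stacks,
no more than two analysis channels per run.

8-bit conversion uses a **per-channel min–max over the entire stack**, not
per frame.  Per-frame rescaling would silently renormalise each time point
and destroy temporal intensity trends; stack-wide scaling keeps frame-to-
frame comparisons meaningful at the cost of letting a single hot frame
compress the rest of the dynamic range.  A constant channel maps to all
zeros with a warning rather than an error so batch runs survive empty
channels.

Optional integer spatial upscaling (typically 2×) uses nearest-neighbour
interpolation by default, preserving crisp label boundaries for
segmentation; bilinear is selectable.  When a pixel size is given it is
divided by the upscale factor for all downstream unit conversions.

## Segmentation

"Adaptive" thresholding is implemented as **per-frame global Otsu**: the
threshold is re-estimated for every frame, then multiplied by
`thr_factor` (default 1.0; > 1 is more stringent).  A locally-adaptive
windowed method was considered and rejected: the fixtures and typical
confocal organelle data have globally bimodal histograms, and a windowed
method would add two parameters (window, offset) without a ground-truth
benefit.  The threshold comparison is inclusive (`≥`).  Because the
underlying Otsu routine returns a value under an exclusive convention
(foreground strictly greater), the implementation converts it to the
equivalent inclusive integer threshold (`⌊t⌋ + 1`) before scaling; on
continuous intensity data the resulting masks are identical, and on crisp
two-level images the inclusive rule then behaves correctly instead of
flooding the frame.

Cleanup order is fixed: opening (disc radius `opening_radius`, default 1)
**before** small-object removal (`min_size`, default 10 px), so that
opening cannot re-fragment components that were already size-filtered;
then optional border clearing (default on).  A zero-variance frame yields
an empty mask and a warning, not an abort.  Components are 8-connected
everywhere, fixed rather than configurable, so CSV outputs remain
comparable across runs.

## Shape descriptors

Ellipse-derived quantities (eccentricity, axis lengths, orientation) come
from central second moments under a **unit-square pixel model**: 1/12 is
added to each marginal second moment, treating every pixel as a 1×1 square
rather than a point.  Point moments systematically underestimate the minor
axis of thin rasterised objects (a 50×10-px ellipse reads as aspect ratio
≈ 5.27 instead of 5.0); the correction brings it to ≈ 4.93.  Orientation
is reported versus the image x-axis, counter-clockwise in y-up convention,
in (−π/2, π/2].

Solidity is the area of the sub-pixel boundary contour (marching squares
at level 0.5) divided by the area of that contour's convex hull.  The
conventional rasterised-hull ratio is biased low for curved shapes (a
radius-20 disc reads 0.963 although a true disc is its own hull); the
contour-polygon form reads 0.975 for the same disc, is exactly 1 for
convex polygons such as rectangles, and can never exceed 1 since the hull
contains the contour.  Perimeter uses the weighted boundary-step estimator
(`skimage.measure.perimeter`), which overestimates smooth contours
slightly — circularity of a radius-20 disc is ≈ 0.91, not 1.0 — but is
reproducible and monotone; circularity values above 1 for small discs are
reported as computed, never clipped.

Degenerate single-pixel components report aspect ratio as an empty CSV
field (NaN) and eccentricity 0.

## Elongated/punctate classification

`elongated ⇔ eccentricity ≥ ecc_thresh AND area ≥ area_thresh`, ties
inclusive; punctate is simply the complement.  AND (rather than OR) keeps
small, high-eccentricity noise fragments out of the elongated class.
Defaults `area_thresh = 50 px`, `ecc_thresh = 0.80` suit the synthetic
fixtures and mid-magnification confocal data; both must be tuned to the
imaging scale in real use.

## Tracking and motility

Linking is greedy and distance-sorted: all (previous, next) centroid pairs
within `max_dist` (default 10 px — an arbitrary default that should be set
from the expected frame-to-frame displacement) are sorted by distance,
ties broken by lower label index, and accepted while both endpoints are
unused.  This is the classical greedy nearest-neighbour scheme, not an
optimal bipartite assignment; it is deterministic and matches an
exhaustive minimum-distance oracle on small instances.  There is no gap
closing: a missed detection terminates its track, and merge/split events
are not modelled.

"Total displacement" is the cumulative path length; because centroid
jitter adds a positive bias to path length, the net start→end displacement
is reported alongside.  Mean velocity is path length over elapsed time,
`(n−1) × frame_interval_s` (default 5 s per frame).  Per-frame mean step
speeds (for the integrated table) assign each step to its later frame;
frame 0 carries NaN rather than a missing row so joins preserve coverage.

## Colocalization

All four metrics are computed from the binary masks over **all** image
pixels (no ROI restriction):

* M1 = |A∩B|/|A|, M2 = |A∩B|/|B|; empty denominators report 0 with a
  logged flag so blank frames do not abort a stack run.
* Pearson r of the 0/1 masks — the phi coefficient of the 2×2 pixel
  contingency table, computed from integer counts for exactness; NaN when
  either mask is constant.
* Percent overlap = Jaccard × 100.  This is a package convention chosen
  for symmetry; |A∩B|/|A| and |A∩B|/min(|A|,|B|) variants exist in the
  literature and give larger numbers, so cross-tool comparisons must check
  the definition.

Pixel counts (n_mito_px, n_lyso_px, n_overlap_px) are emitted per frame so
any alternative normalisation can be recomputed from the CSV.

## Integrated summary

Per-object values are aggregated to per-frame means by default (medians
optional).  The integrated table's column set is fixed and documented
(`lyso_count`, `n_mito`, `frac_elongated`, per-organelle mean shape
descriptors, per-organelle mean step speed, the four colocalization
metrics).  Correlations are pairwise-complete; entries involving constant
columns are NaN and surfaced as undefined, never imputed as 0.  Heatmaps
use fixed colour scales ([−1, 1]; [−2, 2] for difference maps) so figures
from different runs are visually comparable.

## Two-sample comparison

Selection rule: Shapiro–Wilk on each group at α = 0.05 (configurable); if
either rejects → Mann–Whitney U (two-sided; exact for small samples
without ties, normal approximation with continuity correction otherwise).
Otherwise median-centered Levene (robust to residual non-normality); if it
rejects → Welch's t, else Student's t.  Effect sizes are paired to the
test: Cohen's d with pooled SD, Hedges' g = d·(1 − 3/(4(n₁+n₂) − 9)), or
rank-biserial r = 1 − 2U(x)/(n₁n₂).  Note the sign convention: r = +1 when
every value of the *first* group is smaller.  Zero pooled SD yields 0 for
equal means and ±∞ otherwise.

Because the Student branch sits behind three α-level gates, its long-run
selection rate for two equal-variance normal samples is 0.95² × 0.95 ≈
85.7%, with a t-family test chosen ≈ 90.25% of the time — the tests check
against these expectations, not against 100%.  The full select-then-test
pipeline remains calibrated: its null rejection rate at α = 0.05 is within
±0.015 of nominal over 2,000 replicates.

The default sampling unit is the object/track pooled across frames, which
pseudo-replicates when objects persist; a frame-level aggregation mode
(`unit="frame"`) is provided to mitigate this.  No multiple-testing
correction is applied by default (per-metric reporting); a Holm step-down
flag is available.

## Synthetic fixtures

The generator renders filled ellipses without anti-aliasing (a pixel is
foreground iff its centre satisfies the ellipse inequality), so
ground-truth pixel sets match the noise-free image exactly; Gaussian read
noise is added afterwards and the result clipped to 8 bits.  Motion is
linear or a seeded Gaussian random walk; objects may appear or vanish at
scheduled frames.  Overlap schedules build the lysosome channel as the
first k raster pixels of the mitochondrial mask with k = round(f·|A|); the
`coloc-schedule` preset uses four radius-8 discs (788 px total, divisible
by 4) so the fractions {1, 0.75, 0.5, 0.25, 0} are exactly representable.
Ellipses meant to have an exact pixel footprint (e.g. the 50×10 oracle
ellipse) are centred on half-integer coordinates.

Preset problem sizes (128–160 px frames, 5–20 frames, 5–12 objects) were
chosen as the smallest configurations that still exercise every code path
with comfortable object separation; the physical defaults mirror a typical
confocal time-lapse (5 s frame interval).  What the fixtures deliberately
omit: a realistic PSF, photobleaching, intensity gradients, out-of-focus
light, organelle shape change, and touching/overlapping organelles within
one channel.  Passing tests therefore demonstrate correctness of the
measurement pipeline on well-separated, well-contrasted objects — not
segmentation robustness on dim, dense or fusing structures, which always
requires parameter tuning and visual QC on real data (that is what the
overlay PNGs and detection videos are for).

## Outputs and determinism

Every run writes a fixed filename set (CSV + PNG, per-stage), a key=value
copy of its configuration, and a manifest mapping each file to its stage.
CSVs are UTF-8, comma-separated, '.' decimal, with a header and no index
column; reruns with identical input and configuration are byte-identical.
MP4 emission requires an ffmpeg backend; when unavailable the renderer
falls back to a numbered PNG sequence and records the substitution in the
manifest notes.  Videos are off by default (`--video` enables them).

## Known limitations

* Greedy linking can mis-assign during close encounters that an optimal
  assignment (or motion-model tracker) would resolve.
* Otsu assumes a bimodal histogram; very sparse or very dense foreground
  shifts the threshold, which `thr_factor` can only partially correct.
* Binary-mask colocalization inherits segmentation errors; no
  intensity-weighted (Costes-style) variant is provided.
* Object-level pooling across frames inflates the effective sample size in
  comparisons; prefer `unit="frame"` or per-track metrics when objects are
  long-lived.
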