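# Methods

This note documents the models, estimators, and numerical conventions
behind `glycoquant`, the design choices taken where several reasonable
options existed, and what the synthetic validation does and does not show
about real microscopy data.

## The measurement model

A labeling experiment produces co-registered 2-D channels per field:
DAPI (nuclei), a plasma-membrane marker (ZO1 or Na/K-pump antibody), the
clicked probe, and optionally a subcompartment antibody (DFC, nuclear
speckles, or H3K9me3). The analysis treats each field independently
(time courses are separate coverslips, not tracked cells) and each cell
as the unit of observation for compartment intensities; each nucleus is
the unit for subnuclear enrichment.

Probe intensity in a compartment is modeled as signal plus a spatially
uniform nonspecific background *b* common to all pixels. *b* is
estimated as the pooled mean probe intensity over all cell pixels of
untreated control fields and subtracted before any ratio or summary.
Corrected values may be negative; clipping would bias group means toward
positive values, so none is applied. Background correction must precede
enrichment ratios: for compartment signal *f·s* and nucleoplasm signal
*s*, the uncorrected ratio (*f·s + b*)/(*s + b*) is shrunk toward 1.

## Segmentation

Nuclei: Gaussian smoothing (σ = 2 px) → global Otsu → fill holes →
remove objects < 50 px² → Euclidean distance transform → seeds at local
maxima ≥ 10 px apart → watershed. Cells: seeded watershed on the
smoothed membrane channel (marker intensity as ridge landscape), with
the foreground taken as the hole-filled thresholded membrane united with
the nuclei; one basin per nucleus guarantees a cell↔nucleus label
bijection. Compartments: the plasma-membrane band is geometric — pixels
within *w* = 3 px of the cell boundary — rather than marker-thresholded,
because antibody staining quality varies between lines and experiments;
nucleus pixels always win ties over the band so nuclear measurements are
never contaminated; cytoplasm is the rest. The three masks tile each
cell exactly, which the tests assert pixelwise. Border-touching cells
are dropped by default (partial cells bias per-cell means). All
thresholds are relative, so segmentation is exactly invariant to a
global positive gain; watershed ridge ties are resolved by the
deterministic queue order of the flooding implementation.

## Subnuclear enrichment

The marker is thresholded per nucleus (Otsu restricted to that nucleus's
pixels), components < 4 px² removed. Enrichment is computed per nucleus
as the ratio of background-corrected mean probe intensity in the
compartment to that over the remaining nucleoplasm, then averaged across
nuclei with SE = SD/√n; nuclei are also the independence unit for the
Mann–Whitney comparison. Averaging per-nucleus ratios (rather than
pooling pixels) matches reporting enrichment "per analyzed nucleus" and
keeps the estimator robust to nucleus-to-nucleus brightness variation.

One refinement matters quantitatively: segmented nuclear boundaries are
uncertain by roughly a pixel, and boundary pixels straddling the nuclear
envelope carry partial cytoplasmic signal. Including them in the
nucleoplasm reference depresses the denominator and inflates folds by
+0.01–0.03 (measured on synthetic scenes at default noise). The
remainder is therefore taken inside the nucleus eroded by
`erode_nucleus_px` = 2, while the compartment is still detected over the
full nucleus so peripheral compartments (the heterochromatin rim) are
not clipped. With erosion disabled, compartment + remainder tile the
nucleus exactly; with the default, they tile the eroded support, and the
residual estimator bias is below 0.002 fold.

Nuclei with a degenerate threshold (uniform marker), an undersized
compartment, or an empty remainder are excluded and counted, never
silently scored.

## Statistics

- Group summaries: mean, sample SD (n−1), SE; single-observation groups
  flagged with SD 0.
- Uptake comparisons: classic pooled-variance two-sample Student's
  t-test, one-sided; zero pooled variance returns p ∈ {0, 0.5, 1} by the
  sign of the difference, flagged degenerate.
- Enrichment comparisons: two-sided Mann–Whitney U. The exact null
  distribution is used when n₁·n₂ ≤ 400 and no ties are present;
  otherwise a normal approximation with tie-corrected variance and a 0.5
  continuity correction. The exact branch is verified in the tests
  against an independent full enumeration of all C(n₁+n₂, n₁)
  assignments for every n₁, n₂ ≤ 6, and the approximate branch against
  its simulated type-I error (within [0.035, 0.065] at α = 0.05,
  n₁ = n₂ = 30).
- Time courses: exact piecewise-linear interpolation through group
  means; duplicate times are averaged first; queries outside the
  observed range raise rather than extrapolate.

## Gel densitometry

Lanes are located from the column-sum profile: plateau peaks with a
prominence floor of 10% of the profile range, then equal-width spans
centered on the plateaus — unequal spans would dilute lanes unequally
and bias lane-to-lane ratios. When fewer peaks than expected are found
(e.g. empty control lanes), the raster is partitioned into equal-width
lanes and the result flagged. Each lane profile (column mean vs
migration) is integrated above a baseline estimated as the median of its
top and bottom 5% migration windows, summing only the positive part.
The incorporation efficiency is the mean over replicate pairs of
S(−UV)/S(+UV) — per-pair ratios are less biased than a ratio of averages
under multiplicative gel-to-gel gain variation — reported as a percent,
flagged but not capped above 100. Ladder, no-click, untreated and
vehicle lanes are quantified for QC but never enter the ratio. No
cross-lane total-protein normalization is applied by default.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the study conditions the package is validated
under:

- Geometry: 9 non-overlapping, mildly eccentric axis-aligned elliptical
  cells (radii 20–30 px) per 512×512 field, nuclei (9–13 px) fully
  inside cells, 2–6 disk foci (2–4 px) per nucleus for DFC/NS, a 2-px
  nuclear-rim band for heterochromatin; placement by seeded rejection
  sampling with an explicit budget and error.
- Intensities: probe = background (2 AU) + signal, with compartment base
  levels nucleoplasm 100 > cytoplasm 60 > membrane band 40 AU,
  subcompartment pixels carrying exactly fold × the nucleoplasm signal
  (folds default to DFC 1.39, NS 1.22, heterochromatin 1.0, the
  no-enrichment control). Untreated scenes carry background only; −UV
  scenes retain a configurable fraction (default 0.5) of the +UV signal.
- Kinetics: signal scales linearly with labeling time, I(t) = rate·t,
  with the default rate reaching the base levels at 360 min, the longest
  time point in the emulated design.
- Noise: Poisson shot noise (4 photons/AU) then Gaussian read noise
  (SD 2 AU), clipped at zero — SNR ≈ 20 at nucleoplasm level, a standard
  fluorescence-camera model; disable via `FieldSpec.without_noise()`.
- Gels: lanes share a band layout (truncated-Gaussian bands, supports
  kept clear of the baseline windows) scaled to each lane's configured
  integrated signal, so noise-free integration recovers the truth to
  floating-point precision and lane ratios are band-shape independent.

Everything is deterministic per seed (NumPy `SeedSequence` substreams per
stage, condition, time point, and channel); identical spec + seed yields
bit-identical rasters, and identical config + seed yields byte-identical
pipeline tables (no timestamps are written).

What the generator deliberately omits: realistic point-spread functions,
3-D structure, photobleaching, chromatic shift, irregular cell shapes,
spatially varying background, and cell-to-cell expression variability.
Passing recovery tests therefore demonstrates that the estimators are
correct and well calibrated under the assumed noise and geometry model —
not that segmentation would reach the same IoU on real micrographs.

## Validation problem sizes

Recovery experiments run at 50 nuclei (or cells) per condition, five
time points, four gel replicates, 500 Mann–Whitney null replicates (on
disjoint random splits of a once-generated pool of fold-1.0 estimates,
which keeps the null exchangeable while bounding image generation), and
2000 t-test/U-test null replicates. These sizes put Monte-Carlo error
well inside the asserted tolerances (fold bias ≤ 0.05, gel percent ± 3
points, uptake rate ± 10%, rejection rates within ± 1.5 points of α).

## Known limitations

- The geometric membrane band inherits cell-boundary error: where the
  watershed boundary overshoots the true edge, the band straddles
  background pixels and its mean is diluted (visible in the worked
  example: band mean ≈ 20 AU against a rendered 42 AU). Compartment
  ordering and all ratio/recovery statistics are unaffected.
- The per-nucleus Otsu threshold assumes a bimodal marker within each
  nucleus; weak or absent staining excludes the nucleus rather than
  degrading the fold estimate.
- Background is a single scalar per channel; spatially structured
  background (vignetting, debris) is out of scope.
- Lane detection assumes vertical, non-tilted lanes of similar width.
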