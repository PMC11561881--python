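# Methods

This note documents the models, conventions and numerical choices behind
`mrmsi`, in the order the workflow runs.

## Data model and text dialect

An MRM imaging acquisition is a cube `responses[pixel, transition]` of
non-negative MS counts over a row-major raster (0-based `(row, col)`,
origin top-left; default 50 μm square pixels at a 4 Hz scan rate). At most
32 transitions can be monitored in one acquisition (triple-quadrupole duty
cycle limit). `NaN` is the *not acquired* sentinel — a channel absent from
one member of a combined study — and is deliberately distinct from a
measured 0, because conflating them would bias noise estimates.

Vendor exports are not standardized for MRM imaging, so the package defines
its own tab-separated interchange dialect: a `#`-header block (grid
dimensions, pixel size, scan rate, sample id, acquisition date, transition
metadata as one JSON line) followed by one row per pixel with `x`, `y`, one
`Q1>Q3@CE` column per transition and a trailing `roi_label` column. Floats
are written as shortest round-tripping decimals and read back with
round-trip parsing, so read∘write is the identity bit-for-bit. Pixels
missing from a file are filled with 0 and reported in a read log; duplicate
coordinates and negative responses are format errors.

**Common transition axis.** Channels from different acquisitions are merged
when both Q1 and Q3 agree within a tolerance (default 0.1 Th — unit
resolution quadrupoles). The class representative is the channel from the
earliest-acquired image; processing in acquisition-date order makes the
axis independent of argument order. A channel matching two axis entries, or
two channels within one image matching each other, is an ambiguity error
rather than a silent merge.

## ROIs, noise and gating

ROIs are rectangles (half-open bounds), polygons (pixel-center containment,
vertices in pixel units) or explicit pixel lists; `"background"` is the
reserved label for off-tissue pixels. Overlapping specs are an error —
last-writer-wins relabeling silently corrupts downstream statistics.

Noise for a transition is the **mean response of the background pixels of
the same acquisition** (merging studies never pools background across
runs), and `S/N = response / noise`. If the background mean is exactly 0
the smallest positive background response substitutes, preserving ordering
without inventing a scale; if the background is identically 0 the channel
is flagged "no noise estimate" and its S/N set to +inf where signal exists.
Detection uses S/N > 3, quantification S/N > 5, both strict. A channel is
*blank* when fewer than 1% (configurable) of tissue pixels pass detection;
a channel at exactly the threshold count is retained.

Solvent-standard normalization (e.g. dividing by a spiked CUDA channel per
pixel) is implemented but **off by default**: over tissue voids such as
airway lumens the standard response collapses and ratios become artifacts.
The divisor is floored at `epsilon` and the affected pixels are returned as
a flag mask; the synthetic airway scene includes an empty lumen region
precisely so this failure mode stays under test.

## Quantification

Spotting 1 μL of a *c* ng/mL solution deposits *c* pg (1 ng/mL = 1 pg/μL).
A calibration spot's working concentration is `deposited_pg / n_pixels`
(pg/pixel), so replicate spots of the same amount land at different levels
when their footprints differ — which the synthetic slides reproduce by
jittering spot radii. Spot means are computed over the full ROI without S/N
gating (gating would bias low-level means upward).

The calibration model is **unweighted OLS** of mean spot response on
pg/pixel, pooled over replicates, with a free intercept; per-replicate r²
values are reported alongside (their mean is the "average linear
response"). At least 3 distinct levels are required. Per-pixel estimates
are `(response − intercept)/slope` for pixels passing the quantification
gate; negative back-calculations are floored at 0 and flagged rather than
dropped, preserving pixel accounting. A non-positive slope is a
non-identifiable calibration and an error.

Dwell time per transition is modeled as
`floor(1000/scan_rate/n_transitions − interscan_delay)` ms with a default
3 ms interscan delay (at 4 Hz and 6 transitions this gives the instrument's
reported 38 ms). The delay is an assumption — instruments report the actual
value — so the function is a planning aid, not a validated instrument model.

## Rendering

Ion images run the pipeline *quantile threshold → quantile suppression →
min-max scale → colormap* (default viridis). Quantiles are pinned to the
**lower order statistic** (`numpy.quantile(..., method="lower")`): under
that definition suppression is exactly idempotent, which any interpolated
definition breaks because clipping shifts the interpolated quantile.
Quantiles are computed over tissue (non-background) pixels by default since
thresholding exists to remove background; null pixels (not acquired / not
quantified) are excluded from quantile computation and rendered in a
distinct grey. The pipeline has no hidden randomness — re-rendering is
bit-identical — and is monotone in the pixel values.

## Pixel statistics

Region contrasts sample a fixed number of pixels (default 50) uniformly
without replacement per ROI, seeded; both ROIs use the same seed so
comparing an ROI with itself is exactly degenerate (p = 1). The
Mann–Whitney U is computed from rank sums with midranks for ties. The exact
two-sided p (`2·min(P(U≤u), P(U≥u))`, capped at 1) is used when the
combined sample size is ≤ 16 and the data are tie-free, via the standard
count recurrence `N(u; n1, n2) = N(u−n2; n1−1, n2) + N(u; n1, n2−1)`;
otherwise the normal approximation with tie correction and a 0.5 continuity
correction applies. Enumeration over the full 8 vs 8 null shows the
approximation tracks the exact p to ≲ 0.011 at the worst central U values.
BH-FDR is the step-up `q_i = min_{j≥rank(i)} p_(j)·m/j`, capped at 1.

## LC-MS/MS screen

The blank rule compares the mean over study samples to 5× the mean over
blanks (strict >; per-sample comparison is exposed as an alternative
reading). The S/N > 5 rule removes *cells*, not compounds; compound-level
rules then act on the surviving values, which makes the rules
order-independent. QC %RSD is `100·sd/mean` (sample sd, ddof = 1), strict
< 15. Missing values impute to 20% of the per-compound minimum over the
entire sample set; Pareto scaling centers each compound and divides by the
square root of its standard deviation (so the scaled variance equals the
raw sd). PCA is the SVD of the scaled samples × compounds matrix, with each
component's sign fixed so its largest-magnitude loading is positive. Fold
changes use **observed** (unimputed) group means — imputation constants
would distort ratios — with a +inf flag for a zero denominator. Target
selection ranks by descending maximum group mean, tie-broken by descending
|log2 FC|, capped at the 6-transition per-acquisition budget; the composite
is explicitly a convention and is override-friendly. Stereoisomer
aggregation sums members with missing-as-zero and flags how many censored
cells entered each sum.

## Synthetic generators

All generators are pure functions of parameters and seed. Multiplicative
noise is mean-corrected log-normal: `sigma² = ln(1 + CV²)`,
`mu = −sigma²/2`, so the factor has expectation exactly 1 and planted means
and fold changes are exact expectations, not approximations. An additive
half-normal background `background_level·|N(0,1)|` plays everywhere,
giving background pixels a mean response of `background_level·√(2/π)`.

The default tissue scene is a 40×40 raster with a circular section
(radius 14 px) containing an airway-wall annulus (radii 5–8) around an
empty lumen, parenchyma elsewhere, embedding medium outside — enough pixels
(~120 airway, ~490 parenchyma, ~980 background) for 50-pixel sampling.
Calibration slides default to the 0/0.5/1/5/10/25/150/400 pg ladder, three
replicate rows, radius-jittered disk spots, 100 counts per pg/pixel and 8%
CV. Feature tables default to 12 study samples per tissue (3 biological ×
4 technical replicates), 15% CV, blanks at 5% of sample level and QCs at 5%
CV, with base concentrations log-uniform in 20–150 pg/mg.

What the generators do *not* emulate: desorption physics, ion suppression,
spatial autocorrelation of tissue texture, chromatographic artifacts, or
censoring that correlates with concentration. Passing tests therefore
demonstrate the correctness and statistical power of the *processing*, not
instrument-level performance on real tissue.

## Problem sizes and determinism

Test simulations use the study-scale defaults above (50 pixels per group,
triplicate 8-level curves, 100-seed power sweeps); every stochastic test
and the acceptance script derive all randomness from explicit integer
seeds, so reruns are bit-identical.

## Known limitations

- No vendor binary (.raw) or imzML I/O; the text dialect is the only format.
- No matrix-transfer correction between the calibration surface and the
  sample tissue; the calibration matrix is assumed to mimic the sample.
- No automatic tissue segmentation; ROIs are supplied by the user.
- The asymptotic Mann–Whitney branch inherits the usual ~0.01 accuracy of
  the normal approximation near the center of small-sample nulls.
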