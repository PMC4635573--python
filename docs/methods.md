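# Methods

## The estimation model

A rice panicle bears its grain on primary branches, and within one
variety (uniform grain size and filling) the spikelet count grows
linearly with the amount of spikelet-bearing branch material. `spikescan`
exploits this with a per-variety linear model

```
SNPP = slope · trait + intercept
```

where the trait is either the **branch-region area** (pixels of the
segmented spikelet-covered regions) or **TLPB2** (sum of region
moment-ellipse major axes, a total branch length proxy). Because the
trait is measured on coarse 72-dpi scans, individual grains never need
to be resolved; the model bridges the scale gap between branch
morphology and grain counts. Area is the more robust trait: branch
curvature and branch-to-branch adhesion bias a length measurement but
barely affect area.

The slope/intercept are variety- and environment-specific, so the
package supports two fitting protocols:

* **split_80_20** — ordinary least squares on a random 80% of labeled
  panicles, evaluated on the rest (`seed` fixes the split);
* **five_point** — the fast field protocol: five panicles whose trait
  values sit nearest the five equally spaced targets spanning the trait
  range (ties to the lower value; the extreme samples are always
  included), counted by hand, then used to fit the same line. On linear
  data with modest noise it reproduces the 80%-sample fit at a fraction
  of the manual effort.

Panicles used to fit a model are never used to score it; the evaluator
raises on any overlap.

## Segmentation pipeline

Scans are dark plant material on a light background. Steps, in order,
with the conventions that matter:

1. grayscale by the unweighted channel mean (R+G+B)/3, rounded half-up —
   not luminance weights;
2. Otsu threshold on the 256-bin histogram, split `{≤t}`/`{>t}`,
   smallest maximizer on ties; a constant image is an error;
3. binarization, dark-foreground by default (`auto` picks the minority
   class for inverted scans);
4. opening with a radius-1 disk (the 3×3 diamond). This is the scale
   separation step: 1–2 px structures (rachis, bare stems, awns) vanish,
   the ≥8 px-thick spikelet-covered branch regions survive. The radius
   is configurable for other resolutions;
5. hole filling (background components not 4-connected to the border);
6. removal of 8-connected components with strictly fewer than 100 px
   (dust, fragments);
7. labelling, 8-connected foreground / 4-connected holes, labels in
   raster order.

An optional debug overlay `b + b·f` (binary mask `b`, final mask `f`)
codes each pixel 0/1/2 as background / discarded / retained, for visual
inspection of what the cleanup removed.

## Trait measurement

* **area** — exact pixel count per region; total area is their sum.
* **PBL2** — major-axis length of the ellipse with the region's
  normalized second central moments, with the +1/12 per-pixel variance
  added to the diagonal moments (each pixel treated as a unit square).
  This is the convention of the classical region-props tools; it keeps a
  single pixel at length 2√2·√(2/12) ≈ 1.155 rather than 0 and matches
  their numbers on thin regions. `pixel_correction=False` gives raw
  point moments. Note the estimator's known geometry: for a region whose
  mass is uniform along a line of length L the axis evaluates to
  (2/√3)·L ≈ 1.155·L (for a true ellipse it is exactly the full axis);
  the calibration slope absorbs this constant factor.
* **TLPB2** = Σ PBL2 over regions; reported in px and in cm via
  2.54/dpi. Calibration operates on pixel traits (units cancel in the
  linear model).
* **skeleton diagnostic** — thinning-based skeleton with terminals
  (1 skeleton neighbor) and junctions (≥3). Illustrative only; never
  used in estimation.

## Error statistics

* Per-panicle estimation error is **absolute**:
  `|SNPP_cal − SNPP_manual|/SNPP_manual × 100`; summarized as the
  percentage of samples strictly under 5% and under 10%.
* SNPS deviation is **signed** and computed on means:
  `(mean_cal − mean_true)/mean_true × 100`. It is a ratio of means, not
  a mean of ratios — over-estimates and under-estimates cancel, which is
  exactly the behavior of a per-area yield figure.
* Predictions are real-valued by default (deviations of means are then
  meaningful); a rounding flag exists since counts are integers.
* Predictions are floored at zero; values outside the fitted trait
  range raise an extrapolation warning, not an error.

## Synthetic panicles

The generator emulates what the measurement actually sees: a spread
panicle scanned at 72 dpi.

* **Geometry** — a near-vertical rachis (1–2 px wide, one gentle
  sideways bow of 3–8 px) with branches attached every 40 px of arc,
  alternating sides. Each branch is a quadratic Bézier angled ~40–50°
  off the local rachis tangent, fanning slightly outward toward the tip
  so neighbours diverge; a retry loop redraws a branch (damping its
  angle jitter and bend) if its spikelet blob would come within 3 px of
  another branch's, and raises a layout error after bounded retries.
* **Spikelets** — filled ellipses, default semi-axes 9×4 px (≈6×3 mm at
  72 dpi), ±5% size jitter, oriented ±40° alternately off the branch
  tangent, centers spaced evenly along the branch at the branch's
  density. The mean density (0.10 spikelets/px ≈ 2.8 per cm of branch)
  makes consecutive ellipses overlap, so each branch survives opening as
  one connected region.
* **Counts** — a panicle's target SNPP is split over branches
  (largest-remainder, ≥3 each); each branch's density is drawn with a
  7% coefficient of variation and its length set to count/density, so
  branch length carries the count signal and total SNPP is conserved
  exactly. Branch count scales as SNPP/14, clipped to 5–15.
* **Varieties** — per-panicle SNPP is lognormal around the variety mean
  with CV 0.20, echoing observed count distributions.
* **Rendering** — foreground 60, background 235, additive Gaussian
  channel noise (σ = 8); everything driven by one seeded RNG, so images
  and truth are reproducible bit-for-bit.

What it does **not** emulate: awns, shading/color gradients, touching or
overlapping branches, within-variety grain-size drift, scanner artifacts.
Passing tests therefore demonstrate the pipeline's correctness and the
calibration logic under the stated geometry — not robustness to badly
spread or overlapping real panicles, which the measurement contract
excludes anyway.

## Simulation sizes and numerical choices

The end-to-end accuracy trial uses 6 varieties × 100 panicles (means
90–200 spikelets, the package's default variety panel) with a 5-point
area calibration per variety and 95 held-out panicles each — large
enough for stable within-10% fractions while keeping a full run in the
low minutes on one core. Otsu is computed vectorized over all 255
splits (exactly equivalent to the brute-force scan, which the tests run
as an oracle); OLS goes through `scipy.stats.linregress`; flooring,
tie-breaks and connectivity conventions are as listed above. Degenerate
inputs (constant images, constant traits, empty regions, zero manual
counts) raise informative errors rather than returning sentinels.

## Known limitations

* Branch regions that physically touch after spreading merge into one
  region; TLPB2 degrades first, area is mostly unaffected.
* The moment-axis length proxy is biased for long uniform regions by the
  constant (2/√3) factor; harmless under calibration, but TLPB2 in cm
  should not be read as a literal ruler measurement.
* One calibration line per variety/site: grain size and filling rate are
  assumed uniform within the sample; pooling varieties is out of scope.
* No uncertainty intervals beyond R²; the five-point protocol trades
  statistical efficiency for speed by design.
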