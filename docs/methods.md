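# Methods

## Crack segmentation

The imaging pipeline mirrors the standard ImageJ particle-analysis recipe:
RGB → grayscale with the ITU-R 601 luma weights (0.299, 0.587, 0.114,
configurable), an optional centered circular region of interest to avoid
the curved rim of a convex product, Otsu thresholding, small-object
removal, and 8-connected component labeling.

Choices that matter:

- **Pixel pitch.** Physical calibration comes from the scan resolution:
  pitch = 25400/dpi µm (63.5 µm at 400 dpi), and
  area_mm² = area_px·(pitch/1000)². The pitch is a plain config field, so
  a directly measured pitch can replace the dpi-derived one.
- **Otsu on the fixed 0–255 histogram.** The threshold is the integer
  level t ∈ [0, 254] maximizing the between-class variance of the classes
  {≤ t} and {> t} on the 256-bin histogram, ties going to the smallest
  level. This fixed-binning, integer-level convention matches particle-
  analysis tools (and makes the threshold comparable across images);
  libraries that bin over the observed intensity range return bin centers
  instead, which is why the search is implemented here. A constant image
  has no threshold and raises.
- **Polarity.** Cracks are assumed darker than crust: foreground = pixels
  ≤ t. The `light_foreground` flag inverts the rule; the whole pipeline
  is invariant under intensity inversion with the flag flipped (the Otsu
  objective is symmetric, t ↦ 254 − t).
- **ROI handling.** Pixels outside the circle are forced to the
  background side (light for dark cracks) and the threshold is computed
  from the ROI interior only, so the blanked exterior cannot distort the
  histogram. The ROI diameter has no hard default: the sensible choice is
  product-specific (it must fit inside the planar part of the surface),
  so it is an explicit parameter and the full frame is used when absent.
- **Noise reduction.** Default is removal of components below 2 px
  (min_size_px, configurable); a 3×3 median ("despeckle") is available as
  an alternative. Areas are summed exactly in pixel units before the
  single float conversion to mm².

## Heavy-tailed size distribution

Crack areas are modelled with a log-normal body and a power-law tail.

**Log-normal fit.** μ and σ are the MLE mean and divide-by-n SD of ln x;
the back-transformed μ\* = e^μ equals the sample geometric mean exactly
and σ\* = e^σ is the geometric SD. A divide-by-(n−1) option (`ddof=1`)
exists because coefficient tables are sensitive to the convention.
Goodness of fit is the two-sided one-sample KS distance over the full
sample against the fitted log-normal CDF; the reported p-value is the
asymptotic one-sample p. Because the parameters were estimated from the
same data that p is optimistic, which the `params_estimated` flag records
explicitly — no Lilliefors-style correction is applied. The fit is
"distributional": the CCDF is a display and distance device, not the
least-squares target.

**Power-law tail.** For each candidate x_min (every distinct sample value
whose tail holds ≥ `min_tail_size` = 10 points), the continuous MLE
α = 1 + m/Σ ln(x_i/x_min) is computed on the m tail points, the tail is
compared to F(x) = 1 − (x/x_min)^(1−α) by the KS distance evaluated on
both sides of each empirical step, and the candidate with minimal D wins;
ties break toward the smaller x_min (larger tail). Candidates whose tail
values all equal x_min are skipped (the MLE diverges). The normalization
c = (α−1)·x_min^(α−1) makes the density integrate to 1 on [x_min, ∞).
Suffix-sum bookkeeping makes the full scan O(n) per candidate in vector
ops; a 5000-point sample fits in ~0.2 s.

**Acceptance of the tail.** D is compared with the asymptotic one-sample
critical value coeff/√n_tail (1.22/1.36/1.63 at the 10/5/1% levels);
an exact small-n table can be supplied through `exact_table`. No
semi-parametric bootstrap p-value and no likelihood-ratio comparison
against the log-normal are computed — acceptance is the tabulated-maximum
test only.

**Interval rule.** The mass of the fitted log-normal between μ\*/σ\*ᵏ and
μ\*·σ\*ᵏ is 2Φ(k)−1 independent of the parameter values: 68.27%, 95.45%
and 99.73% for k = 1, 2, 3 (customarily quoted as 68.3/95.5/99.7; note
the k=2 convention overstates the analytic mass by 0.05 points).

**Grouping.** Whether coefficients should be fitted per image and averaged
per group, or fitted once on the pooled group sample, is a study-design
question; both are supported (`--group-by`), and the group summary keeps
the raw per-sample values alongside the means so downstream ANOVA-style
comparisons remain possible.

## Color differences

ΔE76 is the Euclidean CIELAB distance, a metric, and is banded into five
perceptibility classes: (0,1] unnoticeable, (1,2] visible to an
experienced observer, (2,3.5] visible to an unexperienced observer,
(3.5,5] clearly noticeable, (5,∞) two different colors. The source bands
are open intervals that leave boundary points unassigned; (lo, hi] is
adopted so the bands partition [0, ∞), with boundary values falling to
the lower (more conservative) band.

CIEDE2000 follows the CIE 2001 recommendation exactly: G chroma
correction a′ = (1+G)a, hue angles by atan2 in [0°, 360°), the standard
branch rules for Δh′ and the hue mean, weighting functions S_L/S_C/S_H,
the rotation term R_T coupling the chroma and hue differences in the blue
region, and parametric factors k_L = k_C = k_H = 1 by default (the usual
reference conditions; configurable). The implementation is symmetric in
its two arguments because all weights are computed from means. Every
intermediate is exposed, so pairwise panels report |ΔL′|, |ΔC′|, |Δh′|
(degrees) and |ΔH′| next to ΔE00 and ΔE76. Published panels of this form
are typically computed from unrounded instrument means, so recomputing
from a table's rounded means can deviate by ±0.01–0.02 in some cells.
An independent library implementation of CIEDE2000 is used in the test
suite as a cross-check oracle (agreement ≤ 1e-4 over 1000 random pairs),
never as the implementation.

## Puncture-texture features

From an ordered (distance mm, force N) trace: the test start is the first
sample at or above a contact threshold (default 0.05 N; 0 selects the
first sample), hardness is the maximum force at or after the start,
crust thickness is the distance from the start to the *first* occurrence
of that maximum, and WOD is the trapezoidal integral of force over
distance from that peak to the last recorded point ("complete
penetration" is taken as the last recorded sample, not the programmed
travel, since instruments may clip). No smoothing is applied by default;
an optional centered moving average defines the working trace for contact
and peak detection (and then for hardness) on noisy instruments, while
WOD always integrates the raw forces. With the default raw trace,
hardness equals the maximum recorded force exactly.

## Synthetic data

Generators are pure functions of parameters + seed and return ground
truth, so fitting and segmentation are tested by round-trip recovery.

- **Area samples.** Log-normal and Pareto samplers (inverse-CDF for the
  Pareto), and a *spliced* sampler: with probability `tail_fraction` an
  exact Pareto draw above x_min, otherwise a log-normal draw rejected
  until below x_min (rejection budget 10⁶). Defaults sit at the scale of
  real amaretti crack areas: μ\* = 0.26 mm², σ\* = 3.3, x_min = 0.25 mm²,
  α = 1.67, n = 5000. The default `tail_fraction="auto"` moment-matches
  the tail weight so the composite's geometric mean equals the nominal
  μ\* (solving (1−tf)·E[ln X | body] + tf·E[ln X | tail] = ln μ\*,
  ≈ 0.40 at the defaults): a mixture is a testing device, not a physical
  claim, and the matched weight is what makes *both* truth parameters
  recoverable by the two fitters. With the defaults, α and μ\* are
  recovered within 3 standard errors in ≥95 of 100 seeded replicates.
  The composite's log-scale spread exceeds ln σ\* (the Pareto tail is
  heavier than the log-normal's), so σ\* is deliberately not part of the
  round-trip contract.
- **Crack images.** Dark random-walk-grown blobs of *exactly* the
  requested pixel areas (4-connected accretion) on a light Gaussian
  background (200 ± 10 vs 40 ± 10, clipped to [0, 255]) — far enough
  apart that Otsu is trivially separable, with a guaranteed Chebyshev gap
  ≥ 2 px between blobs so 8-connected labeling recovers each one. No
  attempt at photorealism: fixtures only need the statistical and
  topological structure the pipeline assumes (no vignetting, specular
  texture, or perspective, so passing tests say nothing about
  illumination robustness on real photographs).
- **Force curves.** Linear rise to (thickness, hardness), exponential
  drop to a plateau, plateau to full travel, optional Gaussian force
  noise; the grid always contains the peak point so the noise-free curve
  round-trips hardness and thickness exactly. Under 5% force noise the
  smoothed extraction recovers hardness within 2% on average, but the
  peak *location* cannot be pinned tighter than noise_sd divided by the
  rise slope (≈5% of thickness at the defaults) by any estimator that
  does not assume the curve shape; the thickness test asserts that
  analytic jitter bound rather than an unattainable 2%. Only the single
  crust peak is modelled — the second (lower-crust) peak of a real
  double-layer product is out of scope.

## Problem sizes and determinism

Test and demonstration problem sizes — 5000-point area samples,
100-replicate recovery batteries, ~100–160 px canvases with a handful of
blobs — are chosen so each statistical tolerance is meaningfully exercised
at interactive runtimes. All randomness flows through explicit
`numpy.random.default_rng` seeds; reruns with equal inputs and seeds are
byte-identical, including CLI outputs.

## Known limitations

- No illumination or perspective correction; shape descriptors beyond
  area are not computed.
- The KS p-value for the log-normal fit ignores parameter estimation
  (flagged, not corrected); the power-law acceptance is the tabulated
  critical-D test only, which is weaker than a bootstrap test.
- Whether a real crack-size distribution is a mixture or a smooth
  crossover between body and tail is not identifiable here; the spliced
  generator is a calibration device.
- ΔE94/CMC color-difference variants and spectral→Lab conversion are out
  of scope; measurements are assumed to arrive as CIELAB.
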