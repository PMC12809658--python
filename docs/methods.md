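# Methods

This note documents the models implemented in `otmsi`, the parameters that
matter, the synthetic data generator, and the numerical and design choices
made where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Theoretical isotopic envelopes

Reference spectra are aggregated isotopic distributions: isotopologues are
pooled by total nucleon count, and each aggregate carries the
probability-weighted mean of its isotopologue masses. This matches the peak
structure observed at resolving powers up to ~60 000, where fine isotopic
structure is not resolved; the package does not attempt fine structure,
isotopic enrichment, or multiply charged envelope deconvolution.

The computation convolves per-element isotope distributions exactly
(exponentiation by squaring over nucleon-count shift arrays), using an
embedded isotope table (IUPAC 2021 atomic masses, representative abundances;
CODATA 2018 electron mass) so results cannot drift with external library
versions. Elements covered: H, C, N, O, F, Na, P, S, Cl, K.

Two conventions fixed here:

* **Peak threshold.** Aggregates below `threshold` (default 0.05) times the
  most intense aggregate are dropped and the rest renormalized to sum 1.
  The threshold is relative to the maximum peak, which keeps envelopes short
  and matches how centroided experimental envelopes look in practice.
* **Charge.** The electron mass is subtracted per positive charge (added per
  negative); m/z is mass divided by |charge|. This reproduces printed
  monoisotopic masses of potassiated lipid cations to three decimals.

## Preprocessing

* TIC is the trapezoid integral of a profile spectrum; normalization scales
  to a target TIC (default 1). Normalization is applied on the full acquired
  range *before* any m/z restriction.
* `restrict_mz` keeps the closed interval [lo, hi]: boundary peaks are
  retained.
* Centroiding detects local maxima (strictly greater than both neighbors;
  plateaus resolve to their leftmost sample; apexes below a configurable
  noise floor of 1e-6 x the spectrum maximum are ignored), integrates the
  contiguous window where intensity >= `height_fraction` x apex, truncates
  the window symmetrically to `max_width` Da, and splits windows of adjacent
  apexes at the minimum between them, so no intensity is counted twice. The
  stick m/z is the intensity-weighted mean over the window, the stick
  intensity its trapezoid area. Defaults follow common Orbitrap practice
  (FWHM windows, 0.2 Da cap); the low-resolution simulated data uses
  20 %-of-maximum windows capped at 0.4 Da.
* Average spectra: profile datasets (common grid) average pointwise;
  centroid datasets pool sticks (merging identical m/z values) and divide by
  the pixel count. No binning or alignment is performed anywhere — the
  downstream transport fit tolerates the resulting m/z jitter.

## Optimal-transport deconvolution

The transport LP is stated in the README. Points that matter:

* **κ semantics.** κ_mixture prices discarding experimental intensity,
  κ_components prices discarding envelope intensity, both in Da per unit of
  (unit-normalized) intensity. A peak pair farther apart than
  κ_mixture + κ_components can never beat the two trash routes, so such
  pairs are pruned from the LP without changing the optimum; this keeps the
  per-pixel programs small.
* **Proportions.** The reported proportion of a component is the
  experimental mass actually transported to it. The raw envelope scale
  coefficients (which additionally count the envelope's own trashed
  intensity) are exposed as `scales`. Only the transported-mass convention
  makes proportions + unexplained = 1 hold exactly.
* **Solver.** `scipy.optimize.linprog` (HiGHS), a deterministic exact
  simplex/IPM implementation; all per-pixel fits are independent, so results
  do not depend on pixel order.
* **Degenerate input.** An empty or zero-intensity pixel yields an all-zero,
  flagged result rather than an exception, so dataset-scale runs never
  abort.
* **Ion images.** By default `deconvolve_dataset` scales each pixel's
  proportions by the pixel's total centroided intensity ("signal" scale).
  For TIC-normalized data this equals the proportion scale up to a constant.
  For unnormalized data the signal scale is the right quantity to compare
  against ion counts: on the proportion scale a lipid's image is confounded
  by the *other* lipids in the denominator — measured on the simulated
  dataset, the PC(38:0) proportion image is mis-ordered across regions
  (higher proportion where the true count is lower) and its
  count-correlation drops from ~0.97 to ~0.63. `scale="proportion"` is
  available where normalized outputs are wanted.

## Annotation

Default stringent penalties κ_mixture = 0.005, κ_components = 0.01 select
only well-matching ions; detection is `proportion > 0` (fast) or
`average proportion > 1e-9` (thorough). The 1e-9 threshold is exposed as a
parameter because it is data-dependent (it corresponds to the gap of a
bimodal average-proportion histogram on real data and should be inspected
per dataset). The monoisotopic-peak matching window used in the κ scan and
in single-ion image extraction is the nearest centroid within +/-0.05 Da
(configurable); a missing match scores intensity 0. Correlations are
Pearson, since intensities are compared on a linear scale. Pixel sampling
for large datasets is uniform without replacement with a recorded seed.
Annotations are tentative MS1 evidence; FDR control and tandem-MS
confirmation are out of scope.

## The synthetic data generator

The generator emulates a low-resolution MALDI acquisition of three
potassiated lipids — PC(38:1) (C46H90NO8PK, high in the top half), PA(44:0)
(C47H93O8PK, high in the bottom half) and PC(38:0) (C46H92NO8PK, high in a
centered square of half the grid dimensions) — on a 40x40 grid partitioned
into four regions with mean ion counts

| region | PC(38:1) | PA(44:0) | PC(38:0) |
|--------|---------:|---------:|---------:|
| 1 (top, outside square)    | 10 000 | 2 000 | 1 000 |
| 2 (bottom, outside square) |  1 000 | 4 000 | 1 000 |
| 3 (top, inside square)     | 10 000 | 2 000 | 2 000 |
| 4 (bottom, inside square)  |  1 000 | 4 000 | 2 000 |

Per pixel and lipid, counts are negative-binomial with the regional mean μ
and variance (cv·μ)² at cv = 0.20 (dispersion size μ²/(var − μ); the
parameterization requires super-Poisson variance and errors otherwise).
Envelope peaks receive multinomial draws with the count as the number of
trials, so stick intensities conserve counts exactly. Ten noise peaks at
uniform m/z positions, with a Dirichlet(1) intensity split, jointly carry
10 % of the final spectrum intensity. Sticks are placed on a uniform 0.005
Da profile grid over 850–862 Da as area densities (trapezoid TIC equals
total sticks) and blurred to fwhm = 0.12 Da (R ≈ 7000 at m/z 800), noise
included before the blur. One master seed spawns a counts stream plus one
stream per pixel, so results are bit-reproducible and order-independent.

The m/z window and the noise split are the generator's own choices (they
are not physically constrained); the window covers the three envelopes plus
margin, and the grid gives ≥ 10 samples per FWHM. With these settings the
PA(44:0) monoisotopic peak (855.624) merges with PC(38:1) M+1 (855.607),
and PC(38:0)'s monoisotopic peak (856.619) merges with PC(38:1) M+2 and
PA(44:0) M+1 — the interference structure the deconvolution is meant to
resolve.

What the generator does **not** emulate: per-pixel TIC artifacts (laser or
matrix variation — the simulated data is deliberately not normalized),
mass-calibration drift, chemically structured background, and in particular
any *within-region* variation of the mean counts: means are constant per
region, so region boundaries are perfectly sharp. Passing tests therefore
demonstrate correctness of the pipeline under clean region geometry, not
performance on tissue with gradual boundaries or textured concentration
fields. This matters when comparing segmentation accuracies against data
whose mean field has within-region texture: with region-constant means even
thresholding the true counts misassigns only the distributional overlap
(a few percent), so segmentation accuracies here sit near their
information-theoretic ceiling.

## Segmentation

* **Naive baseline**: 1-D K-means (scikit-learn, `n_init` restarts,
  seed-controlled) on image intensities; segments are relabeled in
  ascending-mean order so segment k is "high". On sorted 1-D data the
  optimum is an ordered split, which the tests verify against exhaustive
  search.
* **Spatially aware GMM**: per-pixel mixing weights; E-step posteriors from
  current means/variances and weights; spatial step replaces each pixel's
  weights with the Gaussian-kernel-weighted average of posteriors over the
  Chebyshev radius-r square window (σ = r/2, border weights renormalized),
  raised to β/(β+1) and renormalized. β = 0 gives a flat prior (plain GMM;
  verified equivalent to a reference EM to 1e-6 in posterior), β → ∞ uses
  the neighborhood consensus directly. The M-step re-estimates means and
  variances from the smoothed posteriors. Initialization is K-means with 5
  restarts; convergence is a relative log-likelihood change below 1e-6 or
  200 iterations; collapsing variances are floored at 1e-12 x the image
  variance and flagged. This scheme follows the published spatially-aware
  Gaussian-mixture approach for MSI in its two documented limits; the exact
  update equations of the original are not public in the source used here,
  so intermediate-β behavior is an approximation.
* Accuracy against a binary truth mask is the percentage of pixels whose
  high/low assignment matches, with "high" fixed by the fitted means (never
  by best-match search), so an inverted segmentation scores 0 %.
* Zero-proportion pixels participate in the fit (they inform the low
  segment) but are flagged through the image mask; masked-out pixels are
  excluded.

## Problem sizes and defaults used in the reproduction script

`scripts/acceptance.py` and the acceptance tests run the full pipeline on
the default 40x40 generator (1600 pixels, three envelopes, ~4000 transport
LPs per seed) for five seeds and report means. Centroiding uses 20 % of
maximum / 0.4 Da; deconvolution κ_mixture = 0.2, κ_components = 0.5 (looser
than the annotation values because the simulated resolution is low);
segmentation k = 2, r = 3, β = 6. A complete run takes well under a minute
on one CPU.

## Known limitations

* Aggregated envelopes only; no fine structure, no |charge| > 1 testing
  beyond the m/z convention.
* The spatial GMM's β-interpolation is an approximation of the published
  algorithm between its two exact limits (see above).
* The generator's sharp region boundaries place segmentation accuracies
  near their ceiling; see the generator section for what this does and does
  not show about real tissue.
* Annotation thresholds (1e-9, minimum pixel counts) are dataset-dependent
  and exposed as parameters rather than automated.
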