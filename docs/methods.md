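# Methods

## The association score

For one image, let `S` be the query point set (the cell class whose
localization is in question, e.g. CD45+ leukocytes), `T` the reference
point set (e.g. GFP+ or p16+ senescent stromal cells), and `W` the valid
region — the interstitial stroma left after masking the epithelial layer,
hair follicles, muscle and everything outside the tissue.

- Observed statistic: `d_obs = median_i min_j ||s_i − t_j||`. The median
  is used instead of the mean so a handful of query cells far from any
  reference cell cannot dominate the summary.
- Null: `K` Monte-Carlo rounds re-place `|S|` points uniformly over `W`
  while `T` stays fixed; each round records its median NN distance. The
  null is therefore *conditional* on the observed reference geometry, the
  number of query cells, and the exact mask — which is also why no
  analytic edge correction is required: whatever boundary effects the
  window induces are present identically in the null.
- Score: `z = (mean_K − d_obs) / sd_K`, with `sd_K` the population
  standard deviation (divisor `K`) of the sampled medians. Positive `z`
  means the query class is closer to the reference class than random
  placement (association), negative means repulsion.
- Percentile: the fraction of sampled medians strictly greater than
  `d_obs`. Ties count against association (conservative). For `|S|` of
  order 100 or more the sampling distribution of the median is close to
  Gaussian, so the percentile tracks `Φ(z)` (verified to within 0.02 at
  `K = 10,000`); this underlies reading `z = 2` as "observed median below
  ~97.5% of the null medians".

Modes. `point_to_point` is the main analysis. `point_to_region` measures
distance to the nearest pixel center of a reference region raster (used
for the epithelium control: in tissue without the reference cell class,
immune distance to the epithelial layer should not differ from random).
`self` measures each cell's distance to its nearest other same-class cell
and re-places the entire set per null round (the self-association
control). Self-exclusion is by index, not coordinate, so coincident
duplicate detections count as zero-distance neighbours rather than being
dropped.

Degenerate inputs. An empty query or reference set raises a typed error —
an image with no reference cells yields no score, not an infinite
distance. A null with zero spread (e.g. a one-pixel valid region without
jitter variability) raises rather than returning ±∞, since the score is
undefined there.

## Random placement

"Uniform over the valid region" is implemented as a uniform choice among
valid pixels plus independent sub-pixel jitter uniform in [−0.5, 0.5) on
each axis — exactly uniform over the valid area and cheap to sample.
Coordinates are continuous and 0-based with pixel centers at integers
(`x` = column, `y` = row); a point on a pixel boundary belongs to the
pixel whose center is nearest, ties toward the smaller index. All
distances are in pixels; a `pixel_size` scalar (microns/pixel) exists for
reporting only, and the score is dimensionless — multiplying every
coordinate by `c > 0` scales all distance summaries by `c` and leaves the
score unchanged.

Determinism. Every stochastic routine is a pure function of its inputs
and an integer seed (numpy PCG64). Batch runs derive per-sample seeds as
`SHA-256(base_seed, sample_id) mod 2^31`, so results are independent of
processing order. The Monte-Carlo sampler consumes its random stream in a
fixed internal chunking, making outputs bit-reproducible.

Exactness. The nearest-neighbour kernels (a running-minimum scan for up
to 128 reference points, a KD-tree beyond) are bitwise identical to the
all-pairs brute-force scan; this is asserted, not assumed, over a
thousand random instances in the test suite.

## Cohort aggregation

Per-image scores from one cohort are summarized by their mean, sample
standard deviation (`n−1`; the error bars typically drawn), and a
Student-t 95% confidence interval `mean ± t_{0.975,n−1}·sd/√n` — the
standard small-sample interval for the 4–9 images or donors per group
such studies have. The cohort call is `association` if the CI lies above
0, `repulsion` if below, `none` otherwise. Scores from different modes
are never pooled (enforced). `compare_groups` adds a Welch two-sample
t-test between cohorts, reported alongside, never instead of, the
per-group CIs.

## Cell detection

The detector converts one marker channel plus the mask into centroids:
Gaussian smoothing (`smoothing_sigma`, default 2 px) → threshold (Otsu
computed on in-mask pixels only, so bright excluded regions such as
autofluorescent epithelium cannot skew it; or an absolute value) →
8-connected component labeling → area gates (`min_area` 20 px,
`max_area` 2000 px by default) → optional splitting of merged objects →
intensity-weighted centroids, emitted in labeling scan order.

Splitting: components larger than `2·min_area` are re-segmented by
watershed on the smoothed intensity, seeded at local maxima of a
Laplacian-of-Gaussian blob response at scale `split_sigma` (default
`max(1, 0.7·smoothing_sigma)`). The LoG response was chosen over plain
intensity maxima because two spots closer than about twice the combined
PSF + smoothing scale merge into a single intensity maximum; the LoG
separates such pairs down to roughly the PSF scale itself. A centroid
that falls outside its own (non-convex) component is snapped to the
nearest component pixel, so no emitted point ever lies outside the valid
mask.

Defaults are tuned for fixtures and always config-overridable; nothing is
silently adaptive. There is an intrinsic resolution limit: spots closer
than roughly the PSF Rayleigh distance (~2× the spot scale) cannot be
resolved by any intensity-based detector, so one-to-one matched F1 on
densely clustered patterns is information-theoretically capped below 1
regardless of parameters. The detection quality gate (F1 ≥ 0.95 at 3 px
matching, Poisson noise at SNR ≥ 5) is therefore stated — and tested —
on spots separated beyond that limit, while clustered patterns are tested
on what actually matters downstream: the association score computed from
detected points reproduces the clustered-vs-CSR contrast in full.

## Synthetic data

The generator emulates the geometry the analysis assumes, not tissue
appearance. The mask is an elliptical tissue section (semi-axes 0.9 of
the half-dimensions of a 256×256 raster) minus a 20-row epithelial band
and 3 circular follicle holes (radius 8–16 px); the named excluded
regions partition the non-valid pixels exactly. Point patterns: 30
reference "parents" uniform over the valid region, and 150 query
"offspring" that are uniform (CSR — the null the score is calibrated
against), Thomas-like attracted (uniform random parent plus isotropic
Gaussian displacement of scale `sigma_c`, default 5 px — one
interpretable effect-size knob, with CSR recovered as `sigma_c → ∞`), or
hard-core inhibited (re-drawn until ≥ `r_min` from every parent, default
30 px). Mask containment uses rejection, not truncation, so within-mask
placement stays exactly uniform / exactly Gaussian-conditioned; rejection
is capped at 10,000 attempts per point with an explicit infeasibility
error.

Rendering: isotropic Gaussian spots (scale 2 px, peak amplitude 100)
on a constant background of 10, with Poisson shot noise on signal +
background (the standard fluorescence forward model; peak SNR
100/√110 ≈ 9.5) and optional additive Gaussian read noise. Spots are
truncated at 5σ (relative error < 10⁻⁵ of the peak).

What the generator does not emulate: cell morphology and size variation,
intensity phenotypes, chromatic shifts between channels, uneven
illumination, tissue autofluorescence texture, and annotation error in
manual point sets. Passing tests therefore demonstrate the statistical
machinery and the detection pipeline on idealized spot images; they do
not certify detection performance on real histology, where parameter
tuning against the actual staining is expected.

## Problem sizes used in the tests

The statistical acceptance suite runs at sizes chosen to make the checks
decisive while keeping the full run in minutes on one core: the
percentile statement at `K = 100,000` with 200 query points against 50
fixed targets in a full 512×512 window; calibration over 500 seeded CSR
replicates at `K = 10,000` in the irregular holed mask; the power sweep
over `sigma_c ∈ {40, 20, 10, 5}` px with 50 seeds per condition; the
end-to-end detection chain over 40 seeds per pattern; CI coverage over
2,000 simulated cohorts of 8. Production analyses default to
`K = 100,000` rounds per image.

## Known limitations

- The score is conditional on the observed reference pattern; it tests
  association of the query class *given* where the reference class is,
  and is not symmetric in the two classes.
- One score per image; repeated images per donor are aggregated as
  independent samples unless the caller groups them (the manifest makes
  the mapping explicit).
- 2D only; no 3D stacks, time series or stitching.
- Pixel-center rasterization of region polygons means sub-pixel region
  geometry is not represented.
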