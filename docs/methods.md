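# Methods

## Densitometric model

The measurement chain is modeled in two invertible steps.

**Film response.**  Gray value as a function of radioactivity
concentration `R` (cpm) is the saturating exponential

    G(R) = offset + gmax · (1 − exp(−rate · R))

with `offset` the film base fog, `gmax` the dynamic range and `rate` the
sensitivity.  The functional form is a package choice: it captures film
saturation, is strictly monotone for positive parameters, and inverts in
closed form, which makes forward simulation and quantification exactly
consistent.  Calibration fits this family to the co-exposed standards by
Levenberg–Marquardt least squares (`scipy.optimize.curve_fit`) with
positivity bounds on `gmax` and `rate`; a fit is refused (never returned)
if the resulting curve is not strictly monotone over the standards' span,
and at least four distinct radioactivity levels are required.  A second
family — a shape-preserving monotone piecewise cubic (PCHIP) in
`log1p(R)` — is available to probe mismatch between the assumed parametric
family and the true film behaviour.  Gray values outside the calibrated
interval `[G(0), G(R_max)]` are masked (NaN) and counted, never
extrapolated.

**Saturation correction.**  Radioactivity converts to binding-site
density

    C_b = R / (E · B · W_b · S_a) · (K_D + L) / L      [fmol/mg protein]

with the six ligand constants carried in `LigandParams` (all strictly
positive, validated at construction).  No decay correction over exposure
time and no myelin-quenching correction are applied.  Non-specific binding
is assumed negligible by default (total ≈ specific); explicit subtraction
(floored at zero, with the floored-pixel count reported) is available when
a non-specific image exists.

## Laminar profiles

Traverses are anchored equidistantly along the pial contour and connected
to the white-matter contour by the nearest point (minimum length); matched
arc positions are made non-decreasing, which guarantees that no two
traverses cross for consistently oriented contours.  A Laplace-like
streamline alternative (gradient of the normalized-distance field
`d_pial/(d_pial+d_wm)`) is available for strongly curved ribbons.
Traverses longer than 1.5× the median of their area are discarded as
obliquely sectioned cortex; the 1.5 factor operationalizes a qualitative
exclusion rule and can be changed per call.

Profiles are bilinear point samples at `n_bins` equidistant depths between
the pial (0%) and white-matter (100%) endpoints; `n_bins` defaults to 101,
and `n_bins=1` degenerates to the traverse mean.  A sample whose bilinear
stencil touches a masked pixel is masked and skipped by the integrals.

Strata are half-open depth sectors: supragranular `[0, f1)`, granular
`[f1, f2)`, infragranular `[f2, 1)`, with `(f1, f2)` the cortical-depth
fractions of the layer III/IV and IV/V borders (defaults 0.55, 0.70).
Agranular areas carry instead the depth of the lower border of layer III;
their granular sector is the stripe of 3% of cortical depth below it.
Sector means are trapezoidal integrals of the piecewise-linear profile
divided by sector width, and the all-layer mean is the integral over the
full depth; because all four numbers integrate the same interpolant, the
thickness-weighted identity

    mean_all = f1·mean_sg + (f2−f1)·mean_g + (1−f2)·mean_ig

holds to machine precision, for single profiles and for unweighted
per-area aggregates alike.  The all-layer mean is deliberately the
profile integral (thickness-weighted), not the unweighted mean of the
three sector means.

## Fingerprints

A fingerprint is the ordered density vector of the receptor panel for one
area and stratum; four are built per area (all, sg, g, ig) and the
receptor sequence (AMPA, NMDA, kainate, GABAA, GABAA/BZ, GABAB, M1, M2,
M3, alpha4beta2, alpha1, alpha2, 5-HT1A, 5-HT2, D1) is shared across a
collection.  Size is reported both as the plain sum of densities and as
the polar-polygon area `½·sin(2π/k)·Σ r_i·r_{i+1 mod k}`; the sum is used
wherever total receptor expression is compared, the polygon area mirrors
the polar-plot reading.  Z-scoring is per receptor with the sample
(n−1) standard deviation, either within each stratum collection (area
comparisons inside one stratum) or pooled across strata — pooling is
required for strata to be comparable in one space and is the scope used by
the strata-cluster analysis.  Absolute polar plots share one radial scale
across the collection; normalized plots draw the zero-z reference ring.

## Multivariate battery

* **Hierarchical clustering**: Ward linkage on Euclidean distances
  (scipy); the cophenetic correlation of the tree against the input
  distances is reported, along with the correlations of six alternative
  linkages so the linkage choice is auditable on the data at hand.  Note
  that Ward reproduces two-level ultrametrics exactly but re-derives
  heights by the Lance–Williams recursion, so on deeper ultrametrics its
  cophenetic correlation is slightly below 1 while single/complete/average
  reach exactly 1.
* **Cluster count**: k-means (10 seeded restarts) for k = 2..12 scored by
  mean silhouette; partitions whose smallest cluster holds fewer than 5%
  of the observations are skipped, so the selected k counts *main*
  clusters rather than one- or two-point splinters.  Ties resolve to the
  smaller k.
* **MDS**: nonmetric (rank-based) SMACOF minimizing Kruskal stress-1,
  20 seeded restarts, tolerance 1e-6; the metric flavour uses classical
  (Torgerson) scaling, which reproduces plane-embeddable distances
  exactly.
* **Discriminant tests**: the omnibus group-separation statistic is
  `trace(W⁻¹B)/n` with `B` the between-group scatter and `W` a pooled
  within covariance shrunk by the analytic Ledoit–Wolf intensity — with
  15 receptors and 3 replicate brains per area the raw pooled covariance
  is singular, so no Wilks F approximation exists; p-values therefore come
  from label permutations, which keeps type-I error calibrated at any
  dimensionality.  Pairwise two-group tests follow the same recipe and
  are reported uncorrected, as post hoc tests behind a significant
  omnibus.  The permutation p has a resolution floor of
  `1/(n_permutations+1)` and, for tiny groups, of the number of distinct
  label partitions.

## Univariate statistics

Per receptor, a one-way fixed-effects ANOVA with area as the factor and
brains (n = 3) as replicates; the brain is treated as a plain replicate,
not a random effect — a documented simplification.  Raw p-values are
Bonferroni-multiplied by the number of receptor types and reported
unclipped (values above 1 are meaningful only as "not significant"; a
clipped variant exists).  Only receptors whose adjusted ANOVA p ≤ 0.05
enter the follow-up: per area, a one-sample t-test of the replicate
densities against the across-area grand mean of that receptor, treated as
a fixed expected value; these gatekept p-values are deliberately
uncorrected.  Zero-variance replicate sets are flagged degenerate rather
than producing a t statistic, and gate-failing receptors are recorded as
not-tested, never as non-significant.

## Synthetic data: what it emulates and what it does not

The generator plants the qualitative laminar architecture reported for
the human cortex: a canonical supragranular > granular > infragranular
gradient for most receptors; granular densities close to supragranular for
NMDA, GABAA, GABAA/BZ and 5-HT2 (receptors described as dense in the
supragranular *and* granular strata with a low infragranular stratum); a
distinct infragranular maximum for kainate; granular minima for alpha1
and — most extremely — 5-HT1A; and granular maxima of M2 generally and of
alpha4beta2 in the three primary sensory areas (V1, 3b, 41), with boosts
of ~1.4× and ~2.3× over the generic granular level.  Default magnitudes
put ionotropic glutamate/GABA receptors one order of magnitude above the
modulatory receptors, in the hundreds-to-thousands fmol/mg range.

Area identity is a per-(area, receptor) multiplicative lognormal effect
(sd 0.25 on the log scale), matching the roughly two-fold inter-areal
density ranges seen in real surveys.  Between-brain variability
(default CV 0.05) is one multiplicative lognormal factor shared by the
three strata of a (brain, area, receptor) cell — real brains preserve
proportional relations between areas and layers — which also preserves the
planted laminar orderings exactly in every replicate.

Phantoms render each area as an equal segment of a flat or circular-arc
ribbon; pixel values traverse the exact inverse of the densitometric
model, sector borders are antialiased by mixing radioactivity over each
pixel's depth extent, and a 2-px apron beyond the contours keeps bilinear
sampling at the exact endpoints clean.  Additive Gaussian noise acts on
gray values; an optional Poisson term on radioactivity emulates emulsion
grain.  Densities closer than 0.5% to film saturation raise an error
rather than being clipped.  The phantoms contain no histology texture,
vessels, section artifacts or 3-D geometry, so passing round-trip tests
demonstrates correctness of the calibration/profile/integration chain, not
robustness to real-tissue artifacts.

## Problem sizes and numerical choices

Fast tests use a reduced 8-area × 6-receptor design (the six receptors
cover every laminar class).  The strata-cluster analysis uses the 41
granular areas with the full 15-receptor panel; agranular areas are
excluded from clustering by default (their nominal layer IV is a
convention, not a measured granular layer).  Round-trip validation uses a
high-resolution phantom (cortical thickness 1600 px, profile bins at
pixel pitch): sector-border smoothing transfers mass between adjacent
sectors in proportion to the blur width over the sector width, so the
residual bias scales as 1/thickness — at 1600 px the worst-case noiseless
error of the steepest-gradient receptor is ≈0.45%, and the thin granular
sector of agranular areas would need proportionally thicker rendering for
the same accuracy (a resolution limit shared by real measurements).
Seeds enter every stochastic stage explicitly; identical seeds give
bit-identical tables, phantoms and non-plot pipeline artifacts.

## Known limitations

* No myelin-quenching or exposure-decay correction (matching the modeled
  protocol); densities near film saturation are unmeasurable by design.
* The minimum-length traverse construction assumes consistently oriented,
  non-intersecting contours; pathological geometries (re-entrant folds)
  need the streamline option.
* The discriminant permutation test is conservative at its resolution
  floor for very small groups.
* The brain factor is a fixed replicate; no mixed-effects alternative is
  provided.
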