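# Methods

This note documents the models, estimators and design choices behind
`densiforest`, stage by stage, including what the synthetic study system
does and does not emulate.

## The synthetic study system

All stages are validated as parameter recovery against a generator with
known truth. One integer seed drives everything; independent sub-streams
are derived with `numpy.random.SeedSequence` spawn keys (a counter-based
splitting rule), so any stage can be regenerated in isolation and
identical seeds give byte-identical serialized worlds.

**Phylogeny.** A pure-birth (Yule) process, grown forward and rescaled to
a fixed root-to-tip depth, hence exactly ultrametric. The two children of
the root are labelled clades — angiosperms (75% of tips by default) and
gymnosperms — with a stem occupying 30% of tree depth. Yule rather than
birth–death because the tree only has to exercise the covariance code; no
extinct lineages are needed. Synthetic binomials (`Angiogen012_sp0037`)
carry genus/family/order annotations assigned over contiguous tip groups
(3 species per genus, 4 genera per family, 3 families per order).

**Traits.** Wood density evolves as one multivariate-normal draw with
per-tip mean equal to the clade mean (defaults 0.59 and 0.47 g cm⁻³,
within-clade sd ≈ 0.11 via σ² = 0.012 at unit depth) and covariance
σ²·C(λ), where C(λ) scales the off-diagonal shared-path matrix by λ
(default λ = 0.9). Values are clipped to the span of real wood,
[0.05, 1.5] g cm⁻³; clipping is logged because it perturbs normality
slightly (at the default σ² it essentially never triggers).

**Landscape.** A 64×64 half-degree lattice (west edge −20°, north edge
52°). Temperature is a monotone north–south gradient (−2 °C to 26 °C)
plus a smooth Gaussian random field (sd 1 °C, correlation length 4
pixels); moisture, disturbance (a human-modification analogue in [0, 1]),
fire, soil C:N, LAI and forest age are smooth fields in plausible ranges;
growing stock volume rises with temperature and moisture; root mass
fraction is a smooth field around 0.25. Biome codes are thresholded from
temperature and moisture (boreal < 8 °C, tropical ≥ 18 °C wet, dryland
≥ 18 °C dry, temperate otherwise). About 4% of pixels are masked as
no-data to exercise mask propagation.

**Plots.** Community assembly is inverse-distance trait filtering, not a
mechanistic model: at temperature T the target density is
base × (1 + slope·T/100) (base 0.50 g cm⁻³, slope 0.5% per °C) and
species are drawn with weight 1/(|wd − target| + τ)² (τ = 0.02), times a
gymnosperm multiplier exp(−0.18·max(T, 0)) so conifers dominate the cold
end. The only contract is the induced CWD–environment relationship, which
is what the downstream stages test. DBH is lognormal with median 20 cm
and log-sd 0.53 (mean ≈ 22.9 cm, 95% range ≈ 7–57 cm), left-truncated at
the 5 cm calliper; plot areas are lognormal with median 25 m²; censuses
sit around year 2003. An optional planted interaction flips the
disturbance effect on the target density at a set temperature, used by
the partition-recovery checks.

What the generator does **not** emulate: realistic biogeography or
dispersal, demography, measurement error in DBH, the heavy right tail of
real plot-size distributions, name-resolution noise beyond simple
formatting variants, and — importantly — residual spatial autocorrelation
beyond the smooth covariates themselves. Passing tests therefore
demonstrate that the estimators recover planted structure at realistic
noise levels, not that real inventory data meet these assumptions.

## Trait tables

Species means are arithmetic means of records; genus means are means of
species means (not record-weighted), so one heavily sampled species
cannot dominate its genus. Name canonicalization is rule-based
(whitespace, case, authority and rank-marker stripping, an optional
synonym map); full taxonomic resolution is out of scope. Between-source
concordance is OLS of one source's species means on another's over shared
species (pairs with fewer than 3 shared species are skipped).

The taxonomic decomposition fits the nested random-effects model
y = μ + a_family + b_genus(family) + c_species(genus) + e by unbalanced
nested-ANOVA method of moments (Searle's expected-mean-square
coefficients), truncating negative component estimates at zero. Method of
moments was chosen over REML because it is closed-form, exact in the
balanced case used for calibration, and free of convergence tuning; the
equal-components simulation (50×4×4×4) recovers each fraction to
0.25 ± 0.05. Fractions are invariant to affine trait rescaling. The
two-way crossed plot × year decomposition of multi-census CWD uses the
analogous two-way ANOVA estimator with average-replication coefficients.

## Phylogenetic signal

`brownian_covariance` builds C by a single postorder pass (C_ij = depth of
the MRCA); a brute-force path-walk oracle checks it on small trees.

**Pagel's λ**: C(λ) scales only the off-diagonal; μ and σ² are profiled
analytically at each λ (generalized least squares mean, ML variance), and
λ is optimized by bounded scalar search with tolerance 1e-6 on
[0, λ_max], where λ_max is the largest value keeping C(λ) positive
definite (≥ 1 for ultrametric trees, located by bisection up to 1.5).
Boundary candidates are re-checked because flat likelihoods can park the
bounded search mid-interval. p is a χ²(1) likelihood-ratio test against
λ = 0. A 1e-3-step grid search over the same interval serves as the test
oracle, and `phytools::phylosig` as an independent cross-check.

**Blomberg's K** follows the standard ratio form: MSE₀ (deviation from
the phylogenetically corrected mean ā = (1ᵀC⁻¹y)/(1ᵀC⁻¹1)) over the
generalized MSE (C⁻¹-weighted), normalized by the Brownian expectation
(tr C − n/(1ᵀC⁻¹1))/(n − 1), so E[K] = 1 under Brownian motion (verified:
the 100-simulation mean sits in [0.8, 1.2]). The permutation p is the
+1-smoothed fraction of tip shuffles whose generalized error is at most
the observed one (999 permutations by default, matching the order-test
convention). Note that K shrinks rapidly with tree size when λ < 1, so a
K near zero can coexist with a λ̂ near 0.9 on the same data; our
implementation agrees with phytools to four decimals on this regime.

**Order conservatism**: the mean over an order's tips is ranked against
999 shuffles of the whole trait vector; two-tailed
p = 2·min(r_low, r_high)/(n_rand + 1) with inclusive ranks (computed with
a 1e-9 relative tolerance so exact permutation ties count as ties),
capped at 1. Orders under the species threshold (50 by default) are
reported but flagged untested.

## Community metrics

CWD is the basal-area-weighted mean density, B = π(DBH/2)², computed over
matched trees only with renormalized weights — justified by the ≥75%
coverage guarantee rather than imputing unmatched trees. The coverage
rule is strict ("< 75%" excludes), so exactly 0.75 is kept. Latest census
per plot; year ties go to the larger tree count. Richness is rescaled by
Arrhenius species–area scaling S_ref = S_obs (A_ref/A)^z with z = 0.25
(the exponent is configurable because no single value is canonical).
Pixels follow one convention everywhere: north-up, origin top-left,
half-open cells [edge, edge + res); pixel values are unweighted means of
member plots. Basal-area weighting makes CWD invariant to the DBH unit;
pixel-then-global means equal plot-level global means only under equal
per-pixel plot counts (tested both ways).

## Ensemble mapping

The residual correlogram computes binned Moran's I,
I = (n/ΣW)·(Σ w_ij z_i z_j)/(Σ z_i²) with binary distance-bin weights, on
residuals from a thin-plate-spline smoother over standardized coordinates
(+covariates); the null expectation −1/(n − 1) is reported per bin. Any
smooth additive baseline satisfies the contract; the smoother is a
stand-in for a full GAM and is only used diagnostically.

Buffer thinning is random-order greedy acceptance (a point joins the
subsample iff it is > 50 km — great-circle, sphere radius 6,371 km — from
all accepted points), stopping at the target size or exhaustion. Greedy
thinning is O(n·k) and matches the bootstrap spirit; optimal thinning
would be slower and deterministic. Each of the ensemble members draws its
own thinning order and its own hyperparameters: 48 random draws (without
replacement) from a fixed 240-combination random-forest grid
(trees {40…200} × features per split {0.33…1.0} × depth {6…none} × leaf
{1, 3, 5}), scored by k-fold cross-validated R² = 1 − SSE/SST with random
row folds. Folds are split by row, not spatially, because the thinning
already enforces spacing — a documented simplification. The prediction is
the unweighted member mean; uncertainty is the pixel-wise coefficient of
variation with the population (n) standard deviation, deterministic at
small member counts; CV is undefined (NaN, counted) where the mean is
non-positive.

Desk-scale problem sizes used by the tests, the analysis scripts and the
acceptance script: 64×64 landscape, 2,000 plots, 20 members, 8 grid draws
and 5 folds per member, thinned subsamples of ~1,000 points. At these
sizes the ensemble reaches held-out R² ≈ 0.55–0.67 against independent
plots and CV < 5% on effectively all pixels.

## Extrapolation screening

PCA on the standardized training covariates (SVD of the z-scored matrix,
i.e. the correlation structure); k is the smallest number of leading
components whose cumulative explained variance exceeds 90%; one 2-D
convex hull per component pair (k(k−1)/2 hulls; a lone component
degenerates to its interval). Pixels are projected with the training
centering/scaling/eigenvectors and tested against every hull by
half-plane membership with boundary counted as inside (tolerance 1e-9) —
conservative toward interpolation. A pixel is "interpolation" when inside
at least 95% of the hulls; the global summary also reports the share of
pixels so flagged, covering both readings of a coverage threshold.

## Drivers

Screening is two-stage: complete-linkage hierarchical clustering on
1 − |r| merges near-duplicates (|r| > 0.95, first column kept), then the
highest-VIF predictor is dropped iteratively until all VIF < 5. The
importance bootstrap draws one observation per occupied 0.25° cell,
splits 70/30, fits a random forest on the training side and computes
permutation importance on the held-out side (honest "decrease in
accuracy", 3 repeats), and in parallel fits OLS on z-scored response and
predictors for standardized partial-regression coefficients; means, sds
and top-1 counts aggregate over 100 bootstraps.

The partition tree fits response ~ disturbance (2 parameters) per node,
scans an interior decile grid of thresholds per candidate covariate
(O(n log n) rather than exhaustive; grid density configurable), takes the
(covariate, threshold) pair minimizing the two-child SSE, and accepts the
split iff the F statistic [(SSE_pooled − SSE_split)/2]/[SSE_split/(n − 4)]
clears a Bonferroni-adjusted (×|candidates|) p ≤ 0.01 and both children
hold the minimum node size (max(500, 3% of n) by default; smaller floors
are used at desk scale). The F-test-plus-Bonferroni combination is this
package's documented stand-in for published parameter-instability tests;
under a homogeneous-slope null the false-split rate stays below the
adjusted α in simulation. Note that when the response carries a strong
smooth trend in a candidate covariate, intercept instability is genuine
context dependence and the tree will legitimately split on it; the
slope-reversal recovery checks therefore use a flat-intercept planted
design.

## Biomass

Per pixel: stem = CWD × GSV (g cm⁻³ ≡ t m⁻³, so the product is t ha⁻¹);
aboveground = stem × BEF(biome); total = aboveground/(1 − RMF); carbon =
mass × 0.5 by default (the biomass→carbon fraction is configurable
because no single conversion is canonical). The shipped BEF table
(boreal 1.45, temperate 1.35, tropical 1.30, dryland 1.40) is a
documented placeholder keyed to the synthetic biome codes; all
calibration math is BEF-agnostic or uses explicit toy values. Global
totals integrate t ha⁻¹ over spherical pixel areas
(R² Δλ (sin φ₁ − sin φ₂), authalic radius 6,371.007 km) and convert to
GtC. Because total biomass is linear in CWD pixel-wise, the
constant-density percent difference reduces exactly to
(constant/CWD − 1)×100, which doubles as an internal oracle; the
counterfactual holds GSV, BEF and RMF fixed and swaps only the density
map, isolating the contribution of spatial density variation.

## I/O and numerical conventions

Rasters are single-band ESRI ASCII grids (plain text) on a shared WGS84
north-up lattice with one nodata sentinel (−9999) and repr-precision
floats, giving bit-exact round trips; TSVs are written with %.17g floats
and read with round-trip parsing. Newick uses plain unquoted labels with
underscores preserved. Degenerate inputs fail loudly and early: constant
traits, zero basal area, singular covariances (with a jitter suggestion),
RMF ≥ 1, unknown biome codes (masked and counted), empty trait tables.

## Known limitations

- The buffer thinning accepts the first random feasible set; member
  subsamples overlap heavily when few points satisfy the spacing, which
  narrows ensemble spread (CV understates uncertainty in that regime).
- The nested variance estimator can truncate aggressively when a level is
  nearly empty; REML would borrow strength but needs iterative fitting.
- The partition tree's decile grid cannot place a threshold between
  deciles; recovery is only guaranteed to grid resolution.
- The smooth-baseline correlogram depends on the smoothing penalty; an
  over-flexible baseline absorbs genuine short-range structure.
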