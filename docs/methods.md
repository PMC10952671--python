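# Methods

This note documents the models, the synthetic community generator, the
numerical choices and the known limitations of `treedom`.

## Dominance ranking

Within a habitat, counts are converted to within-plot relative abundances
p_ij = n_ij / n_j; plots emptied by the identification filter are dropped
before any computation. The accumulated relative abundance d_i = Σ_j p_ij
sums over species to D = number of plots exactly, which the tests use as a
conservation check. Dominants are the minimal prefix of the d-ranked
species list whose cumulative share reaches the threshold (default 50%);
the species whose inclusion first reaches the threshold is included. Ties
in d_i break by species name (stable mergesort), so dominant sets are
independent of input order. The threshold sweep (50–100%) reuses one
ranking and takes prefixes, which guarantees nestedness by construction.

Quartile classification of dominants uses sample quantiles with linear
interpolation, computed among the dominants of the habitat only; values
exactly on a boundary go to the lower quartile (right-closed intervals).
Class = 4·(abundance quartile − 1) + frequency quartile, so class 16 is
the high-abundance/high-frequency "oligarch" corner. With fewer than four
dominants the classification is skipped with a warning rather than
producing degenerate quartiles.

Mean local abundance averages p_ij over occupied plots only; zeros are
excluded. This matters: including absences would conflate the two axes of
the classification (a species' thinness and its rarity).

## Beta regression

Bounded responses are modelled as Beta(μφ, (1−μ)φ) with logit(μ) = Xβ and
a single precision φ estimated by maximum likelihood
(`statsmodels.othermod.betareg.BetaModel`; quasi-Newton from the default
start). Responses that touch 0 or 1 — mean local abundance is exactly 1
for a monodominant single-plot species — are compressed by
y′ = (y(n−1) + 0.5)/n, the standard boundary adjustment; interior values
move by at most 1/(2n). The candidate set for a response on one continuous
predictor is {intercept, x, habitat, x + habitat, x × habitat}; models are
ranked by AIC and flagged "no support" at ΔAIC > 2. One pooled model with
a habitat factor is the default (per-habitat simple fits are also
reported); per-habitat slopes of an interaction fit are the main effect
plus the habitat's interaction coefficient. Prediction bands use the delta
method on the linear predictor; if the Hessian is singular the point
predictions are kept and the bands are NaN. Species are weighted equally
regardless of occupancy.

The threshold-sweep slope trajectory refits abundance ~ frequency on each
threshold's species set and records the slope sign; fit failures become
gaps ("?"), never aborts, and sets with fewer than four species are
skipped.

## Spatial aggregation

Counts are standardized to the smallest plot area in the habitat,
count′ = round(n_ij · A_min / A_j) with half-up rounding; counts can round
to zero. The NB dispersion k is then estimated by profile maximum
likelihood: the NB mean MLE is the sample mean for any k, so the fit is a
bounded Brent search on log k (tolerance 1e−10), started conceptually at
the moment estimator m²/(s² − m). When the sample variance does not exceed
the mean, k is capped at 1e6 and labelled the Poisson limit. The default
estimate includes all plots of the habitat — absences carry aggregation
information — and is switchable (`include_zeros=False`). Note that the
zero-inclusive estimate on standardized counts reflects occupancy at least
as much as within-stand clumping: a count histogram is invariant to the
spatial arrangement of the plots, and min-area rounding crushes small
counts. This is why the truth-recovery comparison (below) uses a
conditional protocol instead.

The co-dominance index F_i,jk = (n_ij/N_j)(n_ik/N_k) is computed for all
unordered plot pairs, including pairs where the species is absent
(F = 0); excluding them is available as an option. F against pair distance
is smoothed with a local-linear smoother whose span is chosen by 5-fold
cross-validation over {0.2, 0.35, 0.5, 0.75} (span selection subsamples at
most 4000 pairs; the backend is statsmodels lowess, the contract a
data-driven-span, interpolating nonparametric smoother; a fixed span of
0.3 is the fallback when CV is degenerate). Curves are evaluated on 100
grid points between the 1st and 99th percentile of pair distances (tails
trimmed to avoid extrapolation), floored at zero, and relativized by
dividing each species' curve by the column sum at each grid distance;
distances where every species' smoothed F is zero are masked. Curves are
computed for dominants by default, configurable to all species. With
fewer than 10 pairs, unsmoothed binned means are returned with a warning.

Great-circle distances use the haversine formula with the IUGG mean Earth
radius (6371.0088 km). The grid for subsampling lives in a Lambert
cylindrical equal-area projection centred on the data centroid — cells in
degree space would shrink with latitude — with the origin at the projected
bounding-box minimum and half-open cell edges (a plot exactly on an edge
goes to the increasing side). One grid covers the whole study window;
habitats filter occupied cells afterwards. Each subsample replicate draws
one plot uniformly per occupied cell from an independent child stream of
the master seed, so any replicate is individually reproducible.

## Synthetic communities

The generator emulates the structure of a western-Amazonian plot network:
four habitat strata with plot counts 383/54/35/31 (503 total), plot areas
concentrated at 0.1 ha within 0.025–0.213 ha (72% / 26.6% / 1.4% mixture),
Thomas-process plot locations (uniform parents, Gaussian offspring, per-
habitat extents of 1200/800/500/500 km sharing an origin so habitats
intersperse), back-projected to WGS84 around (−6°, −73°).

Species' occupancy φ and conditional abundance a (stems per 0.1 ha where
present) are drawn from a bivariate lognormal parameterized through the
dominance mass m = φ·a: log m ~ Normal(log m₀, σ_m²) with σ_m = 1.1 fixes
the shape of the rank-abundance distribution independently of the
trade-off dial, and an orthogonal component U splits log m between the two
axes so that corr(log φ, log a) = ρ exactly. The median mass m₀ is scaled
per habitat so a 0.1-ha plot holds ≈160 stems regardless of richness
(realistic stem density for stems ≥2.5 cm). The log (rather than logit)
occupancy margin keeps the product decomposition exact; the two are
nearly identical below φ ≈ 0.5, and φ is clipped to [0.005, 0.95].

Why this parameterization: dominance selects species by the product φ·a,
and selecting on a product truncates the joint distribution along the
correlation axis (Berkson's effect). Under a positive pool correlation the
dominant subset's correlation collapses toward zero or below — which is
precisely the empirical phenomenon in western-Amazonian inventories, where
the full dataset shows a positive abundance–occupancy relationship but
dominants show a strong negative one. Fixing Var(log m) rather than the
per-axis variances keeps this selection effect stable as ρ varies, and
recovery of the trade-off direction is therefore defined on the full
community (the 100%-threshold fit), where the dial is expressed; among
dominants the fitted slope is negative under the default ρ = −0.8, and
remains negative even under ρ = +0.8 — by design, not by accident.

Occupancy is realized by spatial thinning: each species has a cluster
centre near a random plot, plots are occupied with probability
proportional to exp(−d/range) normalized to the target occupancy, and the
range grows with k (40–290 km), so strongly clumped species occupy
short-range clusters. Counts in occupied plots are NB(a · area/0.1 ha, k)
floored at 1 (occupied means at least one stem); k is log-uniform on
(0.05, 2). A background pool of rare species tops plots up to 20 stems so
relative abundances are well defined, and per-plot fractions of 14%
morphospecies plus 3% cf./aff. individuals are added for the
identification filter to remove (matching the removal scale the filter
reports on real inventories). Planted archetypes sit at z-score corners of
the pool's margins (oligarch: +2σ on both axes, k = 0.5; local dominant:
+2σ abundance, −0.7σ occupancy, k = 0.08; widespread: the mirror image,
k = 3), one oligarch and two of each other type per habitat.

The two-tier configuration (`sign_flip_config`) gives the abundant eighth
of the pool a strong trade-off (ρ = −0.9) and the rare tail a positive
coupling (ρ = +0.9, lower mass), producing threshold-sweep trajectories
that are negative at 50% and flip positive at intermediate thresholds in
every habitat.

What the generator does **not** emulate: taxonomic error structure beyond
the removal fractions, within-plot stem coordinates, habitat-specific
species sharing (pools are independent per habitat), environmental
gradients, and any forest dynamics. Passing recovery tests therefore show
the pipeline recovers planted structure of this kind, not that real
communities satisfy the generator's assumptions.

## Truth recovery protocol

Spearman correlation between estimated and generating k uses raw counts in
occupied plots of the modal area (0.1 ha), restricted to species with ≥20
occupied plots and mean count ≥2 — the generating k parameterizes count
dispersion where the species is present, so zero-inclusive or area-rescaled
estimates are not comparable to it (typical recovery ≈ 0.6–0.75 in the
383-plot habitat). Oligarch recovery counts planted oligarchs landing in
quartile classes {11, 12, 15, 16}. Slope-sign agreement compares the
full-community beta-regression slope per habitat with sign(ρ).

## Problem sizes and determinism

Default analyses run the full 503-plot network; the test suite uses the
same defaults except for pipeline smoke tests, which shrink the landscape
to ~130 plots. All randomness flows from integer seeds through
`numpy.random.SeedSequence`; replicate streams are spawned children, so
results are reproducible end to end and byte-identical across reruns of
the same configuration.

## Known limitations

- The 50% dominance cut is sensitive to evenness: habitats with steep
  rank-abundance curves yield few dominants, and quartile classes are then
  coarse.
- The zero-inclusive k estimate conflates occupancy and clumping (see
  above); treat it as the field's conventional summary, not as an estimate
  of within-stand dispersion.
- Beta-regression prediction bands are delta-method approximations and can
  be unavailable when the Hessian is singular (flagged, not fatal).
- The lowess-backed smoother can overshoot locally near range edges; only
  the zero floor is enforced, and relativized values are renormalized
  afterwards by construction.
- Exact reproduction of any particular field study's numbers requires that
  study's data; the package reproduces the analysis, and its synthetic
  defaults reproduce the qualitative pattern structure (dominant counts of
  order 10–100 per habitat, trade-off signs, sign-flip thresholds,
  short-range F_rel peaks for local dominants).
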