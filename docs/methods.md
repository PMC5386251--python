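# Methods

This note documents the statistical procedures implemented in `varzea`,
their assumptions, the parameters that matter, and the design choices made
where several reasonable conventions exist.

## Data model

The ingestion format is a long table of (site, species, abundance) records.
Abundance is a positive real, because some source inventories report
importance values rather than stem counts; every operation that needs an
integer individual count (Fisher's alpha, rarefaction by individuals) rounds
half-to-even and logs a warning. Species names are normalized to
`Genus epithet` (case, whitespace, underscores), and obviously non-binomial
determinations are excluded by a configurable regular-expression list
(default: single tokens, `sp./spp.`, `indet`, `cf.`, `aff.`). Taxonomic
synonym resolution is deliberately out of scope: a user-supplied
two-column synonym map is applied after normalization, nothing is resolved
online. Genera are parsed as the first token of the binomial; family counts
require a user-supplied genus→family map and are otherwise reported as
unavailable rather than guessed.

## Dissimilarity

Inventory compilations mix surveys with very different sampling effort, and
most pairwise dissimilarity coefficients are biased upward under partial
sampling. Both implemented metrics therefore use incidence only:

* Forbes F′ similarity `a(n+√n) / (a(n+√n) + 1.5·b·c)`, `n = a+b+c`, where
  `a, b, c` are the shared/unique species counts of a site pair. The package
  standardizes on the **dissimilarity** `1 − F′` everywhere (matrices,
  clustering, ordination); nested pairs score 0, disjoint pairs 1, and a
  pair with an empty site is an error rather than a silent 0/0.
* Simpson turnover `min(b,c) / (a + min(b,c))`, insensitive to richness
  differences.

Matrix association is summarized by plain Pearson r over the strictly lower
triangle (a Mantel permutation test is available as an optional extra but is
not the default, since a single correlation is the quantity of interest).

## Clustering and ordination

* **Ward clustering**: the default is the squared-dissimilarity convention
  (`ward.D2` in the hclust vocabulary, what `scipy`'s `ward` implements);
  the raw-dissimilarity variant (`ward.D`) is exposed as an option because
  compilations in this literature do not always say which was used. Cut
  clusters are matched to reference biome labels by modal label; a site is
  "mismatched" when its cluster's modal label is not its own. The number of
  groups is chosen by maximizing the adjusted Rand index against the
  reference labels (chance-corrected, standard), ties going to the smallest
  k.
* **PCoA**: Gower double-centering of −½D², full eigendecomposition.
  Negative eigenvalues (expected for non-Euclidean incidence metrics) are
  reported, not corrected; the proportion of variation per axis is
  λᵢ / Σ(positive λ). No Cailliez/Lingoes correction by default — that is
  the convention of the ordination software family most community-ecology
  compilations use, and it keeps axis percentages comparable with them.
* **NMDS**: Kruskal stress-1 minimized by non-metric majorization (SMACOF
  with isotonic disparities), 20 random starts plus one PCoA-seeded start,
  tolerance 1e−7, at most 500 iterations, seed required. The reported
  stress is always recomputed from the returned coordinates with a fresh
  isotonic regression (ties in the dissimilarities pooled — the secondary
  tie treatment), so it cannot drift from the optimizer's internal scaling.
  The first NMDS dimension is rigidly rotated to the primary PCoA axis; the
  rotation maximizes the correlation of dimension 1 with the reference
  scores, whose optimizing direction is the least-squares coefficient vector
  of the reference on the coordinates.
* **Climate vectors**: variables are first passed through a greedy
  collinearity filter (drop if |r| > 0.7 with an already-retained variable,
  visiting in a user-controlled priority order). Each retained variable is
  centered, unit-scaled and regressed on the ordination coordinates; the
  fitted direction is the normalized coefficient vector, r² its goodness of
  fit, and significance is a permutation tail probability (default 999
  permutations, α = 0.05, seeded; exact enumeration available for tiny n).

## Fisher's alpha and regional diversity

Fisher's alpha is the parameter of Fisher's log-series, defined implicitly
by `S = α·ln(1 + N/α)`. The root is bracketed and solved to a residual
below 1e−10; `S = N` (every individual a distinct species) has no finite
root and is flagged undefined rather than truncated. Undefined-alpha sites
are excluded from alpha-based models with a logged count; the exclusion
rule is configurable. Note the index derives from the log-series
species-abundance law — it is robust in practice when abundances are
roughly log-normal, but the log-series is what makes α a true parameter,
and the synthetic generator uses the log-series for exactly that reason.

Regional (gamma) richness is compared two ways:

* **Size-based accumulation**: repeated random orderings of sites without
  replacement (default 10 curves), reported as the per-effort mean with the
  min/max envelope; the analytic expectation over all orderings
  (`E[S(k)] = Σᵢ (1 − C(T−Yᵢ,k)/C(T,k))`) is available as the `exact` mode.
  The effort axis can be rescaled from sites to individuals by the biome's
  mean stems per site, since stem density differs systematically among
  biomes.
* **Coverage-based rarefaction/extrapolation** from incidence frequencies
  (T sampling units, Yᵢ incidence counts, U = ΣYᵢ, Q₁ uniques, Q₂
  duplicates). Sample coverage at full effort is
  `Ĉ = 1 − (Q₁/U)·[(T−1)Q₁ / ((T−1)Q₁ + 2Q₂)]`; the coverage *deficit*
  1 − Ĉ is the chance that the next incidence belongs to an unseen species.
  Interpolated richness uses the exact hypergeometric expectation;
  interpolated coverage uses the Good–Turing form with denominator
  C(T−1, t), which is continuous with Ĉ at t = T. Extrapolation follows the
  Chao-type asymptote `S_obs + Q̂₀(1 − (1 − Q₁/(Q₁+T·Q̂₀))^{t−T})` with
  `Q̂₀ = ((T−1)/T)·Q₁²/(2Q₂)` (bias-corrected `Q₁(Q₁−1)/2` fallback, with a
  warning, when Q₂ = 0), bounded at 2T sampling units by default.
  Interpolated values are validated against exhaustive/Monte-Carlo
  subsampling oracles in the test suite rather than trusted as transcribed.

## Quantile regression of diversity on climate

Site diversity in inventory compilations is strongly right-skewed and
shaped by many unrecorded local factors (flooding, succession, soils), so
conditional *means* say little; the package models the whole conditional
distribution. For each climate covariate separately (no multivariable fits,
no multiple-testing correction across the four covariates — each fit is
reported on its own), the conditional τ-quantile of alpha is a line whose
coefficients minimize the pinball loss. The minimization is solved exactly
as a linear program (HiGHS); the τ = 0.5 case is least-absolute-deviation
regression and is cross-checked against an independent IRLS solver in the
tests. The response is raw alpha by default with a log-alpha switch;
biome-level mean comparisons use natural-log alpha (one-way ANOVA,
Tukey–Kramer for unequal n, compact letters by greedy insertion over the
non-significant pair graph).

Standard errors and 95% intervals come from an xy-pair bootstrap
(default B = 1000, seeded; pair resampling is robust to the
heteroskedasticity that motivates quantile regression in the first place).
Degenerate resamples with a constant covariate are redrawn and counted.

The quantile process (default grid τ = 0.01…0.99 in steps of 0.01, no
smoothing across τ) can be inverted into a conditional density at any
covariate value: f ≈ Δτ/ΔQ at grid midpoints, after monotone rearrangement
(sorting) whenever fitted quantiles cross — rearrangement guarantees a
valid density without changing any fitted quantile marginally. Zero-width
steps are skipped with a warning; trapezoid integrals are expected within
[0.95, 1.05] of unity and are verified against the Normal closed form in
the tests. Headline fits use τ ∈ {0.1, 0.3, 0.5, 0.7, 0.9}.

A paired-t utility supports sensitivity analyses of sampling protocol
(e.g. minimum-diameter cutoffs) on matched site sets.

## Synthetic metacommunity generator

The generator produces data with exactly the statistical structure the
analysis assumes, plus full ground truth, so every stage can be tested for
parameter recovery without any external data.

* **Species pools**: per-biome pools with controlled pairwise overlap.
  Each requested overlap is realized as a block of species shared by exactly
  that pair (shared count = round(overlap × smaller pool)); the remainder is
  biome-exclusive. Overlap systems whose implied shared totals exceed a pool
  are rejected as infeasible. Species shared by three or more biomes are not
  generated (except in the degenerate full-overlap case); the contract is
  pairwise intersections, realized within ±1 species.
* **Site communities**: a Hoppe-urn draw in which individual i founds a new
  species with probability α/(α+i) and otherwise joins the species of a
  uniformly chosen earlier individual. This is the sequential representation
  of log-series sampling: the expected species count is Σ_{i<N} α/(α+i) ≈
  α·ln(1+N/α), the abundance law converges to Fisher's log-series with
  x = N/(N+α), the total is exactly N, and α is the *true* parameter — the
  estimator recovers it with relative bias well under 5% at N ≥ 5000. An
  alternative construction (independent logarithmic relative abundances
  followed by a multinomial) loses a large share of expected singletons to
  multinomial zeros and biases richness down ~8%, which is why the urn is
  used. The dataset generator additionally caps species founding at the pool
  size (a finite-pool urn) so extreme sites cannot exhaust their regional
  pool; direct calls raise instead.
* **Climate**: per-biome Gaussian draws (means and spreads default to
  published climate averages of the five Brazilian biomes: mean annual
  temperature in °C, precipitation in mm/yr, precipitation seasonality CV%,
  temperature seasonality sd×100, consecutive dry months), truncated at
  ±3 sd so the support is bounded.
* **Site diversity law**: alpha = exp(μ₀ + σ₀·Φ⁻¹(u)) for latent quantile
  u ~ U(0,1) — a right-skewed log-normal base (defaults μ₀ = ln 12,
  σ₀ = 0.55) — plus, only above the threshold τ₀ = 0.8, an additive climate
  shift `(u−τ₀)/(1−τ₀) · Σⱼ βⱼ(xⱼ − refⱼ)`. The reference refⱼ is anchored
  at the *edge* of the climate support (minimum for positive slopes,
  maximum for negative), making the shift non-negative everywhere; this
  keeps the site law monotone in u, so the stated βⱼ are exactly the
  conditional-quantile slopes: slope(τ) = max(0, (τ−τ₀)/(1−τ₀))·βⱼ — zero
  through the 80th percentile, rising linearly above. Default slopes couple
  diversity positively to temperature and rainfall and negatively to both
  seasonalities. Randomness flows from one global seed through named
  substreams (climate, site sizes, latent quantiles, communities), so any
  stage reproduces in isolation.

What the generator does *not* emulate: spatial autocorrelation, dispersal,
flood-pulse mechanics, habitat subtypes within biomes, taxonomic error, or
species shared by 3+ biomes. Passing recovery tests therefore show that the
estimators are correct under the model's assumptions — not that real
wetland data satisfy those assumptions.

## Problem sizes and numerical choices

The default synthetic system is 196 sites in five biomes (63/58/50/12/13)
with log-normal stems per site (biome means ≈ 1330/1590/1170/680/1440), a
scale at which the full pipeline — generation, both dissimilarity matrices,
clustering, PCoA, seeded multi-start NMDS, rarefaction, coverage, quantile
fits with bootstrap — completes in about a minute on one core. Tests use a
scaled 3-biome system (30 sites) for speed, with replicate counts (40
generator replicates, B = 100–200 bootstrap, 150-replicate coverage
simulations) chosen to keep binomial noise well inside the asserted bands.
Root solving brackets α in [1e−8, 1e8] with outward expansion. Quantile LP
fits are deterministic; NMDS, permutation tests, bootstrap and curve
resampling all require explicit seeds and refuse to run without one.

## Known limitations

* Forbes F′ is undefined when a site is empty; empty sites cannot occur in
  a valid community table, but the error surface exists for direct calls.
* The compact-letter display uses greedy insertion; for pathological
  non-significance graphs it can use more letters than the minimum, though
  the sharing semantics (no shared letter ⇔ significantly different) always
  hold.
* Percentile-bootstrap intervals for extreme quantiles (τ near the coupling
  threshold of the generator) are noticeably noisy at B = 100; B ≥ 200 is
  recommended for τ = 0.9 and is the default in the reproduction script.
* Coverage-based extrapolation inherits the Chao estimator's downward bias
  when rare-species information (Q₁, Q₂) is thin.
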