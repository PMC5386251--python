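# varzea

Diversity and composition statistics for compilations of forest-inventory
data — the kind of analysis used to ask how tree communities (for example,
Brazilian freshwater wetland forests spanning the Amazon, Atlantic Forest,
Cerrado, Caatinga and Pampas biomes) change in composition and diversity
along climatic gradients, when the underlying inventories come from many
research teams with heterogeneous sampling effort.

It is aimed at community ecologists and biogeographers working with
long-format site × species abundance tables plus per-site climate covariates.
The same machinery (incidence-based dissimilarity, coverage-based
rarefaction, quantile regression) applies directly to microbiome and
metagenomic sample-by-taxon tables.

## What it computes

* **Compositional dissimilarity** on presence–absence data, robust to
  partial sampling: the Forbes F′ index,
  `F' = a(n+√n) / (a(n+√n) + 3/2·b·c)` with `n = a+b+c` (returned as the
  dissimilarity `1 − F'`), and Simpson turnover
  `β_sim = min(b,c) / (a + min(b,c))`.
* **Structure**: Ward clustering with reference-label matching and
  adjusted-Rand `k` selection, PCoA (Gower centering, negative eigenvalues
  reported, proportions over positive eigenvalues), NMDS (Kruskal stress-1 by
  non-metric majorization, multi-start + PCoA seed), and fitted climate
  vectors with permutation significance after an `|r| > 0.7` collinearity
  filter.
* **Alpha and gamma diversity**: Fisher's log-series alpha, the root of
  `S = α·ln(1 + N/α)`; random and analytic species-accumulation curves with
  rescaling of effort to individuals; coverage-based
  rarefaction/extrapolation for incidence data, with the sample-coverage
  estimator `Ĉ = 1 − (Q₁/U)·[(T−1)Q₁ / ((T−1)Q₁ + 2Q₂)]` and Chao-type
  extrapolation; species biome-occupancy tables.
* **Diversity–climate models**: exact linear quantile regression (pinball
  loss via LP) of Fisher's alpha on climate covariates, xy-pair bootstrap
  CIs, conditional densities inverted from the quantile process (with
  monotone rearrangement), one-way ANOVA + Tukey–Kramer on log alpha with a
  compact letter display, and a paired *t* utility for sampling-protocol
  sensitivity checks.
* **A synthetic metacommunity generator** with biome-structured species
  pools of controlled pairwise overlap, log-series site communities (Fisher's
  alpha is the true parameter), per-biome Gaussian climate, and right-skewed
  site diversity whose *upper* conditional quantiles shift linearly with
  climate — with full ground truth for recovery testing.

## Worked example

```python
from varzea.simulate import default_config, generate_dataset
from varzea import betadiv, structure, alphadiv, quantreg

ds = generate_dataset(default_config(seed=1))          # 196 sites, 5 biomes
d = betadiv.dissimilarity_matrix(ds.community, "forbes")
d2 = betadiv.dissimilarity_matrix(ds.community, "simpson")
print(round(betadiv.matrix_correlation(d, d2), 3))     # 0.984

tree = structure.ward_cluster(d)
best_k, _ = structure.select_k(tree, ds.metadata.biome_of(), range(2, 9))
match = structure.cut_and_match(tree, best_k, ds.metadata.biome_of())
print(best_k, round(match.mismatch_overall, 3))        # 5 0.0

alphas = alphadiv.alpha_records(ds.summary.df)
m = alphas.merge(ds.metadata.df[["site_id", "mat"]], on="site_id").dropna()
for tau in (0.1, 0.9):
    print(tau, round(quantreg.quantile_fit(m["alpha"], m["mat"], tau).slope, 2))
# 0.1 -0.04
# 0.9 1.52
```

The Forbes and Simpson matrices agree almost perfectly (r = 0.984), Ward
clustering recovers the five biomes at k = 5 with no sites mismatched, and
the quantile fits show the generator's signature pattern: diversity is
nearly unrelated to temperature at the 10th percentile but clearly related
at the 90th — climate constrains *maximal*, not typical, site diversity.

A `varzea` command-line interface wraps the same functions
(`simulate | dissim | cluster | ordinate | alpha | rarefy | occupancy |
quantreg | run | validate`); `varzea run config.yaml` executes the whole
pipeline from a YAML configuration and writes every table to an output
directory.

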