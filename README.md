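# morphodist

Multivariate resemblance and permutation inference for mixed-scale artefact
attribute data, built for lithic flake morphometrics.

Archaeological flake assemblages are routinely recorded with attribute
protocols that mix measurement scales: calliper dimensions and angles
(continuous), expression grades such as bulb development (ordinal), and
categorical states such as raw material or platform type (nominal) — with
plenty of missing cells, since broken flakes cannot be measured completely.
`morphodist` quantifies morphological resemblance among such objects and
tests whether groups (e.g. successive cultural phases at one site) differ in
multivariate centroid position and in within-group dispersion.

## Method

The core resemblance procedure combines multiple imputation with mixed-data
PCA and Mahalanobis-type distances:

1. **Imputation.** Each missing cell is filled with a random draw from that
   variable's observed empirical distribution, repeated *m* times
   (default *m* = 1000) to produce differently completed tables.
2. **Mixed-data PCA.** Each completed table is encoded (continuous and
   ordinal-rank columns z-scored; nominal categories as centred indicators
   weighted by 1/√*p<sub>k</sub>*, the FAMD convention) and
   eigen-decomposed into uncorrelated PCs.
3. **Distances.** For each completed table, the inter-individual distance is
   Euclidean over variance-standardised PC scores — the Mahalanobis distance
   in encoded space over the retained components.
4. **Combination.** The *m* distance matrices are combined per pair into a
   median matrix with 95% percentile bounds (the interval width reflects
   imputation uncertainty); each object's *m* PC1/PC2 positions (sign- and
   Procrustes-aligned across imputations) are averaged into a centroid with
   a 95% confidence ellipse for plotting.

Before analysis, the five geometry measurements (length, width, thickness,
platform width, platform thickness) can be converted to scale-free **shape
variables** by dividing each by the per-flake geometric mean, and records
are filtered to a configurable missingness cap (default 20%, i.e. at most
3 of 16 attributes missing).

Group differences are tested on the median distance matrix:

- **PERMANOVA** partitions the total sum of squared distances,
  SS<sub>T</sub> = SS<sub>A</sub> + SS<sub>W</sub>, and compares groups with
  the pseudo-F statistic
  *F* = (SS<sub>A</sub>/(a−1)) / (SS<sub>W</sub>/(N−a)), with
  *R*² = SS<sub>A</sub>/SS<sub>T</sub> and a permutation p-value
  (*b*+1)/(*m*+1).
- **PERMDISP** (multivariate Levene analog) embeds the distances by
  principal coordinates, measures each object's distance to its group
  centroid (imaginary-axis corrected), and F-tests those distances with
  permutation significance.

Pairwise contrasts are balanced by random down-sampling of the larger group
and Bonferroni-corrected. Variable associations are summarised by a
heterogeneous correlation matrix (Pearson / polychoric / tetrachoric /
polyserial / biserial by scale, two-step latent-Gaussian estimation,
pairwise deletion).

A synthetic-assemblage generator with a shared latent Gaussian space,
phase-graded mean shifts, per-phase dispersion multipliers and MCAR
missingness makes every stage testable with known ground truth.

## Worked example

```python
import morphodist as md

cfg = md.SimulationConfig(n_per_group=60, missing_rate=0.10, seed=1)
table, truth = md.simulate_assemblage(cfg)
table = md.to_shape_variables(md.filter_flakes(table))

dist, ordn = md.run_flexdist(table, cfg=md.AnalysisConfig(n_iterations=50, seed=1))
print("PC1+PC2 variance: %.1f%%" % ordn.variance_pct[:2].sum())
print("mean 95%% CI width of pairwise distances: %.2f" % dist.mean_ci_width())

tests = md.pairwise_tests(dist.median, table.group.to_numpy(), n_perm=199, seed=1)
print(tests[["pair", "test", "n", "F", "R2", "p", "significant"]].round(4).to_string(index=False))
```

prints (abridged):

```
PC1+PC2 variance: 11.8%
mean 95% CI width of pairwise distances: 1.73
   pair      test   n      F     R2     p  significant
1 vs. 2 permanova 110 0.9634 0.0088 0.535        False
1 vs. 4 permanova 110 2.0442 0.0186 0.005         True
2 vs. 4 permanova 110 1.5646 0.0143 0.005         True
...
```

The simulated sequence carries a graded latent shift between phases, so the
most separated pair (1 vs. 4) shows the largest *R*² and a significant
PERMANOVA after Bonferroni correction, while adjacent phases at this sample
size do not — the p-value floor with 199 permutations is 1/200 = 0.005.

The same analysis runs from the shell:

```sh
morphodist simulate --n-per-group 60 --missing-rate 0.1 --seed 1 --out synth.csv
morphodist run --input synth.csv --variant main --fast --seed 1 --out results/
morphodist report results/
```

`run` supports the sensitivity variants `complete_cases`,
`no_size_correction`, `exclude_raw_material`, `dolerite_only` and
`group_by_raw_material` next to `main`.

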