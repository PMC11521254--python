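# cgflow

Renormalization-group-inspired coarse-graining of single-cell transcriptomes.

## The problem

Single-cell RNA-seq yields a cells × genes count matrix with thousands of
correlated gene variables. Standard analyses pick a single scale — cluster
the cells, or project onto a few principal components. `cgflow` instead
treats the genome as a many-body interacting system and tracks how its
statistical structure evolves across a *hierarchy* of scales, in the spirit
of the renormalization group: correlation strength plays the role of
spatial proximity, and coarse-graining reveals mesoscale structure (gene
modules, emergent non-Gaussianity) invisible at single-gene resolution.
It is aimed at computational biologists who want a quantitative, multiscale
description of how correlation structure changes between conditions — for
example between age groups.

## The method

**Normalization.** Counts are modelled as negative binomial,
X<sub>cg</sub> ~ NB(μ<sub>cg</sub>, θ), with the mean estimated analytically
from the margins, μ̂<sub>cg</sub> = (Σ<sub>j</sub>X<sub>cj</sub>)(Σ<sub>i</sub>X<sub>ig</sub>)/Σ<sub>ij</sub>X<sub>ij</sub>,
and converted to Pearson residuals
Z<sub>cg</sub> = (X<sub>cg</sub> − μ̂<sub>cg</sub>)/√(μ̂<sub>cg</sub> + μ̂<sub>cg</sub>²/θ)
with θ = 50 by default. Each gene is then standardized to mean 0, variance 1.

**Real-space flow.** At each depth the gene–gene Pearson correlation matrix
is computed, maximally correlated pairs are greedily matched down the ranked
list, and each pair is replaced by its sum rescaled to unit variance — a
*metagene*, the analogue of a Kadanoff block spin:

    Y(k+1) = Z · (Y_g1(k) + Y_g2(k)),   Z: unit-variance normalizer.

Starting from N genes this yields ⌊N/2^k⌋ metagenes at depth k, iterated
until one variable remains.

**Momentum-space flow.** The correlation matrix C is eigendecomposed,
C v(λ) = λ v(λ), and the data are projected onto the top K* modes with
P̃ = Σ<sub>K≤K*</sub> u(λ<sub>K</sub>)u(λ<sub>K</sub>)ᵀ, progressively
zeroing the loadings of low-variance components.

**Flow statistics.** Each scale is summarized by the spectral gap of the
correlation matrix (max difference of consecutive sorted eigenvalues,
optionally normalized by λ₁), per-variable standardized fourth moments
m₄/m₂² (Gaussian reference 3), sample-size-adjusted Anderson–Darling
normality statistics A\*² = A²(1 + 0.75/n + 2.25/n²), and marginal density
summaries. Baselines come from marginally resampled nulls (per-gene
permutation across cells, destroying all inter-gene correlation) and the
Marchenko–Pastur random-matrix law for the eigenvalue bulk.

## Worked example

Simulate counts with two planted 50-gene correlation blocks among 400 genes
(1000 cells), normalize, and run the real-space flow with a resampled null:

```python
from cgflow import RealSpaceFlow, normalize, simulate

spec = simulate.SyntheticSpec(n_cells=1000, n_genes=400, block_sizes=(50, 50),
                              rho_within=0.8, seed=0)
counts, labels = simulate.generate_block_counts(spec)
expr = normalize.standardize(normalize.pearson_residuals(counts))
res = RealSpaceFlow(expr, max_depth=4).fit(null_replicates=3, null_seed=0)
print(res.summary().round(3))
```

```
       n_variables  spectral_gap  spectral_gap_norm  median_kurtosis  median_AD  AD_reject_5pct  null_median_kurtosis  null_AD_reject_5pct
scale
0              400        21.431              0.668           24.926     75.094             1.0                24.926                  1.0
1              200        14.508              0.706           23.108     55.506             1.0                23.783                  1.0
2              100         9.617              0.801           20.334     39.370             1.0                23.587                  1.0
3               50         5.311              0.705           15.755     26.049             1.0                17.781                  1.0
4               25         2.464              0.483           11.169     15.749             1.0                12.604                  1.0
```

Reading the table: the *normalized* spectral gap climbs from 0.67 to 0.80 as
coarse-graining consolidates the planted blocks, then shrinks once a block
spans only a few metagenes. On the same data with inter-gene correlations
destroyed, the null gap is an order of magnitude smaller at every depth
(`res.null.median_gap_normalized()` → 0.018, 0.030, 0.042, 0.041, 0.059):
the gap is a genuine signature of planted structure, not of the marginals.
Kurtosis and Anderson–Darling columns show heavy-tailed, strongly
non-Gaussian variables at all scales — at depth 0 the null matches the real
data exactly (resampling preserves marginals). Metagene memberships recover
the planted modules: at depth 3 the mean membership purity against the true
block labels is 0.99.

The same analysis runs from the shell:

```bash
cgflow simulate --n-cells 1000 --n-genes 400 --block-sizes 50,50 --seed 0 --out sim/
cgflow normalize sim/matrix.mtx --out expr.tsv
cgflow flow-real expr.tsv --max-depth 4 --null-replicates 3 --out flow/
cgflow compare run_young/ run_old/        # spectral view across groups
```

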