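# Methods note

This note records the generative models, the statistical conventions, the
parameter defaults and why they were chosen, and the limits of what the
simulators emulate. All empirical figures quoted here are computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## 1. Single-EV read generator (`evlink.synthdata.EVPopulationModel`)

Each synthetic EV receives:

1. a number of distinct surface proteins k drawn from a mixture: a point mass
   `p_singleton = 0.62` at k = 1, with the remaining mass a zero-truncated
   negative binomial (r = 6, p = 0.5) shifted to k ≥ 2 and renormalized on
   2..`k_max` (default 20). The mixture puts the non-singleton mode at k = 5
   and >90% of mass on k ≤ 10, reproducing the shape reported for proximity
   barcoding data: most EVs display a single panel protein, and multi-protein
   EVs cluster around a handful of proteins;
2. a uniformly random k-subset of the panel (or a co-occurrence-weighted
   subset when a co-occurrence matrix is supplied: proteins are chosen
   sequentially with weights proportional to the product of their
   co-occurrence with already-chosen proteins);
3. for every (EV, protein) incidence, `1 + Poisson(mean − 1)` reads with
   `reads_per_protein_mean = 3.0`, so every true incidence yields at least one
   read;
4. barcode/ligation noise: `noise_rate/(1 − noise_rate) × T` unit reads (T =
   true read count) placed on (random existing EV, random panel protein)
   pairs, so the expected share of noise reads is `noise_rate`. Default
   `noise_rate = 0.05`; noise that happens to land on a true incidence is
   indistinguishable from signal, so the realized pure-noise share slightly
   undershoots the nominal rate.

With noise on, observed singleton fractions fall well below the planted 0.62
(≈0.39 at the default rate) because spurious proteins promote true singletons
into apparent multi-protein EVs; distribution-level checks therefore use
`noise_rate = 0`.

## 2. Count-matrix QC (`evlink.denoise`)

The chain is: (a) drop EVs displaying strictly more than
`max_proteins_per_ev = 5` distinct proteins (tag-collision suspects); (b) form
the independence expectation E = outer(rowsums, colsums)/N — the only
dimensionally consistent reading of "expected counts from marginal products" —
and the Pearson residual χ = (D − E)/√E; (c) keep cells with χ at or above the
`quantile = 0.95` quantile computed over the *nonzero cells of that sample's
matrix*, then drop emptied rows. Properties that follow by construction and
are verified by tests: sum(E) = sum(D) to 1e-9; χ ≡ 0 for rank-one matrices;
on independence-null data ~5% of nonzero cells survive; re-applying the filter
at the realized cutoff is a no-op.

The quantile population ("nonzero cells") and per-sample thresholds are
deliberate: pooling across samples would let a deep sample set the threshold
for a shallow one, and including structural zeros would make the cutoff depend
on matrix sparsity rather than signal strength.

## 3. EV types and phenotypes (`evlink.evtypes`)

EV types are singletons and unordered pairs of markers. With 12 prioritized
markers, the marker-pairs-only scheme yields 12 + C(12,2) = 78 types; the
marker-vs-panel scheme (every pair containing at least one marker, panel size
113) yields 12×101 + 66 = 1278. Labels are canonical and alphabetical
("EV_A & B"). An EV qualifies for a type if it displays *at least* the type's
markers (default), or exactly them (`exact`). Abundance = qualifying EVs /
total QC-passed EVs in the sample. A zero abundance is a measured zero, not a
missing value.

## 4. Association model (`evlink.assoc`)

Y\* = (Y − μ̂)/σ̂ with the sample (n−1) standard deviation; X\* =
Φ⁻¹((rank − ½)/n) with average ranks on ties. OLS of Y\* on
{1, X\*, sex, age, X\*·sex}, male = 1. Conventions:

- the EV term's effect size is reported as partial R² = t²/(t² + df_resid),
  the squared partial correlation given the covariates (not the semi-partial
  ΔR²);
- 95% CIs use the t distribution with n − 5 df;
- BH-FDR is pooled across the full family by default (`per_analysis`
  optionally restricts the family to one exposure);
- missing data are dropped listwise and the n actually used is reported;
  transforms are applied after deletion.

Simulated traits are generated directly on the standardized scale, so fits of
simulated cohorts set `traits_standardized=True` (or `pre_transformed=True`
for `fit_association`); re-standardizing a generated trait would shrink a
planted β by the trait's realized SD.

## 5. Cohort generator (`evlink.synthdata.CohortModel`)

Defaults: n = 96 individuals, sex ratio 0.5, ages uniform on (40, 75) — a
plausible adult cardiometabolic-cohort window; nothing downstream depends on
the specific endpoints because age enters linearly and the tests verify affine
invariance. Genotypes are Hardy–Weinberg biallelic SNPs with MAF uniform on
`maf_range`, no LD, evenly spaced positions. EV abundance arises from a
unit-variance liability (planted SNP effects on standardized dosages plus
Gaussian residual) mapped through a logistic link, so genetic signal survives
the downstream rank transform. Traits are built on the standardized scale as
β_main·X\* + β_int·X\*·sex + sex/age terms + N(0, `trait_noise_sd`²).

`trait_noise_sd = 2.6` for the planted-effect scenario (β = −1.62): in the
interaction model the X·sex column absorbs roughly half of X's variance at
sex ratio 0.5 (the residual sum of squares of X on the covariates is ≈55, not
≈95, at n = 96), and σ = 2.6 is the noise level at which the planted main
effect carries a partial R² of ≈0.17 — measured median 0.168 over 500
cohorts, with 95% CI coverage 0.944. A naive calculation ignoring that
collinearity suggests σ ≈ 3.5 and realizes partial R² ≈ 0.10.

A complex trait is built from declared per-SNP effects rescaled so the total
heritability equals `complex_trait_h2`; the per-SNP h² truth is recorded and
written alongside the cohort.

## 6. GWAS, SNP sets, enrichment (`evlink.genetics`)

- GWAS phenotype: residuals of abundance on {1, sex, age}, then inverse-normal
  transformed. Per-SNP simple regression in closed form (intercept + dosage,
  df = n − 2); monomorphic SNPs return NaN with a warning. λ_GC = median
  χ²/χ²₀.₅(1). MAF filters are strict (> threshold): 0.05 for general QC, 0.2
  for the small-n EV GWAS where rare-variant tests are hopeless.
- SNP sets: for each marker, the union of SNPs with P < 1e-6 across all pair
  phenotypes containing it, plus one pooled marker-pair set → 13 sets for 12
  markers. Each SNP contributes a flank [pos − 1000, pos + 1001) (0-based
  half-open; +1 kb on each side), intervals are merged, membership is computed
  by binary search, and sets are written as BED.
- Enrichment score = (annotation's share of trait h²)/(annotation's share of
  SNPs), with a delete-one block jackknife SE over 200 contiguous SNP blocks.
  By construction the all-SNP annotation scores exactly 1 and an annotation
  holding all h² on a quarter of SNPs scores exactly 4. In the planted design
  the causal SNPs carry `f` times the average per-SNP h² uniformly, so any
  detected subset of them scores exactly `f` regardless of GWAS power — which
  is what makes the end-to-end recovery test robust at n = 96.
- Bookkeeping helpers: Bonferroni threshold 5e-8/1278 = 3.9e-11 for the
  pairwise scan; 17 univariate traits + 1 multivariate test = 18 P-values per
  gene in gene-level lookups.

## 7. Pipeline (`evlink.pipeline`, `evlink run`)

Eight stages (simulate, parse, denoise, quantify, associate, gwas, snpsets,
enrich) with per-stage seeds spawned from one `SeedSequence`, a JSON manifest
recording parameters, output SHA-256 hashes and counts, pre-flight dependency
validation (fails before any compute), and resume inputs for every stage
boundary. Identical configs produce byte-identical outputs.

## 8. What the generators emulate — and don't

Emulated: the proteins-per-EV distribution shape, barcode noise as a read-level
contamination rate, protein co-occurrence, logistic-link genetic control of EV
abundance, sex/age structure, planted trait effects with interactions, and
per-SNP heritability truth.

Not emulated: PCR amplification bias and read-depth heterogeneity between
samples; linkage disequilibrium, population structure, and relatedness (no
kinship correction is implemented, so λ checks only make sense on unrelated
simulated cohorts); cell-of-origin mixtures; batch effects; genotyping error;
and any real protein biology — panels are labeled P001…P113 and effects are
whatever the configuration plants.

## 9. Numerical conventions

Positions are 0-based half-open internally and converted to 1-based only when
writing VCF. Quantiles use numpy's default (linear interpolation). All seeds
derive from user-facing integer seeds via `SeedSequence`; derived integer
seeds are reduced mod 2³¹. Matrices are stored as dense int arrays in memory
and MatrixMarket + row/column TSVs on disk. Statistical fits delegate to
statsmodels (OLS, BH); the per-SNP GWAS is a vectorized closed form validated
against statsmodels to 1e-10 relative tolerance.

## 10. Limitations

Small-n GWAS (n = 96) has power only for large planted effects; the SNP-set
machinery is validated on planted truth, not on realistic effect-size
distributions. The enrichment SE is a block jackknife over independent SNPs —
with real LD the blocks would need to respect correlation structure. The
association model is a fixed five-parameter design; no covariate selection,
mixed models, or robust SEs are provided.
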