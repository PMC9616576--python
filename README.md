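# evlink

Linking single extracellular-vesicle (EV) surface proteomes to obesity traits
and genetics — a simulation and analysis toolkit.

## The problem

Extracellular vesicles circulate in blood and carry surface proteins inherited
from their cells of origin. Proximity barcoding assays tag every EV and every
surface protein with DNA barcodes, so a sequencing read links one EV to one
protein; millions of reads yield a sparse EV × protein count matrix per
plasma sample. With a 113-protein panel and a subset of 12 prioritized
markers, one can define EV *types* — subpopulations displaying a marker or a
pair of markers — measure each type's abundance per person, and ask:

1. Which EV types associate with obesity traits (BMI, waist circumference,
   waist-hip ratio, body-composition measures) after adjusting for sex and age,
   allowing an exposure-by-sex interaction?
2. Which genetic variants drive EV-type abundances (a GWAS on each pairwise
   phenotype), and is trait heritability enriched near those variants?

`evlink` implements the full chain as a library plus a thin CLI, together with
generative models that simulate the raw data with planted, known truth, so
every statistical step can be validated against the ground truth that produced
its input.

## Core model

For trait Y and EV-type abundance A in a cohort of n individuals:

- Y\* = (Y − μ̂)/σ̂ (sample standard deviation), X\* = Φ⁻¹((rank(A) − ½)/n)
  (rank-based inverse normal transform, average ranks on ties).
- OLS: Y\* = μ + β_EV·X\* + β_sex·sex + β_age·age + β_int·X\*·sex + ε,
  with male = 1. The EV term's partial R² is t²/(t² + df_resid); P-values are
  Benjamini–Hochberg adjusted across the whole family of tests.
- Count-matrix QC ("chi filter"): drop EVs displaying more than 5 proteins,
  form the independence expectation E_ij = r_i·c_j/N from row and column sums,
  compute χ_ij = (D_ij − E_ij)/√E_ij, and keep cells whose residual reaches the
  95th percentile of χ over the nonzero cells of that sample.
- GWAS: abundance residualized on sex and age, inverse-normal transformed,
  then a per-SNP simple linear regression on dosage (closed form, df = n − 2),
  with MAF filtering and genomic-control λ from the median test statistic.
- SNP sets: per marker, the union of SNPs with P < 10⁻⁶ over all pair
  phenotypes containing that marker, plus one pooled marker-pair set; each SNP
  contributes a ±1 kb flank, intervals are merged, and heritability enrichment
  is (share of trait h² in the annotation)/(share of SNPs annotated), with a
  delete-one block-jackknife standard error.

## Worked example

Simulate a single-EV read table and profile it
(`examples/01_simulate_and_profile.py`):

```text
reads emitted: 69756 rows, 191024 total reads
count matrix: 20000 EVs x 113 proteins
singleton fraction: 0.386 (share of EVs showing exactly one protein; the model
plants 0.62 of true singletons, and barcode noise adds spurious extra proteins)
proteins-per-EV histogram (first 5 bins): 1: 7722, 2: 4124, 3: 1529, 4: 1092, 5: 1007
```

Denoise it (`examples/02_denoise.py`):

```text
EVs in: 10000
after protein-count cap (<= 5 proteins): 7411
EVs out: 860
residual cutoff (95th percentile of chi over nonzero cells): 21.147
surviving nonzero-cell fraction: 0.050 (close to 0.05 by construction)
```

Associate EV types with traits in a 96-person cohort carrying one planted
effect of −1.62 on BMI (`examples/03_associations.py`):

```text
exposure      trait   beta_ev       se        p   partial_r2        q
  EV_M01        BMI -1.688653 0.391377 0.000041 1.698305e-01 0.000284
  EV_M01 total_lean -0.595970 0.362448 0.103567 2.885364e-02 0.362483
  EV_M01         WC  0.067073 0.403891 0.868473 3.029658e-04 0.997058

top hit: EV_M01 vs BMI, beta = -1.69 (planted -1.62), partial R^2 = 0.17, q = 2.84e-04
```

Run the full pipeline with planted genetics
(`examples/04_gwas_and_enrichment.py`):

```text
stages run: simulate, parse, denoise, quantify, associate, gwas, snpsets, enrich
median GWAS lambda across EV phenotypes: 0.987 (near 1 = calibrated)
SNP-set sizes: {"P001": 6, "P002": 7, "P003": 8, "P004": 5, "marker_pairs": 13}
  annotation  score       se
        P001    3.0 0.062815
marker_pairs    3.0 0.062815
```

The generative truth concentrates 3× the average per-SNP heritability on the
EV-causal SNPs, and the recovered enrichment scores are 3.0 within the
jackknife standard errors.

The same pipeline is exposed as a CLI:

```bash
evlink run --out demo_run --seed 4        # default demonstration scenario
evlink run --config my_run.yaml           # or a declarative YAML config
evlink denoise --in matrix_s1 --out clean_s1 --panel-size 113
```

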