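"""Genetics of EV phenotypes: GWAS preparation, linear scans, SNP-set
annotation, and heritability-enrichment scoring.

Each EV phenotype is adjusted for fixed covariates, the residuals are
inverse-normal transformed to Z-scores, and every MAF-filtered SNP is tested by
simple linear regression. Sub-threshold SNPs from the pairwise-phenotype scans
are pooled into per-marker sets (one set per marker, union over every pair
phenotype containing it, plus one set from the marker-marker pair phenotypes),
flanked by a window, and scored for heritability enrichment:

    enrichment = (share of trait h2 in the annotated SNPs) / (share of SNPs annotated)

computed directly against per-SNP heritability contributions, with a block
jackknife standard error. Kinship correction is not applied here; pre-adjusted
phenotypes can be supplied directly to the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import assoc

GWAS_COLUMNS = ("snp", "chr", "pos", "effect_allele", "beta", "se", "p")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with map information.

    Dosages are allele counts in {0, 1, 2} (floats in [0, 2] allowed for
    imputed data). Positions are stored 0-based internally.
    """

    dosages: np.ndarray  # (n_individuals, n_snps)
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 0-based
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n_snps = self.dosages.shape[1]
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == n_snps):
            raise ValueError("map arrays must match number of SNP columns")
        if (self.pos < 0).any():
            raise ValueError("positions must be non-negative")
        if ((self.dosages < 0) | (self.dosages > 2)).any():
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency from the dosages."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, keep],
            self.snp_ids[keep],
            self.chrom[keep],
            self.pos[keep],
            None if self.ref is None else self.ref[keep],
            None if self.alt is None else self.alt[keep],
        )

    # ---------------------------------------------------------------- IO ---

    def write_dosage(self, path: str, individual_ids: Sequence[str] | None = None) -> None:
        """Tab-separated dosage matrix: snp, chr, pos, then one column per individual."""
        ids = individual_ids or [f"ind{i + 1:03d}" for i in range(self.n_individuals)]
        df = pd.DataFrame(self.dosages.T, columns=list(ids))
        df.insert(0, "pos", self.pos)
        df.insert(0, "chr", self.chrom)
        df.insert(0, "snp", self.snp_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_dosage(cls, path: str) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = df[["snp", "chr", "pos"]]
        dos = df.drop(columns=["snp", "chr", "pos"]).to_numpy(dtype=float).T
        return cls(dos, meta["snp"].to_numpy(), meta["chr"].to_numpy(), meta["pos"].to_numpy())

    def write_vcf(self, path: str, individual_ids: Sequence[str] | None = None) -> None:
        """Minimal VCFv4.2 with GT genotypes (requires integer dosages).

        VCF positions are 1-based; internal 0-based positions are shifted on write.
        """
        if not np.allclose(self.dosages, np.round(self.dosages)):
            raise ValueError("VCF GT output requires hard-called (integer) dosages")
        ids = list(individual_ids or (f"ind{i + 1:03d}" for i in range(self.n_individuals)))
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        ref = self.ref if self.ref is not None else np.full(self.n_snps, "A", dtype=object)
        alt = self.alt if self.alt is not None else np.full(self.n_snps, "G", dtype=object)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in pd.unique(self.chrom):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
            rounded = np.round(self.dosages).astype(int)
            for j in range(self.n_snps):
                gts = "\t".join(gt_map[g] for g in rounded[:, j])
                fh.write(
                    f"{self.chrom[j]}\t{self.pos[j] + 1}\t{self.snp_ids[j]}\t"
                    f"{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
                )

    @classmethod
    def read_vcf(cls, path: str) -> "GenotypeMatrix":
        """Read GT dosages from a VCF via cyvcf2 (positions converted to 0-based)."""
        from cyvcf2 import VCF

        vcf = VCF(path)
        snp_ids, chrom, pos, ref, alt, rows = [], [], [], [], [], []
        for variant in vcf:
            snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
            chrom.append(variant.CHROM)
            pos.append(variant.POS - 1)
            ref.append(variant.REF)
            alt.append(variant.ALT[0] if variant.ALT else ".")
            gts = variant.genotype.array()[:, :2]
            rows.append(np.where(gts < 0, np.nan, gts).sum(axis=1))
        return cls(
            np.asarray(rows, dtype=float).T,
            np.asarray(snp_ids, dtype=object),
            np.asarray(chrom, dtype=object),
            np.asarray(pos, dtype=np.int64),
            np.asarray(ref, dtype=object),
            np.asarray(alt, dtype=object),
        )


# --------------------------------------------------------------- phenotype ---


def prepare_gwas_phenotype(ev_abundance: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Adjust an EV abundance for fixed covariates and Z-score the residuals.

    Fits abundance ~ intercept + covariates by OLS, then maps the residuals to
    standard-normal quantiles by the rank-based inverse normal transform.
    """
    y = np.asarray(ev_abundance, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != y.size:
        C = C.T
    if C.shape[0] != y.size:
        raise ValueError("covariate rows must match phenotype length")
    X = sm.add_constant(C, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate matrix")
    resid = sm.OLS(y, X).fit().resid
    if np.ptp(resid) < 1e-12 * max(1.0, np.abs(resid).max(), 1e-300):
        warnings.warn(
            "residuals are numerically tied; INT output driven by rank noise",
            RuntimeWarning,
            stacklevel=2,
        )
    return assoc.inverse_gaussian_transform(resid)


def maf_filter(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly above the threshold."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError("threshold must be in [0, 0.5)")
    return G.subset(G.maf() > threshold)


# -------------------------------------------------------------------- scan ---


@dataclass
class GWASResult:
    """Per-SNP summary statistics for one phenotype scan."""

    phenotype: str
    table: pd.DataFrame  # columns GWAS_COLUMNS
    lambda_gc: float

    def write(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str, phenotype: str = "") -> "GWASResult":
        table = pd.read_csv(path, sep="\t")
        chi2 = scipy.stats.chi2.isf(table["p"].to_numpy(), df=1)
        lam = float(np.median(chi2) / scipy.stats.chi2.ppf(0.5, df=1))
        return cls(phenotype, table, lam)


def linear_gwas(Z: np.ndarray, G: GenotypeMatrix, phenotype: str = "phenotype") -> GWASResult:
    """Per-SNP simple linear regression of the Z-scored phenotype on dosage.

    Closed-form slope/SE/two-sided t-test with an intercept, vectorized over
    SNPs. Monomorphic SNPs are skipped (NaN statistics) with a warning. The
    genomic-control lambda (median chi-square over its null median) is reported.
    """
    z = np.asarray(Z, dtype=float)
    if z.size != G.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    n = z.size
    g = G.dosages
    gc = g - g.mean(axis=0)
    zc = z - z.mean()
    sgg = (gc**2).sum(axis=0)
    constant = sgg == 0
    if constant.any():
        warnings.warn(
            f"skipping {int(constant.sum())} monomorphic SNP(s)", RuntimeWarning, stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (gc * zc[:, None]).sum(axis=0) / sgg
        rss = (zc**2).sum() - beta**2 * sgg
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sgg)
        t = beta / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    beta[constant] = se[constant] = p[constant] = np.nan
    chi2 = t[~constant] ** 2
    lam = float(np.median(chi2) / scipy.stats.chi2.ppf(0.5, df=1)) if chi2.size else float("nan")
    table = pd.DataFrame(
        {
            "snp": G.snp_ids,
            "chr": G.chrom,
            "pos": G.pos,
            "effect_allele": G.alt if G.alt is not None else "G",
            "beta": beta,
            "se": se,
            "p": p,
        }
    )
    return GWASResult(phenotype, table, lam)


def bonferroni_threshold(n_tests: int, alpha: float = 5e-8) -> float:
    """Genome-wide significance threshold divided by the number of phenotype scans."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def gene_test_count(n_univariate_traits: int = 17, multivariate: bool = True) -> int:
    """Association P-values per gene when scoring each univariate GWAS plus one
    combined multi-trait analysis (17 + 1 = 18 in the adiposity screen)."""
    return n_univariate_traits + int(multivariate)


# -------------------------------------------------------------- annotation ---


@dataclass
class SNPAnnotation:
    """A labelled SNP set with (optionally) flanked intervals and membership."""

    label: str
    snps: frozenset[str]
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)  # 0-based half-open
    membership: np.ndarray | None = None  # aligned to a GenotypeMatrix SNP order
    proportion_of_snps: float = float("nan")

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for start, end in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\t{self.label}\n")


def extract_snp_sets(
    results: Mapping[str, pd.DataFrame],
    phenotype_markers: Mapping[str, frozenset[str]],
    markers: Sequence[str],
    p_threshold: float = 1e-6,
) -> list[SNPAnnotation]:
    """Pool sub-threshold SNPs from pairwise-phenotype scans into marker sets.

    For each prioritized marker, the union of SNPs with P < threshold over every
    pair phenotype containing that marker forms one set; a final set pools the
    marker-marker pair phenotypes. 12 markers therefore yield 13 sets. Empty
    sets are retained (with a warning) so downstream bookkeeping stays aligned.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    marker_set = set(markers)
    hits: dict[str, set[str]] = {}
    for label, table in results.items():
        sub = table.loc[table["p"] < p_threshold, "snp"]
        hits[label] = set(sub.astype(str))
    annotations = []
    for m in markers:
        snps: set[str] = set()
        for label, mk in phenotype_markers.items():
            if m in mk:
                snps |= hits.get(label, set())
        if not snps:
            warnings.warn(f"marker set {m!r} is empty at P<{p_threshold}", RuntimeWarning, stacklevel=2)
        annotations.append(SNPAnnotation(label=m, snps=frozenset(snps)))
    pair_snps: set[str] = set()
    for label, mk in phenotype_markers.items():
        if len(mk) == 2 and mk <= marker_set:
            pair_snps |= hits.get(label, set())
    if not pair_snps:
        warnings.warn(f"marker-pair set is empty at P<{p_threshold}", RuntimeWarning, stacklevel=2)
    annotations.append(SNPAnnotation(label="marker_pairs", snps=frozenset(pair_snps)))
    return annotations


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def annotate_flanks(
    annotation: SNPAnnotation, G: GenotypeMatrix, window_bp: int = 1000
) -> SNPAnnotation:
    """Flank each member SNP by ``window_bp`` on both sides and mark every SNP
    of ``G`` that falls inside the merged intervals as annotation-positive.

    Intervals are 0-based half-open [pos - w, pos + w + 1), clipped at zero and
    merged per chromosome. The annotated-SNP proportion is computed over all of
    ``G``'s SNPs.
    """
    member = np.isin(G.snp_ids.astype(str), list(annotation.snps))
    intervals: dict[str, list[tuple[int, int]]] = {}
    for j in np.flatnonzero(member):
        chrom = str(G.chrom[j])
        start = max(int(G.pos[j]) - window_bp, 0)
        end = int(G.pos[j]) + window_bp + 1
        intervals.setdefault(chrom, []).append((start, end))
    intervals = {c: _merge_intervals(iv) for c, iv in intervals.items()}
    membership = np.zeros(G.n_snps, dtype=bool)
    for c, iv in intervals.items():
        on_chrom = np.flatnonzero(G.chrom.astype(str) == c)
        pos = G.pos[on_chrom]
        starts = np.array([s for s, _ in iv])
        ends = np.array([e for _, e in iv])
        # merged intervals are disjoint and sorted; searchsorted locates each SNP
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        membership[on_chrom[inside]] = True
    return SNPAnnotation(
        label=annotation.label,
        snps=annotation.snps,
        intervals=intervals,
        membership=membership,
        proportion_of_snps=float(membership.mean()) if G.n_snps else float("nan"),
    )


# -------------------------------------------------------------- enrichment ---


@dataclass(frozen=True)
class EnrichmentResult:
    """Heritability-enrichment score for one annotation on one trait."""

    annotation: str
    trait: str
    score: float
    se: float
    proportion_h2: float
    proportion_snps: float

    def __post_init__(self) -> None:
        assert self.score >= 0.0


def enrichment_score(
    annotation: SNPAnnotation,
    snp_h2: np.ndarray,
    trait: str = "trait",
    n_blocks: int = 200,
) -> EnrichmentResult:
    """Score = (share of heritability in the annotation) / (share of SNPs annotated).

    ``snp_h2`` gives every SNP's true heritability contribution (known in
    simulation); the SE is a delete-one block jackknife over ``n_blocks``
    contiguous SNP blocks.
    """
    if annotation.membership is None:
        raise ValueError("annotation lacks membership; run annotate_flanks first")
    h2 = np.asarray(snp_h2, dtype=float)
    mask = annotation.membership.astype(bool)
    if h2.size != mask.size:
        raise ValueError("snp_h2 length does not match annotation membership")
    total_h2 = h2.sum()
    if total_h2 <= 0:
        raise ValueError("total heritability must be positive")
    n_annot = int(mask.sum())
    if n_annot == 0:
        raise ValueError("annotation covers zero SNPs; enrichment undefined")

    def _score(keep: np.ndarray) -> float:
        th = h2[keep].sum()
        prop_snps = mask[keep].mean()
        if th <= 0 or prop_snps == 0:
            return np.nan
        return (h2[keep & mask].sum() / th) / prop_snps

    full = _score(np.ones(h2.size, dtype=bool))
    n_blocks = min(n_blocks, h2.size)
    bounds = np.linspace(0, h2.size, n_blocks + 1).astype(int)
    pseudo = []
    for b in range(n_blocks):
        keep = np.ones(h2.size, dtype=bool)
        keep[bounds[b] : bounds[b + 1]] = False
        pseudo.append(_score(keep))
    pseudo_arr = np.asarray(pseudo, dtype=float)
    valid = np.isfinite(pseudo_arr)
    B = int(valid.sum())
    if B > 1:
        se = float(np.sqrt((B - 1) / B * ((pseudo_arr[valid] - pseudo_arr[valid].mean()) ** 2).sum()))
    else:
        se = float("nan")
    return EnrichmentResult(
        annotation=annotation.label,
        trait=trait,
        score=float(full),
        se=se,
        proportion_h2=float(h2[mask].sum() / total_h2),
        proportion_snps=float(n_annot / h2.size),
    )
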