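"""Synthetic data with the statistical structure the analysis assumes.

Two generators are provided. ``generate_ev_sample`` emulates a deep-sequenced
single-EV assay: a majority-singleton vesicle population (default 62% carry one
protein type), a proteins-per-vesicle distribution concentrated on 1-10 with
the non-singleton mode near 5, optional marker co-occurrence, per-incidence
read depth, and a uniform background of spurious (EV tag, protein tag) read
pairs. ``generate_cohort`` emulates a small genotyped cohort (default 96
individuals) with known EV-abundance effects (and sex interactions) on
anthropometric traits, Hardy-Weinberg genotypes without LD, and a complex
trait whose per-SNP heritability contributions are recorded as ground truth
for enrichment scoring.

The truth tables retained alongside each generated dataset make every
downstream estimate checkable against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from . import assoc
from .genetics import GenotypeMatrix
from .panel import ProteinPanel

TRAIT_NAMES = (
    "BMI",
    "WC",
    "WHR",
    "total_lean",
    "trunk_fat",
    "trunk_lean",
    "visceral_fat",
)


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


def default_proteins_per_ev_dist(
    p_singleton: float = 0.62,
    nb_n: float = 6.0,
    nb_p: float = 0.5,
    k_max: int = 20,
) -> np.ndarray:
    """Distribution of distinct proteins per vesicle.

    A point mass ``p_singleton`` at k=1, with the remainder following a
    negative binomial restricted to k in [2, k_max] and renormalized; the
    defaults put the non-singleton mode at k=5. Returns probabilities for
    k = 1..k_max.
    """
    if not 0.0 <= p_singleton < 1.0:
        raise ConfigError("p_singleton must be in [0, 1)")
    k = np.arange(2, k_max + 1)
    tail = scipy.stats.nbinom.pmf(k, nb_n, nb_p)
    tail = tail / tail.sum() * (1.0 - p_singleton)
    return np.concatenate([[p_singleton], tail])


@dataclass
class EVPopulationModel:
    """Generative model for one sample's single-EV read table.

    Parameters
    ----------
    panel
        Protein panel; co-occurrence weights are indexed by its column order.
    n_evs
        Number of vesicles in the sample.
    proteins_per_ev_dist
        Probabilities over k = 1..K distinct proteins per vesicle.
    cooccurrence
        Optional symmetric non-negative matrix; after the first (uniform)
        protein pick, the next protein's weight is the product of its
        co-occurrence entries with the proteins already on the vesicle.
    noise_rate
        Fraction of all reads that are background: unit-count reads assigned to
        a uniformly random (existing EV tag, random protein) pair.
    reads_per_protein_mean
        Mean of the shifted-Poisson (1 + Poisson(mean - 1)) read depth per true
        vesicle-protein incidence.
    """

    panel: ProteinPanel = field(default_factory=ProteinPanel.default)
    n_evs: int = 10_000
    proteins_per_ev_dist: np.ndarray = field(default_factory=default_proteins_per_ev_dist)
    cooccurrence: np.ndarray | None = None
    noise_rate: float = 0.05
    reads_per_protein_mean: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.proteins_per_ev_dist = np.asarray(self.proteins_per_ev_dist, dtype=float)
        if not np.isclose(self.proteins_per_ev_dist.sum(), 1.0):
            raise ConfigError("proteins_per_ev_dist must sum to 1")
        if (self.proteins_per_ev_dist < 0).any():
            raise ConfigError("proteins_per_ev_dist must be non-negative")
        if len(self.proteins_per_ev_dist) > len(self.panel):
            raise ConfigError("proteins-per-EV support exceeds panel size")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ConfigError("noise_rate must be in [0, 1)")
        if self.reads_per_protein_mean < 1.0:
            raise ConfigError("reads_per_protein_mean must be >= 1")
        if self.cooccurrence is not None:
            self.cooccurrence = np.asarray(self.cooccurrence, dtype=float)
            n = len(self.panel)
            if self.cooccurrence.shape != (n, n):
                raise ConfigError("cooccurrence must be panel_size x panel_size")
            if (self.cooccurrence < 0).any():
                raise ConfigError("cooccurrence weights must be >= 0")
            if not np.allclose(self.cooccurrence, self.cooccurrence.T):
                raise ConfigError("cooccurrence must be symmetric")


@dataclass
class EVSample:
    """A generated read table plus the vesicle-level ground truth."""

    sample_id: str
    reads: pd.DataFrame  # sample_id, ev_tag, protein_tag, read_count
    truth: pd.DataFrame  # ev_tag, protein_tag (true incidences only)
    panel: ProteinPanel


def _sample_protein_sets(model: EVPopulationModel, k: np.ndarray, rng: np.random.Generator):
    """Choose k[i] distinct proteins for each vesicle."""
    n_prot = len(model.panel)
    if model.cooccurrence is None:
        # uniform k-subsets via random-key sort
        keys = rng.random((k.size, n_prot))
        order = np.argsort(keys, axis=1)
        return [order[i, : k[i]] for i in range(k.size)]
    chosen_all = []
    for ki in k:
        chosen = [int(rng.integers(n_prot))]
        weights = model.cooccurrence[chosen[0]].copy()
        for _ in range(int(ki) - 1):
            w = weights.copy()
            w[chosen] = 0.0
            if w.sum() == 0:  # isolated protein; fall back to uniform
                w = np.ones(n_prot)
                w[chosen] = 0.0
            nxt = int(rng.choice(n_prot, p=w / w.sum()))
            chosen.append(nxt)
            weights *= model.cooccurrence[nxt]
        chosen_all.append(np.asarray(chosen))
    return chosen_all


def generate_ev_sample(
    model: EVPopulationModel, sample_id: str, rng: np.random.Generator | None = None
) -> EVSample:
    """Simulate one sample's PBA read table.

    Every true vesicle-protein incidence receives at least one read, so the
    truth table is always consistent with the emitted reads. Same model seed
    implies byte-identical output.
    """
    if model.n_evs == 0:
        raise ValueError("n_evs is 0: cannot generate an empty sample")
    rng = rng or np.random.default_rng(model.seed)
    k_support = np.arange(1, len(model.proteins_per_ev_dist) + 1)
    k = rng.choice(k_support, size=model.n_evs, p=model.proteins_per_ev_dist)
    protein_sets = _sample_protein_sets(model, k, rng)

    width = max(7, len(str(model.n_evs)))
    ev_tags = np.array(
        [f"{sample_id}_EV{i:0{width}d}" for i in range(model.n_evs)], dtype=object
    )
    ev_idx = np.repeat(np.arange(model.n_evs), k)
    prot_idx = np.concatenate(protein_sets)
    reads = 1 + rng.poisson(model.reads_per_protein_mean - 1.0, size=prot_idx.size)

    proteins = np.asarray(model.panel.proteins, dtype=object)
    truth = pd.DataFrame({"ev_tag": ev_tags[ev_idx], "protein_tag": proteins[prot_idx]})

    total_true = int(reads.sum())
    n_noise = int(round(model.noise_rate / (1.0 - model.noise_rate) * total_true))
    frames = [
        pd.DataFrame(
            {
                "ev_tag": ev_tags[ev_idx],
                "protein_tag": proteins[prot_idx],
                "read_count": reads,
            }
        )
    ]
    if n_noise:
        frames.append(
            pd.DataFrame(
                {
                    "ev_tag": ev_tags[rng.integers(model.n_evs, size=n_noise)],
                    "protein_tag": proteins[rng.integers(len(proteins), size=n_noise)],
                    "read_count": np.ones(n_noise, dtype=np.int64),
                }
            )
        )
    table = (
        pd.concat(frames, ignore_index=True)
        .groupby(["ev_tag", "protein_tag"], sort=True, as_index=False)["read_count"]
        .sum()
    )
    table.insert(0, "sample_id", sample_id)
    return EVSample(sample_id=sample_id, reads=table, truth=truth, panel=model.panel)


# ------------------------------------------------------------------ cohort ---


@dataclass
class CohortModel:
    """Generative model for a genotyped cohort with EV-abundance phenotypes.

    ``ev_effects`` maps EV-type labels to per-trait (main effect, sex
    interaction) pairs applied on the standardized-trait scale with the
    inverse-normal-transformed abundance as exposure (male coded 1).
    ``ev_snp_effects`` plants causal SNPs (by index) on the latent abundance
    scale; ``complex_trait_effects`` plants per-SNP effects on a scalar complex
    trait, rescaled so their squared sum equals ``complex_trait_h2``.
    """

    n_individuals: int = 96
    sex_ratio: float = 0.5
    age_range: tuple[float, float] = (40.0, 75.0)
    ev_types: tuple[str, ...] = ("EV_M01",)
    ev_effects: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    sex_effect: float = 0.0
    age_effect: float = 0.0
    trait_noise_sd: float = 1.0
    trait_names: tuple[str, ...] = TRAIT_NAMES
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_spacing_bp: int = 5000
    ev_snp_effects: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    complex_trait_effects: Mapping[int, float] = field(default_factory=dict)
    complex_trait_h2: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 3:
            raise ConfigError("n_individuals must be >= 3")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.complex_trait_h2 <= 1.0:
            raise ConfigError("complex_trait_h2 must be in [0, 1]")
        for label, per_trait in self.ev_effects.items():
            if label not in self.ev_types:
                raise ConfigError(f"ev_effects references unknown EV type {label!r}")
            unknown = set(per_trait) - set(self.trait_names)
            if unknown:
                raise ConfigError(f"ev_effects references unknown trait(s) {sorted(unknown)}")
        for label, per_snp in self.ev_snp_effects.items():
            if label not in self.ev_types:
                raise ConfigError(f"ev_snp_effects references unknown EV type {label!r}")
            bad = [j for j in per_snp if not 0 <= j < self.n_snps]
            if bad:
                raise ConfigError(f"ev_snp_effects SNP indices out of range: {bad[:5]}")
        bad = [j for j in self.complex_trait_effects if not 0 <= j < self.n_snps]
        if bad:
            raise ConfigError(f"complex_trait_effects SNP indices out of range: {bad[:5]}")
        if self.complex_trait_h2 > 0 and not self.complex_trait_effects:
            raise ConfigError("complex_trait_h2 > 0 requires complex_trait_effects")


@dataclass
class CohortData:
    """Generated cohort: genotypes, EV abundances, phenotypes, and truth."""

    genotypes: GenotypeMatrix
    ev_abundance: pd.DataFrame  # individuals x EV types, values in (0, 1)
    phenotypes: pd.DataFrame  # sex, age, traits, complex_trait
    snp_h2: np.ndarray  # per-SNP heritability contribution to the complex trait
    individual_ids: tuple[str, ...]


def _standardize_columns(g: np.ndarray) -> np.ndarray:
    sd = g.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (g - g.mean(axis=0)) / sd


def generate_cohort(model: CohortModel, rng: np.random.Generator | None = None) -> CohortData:
    """Simulate genotypes, EV abundances and traits with the declared effects.

    Abundances arise from a unit-variance latent liability (genetic part from
    the planted causal SNPs on standardized dosages, Gaussian residual) mapped
    through a logistic link, so any planted genetic signal survives the
    rank-based transform applied downstream. Traits are built on the
    standardized scale exactly as the association model assumes.
    """
    rng = rng or np.random.default_rng(model.seed)
    n = model.n_individuals
    ids = tuple(f"ind{i + 1:03d}" for i in range(n))

    sex = rng.binomial(1, model.sex_ratio, size=n).astype(float)
    age = rng.uniform(*model.age_range, size=n)
    age_std = (age - age.mean()) / (age.std(ddof=0) or 1.0)

    mafs = rng.uniform(*model.maf_range, size=model.n_snps)
    dosages = rng.binomial(2, mafs, size=(n, model.n_snps)).astype(float)
    G = GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"rs{j + 1:06d}" for j in range(model.n_snps)], dtype=object),
        chrom=np.array(["1"] * model.n_snps, dtype=object),
        pos=np.arange(model.n_snps, dtype=np.int64) * model.snp_spacing_bp + 10_000,
    )
    g_std = _standardize_columns(dosages)

    abundance: dict[str, np.ndarray] = {}
    x_star: dict[str, np.ndarray] = {}
    for label in model.ev_types:
        genetic = np.zeros(n)
        var_g = 0.0
        for j, beta in model.ev_snp_effects.get(label, {}).items():
            genetic += beta * g_std[:, j]
            var_g += beta**2
        resid_sd = np.sqrt(max(1.0 - var_g, 0.0))
        liability = genetic + rng.normal(0.0, resid_sd, size=n)
        abundance[label] = scipy.special.expit(liability - 2.0)
        x_star[label] = assoc.inverse_gaussian_transform(abundance[label])

    pheno = {"sex": sex, "age": age}
    for trait in model.trait_names:
        y = model.sex_effect * sex + model.age_effect * age_std
        for label, per_trait in model.ev_effects.items():
            if trait in per_trait:
                beta_main, beta_int = per_trait[trait]
                y = y + beta_main * x_star[label] + beta_int * x_star[label] * sex
        pheno[trait] = y + rng.normal(0.0, model.trait_noise_sd, size=n)

    snp_h2 = np.zeros(model.n_snps)
    if model.complex_trait_effects:
        idx = np.fromiter(model.complex_trait_effects.keys(), dtype=int)
        raw = np.fromiter(model.complex_trait_effects.values(), dtype=float)
        if model.complex_trait_h2 > 0:
            raw = raw * np.sqrt(model.complex_trait_h2 / (raw**2).sum())
        snp_h2[idx] = raw**2
        env_sd = np.sqrt(max(1.0 - snp_h2.sum(), 0.0))
        pheno["complex_trait"] = g_std[:, idx] @ raw + rng.normal(0.0, env_sd, size=n)
    else:
        pheno["complex_trait"] = rng.normal(0.0, 1.0, size=n)

    return CohortData(
        genotypes=G,
        ev_abundance=pd.DataFrame(abundance, index=pd.Index(ids, name="sample_id")),
        phenotypes=pd.DataFrame(pheno, index=pd.Index(ids, name="sample_id")),
        snp_h2=snp_h2,
        individual_ids=ids,
    )


def write_cohort(cohort: CohortData, outdir: str) -> dict[str, str]:
    """Write genotypes (VCF + dosage TSV), abundances, phenotypes, and SNP truth."""
    import os

    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "dosage": os.path.join(outdir, "genotypes.dosage.tsv"),
        "ev_abundance": os.path.join(outdir, "ev_abundance.tsv"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "snp_h2": os.path.join(outdir, "snp_h2.tsv"),
    }
    cohort.genotypes.write_vcf(paths["vcf"], cohort.individual_ids)
    cohort.genotypes.write_dosage(paths["dosage"], cohort.individual_ids)
    cohort.ev_abundance.to_csv(paths["ev_abundance"], sep="\t")
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t")
    pd.DataFrame(
        {"snp": cohort.genotypes.snp_ids, "h2": cohort.snp_h2}
    ).to_csv(paths["snp_h2"], sep="\t", index=False)
    return paths
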