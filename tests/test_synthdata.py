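"""Generators: single-EV read tables and genotyped cohorts with known truth."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from evlink.assoc import fit_association, inverse_gaussian_transform
from evlink.panel import ProteinPanel
from evlink.pba import parse_reads, summarize_profile
from evlink.synthdata import (
    CohortModel,
    ConfigError,
    EVPopulationModel,
    default_proteins_per_ev_dist,
    generate_cohort,
    generate_ev_sample,
)


def small_model(**kw):
    defaults = dict(panel=ProteinPanel.default(20, 4), n_evs=500, seed=0)
    defaults.update(kw)
    return EVPopulationModel(**defaults)


class TestProteinsPerEVDist:
    def test_sums_to_one_with_singleton_mass(self):
        dist = default_proteins_per_ev_dist()
        assert np.isclose(dist.sum(), 1.0)
        assert dist[0] == pytest.approx(0.62)

    def test_nonsingleton_mode_near_five(self):
        dist = default_proteins_per_ev_dist()
        # k = index + 1; mode of the k >= 2 remainder
        assert np.argmax(dist[1:]) + 2 == 5

    def test_support_within_one_to_ten_dominates(self):
        dist = default_proteins_per_ev_dist()
        assert dist[:10].sum() > 0.9


class TestGenerateEVSample:
    def test_forced_singletons(self):
        model = small_model(proteins_per_ev_dist=[1.0], noise_rate=0.0)
        sample = generate_ev_sample(model, "s1")
        per_ev = sample.reads.groupby("ev_tag")["protein_tag"].nunique()
        assert (per_ev == 1).all()

    def test_singleton_fraction_within_binomial_error(self):
        model = small_model(n_evs=10_000, noise_rate=0.0, seed=11)
        sample = generate_ev_sample(model, "s1")
        m = parse_reads(sample.reads, model.panel, "s1")
        frac = summarize_profile(m).singleton_fraction
        se = np.sqrt(0.62 * 0.38 / 10_000)
        assert abs(frac - 0.62) < 4 * se

    def test_seed_determinism_byte_identical(self):
        a = generate_ev_sample(small_model(seed=42), "s1").reads.to_csv()
        b = generate_ev_sample(small_model(seed=42), "s1").reads.to_csv()
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_ev_sample(small_model(seed=1), "s1").reads
        b = generate_ev_sample(small_model(seed=2), "s1").reads
        assert not a.equals(b)

    def test_zero_evs_rejected(self):
        with pytest.raises(ValueError, match="n_evs"):
            generate_ev_sample(small_model(n_evs=0), "s1")

    def test_truth_consistent_with_reads(self):
        sample = generate_ev_sample(small_model(noise_rate=0.1, seed=3), "s1")
        emitted = set(zip(sample.reads["ev_tag"], sample.reads["protein_tag"]))
        truth = set(zip(sample.truth["ev_tag"], sample.truth["protein_tag"]))
        assert truth <= emitted  # every true incidence got >= 1 read

    def test_noise_rate_realized(self):
        model = small_model(n_evs=5000, noise_rate=0.2, seed=4)
        sample = generate_ev_sample(model, "s1")
        truth_pairs = set(zip(sample.truth["ev_tag"], sample.truth["protein_tag"]))
        is_true = sample.reads.apply(
            lambda r: (r["ev_tag"], r["protein_tag"]) in truth_pairs, axis=1
        )
        # noise reads that landed on a true incidence are indistinguishable, so
        # the pure-noise read share slightly undershoots the nominal rate
        noise_share = sample.reads.loc[~is_true, "read_count"].sum() / sample.reads["read_count"].sum()
        assert 0.1 < noise_share <= 0.21

    def test_goodness_of_fit_at_scale(self):
        """Empirical proteins-per-EV distribution matches the model (chi-square GOF)."""
        model = EVPopulationModel(
            panel=ProteinPanel.default(113, 12), n_evs=100_000, noise_rate=0.0, seed=5
        )
        sample = generate_ev_sample(model, "s1")
        k = sample.truth.groupby("ev_tag")["protein_tag"].nunique()
        observed = np.bincount(k, minlength=len(model.proteins_per_ev_dist) + 1)[1:]
        expected = model.proteins_per_ev_dist * model.n_evs
        keep = expected > 5
        stat, p = scipy.stats.chisquare(
            observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum()
        )
        assert p > 0.01

    def test_cooccurrence_enriches_pairs(self):
        panel = ProteinPanel.default(10, 2)
        co = np.ones((10, 10))
        co[0, 1] = co[1, 0] = 50.0
        dist = default_proteins_per_ev_dist(k_max=8)
        base = EVPopulationModel(
            panel=panel, n_evs=4000, noise_rate=0.0, proteins_per_ev_dist=dist, seed=6
        )
        enriched = EVPopulationModel(
            panel=panel, n_evs=4000, noise_rate=0.0, proteins_per_ev_dist=dist,
            cooccurrence=co, seed=6,
        )
        def pair_frac(model):
            s = generate_ev_sample(model, "s1")
            m = parse_reads(s.reads, panel, "s1")
            return summarize_profile(m).per_pair_ev_fraction[("P001", "P002")]
        assert pair_frac(enriched) > 2 * pair_frac(base)

    @pytest.mark.parametrize(
        "kw",
        [
            {"proteins_per_ev_dist": [0.5, 0.4]},  # does not sum to 1
            {"noise_rate": 1.0},
            {"noise_rate": -0.1},
            {"reads_per_protein_mean": 0.5},
        ],
    )
    def test_invalid_models_rejected(self, kw):
        with pytest.raises(ConfigError):
            small_model(**kw)


class TestGenerateCohort:
    def test_null_model_uncorrelated(self):
        model = CohortModel(n_individuals=96, n_snps=50, trait_noise_sd=1.0, seed=7)
        data = generate_cohort(model)
        r = np.corrcoef(data.ev_abundance.iloc[:, 0], data.phenotypes["BMI"])[0, 1]
        assert abs(r) < 3 / np.sqrt(96)  # null bound

    def test_planted_effect_detected(self):
        model = CohortModel(
            n_individuals=96,
            ev_effects={"EV_M01": {"BMI": (-1.62, 0.0)}},
            trait_noise_sd=2.6,
            n_snps=50,
            seed=8,
        )
        data = generate_cohort(model)
        # traits are generated directly on the standardized scale, so the fit
        # takes them as-is; the exposure enters through the rank-based INT
        res = fit_association(
            data.phenotypes["BMI"].to_numpy(),
            inverse_gaussian_transform(data.ev_abundance["EV_M01"].to_numpy()),
            data.phenotypes["sex"].to_numpy(),
            data.phenotypes["age"].to_numpy(),
            pre_transformed=True,
        )
        lo, hi = res.ci_ev()
        assert lo < -1.62 < hi

    def test_saturated_model_error_propagates(self):
        model = CohortModel(n_individuals=3, n_snps=10, seed=9)
        data = generate_cohort(model)
        with pytest.raises(ValueError):
            fit_association(
                data.phenotypes["BMI"].to_numpy(),
                data.ev_abundance.iloc[:, 0].to_numpy(),
                data.phenotypes["sex"].to_numpy(),
                data.phenotypes["age"].to_numpy(),
            )

    def test_maf_within_declared_range(self):
        model = CohortModel(n_individuals=300, n_snps=400, maf_range=(0.2, 0.4), seed=10)
        data = generate_cohort(model)
        maf = data.genotypes.maf()
        assert (maf > 0.1).all() and (maf < 0.5).all()

    def test_snp_h2_truth_recorded(self):
        model = CohortModel(
            n_individuals=96,
            n_snps=100,
            complex_trait_effects={0: 1.0, 1: 1.0},
            complex_trait_h2=0.5,
            seed=11,
        )
        data = generate_cohort(model)
        assert data.snp_h2.sum() == pytest.approx(0.5)
        assert data.snp_h2[0] == pytest.approx(0.25)
        assert (data.snp_h2[2:] == 0).all()

    def test_seed_determinism(self):
        a = generate_cohort(CohortModel(seed=12, n_snps=30))
        b = generate_cohort(CohortModel(seed=12, n_snps=30))
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_individuals": 2},
            {"maf_range": (0.0, 0.5)},
            {"complex_trait_h2": 1.5, "complex_trait_effects": {0: 1.0}},
            {"ev_effects": {"EV_NOPE": {"BMI": (1.0, 0.0)}}},
            {"ev_snp_effects": {"EV_M01": {999: 1.0}}, "n_snps": 10},
            {"ev_effects": {"EV_M01": {"NOT_A_TRAIT": (1.0, 0.0)}}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            CohortModel(seed=0, **kw)
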