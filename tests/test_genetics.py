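"""GWAS preparation, linear scans, SNP-set annotation, enrichment scoring."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from evlink.genetics import (
    GenotypeMatrix,
    SNPAnnotation,
    annotate_flanks,
    bonferroni_threshold,
    enrichment_score,
    extract_snp_sets,
    gene_test_count,
    linear_gwas,
    maf_filter,
    prepare_gwas_phenotype,
)
from evlink.synthdata import CohortModel, generate_cohort


def make_genotypes(dosages, spacing=5000, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    p = dosages.shape[1]
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"rs{j}" for j in range(p)], dtype=object),
        chrom=np.array([chrom] * p, dtype=object),
        pos=np.arange(p, dtype=np.int64) * spacing + 10_000,
    )


class TestPrepareGwasPhenotype:
    def test_output_is_standard_normal_scores(self):
        rng = np.random.default_rng(0)
        z = prepare_gwas_phenotype(rng.exponential(size=60), rng.normal(size=(60, 2)))
        assert abs(z.mean()) < 1e-8
        assert 0.8 < z.std() < 1.1

    def test_orthogonal_covariate_limit(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        yc = y - y.mean()
        c = rng.normal(size=50)
        c -= c.mean()
        c -= yc * (c @ yc) / (yc @ yc)  # exactly orthogonal to centered y
        from evlink.assoc import inverse_gaussian_transform

        assert np.allclose(prepare_gwas_phenotype(y, c), inverse_gaussian_transform(y - y.mean()))

    def test_near_tied_residuals_flagged(self):
        age = np.linspace(30, 60, 40)
        with pytest.warns(RuntimeWarning, match="tied"):
            prepare_gwas_phenotype(2.0 * age, age)

    def test_rank_deficient_covariates_rejected(self):
        y = np.arange(10.0)
        C = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(np.linalg.LinAlgError):
            prepare_gwas_phenotype(y, C)


class TestMafFilter:
    def test_strict_boundary(self):
        # per-SNP dosage means 0.2, 0.4, 0.6 over 10 individuals -> MAF 0.1, 0.2, 0.3
        d = np.zeros((10, 3))
        d[:2, 0] = 1
        d[:4, 1] = 1
        d[:6, 2] = 1
        G = make_genotypes(d)
        out = maf_filter(G, 0.2)
        assert list(out.snp_ids) == ["rs2"]

    def test_threshold_zero_drops_monomorphic_only(self):
        d = np.column_stack([np.zeros(6), np.ones(6) * 2, [0, 1, 0, 0, 1, 2]])
        out = maf_filter(make_genotypes(d), 0.0)
        assert list(out.snp_ids) == ["rs2"]

    def test_nested_outputs(self):
        rng = np.random.default_rng(2)
        G = make_genotypes(rng.binomial(2, rng.uniform(0.02, 0.5, 200), size=(100, 200)))
        loose = set(maf_filter(G, 0.05).snp_ids)
        strict = set(maf_filter(G, 0.2).snp_ids)
        assert strict <= loose


class TestLinearGwas:
    def test_betas_match_statsmodels_closed_form(self):
        rng = np.random.default_rng(3)
        G = make_genotypes(rng.binomial(2, 0.3, size=(96, 20)))
        z = rng.normal(size=96)
        res = linear_gwas(z, G)
        for j in range(20):
            fit = sm.OLS(z, sm.add_constant(G.dosages[:, j])).fit()
            assert res.table["beta"][j] == pytest.approx(fit.params[1], rel=1e-10)
            assert res.table["se"][j] == pytest.approx(fit.bse[1], rel=1e-10)
            assert res.table["p"][j] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_monomorphic_snp_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        d[:, 1] = 1.0
        with pytest.warns(RuntimeWarning, match="monomorphic"):
            res = linear_gwas(rng.normal(size=50), make_genotypes(d))
        assert np.isnan(res.table["beta"][1])
        assert np.isfinite(res.table["beta"][[0, 2]]).all()

    def test_single_causal_snp_found(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            G = make_genotypes(rng.binomial(2, 0.3, size=(96, 500)))
            g = G.dosages[:, 137]
            gs = (g - g.mean()) / g.std()
            z = np.sqrt(0.35) * gs + np.sqrt(0.65) * rng.normal(size=96)
            res = linear_gwas(z, G)
            hits += res.table["p"].idxmin() == 137
        assert hits >= 190  # >= 95% of replicates

    def test_permuted_phenotype_calibrated(self):
        rng = np.random.default_rng(6)
        G = make_genotypes(rng.binomial(2, 0.3, size=(96, 5000)))
        g = G.dosages[:, 0]
        z = g + rng.normal(size=96)
        res = linear_gwas(rng.permutation(z), G)
        rate = (res.table["p"] < 0.05).mean()
        assert abs(rate - 0.05) < 0.01


class TestBookkeeping:
    def test_bonferroni_over_pairwise_scans(self):
        thr = bonferroni_threshold(12 * (113 - 12) + 66)
        assert thr == pytest.approx(3.9e-11, rel=0.05)

    def test_gene_level_pvalue_count(self):
        assert gene_test_count(17, multivariate=True) == 18


def _fake_results(markers, panel_others, p_for):
    """Build pairwise-scan tables; p_for maps (label, snp) -> p."""
    from evlink.evtypes import EVTypeDefinition

    labels = []
    for i, m in enumerate(markers):
        for o in panel_others + [x for x in markers[i + 1 :]]:
            labels.append(EVTypeDefinition(frozenset({m, o})).label)
    labels = sorted(set(labels))
    results, pheno_markers = {}, {}
    snps = [f"rs{j}" for j in range(8)]
    for lab in labels:
        mk = EVTypeDefinition.from_label(lab).marker_set
        pheno_markers[lab] = mk
        results[lab] = pd.DataFrame(
            {"snp": snps, "p": [p_for(lab, s) for s in snps]}
        )
    return results, pheno_markers


class TestExtractSnpSets:
    def test_twelve_markers_give_thirteen_sets(self):
        markers = [f"M{i}" for i in range(12)]
        results, pheno = _fake_results(markers, ["O1", "O2"], lambda l, s: 0.5)
        sets = extract_snp_sets(results, pheno, markers)
        assert len(sets) == 13
        assert sets[-1].label == "marker_pairs"

    def test_one_marker_gives_two_sets(self):
        results, pheno = _fake_results(["M0"], ["O1"], lambda l, s: 0.5)
        sets = extract_snp_sets(results, pheno, ["M0"])
        assert len(sets) == 2

    def test_threshold_one_includes_every_snp(self):
        markers = ["M0", "M1"]
        results, pheno = _fake_results(markers, ["O1"], lambda l, s: 0.5)
        sets = extract_snp_sets(results, pheno, markers, p_threshold=0.9999999)
        assert all(len(s.snps) == 8 for s in sets)

    def test_union_and_pair_set_membership(self):
        markers = ["M0", "M1"]

        def p_for(label, snp):
            if label == "EV_M0 & O1" and snp == "rs1":
                return 1e-8
            if label == "EV_M0 & M1" and snp == "rs2":
                return 1e-9
            return 0.5

        results, pheno = _fake_results(markers, ["O1"], p_for)
        sets = {s.label: s.snps for s in extract_snp_sets(results, pheno, markers)}
        assert sets["M0"] == {"rs1", "rs2"}
        assert sets["M1"] == {"rs2"}  # only via the M0 & M1 pair phenotype
        assert sets["marker_pairs"] == {"rs2"}

    def test_nested_in_threshold(self):
        rng = np.random.default_rng(7)
        markers = ["M0", "M1", "M2"]
        pvals = {}

        def p_for(label, snp):
            return pvals.setdefault((label, snp), rng.uniform(1e-9, 1))

        results, pheno = _fake_results(markers, ["O1"], p_for)
        loose = extract_snp_sets(results, pheno, markers, p_threshold=0.5)
        strict = extract_snp_sets(results, pheno, markers, p_threshold=0.01)
        for a, b in zip(strict, loose):
            assert a.snps <= b.snps


class TestAnnotateFlanks:
    def test_close_members_merge(self):
        G = make_genotypes(np.ones((4, 3)), spacing=500)
        ann = annotate_flanks(SNPAnnotation("a", frozenset({"rs0", "rs1"})), G, 1000)
        assert len(ann.intervals["1"]) == 1

    def test_window_zero_marks_members_only(self):
        G = make_genotypes(np.ones((4, 5)), spacing=500)
        ann = annotate_flanks(SNPAnnotation("a", frozenset({"rs2"}), ), G, 0)
        assert ann.membership.sum() == 1 and ann.membership[2]
        assert ann.intervals["1"] == [(11_000, 11_001)]

    def test_interval_clipped_at_zero(self):
        G = GenotypeMatrix(
            np.ones((3, 1)), np.array(["rs0"], dtype=object),
            np.array(["1"], dtype=object), np.array([0]),
        )
        ann = annotate_flanks(SNPAnnotation("a", frozenset({"rs0"})), G, 1000)
        assert ann.intervals["1"] == [(0, 1001)]

    def test_neighbors_inside_window_become_positive(self):
        G = make_genotypes(np.ones((4, 5)), spacing=400)
        ann = annotate_flanks(SNPAnnotation("a", frozenset({"rs2"})), G, 1000)
        # 1 kb window catches rs0..rs4 at 400 bp spacing: rs2 +- 2 neighbours
        assert ann.membership.sum() == 5
        assert ann.proportion_of_snps == 1.0


class TestEnrichmentScore:
    def _annotation(self, mask):
        return SNPAnnotation("a", frozenset(), membership=np.asarray(mask, dtype=bool),
                             proportion_of_snps=float(np.mean(mask)))

    def test_all_snps_score_one(self):
        rng = np.random.default_rng(8)
        h2 = rng.uniform(size=400)
        res = enrichment_score(self._annotation(np.ones(400)), h2)
        assert res.score == pytest.approx(1.0)

    def test_concentrated_quarter_scores_four(self):
        h2 = np.zeros(400)
        mask = np.zeros(400, dtype=bool)
        mask[:100] = True
        h2[:100] = 0.005
        res = enrichment_score(self._annotation(mask), h2)
        assert res.score == pytest.approx(4.0)

    def test_random_annotation_centers_on_one(self):
        rng = np.random.default_rng(9)
        h2 = rng.uniform(size=1000)
        scores = []
        for _ in range(100):
            mask = np.zeros(1000, dtype=bool)
            mask[rng.choice(1000, 200, replace=False)] = True
            scores.append(enrichment_score(self._annotation(mask), h2).score)
        scores = np.asarray(scores)
        assert abs(scores.mean() - 1.0) < 2 * scores.std(ddof=1) / 10 + 0.02

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError, match="zero SNPs"):
            enrichment_score(self._annotation(np.zeros(10)), np.ones(10))

    def test_zero_heritability_errors(self):
        with pytest.raises(ValueError, match="heritability"):
            enrichment_score(self._annotation(np.ones(10)), np.zeros(10))

    def test_jackknife_se_positive_for_uneven_annotation(self):
        rng = np.random.default_rng(10)
        h2 = rng.uniform(size=500)
        mask = np.zeros(500, dtype=bool)
        mask[::7] = True
        res = enrichment_score(self._annotation(mask), h2)
        assert res.se > 0


def test_end_to_end_planted_enrichment_recovers_ratio():
    """Planted f/s = 3: causal SNPs for EV phenotypes carry 3x the average
    per-SNP heritability; GWAS extraction + flanking + scoring recovers ~3."""
    rng = np.random.default_rng(11)
    n_snps, n_causal_per, n_phen = 1000, 3, 24
    markers = [f"M{i}" for i in range(4)]
    phen_markers = {}
    ev_snp_effects = {}
    labels = []
    idx = 0
    from evlink.evtypes import EVTypeDefinition

    from itertools import combinations
    pair_list = [frozenset(p) for p in combinations(markers, 2)]
    for i in range(n_phen):
        lab = f"EV_{sorted(pair_list[i % len(pair_list)])[0]} & X{i:02d}"
        mk = frozenset({sorted(pair_list[i % len(pair_list)])[0], f"X{i:02d}"})
        phen_markers[lab] = mk
        ev_snp_effects[lab] = {idx + j: 0.5 for j in range(n_causal_per)}
        labels.append(lab)
        idx += n_causal_per
    causal = np.arange(idx)
    f_share = 3.0 * len(causal) / n_snps
    effects = {int(j): np.sqrt(f_share / len(causal)) for j in causal}
    others = [j for j in range(n_snps) if j >= idx]
    for j in others:
        effects[int(j)] = np.sqrt((1 - f_share) / len(others))
    model = CohortModel(
        n_individuals=96,
        ev_types=tuple(labels),
        ev_snp_effects=ev_snp_effects,
        complex_trait_effects=effects,
        complex_trait_h2=0.6,
        n_snps=n_snps,
        maf_range=(0.25, 0.5),
        seed=13,
    )
    data = generate_cohort(model)
    covars = data.phenotypes[["sex", "age"]].to_numpy()
    results = {}
    for lab in labels:
        z = prepare_gwas_phenotype(data.ev_abundance[lab].to_numpy(), covars)
        results[lab] = linear_gwas(z, data.genotypes, lab).table
    sets = extract_snp_sets(results, phen_markers, markers)
    pooled = frozenset().union(*(s.snps for s in sets))
    assert pooled  # at least some causal SNPs detected
    ann = annotate_flanks(SNPAnnotation("pooled", pooled), data.genotypes, 1000)
    res = enrichment_score(ann, data.snp_h2)
    assert abs(res.score - 3.0) <= max(res.se, 0.1)
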