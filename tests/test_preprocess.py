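import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbqtl import preprocess as pp
from mbqtl.io import GenotypeTable, TaxaTable


def taxa_from(matrix, subjects=None, features=None):
    matrix = np.asarray(matrix)
    subjects = subjects or [f"s{i}" for i in range(matrix.shape[0])]
    features = features or [f"f{i}" for i in range(matrix.shape[1])]
    return TaxaTable(pd.DataFrame(matrix, index=subjects, columns=features))


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = taxa_from([[1500, 300, 200, 0]])
        out = pp.rarefy(t, depth=2000, seed=0)
        assert out.data.iloc[0].tolist() == [1500, 300, 200, 0]

    def test_shallow_sample_dropped(self):
        t = taxa_from([[1999, 0], [1500, 500]])
        out = pp.rarefy(t, depth=2000, seed=0)
        assert list(out.subject_ids) == ["s1"]

    def test_subsampling_matches_hypergeometric_moments(self):
        t = taxa_from([[10_000, 10_000]])
        out = pp.rarefy(t, depth=2000, seed=1)
        # hypergeometric sd for one taxon drawn 2000 from 20000 (half marked)
        n, K, N = 2000, 10_000, 20_000
        sd = np.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
        assert abs(out.data.iloc[0, 0] - 1000) <= 4 * sd
        assert out.data.iloc[0].sum() == 2000

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            pp.rarefy(taxa_from([[5]]), depth=0)

    def test_totals_exact_and_idempotent(self):
        rng = np.random.default_rng(3)
        t = taxa_from(rng.integers(0, 2000, size=(5, 8)))
        out = pp.rarefy(t, depth=2000, seed=2)
        assert (out.data.sum(axis=1) == 2000).all()
        again = pp.rarefy(out, depth=2000, seed=9)
        pd.testing.assert_frame_equal(again.data, out.data)


class TestDetectionProbability:
    def test_design_bound_met_at_depth_2000(self):
        assert pp.detection_probability(2000, 0.0015) >= 0.95

    def test_closed_form_value(self):
        assert pp.detection_probability(2000, 0.0015) == \
            pytest.approx(0.9503, abs=1e-4)

    def test_zero_abundance_never_detected(self):
        assert pp.detection_probability(2000, 0.0) == 0.0

    def test_domain_check(self):
        with pytest.raises(ValueError):
            pp.detection_probability(2000, 1.5)


class TestBinTaxonomy:
    def test_family_counts_sum_members(self, toy_taxa):
        out = pp.bin_taxonomy(toy_taxa, ranks=("family",))
        rumi = [c for c in out.feature_ids if "Ruminococcaceae" in c]
        assert len(rumi) == 1
        assert out.data[rumi[0]].tolist() == \
            toy_taxa.data["A"].tolist()

    def test_per_rank_sums_conserve_sample_totals(self, toy_taxa):
        out = pp.bin_taxonomy(toy_taxa)
        totals = toy_taxa.sample_totals()
        for rank in pp.BINNING_RANKS:
            cols = [c for c in out.feature_ids if out.ranks[c] == rank]
            assert np.allclose(out.data[cols].sum(axis=1), totals)

    def test_phylum_count(self, toy_taxa):
        out = pp.bin_taxonomy(toy_taxa, ranks=("phylum",))
        assert out.data.shape[1] == 3

    def test_missing_rank_binned_as_unclassified(self):
        t = TaxaTable(pd.DataFrame([[5]], index=["s1"], columns=["X"]),
                      pd.Series({"X": "k__Bacteria;p__Firmicutes"}))
        out = pp.bin_taxonomy(t, ranks=("family",))
        assert any("unclassified" in c for c in out.feature_ids)


class TestCollapseCorrelated:
    def test_duplicate_feature_merged(self):
        base = np.random.default_rng(0).poisson(50, size=(20, 1))
        t = taxa_from(np.hstack([base, base, base * 0 + 7]))
        out, cmap = pp.collapse_correlated(t)
        assert out.data.shape[1] == 2
        sizes = sorted(len(v) for v in cmap.members.values())
        assert sizes == [1, 2]

    def test_independent_features_kept(self):
        rng = np.random.default_rng(1)
        t = taxa_from(rng.poisson(100, size=(1000, 2)))
        out, _ = pp.collapse_correlated(t)
        assert out.data.shape[1] == 2

    def test_threshold_is_strict(self):
        # a pair at exactly the threshold correlation must NOT merge
        rng = np.random.default_rng(2)
        x = rng.normal(100, 10, 500)
        y = 0.9 * x + rng.normal(0, 5, 500)
        mat = np.clip(np.column_stack([x, y]), 0, None)
        rr = np.corrcoef(mat[:, 0], mat[:, 1])[0, 1]
        out, _ = pp.collapse_correlated(taxa_from(mat), r_threshold=rr)
        assert out.data.shape[1] == 2
        merged, _ = pp.collapse_correlated(taxa_from(mat),
                                           r_threshold=rr - 1e-9)
        assert merged.data.shape[1] == 1

    def test_representative_is_most_abundant(self):
        base = np.random.default_rng(4).poisson(100, size=(30, 1)).astype(float)
        t = taxa_from(np.hstack([base * 0.5, base]))  # f1 most abundant
        out, cmap = pp.collapse_correlated(t)
        assert list(out.feature_ids) == ["f1"]

    def test_zero_variance_feature_is_singleton(self):
        t = taxa_from([[5, 1], [5, 2], [5, 3], [5, 4]])
        out, cmap = pp.collapse_correlated(t)
        assert out.data.shape[1] == 2


class TestSnpFilters:
    def geno(self, cols):
        data = pd.DataFrame(cols)
        data.index = [f"s{i}" for i in range(len(data))]
        return GenotypeTable(data.astype(float))

    def test_maf_boundary_inclusive_exclusion(self):
        # 10 subjects: dosage sum 2 -> MAF 0.1 exactly -> excluded
        g = self.geno({"rs_at": [2] + [0] * 9, "rs_above": [2, 1] + [0] * 8,
                       "rs_het": [1] * 10})
        out = pp.maf_filter(g, floor=0.1)
        assert list(out.snp_ids) == ["rs_above", "rs_het"]

    def test_maf_uses_minor_allele(self):
        g = self.geno({"rs_major": [2] * 9 + [1]})  # freq 0.95 -> MAF 0.05
        assert list(pp.maf_filter(g).snp_ids) == []

    def test_callrate_filter(self):
        cols = {"rs_full": [0.0, 1.0, 2.0, 1.0, 0.0,
                            1.0, 1.0, 1.0, 2.0, 1.0],
                "rs_low": [0.0, np.nan, 2.0, np.nan, 0.0,
                           1.0, 1.0, 1.0, 2.0, 1.0]}
        g = self.geno(cols)
        out = pp.callrate_filter(g, min_callrate=0.95)
        assert list(out.snp_ids) == ["rs_full"]

    def test_163_snp_fixture_yields_154(self):
        """A 163-SNP panel engineered with 9 failing SNPs leaves 154."""
        rng = np.random.default_rng(0)
        n = 400
        cols = {}
        for i in range(154):
            cols[f"ok{i:03d}"] = rng.binomial(2, 0.3, n).astype(float)
        for i in range(5):  # low MAF
            cols[f"lowmaf{i}"] = rng.binomial(2, 0.02, n).astype(float)
        for i in range(4):  # low call rate
            c = rng.binomial(2, 0.3, n).astype(float)
            c[: n // 2] = np.nan
            cols[f"lowcall{i}"] = c
        g = self.geno(cols)
        out = pp.callrate_filter(pp.maf_filter(g, floor=0.1),
                                 min_callrate=0.95)
        assert out.data.shape[1] == 154

    def test_filters_idempotent(self):
        rng = np.random.default_rng(5)
        g = self.geno({f"rs{i}": rng.binomial(2, rng.uniform(0.05, 0.5), 50)
                       .astype(float) for i in range(20)})
        once = pp.maf_filter(g)
        twice = pp.maf_filter(once)
        assert list(once.snp_ids) == list(twice.snp_ids)


class TestTransforms:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0), (1.0, np.pi / 2), (0.25, np.pi / 6)])
    def test_arcsine_sqrt_values(self, x, expected):
        assert pp.transform_arcsine_sqrt(x) == pytest.approx(expected)

    def test_arcsine_domain(self):
        with pytest.raises(ValueError):
            pp.transform_arcsine_sqrt(1.0001)

    def test_inverse_recovers(self):
        x = np.linspace(0, 1, 101)
        back = pp.inverse_arcsine_sqrt(pp.transform_arcsine_sqrt(x))
        assert np.allclose(back, x, atol=1e-12)

    def test_monotone(self):
        x = np.linspace(0, 1, 200)
        y = pp.transform_arcsine_sqrt(x)
        assert (np.diff(y) > 0).all()

    def test_power_transform_normal_lambda_near_one(self):
        x = np.random.default_rng(0).normal(10, 2, 1000)
        _, lam = stats.yeojohnson(x)
        assert abs(lam - 1) < 0.15
        out = pp.power_transform(x)
        assert abs(out.mean()) < 1e-9

    def test_power_transform_lognormal_lambda_near_zero(self):
        # for data >> 1 Yeo-Johnson approaches the Box-Cox log limit
        x = np.exp(np.random.default_rng(1).normal(3, 1, 1000))
        _, lam = stats.yeojohnson(x)
        assert abs(lam) < 0.15

    def test_power_transform_constant_unchanged(self):
        with pytest.warns(UserWarning):
            out = pp.power_transform(np.full(10, 3.0))
        assert (out == 3.0).all()


class TestOutlierMask:
    def test_extreme_value_excluded(self):
        # mean 14.09, IQR 5 -> only 100 is > 3*IQR from the mean
        x = list(range(1, 11)) + [100]
        mask = pp.outlier_mask(x)
        assert mask.tolist() == [True] * 10 + [False]

    def test_rule_uses_mean_not_median(self):
        # an extreme value drags the mean far enough that near values
        # survive while distant small values are excluded too
        x = np.array([1.0, 2, 3, 4, 100])
        mask = pp.outlier_mask(x)
        # mean 22, IQR 2: every value is > 6 from the mean
        assert not mask.any()

    def test_clean_data_all_included(self):
        mask = pp.outlier_mask(np.arange(10, dtype=float))
        assert mask.all()

    def test_constant_vector_all_included(self):
        assert pp.outlier_mask(np.full(6, 2.0)).all()


class TestPrevalenceSplit:
    def test_boundary_inclusive(self):
        # 4 subjects: prevalence exactly 0.75 -> linear
        t = taxa_from([[1, 1], [1, 0], [1, 1], [0, 1]])
        split = pp.prevalence_split(t, threshold=0.75)
        assert set(split.linear_features) == {"f0", "f1"}

    def test_below_boundary_logistic(self):
        t = taxa_from([[1], [1], [1], [0], [0]])  # prevalence 0.6
        split = pp.prevalence_split(t, threshold=0.75)
        assert split.logistic_features == ["f0"]

    def test_all_zero_taxon_logistic(self):
        t = taxa_from([[0, 1], [0, 1], [0, 1], [0, 1]])
        split = pp.prevalence_split(t)
        assert split.logistic_features == ["f0"]
        assert split.prevalence["f0"] == 0.0


class TestGenotypePcs:
    def test_pc1_separates_planted_subpopulations(self):
        rng = np.random.default_rng(6)
        n, m = 200, 60
        maf_a = rng.uniform(0.1, 0.5, m)
        shift = np.clip(maf_a + rng.choice([-0.25, 0.25], m), 0.02, 0.5)
        pop = np.repeat([0, 1], n // 2)
        dos = np.where(pop[:, None] == 0,
                       rng.binomial(2, maf_a, (n, m)),
                       rng.binomial(2, shift, (n, m)))
        g = GenotypeTable(pd.DataFrame(
            dos.astype(float), index=[f"s{i}" for i in range(n)],
            columns=[f"rs{j}" for j in range(m)]))
        pcs = pp.genotype_pcs(g, k=3)
        r = np.corrcoef(pcs["PC1"], pop)[0, 1]
        assert abs(r) > 0.9

    def test_identical_subjects_zero_scores(self):
        g = GenotypeTable(pd.DataFrame(
            [[1.0, 2.0]] * 5, index=[f"s{i}" for i in range(5)],
            columns=["a", "b"]))
        with pytest.warns(UserWarning):
            pcs = pp.genotype_pcs(g, k=2)
        assert pcs.shape[1] == 0

    def test_variance_explained_non_increasing(self, small_cohort):
        g, _, _ = small_cohort
        pcs = pp.genotype_pcs(g, k=3)
        variances = pcs.var(axis=0).to_numpy()
        assert (np.diff(variances) <= 1e-9).all()
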