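import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import kstest

from cvgwas.assoc import (
    AssocConfig,
    allelic_or_from_counts,
    fit_logistic,
    gwas_scan,
    select_suggestive,
)
from cvgwas.io import ValidationError
from cvgwas.phenotype import consolidate_imputations, impute_missing, modeling_cohort
from cvgwas.sim import SimConfig, simulate_cohort

from _oracles import newton_logistic_oracle


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        beta, _, conv = fit_logistic(np.empty((100, 0)), y)
        assert conv
        assert beta[0] == pytest.approx(logit(0.3), abs=1e-10)

    def test_binary_predictor_equals_cross_product_or(self):
        # 2x2 table: exposed 30 (12 cases), unexposed 70 (14 cases)
        x = np.array([1.0] * 30 + [0.0] * 70)
        y = np.array([1.0] * 12 + [0.0] * 18 + [1.0] * 14 + [0.0] * 56)
        beta, _, _ = fit_logistic(x[:, None], y)
        or_table = (12 * 56) / (18 * 14)
        assert np.exp(beta[1]) == pytest.approx(or_table, rel=1e-8)

    def test_matches_independent_newton_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 1 / (1 + np.exp(-(0.3 + X @ [0.8, -0.5])))).astype(float)
        beta, _, conv = fit_logistic(X, y)
        oracle = newton_logistic_oracle(X, y)
        assert conv
        np.testing.assert_allclose(beta, oracle, atol=1e-8)

    def test_separation_flagged_not_raised(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(float)
        beta, _, conv = fit_logistic(x[:, None], y)
        assert not conv

    def test_non_binary_response_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones((3, 1)), np.array([0.0, 1.0, 2.0]))


@pytest.fixture(scope="module")
def scanned(modeling_ready):
    gm, coh = modeling_ready
    return gm, coh, gwas_scan(gm, coh)


class TestGwasScan:
    def test_consistency_with_standalone_fit(self, scanned):
        gm, coh, res = scanned
        from cvgwas.features import encode_clinical

        enc = encode_clinical(coh, ("age_q", "cisplatin_dose"))
        y = coh.df["label"].to_numpy()
        j = 17
        X = np.column_stack([gm.dosages[:, j], enc.to_numpy()])
        beta, cov, _ = fit_logistic(X, y)
        assert res.loc[j, "beta"] == pytest.approx(beta[1], abs=1e-6)
        assert res.loc[j, "se"] == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-5)

    def test_monomorphic_variant_yields_na_row(self, modeling_ready):
        gm, coh = modeling_ready
        gm2 = gm.subset(variants=gm.rsids[:5])
        D = gm2.dosages.copy()
        D[:, 2] = 0.0
        from cvgwas.io import GenotypeMatrix

        gm2 = GenotypeMatrix(gm2.sample_ids, gm2.variants, D)
        res = gwas_scan(gm2, coh)
        assert bool(res.loc[2, "monomorphic"])
        assert np.isnan(res.loc[2, "p_wald"])
        assert res.drop(index=2)["p_wald"].notna().all()

    def test_per_variant_complete_case_n(self, modeling_ready):
        gm, coh = modeling_ready
        D = gm.dosages.copy()
        D[:11, 3] = np.nan
        from cvgwas.io import GenotypeMatrix

        gm2 = GenotypeMatrix(gm.sample_ids, gm.variants, D)
        res = gwas_scan(gm2, coh)
        assert res.loc[3, "n_used"] == gm.n_samples - 11
        assert res.loc[4, "n_used"] == gm.n_samples

    def test_planted_causal_power(self):
        """A strongly associated variant (OR 2, MAF 0.3) reaches the
        suggestive threshold in nearly all replicates at n=2000."""
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            cfg = SimConfig(n_samples=2000, n_snps=50, maf_spectrum=(0.3, 0.3),
                            causal_snps=((7, 0.7),), clinical_effects={}, seed=700 + s)
            c = simulate_cohort(cfg)
            coh = consolidate_imputations(impute_missing(modeling_cohort(c.clinical)))
            gm = c.genotypes.subset(samples=coh.sample_ids)
            res = gwas_scan(gm, coh)
            if res.loc[7, "p_wald"] < 1e-4:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_null_calibration_and_uniformity(self):
        """Null Wald p-values: type-I fraction at 0.05 in [0.04, 0.06] and
        KS distance to U(0,1) below 0.02 over 10,000 variants."""
        cfg = SimConfig(n_samples=2000, n_snps=10_000, maf_spectrum=(0.05, 0.5),
                        causal_snps=(), clinical_effects={}, seed=77)
        c = simulate_cohort(cfg)
        coh = consolidate_imputations(impute_missing(modeling_cohort(c.clinical)))
        gm = c.genotypes.subset(samples=coh.sample_ids)
        res = gwas_scan(gm, coh)
        p = res["p_wald"].dropna().to_numpy()
        assert 0.04 <= (p < 0.05).mean() <= 0.06
        assert kstest(p, "uniform").statistic < 0.02

    def test_covariate_adjustment_stability(self, scanned):
        """Adjusting for covariates independent of genotype moves each beta
        by less than 3 SE."""
        gm, coh, res = scanned
        unadj = gwas_scan(gm, coh, AssocConfig(covariates=()))
        ok = res["converged"] & unadj["converged"]
        shift = np.abs(res.loc[ok, "beta"] - unadj.loc[ok, "beta"])
        assert (shift < 3 * res.loc[ok, "se"]).all()


class TestSelectSuggestive:
    def test_empty_when_nothing_below_threshold(self):
        res = pd.DataFrame({"rsid": ["a", "b"], "p_wald": [0.5, 0.2]})
        assert select_suggestive(res, 1e-4) == []

    def test_threshold_one_keeps_all_sorted(self):
        res = pd.DataFrame({"rsid": ["a", "b", "c"], "p_wald": [0.5, 0.2, np.nan]})
        assert select_suggestive(res, 1.0) == ["b", "a"]

    def test_planted_causal_ranks_first(self):
        cfg = SimConfig(n_samples=2000, n_snps=60, maf_spectrum=(0.3, 0.4),
                        causal_snps=((30, 0.8),), clinical_effects={}, seed=12)
        c = simulate_cohort(cfg)
        coh = consolidate_imputations(impute_missing(modeling_cohort(c.clinical)))
        gm = c.genotypes.subset(samples=coh.sample_ids)
        hits = select_suggestive(gwas_scan(gm, coh), 1e-4)
        assert hits and hits[0] == gm.rsids[30]


class TestAllelicOR:
    def test_symmetry_is_one(self):
        or_, _, corrected = allelic_or_from_counts([[10, 10], [10, 10]])
        assert or_ == pytest.approx(1.0) and not corrected

    def test_cross_product(self):
        or_, (lo, hi), _ = allelic_or_from_counts([[20, 10], [10, 20]])
        assert or_ == pytest.approx(4.0)
        assert lo < 4.0 < hi

    def test_zero_cell_haldane_correction(self):
        or_, _, corrected = allelic_or_from_counts([[5, 0], [3, 7]])
        assert corrected and np.isfinite(or_)

    def test_zero_margin_errors(self):
        with pytest.raises(ValidationError):
            allelic_or_from_counts([[0, 0], [3, 7]])
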