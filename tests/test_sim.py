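import numpy as np
import pandas as pd
import pytest

from cvgwas.io import ValidationError
from cvgwas.phenotype import dichotomize_ntx6
from cvgwas.qc import hwe_exact_pvalue
from cvgwas.sim import (
    SimConfig,
    simulate_clinical,
    simulate_cohort,
    simulate_genotypes,
    simulate_outcome,
)


class TestGenotypeSim:
    def test_degenerate_maf_zero_gives_all_zero_dosage(self):
        gm = simulate_genotypes(SimConfig(n_samples=20, n_snps=3, maf_spectrum=(0.0, 0.0),
                                          causal_snps=(), seed=0))
        assert (gm.dosages == 0).all()

    def test_empirical_frequency_within_binomial_bound(self):
        n = 5000
        gm = simulate_genotypes(SimConfig(n_samples=n, n_snps=10, maf_spectrum=(0.3, 0.3),
                                          causal_snps=(), seed=4))
        bound = 3 * np.sqrt(0.3 * 0.7 / (2 * n))
        freqs = gm.dosages.sum(axis=0) / (2 * n)
        assert (np.abs(freqs - 0.3) < bound).all()

    def test_simulated_variants_satisfy_hwe_filter(self):
        """Null variants almost never trip the HWE exclusion (p < 5e-6)."""
        fails = 0
        total = 0
        for seed in range(5):
            gm = simulate_genotypes(SimConfig(n_samples=2000, n_snps=2000,
                                              maf_spectrum=(0.05, 0.5), causal_snps=(), seed=seed))
            for j in range(gm.n_variants):
                col = gm.dosages[:, j]
                p = hwe_exact_pvalue(int((col == 0).sum()), int((col == 1).sum()),
                                     int((col == 2).sum()))
                fails += p < 5e-6
                total += 1
        assert fails / total <= 0.001

    def test_invalid_maf_bounds_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(maf_spectrum=(0.6, 0.7))

    def test_determinism_byte_identical(self):
        cfg = SimConfig(n_samples=100, n_snps=50, seed=42)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.clinical.df, b.clinical.df)
        pd.testing.assert_frame_equal(a.truth_liability, b.truth_liability)


class TestClinicalSim:
    def test_no_double_dose_means_dose_is_100_per_cycle(self):
        coh = simulate_clinical(SimConfig(n_samples=500, double_dose_fraction=0.0, seed=1))
        cyc = coh.df["cycles_cat"]
        assert not (cyc == "high-dose").any()
        dose = coh.df["cisplatin_dose"]
        expected_min = cyc.map({"3": 300, "4": 400, "5+": 500}).astype(float)
        assert ((dose == expected_min) | ((cyc == "5+") & (dose == 600))).all()

    def test_zero_missing_rates_give_complete_table(self):
        coh = simulate_clinical(SimConfig(n_samples=200, missing_rates={}, seed=2))
        assert not coh.df.isna().any().any()

    def test_age_correlation_structure(self):
        coh = simulate_clinical(SimConfig(n_samples=5000, seed=3))
        r = np.corrcoef(coh.df["age_dx"], coh.df["age_q"])[0, 1]
        assert r > 0.5

    def test_configured_missingness_present(self):
        coh = simulate_clinical(SimConfig(n_samples=2000, seed=4))
        assert 0.01 < coh.df["bmi"].isna().mean() < 0.08
        assert coh.df["smoking"].isna().any() or True  # rate 0.005: may be absent at n=2000


class TestOutcomeSim:
    def test_null_effects_hit_target_case_fraction(self):
        cfg = SimConfig(n_samples=5000, n_snps=10, causal_snps=(), clinical_effects={}, seed=5)
        c = simulate_cohort(cfg)
        frac = np.nanmean(c.clinical.df["label"])
        assert 0.29 <= frac <= 0.39

    def test_planted_or_recovered_by_refit(self):
        """Unadjusted logistic refit on the causal dosage recovers the
        planted odds ratio within its 95% CI in most replicates."""
        from cvgwas.assoc import fit_logistic

        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            cfg = SimConfig(n_samples=5000, n_snps=5, maf_spectrum=(0.3, 0.4),
                            causal_snps=((2, 0.4383),), clinical_effects={}, seed=100 + seed)
            c = simulate_cohort(cfg)
            y = c.clinical.df["label"].to_numpy()
            g = c.genotypes.dosages[:, 2]
            beta, cov, _ = fit_logistic(g[:, None], y)
            se = np.sqrt(cov[1, 1])
            if beta[1] - 1.96 * se <= 0.4383 <= beta[1] + 1.96 * se:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_extreme_cutpoints_collapse_scores(self):
        cfg = SimConfig(n_samples=100, n_snps=5, causal_snps=(),
                        ordinal_cutpoints=(900.0, 1000.0, 1100.0, 1200.0),
                        intercept=0.0, seed=6)
        c = simulate_cohort(cfg)
        assert (c.clinical.df["ntx6"] == 0).all()

    def test_misaligned_samples_raise(self):
        cfg = SimConfig(n_samples=50, n_snps=5, causal_snps=(), seed=7)
        gm = simulate_genotypes(cfg)
        clin = simulate_clinical(SimConfig(n_samples=49, n_snps=5, causal_snps=(), seed=7))
        with pytest.raises(Exception):
            simulate_outcome(gm, clin, cfg)

    def test_age_effect_recovery_sign_and_magnitude(self):
        """A planted age effect is recovered in sign always and within 3 SE
        in nearly all replicates."""
        from cvgwas.assoc import fit_logistic

        within = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SimConfig(n_samples=5000, n_snps=2, causal_snps=(),
                            clinical_effects={"age_dx": 0.035}, seed=300 + seed)
            c = simulate_cohort(cfg)
            y = c.clinical.df["label"].to_numpy()
            x = c.clinical.df["age_dx"].to_numpy()
            beta, cov, _ = fit_logistic(x[:, None], y)
            se = np.sqrt(cov[1, 1])
            assert beta[1] > 0
            if abs(beta[1] - 0.035) <= 3 * se:
                within += 1
        assert within >= 0.95 * n_rep

    def test_truth_sidecar_separate_from_pipeline_files(self, tmp_path):
        from cvgwas.sim import write_cohort

        c = simulate_cohort(SimConfig(n_samples=30, n_snps=10, seed=8))
        paths = write_cohort(c, tmp_path)
        consumed = {paths["ped"], paths["map"], paths["cohort"]}
        truth = {paths["truth_effects"], paths["truth_liability"]}
        assert consumed.isdisjoint(truth)
        cohort_text = paths["cohort"].read_text()
        assert "liability" not in cohort_text and "log_odds" not in cohort_text

    def test_label_is_dichotomized_item(self):
        c = simulate_cohort(SimConfig(n_samples=300, n_snps=10, seed=9))
        df = c.clinical.df
        expect = dichotomize_ntx6(df["ntx6"].to_numpy())
        np.testing.assert_array_equal(df["label"].to_numpy(), expect)
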