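import numpy as np
import pytest

from cvgwas.io import CohortTable
from cvgwas.phenotype import consolidate_imputations, impute_missing, modeling_cohort
from cvgwas.sim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort at desk scale (400 x 300)."""
    return simulate_cohort(SimConfig(n_samples=400, n_snps=300, seed=11))


@pytest.fixture(scope="session")
def modeling_ready(small_cohort):
    """Label-complete, imputation-consolidated cohort aligned to genotypes."""
    coh = modeling_cohort(small_cohort.clinical)
    coh = consolidate_imputations(impute_missing(coh))
    gm = small_cohort.genotypes.subset(samples=coh.sample_ids)
    return gm, coh


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects and shuffled labels (pure noise)."""
    c = simulate_cohort(
        SimConfig(n_samples=400, n_snps=300, causal_snps=(), clinical_effects={}, seed=23)
    )
    coh = modeling_cohort(c.clinical)
    coh = consolidate_imputations(impute_missing(coh))
    rng = np.random.default_rng(23)
    df = coh.df.copy()
    lab = df["label"].to_numpy().copy()
    rng.shuffle(lab)
    df["label"] = lab
    gm = c.genotypes.subset(samples=df.index.tolist())
    return gm, CohortTable(df)
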