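"""Synthetic cohort generator.

Emulates the statistical structure of a chemotherapy late-effects cohort:
~400 testicular cancer survivors genotyped on a SNP array, self-reported
hearing difficulty on a 0-4 ordinal item dichotomized at >= 2 (~34% cases),
cumulative cisplatin dose of 100 mg/m2 per treatment cycle with a ~10%
double-dose subgroup, a handful of planted causal variants with per-allele
odds ratios in the 1.1-2.1 range, clinical effects of age and cycle count,
and missing-completely-at-random gaps in BMI and smoking.

The ordinal outcome follows a latent-liability model: liability =
intercept + sum(dosage x log-OR) + sum(covariate x log-OR) + standard
logistic noise, cut at four strictly increasing thresholds.  Because the
noise is logistic, the dichotomized outcome obeys a logistic regression
exactly, making parameter-recovery tests well-posed.  The ground truth
(causal variants, effects, per-sample liability) is kept in a sidecar that
the analysis pipeline never reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from cvgwas.features import encode_clinical
from cvgwas.io import (
    AlignmentError,
    CohortTable,
    GenotypeMatrix,
    ValidationError,
    write_cohort_table,
    write_plink_text,
)
from cvgwas.phenotype import dichotomize_ntx6
from cvgwas.priors import PRIOR_SNPS

_BASES = np.array(list("ACGT"))

#: planted per-allele log odds ratios; indices < 26 fall on the packaged
#: prior panel (mirroring review-known variants), one falls outside it
#: (a variant only the GWAS can find)
DEFAULT_CAUSAL = (
    (22, 0.4383),   # prior-panel variant, OR 1.55
    (1, 0.3148),    # prior-panel variant, OR 1.37
    (200, 0.7372),  # non-prior variant, OR 2.09
    (14, 0.6098),   # prior-panel variant, OR 1.84
    (2, 0.1044),    # prior-panel variant, OR 1.11
    (18, 0.3001),   # prior-panel variant, OR 1.35
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults reproduce the emulated cohort conditions."""

    n_samples: int = 400
    n_snps: int = 1000
    maf_spectrum: tuple[float, float] = (0.05, 0.5)
    #: None -> the default planted panel, restricted to indices < n_snps
    causal_snps: tuple[tuple[int, float], ...] | None = None
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: {"age_dx": 0.035, "cycles_cat": 0.55}
    )
    intercept: float | None = None  # None -> calibrated to target_case_fraction
    target_case_fraction: float = 0.344
    ordinal_cutpoints: tuple[float, float, float, float] = (-1.5, 0.0, 1.8, 3.5)
    double_dose_fraction: float = 0.10
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.04, "smoking": 0.005}
    )
    missing_mechanism: str = "mcar"  # or "mar_age": odds of missingness rise with age
    genotype_missing_rate: float = 0.0
    name_prior_snps: bool = True  # label the first 26 variants with the prior panel rsIDs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.causal_snps is None:
            object.__setattr__(
                self,
                "causal_snps",
                tuple((i, e) for i, e in DEFAULT_CAUSAL if i < self.n_snps),
            )
        lo, hi = self.maf_spectrum
        if not (0 <= lo <= hi <= 0.5):
            raise ValidationError(f"MAF bounds must satisfy 0 <= lo <= hi <= 0.5, got {self.maf_spectrum}")
        if list(self.ordinal_cutpoints) != sorted(set(self.ordinal_cutpoints)):
            raise ValidationError("ordinal cutpoints must be strictly increasing")
        for idx, _ in self.causal_snps:
            if not (0 <= idx < self.n_snps):
                raise ValidationError(f"causal index {idx} out of range for {self.n_snps} SNPs")
        for name, rate in self.missing_rates.items():
            if not (0 <= rate <= 1):
                raise ValidationError(f"missing rate for {name!r} must be in [0,1]")
            if rate > 0 and name in self.clinical_effects:
                raise ValidationError(f"covariate {name!r} cannot both carry an effect and be masked")
        if not (0 <= self.double_dose_fraction <= 1):
            raise ValidationError("double_dose_fraction must be in [0,1]")
        if not (0 <= self.genotype_missing_rate <= 1):
            raise ValidationError("genotype_missing_rate must be in [0,1]")
        if self.missing_mechanism not in ("mcar", "mar_age"):
            raise ValidationError(f"unknown missing mechanism {self.missing_mechanism!r}")
        if self.n_samples < 2 or self.n_snps < 1:
            raise ValidationError("need at least 2 samples and 1 SNP")


@dataclass
class SyntheticCohort:
    """Generated data plus the ground truth kept out of the pipeline's reach."""

    genotypes: GenotypeMatrix
    clinical: CohortTable
    truth_effects: pd.DataFrame  # causal rsid, variant index, per-allele log-OR
    truth_liability: pd.DataFrame  # per-sample linear predictor and liability


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _sample_ids(config: SimConfig) -> list[str]:
    return [f"S{i:04d}" for i in range(config.n_samples)]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Independent biallelic variants in Hardy-Weinberg proportions.

    Each variant's minor allele frequency is drawn uniformly from the
    configured spectrum; dosages are Binomial(2, f) draws, then recoded so
    that allele2 is the empirical minor allele (the same canonical coding
    the PLINK-text reader produces, so a write/read round trip is exact).
    """
    rng = _rng(config, 0)
    n, v = config.n_samples, config.n_snps
    lo, hi = config.maf_spectrum
    mafs = rng.uniform(lo, hi, size=v) if hi > lo else np.full(v, lo)
    dosages = rng.binomial(2, mafs, size=(n, v)).astype(float)
    base_idx = rng.integers(0, 4, size=v)
    alt_off = rng.integers(1, 4, size=v)
    allele1 = _BASES[base_idx]
    allele2 = _BASES[(base_idx + alt_off) % 4]
    if config.genotype_missing_rate > 0:
        mask = rng.random((n, v)) < config.genotype_missing_rate
        dosages[mask] = np.nan
    # canonical minor-allele coding over the OBSERVED genotypes (same rule
    # the PLINK-text reader applies); ties at 0.5 keep the lexicographically
    # smaller allele as allele2 (matches io.minor_allele_order)
    counts2 = np.nansum(dosages, axis=0)
    n_obs = (~np.isnan(dosages)).sum(axis=0)
    flip = (counts2 > n_obs) | ((counts2 == n_obs) & (allele1 < allele2))
    flip &= counts2 > 0  # monomorphic columns stay as drawn
    dosages[:, flip] = 2 - dosages[:, flip]
    allele1[flip], allele2[flip] = allele2[flip].copy(), allele1[flip].copy()
    rsids = [
        PRIOR_SNPS[j] if (config.name_prior_snps and j < len(PRIOR_SNPS)) else f"rs9{j:06d}"
        for j in range(v)
    ]
    variants = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": [str(1 + j % 22) for j in range(v)],
            "pos": np.arange(1, v + 1) * 1000,
            "allele1": allele1,
            "allele2": allele2,
        }
    )
    return GenotypeMatrix(_sample_ids(config), variants, dosages)


def simulate_clinical(config: SimConfig) -> CohortTable:
    """Clinical covariates with the emulated marginal structure.

    Cumulative cisplatin dose is 100 mg/m2 per cycle (200 mg/m2 per cycle
    for the double-dose subgroup, recorded as the 'high-dose' cycle
    category); age at questionnaire is age at diagnosis plus a 7-30 year
    follow-up gap, giving the two a strong positive correlation.
    """
    rng = _rng(config, 1)
    n = config.n_samples
    age_dx = np.clip(rng.normal(31.0, 7.0, n), 15, 60)
    age_q = age_dx + rng.uniform(7.0, 30.0, n)
    double = rng.random(n) < config.double_dose_fraction
    cyc_norm = rng.choice(["3", "4", "5+"], size=n, p=[0.30, 0.62, 0.08])
    cycles_cat = np.where(double, "high-dose", cyc_norm)
    n_cycles = np.select(
        [cycles_cat == "3", cycles_cat == "4", cycles_cat == "5+"],
        [3, 4, rng.choice([5, 6], size=n)],
        default=rng.choice([3, 4], size=n),  # high-dose arm ran 3-4 cycles
    )
    dose_per_cycle = np.where(double, 200.0, 100.0)
    cisplatin_dose = dose_per_cycle * n_cycles
    bmi = np.clip(rng.normal(23.5, 4.0, n), 16, 45)
    gfr = np.clip(rng.normal(122.0, 16.0, n), 60, 180)
    alcohol = np.clip(np.round(rng.gamma(1.4, 4.5, n)), 0, 40)
    histology = rng.choice(["seminoma", "non-seminoma"], size=n, p=[0.21, 0.79])
    igcccg = rng.choice(["good", "intermediate", "poor"], size=n, p=[0.81, 0.14, 0.05])
    smoking = rng.choice(["never", "former", "current"], size=n, p=[0.45, 0.33, 0.22])
    df = pd.DataFrame(
        {
            "sample_id": _sample_ids(config),
            "age_dx": np.round(age_dx, 1),
            "age_q": np.round(age_q, 1),
            "bmi": np.round(bmi, 1),
            "gfr": np.round(gfr, 1),
            "cisplatin_dose": cisplatin_dose,
            "cycles_cat": cycles_cat,
            "histology": histology,
            "igcccg": igcccg,
            "alcohol": alcohol,
            "smoking": smoking,
        }
    )
    for col, rate in config.missing_rates.items():
        if col not in df.columns or rate == 0:
            continue
        if config.missing_mechanism == "mar_age":
            z = (age_q - age_q.mean()) / max(age_q.std(), 1e-9)
            p = expit(z + np.log(rate / (1 - rate) if rate < 1 else 1e9))
            mask = rng.random(n) < p
        else:
            mask = rng.random(n) < rate
        df.loc[mask, col] = np.nan
    return CohortTable(df)


def _linear_predictor(
    genotypes: GenotypeMatrix, clinical: CohortTable, config: SimConfig
) -> np.ndarray:
    lp = np.zeros(config.n_samples)
    D = np.nan_to_num(genotypes.dosages, nan=0.0)
    for idx, eff in config.causal_snps:
        lp += eff * D[:, idx]
    encoded = encode_clinical(clinical)
    for name, eff in config.clinical_effects.items():
        if name not in encoded.columns:
            raise ValidationError(f"clinical effect on unknown covariate {name!r}")
        col = encoded[name].to_numpy()
        if np.isnan(col).any():
            raise ValidationError(f"covariate {name!r} with planted effect has missing values")
        lp += eff * (col - np.nanmean(col))
    return lp


def calibrate_intercept(lp: np.ndarray, cutpoint: float, target: float) -> float:
    """Solve E[sigmoid(intercept + lp - cutpoint)] = target for the intercept."""
    f = lambda b0: expit(b0 + lp - cutpoint).mean() - target
    return float(brentq(f, -50, 50))


def simulate_outcome(
    genotypes: GenotypeMatrix, clinical: CohortTable, config: SimConfig
) -> tuple[CohortTable, pd.DataFrame]:
    """Fill the ordinal hearing item (plus companion items) and the label.

    Returns the completed cohort table and the per-sample truth sidecar.
    """
    if genotypes.sample_ids != clinical.sample_ids:
        raise AlignmentError("genotype and clinical sample ids are not aligned")
    rng = _rng(config, 2)
    lp = _linear_predictor(genotypes, clinical, config)
    cuts = np.asarray(config.ordinal_cutpoints)
    b0 = (
        config.intercept
        if config.intercept is not None
        else calibrate_intercept(lp, cuts[1], config.target_case_fraction)
    )
    liability = b0 + lp + rng.logistic(size=config.n_samples)
    ntx6 = np.searchsorted(cuts, liability).astype(float)
    # companion items: same latent signal, independent noise of varying scale
    ntx7 = np.searchsorted(cuts, 0.55 * (b0 + lp) + 1.3 * rng.logistic(size=config.n_samples)).astype(float)
    hcq1 = np.searchsorted(cuts, 0.6 * liability + 0.9 * rng.logistic(size=config.n_samples)).astype(float)
    hcq2 = np.searchsorted(cuts, liability + 0.55 * rng.logistic(size=config.n_samples)).astype(float)
    df = clinical.df.copy()
    df["ntx6"], df["ntx7"], df["hcq1"], df["hcq2"] = ntx6, ntx7, hcq1, hcq2
    rate = config.missing_rates.get("ntx6", 0.0)
    if rate > 0:
        df.loc[rng.random(config.n_samples) < rate, ["ntx6"]] = np.nan
    df["label"] = dichotomize_ntx6(df["ntx6"].to_numpy())
    truth = pd.DataFrame(
        {
            "sample_id": clinical.sample_ids,
            "linear_predictor": lp,
            "intercept": b0,
            "liability": liability,
        }
    )
    return CohortTable(df.reset_index()), truth


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate genotypes, covariates and outcomes in one call."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    gm = simulate_genotypes(config)
    clinical = simulate_clinical(config)
    cohort, truth_liab = simulate_outcome(gm, clinical, config)
    truth_eff = pd.DataFrame(
        {
            "rsid": [gm.rsids[idx] for idx, _ in config.causal_snps],
            "variant_index": [idx for idx, _ in config.causal_snps],
            "log_odds": [eff for _, eff in config.causal_snps],
        }
    )
    return SyntheticCohort(gm, cohort, truth_eff, truth_liab)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write PLINK text genotypes, the cohort table, and the truth sidecars.

    Truth files are clearly named and live beside (never inside) the files
    the pipeline consumes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped, map_ = write_plink_text(cohort.genotypes, outdir / "genotypes")
    table = write_cohort_table(cohort.clinical, outdir / "cohort.csv")
    eff = outdir / "truth_effects.csv"
    cohort.truth_effects.to_csv(eff, index=False)
    liab = outdir / "truth_liability.csv"
    cohort.truth_liability.to_csv(liab, index=False)
    return {"ped": ped, "map": map_, "cohort": table, "truth_effects": eff, "truth_liability": liab}
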