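"""Variant- and sample-level genotype quality control.

Variant filters mirror standard array QC: exclude variants with call rate
strictly below 0.98, Hardy-Weinberg exact-test p-value strictly below
5e-6, or minor allele frequency strictly below 0.01.  Sample QC removes
samples with call rate below 0.97 or autosomal heterozygosity more than 3
standard deviations from the cohort mean.  Variant filters run first, once;
the composition is a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cvgwas.io import GenotypeMatrix, ValidationError


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; comparisons are strict (a variant exactly at a
    threshold passes)."""

    min_call_rate: float = 0.98
    hwe_alpha: float = 5e-6
    min_maf: float = 0.01
    sample_min_call_rate: float = 0.97
    het_sd_bound: float = 3.0
    enable_sample_qc: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "hwe_alpha", "min_maf", "sample_min_call_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.het_sd_bound <= 0:
            raise ValidationError("het_sd_bound must be positive")


def call_rate(gm: GenotypeMatrix, variant: int | str) -> float:
    """Fraction of samples with a called genotype at the variant."""
    j = _variant_index(gm, variant)
    col = gm.dosages[:, j]
    return float(np.mean(~np.isnan(col)))


def minor_allele_frequency(gm: GenotypeMatrix, variant: int | str) -> float:
    """min(f, 1-f) where f is the allele2 frequency among called genotypes."""
    j = _variant_index(gm, variant)
    col = gm.dosages[:, j]
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValidationError("allele frequency undefined: all genotypes missing")
    f = obs.sum() / (2 * obs.size)
    return float(min(f, 1 - f))


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) whose conditional probability does
    not exceed that of the observed count.  Probabilities follow the
    standard recurrence, which is stable at large counts.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or c != int(c):
            raise ValidationError("genotype counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValidationError("at least one genotype required")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele count
    # attainable het counts share the parity of the rare-allele count
    het_lo = rare % 2
    het_hi = min(rare, 2 * n - rare)
    hets = np.arange(het_lo, het_hi + 1, 2)
    if hets.size == 1:
        return 1.0
    # unnormalized probabilities via the recurrence
    # P(h+2)/P(h) = (rare-h)(2n-rare-h) / ((h+2)(h+1))  [divided by 4... folded in]
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for i in range(hets.size - 1):
        h = hets[i]
        probs[i + 1] = probs[i] * (rare - h) * (2 * n - rare - h) / ((h + 2.0) * (h + 1.0))
        if probs[i + 1] > 1e250:  # rescale to avoid overflow
            probs[: i + 2] /= probs[i + 1]
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= p_obs * (1 + 1e-10)].sum()
    return float(min(p, 1.0))


def variant_qc_report(gm: GenotypeMatrix, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-variant call rate, MAF, HWE p and pass flags (strict-threshold
    semantics; overall pass is the conjunction of the three criteria)."""
    thresholds = thresholds or QCThresholds()
    D = gm.dosages
    called = ~np.isnan(D)
    n_called = called.sum(axis=0)
    cr = n_called / gm.n_samples if gm.n_samples else np.zeros(gm.n_variants)
    alt = np.nansum(D, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    maf = np.minimum(f, 1 - f)
    hwe = np.full(gm.n_variants, np.nan)
    for j in range(gm.n_variants):
        if n_called[j] == 0:
            continue
        col = D[called[:, j], j]
        hwe[j] = hwe_exact_pvalue(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    pass_cr = cr >= thresholds.min_call_rate
    pass_hwe = ~(hwe < thresholds.hwe_alpha)  # NaN passes (undefined, caught by call rate)
    pass_maf = ~(maf < thresholds.min_maf)
    report = pd.DataFrame(
        {
            "rsid": gm.variants["rsid"],
            "call_rate": cr,
            "maf": maf,
            "hwe_p": hwe,
            "pass_call_rate": pass_cr,
            "pass_hwe": pass_hwe,
            "pass_maf": pass_maf,
        }
    )
    report["pass"] = report[["pass_call_rate", "pass_hwe", "pass_maf"]].all(axis=1)
    return report


def apply_variant_filters(
    gm: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing any criterion; return the filtered matrix and
    the full per-variant report (one row per input variant)."""
    report = variant_qc_report(gm, thresholds)
    keep = report["pass"].to_numpy()
    return gm.subset(variants=keep), report


def sample_qc(
    gm: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove samples with low call rate or outlying heterozygosity.

    Heterozygosity is the het fraction among called genotypes; the +/- SD
    rule is skipped (documented in the report) when fewer than two samples
    or zero spread make the bound undefined.
    """
    thresholds = thresholds or QCThresholds()
    D = gm.dosages
    called = ~np.isnan(D)
    n_called = called.sum(axis=1)
    cr = n_called / gm.n_variants if gm.n_variants else np.ones(gm.n_samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, np.nansum(D == 1, axis=1) / n_called, np.nan)
    pass_cr = cr >= thresholds.sample_min_call_rate
    het_rule_applied = gm.n_samples >= 2 and np.nanstd(het) > 0
    if het_rule_applied:
        mu, sd = np.nanmean(het), np.nanstd(het, ddof=1)
        pass_het = np.abs(het - mu) <= thresholds.het_sd_bound * sd
        pass_het |= np.isnan(het)
    else:
        pass_het = np.ones(gm.n_samples, dtype=bool)
    if not thresholds.enable_sample_qc:
        pass_cr = np.ones(gm.n_samples, dtype=bool)
        pass_het = np.ones(gm.n_samples, dtype=bool)
    report = pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "call_rate": cr,
            "heterozygosity": het,
            "pass_call_rate": pass_cr,
            "pass_heterozygosity": pass_het,
            "het_rule_applied": het_rule_applied and thresholds.enable_sample_qc,
        }
    )
    report["pass"] = report["pass_call_rate"] & report["pass_heterozygosity"]
    keep = report["pass"].to_numpy()
    return gm.subset(samples=keep), report


def run_qc(
    gm: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Variant filters first, then sample QC, each applied once."""
    filtered, vreport = apply_variant_filters(gm, thresholds)
    cleaned, sreport = sample_qc(filtered, thresholds)
    return cleaned, vreport, sreport


def _variant_index(gm: GenotypeMatrix, variant: int | str) -> int:
    if isinstance(variant, str):
        hits = np.flatnonzero((gm.variants["rsid"] == variant).to_numpy())
        if not hits.size:
            raise ValidationError(f"unknown variant {variant!r}")
        return int(hits[0])
    if not (0 <= variant < gm.n_variants):
        raise ValidationError(f"variant index {variant} out of range")
    return int(variant)
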