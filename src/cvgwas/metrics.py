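"""Performance metrics, attribution, and cohort-comparison statistics.

ROC-AUC uses the rank (Mann-Whitney) formulation with ties counted 1/2;
confusion-matrix rates use score >= 0.50 as the positive call.  Mean AUC
across repeated splits gets a normal-approximation 95% CI (mean +/- 1.96
SD/sqrt(R)); a bootstrap alternative is provided.  SHAP attributions for
the linear-logistic model are exact: coefficient times deviation from the
training-background mean, on the log-odds scale.  Cohort tables are
compared with the tie-corrected Mann-Whitney U test (ordinal/continuous)
or the chi-squared test with Yates continuity correction (2x2 categorical).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from cvgwas.io import ValidationError


def roc_auc(scores, labels) -> float:
    """Probability a random case outranks a random control (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must align")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def confusion_metrics(scores, labels, cutoff: float = 0.50) -> dict[str, float]:
    """Confusion counts and derived rates at the given score cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pred = (s >= cutoff).astype(float)
    tp = float(((pred == 1) & (y == 1)).sum())
    fp = float(((pred == 1) & (y == 0)).sum())
    tn = float(((pred == 0) & (y == 0)).sum())
    fn = float(((pred == 0) & (y == 1)).sum())
    div = lambda a, b: a / b if b > 0 else np.nan
    sens = div(tp, tp + fn)
    spec = div(tn, tn + fp)
    ppv = div(tp, tp + fp)
    npv = div(tn, tn + fn)
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else np.nan
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": sens, "specificity": spec,
        "ppv": ppv, "npv": npv,
        "fdr": 1 - ppv if not np.isnan(ppv) else np.nan,
        "for": 1 - npv if not np.isnan(npv) else np.nan,
        "mcc": float(mcc) if not np.isnan(mcc) else np.nan,
    }


def aggregate_ci(values, method: str = "normal", n_boot: int = 2000,
                 seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Mean of per-repeat values with a 95% CI.

    ``normal``: mean +/- 1.96 SD/sqrt(R).  ``bootstrap``: percentile CI of
    the resampled mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values")
    m = float(v.mean())
    if method == "normal":
        half = 1.959963984540054 * v.std(ddof=1) / np.sqrt(v.size)
        return m, (m - half, m + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return m, (float(lo), float(hi))
    raise ValidationError(f"unknown CI method {method!r}")


def linear_shap(coef, intercept: float, X, background_means) -> tuple[np.ndarray, float]:
    """Exact SHAP attributions for a linear-logistic model (log-odds scale).

    Attribution of feature j on sample i is ``coef_j * (x_ij - mean_j)``
    where the means come from the training background; the base value plus
    the attributions reconstructs the log-odds prediction exactly.
    """
    coef = np.asarray(coef, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bg = np.asarray(background_means, dtype=float)
    if bg.shape != coef.shape or X.shape[1] != coef.size:
        raise ValidationError("coef, background means and X widths must agree")
    phi = coef[None, :] * (X - bg[None, :])
    base = float(intercept + coef @ bg)
    return phi, base


def selection_frequency(report) -> pd.Series:
    """Feature -> number of repeats (of the 30 repeat-level models) in which
    it was selected in at least one outer fold; sorted descending."""
    counts: dict[str, int] = {}
    for r in range(report.n_repeats):
        chosen = set()
        for rec in report.fits[r]:
            chosen.update(rec.features)
        for f in chosen:
            counts[f] = counts.get(f, 0) + 1
    ser = pd.Series(counts, dtype=int)
    return ser.sort_values(ascending=False, kind="mergesort")


def mwu_tie_corrected(counts_a, counts_b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U from ordinal category counts.

    Inputs are per-category counts over the same ordered categories.
    Returns (U of group A, z with tie-corrected variance, two-sided p from
    the normal approximation).
    """
    a = np.asarray(counts_a, dtype=int)
    b = np.asarray(counts_b, dtype=int)
    if a.shape != b.shape:
        raise ValidationError("count vectors must cover the same categories")
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError("each group needs at least one observation")
    xa = np.repeat(np.arange(a.size), a)
    xb = np.repeat(np.arange(b.size), b)
    return mwu_from_samples(xa, xb)


def mwu_from_samples(xa, xb) -> tuple[float, float, float]:
    """Tie-corrected normal-approximation Mann-Whitney on raw samples."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    na, nb = xa.size, xb.size
    if na == 0 or nb == 0:
        raise ValidationError("each group needs at least one observation")
    pooled = np.concatenate([xa, xb])
    ranks = stats.rankdata(pooled)
    u = ranks[:na].sum() - na * (na + 1) / 2
    n = na + nb
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = na * nb / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u), 0.0, 1.0
    z = (u - na * nb / 2) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(u), float(z), float(min(p, 1.0))


def chi2_contingency(table, continuity_correction: bool = True) -> tuple[float, float]:
    """Pearson chi-squared test of independence; Yates correction for 2x2."""
    t = np.asarray(table, dtype=float)
    if t.sum() <= 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    correction = continuity_correction and t.shape == (2, 2)
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def cohort_comparison(cohort) -> pd.DataFrame:
    """Baseline-characteristics comparison of cases vs controls.

    Ordinal/continuous covariates use the tie-corrected Mann-Whitney test;
    2x2 categorical ones the Yates-corrected chi-squared test.  Continuous
    variables are annotated with a Shapiro-Wilk normality p-value (report
    annotation only; it drives no decision).
    """
    from cvgwas.features import encode_clinical

    df = cohort.df
    y = df["label"]
    enc = encode_clinical(cohort)
    rows = []
    for col in enc.columns:
        x = enc[col]
        keep = x.notna() & y.notna()
        xa, xb = x[keep & (y == 1)], x[keep & (y == 0)]
        if len(xa) == 0 or len(xb) == 0:
            continue
        if col == "histology":
            tab = np.array(
                [[(xa == 0).sum(), (xa == 1).sum()], [(xb == 0).sum(), (xb == 1).sum()]]
            )
            stat, p = chi2_contingency(tab)
            test = "chi2_yates"
        else:
            _, stat, p = mwu_from_samples(xa.to_numpy(), xb.to_numpy())
            test = "mwu"
        shapiro_p = np.nan
        if x.nunique() > 8:  # treat as continuous
            shapiro_p = float(stats.shapiro(x[keep]).pvalue)
        rows.append(
            {
                "covariate": col,
                "test": test,
                "statistic": stat,
                "p_value": p,
                "median_affected": float(xa.median()),
                "median_non_affected": float(xb.median()),
                "shapiro_p": shapiro_p,
            }
        )
    return pd.DataFrame(rows)
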