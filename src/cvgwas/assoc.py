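"""Covariate-adjusted per-variant logistic association (the GWAS engine).

Each variant is tested with ``label ~ dosage + covariates`` by maximum
likelihood (Newton/IRLS), reporting the per-allele log-odds, Wald standard
error, odds ratio with 95% CI, and two-sided Wald p-value.  Missing
dosages are handled per-variant as complete-case, matching the behavior of
standard GWAS tooling; the default adjustment set is age at questionnaire
and cumulative cisplatin dose.  The scan is vectorized across variants:
designs differ only in the dosage column, so the Newton updates for all
variants are batched into stacked (p x p) solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from cvgwas.features import encode_clinical
from cvgwas.io import CohortTable, GenotypeMatrix, ValidationError

MAX_ABS_BETA = 15.0  # beyond this the fit is flagged as (quasi-)separated


@dataclass(frozen=True)
class AssocConfig:
    covariates: tuple[str, ...] = ("age_q", "cisplatin_dose")
    suggestive_p: float = 1e-4
    max_iter: int = 50
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if not (0 < self.suggestive_p < 1):
            raise ValidationError("suggestive_p must be in (0, 1)")


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    add_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic regression via IRLS.

    Returns ``(coefficients, covariance, converged)`` with the intercept
    first when ``add_intercept``.  The covariance is the inverse observed
    information at the optimum.  Non-convergence (including separation,
    detected as a coefficient exceeding 15 in absolute value) is flagged,
    not raised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] != 1 and len(y) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("response must be binary 0/1")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("design matrix is rank deficient")
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    beta[0] = logit(ybar) if add_intercept else 0.0
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        w = mu * (1 - mu)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step-halving keeps the likelihood monotone near separation
        for _ in range(30):
            cand = beta + step
            ll_new = float(np.sum(y * (X @ cand) - np.logaddexp(0.0, X @ cand)))
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if abs(ll_new - ll_old) < tol * (abs(ll_new) + 1.0):
            converged = True
            break
        ll_old = ll_new
    if np.abs(beta).max() > MAX_ABS_BETA:
        converged = False
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, converged


def _batched_scan(
    G: np.ndarray,
    C: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Newton iterations for all variants at once.

    ``G`` is (n, V) dosage with NaN missing; ``C`` (n, c) complete
    covariates; per-variant design is [1, g, C] and missing dosages carry
    weight zero (complete-case per variant).
    """
    n, V = G.shape
    c = C.shape[1]
    p = 2 + c
    M = (~np.isnan(G)).astype(float)  # (n, V)
    Gf = np.nan_to_num(G, nan=0.0)
    n_used = M.sum(axis=0)
    # complete-case monomorphic detection
    with np.errstate(invalid="ignore"):
        mean_g = (Gf * M).sum(axis=0) / np.maximum(n_used, 1)
        var_g = ((Gf - mean_g) ** 2 * M).sum(axis=0) / np.maximum(n_used, 1)
    mono = (var_g <= 0) | (n_used < p)
    Mt, Gt = M.T.copy(), Gf.T.copy()  # (V, n)
    beta = np.zeros((V, p))
    with np.errstate(divide="ignore"):
        ybar = np.clip((Mt * y).sum(1) / np.maximum(n_used, 1), 1e-12, 1 - 1e-12)
    beta[:, 0] = logit(ybar)
    active = ~mono
    ll_old = np.full(V, -np.inf)
    converged = np.zeros(V, dtype=bool)
    H = np.zeros((V, p, p))
    for _ in range(max_iter):
        if not active.any():
            break
        eta = beta[:, [0]] + beta[:, [1]] * Gt + beta[:, 2:] @ C.T  # (V, n)
        mu = expit(eta)
        w = mu * (1 - mu) * Mt
        r = (y[None, :] - mu) * Mt
        g0 = r.sum(1)
        g1 = (r * Gt).sum(1)
        gC = r @ C
        grad = np.column_stack([g0, g1, gC])
        H[:, 0, 0] = w.sum(1)
        H[:, 0, 1] = H[:, 1, 0] = (w * Gt).sum(1)
        H[:, 0, 2:] = w @ C
        H[:, 2:, 0] = H[:, 0, 2:]
        H[:, 1, 1] = (w * Gt * Gt).sum(1)
        H[:, 1, 2:] = (w * Gt) @ C
        H[:, 2:, 1] = H[:, 1, 2:]
        H[:, 2:, 2:] = np.einsum("vn,nc,nd->vcd", w, C, C, optimize=True)
        idx = np.flatnonzero(active)
        try:
            step = np.linalg.solve(H[idx], grad[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(H[i], grad[i], rcond=None)[0] for i in idx]
            )
        beta[idx] += step
        ll = (Mt * (y[None, :] * eta - np.logaddexp(0.0, eta))).sum(1)
        done = np.abs(ll - ll_old) < tol * (np.abs(ll) + 1.0)
        sep = np.abs(beta).max(axis=1) > MAX_ABS_BETA
        converged |= active & done & ~sep
        active = active & ~done & ~sep
        ll_old = ll
    # final information matrix at the optimum
    eta = beta[:, [0]] + beta[:, [1]] * Gt + beta[:, 2:] @ C.T
    mu = expit(eta)
    w = mu * (1 - mu) * Mt
    H[:, 0, 0] = w.sum(1)
    H[:, 0, 1] = H[:, 1, 0] = (w * Gt).sum(1)
    H[:, 0, 2:] = w @ C
    H[:, 2:, 0] = H[:, 0, 2:]
    H[:, 1, 1] = (w * Gt * Gt).sum(1)
    H[:, 1, 2:] = (w * Gt) @ C
    H[:, 2:, 1] = H[:, 1, 2:]
    H[:, 2:, 2:] = np.einsum("vn,nc,nd->vcd", w, C, C, optimize=True)
    se = np.full(V, np.nan)
    ok = np.flatnonzero(~mono)
    if ok.size:
        try:
            cov = np.linalg.inv(H[ok])
        except np.linalg.LinAlgError:
            cov = np.stack([np.linalg.pinv(H[i]) for i in ok])
        se[ok] = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
    beta_g = np.where(mono, np.nan, beta[:, 1])
    return {
        "beta": beta_g,
        "se": se,
        "n_used": n_used.astype(int),
        "converged": converged & ~mono,
        "monomorphic": mono,
    }


def gwas_scan(
    gm: GenotypeMatrix,
    cohort: CohortTable,
    config: AssocConfig | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant covariate-adjusted association scan.

    ``sample_ids`` restricts the scan (e.g., to a training fold); by
    default all samples with a non-missing label are used.  Covariates must
    be complete (run imputation first).  Monomorphic variants yield NA
    statistics with a flag and the scan continues.
    """
    config = config or AssocConfig()
    cohort = cohort.aligned_to(gm)
    df = cohort.df
    if sample_ids is None:
        sample_ids = [s for s in gm.sample_ids if not np.isnan(df.loc[s, "label"])]
    rows = [gm.sample_ids.index(s) for s in sample_ids]
    y = df.loc[sample_ids, "label"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("labels must be non-missing within the scanned subset")
    enc = encode_clinical(cohort, tuple(config.covariates) + ("age_q",))
    missing_cov = [c for c in config.covariates if c not in enc.columns]
    if missing_cov:
        raise ValidationError(f"covariates absent from cohort table: {missing_cov}")
    C = enc.loc[sample_ids, list(config.covariates)].to_numpy(dtype=float)
    if np.isnan(C).any():
        raise ValidationError("covariates contain missing values; impute first")
    G = gm.dosages[rows, :]
    out = _batched_scan(G, C, y, max_iter=config.max_iter, tol=config.tol)
    z = out["beta"] / out["se"]
    p = 2 * stats.norm.sf(np.abs(z))
    res = pd.DataFrame(
        {
            "rsid": gm.variants["rsid"],
            "chrom": gm.variants["chrom"],
            "pos": gm.variants["pos"],
            "allele1": gm.variants["allele1"],
            "allele2": gm.variants["allele2"],
            "beta": out["beta"],
            "se": out["se"],
            "or_point": np.exp(out["beta"]),
            "or_low": np.exp(out["beta"] - 1.959963984540054 * out["se"]),
            "or_high": np.exp(out["beta"] + 1.959963984540054 * out["se"]),
            "p_wald": p,
            "n_used": out["n_used"],
            "converged": out["converged"],
            "monomorphic": out["monomorphic"],
        }
    )
    return res


def select_suggestive(results: pd.DataFrame, suggestive_p: float = 1e-4) -> list[str]:
    """rsIDs with Wald p below the suggestive threshold, ascending p."""
    ok = results.dropna(subset=["p_wald"])
    hits = ok[ok["p_wald"] < suggestive_p].sort_values(["p_wald", "rsid"], kind="mergesort")
    return hits["rsid"].tolist()


def allelic_or_from_counts(counts: np.ndarray) -> tuple[float, tuple[float, float], bool]:
    """Unadjusted allelic odds ratio from a 2x2 allele-count table.

    Rows are case/control, columns risk/other allele.  Returns the
    cross-product OR, the Woolf (log-scale) 95% CI, and whether the Haldane
    0.5 correction was applied to a zero cell.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("zero margin: odds ratio undefined")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    or_ = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = float(np.sqrt((1 / t).sum()))
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * 1.959963984540054 * se)
    return float(or_), (float(lo), float(hi)), corrected


def write_summary_stats(results: pd.DataFrame, path) -> None:
    """Summary-statistics TSV (variant, alleles, beta, se, OR, CI, p, n)."""
    cols = [
        "rsid", "chrom", "pos", "allele1", "allele2",
        "beta", "se", "or_point", "or_low", "or_high", "p_wald", "n_used",
    ]
    results[cols].to_csv(path, sep="\t", index=False, na_rep="NA")
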