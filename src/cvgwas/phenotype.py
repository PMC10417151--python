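"""Outcome construction and missing-covariate imputation.

The self-reported hearing item (0 = not at all ... 4 = very much) is
dichotomized at >= 2 into the binary modeling label; samples with a missing
item are excluded from modeling but retained through QC reporting.
Missing predictor values (typically BMI and smoking) are filled by chained
multiple imputation: ten completed copies, each produced by iterated
per-variable regression imputation -- stochastic linear regression for
continuous variables, predictive-mean-matching donor draws for
ordinal/categorical ones.  Observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cvgwas.features import encode_clinical
from cvgwas.io import CATEGORICAL_COVARIATES, COVARIATE_COLUMNS, CohortTable, ValidationError


@dataclass(frozen=True)
class ImputeConfig:
    n_iterations: int = 10  # number of completed copies
    n_chained_passes: int = 5  # sweeps over incomplete columns per copy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_chained_passes < 1:
            raise ValidationError("iteration counts must be >= 1")


def dichotomize_ntx6(score):
    """Map ordinal hearing scores to the binary label: 0-1 -> 0, 2-4 -> 1.

    Accepts scalars or arrays; missing scores propagate as NaN (such samples
    are excluded from modeling downstream).
    """
    arr = np.asarray(score, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size and not np.isin(obs, [0, 1, 2, 3, 4]).all():
        bad = obs[~np.isin(obs, [0, 1, 2, 3, 4])]
        raise ValidationError(f"scores outside 0-4 domain: {np.unique(bad)}")
    out = np.where(np.isnan(arr), np.nan, (arr >= 2).astype(float))
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


def spearman_corr(x, y) -> float:
    """Spearman rank correlation with average ranks for ties and pairwise
    deletion of missing observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("inputs must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("need at least 3 paired non-missing observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _ordinal_codes(series: pd.Series, col: str) -> pd.Series:
    if col in CATEGORICAL_COVARIATES:
        levels = CATEGORICAL_COVARIATES[col]
        return series.map({lev: float(i) for i, lev in enumerate(levels)})
    return series.astype(float)


def _decode(value: float, col: str):
    if col in CATEGORICAL_COVARIATES:
        levels = CATEGORICAL_COVARIATES[col]
        return levels[int(np.clip(round(value), 0, len(levels) - 1))]
    return value


def _design(encoded: pd.DataFrame, exclude: str) -> np.ndarray:
    """Complete predictor block: other covariates, mean-filled, standardized."""
    X = encoded.drop(columns=[exclude]).to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _impute_once(df: pd.DataFrame, incomplete: list[str], config: ImputeConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    out = df.copy()
    masks = {c: df[c].isna().to_numpy() for c in incomplete}
    # initialize missing cells with the observed mean/mode
    for col in incomplete:
        obs = df[col].dropna()
        fill = obs.mean() if col not in CATEGORICAL_COVARIATES else obs.mode().iloc[0]
        out.loc[masks[col], col] = fill
    for _ in range(config.n_chained_passes):
        for col in incomplete:
            mask = masks[col]
            enc = pd.DataFrame({c: _ordinal_codes(out[c], c) for c in out.columns})
            X = _design(enc, col)
            y_obs = _ordinal_codes(df[col], col).to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones((~mask).sum()), X[~mask]]), y_obs[~mask], rcond=None
            )
            pred = np.column_stack([np.ones(len(X)), X]) @ beta
            resid = y_obs[~mask] - pred[~mask]
            if col in CATEGORICAL_COVARIATES:
                # predictive-mean matching: draw a donor among the 5 observed
                # rows with the closest predicted value
                donors = np.flatnonzero(~mask)
                for i in np.flatnonzero(mask):
                    near = donors[np.argsort(np.abs(pred[donors] - pred[i]))[:5]]
                    out.iloc[i, out.columns.get_loc(col)] = df[col].iloc[rng.choice(near)]
            else:
                sd = resid.std(ddof=1) if resid.size > 1 else 0.0
                draws = pred[mask] + rng.normal(0, sd, size=mask.sum())
                out.loc[mask, col] = draws
    return out


def impute_missing(cohort: CohortTable, config: ImputeConfig | None = None) -> list[CohortTable]:
    """Multiple imputation of missing covariates: ten completed copies.

    Only originally-missing cells differ across copies; categorical values
    stay within their domains by construction (donor draws).
    """
    config = config or ImputeConfig()
    df = cohort.df
    covars = [c for c in COVARIATE_COLUMNS if c in df.columns]
    incomplete = [c for c in covars if df[c].isna().any()]
    for col in incomplete:
        if df[col].isna().all():
            raise ValidationError(f"covariate {col!r} is entirely missing: no donor information")
    if not incomplete:
        return [cohort.copy() for _ in range(config.n_iterations)]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(7,)))
    copies = []
    for _ in range(config.n_iterations):
        filled = _impute_once(df[covars], incomplete, config, rng)
        full = df.copy()
        full[covars] = filled
        copies.append(CohortTable(full))
    return copies


def consolidate_imputations(copies: list[CohortTable]) -> CohortTable:
    """Collapse the completed copies to one analysis dataset: cellwise mean
    for continuous covariates, modal vote for categorical ones."""
    if not copies:
        raise ValidationError("no imputed copies to consolidate")
    base = copies[0].df.copy()
    for col in base.columns:
        if not any(c.df[col].isna().any() or not c.df[col].equals(base[col]) for c in copies):
            continue
        stack = pd.concat([c.df[col] for c in copies], axis=1)
        if col in CATEGORICAL_COVARIATES:
            base[col] = stack.mode(axis=1)[0]
        elif pd.api.types.is_numeric_dtype(base[col]):
            base[col] = stack.mean(axis=1)
    return CohortTable(base)


def item_correlations(cohort: CohortTable) -> pd.DataFrame:
    """Spearman correlations of the hearing item with its companions."""
    rows = []
    for other in ("ntx7", "hcq1", "hcq2"):
        if other in cohort.df.columns and cohort.df[other].notna().sum() >= 3:
            rho = spearman_corr(cohort.df["ntx6"].to_numpy(), cohort.df[other].to_numpy())
            rows.append({"item": other, "spearman_rho": rho})
    return pd.DataFrame(rows)


def modeling_cohort(cohort: CohortTable) -> CohortTable:
    """Samples eligible for modeling: those with a non-missing hearing item."""
    keep = cohort.df["ntx6"].notna()
    return CohortTable(cohort.df.loc[keep].copy())


# re-exported for convenience
__all__ = [
    "ImputeConfig",
    "dichotomize_ntx6",
    "spearman_corr",
    "impute_missing",
    "consolidate_imputations",
    "item_correlations",
    "modeling_cohort",
    "encode_clinical",
]
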