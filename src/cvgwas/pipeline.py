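"""Nested cross-validated logistic regression with inner-fold GWAS selection.

The defining property of this engine is test-set isolation: for every outer
fold, the association scan that nominates suggestive SNPs, the forward
feature selection, the hyperparameter choice, and the feature normalization
all see only that fold's training samples.  Five stratified outer folds
estimate generalization; five stratified inner folds within each outer
training set drive selection and tuning; the whole procedure repeats over
30 random splits.

Feature candidates are registered in a fixed order -- clinical features,
then the prior SNP panel, then GWAS-suggestive SNPs by ascending p -- and
greedy forward selection adds, at each step, the candidate with the best
mean inner-validation ROC-AUC (ties broken by registration order) until the
plateau rule fires.  Two negative controls accompany the pipeline: a
permutation control (every predictor column independently permuted) and a
random-SNP control (k unselected random variants appended to the fixed
clinical pair).

By default the association scan runs once per outer fold on its full
training set; a stricter per-inner-fold mode and a deliberately broken
all-samples mode (for leakage diagnosis) are selectable via
``SelectionConfig.gwas_scope``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from cvgwas.assoc import AssocConfig, gwas_scan, select_suggestive
from cvgwas.features import CLINICAL_FEATURES, encode_clinical, genotype_frame
from cvgwas.io import CohortTable, GenotypeMatrix, ValidationError
from cvgwas.metrics import aggregate_ci, roc_auc
from cvgwas.priors import PRIOR_SNPS


@dataclass(frozen=True)
class SplitConfig:
    n_repeats: int = 30
    n_outer: int = 5
    n_inner: int = 5

    def __post_init__(self) -> None:
        if min(self.n_repeats, 1) < 1 or self.n_outer < 2 or self.n_inner < 2:
            raise ValidationError("need n_repeats >= 1 and at least 2 folds per level")


@dataclass(frozen=True)
class SelectionConfig:
    prior_snps: tuple[str, ...] = PRIOR_SNPS
    suggestive_p: float = 1e-4
    clinical_pool: tuple[str, ...] = CLINICAL_FEATURES
    plateau_epsilon: float = 0.005
    plateau_patience: int = 2
    max_features: int = 28
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    selection_c: float = 1.0  # regularization used during forward selection
    gwas_scope: str = "outer_train"  # "inner_train" (strict) | "all" (broken; diagnosis only)
    assoc: AssocConfig = field(default_factory=AssocConfig)

    def __post_init__(self) -> None:
        if self.plateau_epsilon <= 0 or self.plateau_patience < 1:
            raise ValidationError("plateau parameters must be positive")
        if self.max_features < 1:
            raise ValidationError("max_features must be >= 1")
        if self.gwas_scope not in ("outer_train", "inner_train", "all"):
            raise ValidationError(f"unknown gwas_scope {self.gwas_scope!r}")


@dataclass
class SplitPlan:
    """Stratified fold assignments: ``outer[r, i]`` is sample i's outer fold
    in repeat r; ``inner[r, k, i]`` its inner fold within outer-training set
    k (or -1 if sample i is in fold k's test set)."""

    n_repeats: int
    n_outer: int
    n_inner: int
    outer: np.ndarray
    inner: np.ndarray
    seed: int


@dataclass
class FitRecord:
    """One outer-fold model: what was selected, how it was tuned, and the
    out-of-fold scores it produced."""

    repeat: int
    fold: int
    features: list[str]
    auc_path: list[float]  # mean inner-validation AUC after each addition
    candidate_pool: list[str]
    c_value: float
    coef: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    fill: np.ndarray
    test_ids: list[str]
    test_scores: np.ndarray


@dataclass
class RunReport:
    mode: str
    seed: int
    sample_ids: list[str]
    labels: np.ndarray
    n_repeats: int
    fits: list[list[FitRecord]]  # [repeat][outer fold]
    scores: np.ndarray  # (n_repeats, n_samples) out-of-fold scores
    repeat_aucs: np.ndarray
    control: str | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.repeat_aucs))

    @property
    def auc_ci(self) -> tuple[float, float]:
        return aggregate_ci(self.repeat_aucs)[1]

    def mean_scores(self) -> pd.Series:
        """Per-sample mean out-of-fold score across repeats."""
        return pd.Series(self.scores.mean(axis=0), index=self.sample_ids)


def make_split_plan(
    labels, seed: int, splits: SplitConfig | None = None
) -> SplitPlan:
    """Stratified nested fold assignments, deterministic given the seed."""
    splits = splits or SplitConfig()
    y = np.asarray(labels, dtype=int)
    n = y.size
    counts = np.bincount(y, minlength=2)
    if counts.min() < splits.n_outer:
        raise ValidationError(
            f"smallest class has {counts.min()} samples; need >= {splits.n_outer}"
        )
    state = np.random.SeedSequence(seed).generate_state(
        splits.n_repeats * (1 + splits.n_outer), dtype=np.uint32
    ) & 0x7FFFFFFF
    outer = np.zeros((splits.n_repeats, n), dtype=int)
    inner = np.full((splits.n_repeats, splits.n_outer, n), -1, dtype=int)
    s = 0
    for r in range(splits.n_repeats):
        skf = StratifiedKFold(splits.n_outer, shuffle=True, random_state=int(state[s]))
        s += 1
        for k, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
            outer[r, test_idx] = k
            skf_in = StratifiedKFold(splits.n_inner, shuffle=True, random_state=int(state[s]))
            s += 1
            for f, (_, val_idx) in enumerate(skf_in.split(np.zeros(train_idx.size), y[train_idx])):
                inner[r, k, train_idx[val_idx]] = f
    return SplitPlan(splits.n_repeats, splits.n_outer, splits.n_inner, outer, inner, seed)


# ---------------------------------------------------------------------------
# Penalized logistic solver (intercept unpenalized)
# ---------------------------------------------------------------------------


def ridge_logistic(
    X: np.ndarray, y: np.ndarray, c_value: float, max_iter: int = 100, tol: float = 1e-12
) -> tuple[float, np.ndarray]:
    """L2-penalized logistic regression by Newton's method.

    Minimizes the cross-entropy plus ``1/(2C) * ||w||^2`` (intercept
    unpenalized), the same objective scikit-learn's solver targets, so the
    two agree to solver tolerance.  Returns ``(intercept, coefficients)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    lam = 1.0 / c_value
    beta = np.zeros(p + 1)
    Xa = np.column_stack([np.ones(n), X])
    pen = np.zeros(p + 1)
    pen[1:] = lam
    obj_old = np.inf
    for _ in range(max_iter):
        eta = Xa @ beta
        mu = expit(eta)
        obj = float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * lam * (beta[1:] @ beta[1:]))
        grad = Xa.T @ (mu - y) + pen * beta
        w = mu * (1 - mu)
        H = (Xa * w[:, None]).T @ Xa + np.diag(pen)
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            eta_c = Xa @ cand
            obj_c = float(
                np.sum(np.logaddexp(0.0, eta_c) - y * eta_c) + 0.5 * lam * (cand[1:] @ cand[1:])
            )
            if obj_c <= obj + 1e-12:
                break
            t /= 2
        beta = beta - t * step
        if abs(obj_c - obj_old) < tol * (abs(obj_c) + 1.0):
            break
        obj_old = obj_c
    return float(beta[0]), beta[1:]


def _scores(X: np.ndarray, intercept: float, coef: np.ndarray) -> np.ndarray:
    return expit(intercept + X @ coef)


def _train_prepared(M: np.ndarray, train_rows: np.ndarray, cols: np.ndarray):
    """Training-fold normalization (and training-mode imputation for any
    missing dosage cells); returns a closure that transforms row subsets."""
    block = M[np.ix_(train_rows, cols)]
    fill = np.zeros(cols.size)
    for j in range(cols.size):
        col = block[:, j]
        if np.isnan(col).any():
            obs = col[~np.isnan(col)]
            vals, cnts = np.unique(obs, return_counts=True)
            fill[j] = vals[np.argmax(cnts)] if vals.size else 0.0
    block = np.where(np.isnan(block), fill, block)
    center = block.mean(axis=0)
    scale = block.std(axis=0)
    scale[scale == 0] = 1.0

    def transform(rows: np.ndarray) -> np.ndarray:
        B = M[np.ix_(rows, cols)]
        B = np.where(np.isnan(B), fill, B)
        return (B - center) / scale

    return transform, center, scale, fill


def _prepare_folds(
    M: np.ndarray,
    y: np.ndarray,
    train_rows: np.ndarray,
    inner_assign: np.ndarray,
    cols: np.ndarray,
    n_inner: int,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Per inner fold, the candidate block standardized (and missing
    dosages mode-imputed) with that fold's training statistics only.
    Standardization is columnwise, so candidate subsets are plain slices."""
    folds = []
    for f in range(n_inner):
        val = train_rows[inner_assign[train_rows] == f]
        tr = train_rows[(inner_assign[train_rows] != f) & (inner_assign[train_rows] >= 0)]
        transform, *_ = _train_prepared(M, tr, cols)
        folds.append((transform(tr), y[tr], transform(val), y[val]))
    return folds


def _mean_fold_auc(folds, idxs: list[int] | np.ndarray, c_value: float) -> float:
    aucs = []
    for Ztr, ytr, Zval, yval in folds:
        b0, w = ridge_logistic(Ztr[:, idxs], ytr, c_value)
        aucs.append(roc_auc(_scores(Zval[:, idxs], b0, w), yval))
    return float(np.mean(aucs))


def _batched_ridge(
    B: np.ndarray, C: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 40,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fit, for every candidate column c of ``C`` at once, the penalized
    logistic model with design [1, c, B] (same objective as
    :func:`ridge_logistic`); returns coefficients of shape (V, 2 + k).

    Used by forward selection, where per-step designs differ only in the
    candidate column -- the Newton updates batch into stacked small solves
    exactly like the association scan.
    """
    n, k = B.shape
    V = C.shape[1]
    p = 2 + k
    Ct = np.ascontiguousarray(C.T)  # (V, n)
    beta = np.zeros((V, p))
    pen = np.full(p, lam)
    pen[0] = 0.0
    H = np.zeros((V, p, p))
    obj_old = np.full(V, np.inf)
    active = np.ones(V, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = beta[:, [0]] + beta[:, [1]] * Ct + beta[:, 2:] @ B.T  # (V, n)
        mu = expit(eta)
        obj = np.logaddexp(0.0, eta).sum(1) - (y[None, :] * eta).sum(1) \
            + 0.5 * lam * (beta[:, 1:] ** 2).sum(1)
        r = mu - y[None, :]
        grad = np.column_stack([r.sum(1), (r * Ct).sum(1), r @ B]) + pen * beta
        w = mu * (1 - mu)
        H[:, 0, 0] = w.sum(1)
        H[:, 0, 1] = H[:, 1, 0] = (w * Ct).sum(1)
        H[:, 0, 2:] = w @ B
        H[:, 2:, 0] = H[:, 0, 2:]
        H[:, 1, 1] = (w * Ct * Ct).sum(1)
        H[:, 1, 2:] = (w * Ct) @ B
        H[:, 2:, 1] = H[:, 1, 2:]
        H[:, 2:, 2:] = np.einsum("vn,nc,nd->vcd", w, B, B, optimize=True)
        H[:, np.arange(p), np.arange(p)] += pen
        idx = np.flatnonzero(active)
        step = np.linalg.solve(H[idx], grad[idx][..., None])[..., 0]
        # vectorized backtracking keeps the strictly convex objective monotone
        t = np.ones(idx.size)
        for _ in range(20):
            cand = beta[idx] - t[:, None] * step
            eta_c = cand[:, [0]] + cand[:, [1]] * Ct[idx] + cand[:, 2:] @ B.T
            obj_c = np.logaddexp(0.0, eta_c).sum(1) - (y[None, :] * eta_c).sum(1) \
                + 0.5 * lam * (cand[:, 1:] ** 2).sum(1)
            bad = obj_c > obj[idx] + 1e-12
            if not bad.any():
                break
            t[bad] /= 2
        beta[idx] = beta[idx] - t[:, None] * step
        done = np.abs(obj - obj_old) < tol * (np.abs(obj) + 1.0)
        active &= ~done
        obj_old = obj
    return beta


def _auc_rows(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise tie-aware ROC-AUC for a (V, n) score matrix."""
    from scipy.stats import rankdata

    n1 = int((y == 1).sum())
    n0 = y.size - n1
    ranks = rankdata(S, axis=1)
    u = ranks[:, y == 1].sum(axis=1) - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


def inner_select_features(
    M: np.ndarray,
    y: np.ndarray,
    train_rows: np.ndarray,
    inner_assign: np.ndarray,
    candidates: list[int],
    config: SelectionConfig,
    n_inner: int,
    candidate_names: list[str] | None = None,
) -> tuple[list[int], list[float]]:
    """Greedy forward selection on inner folds with the plateau stop rule.

    At each step every remaining candidate is evaluated (exhaustive per
    step) by mean inner-validation ROC-AUC; the best joins the sequence
    (ties resolved by registration order).  Selection stops when the best
    addition has improved the running best by less than ``plateau_epsilon``
    for ``plateau_patience`` consecutive steps, and the returned set is the
    prefix up to the last real improvement.  Returns (selected column
    indices, mean-AUC path).
    """
    if not candidates:
        raise ValidationError("empty candidate pool")
    pool = np.array(list(candidates), dtype=int)
    folds = _prepare_folds(M, y, train_rows, inner_assign, pool, n_inner)
    pos = {int(c): i for i, c in enumerate(pool)}
    remaining = list(candidates)
    selected: list[int] = []
    path: list[float] = []
    best_auc = -np.inf
    best_len = 0
    stall = 0
    lam = 1.0 / config.selection_c
    while remaining and len(selected) < config.max_features:
        base = [pos[c] for c in selected]
        rem = [pos[c] for c in remaining]
        fold_aucs = np.zeros((len(folds), len(rem)))
        for f, (Ztr, ytr, Zval, yval) in enumerate(folds):
            beta = _batched_ridge(Ztr[:, base], Ztr[:, rem], ytr, lam)
            S = beta[:, [0]] + beta[:, [1]] * Zval[:, rem].T + beta[:, 2:] @ Zval[:, base].T
            fold_aucs[f] = _auc_rows(S, yval)
        step_aucs = fold_aucs.mean(axis=0)
        j = int(np.argmax(step_aucs))  # first max = registration order
        selected.append(remaining.pop(j))
        path.append(float(step_aucs[j]))
        if step_aucs[j] >= best_auc + config.plateau_epsilon or not np.isfinite(best_auc):
            best_auc = max(best_auc, step_aucs[j])
            best_len = len(selected)
            stall = 0
        else:
            best_auc = max(best_auc, step_aucs[j])
            stall += 1
            if stall >= config.plateau_patience:
                break
    return selected[:best_len], path


def fit_outer_model(
    M: np.ndarray,
    y: np.ndarray,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    inner_assign: np.ndarray,
    cols: np.ndarray,
    config: SelectionConfig,
    n_inner: int,
) -> tuple[float, float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pick the regularization strength on the inner folds, refit on the full
    outer-training set, and score the held-out test samples."""
    folds = _prepare_folds(M, y, train_rows, inner_assign, cols, n_inner)
    all_idx = np.arange(cols.size)
    grid_aucs = [_mean_fold_auc(folds, all_idx, c) for c in config.c_grid]
    c_value = config.c_grid[int(np.argmax(grid_aucs))]
    transform, center, scale, fill = _train_prepared(M, train_rows, cols)
    b0, w = ridge_logistic(transform(train_rows), y[train_rows], c_value)
    test_scores = _scores(transform(test_rows), b0, w)
    return c_value, b0, w, center, scale, fill, test_scores


def _assemble(
    gm: GenotypeMatrix | None,
    cohort: CohortTable,
    config: SelectionConfig,
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Build the numeric feature matrix (clinical then genotype columns)."""
    if gm is not None:
        cohort = cohort.aligned_to(gm)
    clin = encode_clinical(cohort, config.clinical_pool)
    clin_names = [c for c in config.clinical_pool if c in clin.columns]
    if clin[clin_names].isna().any().any():
        raise ValidationError("clinical features contain missing values; impute first")
    blocks = [clin[clin_names].to_numpy(dtype=float)]
    geno_names: list[str] = []
    if gm is not None:
        gf = genotype_frame(gm)
        geno_names = list(gf.columns)
        blocks.append(gf.to_numpy(dtype=float))
    M = np.column_stack(blocks) if blocks else np.empty((cohort.n_samples, 0))
    y = cohort.df["label"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("labels must be complete; drop samples with missing outcome first")
    return M, clin_names + geno_names, y, cohort.sample_ids


def run_pipeline(
    gm: GenotypeMatrix | None,
    cohort: CohortTable,
    mode: str = "clinical_plus_genetic",
    selection: SelectionConfig | None = None,
    splits: SplitConfig | None = None,
    seed: int = 0,
    _permute_seed: int | None = None,
    _permute_identity: bool = False,
) -> RunReport:
    """Execute the full repeated nested-CV procedure and aggregate a report.

    ``mode`` is ``clinical_only`` (genotypes ignored for modeling) or
    ``clinical_plus_genetic``.  The private permutation arguments implement
    the permutation control without duplicating the engine.
    """
    if mode not in ("clinical_only", "clinical_plus_genetic"):
        raise ValidationError(f"unknown mode {mode!r}")
    selection = selection or SelectionConfig()
    splits = splits or SplitConfig()
    use_geno = mode == "clinical_plus_genetic" and gm is not None
    if _permute_seed is not None and use_geno:
        raise ValidationError("the permutation control runs on clinical_only inputs")
    M, names, y, sample_ids = _assemble(gm if use_geno else None, cohort, selection)
    name_to_col = {nm: j for j, nm in enumerate(names)}
    clin_cols = [name_to_col[c] for c in selection.clinical_pool if c in name_to_col]
    plan = make_split_plan(y, seed, splits)
    n = len(sample_ids)

    scan_cache: dict[tuple, list[str]] = {}

    def suggestive_for(sample_subset: tuple[str, ...]) -> list[str]:
        if sample_subset in scan_cache:
            return scan_cache[sample_subset]
        cfg = replace(selection.assoc, suggestive_p=selection.suggestive_p)
        res = gwas_scan(gm, cohort, cfg, sample_ids=list(sample_subset))
        hits = select_suggestive(res, selection.suggestive_p)
        scan_cache[sample_subset] = hits
        return hits

    fits: list[list[FitRecord]] = []
    scores = np.full((plan.n_repeats, n), np.nan)
    repeat_aucs = np.zeros(plan.n_repeats)
    prior_present = [s for s in selection.prior_snps if s in name_to_col] if use_geno else []
    for r in range(plan.n_repeats):
        Mr = M
        if _permute_seed is not None and not _permute_identity:
            # fresh independent permutation of every predictor column per
            # repeat, so the 30-repeat mean is free of single-draw luck
            prng = np.random.default_rng(
                np.random.SeedSequence(entropy=_permute_seed, spawn_key=(101, r))
            )
            Mr = M.copy()
            for j in range(Mr.shape[1]):
                Mr[:, j] = Mr[prng.permutation(n), j]
        fold_fits: list[FitRecord] = []
        fold_aucs: list[float] = []
        for k in range(plan.n_outer):
            test_rows = np.flatnonzero(plan.outer[r] == k)
            train_rows = np.flatnonzero(plan.outer[r] != k)
            inner_assign = plan.inner[r, k]
            pool_names = [names[j] for j in clin_cols]
            if use_geno:
                pool_names += [s for s in prior_present if s not in pool_names]
                if selection.gwas_scope == "all":
                    hits = suggestive_for(tuple(sample_ids))
                elif selection.gwas_scope == "inner_train":
                    merged: list[str] = []
                    for f in range(plan.n_inner):
                        tr = train_rows[(inner_assign[train_rows] != f) & (inner_assign[train_rows] >= 0)]
                        for h in suggestive_for(tuple(sample_ids[i] for i in tr)):
                            if h not in merged:
                                merged.append(h)
                    hits = merged
                else:
                    hits = suggestive_for(tuple(sample_ids[i] for i in train_rows))
                pool_names += [h for h in hits if h not in pool_names]
            pool_cols = [name_to_col[nm] for nm in pool_names]
            sel_cols, path = inner_select_features(
                Mr, y, train_rows, inner_assign, pool_cols, selection, plan.n_inner
            )
            cols = np.array(sel_cols, dtype=int)
            c_value, b0, w, center, scale, fill, test_scores = fit_outer_model(
                Mr, y, train_rows, test_rows, inner_assign, cols, selection, plan.n_inner
            )
            scores[r, test_rows] = test_scores
            fold_aucs.append(roc_auc(test_scores, y[test_rows]))
            fold_fits.append(
                FitRecord(
                    repeat=r, fold=k,
                    features=[names[j] for j in sel_cols],
                    auc_path=path,
                    candidate_pool=pool_names,
                    c_value=c_value, coef=w, intercept=b0,
                    center=center, scale=scale, fill=fill,
                    test_ids=[sample_ids[i] for i in test_rows],
                    test_scores=test_scores,
                )
            )
        fits.append(fold_fits)
        # repeat-level AUC is the mean over outer-fold AUCs (pooling the
        # fold scores instead mixes per-fold calibrations and carries a
        # small pessimistic artifact on null data)
        repeat_aucs[r] = float(np.mean(fold_aucs))
    return RunReport(
        mode=mode, seed=seed, sample_ids=sample_ids, labels=y,
        n_repeats=plan.n_repeats, fits=fits, scores=scores,
        repeat_aucs=repeat_aucs,
        control=None if _permute_seed is None else "permutation",
    )


def permutation_control(
    cohort: CohortTable,
    selection: SelectionConfig | None = None,
    splits: SplitConfig | None = None,
    seed: int = 0,
    identity: bool = False,
) -> RunReport:
    """Clinical-only pipeline with every predictor column independently
    permuted before training (labels untouched).  With ``identity`` the
    permutation is skipped, which must reproduce the plain run exactly."""
    return run_pipeline(
        None, cohort, mode="clinical_only",
        selection=selection, splits=splits, seed=seed,
        _permute_seed=seed + 1 if not identity else seed + 1,
        _permute_identity=identity,
    )


def fixed_feature_run(
    gm: GenotypeMatrix | None,
    cohort: CohortTable,
    features: list[str],
    selection: SelectionConfig | None = None,
    splits: SplitConfig | None = None,
    seed: int = 0,
) -> RunReport:
    """Nested CV with a fixed feature set (no selection); the regularization
    strength is still tuned on the inner folds."""
    selection = selection or SelectionConfig()
    splits = splits or SplitConfig()
    M, names, y, sample_ids = _assemble(gm, cohort, selection)
    name_to_col = {nm: j for j, nm in enumerate(names)}
    unknown = [f for f in features if f not in name_to_col]
    if unknown:
        raise ValidationError(f"unknown features: {unknown}")
    cols = np.array([name_to_col[f] for f in features], dtype=int)
    plan = make_split_plan(y, seed, splits)
    n = len(sample_ids)
    fits: list[list[FitRecord]] = []
    scores = np.full((plan.n_repeats, n), np.nan)
    repeat_aucs = np.zeros(plan.n_repeats)
    for r in range(plan.n_repeats):
        fold_fits = []
        fold_aucs = []
        for k in range(plan.n_outer):
            test_rows = np.flatnonzero(plan.outer[r] == k)
            train_rows = np.flatnonzero(plan.outer[r] != k)
            c_value, b0, w, center, scale, fill, test_scores = fit_outer_model(
                M, y, train_rows, test_rows, plan.inner[r, k], cols, selection, plan.n_inner
            )
            scores[r, test_rows] = test_scores
            fold_aucs.append(roc_auc(test_scores, y[test_rows]))
            fold_fits.append(
                FitRecord(
                    repeat=r, fold=k, features=list(features), auc_path=[],
                    candidate_pool=list(features), c_value=c_value, coef=w,
                    intercept=b0, center=center, scale=scale, fill=fill,
                    test_ids=[sample_ids[i] for i in test_rows], test_scores=test_scores,
                )
            )
        fits.append(fold_fits)
        repeat_aucs[r] = float(np.mean(fold_aucs))
    return RunReport(
        mode="fixed_features", seed=seed, sample_ids=sample_ids, labels=y,
        n_repeats=plan.n_repeats, fits=fits, scores=scores, repeat_aucs=repeat_aucs,
    )


def random_snp_control(
    gm: GenotypeMatrix,
    cohort: CohortTable,
    k: int,
    clinical_pair: tuple[str, str] = ("age_dx", "cycles_cat"),
    selection: SelectionConfig | None = None,
    splits: SplitConfig | None = None,
    seed: int = 0,
) -> RunReport:
    """Append ``k`` randomly chosen QC-passed SNPs (no selection) to the
    fixed informative clinical pair."""
    if k > gm.n_variants:
        raise ValidationError(f"k={k} exceeds the {gm.n_variants} available SNPs")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(13,)))
    chosen = list(np.array(gm.rsids)[rng.choice(gm.n_variants, size=k, replace=False)]) if k else []
    report = fixed_feature_run(
        gm, cohort, list(clinical_pair) + chosen, selection, splits, seed
    )
    report.control = "random_snp"
    return report


def label_shuffled_run(
    gm: GenotypeMatrix | None,
    cohort: CohortTable,
    mode: str = "clinical_plus_genetic",
    selection: SelectionConfig | None = None,
    n_repeats: int = 30,
    splits: SplitConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Repeat-level test AUCs of the pipeline under randomly reassigned labels.

    Each repeat draws a fresh random reassignment of the label vector and
    runs one full nested-CV pass (including whatever association-scan scope
    the selection config specifies), so the mean over repeats estimates the
    procedure's null-data operating point free of single-shuffle luck.
    This is the leakage diagnostic: with ``gwas_scope="outer_train"`` the
    mean must sit at chance, while the deliberately broken
    ``gwas_scope="all"`` leaks test information through the scan and
    inflates it.
    """
    splits = splits or SplitConfig()
    base = cohort.df.copy()
    labels = base["label"].to_numpy().copy()
    aucs = np.zeros(n_repeats)
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(211, r)))
        lab = labels.copy()
        rng.shuffle(lab)
        df = base.copy()
        df["label"] = lab
        rep = run_pipeline(
            gm, CohortTable(df), mode=mode, selection=selection,
            splits=replace(splits, n_repeats=1),
            seed=int(rng.integers(2**31)),
        )
        aucs[r] = rep.repeat_aucs[0]
    return aucs


def shap_summary(
    report: RunReport,
    gm: GenotypeMatrix | None,
    cohort: CohortTable,
    selection: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Mean absolute SHAP attribution per feature over all out-of-fold
    predictions, ranked by importance.

    Each outer-fold model attributes its test samples' log-odds exactly:
    features were standardized to the training fold, so the training
    background mean is zero and the attribution of feature j on sample i is
    ``coef_j * x_std_ij``.
    """
    from cvgwas.metrics import linear_shap

    selection = selection or SelectionConfig()
    use_geno = report.mode != "clinical_only" and gm is not None
    M, names, _, sample_ids = _assemble(gm if use_geno else None, cohort, selection)
    if sample_ids != report.sample_ids:
        raise ValidationError("cohort does not match the report's samples")
    name_to_col = {nm: j for j, nm in enumerate(names)}
    id_to_row = {s: i for i, s in enumerate(sample_ids)}
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for fold_fits in report.fits:
        for rec in fold_fits:
            if not rec.features:
                continue
            cols = np.array([name_to_col[f] for f in rec.features])
            rows = np.array([id_to_row[s] for s in rec.test_ids])
            X = M[np.ix_(rows, cols)]
            X = np.where(np.isnan(X), rec.fill, X)
            Xstd = (X - rec.center) / rec.scale
            phi, _ = linear_shap(rec.coef, rec.intercept, Xstd, np.zeros(len(rec.features)))
            for j, f in enumerate(rec.features):
                sums[f] = sums.get(f, 0.0) + float(np.abs(phi[:, j]).sum())
                counts[f] = counts.get(f, 0) + len(rows)
    out = pd.DataFrame(
        {
            "feature": list(sums),
            "mean_abs_shap": [sums[f] / counts[f] for f in sums],
            "n_predictions": [counts[f] for f in sums],
        }
    ).sort_values("mean_abs_shap", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)
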