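"""Cross-validated permutation inference for brain-behavior models.

The estimation scheme: subjects are split into k stratified folds; for each
fold an OLS model (behavioral score on cluster gradient coordinates) is fit
on the remaining folds and evaluated *out of sample* on the held-out fold,
yielding an out-of-sample F (from the test-fold R^2) and per-predictor
t-values. The across-fold averages of these statistics are the real test
statistics. Their null distribution is built by permuting the training-fold
dependent variable, refitting, evaluating on the intact test fold, and
averaging across folds exactly as for the real statistics, so real and null
quantities are exchangeable under the no-association hypothesis and the
add-one permutation p-values are calibrated. A cross-fold-average model is
additionally validated on a disjoint hold-out (lockbox) sample against its
own permutation null. FDR control uses Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FoldAssignment",
    "CVModelResult",
    "HoldoutResult",
    "bilateral_average",
    "stratified_folds",
    "fold_fit_eval",
    "cv_permutation_model",
    "fdr_adjust",
    "holdout_validation",
    "spearman_screen",
]


# ---------------------------------------------------------------------------
# fold construction

@dataclass
class FoldAssignment:
    """Subject -> fold mapping from stratified assignment."""

    fold_of: np.ndarray  # (n,) int in [0, k)
    k: int
    seed: int
    bin_edges: np.ndarray

    def train_test(self, fold: int):
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, test


def stratified_folds(
    y: np.ndarray, k: int, n_bins: int | None = None, seed: int = 0
) -> FoldAssignment:
    """Random non-overlapping folds stratified by the dependent variable.

    Subjects are ranked by ``y``, cut into ``n_bins`` quantile bins
    (default: one per fold), shuffled within each bin, and dealt round-robin
    across folds (the deal continues across bins so global fold sizes also
    differ by at most one).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more folds than subjects")
    n_bins = k if n_bins is None else n_bins
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    chunks = np.array_split(order, n_bins)
    fold_of = np.empty(n, dtype=int)
    deal = 0
    edges = []
    for chunk in chunks:
        if chunk.size:
            edges.append(y[chunk].max())
        for idx in rng.permutation(chunk):
            fold_of[idx] = deal % k
            deal += 1
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed, bin_edges=np.asarray(edges))


# ---------------------------------------------------------------------------
# homolog averaging

def bilateral_average(
    table: pd.DataFrame,
    pairs: list[tuple[int, int]],
    min_rho: float = 0.6,
    n_axes: int | None = None,
):
    """Average left/right homolog cluster columns when highly correlated.

    For each declared cluster-id pair, the across-subject Pearson
    correlation of the two columns is computed on every gradient axis; if it
    is >= ``min_rho`` on *all* axes the pair is replaced by its mean column
    (named ``c<L>c<R>_g<axis>``), otherwise both columns are kept and the
    decision is recorded.

    Returns ``(new_table, decisions)`` where decisions is a list of dicts.
    """
    if n_axes is None:
        n_axes = max(
            int(c.rsplit("_g", 1)[1]) for c in table.columns if "_g" in c
        )
    out = table.copy()
    decisions = []
    for left, right in pairs:
        if left == right:
            raise ValueError(f"cannot pair cluster {left} with itself")
        cols_l = [f"c{left}_g{a}" for a in range(1, n_axes + 1)]
        cols_r = [f"c{right}_g{a}" for a in range(1, n_axes + 1)]
        missing = [c for c in cols_l + cols_r if c not in out.columns]
        if missing:
            raise ValueError(f"pair ({left}, {right}): missing column(s) {missing}")
        rhos = [
            float(np.corrcoef(out[a], out[b])[0, 1]) for a, b in zip(cols_l, cols_r)
        ]
        merged = all(r >= min_rho for r in rhos)
        decisions.append(
            {"left": left, "right": right, "rho_per_axis": rhos, "merged": merged}
        )
        if merged:
            for a, (cl, cr) in enumerate(zip(cols_l, cols_r), start=1):
                out[f"c{left}c{right}_g{a}"] = (out[cl] + out[cr]) / 2.0
                out = out.drop(columns=[cl, cr])
    return out, decisions


# ---------------------------------------------------------------------------
# fold-wise fitting

def _augment(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _eval_on_test(
    betas: np.ndarray, X_test: np.ndarray, y_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-sample F and per-predictor t for one or many coefficient
    vectors (columns of ``betas``, intercept first).

    ``y_test`` may be a single vector or one column per coefficient vector
    (used for permutation nulls).

    F = (R^2/p) / ((1-R^2)/(n_test-p-1)) with R^2 from test-fold centering,
    floored at 0 for negative R^2 and +inf when the test residual is exactly
    zero. t_j = beta_j / sqrt(sigma2_test * [(X_test' X_test)^-1]_jj) with
    sigma2_test = SS_res / (n_test - p - 1).
    """
    Xa = _augment(X_test)
    n_test, p1 = Xa.shape
    p = p1 - 1
    if n_test <= p + 1:
        raise ValueError("test fold too small for the predictor count")
    preds = Xa @ betas  # (n_test, m)
    y2 = y_test[:, None] if y_test.ndim == 1 else y_test
    resid = y2 - preds
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((y2 - y2.mean(axis=0)) ** 2).sum(axis=0)
    dof = n_test - p - 1
    # perfect fit up to floating rounding -> +inf sentinel
    perfect = ss_res <= 1e-12 * np.maximum(ss_tot, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), -np.inf)
        F = np.where(
            perfect,
            np.inf,
            np.where(r2 <= 0, 0.0, (r2 / p) / np.maximum((1 - r2) / dof, 1e-300)),
        )
        xtx_inv_diag = np.diag(np.linalg.inv(Xa.T @ Xa))[1:]  # predictors only
        sigma2 = ss_res / dof
        denom = np.sqrt(sigma2[None, :] * xtx_inv_diag[:, None])
        t = np.where(denom > 0, betas[1:, :] / denom, np.inf * np.sign(betas[1:, :]))
    return F, t  # F: (m,), t: (p, m)


def fold_fit_eval(
    y: np.ndarray,
    X: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """OLS fit on the training set, out-of-sample evaluation on the test set.

    Returns ``(beta, F, t)`` with ``beta`` including the intercept first
    and ``t`` covering the predictors only.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if train.size <= p + 1 or test.size <= p + 1:
        raise ValueError("train and test sets must each exceed p + 1 observations")
    Xtr = _augment(X[train])
    if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
        raise ValueError("singular training design matrix")
    beta, *_ = np.linalg.lstsq(Xtr, y[train], rcond=None)
    F, t = _eval_on_test(beta[:, None], X[test], y[test])
    return beta, float(F[0]), t[:, 0]


# ---------------------------------------------------------------------------
# cross-validated permutation model

@dataclass
class CVModelResult:
    """Fold-wise and aggregated statistics with permutation nulls."""

    predictors: list[str]
    folds: FoldAssignment
    fold_betas: np.ndarray  # (k, p+1)
    fold_F: np.ndarray  # (k,)
    fold_t: np.ndarray  # (k, p)
    mean_F: float
    mean_t: np.ndarray  # (p,)
    null_F_folds: np.ndarray  # (k, n_perm) fold-level null pool
    null_t_folds: np.ndarray  # (k, n_perm, p)
    null_F: np.ndarray  # (n_perm,) fold-averaged nulls used for p
    null_t: np.ndarray  # (n_perm, p)
    p_F: float
    p_t: np.ndarray  # (p,)
    q_F: float | None = None
    q_t: np.ndarray | None = None
    n_perm: int = 0
    seed: int = 0


def _perm_p(real: float, null: np.ndarray) -> float:
    """Add-one permutation p-value on absolute values; +inf sentinels in the
    null pool are excluded (with a warning)."""
    finite = np.isfinite(null)
    if not finite.all():
        warnings.warn(
            f"excluding {int((~finite).sum())} non-finite null value(s)",
            RuntimeWarning,
            stacklevel=3,
        )
        null = null[finite]
    if not np.isfinite(real):
        return 1.0 / (null.size + 1.0)
    return (1.0 + np.sum(np.abs(null) >= abs(real))) / (null.size + 1.0)


def cv_permutation_model(
    y: np.ndarray,
    X: np.ndarray,
    folds: FoldAssignment,
    n_perm: int = 1000,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> CVModelResult:
    """k-fold out-of-sample statistics with a permutation null.

    For every fold the real model is fit on the training folds and
    evaluated out of sample on the test fold. For each of ``n_perm``
    permutation iterations one permutation of the subject-to-score
    assignment is drawn and shared across folds: predictor rows are
    permuted against the (fixed) dependent variable, the model refit per
    fold and evaluated on the test fold, and the k fold null statistics of
    the iteration are averaged exactly as the real statistics are.
    Permuting the assignment rather than y against a fixed fold layout
    matters because the folds are stratified *by* y: it keeps the
    stratified y-to-fold structure identical between real and null
    statistics, which makes them exactly exchangeable under the
    no-association hypothesis and the add-one p-values calibrated.
    Deterministic given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    k = folds.k
    rng = np.random.default_rng(seed)

    fold_betas = np.empty((k, p + 1))
    fold_F = np.empty(k)
    fold_t = np.empty((k, p))
    null_F_folds = np.empty((k, n_perm))
    null_t_folds = np.empty((k, n_perm, p))

    n = y.size
    # one permutation of the subject-to-score assignment per iteration,
    # shared by all folds (predictor rows permuted, y and folds fixed)
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])  # (n_perm, n)
    Xa = _augment(X)

    for f in range(k):
        train, test = folds.train_test(f)
        beta, F, t = fold_fit_eval(y, X, train, test)
        fold_betas[f], fold_F[f], fold_t[f] = beta, F, t

        Xtr_b = Xa[perm_idx[:, train]]  # (n_perm, n_train, p+1)
        xtx = Xtr_b.transpose(0, 2, 1) @ Xtr_b
        xty = (Xtr_b * y[train][None, :, None]).sum(axis=1)
        betas_null = np.linalg.solve(xtx, xty[:, :, None])[:, :, 0]  # (n_perm, p+1)

        Xte_b = Xa[perm_idx[:, test]]  # (n_perm, n_test, p+1)
        preds = (Xte_b @ betas_null[:, :, None])[:, :, 0]
        y_te = y[test]
        ss_res = ((y_te[None, :] - preds) ** 2).sum(axis=1)
        ss_tot = ((y_te - y_te.mean()) ** 2).sum()
        n_test = test.size
        dof = n_test - p - 1
        perfect = ss_res <= 1e-12 * max(ss_tot, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (
                1.0 - ss_res / ss_tot
                if ss_tot > 0
                else np.full_like(ss_res, -np.inf)
            )
            Fn = np.where(
                perfect,
                np.inf,
                np.where(r2 <= 0, 0.0, (r2 / p) / np.maximum((1 - r2) / dof, 1e-300)),
            )
            xtx_te = Xte_b.transpose(0, 2, 1) @ Xte_b
            diag = np.diagonal(np.linalg.inv(xtx_te), axis1=1, axis2=2)[:, 1:]
            sigma2 = ss_res / dof
            tn = betas_null[:, 1:] / np.sqrt(sigma2[:, None] * diag)
        null_F_folds[f] = Fn
        null_t_folds[f] = tn

    mean_F = float(fold_F.mean())
    mean_t = fold_t.mean(axis=0)
    null_F = null_F_folds.mean(axis=0)
    null_t = null_t_folds.mean(axis=0)
    p_F = _perm_p(mean_F, null_F)
    p_t = np.array([_perm_p(mean_t[j], null_t[:, j]) for j in range(p)])

    return CVModelResult(
        predictors=list(predictors) if predictors else [f"x{j}" for j in range(p)],
        folds=folds,
        fold_betas=fold_betas,
        fold_F=fold_F,
        fold_t=fold_t,
        mean_F=mean_F,
        mean_t=mean_t,
        null_F_folds=null_F_folds,
        null_t_folds=null_t_folds,
        null_F=null_F,
        null_t=null_t,
        p_F=p_F,
        p_t=p_t,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# FDR

def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# hold-out (lockbox) validation

@dataclass
class HoldoutResult:
    """Cross-fold-average model evaluated on the lockbox sample."""

    beta: np.ndarray  # (p+1,) averaged coefficients
    F: float
    t: np.ndarray  # (p,)
    null_F: np.ndarray
    null_t: np.ndarray  # (n_perm, p)
    p_F: float
    p_t: np.ndarray
    q_t: np.ndarray = field(default=None)
    n_perm: int = 0
    seed: int = 0


def holdout_validation(
    result: CVModelResult,
    y_holdout: np.ndarray,
    X_holdout: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> HoldoutResult:
    """Apply the averaged fold coefficients to a disjoint hold-out sample.

    The averaged beta is held fixed; nulls come from permuting the hold-out
    dependent variable and recomputing F and t with the same coefficients.
    """
    y = np.asarray(y_holdout, dtype=float)
    X = np.asarray(X_holdout, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != result.fold_betas.shape[1] - 1:
        raise ValueError("hold-out predictor count differs from the fitted model")
    beta = result.fold_betas.mean(axis=0)
    F_real, t_real = _eval_on_test(beta[:, None], X, y)
    rng = np.random.default_rng(seed)
    Xa = _augment(X)
    preds = Xa @ beta
    n, p1 = Xa.shape
    p = p1 - 1
    dof = n - p - 1
    xtx_inv_diag = np.diag(np.linalg.inv(Xa.T @ Xa))[1:]
    ss_tot = ((y - y.mean()) ** 2).sum()
    perms = rng.permuted(np.broadcast_to(y, (n_perm, n)).copy(), axis=1)
    ss_res = ((perms - preds[None, :]) ** 2).sum(axis=1)
    perfect = ss_res <= 1e-12 * max(ss_tot, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.full_like(ss_res, -np.inf)
        null_F = np.where(
            perfect,
            np.inf,
            np.where(r2 <= 0, 0.0, (r2 / p) / np.maximum((1 - r2) / dof, 1e-300)),
        )
        sigma2 = ss_res / dof
        null_t = beta[None, 1:] / np.sqrt(sigma2[:, None] * xtx_inv_diag[None, :])
    p_F = _perm_p(float(F_real[0]), null_F)
    p_t = np.array(
        [_perm_p(t_real[j, 0], null_t[:, j]) for j in range(p)]
    )
    return HoldoutResult(
        beta=beta,
        F=float(F_real[0]),
        t=t_real[:, 0],
        null_F=null_F,
        null_t=null_t,
        p_F=p_F,
        p_t=p_t,
        q_t=fdr_adjust(p_t),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-task screening

def spearman_screen(x: np.ndarray, tasks: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of ``x`` with every task column, BH-adjusted.

    Constant columns get NaN correlations and are flagged rather than
    entering the FDR family.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 paired observations")
    rows = []
    for col in tasks.columns:
        v = tasks[col].to_numpy(dtype=float)
        if np.std(v) == 0 or np.std(x) == 0:
            rows.append((col, np.nan, np.nan, True))
        else:
            rho, pval = spearmanr(x, v)
            rows.append((col, float(rho), float(pval), False))
    frame = pd.DataFrame(rows, columns=["task", "rho", "p", "constant"])
    frame["q"] = np.nan
    ok = ~frame["constant"]
    if ok.any():
        frame.loc[ok, "q"] = fdr_adjust(frame.loc[ok, "p"].to_numpy())
    return frame
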