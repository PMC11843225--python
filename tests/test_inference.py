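import itertools

import numpy as np
import pandas as pd
import pytest

from gradvar.inference import (
    bilateral_average,
    cv_permutation_model,
    fdr_adjust,
    fold_fit_eval,
    holdout_validation,
    spearman_screen,
    stratified_folds,
)


# ---------------------------------------------------------------------------
# stratified folds

def test_folds_partition_subjects(rng):
    y = rng.standard_normal(100)
    fa = stratified_folds(y, 10, seed=1)
    sizes = np.bincount(fa.fold_of, minlength=10)
    assert sizes.tolist() == [10] * 10
    assert np.array_equal(np.sort(np.unique(fa.fold_of)), np.arange(10))


def test_constant_y_reduces_to_random_split():
    y = np.ones(30)
    fa = stratified_folds(y, 5, n_bins=1, seed=2)
    assert np.bincount(fa.fold_of).tolist() == [6] * 5


def test_stratification_balances_fold_means(rng):
    """Variance of fold-mean y is smaller with stratification than with a
    random (single-bin) split, averaged over 100 seeds."""
    y = rng.standard_normal(100)
    var_strat, var_rand = [], []
    for seed in range(100):
        fa_s = stratified_folds(y, 10, seed=seed)
        fa_r = stratified_folds(y, 10, n_bins=1, seed=seed)
        var_strat.append(np.var([y[fa_s.fold_of == f].mean() for f in range(10)]))
        var_rand.append(np.var([y[fa_r.fold_of == f].mean() for f in range(10)]))
    assert np.mean(var_strat) < np.mean(var_rand)


def test_folds_errors():
    with pytest.raises(ValueError):
        stratified_folds(np.arange(5.0), 6)
    with pytest.raises(ValueError):
        stratified_folds(np.arange(5.0), 1)


# ---------------------------------------------------------------------------
# fold_fit_eval

def test_noise_free_relation_gives_infinite_f(rng):
    X = rng.standard_normal((40, 2))
    y = 1.0 + X @ np.array([2.0, -1.0])
    beta, F, t = fold_fit_eval(y, X, np.arange(25), np.arange(25, 40))
    assert np.isinf(F)
    np.testing.assert_allclose(beta, [1.0, 2.0, -1.0], atol=1e-8)


def test_negative_out_of_sample_r2_floors_f_at_zero(rng):
    # training relation reversed in the test split -> negative R^2
    X = rng.standard_normal((60, 1))
    y = np.concatenate([3.0 * X[:40, 0], -3.0 * X[40:, 0]]) + 0.01 * rng.standard_normal(60)
    _, F, _ = fold_fit_eval(y, X, np.arange(40), np.arange(40, 60))
    assert F == 0.0


def test_statistics_match_long_hand_oracle(rng):
    n_train, n_test, p = 20, 10, 2
    X = rng.standard_normal((30, p))
    y = X @ np.array([0.5, -0.8]) + rng.standard_normal(30)
    train, test = np.arange(n_train), np.arange(n_train, 30)
    beta, F, t = fold_fit_eval(y, X, train, test)

    # independent long-hand computation of the same formulas
    Xtr = np.column_stack([np.ones(n_train), X[train]])
    b = np.linalg.inv(Xtr.T @ Xtr) @ Xtr.T @ y[train]
    Xte = np.column_stack([np.ones(n_test), X[test]])
    pred = Xte @ b
    ss_res = ((y[test] - pred) ** 2).sum()
    ss_tot = ((y[test] - y[test].mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    F_oracle = (r2 / p) / ((1 - r2) / (n_test - p - 1))
    sigma2 = ss_res / (n_test - p - 1)
    diag = np.diag(np.linalg.inv(Xte.T @ Xte))[1:]
    t_oracle = b[1:] / np.sqrt(sigma2 * diag)

    np.testing.assert_allclose(beta, b, atol=1e-10)
    assert F == pytest.approx(F_oracle, abs=1e-10)
    np.testing.assert_allclose(t, t_oracle, atol=1e-10)


def test_singular_design_rejected(rng):
    X = np.ones((30, 2))
    with pytest.raises(ValueError):
        fold_fit_eval(rng.standard_normal(30), X, np.arange(20), np.arange(20, 30))


# ---------------------------------------------------------------------------
# bilateral averaging

def _grad_table(rng, n=40, clusters=(1, 2), axes=2):
    data = {}
    for c in clusters:
        for a in range(1, axes + 1):
            data[f"c{c}_g{a}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


def test_identical_homologs_are_averaged(rng):
    t = _grad_table(rng)
    for a in (1, 2):
        t[f"c2_g{a}"] = t[f"c1_g{a}"]
    out, log = bilateral_average(t, [(1, 2)], min_rho=0.6)
    assert log[0]["merged"]
    assert "c1c2_g1" in out.columns and "c1_g1" not in out.columns
    np.testing.assert_allclose(out["c1c2_g1"], t["c1_g1"])


def test_weakly_correlated_homologs_kept_separate(rng):
    t = _grad_table(rng)  # independent columns, |r| small
    out, log = bilateral_average(t, [(1, 2)], min_rho=0.6)
    assert not log[0]["merged"]
    assert "c1_g1" in out.columns and "c2_g1" in out.columns


def test_anticorrelated_homologs_kept_separate(rng):
    t = _grad_table(rng)
    for a in (1, 2):
        t[f"c2_g{a}"] = -t[f"c1_g{a}"]
    out, log = bilateral_average(t, [(1, 2)], min_rho=0.6)
    assert not log[0]["merged"]
    assert log[0]["rho_per_axis"][0] == pytest.approx(-1.0)


def test_self_pairing_rejected(rng):
    with pytest.raises(ValueError):
        bilateral_average(_grad_table(rng), [(1, 1)])


# ---------------------------------------------------------------------------
# cv_permutation_model

def test_strong_signal_reaches_minimum_p(rng):
    X = rng.standard_normal((80, 2))
    y = X[:, 0] + 0.05 * rng.standard_normal(80)
    folds = stratified_folds(y, 5, seed=0)
    res = cv_permutation_model(y, X, folds, n_perm=99, seed=0)
    assert res.p_F == pytest.approx(1.0 / 100.0)
    assert res.p_t[0] == pytest.approx(1.0 / 100.0)


def test_cv_model_deterministic_given_seed(rng):
    X = rng.standard_normal((60, 3))
    y = rng.standard_normal(60)
    folds = stratified_folds(y, 5, seed=4)
    r1 = cv_permutation_model(y, X, folds, n_perm=50, seed=9)
    r2 = cv_permutation_model(y, X, folds, n_perm=50, seed=9)
    assert r1.p_F == r2.p_F
    np.testing.assert_array_equal(r1.null_F, r2.null_F)
    np.testing.assert_array_equal(r1.fold_betas, r2.fold_betas)


def test_null_pool_shapes(rng):
    X = rng.standard_normal((60, 3))
    y = rng.standard_normal(60)
    folds = stratified_folds(y, 5, seed=4)
    res = cv_permutation_model(y, X, folds, n_perm=25, seed=1)
    assert res.null_F_folds.shape == (5, 25)
    assert res.null_t_folds.shape == (5, 25, 3)
    assert res.null_F.shape == (25,)
    assert 0 < res.p_F <= 1


# ---------------------------------------------------------------------------
# FDR

def _bh_oracle(p):
    """Literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.04], [0.04]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
    ],
)
def test_fdr_known_cases(p, expected):
    np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)


def test_fdr_matches_step_up_oracle_on_grid():
    grid = [0.001, 0.01, 0.04, 0.2, 0.5, 1.0]
    for length in (2, 3, 4):
        for combo in itertools.combinations_with_replacement(grid, length):
            np.testing.assert_allclose(
                fdr_adjust(list(combo)), _bh_oracle(combo), atol=1e-12
            )


def test_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# holdout validation

def _fitted_cv(rng, beta=(-0.5, 0.0), n=100, noise=0.1, n_perm=50):
    p = len(beta)
    X = rng.standard_normal((n, p))
    y = X @ np.asarray(beta) + noise * rng.standard_normal(n)
    folds = stratified_folds(y, 5, seed=0)
    return cv_permutation_model(y, X, folds, n_perm=n_perm, seed=0), X, y


def test_holdout_noise_free_reaches_minimum_p(rng):
    res, X, _ = _fitted_cv(rng, noise=0.0)
    beta = res.fold_betas.mean(axis=0)
    Xh = rng.standard_normal((60, 2))
    yh = beta[0] + Xh @ beta[1:]
    hres = holdout_validation(res, yh, Xh, n_perm=199, seed=1)
    assert hres.p_F == pytest.approx(1.0 / 200.0)


def test_holdout_zero_coefficients_give_zero_f(rng):
    res, X, y = _fitted_cv(rng)
    res.fold_betas[:] = 0.0
    Xh = rng.standard_normal((50, 2))
    yh = rng.standard_normal(50)
    hres = holdout_validation(res, yh, Xh, n_perm=99, seed=2)
    assert hres.F == 0.0
    assert hres.p_F > 0.5


def test_holdout_sign_recovery_of_planted_negative_effect():
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        res, _, _ = _fitted_cv(r, beta=(-0.4, 0.0), n=200, noise=0.9, n_perm=30)
        Xh = r.standard_normal((200, 2))
        yh = -0.4 * Xh[:, 0] + 0.9 * r.standard_normal(200)
        hres = holdout_validation(res, yh, Xh, n_perm=99, seed=seed)
        hits += hres.t[0] < 0
    assert hits >= 18  # >= 90% of seeds


def test_holdout_predictor_mismatch_rejected(rng):
    res, _, _ = _fitted_cv(rng)
    with pytest.raises(ValueError):
        holdout_validation(res, rng.standard_normal(30), rng.standard_normal((30, 3)))


# ---------------------------------------------------------------------------
# spearman screen

def test_monotone_transform_gives_rho_one(rng):
    x = rng.standard_normal(30)
    tasks = pd.DataFrame({"a": np.exp(x), "b": -x**3})
    out = spearman_screen(x, tasks).set_index("task")
    assert out.loc["a", "rho"] == pytest.approx(1.0)
    assert out.loc["b", "rho"] == pytest.approx(-1.0)


def test_constant_task_flagged(rng):
    x = rng.standard_normal(20)
    out = spearman_screen(x, pd.DataFrame({"c": np.ones(20)}))
    assert out.iloc[0]["constant"]
    assert np.isnan(out.iloc[0]["rho"])


def test_rho_matches_rank_covariance_oracle(rng):
    x = rng.standard_normal(50)
    tasks = pd.DataFrame({"t": rng.standard_normal(50)})
    out = spearman_screen(x, tasks)
    rx = np.argsort(np.argsort(x))
    rt = np.argsort(np.argsort(tasks["t"].to_numpy()))
    oracle = np.corrcoef(rx, rt)[0, 1]
    assert out.iloc[0]["rho"] == pytest.approx(oracle, abs=1e-10)


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
)
def test_fdr_matches_step_up_oracle_for_arbitrary_vectors(p):
    np.testing.assert_allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)
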