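"""LASSO/minimum-norm fitting, the all-pairs engine, controls, k-NN."""

import numpy as np
import pytest

from atlasrep.atlas_data import stratified_split
from atlasrep.linear_classifiers import (
    LAMBDA_GRID,
    fit_lasso,
    fit_minimum_norm,
    knn_area_auroc,
    pairwise_classify,
    permutation_control,
    select_lambda,
)
from conftest import make_dataset


@pytest.mark.parametrize("lam", [0.1, 0.25, 0.5, 0.9])
def test_lasso_1d_closed_form(lam):
    """cost (w-1)^2/2 + lam|w| is minimized at w = 1 - lam (no intercept)."""
    X = np.array([[-1.0], [1.0]])
    y = np.array([-1.0, 1.0])
    m = fit_lasso(X, y, lam, fit_intercept=False)
    assert m.coef[0] == pytest.approx(1 - lam, abs=1e-6)
    assert m.intercept == 0.0


def test_lasso_kill_threshold_zeroes_everything():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 10))
    y = rng.integers(0, 2, 30).astype(float)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / X.shape[0]
    m = fit_lasso(X, y, lam_max * 1.01)
    assert m.n_nonzero == 0
    assert np.ptp(m.predict(X)) == 0.0  # constant predictions


def test_lasso_zero_penalty_matches_minimum_norm():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(8, 30))  # genes > samples
    y = rng.normal(size=8)
    pred_lasso = fit_lasso(X, y, 0.0).predict(X)
    pred_mn = fit_minimum_norm(X, y).predict(X)
    np.testing.assert_allclose(pred_lasso, pred_mn, atol=1e-8)


def test_minimum_norm_simple_line():
    m = fit_minimum_norm(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]))
    assert m.coef[0] == pytest.approx(1.0)
    assert m.intercept == pytest.approx(0.0)


def test_minimum_norm_splits_duplicated_columns_equally():
    rng = np.random.default_rng(2)
    g = rng.normal(size=12)
    X = np.column_stack([g, g])
    y = 3.0 * g + 1.0
    m = fit_minimum_norm(X, y)
    assert m.coef[0] == pytest.approx(m.coef[1], abs=1e-8)
    assert m.coef.sum() == pytest.approx(3.0, abs=1e-8)


def test_minimum_norm_underdetermined_is_interpolating_and_minimal():
    """p > n: residuals are exactly 0 and no null-space move shrinks the norm."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(2, 5))
    y = rng.normal(size=2)
    m = fit_minimum_norm(X, y, fit_intercept=False)
    np.testing.assert_allclose(m.predict(X), y, atol=1e-10)
    # oracle: grid over the 3-dim null space of X around the solution
    _, _, vt = np.linalg.svd(X)
    null = vt[2:]  # rows spanning the null space
    base = np.linalg.norm(m.coef)
    grid = np.linspace(-1, 1, 7)
    for a in grid:
        for b in grid:
            for c in grid:
                alt = m.coef + a * null[0] + b * null[1] + c * null[2]
                np.testing.assert_allclose(X @ alt, y, atol=1e-10)
                assert np.linalg.norm(alt) >= base - 1e-9


def test_sparsity_increases_with_penalty(small_pair):
    a = small_pair[0]
    idx = np.flatnonzero(np.isin(a.labels, list(set(a.labels))[:2]))
    y = (a.labels[idx] == sorted(set(a.labels[idx]))[0]).astype(float)
    weak = fit_lasso(a.X[idx], y, 0.01)
    strong = fit_lasso(a.X[idx], y, 0.9)
    assert strong.n_nonzero <= weak.n_nonzero


def test_pairwise_toy_shape_and_symmetry():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 8)) + np.repeat([[0], [3], [6]], 10, axis=0)
    ds = make_dataset(X, ["r1"] * 10 + ["r2"] * 10 + ["r3"] * 10)
    mat = pairwise_classify(ds, stratified_split(ds, 0), lam=0.1)
    vals = mat.values[np.triu_indices(3, k=1)]
    assert np.isfinite(vals).all() and ((0 <= vals) & (vals <= 1)).all()
    np.testing.assert_array_equal(mat.values, mat.values.T)
    assert np.isnan(np.diag(mat.values)).all()


def test_pairwise_disjoint_signatures_perfect():
    X = np.zeros((20, 4))
    X[:10, 0] = 5.0
    X[10:, 1] = 5.0
    ds = make_dataset(X, ["r1"] * 10 + ["r2"] * 10)
    mat = pairwise_classify(ds, stratified_split(ds, 0), lam=0.1)
    assert mat.values[0, 1] == pytest.approx(1.0)


def test_pairwise_identical_distributions_near_chance():
    """Two regions drawn from one distribution: mean AUROC within 3 SE of 0.5."""
    vals = []
    for s in range(20):
        rng = np.random.default_rng(100 + s)
        X = rng.normal(size=(24, 6))
        ds = make_dataset(X, ["r1"] * 12 + ["r2"] * 12)
        mat = pairwise_classify(ds, stratified_split(ds, s), lam=0.0, model="linreg")
        vals.append(mat.values[0, 1])
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - 0.5) < 3 * se + 0.02


def test_permutation_control_semantics(small_pair):
    """Permuting labels by hand reproduces permutation_control exactly."""
    a = small_pair[0]
    folds = stratified_split(a, 9)
    mat_ctrl = permutation_control(a, folds, lam=0.1, seed=21)
    manual = a.copy()
    manual.labels = a.labels[np.random.default_rng(21).permutation(a.n_samples)]
    mat_manual = pairwise_classify(manual, folds, lam=0.1)
    np.testing.assert_allclose(mat_ctrl.values, mat_manual.values, equal_nan=True)
    # a different permutation gives a different matrix
    other = permutation_control(a, folds, lam=0.1, seed=22)
    assert not np.allclose(mat_ctrl.values, other.values, equal_nan=True)


def _separable_dataset(n_per=120, seed=0):
    # gene 0 cleanly separates with a margin large enough that even the
    # heaviest grid penalty keeps a nonzero coefficient
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, 5), scale=0.05)
    X[:n_per, 0] += 8.0
    return make_dataset(X, ["r1"] * n_per + ["r2"] * n_per)


def test_select_lambda_tie_breaks_to_smallest():
    ds = _separable_dataset()
    table = select_lambda(ds, stratified_split(ds, 0), min_area_n=100, seed=0)
    assert len(table) == 1
    row = table.iloc[0]
    # a single clean marker: every penalty separates perfectly -> first of ties
    assert all(row[f"auroc_lambda_{lam}"] == pytest.approx(1.0) for lam in LAMBDA_GRID)
    assert row["best_lambda"] == 0.01


def test_select_lambda_singleton_grid_and_eligibility():
    ds = _separable_dataset()
    table = select_lambda(ds, stratified_split(ds, 0), grid=(0.1,), min_area_n=100)
    assert table.iloc[0]["best_lambda"] == 0.1
    with pytest.raises(ValueError):
        select_lambda(ds, stratified_split(ds, 0), min_area_n=1000)


def test_knn_perfectly_separated_regions():
    X = np.zeros((24, 3))
    X[:12, 0] = 10.0
    X[12:, 1] = 10.0
    ds = make_dataset(X, ["rA"] * 12 + ["rB"] * 12)
    per_region = knn_area_auroc(ds, stratified_split(ds, 0), k=5)
    assert per_region["rA"] == pytest.approx(1.0)
    assert per_region["rB"] == pytest.approx(1.0)


def test_knn_shuffled_labels_near_chance():
    vals = []
    for s in range(8):
        rng = np.random.default_rng(200 + s)
        X = rng.normal(size=(60, 5))
        labels = rng.permutation(["r1"] * 20 + ["r2"] * 20 + ["r3"] * 20)
        ds = make_dataset(X, labels)
        per_region = knn_area_auroc(ds, stratified_split(ds, s), k=5)
        vals.append(per_region.mean())
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - 0.5) < 3 * se + 0.03
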