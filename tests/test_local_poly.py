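import numpy as np
import pytest

from kwlpr.dataio import fit_scaler
from kwlpr.exceptions import EmptyNeighborhoodError, KwlprError
from kwlpr.kernels import kernel_value, product_weights
from kwlpr.local_poly import (
    KwlprModel,
    local_design,
    loo_predictions,
    smoother_matrix,
)


def nw_oracle(X, y, x0, kernel, h):
    """Independent Nadaraya-Watson weighted-average computation."""
    w = product_weights(kernel, h, X, x0)
    return float(w @ y / w.sum())


def wls_oracle(X, y, x0, kernel, h, degree):
    """Explicit (X^T W X)^{-1} X^T W y solve via matrix inverse."""
    w = product_weights(kernel, h, X, x0)
    T = local_design(X, x0, degree)
    A = T.T @ np.diag(w) @ T
    return np.linalg.inv(A) @ (T.T @ np.diag(w) @ y)


# -- local design ----------------------------------------------------------


def test_local_design_degree0_is_ones():
    T = local_design(np.zeros((3, 2)), [0.0, 0.0], 0)
    np.testing.assert_array_equal(T, np.ones((3, 1)))


def test_local_design_degree1_centers_at_query():
    X = np.array([[0.0], [1.0], [2.0]])
    T = local_design(X, [1.0], 1)
    np.testing.assert_array_equal(T[:, 0], [1, 1, 1])
    np.testing.assert_array_equal(T[:, 1], [-1, 0, 1])


def test_local_design_degree1_width():
    T = local_design(np.zeros((3, 2)), [0.0, 0.0], 1)
    assert T.shape == (3, 3)  # 1 + p*d columns, additive terms only
    with pytest.raises(KwlprError):
        local_design(np.zeros((3, 2)), [0.0, 0.0], 2)


# -- fit_at ----------------------------------------------------------------


def test_single_training_point_weighted_mean():
    m = KwlprModel(X=[[2.0]], y=[5.0], degree=0, kernel="gaussian",
                   bandwidths=[1.0])
    assert m.fit_at([1.3]).prediction == pytest.approx(5.0)


def test_nadaraya_watson_worked_example():
    # training {(0,0),(1,1),(2,4)}, h=1, gaussian, query at 1:
    # (K(1)*0 + K(0)*1 + K(1)*4) / (K(1)+K(0)+K(1))
    m = KwlprModel(X=[[0.0], [1.0], [2.0]], y=[0.0, 1.0, 4.0], degree=0,
                   kernel="gaussian", bandwidths=[1.0])
    k0, k1 = kernel_value("gaussian", 0.0), kernel_value("gaussian", 1.0)
    expected = (k1 * 0 + k0 * 1 + k1 * 4) / (2 * k1 + k0)
    fit = m.fit_at([1.0])
    assert fit.prediction == pytest.approx(expected, abs=1e-12)
    assert fit.prediction == pytest.approx(1.548137, abs=1e-6)
    assert fit.effective_weight_sum == pytest.approx(2 * k1 + k0, rel=1e-12)


def test_local_linear_reproduces_affine_truth(rng):
    X = rng.uniform(-2, 2, size=(15, 1))
    y = 2.0 * X[:, 0] + 1.0
    for h in (0.1, 0.5, 3.0):
        for kernel in ("gaussian", "epanechnikov"):
            m = KwlprModel(X=X, y=y, degree=1, kernel=kernel, bandwidths=[h])
            for x0 in (0.0, 1.2, -1.7):
                # exactness needs >= 2 distinct positively weighted points
                if np.count_nonzero(product_weights(kernel, [h], X, [x0])) < 2:
                    continue
                fit = m.fit_at([x0])
                assert fit.prediction == pytest.approx(2 * x0 + 1, abs=1e-8)


def test_empty_neighborhood_raises_with_advice():
    m = KwlprModel(X=[[0.0], [0.1], [0.2]], y=[1.0, 2.0, 3.0], degree=0,
                   kernel="uniform", bandwidths=[0.05])
    with pytest.raises(EmptyNeighborhoodError, match="bandwidth"):
        m.fit_at([5.0])


def test_fit_at_matches_explicit_solve(rng):
    for _ in range(40):
        n = int(rng.integers(5, 21))
        d = int(rng.integers(1, 4))
        degree = int(rng.integers(0, 2))
        X = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        h = rng.uniform(0.5, 2.0, size=d)
        x0 = X[int(rng.integers(0, n))]
        m = KwlprModel(X=X, y=y, degree=degree, kernel="gaussian", bandwidths=h)
        beta = m.fit_at(x0).beta
        np.testing.assert_allclose(
            beta, wls_oracle(X, y, x0, "gaussian", h, degree), atol=1e-8
        )


# -- predict ---------------------------------------------------------------


def test_predict_applies_scaler_and_is_deterministic(sine_ds):
    ds, _ = sine_ds
    m = KwlprModel.fit(ds, degree=0, kernel="gaussian", bandwidths=[0.3])
    p1 = m.predict(ds.X_valid)
    p2 = m.predict(ds.X_valid)
    np.testing.assert_array_equal(p1, p2)
    # consistent with fit_at row by row
    Xs = m.scaler.transform(ds.X_valid)
    for i in range(5):
        assert p1[i] == pytest.approx(m.fit_at(Xs[i]).prediction, rel=1e-10)


def test_huge_uniform_bandwidth_gives_global_mean(rng):
    X = rng.normal(size=(12, 1))
    y = rng.normal(size=12)
    m = KwlprModel(X=X, y=y, degree=0, kernel="uniform", bandwidths=[1e3])
    np.testing.assert_allclose(m.predict_scaled(X), np.full(12, y.mean()),
                               rtol=1e-12)


def test_huge_gaussian_bandwidth_matches_global_ols(rng):
    X = rng.normal(size=(20, 2))
    y = rng.normal(size=20)
    m = KwlprModel(X=X, y=y, degree=1, kernel="gaussian", bandwidths=[1e6, 1e6])
    U = np.hstack([np.ones((20, 1)), X])
    beta = np.linalg.lstsq(U, y, rcond=None)[0]
    np.testing.assert_allclose(m.predict_scaled(X), U @ beta, atol=1e-6)


def test_local_constant_predictions_are_convex_combinations(sine_ds):
    ds, _ = sine_ds
    for kernel in ("gaussian", "epanechnikov", "uniform"):
        m = KwlprModel.fit(ds, degree=0, kernel=kernel, bandwidths=[0.5])
        pred = m.predict(ds.X)
        assert np.all(pred >= ds.y_train.min() - 1e-12)
        assert np.all(pred <= ds.y_train.max() + 1e-12)


def test_small_bandwidth_converges_to_own_response(rng):
    X = rng.uniform(0, 10, size=(15, 1))
    y = rng.normal(size=15)
    m = KwlprModel(X=X, y=y, degree=0, kernel="gaussian", bandwidths=[1e-3])
    np.testing.assert_allclose(m.predict_scaled(X), y, atol=1e-8)


def test_permutation_of_training_rows_never_changes_predictions(rng, sine_ds):
    ds, _ = sine_ds
    m = KwlprModel.fit(ds, degree=1, kernel="gaussian", bandwidths=[0.4])
    perm = rng.permutation(m.n)
    m2 = KwlprModel(X=m.X[perm], y=m.y[perm], degree=1, kernel="gaussian",
                    bandwidths=[0.4], scaler=m.scaler)
    np.testing.assert_allclose(m.predict(ds.X_valid), m2.predict(ds.X_valid),
                               rtol=1e-10)


def test_predict_dimension_mismatch(sine_ds):
    ds, _ = sine_ds
    m = KwlprModel.fit(ds, degree=0, kernel="gaussian", bandwidths=[0.3])
    with pytest.raises(KwlprError, match="columns"):
        m.predict(np.zeros((3, 2)))


# -- smoother matrix and LOO ----------------------------------------------


@pytest.mark.parametrize("degree", [0, 1])
def test_smoother_matrix_reproduces_predictions(degree, sine_ds):
    ds, _ = sine_ds
    m = KwlprModel.fit(ds, degree=degree, kernel="gaussian", bandwidths=[0.35])
    Xs = m.scaler.transform(ds.X_valid)
    L, empty = smoother_matrix(m, Xs)
    assert not empty.any()
    np.testing.assert_allclose(L @ m.y, m.predict(ds.X_valid), rtol=1e-12)


@pytest.mark.parametrize("degree", [0, 1])
@pytest.mark.parametrize("kernel", ["gaussian", "epanechnikov"])
def test_loo_shortcut_equals_literal_refit(degree, kernel, sine_ds):
    ds, _ = sine_ds
    m = KwlprModel.fit(ds, degree=degree, kernel=kernel, bandwidths=[0.6])
    loo_s, empty_s = loo_predictions(m, method="shortcut")
    loo_r, empty_r = loo_predictions(m, method="refit")
    np.testing.assert_array_equal(empty_s, empty_r)
    keep = ~empty_s
    np.testing.assert_allclose(loo_s[keep], loo_r[keep], atol=1e-10)
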