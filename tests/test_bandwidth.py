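import numpy as np
import pytest

from kwlpr.bandwidth import (
    aic_objective,
    lscv_objective,
    plugin_bandwidth,
    select_bandwidth,
)
from kwlpr.dataio import fit_scaler
from kwlpr.exceptions import KwlprError, UnsupportedMethodError
from kwlpr.kernels import KERNEL_CONSTANTS
from kwlpr.local_poly import KwlprModel
from kwlpr.metrics import rmse


def literal_loo_cv(X, y, degree, kernel, h):
    """Brute-force refit-per-left-out-point leave-one-out CV oracle."""
    n = len(y)
    sq = []
    for i in range(n):
        keep = np.arange(n) != i
        m = KwlprModel(X=X[keep], y=y[keep], degree=degree, kernel=kernel,
                       bandwidths=h)
        sq.append((y[i] - m.predict_scaled(X[i][None, :])[0]) ** 2)
    return float(np.mean(sq))


def test_two_point_lscv_is_one():
    # each LOO prediction is the other point's response
    X = np.array([[0.0], [1.0]])
    y = np.array([0.0, 1.0])
    for h in (0.2, 1.0, 7.0):
        assert lscv_objective([h], X, y, 0, "gaussian") == pytest.approx(1.0)


def test_lscv_is_pure_function(sine_ds):
    ds, _ = sine_ds
    sc = fit_scaler(ds)
    Xs, y = sc.transform(ds.X_train), ds.y_train
    a = lscv_objective([0.4], Xs, y, 0, "gaussian")
    b = lscv_objective([0.4], Xs, y, 0, "gaussian")
    assert a == b


def test_lscv_matches_brute_force_oracle_on_grid(rng):
    n = 20
    x = np.sort(rng.uniform(0, 2 * np.pi, n))
    y = np.sin(x) + rng.normal(0, 0.25, n)
    X = x[:, None]
    for degree in (0, 1):
        for h in np.linspace(0.05, 3.0, 30):
            fast = lscv_objective([h], X, y, degree, "gaussian")
            slow = literal_loo_cv(X, y, degree, "gaussian", np.array([h]))
            assert fast == pytest.approx(slow, abs=1e-10)


def test_lscv_penalizes_empty_neighborhoods():
    # uniform kernel, h too small: every LOO neighborhood is empty
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0.0, 1.0, 0.0, 1.0])
    val = lscv_objective([0.01], X, y, 0, "uniform")
    assert val > 1e5  # large finite penalty, never an exception
    assert np.isfinite(val)


def test_aicc_overfit_barrier_returns_inf():
    X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
    y = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
    # tiny uniform bandwidth: each point dominates its own fit, tr(H) -> n
    assert aic_objective([0.01], X, y, 0, "uniform") == np.inf


def test_aicc_finite_in_oversmooth_limit(sine_ds):
    ds, _ = sine_ds
    sc = fit_scaler(ds)
    Xs, y = sc.transform(ds.X_train), ds.y_train
    val = aic_objective([1e6], Xs, y, 0, "gaussian")
    assert np.isfinite(val)
    # tr(H) -> 1 and sigma2 -> variance about the mean
    n = len(y)
    expected = np.log(np.mean((y - y.mean()) ** 2)) + (1 + 1 / n) / (1 - 3 / n)
    assert val == pytest.approx(expected, abs=1e-3)


def test_aicc_minimizer_is_interior(sine_ds):
    ds, _ = sine_ds
    sc = fit_scaler(ds)
    Xs, y = sc.transform(ds.X_train), ds.y_train
    grid = np.geomspace(0.05, 5.0, 25)
    vals = [aic_objective([h], Xs, y, 0, "gaussian") for h in grid]
    k = int(np.argmin(vals))
    assert 0 < k < len(grid) - 1


def test_bias_variance_shape_on_sine(sine_ds):
    """In-sample RMSE_C non-decreasing in h; LOO CV has an interior minimum."""
    ds, _ = sine_ds
    sc = fit_scaler(ds)
    Xs, y = sc.transform(ds.X_train), ds.y_train
    grid = np.geomspace(0.05, 5.0, 12)
    rmse_c, cv = [], []
    for h in grid:
        m = KwlprModel(X=Xs, y=y, degree=0, kernel="gaussian", bandwidths=[h])
        rmse_c.append(rmse(y, m.fitted()))
        cv.append(lscv_objective([h], Xs, y, 0, "gaussian"))
    assert np.all(np.diff(rmse_c) >= -1e-9)  # oversmoothing worsens the fit
    k = int(np.argmin(cv))
    assert 0 < k < len(grid) - 1  # interior minimum: over/underfitting both hurt


# -- direct plug-in --------------------------------------------------------


def test_plugin_linear_truth_hits_upper_bound(rng):
    x = rng.uniform(0, 1, 40)
    y = 3.0 * x + 2.0
    h = plugin_bandwidth(x, y, bounds=(0.05, 5.0))
    assert h[0] == pytest.approx(5.0)


def test_plugin_is_deterministic(rng):
    x = rng.uniform(0, 1, 31)
    y = np.exp(x) + rng.normal(0, 0.1, 31)
    h1 = plugin_bandwidth(x, y)
    h2 = plugin_bandwidth(x, y)
    assert h1[0] == h2[0]
    assert 0.05 <= h1[0] <= 5.0


def test_plugin_quadratic_matches_closed_form_rate(rng):
    # y = x^2 on [0,1]: m'' = 2 so theta22 = 4; known noise sd
    n, sigma = 50, 0.05
    x = rng.uniform(0, 1, n)
    y = x**2 + rng.normal(0, sigma, n)
    roughness, mu2 = KERNEL_CONSTANTS["gaussian"]
    h_opt = (roughness * sigma**2 * np.ptp(x) / (n * mu2**2 * 4.0)) ** 0.2
    h = plugin_bandwidth(x, y)[0]
    assert h_opt / 2 < h < h_opt * 2


def test_plugin_rejects_multivariate():
    X = np.zeros((10, 2))
    with pytest.raises(UnsupportedMethodError, match="cv.ls"):
        select_bandwidth("plugin", X, np.zeros(10), 1, "gaussian")


# -- multistart selection --------------------------------------------------


def test_select_matches_dense_grid_minimizer(sine_ds):
    ds, _ = sine_ds
    sc = fit_scaler(ds)
    Xs, y = sc.transform(ds.X_train), ds.y_train
    sel = select_bandwidth("cv.ls", Xs, y, 0, "gaussian", seed=1)
    grid = np.geomspace(0.05, 5.0, 400)
    vals = [lscv_objective([h], Xs, y, 0, "gaussian") for h in grid]
    assert sel.objective_value <= min(vals) + 1e-8
    assert abs(np.log(sel.selected[0]) - np.log(grid[int(np.argmin(vals))])) < 0.05
    # invariant: reported objective equals the objective at the selection
    assert sel.objective_value == pytest.approx(
        lscv_objective(sel.selected, Xs, y, 0, "gaussian"), rel=1e-12
    )


def test_selection_reproducible_given_seed(sine_ds):
    ds, _ = sine_ds
    sc = fit_scaler(ds)
    Xs, y = sc.transform(ds.X_train), ds.y_train
    a = select_bandwidth("cv.aic", Xs, y, 1, "gaussian", seed=7)
    b = select_bandwidth("cv.aic", Xs, y, 1, "gaussian", seed=7)
    np.testing.assert_array_equal(a.selected, b.selected)
    assert a.objective_value == b.objective_value


def test_selected_bandwidth_beats_misscaled_alternatives(sine_ds):
    """The cv.ls choice out-predicts h/10 and 10h on held-out data."""
    ds, truth = sine_ds
    sc = fit_scaler(ds)
    Xs, y = sc.transform(ds.X_train), ds.y_train
    sel = select_bandwidth("cv.ls", Xs, y, 0, "gaussian", seed=1)

    def holdout_rmse(h):
        m = KwlprModel.fit(ds, 0, "gaussian", [h])
        return rmse(ds.y_valid, m.predict(ds.X_valid))

    h = sel.selected[0]
    assert holdout_rmse(h) < holdout_rmse(h / 10)
    assert holdout_rmse(h) < holdout_rmse(min(10 * h, 50.0))


def test_invalid_arguments():
    X = np.zeros((5, 1))
    y = np.zeros(5)
    with pytest.raises(KwlprError):
        select_bandwidth("nope", X, y, 0, "gaussian")
    with pytest.raises(KwlprError):
        select_bandwidth("cv.ls", X, y, 0, "gaussian", bounds=(-1, 2))
    with pytest.raises(KwlprError):
        select_bandwidth("cv.ls", X, y, 0, "gaussian", n_restarts=0)
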