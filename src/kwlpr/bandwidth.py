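"""Automatic data-driven bandwidth selection.

Three selectors are offered, matching the front-end names ``cv.ls``,
``cv.aic`` and ``plugin``:

* least-squares cross-validation: minimize the mean squared leave-one-out
  prediction error CV(h) = (1/n) sum_i (y_i - mhat_{-i}(x_i))^2;
* expected Kullback-Leibler cross-validation, concretized as the
  Hurvich-Simonoff-Tsai corrected AIC for linear smoothers,
  AICc(h) = ln(sigma2hat) + (1 + tr(H)/n) / (1 - (tr(H)+2)/n),
  with a +inf barrier once tr(H)+2 >= n (the overfit regime);
* the 1-D direct plug-in bandwidth for local-linear regression
  (blocked-quartic pilot estimates of curvature and noise variance plugged
  into the asymptotically optimal rate formula).

Search is a seeded multistart bounded Nelder-Mead over log-bandwidths, so
every selection is a pure function of (data, method, bounds, restarts, seed).
Bandwidths live on the auto-scaled variable scale, hence the fixed default
search box [0.05, 5] is meaningful for any dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import KwlprError, UnsupportedMethodError
from .kernels import KERNEL_CONSTANTS, validate_bandwidths
from .local_poly import KwlprModel, hat_diagonal, loo_predictions

BW_METHODS = ("cv.ls", "cv.aic", "plugin")
DEFAULT_BOUNDS = (0.05, 5.0)


@dataclass(frozen=True)
class BandwidthSelection:
    """Outcome of one bandwidth search."""

    method: str
    selected: np.ndarray
    objective_value: float
    n_restarts: int
    seed: int


def _template_model(X, y, degree, kernel, h) -> KwlprModel:
    return KwlprModel(X=np.atleast_2d(np.asarray(X, float)), y=y,
                      degree=degree, kernel=kernel, bandwidths=h)


def lscv_objective(h, X, y, degree, kernel) -> float:
    """Mean squared leave-one-out residual at bandwidth ``h`` (total function).

    Rows whose leave-one-out neighborhood is empty (compact kernel, h too
    small) contribute a large finite penalty of 1e6 * var(y) each, so the
    optimizer is pushed away from degenerate bandwidths without ever seeing
    an exception.
    """
    y = np.asarray(y, dtype=float)
    model = _template_model(X, y, degree, kernel, h)
    loo, empty = loo_predictions(model)
    penalty = 1e6 * max(float(np.var(y)), 1.0)
    sq = np.where(empty, penalty, (y - np.where(empty, 0.0, loo)) ** 2)
    return float(sq.mean())


def aic_objective(h, X, y, degree, kernel) -> float:
    """AICc of the smoother at bandwidth ``h`` (extended-real: may be +inf)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    model = _template_model(X, y, degree, kernel, h)
    diag = hat_diagonal(model)
    tr_h = float(np.nansum(diag))
    if not np.isfinite(tr_h) or tr_h + 2.0 >= n:
        return np.inf
    fitted = model.fitted()
    sigma2 = float(np.mean((y - fitted) ** 2))
    if sigma2 <= 0.0:
        return -np.inf
    return float(np.log(sigma2) + (1.0 + tr_h / n) / (1.0 - (tr_h + 2.0) / n))


_OBJECTIVES = {"cv.ls": lscv_objective, "cv.aic": aic_objective}


# ---------------------------------------------------------------------------
# direct plug-in (1-D local-linear)


def _blocked_quartic(x, y, n_blocks):
    """Quartic OLS fits on ordered blocks; returns (RSS, second-derivative
    values at the data points, residual dof)."""
    order = np.argsort(x, kind="stable")
    idx_blocks = np.array_split(order, n_blocks)
    rss = 0.0
    m2 = np.empty_like(np.asarray(x, float))
    dof = 0
    for idx in idx_blocks:
        xb, yb = x[idx], y[idx]
        deg = min(4, len(idx) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            coef = np.polynomial.polynomial.polyfit(xb, yb, deg)
        fit = np.polynomial.polynomial.polyval(xb, coef)
        rss += float(np.sum((yb - fit) ** 2))
        dof += len(idx) - (deg + 1)
        d2 = np.polynomial.polynomial.polyder(coef, 2)
        m2[idx] = np.polynomial.polynomial.polyval(xb, d2)
    return rss, m2, dof


def plugin_bandwidth(x, y, kernel: str = "gaussian",
                     bounds=DEFAULT_BOUNDS) -> np.ndarray:
    """Direct plug-in bandwidth for 1-D local-linear regression.

    Blocked-quartic pilot fits (block count chosen by Mallows' Cp) estimate
    the curvature functional theta22 = (1/n) sum m''(x_i)^2 and the residual
    variance; these are plugged into the asymptotically optimal bandwidth

        h = [ R(K) sigma2 (b - a) / ( n mu2(K)^2 theta22 ) ]^(1/5),

    clipped to ``bounds``.  Exactly linear data drive theta22 to ~0 and the
    returned bandwidth to the upper bound.  Deterministic: no randomness.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    n = x.size
    if n != y.size:
        raise KwlprError("x and y disagree in length")
    if n < 6:
        raise KwlprError("plug-in selection needs at least 6 points")
    n_max = max(min(n // 20, 5), 1)
    rss_max, _, dof_max = _blocked_quartic(x, y, n_max)
    scale = rss_max / max(dof_max, 1)
    best = None
    for nb in range(1, n_max + 1):
        rss, m2, _ = _blocked_quartic(x, y, nb)
        cp = rss / max(scale, np.finfo(float).tiny) - (n - 10 * nb)
        if best is None or cp < best[0]:
            best = (cp, rss, m2, nb)
    _, rss, m2, nb = best
    sigma2 = rss / max(n - 5 * nb, 1)
    theta22 = float(np.mean(m2**2))
    span = float(np.ptp(x))
    roughness, mu2 = KERNEL_CONSTANTS[kernel]
    if theta22 < 1e-12 or span <= 0.0 or sigma2 <= 0.0:
        return np.array([bounds[1]])
    h = (roughness * sigma2 * span / (n * mu2**2 * theta22)) ** 0.2
    return np.array([float(np.clip(h, *bounds))])


# ---------------------------------------------------------------------------
# multistart search


def select_bandwidth(method: str, X, y, degree: int, kernel: str,
                     bounds=DEFAULT_BOUNDS, n_restarts: int = 5,
                     seed: int = 1) -> BandwidthSelection:
    """Select a per-descriptor bandwidth vector by the chosen method.

    ``cv.ls``/``cv.aic`` run a seeded multistart bounded Nelder-Mead over
    log-bandwidths; ``plugin`` dispatches to the deterministic 1-D
    direct-plug-in selector (local-linear only).  Deterministic given
    ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    d = X.shape[1]
    lo, hi = float(bounds[0]), float(bounds[1])
    if not (0.0 < lo < hi):
        raise KwlprError(f"invalid bandwidth bounds {bounds!r}")
    if n_restarts < 1:
        raise KwlprError("n_restarts must be >= 1")

    if method == "plugin":
        if d != 1 or degree != 1:
            raise UnsupportedMethodError(
                "the direct plug-in selector supports a single descriptor with "
                "the local-linear estimator; use cv.ls or cv.aic instead"
            )
        h = plugin_bandwidth(X[:, 0], y, kernel=kernel, bounds=(lo, hi))
        return BandwidthSelection(method=method, selected=h,
                                  objective_value=float("nan"),
                                  n_restarts=n_restarts, seed=seed)
    if method not in _OBJECTIVES:
        raise KwlprError(f"unknown bandwidth method {method!r}; choose from {BW_METHODS}")
    objective = _OBJECTIVES[method]

    log_lo, log_hi = np.log(lo), np.log(hi)

    def f(z):
        val = objective(np.exp(z), X, y, degree, kernel)
        return val if np.isfinite(val) else 1e308

    rng = np.random.default_rng(seed)
    starts = [np.full(d, 0.5 * (log_lo + log_hi))]
    for _ in range(n_restarts - 1):
        starts.append(rng.uniform(log_lo, log_hi, size=d))

    best_z, best_val = None, np.inf
    for z0 in starts:
        res = optimize.minimize(
            f, z0, method="Nelder-Mead",
            bounds=[(log_lo, log_hi)] * d,
            options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 400 * d},
        )
        if res.fun < best_val:
            best_z, best_val = res.x, res.fun
    # guard: compare against the box edges
    for z_edge in (np.full(d, log_lo), np.full(d, log_hi)):
        val = f(z_edge)
        if val < best_val:
            warnings.warn(
                "bandwidth search did not improve on a bounds-edge evaluation; "
                "returning the edge", stacklevel=2,
            )
            best_z, best_val = z_edge, val
    selected = np.clip(np.exp(best_z), lo, hi)
    obj_val = objective(selected, X, y, degree, kernel)
    return BandwidthSelection(method=method, selected=selected,
                              objective_value=float(obj_val),
                              n_restarts=n_restarts, seed=seed)


def select_for_dataset(method: str, ds, degree: int, kernel: str,
                       scaler=None, **kwargs) -> BandwidthSelection:
    """Convenience wrapper: auto-scale ``ds``'s training split, then select."""
    from .dataio import fit_scaler

    scaler = scaler or fit_scaler(ds)
    Xs = scaler.transform(ds.X_train)
    return select_bandwidth(method, Xs, ds.y_train, degree, kernel, **kwargs)
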