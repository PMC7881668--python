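"""Kernel-weighted local polynomial regression (the KwLPR estimator).

At each query point x0 a degree-p polynomial is fitted by weighted least
squares, with kernel weights that shrink with the scaled distance from x0:

    min_beta  sum_i ( y_i - sum_j beta_j (x_i - x0)^j )^2 * K((x_i - x0)/h)

The prediction is the local intercept beta_0.  Degree p=0 is the
local-constant (Nadaraya-Watson) estimator "lc" — a kernel-weighted average;
p=1 is the local-linear estimator "ll" with additive first-order terms (no
cross terms) in the multivariate case.  Both are linear smoothers: the fitted
value at any query is a fixed linear combination l(x0)^T y of the training
responses, which this module exposes as the smoother matrix (used for exact
leave-one-out shortcuts and the AICc bandwidth objective).

All localization happens on auto-scaled descriptors; bandwidths are
interpreted on the scaled scale.  The closed form (X^T W X)^{-1} X^T W y is
the contract, not the algorithm: solves go through LAPACK with a small ridge
fallback for ill-conditioned neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import Dataset, ScalingModel, fit_scaler
from .exceptions import EmptyNeighborhoodError, KwlprError, NumericalError
from .kernels import product_weights, validate_bandwidths, weight_matrix

ESTIMATOR_DEGREE = {"lc": 0, "ll": 1}
DEGREE_ESTIMATOR = {0: "lc", 1: "ll"}


@dataclass(frozen=True)
class LocalFit:
    """One weighted local solve: coefficients, total weight, prediction."""

    beta: np.ndarray
    effective_weight_sum: float
    prediction: float


@dataclass(frozen=True)
class KwlprModel:
    """A frozen KwLPR model: scaled training data plus smoothing choices.

    ``X`` must already be on the auto-scaled scale; ``scaler`` (optional) maps
    raw descriptors onto it, enabling :meth:`predict` on raw inputs.
    """

    X: np.ndarray
    y: np.ndarray
    degree: int
    kernel: str
    bandwidths: np.ndarray
    scaler: ScalingModel | None = None
    ridge_fallback: float = 1e-8
    response_name: str = field(default="response", compare=False)

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float)
        if self.degree not in (0, 1):
            raise KwlprError("only degrees 0 (lc) and 1 (ll) are supported")
        if X.shape[0] != y.shape[0]:
            raise KwlprError("X and y disagree in length")
        h = validate_bandwidths(self.bandwidths, X.shape[1])
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "bandwidths", h)

    # ------------------------------------------------------------------
    @classmethod
    def fit(cls, ds: Dataset, degree: int, kernel: str, bandwidths,
            ridge_fallback: float = 1e-8) -> "KwlprModel":
        """Auto-scale the training split of ``ds`` and freeze the model."""
        scaler = fit_scaler(ds)
        return cls(
            X=scaler.transform(ds.X_train),
            y=ds.y_train,
            degree=degree,
            kernel=kernel,
            bandwidths=bandwidths,
            scaler=scaler,
            ridge_fallback=ridge_fallback,
            response_name=ds.response_name,
        )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def estimator(self) -> str:
        return DEGREE_ESTIMATOR[self.degree]

    def with_bandwidths(self, h) -> "KwlprModel":
        return replace(self, bandwidths=np.asarray(h, dtype=float))

    # ------------------------------------------------------------------
    def fit_at(self, x0) -> LocalFit:
        """Weighted local polynomial solve at one scaled query point."""
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        w = product_weights(self.kernel, self.bandwidths, self.X, x0)
        s = float(w.sum())
        if s <= 0.0:
            raise EmptyNeighborhoodError(
                f"no training point receives positive weight at query {x0}; "
                "increase the bandwidth or use the gaussian kernel",
                query_ids=[tuple(x0)],
            )
        T = local_design(self.X, x0, self.degree)
        A = T.T @ (w[:, None] * T)
        b = T.T @ (w * self.y)
        beta = _solve_with_ridge(A, b, self.ridge_fallback)
        return LocalFit(beta=beta, effective_weight_sum=s, prediction=float(beta[0]))

    def predict(self, Xnew) -> np.ndarray:
        """Predict responses for raw (unscaled) descriptor rows."""
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        if Xnew.shape[1] != self.d:
            raise KwlprError(
                f"query matrix has {Xnew.shape[1]} columns, model expects {self.d}"
            )
        Xs = self.scaler.transform(Xnew) if self.scaler is not None else Xnew
        return self.predict_scaled(Xs)

    def predict_scaled(self, Xq) -> np.ndarray:
        """Predict responses for already-scaled query rows."""
        L, empty = smoother_matrix(self, Xq, on_empty="flag")
        if empty.any():
            raise EmptyNeighborhoodError(
                f"empty kernel neighborhood at query row(s) "
                f"{np.flatnonzero(empty).tolist()}; increase the bandwidth or "
                "use the gaussian kernel",
                query_ids=np.flatnonzero(empty).tolist(),
            )
        return L @ self.y

    def fitted(self) -> np.ndarray:
        """In-sample (calibration) predictions at the training points."""
        return self.predict_scaled(self.X)


def local_design(X, x0, degree: int) -> np.ndarray:
    """Local design matrix centered at the query point.

    degree 0: a single all-ones column; degree 1: [1, x_i1-x0_1, ..., x_id-x0_d].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if degree not in (0, 1):
        raise KwlprError("only degrees 0 and 1 are supported")
    ones = np.ones((X.shape[0], 1))
    if degree == 0:
        return ones
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    return np.hstack([ones, X - x0])


def _solve_with_ridge(A, b, ridge_fallback: float) -> np.ndarray:
    """Solve A beta = b, retrying with a trace-scaled ridge if singular."""
    try:
        beta = np.linalg.solve(A, b)
        if np.isfinite(beta).all():
            return beta
    except np.linalg.LinAlgError:
        pass
    m = A.shape[0]
    lam = ridge_fallback * max(np.trace(A) / m, 1.0)
    try:
        beta = np.linalg.solve(A + lam * np.eye(m), b)
    except np.linalg.LinAlgError as err:
        raise NumericalError("local solve singular even after ridge fallback") from err
    if not np.isfinite(beta).all():
        raise NumericalError("local solve produced non-finite coefficients")
    return beta


def smoother_matrix(model: KwlprModel, Xq, on_empty: str = "raise"):
    """Linear-smoother matrix L with prediction(q) = L[q] @ y.

    Returns ``(L, empty)`` where ``empty`` flags query rows whose kernel
    neighborhood carries zero total weight (their L rows are NaN).
    ``on_empty``: "raise" or "flag".
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    W = weight_matrix(model.kernel, model.bandwidths, model.X, Xq)
    rowsum = W.sum(axis=1)
    empty = rowsum <= 0.0
    if empty.any() and on_empty == "raise":
        raise EmptyNeighborhoodError(
            f"empty kernel neighborhood at query row(s) {np.flatnonzero(empty).tolist()}",
            query_ids=np.flatnonzero(empty).tolist(),
        )
    nq, n = W.shape
    if model.degree == 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            L = W / rowsum[:, None]
        L[empty] = np.nan
        return L, empty

    # local-linear: l(q) = e1^T (T^T W T)^{-1} T^T W per query, batched
    D = Xq[:, None, :] - model.X[None, :, :]                 # (nq, n, d)
    T = np.concatenate([np.ones((nq, n, 1)), D], axis=2)     # (nq, n, d+1)
    WT = W[:, :, None] * T
    A = np.einsum("qnm,qnl->qml", T, WT)                     # (nq, m, m)
    m = model.d + 1
    e1 = np.zeros(m)
    e1[0] = 1.0
    ok = ~empty
    z = np.full((nq, m), np.nan)
    if ok.any():
        z[ok] = _batched_solve(A[ok], e1, model.ridge_fallback)
    L = np.einsum("qm,qnm->qn", z, WT)
    L[empty] = np.nan
    return L, empty


def _batched_solve(A, e1, ridge_fallback: float) -> np.ndarray:
    """Solve A_q z_q = e1 for a stack of small symmetric systems."""
    m = A.shape[-1]
    rhs = np.broadcast_to(e1, A.shape[:-2] + (m,))[..., None]
    try:
        z = np.linalg.solve(A, rhs)[..., 0]
        if np.isfinite(z).all():
            return z
    except np.linalg.LinAlgError:
        pass
    # per-query fallback with ridge for the offending systems only
    z = np.empty(A.shape[:-2] + (m,))
    for q in range(A.shape[0]):
        z[q] = _solve_with_ridge(A[q], e1, ridge_fallback)
    return z


def hat_diagonal(model: KwlprModel) -> np.ndarray:
    """Diagonal of the smoother (hat) matrix at the training points.

    Entry i is the weight observation i gives its own fitted value; NaN where
    the neighborhood is empty (cannot happen for kernels positive at 0 —
    every supported kernel — since a point always neighbors itself).
    """
    L, _ = smoother_matrix(model, model.X, on_empty="flag")
    return np.diagonal(L)


def loo_predictions(model: KwlprModel, method: str = "shortcut"):
    """Leave-one-out predictions over the training set, bandwidths held fixed.

    ``method="shortcut"`` uses the exact rank-one downdate identity for linear
    smoothers fitted by weighted least squares,

        yhat_{-i} = (yhat_i - L_ii y_i) / (1 - L_ii),

    which agrees with literally refitting without row i (``method="refit"``)
    up to floating point.  Rows where 1 - L_ii is too small for the division
    to be accurate (the left-out point dominates its own fit) fall back to a
    literal refit automatically.  Returns ``(loo, empty)`` where ``empty``
    flags rows whose leave-one-out neighborhood carries no weight at all.
    """
    n = model.n
    if method == "refit":
        loo = np.full(n, np.nan)
        empty = np.zeros(n, dtype=bool)
        keep = np.ones(n, dtype=bool)
        for i in range(n):
            keep[i] = False
            sub = replace(model, X=model.X[keep], y=model.y[keep], scaler=None)
            try:
                loo[i] = sub.predict_scaled(model.X[i][None, :])[0]
            except (EmptyNeighborhoodError, NumericalError):
                empty[i] = True
            keep[i] = True
        return loo, empty
    if method != "shortcut":
        raise KwlprError(f"unknown LOO method {method!r}")

    L, row_empty = smoother_matrix(model, model.X, on_empty="flag")
    diag = np.diagonal(L)
    denom = 1.0 - diag
    fitted = L @ model.y
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (fitted - diag * model.y) / denom
    # near-cancellation (the point dominates its own fit): literal refit
    fallback = row_empty | ~np.isfinite(denom) | (denom <= 1e-4)
    empty = np.zeros(n, dtype=bool)
    if fallback.any():
        keep = np.ones(n, dtype=bool)
        for i in np.flatnonzero(fallback):
            keep[i] = False
            sub = replace(model, X=model.X[keep], y=model.y[keep], scaler=None)
            try:
                loo[i] = sub.predict_scaled(model.X[i][None, :])[0]
            except (EmptyNeighborhoodError, NumericalError):
                loo[i] = np.nan
                empty[i] = True
            keep[i] = True
    return loo, empty
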