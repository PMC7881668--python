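"""Validation workflows: the full metric panel and the Y-scrambling test.

``validate`` assembles calibration, leave-one-out and external-validation
statistics into one :class:`~kwlpr.metrics.ValidationReport`.

``y_scramble`` is the chance-correlation check: training responses are
randomly permuted (descriptors untouched), the model is refitted with the
same degree/kernel/bandwidths, and the permuted R^2 / Q^2_LOO distribution is
compared against the true values.  A genuine structure-activity relationship
collapses under scrambling; a chance correlation does not.  Because lc/ll are
linear smoothers whose weights do not involve y, the smoother matrix is
computed once and reused across permutations — algebraically identical to
refitting per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import Dataset
from .exceptions import KwlprError
from .local_poly import KwlprModel, loo_predictions, smoother_matrix
from .metrics import ValidationReport, ccc, mae, q2_external, q2_loo, r2_rmse, rmse


def validate(model: KwlprModel, ds: Dataset, on_empty: str = "raise") -> ValidationReport:
    """Compute the full validation panel for ``model`` fitted on ``ds``.

    With an empty validation split the external metrics are reported as
    absent (None), never as zero.
    """
    if model.n != ds.n_train:
        raise KwlprError(
            f"model was fitted on {model.n} rows but the dataset has "
            f"{ds.n_train} training rows"
        )
    fitted = model.predict(ds.X_train)
    r2, rmse_c = r2_rmse(ds.y_train, fitted)
    q2, rmse_cv = q2_loo(model, on_empty=on_empty)
    _, loo_empty = loo_predictions(model)

    external = {}
    if ds.n_valid >= 2:
        yhat_v = model.predict(ds.X_valid)
        q2f1, q2f2, q2f3 = q2_external(ds.y_valid, yhat_v, ds.y_train)
        external = dict(
            q2_f1=q2f1, q2_f2=q2f2, q2_f3=q2f3,
            ccc=ccc(ds.y_valid, yhat_v),
            rmse_p=rmse(ds.y_valid, yhat_v),
            mae=mae(ds.y_valid, yhat_v),
        )
    return ValidationReport(
        r2=r2, rmse_c=rmse_c, q2_loo=q2, rmse_cv=rmse_cv,
        n_train=ds.n_train, n_valid=ds.n_valid,
        loo_excluded=int(loo_empty.sum()), **external,
    )


@dataclass(frozen=True)
class ScrambleResult:
    """Outcome of a Y-scrambling run."""

    n_permutations: int
    permuted_r2: np.ndarray
    permuted_q2: np.ndarray
    true_r2: float
    true_q2: float
    seed: int
    n_failed: int = 0

    @property
    def p_value_r2(self) -> float:
        """Fraction of permutations whose R^2 reaches the true model's."""
        ok = np.isfinite(self.permuted_r2)
        return float(np.mean(self.permuted_r2[ok] >= self.true_r2))


def y_scramble(model: KwlprModel, n_permutations: int = 500, seed: int = 1,
               identity_first: bool = False) -> ScrambleResult:
    """Y-scrambling (Y-randomization) with bandwidths held fixed.

    Each permutation k draws its own generator ``default_rng([seed, k])`` (a
    counter scheme: results do not depend on execution order).  With
    ``identity_first`` permutation 0 is the identity, so its R^2 equals the
    true model's exactly.  Per-permutation numerical failures are recorded
    as NaN and counted, never silently dropped.
    """
    if n_permutations < 1:
        raise KwlprError("n_permutations must be >= 1")
    n = model.n
    # weights depend only on X and h: one smoother/LOO pass serves every y
    L, row_empty = smoother_matrix(model, model.X, on_empty="flag")
    diag = np.diagonal(L)
    denom = 1.0 - diag
    loo_bad = row_empty | (denom <= np.finfo(float).eps)

    def panel(y):
        fitted = L @ y
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss <= 0.0 or row_empty.any():
            return np.nan, np.nan
        r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / tss
        if loo_bad.any():
            return r2, np.nan
        loo = (fitted - diag * y) / denom
        q2 = 1.0 - float(np.sum((y - loo) ** 2)) / tss
        return r2, q2

    true_r2, true_q2 = panel(model.y)
    perm_r2 = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    n_failed = 0
    for k in range(n_permutations):
        if identity_first and k == 0:
            perm = np.arange(n)
        else:
            perm = np.random.default_rng([seed, k]).permutation(n)
        r2_k, q2_k = panel(model.y[perm])
        if not np.isfinite(r2_k):
            n_failed += 1
        perm_r2[k] = r2_k
        perm_q2[k] = q2_k
    return ScrambleResult(
        n_permutations=n_permutations,
        permuted_r2=perm_r2, permuted_q2=perm_q2,
        true_r2=true_r2, true_q2=true_q2,
        seed=seed, n_failed=n_failed,
    )
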