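"""Model-quality statistics for QSAR/QSAAR validation.

The panel reported for every fitted model:

* calibration: R^2 = 1 - RSS/TSS and RMSE_C on the training set;
* internal: Q^2_LOO = 1 - PRESS/TSS and RMSE_CV from leave-one-out
  cross-validation with bandwidths held fixed at their selected values;
* external: Q^2_F1 (reference variance about the training mean), Q^2_F2
  (about the validation mean), Q^2_F3 (per-observation training variance),
  Lin's concordance correlation coefficient CCC, RMSE_P and MAE on the
  validation set.

RMSE uses the 1/n denominator throughout; CCC uses population (1/n)
moments, Lin's original form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyNeighborhoodError, UndefinedMetricError
from .local_poly import KwlprModel, loo_predictions


def _pair(observed, predicted, min_len=2):
    y = np.asarray(observed, dtype=float).reshape(-1)
    yhat = np.asarray(predicted, dtype=float).reshape(-1)
    if y.size != yhat.size:
        raise UndefinedMetricError("observed and predicted disagree in length")
    if y.size < min_len:
        raise UndefinedMetricError(f"need at least {min_len} pairs")
    return y, yhat


def rmse(observed, predicted) -> float:
    y, yhat = _pair(observed, predicted, min_len=1)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(observed, predicted) -> float:
    y, yhat = _pair(observed, predicted, min_len=1)
    return float(np.mean(np.abs(y - yhat)))


def r2_rmse(observed, predicted) -> tuple[float, float]:
    """Determination coefficient and root-mean-square error."""
    y, yhat = _pair(observed, predicted)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0.0:
        raise UndefinedMetricError("observed values have zero variance; R^2 undefined")
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss, float(np.sqrt(rss / y.size))


def q2_external(y_valid, yhat_valid, y_train) -> tuple[float, float, float]:
    """External predictivity coefficients (Q^2_F1, Q^2_F2, Q^2_F3).

    They differ only in the reference variance: training mean, validation
    mean, or the training variance per observation.
    """
    yv, yhat = _pair(y_valid, yhat_valid)
    yt = np.asarray(y_train, dtype=float).reshape(-1)
    if yt.size < 2:
        raise UndefinedMetricError("need at least 2 training responses")
    press = float(np.sum((yv - yhat) ** 2))
    ref1 = float(np.sum((yv - yt.mean()) ** 2))
    ref2 = float(np.sum((yv - yv.mean()) ** 2))
    ref3 = float(np.sum((yt - yt.mean()) ** 2))
    if min(ref1, ref2, ref3) <= 0.0:
        raise UndefinedMetricError("degenerate reference variance in Q^2 computation")
    q2f1 = 1.0 - press / ref1
    q2f2 = 1.0 - press / ref2
    q2f3 = 1.0 - (press / yv.size) / (ref3 / yt.size)
    return q2f1, q2f2, q2f3


def ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    y, yhat = _pair(observed, predicted)
    n = y.size
    my, mp = y.mean(), yhat.mean()
    sy2 = float(np.mean((y - my) ** 2))
    sp2 = float(np.mean((yhat - mp) ** 2))
    sxy = float(np.mean((y - my) * (yhat - mp)))
    denom = sy2 + sp2 + (my - mp) ** 2
    if denom <= 0.0:
        raise UndefinedMetricError("both sequences constant and equal; CCC undefined")
    return float(2.0 * sxy / denom)


def q2_loo(model: KwlprModel, on_empty: str = "raise") -> tuple[float, float]:
    """Leave-one-out Q^2 and RMSE_CV over the model's training set.

    Bandwidths are held fixed at their selected values (LOO re-selection
    would conflate bandwidth stability with predictive ability).  Rows whose
    leave-one-out neighborhood is empty raise by default; with
    ``on_empty="exclude"`` they are dropped and counted.
    """
    loo, empty = loo_predictions(model)
    if empty.any():
        if on_empty == "raise":
            raise EmptyNeighborhoodError(
                f"empty leave-one-out neighborhood for training row(s) "
                f"{np.flatnonzero(empty).tolist()}",
                query_ids=np.flatnonzero(empty).tolist(),
            )
        if on_empty != "exclude":
            raise ValueError("on_empty must be 'raise' or 'exclude'")
    keep = ~empty
    y = model.y[keep]
    press = float(np.sum((y - loo[keep]) ** 2))
    tss = float(np.sum((model.y - model.y.mean()) ** 2))
    if tss <= 0.0:
        raise UndefinedMetricError("training responses have zero variance")
    return 1.0 - press / tss, float(np.sqrt(press / max(keep.sum(), 1)))


@dataclass(frozen=True)
class ValidationReport:
    """The nine-metric panel for one fitted model.

    External fields are None when the dataset has no validation split.
    """

    r2: float
    rmse_c: float
    q2_loo: float
    rmse_cv: float
    n_train: int
    q2_f1: float | None = None
    q2_f2: float | None = None
    q2_f3: float | None = None
    ccc: float | None = None
    rmse_p: float | None = None
    mae: float | None = None
    n_valid: int = 0
    loo_excluded: int = field(default=0, compare=False)

    _DISPLAY = ("r2", "rmse_c", "q2_loo", "rmse_cv", "q2_f1", "q2_f2",
                "q2_f3", "ccc", "rmse_p", "mae")

    def to_dict(self, ndigits: int | None = None) -> dict:
        """Flat dict of the panel; ``ndigits=2`` matches report display."""
        out = {}
        for name in self._DISPLAY:
            val = getattr(self, name)
            if val is not None and ndigits is not None:
                val = round(val, ndigits)
            out[name] = val
        out["n_train"] = self.n_train
        out["n_valid"] = self.n_valid
        return out
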