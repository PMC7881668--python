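"""Applicability-domain analysis: leverages and the Williams plot table.

Classical Williams-plot practice: leverages come from the global auto-scaled
training design with intercept, U = [1 | Z_train],

    h_i = u_i^T (U^T U)^{-1} u_i,        h* = 3 (d + 1) / n_train,

validation rows are scored against the training normal matrix (no
refitting), and standardized residuals are (y - yhat)/RMSE_C with the
training RMSE as the scale for both splits.  A compound is an X-outlier when
h_i > h* (strict) and a Y-outlier when |standardized residual| > 3 (strict).
The KwLPR model itself is nonparametric, but the AD convention is
model-agnostic by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Dataset, ScalingModel, fit_scaler
from .exceptions import RankDeficiencyError, UndefinedMetricError
from .local_poly import KwlprModel
from .metrics import rmse

#: standardized-residual band for Y-outlier flagging
RESIDUAL_BAND = 3.0


@dataclass(frozen=True)
class ADReport:
    """Per-compound applicability-domain table plus the critical leverage."""

    table: pd.DataFrame
    critical_leverage: float
    residual_band: float = RESIDUAL_BAND

    @property
    def n_x_outliers(self) -> int:
        return int(self.table["x_outlier"].sum())

    @property
    def n_y_outliers(self) -> int:
        return int(self.table["y_outlier"].sum())


def critical_leverage(d: int, n_train: int) -> float:
    """Warning leverage h* = 3 (d + 1) / n_train."""
    return 3.0 * (d + 1) / n_train


def leverages(ds: Dataset, scaler: ScalingModel | None = None):
    """Leverage of every row against the training design; returns (h, h*).

    Training leverages sum to d + 1 (hat-matrix trace).  Raises
    :class:`RankDeficiencyError` naming collinear columns when the training
    design is rank deficient.
    """
    scaler = scaler or fit_scaler(ds)
    Z = scaler.transform(ds.X)
    U = np.hstack([np.ones((ds.n, 1)), Z])
    Ut = U[ds.train_mask]
    G = Ut.T @ Ut
    rank = np.linalg.matrix_rank(Ut)
    if rank < U.shape[1]:
        corr = np.corrcoef(Z[ds.train_mask], rowvar=False)
        names = ds.descriptor_names
        suspects = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names)) for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise RankDeficiencyError(
            f"training design matrix is rank deficient (rank {rank} < "
            f"{U.shape[1]}); collinear column pair(s): {suspects or 'unidentified'}"
        )
    h = np.einsum("ij,ij->i", U @ np.linalg.inv(G), U)
    return h, critical_leverage(ds.d, ds.n_train)


def williams_table(model: KwlprModel, ds: Dataset) -> ADReport:
    """Assemble the Williams-plot table for every compound in ``ds``.

    Flags use strict inequalities: a residual of exactly 3*RMSE_C or a
    leverage of exactly h* is not flagged.
    """
    h, hstar = leverages(ds, scaler=model.scaler)
    predicted = model.predict(ds.X)
    residual = ds.response - predicted
    rmse_c = rmse(ds.y_train, predicted[ds.train_mask])
    if rmse_c <= 0.0:
        raise UndefinedMetricError(
            "training RMSE is zero; standardized residuals undefined"
        )
    std_resid = residual / rmse_c
    table = pd.DataFrame(
        {
            "compound_id": ds.compound_id,
            "split": ds.split,
            "observed": ds.response,
            "predicted": predicted,
            "leverage": h,
            "standardized_residual": std_resid,
            "x_outlier": h > hstar,
            "y_outlier": np.abs(std_resid) > RESIDUAL_BAND,
        }
    )
    return ADReport(table=table, critical_leverage=hstar)
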