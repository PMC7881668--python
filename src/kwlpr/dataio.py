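"""Reading, writing and auto-scaling the CSV input matrix.

A modeling task is described by one comma-separated table (UTF-8, header row,
"." decimal mark) holding a compound identifier, a train/validation split
flag, one response column and one or more numeric descriptor columns.  Column
roles are assigned by name through a :class:`Schema`, never by position.
Auto-scaling (column-wise standardization to zero mean / unit variance) is
always fitted on the training rows only and then applied to every row, so
validation compounds never leak into the scaling parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DataValidationError,
    ParseError,
    SchemaError,
    ZeroVarianceError,
)

TRAIN_LABELS = frozenset({"train", "training", "t"})
VALID_LABELS = frozenset({"valid", "validation", "test", "v"})

#: canonical internal split labels
TRAIN, VALIDATION = "train", "validation"


@dataclass(frozen=True)
class Schema:
    """Column-role mapping for the input CSV."""

    id_col: str = "compound_id"
    split_col: str = "split"
    response_col: str = "response"
    #: explicit descriptor column names; None means "every remaining column"
    descriptor_cols: tuple[str, ...] | None = None


@dataclass
class Dataset:
    """A validated modeling table.

    Attributes
    ----------
    compound_id : array of str, one label per row (row order preserved).
    split : array of {"train", "validation"} per row.
    response : float array, the modeled endpoint (e.g. pLC50).
    descriptors : DataFrame of float descriptor columns, n rows x d columns.
    response_name : name of the response column for round-tripping.
    """

    compound_id: np.ndarray
    split: np.ndarray
    response: np.ndarray
    descriptors: pd.DataFrame
    response_name: str = "response"
    id_name: str = "compound_id"
    split_name: str = "split"

    def __post_init__(self):
        self.compound_id = np.asarray(self.compound_id, dtype=object)
        self.split = np.asarray(self.split, dtype=object)
        self.response = np.asarray(self.response, dtype=float)
        n = len(self.compound_id)
        if not (len(self.split) == len(self.response) == len(self.descriptors) == n):
            raise DataValidationError("id, split, response and descriptors disagree in length")
        bad = set(self.split) - {TRAIN, VALIDATION}
        if bad:
            raise DataValidationError(f"unnormalized split labels: {sorted(bad)}")
        if not np.isfinite(self.response).all():
            raise DataValidationError("missing/non-finite values in response")
        if not np.isfinite(self.descriptors.to_numpy(dtype=float)).all():
            raise DataValidationError("missing/non-finite values in descriptors")
        if self.d < 1:
            raise DataValidationError("at least one descriptor column is required")
        if self.n_train == 0:
            raise DataValidationError("training split is empty")
        if self.n_train < self.d + 2:
            raise DataValidationError(
                f"need at least d+2={self.d + 2} training rows, got {self.n_train}"
            )
        if self.n_valid == 0:
            warnings.warn(
                "dataset has no validation rows; external validation unavailable",
                stacklevel=3,
            )

    # -- convenience views -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.response)

    @property
    def d(self) -> int:
        return self.descriptors.shape[1]

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.descriptors.columns)

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == TRAIN

    @property
    def valid_mask(self) -> np.ndarray:
        return self.split == VALIDATION

    @property
    def n_train(self) -> int:
        return int(self.train_mask.sum())

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def X(self) -> np.ndarray:
        return self.descriptors.to_numpy(dtype=float)

    @property
    def X_train(self) -> np.ndarray:
        return self.X[self.train_mask]

    @property
    def X_valid(self) -> np.ndarray:
        return self.X[self.valid_mask]

    @property
    def y_train(self) -> np.ndarray:
        return self.response[self.train_mask]

    @property
    def y_valid(self) -> np.ndarray:
        return self.response[self.valid_mask]


def normalize_split_label(raw) -> str:
    """Map a raw split flag to the canonical {train, validation} labels."""
    label = str(raw).strip().lower()
    if label in TRAIN_LABELS:
        return TRAIN
    if label in VALID_LABELS:
        return VALIDATION
    raise DataValidationError(
        f"unrecognized split label {raw!r}; use one of "
        f"{sorted(TRAIN_LABELS)} / {sorted(VALID_LABELS)}"
    )


def read_dataset(path, schema: Schema = Schema()) -> Dataset:
    """Read and validate a modeling CSV.

    Raises :class:`SchemaError` for missing columns, :class:`ParseError`
    (naming row and column) for non-numeric cells, and
    :class:`DataValidationError` for split/missing-value violations.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    for role, col in (
        ("id", schema.id_col),
        ("split", schema.split_col),
        ("response", schema.response_col),
    ):
        if col not in frame.columns:
            raise SchemaError(f"{role} column {col!r} not found in {path}")
    if schema.descriptor_cols is None:
        reserved = {schema.id_col, schema.split_col, schema.response_col}
        descriptor_cols = [c for c in frame.columns if c not in reserved]
    else:
        descriptor_cols = list(schema.descriptor_cols)
        missing = [c for c in descriptor_cols if c not in frame.columns]
        if missing:
            raise SchemaError(f"descriptor column(s) {missing} not found in {path}")
    if not descriptor_cols:
        raise SchemaError("no descriptor columns left after applying the schema")

    numeric = {}
    for col in [schema.response_col, *descriptor_cols]:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric value {frame[col].iloc[row]!r} in column {col!r}, "
                f"row {row + 2} of {path} (1-based, counting the header)"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise DataValidationError(
                f"missing value in column {col!r}, row {row + 2} of {path}; "
                "rows with missing values are rejected, not imputed"
            )
        numeric[col] = converted.to_numpy(dtype=float)

    split = np.array([normalize_split_label(v) for v in frame[schema.split_col]], dtype=object)
    return Dataset(
        compound_id=frame[schema.id_col].to_numpy(dtype=object),
        split=split,
        response=numeric[schema.response_col],
        descriptors=pd.DataFrame({c: numeric[c] for c in descriptor_cols}),
        response_name=schema.response_col,
        id_name=schema.id_col,
        split_name=schema.split_col,
    )


def write_dataset(ds: Dataset, path) -> None:
    """Write a Dataset back to CSV (inverse of :func:`read_dataset`)."""
    out = pd.DataFrame({ds.id_name: ds.compound_id, ds.split_name: ds.split})
    out[ds.response_name] = ds.response
    for col in ds.descriptor_names:
        out[col] = ds.descriptors[col].to_numpy()
    out.to_csv(path, index=False)


def dataset_from_arrays(
    ids, split, response, X, descriptor_names, response_name="response"
) -> Dataset:
    """Assemble a Dataset from in-memory arrays (used by the fixture module)."""
    return Dataset(
        compound_id=np.asarray(ids, dtype=object),
        split=np.asarray([normalize_split_label(s) for s in split], dtype=object),
        response=np.asarray(response, dtype=float),
        descriptors=pd.DataFrame(np.asarray(X, dtype=float), columns=list(descriptor_names)),
        response_name=response_name,
    )


# ---------------------------------------------------------------------------
# auto-scaling


@dataclass(frozen=True)
class ScalingModel:
    """Per-descriptor standardization parameters, fitted on training rows only.

    Uses the sample (n-1 denominator) standard deviation.
    """

    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...] = field(default=())

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) / self.sd

    def inverse(self, Xs) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.sd + self.mean


def fit_scaler(ds: Dataset) -> ScalingModel:
    """Fit auto-scaling parameters on the training rows of ``ds``.

    Raises :class:`ZeroVarianceError` naming any constant training column.
    """
    Xt = ds.X_train
    if Xt.shape[0] < 2:
        raise DataValidationError("need at least 2 training rows to fit a scaler")
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        names = [ds.descriptor_names[j] for j in zero]
        raise ZeroVarianceError(f"zero-variance training column(s): {names}")
    return ScalingModel(mean=mean, sd=sd, columns=tuple(ds.descriptor_names))


def write_predictions_table(path, ds: Dataset, predicted, leverage=None,
                            standardized_residual=None) -> pd.DataFrame:
    """Write the per-compound predictions CSV and return it as a DataFrame.

    Columns: compound_id, split, observed, predicted, residual, and, when
    available, leverage and standardized_residual.
    """
    predicted = np.asarray(predicted, dtype=float)
    table = pd.DataFrame(
        {
            "compound_id": ds.compound_id,
            "split": ds.split,
            "observed": ds.response,
            "predicted": predicted,
            "residual": ds.response - predicted,
        }
    )
    if leverage is not None:
        table["leverage"] = np.asarray(leverage, dtype=float)
    if standardized_residual is not None:
        table["standardized_residual"] = np.asarray(standardized_residual, dtype=float)
    if path is not None:
        table.to_csv(path, index=False)
    return table
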