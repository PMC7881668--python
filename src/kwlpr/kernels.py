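"""Scalar kernels and the multivariate product-kernel weight.

The localization weight of training point x_i relative to a query x0 is the
product of scalar kernel evaluations over descriptors,

    w_i = prod_j K((x_ij - x0_j) / h_j),

with one bandwidth h_j per descriptor on the auto-scaled variable scale.
Normalization constants are kept (they cancel inside the estimator but make
printed weights comparable across implementations).
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import KwlprError

_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)

#: kernels every front-end must offer
MANDATORY_KERNELS = ("gaussian", "epanechnikov", "uniform")


def _gaussian(u):
    return _INV_SQRT_2PI * np.exp(-0.5 * u * u)


def _epanechnikov(u):
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)


def _uniform(u):
    return np.where(np.abs(u) <= 1.0, 0.5, 0.0)


_KERNELS = {
    "gaussian": _gaussian,
    "epanechnikov": _epanechnikov,
    "uniform": _uniform,
    # optional extras behind the same interface
    "triangular": lambda u: np.where(np.abs(u) <= 1.0, 1.0 - np.abs(u), 0.0),
    "biweight": lambda u: np.where(np.abs(u) <= 1.0, 0.9375 * (1.0 - u * u) ** 2, 0.0),
}

#: (roughness R(K) = int K^2, second moment mu2(K) = int u^2 K) per kernel;
#: used by the direct plug-in bandwidth formula.
KERNEL_CONSTANTS = {
    "gaussian": (_INV_SQRT_2PI / 2.0, 1.0),          # 1/(2*sqrt(pi)), 1
    "epanechnikov": (0.6, 0.2),
    "uniform": (0.5, 1.0 / 3.0),
    "triangular": (2.0 / 3.0, 1.0 / 6.0),
    "biweight": (5.0 / 7.0, 1.0 / 7.0),
}


def available_kernels() -> tuple[str, ...]:
    return tuple(_KERNELS)


def _resolve(name: str):
    try:
        return _KERNELS[name]
    except KeyError:
        raise KwlprError(
            f"unknown kernel {name!r}; choose from {sorted(_KERNELS)}"
        ) from None


def kernel_value(name: str, u):
    """Evaluate the scalar kernel K(u); vectorized over ``u``."""
    return _resolve(name)(np.asarray(u, dtype=float))


def validate_bandwidths(h, d: int) -> np.ndarray:
    h = np.atleast_1d(np.asarray(h, dtype=float))
    if h.shape != (d,):
        raise KwlprError(f"bandwidth vector has shape {h.shape}, expected ({d},)")
    if not (np.isfinite(h).all() and (h > 0).all()):
        raise KwlprError("bandwidths must be strictly positive and finite")
    return h


def product_weights(name: str, h, X, x0) -> np.ndarray:
    """Product-kernel weights of each training row relative to one query point.

    Parameters are on the auto-scaled variable scale: ``X`` is n x d, ``x0``
    a length-d query, ``h`` a length-d bandwidth vector.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    d = X.shape[1]
    if x0.shape != (d,):
        raise KwlprError(f"query point has shape {x0.shape}, expected ({d},)")
    h = validate_bandwidths(h, d)
    K = _resolve(name)
    return np.prod(K((X - x0) / h), axis=1)


def weight_matrix(name: str, h, X, Xq) -> np.ndarray:
    """Stacked product weights: entry (q, i) weights training row i at query q."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if X.shape[1] != Xq.shape[1]:
        raise KwlprError("query and training descriptor dimensions differ")
    h = validate_bandwidths(h, X.shape[1])
    K = _resolve(name)
    U = (Xq[:, None, :] - X[None, :, :]) / h
    return np.prod(K(U), axis=2)
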