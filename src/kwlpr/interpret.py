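"""Post-hoc interpretability: correlation PCA, biplot tables, pairwise r.

A kernel-weighted local model has no single global equation, so variable
influence is read off a principal component analysis of the auto-scaled
modeling variables (descriptors, and by default the modeled response too).
Loadings are reported on the correlation scale — eigenvector times the
square root of its eigenvalue — so each entry is the Pearson correlation
between the original (scaled) variable and the component scores, and biplot
geometry carries its usual reading: adjacent loading vectors mean positive
correlation, opposite vectors negative, right angles none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Dataset
from .exceptions import KwlprError, UndefinedMetricError, ZeroVarianceError


@dataclass(frozen=True)
class PcaSummary:
    """Correlation-PCA output: scores, correlation-scaled loadings, ratios."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    variables: tuple[str, ...]


def pca_biplot_table(ds: Dataset, include_response: bool = True,
                     n_components: int | None = None) -> PcaSummary:
    """Correlation PCA over the dataset's modeling variables.

    Columns are standardized over all rows, the correlation matrix is
    eigendecomposed, and component signs are fixed by making each
    component's largest-magnitude loading positive, so the output is
    deterministic and invariant to row order.
    """
    cols = list(ds.descriptor_names)
    mat = [ds.descriptors[c].to_numpy(dtype=float) for c in cols]
    if include_response:
        cols.append(ds.response_name)
        mat.append(ds.response)
    if len(cols) < 2:
        raise KwlprError("PCA needs at least 2 variables; include the response")
    Z = np.column_stack(mat)
    sd = Z.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd <= 0)
    if constant.size:
        raise ZeroVarianceError(
            f"constant column(s) in PCA input: {[cols[j] for j in constant]}"
        )
    Z = (Z - Z.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    k = n_components or len(cols)
    eigval, eigvec = eigval[:k], eigvec[:, :k]
    # deterministic sign: largest-|.| loading positive per component
    for j in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[pivot, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(eigval)
    scores = Z @ eigvec
    pcs = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    return PcaSummary(
        scores=pd.DataFrame(scores, columns=pcs),
        loadings=pd.DataFrame(loadings, index=cols, columns=pcs),
        explained_variance_ratio=eigval / len(cols),
        variables=tuple(cols),
    )


def pairwise_correlation(a, b) -> float:
    """Pearson correlation between two vectors (length >= 3)."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size != b.size or a.size < 3:
        raise UndefinedMetricError("need two equal-length vectors of length >= 3")
    if a.std() <= 0 or b.std() <= 0:
        raise UndefinedMetricError("zero-variance input; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def correlation_notes(summary: PcaSummary, components=("PC1", "PC2")) -> list[str]:
    """Textual reading of biplot geometry per variable pair.

    The angle between two loading vectors in the chosen component plane is
    classified the usual way: adjacent (< 30 deg) high positive correlation,
    acute moderate positive, near-right none, obtuse moderate negative,
    straight (> 150 deg) high negative.
    """
    L = summary.loadings.loc[:, list(components)].to_numpy()
    names = list(summary.loadings.index)
    notes = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u, v = L[i], L[j]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu <= 0 or nv <= 0:
                continue
            angle = float(np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1, 1))))
            if angle < 30:
                verdict = "high positive correlation"
            elif angle < 75:
                verdict = "moderate positive correlation"
            elif angle <= 105:
                verdict = "little or no correlation"
            elif angle <= 150:
                verdict = "moderate negative correlation"
            else:
                verdict = "high negative correlation"
            notes.append(
                f"{names[i]} vs {names[j]}: angle {angle:.0f} deg in the "
                f"{'/'.join(components)} plane suggests {verdict}"
            )
    return notes
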