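"""Matrix hygiene applied before any clock analysis.

Two operations mirror the standard preprocessing of array-based DNAm
datasets: removing CpGs measured in too few samples, and k-nearest-neighbour
imputation of the remaining missing cells (neighbours are CpGs, distance is
Euclidean over pairwise-complete sample overlap).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, ValidationError

__all__ = ["filter_by_coverage", "knn_impute"]

#: Minimum number of shared observed samples for a CpG pair to be comparable.
MIN_SHARED_SAMPLES = 3


def filter_by_coverage(m: BetaMatrix, max_missing_frac: float = 0.30) -> BetaMatrix:
    """Drop CpGs whose missing fraction exceeds ``max_missing_frac``.

    The threshold is inclusive: a CpG missing in exactly
    ``max_missing_frac`` of samples is retained; strictly greater fractions
    are removed ("more than X% missing" reading). The sample set is
    unchanged. Idempotent.
    """
    if not (0.0 <= max_missing_frac < 1.0):
        raise ValidationError("max_missing_frac must lie in [0, 1)")
    frac = m.missing.mean(axis=1)
    keep = frac[frac <= max_missing_frac].index
    if len(keep) == 0:
        raise ValidationError(
            f"coverage filter at {max_missing_frac} removed every CpG"
        )
    return BetaMatrix(m.values.loc[keep].copy())


def knn_impute(
    m: BetaMatrix,
    k: int = 5,
    min_shared: int = MIN_SHARED_SAMPLES,
) -> BetaMatrix:
    """Impute missing cells from the ``k`` nearest CpGs.

    For each missing cell (CpG *i*, sample *s*) the imputed value is the
    unweighted mean, at sample *s*, of the ``k`` CpGs nearest to *i* in
    Euclidean distance. Distances are computed over the samples where both
    CpGs are observed (requiring at least ``min_shared`` shared samples) and
    normalized by the overlap size, so CpG pairs with different overlaps are
    comparable. Only CpGs observed at sample *s* are candidate donors.

    Observed cells are never altered; imputed values are clipped to [0, 1].

    Raises
    ------
    ValidationError
        If a CpG has no observed value, ``k < 1``, or fewer than ``k``
        candidate donors exist for some missing cell.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = m.to_numpy()
    obs = ~np.isnan(X)
    if (~obs).sum() == 0:
        return BetaMatrix(m.values.copy())
    if (obs.sum(axis=1) == 0).any():
        bad = m.values.index[obs.sum(axis=1) == 0][0]
        raise ValidationError(f"CpG {bad!r} has no observed value; cannot impute")

    # Pairwise mean squared difference over shared observed samples, via the
    # usual masked-expansion identity: sum_s w_i w_j (x_i - x_j)^2 =
    # (x^2 w')W^T + W(x^2 w')^T - 2 (xw)(xw)^T.
    A = np.where(obs, X, 0.0)
    W = obs.astype(float)
    B = A * A
    shared = W @ W.T
    sq = B @ W.T + W @ B.T - 2.0 * (A @ A.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared >= min_shared, sq / np.maximum(shared, 1), np.inf)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)  # guard tiny negative round-off

    out = X.copy()
    rows, cols = np.nonzero(~obs)
    for i, s in zip(rows, cols):
        candidates = np.nonzero(obs[:, s] & np.isfinite(d2[i]))[0]
        if candidates.size < k:
            raise ValidationError(
                f"k={k} exceeds the {candidates.size} candidate neighbour CpGs "
                f"for CpG {m.values.index[i]!r} at sample {m.values.columns[s]!r}"
            )
        nearest = candidates[np.argsort(d2[i, candidates], kind="stable")[:k]]
        out[i, s] = float(np.clip(X[nearest, s].mean(), 0.0, 1.0))

    return BetaMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))
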