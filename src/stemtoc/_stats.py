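"""Vectorized least-squares kernels shared by the selection and benchmark code.

These fit thousands of per-CpG regressions in one shot via the normal
equations; single-response model fits elsewhere go through statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["mass_simple_ols", "mass_multiple_ols", "aliased_columns"]

_EPS = 1e-14


def mass_simple_ols(Y: np.ndarray, x: np.ndarray):
    """OLS of each row of ``Y`` (responses, possibly NaN) on ``x``.

    Returns ``(slope, se, t, p, n_obs)`` arrays. Two-tailed p-values use the
    t distribution with ``n_obs - 2`` df. Degenerate rows (zero residual and
    zero slope, i.e. constant response) report slope 0, t 0, p 1; exact
    noiseless fits with nonzero slope report p 0.
    """
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    obs = ~np.isnan(Y)
    n = obs.sum(axis=1).astype(float)
    if (n < 3).any():
        raise ValueError("each regression needs at least 3 observed samples")
    W = obs.astype(float)
    Yz = np.where(obs, Y, 0.0)

    sx = W @ x
    sxx = W @ (x * x)
    xm = sx / n
    Sxx = sxx - n * xm**2
    if (Sxx <= _EPS).any():
        raise ValueError("zero predictor variance over the observed samples")

    sy = Yz.sum(axis=1)
    ym = sy / n
    Sxy = Yz @ x - n * xm * ym
    Syy = (Yz * Yz).sum(axis=1) - n * ym**2

    slope = Sxy / Sxx
    rss = np.maximum(Syy - slope * Sxy, 0.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 / Sxx)
        t = slope / se
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df), 0.0)

    exact = rss <= _EPS * np.maximum(Syy, 1.0)
    nonzero = np.abs(slope) > 1e-12
    # noiseless nonzero slope -> p ~ 0; constant response -> slope 0, p 1
    p = np.where(exact & nonzero, 0.0, p)
    t = np.where(exact & nonzero, np.inf, t)
    se = np.where(exact & nonzero, 0.0, se)
    constant = Syy <= _EPS
    slope = np.where(constant, 0.0, slope)
    t = np.where(constant, 0.0, t)
    se = np.where(constant, 0.0, se)
    p = np.where(constant, 1.0, p)
    return slope, se, t, np.clip(p, 0.0, 1.0), n.astype(int)


def mass_multiple_ols(Y: np.ndarray, X: np.ndarray, coef_index: int):
    """OLS of each row of ``Y`` on design ``X``; stats for one coefficient.

    ``X`` must be full rank and include any intercept column. Returns
    ``(coef, se, t, p)`` for column ``coef_index``, with ``n - p`` df.
    NaN responses are not supported here; impute first.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("responses contain missing values; impute first")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (+1); got n={n}, p={p}")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T                      # p x n
    coefs = Y @ H.T                        # m x p
    resid = Y - coefs @ X.T
    df = n - p
    sigma2 = (resid * resid).sum(axis=1) / df
    vjj = XtX_inv[coef_index, coef_index]
    se = np.sqrt(np.maximum(sigma2 * vjj, 0.0))
    coef = coefs[:, coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pval = np.where(
        se > 0,
        2.0 * stats.t.sf(np.abs(np.where(se > 0, t, 0.0)), df),
        np.where(np.abs(coef) > 1e-12, 0.0, 1.0),
    )
    t = np.where(se > 0, t, np.where(np.abs(coef) > 1e-12, np.inf, 0.0))
    return coef, se, t, np.clip(pval, 0.0, 1.0)


def aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of design columns made redundant by collinearity (QR pivoting)."""
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    _, _, piv = qr(X, pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]
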