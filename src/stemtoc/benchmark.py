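"""Evaluation statistics for mitotic clocks.

Covers the standard clock-benchmarking toolkit: age correlation (Pearson /
Spearman with the regression-slope t-test p-value), covariate-adjusted
association of a score with age, the total number of stem-cell divisions
(TNSC = intrinsic annual rate x age), the relative intrinsic rate
(RIR = median(score / age) x 10), rank-based AUC for group discrimination,
one-tailed Wilcoxon rank-sum group tests, and paired clock-vs-clock
comparisons of a metric across datasets via the Wilcoxon signed-rank test.

Note on pairing: an unpaired "rank sum" test cannot compare two clocks on
the *same* datasets, so the paired comparison is the signed-rank test over
per-dataset metric differences, zero differences dropped (Pratt mode
optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import aliased_columns
from .datamodel import SampleSheet, ValidationError

__all__ = [
    "CorrelationResult",
    "correlate",
    "multivariate_assoc",
    "compute_tnsc",
    "compute_rir",
    "age_adjust",
    "auc",
    "wilcoxon_group_test",
    "ClockComparisonResult",
    "compare_clocks",
]

#: Largest combined sample size for which the rank-sum test enumerates the
#: exact null distribution (ties force the normal approximation).
EXACT_CUTOFF = 12


@dataclass
class CorrelationResult:
    """Pearson and Spearman coefficients with the two-tailed slope p-value."""

    pcc: float
    scc: float
    p: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson + Spearman correlation of paired observations.

    The two-tailed p-value is for the slope of the simple linear regression
    of y on x, identical to the PCC t-test with n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError("need at least 3 paired finite observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in x or y")
    pcc, p = stats.pearsonr(x, y)
    scc = stats.spearmanr(x, y).statistic
    return CorrelationResult(float(pcc), float(scc), float(p), int(x.size))


def multivariate_assoc(
    score: Sequence[float],
    design: pd.DataFrame,
    categorical: str = "dummy",
) -> pd.DataFrame:
    """Least-squares fit of a score on age plus named covariates.

    Categorical covariates (object/category dtype, e.g. smoking status) are
    expanded as dummy codes (first level dropped) or, with
    ``categorical="ordinal"``, as ordered integer codes. Returns a table of
    coefficients, SEs, t and two-tailed p for every term including the
    intercept. Rank-deficient designs raise, naming the aliased columns.
    """
    y = np.asarray(score, dtype=float)
    X_parts: list[pd.Series | pd.DataFrame] = []
    for col in design.columns:
        s = design[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            if categorical == "ordinal":
                codes = s.astype("category").cat.codes.astype(float)
                X_parts.append(codes.rename(col))
            else:
                X_parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
        else:
            X_parts.append(s.astype(float))
    X = pd.concat(X_parts, axis=1)
    n, p = X.shape
    if n <= p + 1:
        raise ValidationError(f"need n > p + 1; got n={n}, p={p}")
    Xc = sm.add_constant(X, prepend=True)
    bad = aliased_columns(Xc.to_numpy(dtype=float), list(Xc.columns))
    if bad:
        raise ValidationError(f"rank-deficient design; aliased columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    return pd.DataFrame(
        {
            "term": Xc.columns,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )


def compute_tnsc(
    rates: Mapping[str, float] | pd.Series,
    sheet: SampleSheet,
    tissue_col: str = "tissue",
    log2: bool = False,
) -> pd.Series:
    """Total number of stem-cell divisions per sample: TNSC = IR x age.

    ``rates`` maps tissue label to the intrinsic annual stem-cell division
    rate (IR). ``log2=True`` returns log2(TNSC) for display parity on
    wide-dynamic-range tissues (requires TNSC > 0).
    """
    rates = pd.Series(rates, dtype=float)
    tissues = sheet.column(tissue_col).astype(str)
    missing = sorted(set(tissues) - set(rates.index))
    if missing:
        raise ValidationError(f"tissues absent from rate table: {missing}")
    age = pd.to_numeric(sheet.column("age"), errors="raise").astype(float)
    tnsc = rates.loc[tissues].to_numpy() * age.to_numpy()
    out = pd.Series(tnsc, index=sheet.data.index, name="tnsc")
    if log2:
        if (out <= 0).any():
            raise ValidationError("log2 transform requires TNSC > 0")
        out = np.log2(out).rename("log2_tnsc")
    return out


def compute_rir(scores: Sequence[float], ages: Sequence[float]) -> float:
    """Relative intrinsic rate: median(score / age) x 10 (per-decade scale)."""
    s = np.asarray(scores, dtype=float)
    a = np.asarray(ages, dtype=float)
    if s.shape != a.shape:
        raise ValidationError("scores and ages must be paired")
    if (a <= 0).any():
        raise ValidationError("all ages must be positive")
    return float(np.median(s / a) * 10.0)


def age_adjust(values: Sequence[float], ages: Sequence[float], per_decade: bool = True) -> np.ndarray:
    """Divide age-cumulative loads by chronological age (x10 for per-decade)."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if (a <= 0).any():
        raise ValidationError("all ages must be positive")
    return v / a * (10.0 if per_decade else 1.0)


def auc(scores: Sequence[float], labels: Sequence[int] | Sequence[bool]) -> float:
    """Rank-based AUC: P(random positive scores above random negative).

    Equal to the Mann-Whitney U statistic divided by n1*n2, ties counted
    one-half.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    n1 = int(lab.sum())
    n0 = int((~lab).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be nonempty")
    ranks = stats.rankdata(s)  # average ranks: half-credit for ties
    u = ranks[lab].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def wilcoxon_group_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alternative: str = "greater",
    method: str = "auto",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value for group a vs group b.

    ``alternative="greater"`` tests that a tends to exceed b. ``method``:
    "exact" enumerates the null (small samples, no ties), "asymptotic" uses
    the normal approximation with tie correction and continuity correction;
    "auto" picks exact when n_a + n_b <= 12 and there are no ties.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    if method == "auto":
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size + b.size <= EXACT_CUTOFF and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


@dataclass
class ClockComparisonResult:
    """Pairwise clock comparison of a metric across shared datasets.

    ``metric`` is the clocks x datasets matrix compared; ``p_values`` holds,
    for each ordered pair (row A, column B), the one-tailed paired
    signed-rank p-value that A's metric exceeds B's across datasets
    (diagonal NaN).
    """

    metric_name: str
    metric: pd.DataFrame
    p_values: pd.DataFrame


def compare_clocks(
    metric_matrix: pd.DataFrame,
    alternative: str = "greater",
    metric_name: str = "PCC",
    zero_method: str = "wilcox",
) -> ClockComparisonResult:
    """One-tailed paired signed-rank comparison of clocks across datasets.

    ``metric_matrix`` is clocks x datasets (e.g. per-dataset PCC with age, or
    per-dataset AUC). For each ordered pair (A, B) the per-dataset
    differences A - B are tested with the Wilcoxon signed-rank test
    (``alternative`` applied to A - B); NAs are dropped pairwise and zero
    differences are dropped under the default "wilcox" rule ("pratt"
    optional). All-zero or <2 complete pairs yield p = 1 / NaN with a
    warning (no evidence either way).
    """
    if metric_matrix.shape[0] < 2 or metric_matrix.shape[1] < 2:
        raise ValidationError("need at least 2 clocks and 2 datasets")
    clocks = metric_matrix.index.tolist()
    pmat = pd.DataFrame(np.nan, index=clocks, columns=clocks)
    for a in clocks:
        for b in clocks:
            if a == b:
                continue
            d = (metric_matrix.loc[a] - metric_matrix.loc[b]).dropna().to_numpy(float)
            if d.size < 2:
                warnings.warn(f"fewer than 2 complete pairs for {a!r} vs {b!r}", stacklevel=2)
                continue
            if np.all(d == 0):
                pmat.loc[a, b] = 1.0  # zeros dropped -> no evidence
                continue
            res = stats.wilcoxon(d, alternative=alternative, zero_method=zero_method)
            pmat.loc[a, b] = float(res.pvalue)
    return ClockComparisonResult(metric_name, metric_matrix.copy(), pmat)
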