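import numpy as np
import pandas as pd
import pytest

from stemtoc import BetaMatrix, SampleSheet


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_beta(rng):
    """10 CpGs x 6 samples of valid betas, no missing values."""
    vals = rng.uniform(0.02, 0.9, size=(10, 6))
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i:03d}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
    )


@pytest.fixture
def pd_sheet():
    """Population-doubling series for 6 samples."""
    return SampleSheet(
        pd.DataFrame(
            {
                "population_doublings": [5.0, 15.0, 25.0, 35.0, 45.0, 55.0],
                "days_in_culture": [5.0, 15.0, 25.0, 35.0, 45.0, 55.0],
                "condition": "baseline",
            },
            index=[f"s{j}" for j in range(6)],
        )
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def quantile_oracle(values, q):
    """Sort-and-interpolate order-statistic quantile at position 1+(n-1)q."""
    v = sorted(values)
    h = 1 + (len(v) - 1) * q  # 1-based fractional position
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v))
    frac = h - lo
    return v[lo - 1] * (1 - frac) + v[hi - 1] * frac


def bh_oracle(p):
    """BH step-up by sorting and cumulative min, returned in input order."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        q[i] = running
    return q


def ols_oracle(x, y):
    """Closed-form simple OLS slope/se/t from the textbook formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    sigma2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return slope, se, slope / se


def auc_oracle(scores, labels):
    """O(n^2) pairwise enumeration, ties counted one-half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def ranksum_exact_oracle(a, b):
    """One-tailed (a > b) rank-sum p by enumerating all rank assignments."""
    from itertools import combinations

    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n = len(pooled)
    count = total = 0
    for combo in combinations(range(1, n + 1), len(a)):
        total += 1
        if sum(combo) >= observed:
            count += 1
    return count / total
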