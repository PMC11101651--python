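"""Clock scoring engines.

The relative mitotic-age score of a sample is a summary of its beta values
over a clock's CpGs:

* ``upper_quantile`` — the q-th order-statistic quantile (default q = 0.95)
  of the sample's clock-CpG betas. Because subclonal methylation gains hit a
  small, subject-specific CpG subset, an upper quantile captures the most
  advanced subclone where a plain average is diluted.
* ``mean`` — arithmetic mean (epiTOC-style hypermethylation clocks).
* ``one_minus_mean`` — 1 - mean, for hypomethylation clocks reported on a
  "higher = more divisions" orientation.
* ``linear`` — intercept + sum(weight * beta) (RepliTali-style fits).

Quantile convention: linear interpolation between order statistics at
position 1 + (n - 1) q; a nearest-rank-upper mode (the order statistic at or
above that position) is available for sensitivity analysis, under which a
95% UQ over 20 CpGs equals the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, ClockDefinition, ValidationError

__all__ = [
    "score_upper_quantile",
    "score_mean",
    "score_one_minus_mean",
    "score_linear",
    "score",
    "EffectSizeCurve",
    "choose_uq_threshold",
]

QUANTILE_MODES = ("linear", "nearest_upper")
DEFAULT_MIN_COVERAGE = 0.8


def _clock_values(
    m: BetaMatrix,
    clock: ClockDefinition,
    min_coverage: float,
    lenient: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Clock-CpG submatrix (CpGs x samples) and per-sample usability mask.

    Coverage of a sample = observed clock CpGs / clock size; samples below
    ``min_coverage`` raise, or are masked out with a warning under lenient
    mode.
    """
    present = [c for c in clock.cpg_ids if c in set(m.cpg_ids)]
    if not present:
        raise ValidationError(f"no clock CpGs of {clock.name!r} present in matrix")
    sub = m.values.loc[present].to_numpy(dtype=float)
    n_obs = (~np.isnan(sub)).sum(axis=0)
    coverage = n_obs / clock.n_cpgs
    low = coverage < min_coverage
    if low.any():
        bad = [s for s, b in zip(m.sample_ids, low) if b]
        msg = (
            f"samples below {min_coverage:.0%} coverage of clock "
            f"{clock.name!r}: {bad[:5]}{'...' if len(bad) > 5 else ''}"
        )
        if not lenient:
            raise ValidationError(msg)
        warnings.warn(msg + " (scored as NA)", stacklevel=3)
    return sub, ~low


def _uq(values: np.ndarray, q: float, mode: str) -> float:
    v = values[~np.isnan(values)]
    if mode == "linear":
        return float(np.quantile(v, q))
    if mode == "nearest_upper":
        # next order statistic at or above position 1 + (n-1) q; at q = 0.95
        # over 20 values this is the maximum
        return float(np.quantile(v, q, method="higher"))
    raise ValidationError(f"unknown quantile mode {mode!r}; expected {QUANTILE_MODES}")


def _table(m: BetaMatrix, clock: ClockDefinition, vals: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": m.sample_ids, "clock_name": clock.name, "score": vals}
    )


def score_upper_quantile(
    m: BetaMatrix,
    clock: ClockDefinition,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    lenient: bool = False,
    mode: str = "linear",
) -> pd.DataFrame:
    """Per-sample upper-quantile score over the clock CpGs."""
    if clock.method != "upper_quantile":
        raise ValidationError(f"clock {clock.name!r} is not an upper_quantile clock")
    sub, ok = _clock_values(m, clock, min_coverage, lenient)
    out = np.full(sub.shape[1], np.nan)
    for j in np.nonzero(ok)[0]:
        out[j] = _uq(sub[:, j], clock.quantile_q, mode)
    return _table(m, clock, out)


def score_mean(
    m: BetaMatrix,
    clock: ClockDefinition,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    lenient: bool = False,
) -> pd.DataFrame:
    """Per-sample arithmetic mean of non-missing clock-CpG betas."""
    if clock.method != "mean":
        raise ValidationError(f"clock {clock.name!r} is not a mean clock")
    sub, ok = _clock_values(m, clock, min_coverage, lenient)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(sub, axis=0)
    return _table(m, clock, np.where(ok, means, np.nan))


def score_one_minus_mean(
    m: BetaMatrix,
    clock: ClockDefinition,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    lenient: bool = False,
) -> pd.DataFrame:
    """1 - mean over the clock CpGs, oriented so higher = more divisions.

    The raw mean (the hypomethylation-clock display value, where *smaller*
    means a larger deviation from the methylated ground state) is reported
    alongside in a ``raw_mean`` column for transparency.
    """
    if clock.method != "one_minus_mean":
        raise ValidationError(f"clock {clock.name!r} is not a one_minus_mean clock")
    sub, ok = _clock_values(m, clock, min_coverage, lenient)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(sub, axis=0)
    means = np.where(ok, means, np.nan)
    out = _table(m, clock, 1.0 - means)
    out["raw_mean"] = means
    return out


def score_linear(
    m: BetaMatrix,
    clock: ClockDefinition,
    subset: bool = False,
) -> pd.DataFrame:
    """intercept + sum(weight_c * beta_c); not bounded to [0, 1].

    All weighted CpGs must be present and observed unless ``subset=True``,
    which restricts the sum to the CpGs present in the matrix (mirroring the
    use of an EPIC-trained clock on a 450k array).
    """
    if clock.method != "linear":
        raise ValidationError(f"clock {clock.name!r} is not a linear clock")
    present = [c for c in clock.cpg_ids if c in set(m.cpg_ids)]
    absent = [c for c in clock.cpg_ids if c not in set(m.cpg_ids)]
    if absent and not subset:
        raise ValidationError(
            f"clock {clock.name!r}: weighted CpGs absent from matrix: "
            f"{absent[:10]}{'...' if len(absent) > 10 else ''}"
        )
    if not present:
        raise ValidationError(f"no clock CpGs of {clock.name!r} present in matrix")
    sub = m.values.loc[present].to_numpy(dtype=float)
    if np.isnan(sub).any() and not subset:
        raise ValidationError(
            f"clock {clock.name!r}: missing beta values for weighted CpGs; "
            "impute first or use subset mode"
        )
    w = np.array([clock.weights[c] for c in present])
    contrib = np.where(np.isnan(sub), 0.0, sub) * w[:, None]
    vals = clock.intercept + contrib.sum(axis=0)
    return _table(m, clock, vals)


def score(m: BetaMatrix, clock: ClockDefinition, **kwargs) -> pd.DataFrame:
    """Dispatch to the scorer matching ``clock.method``."""
    if clock.method == "upper_quantile":
        return score_upper_quantile(m, clock, **kwargs)
    if clock.method == "mean":
        return score_mean(m, clock, **kwargs)
    if clock.method == "one_minus_mean":
        return score_one_minus_mean(m, clock, **kwargs)
    return score_linear(m, clock, **kwargs)


# ---------------------------------------------------------------------------
# upper-quantile threshold selection
# ---------------------------------------------------------------------------

@dataclass
class EffectSizeCurve:
    """Group effect size of the UQ score across a grid of quantile thresholds.

    ``effect_size[i]`` is the mean per-sample UQ score in the at-risk group
    minus the mean in the healthy group at ``quantile_grid[i]``;
    ``dispersion[i]`` is the bootstrap SE of that difference. ``chosen_q`` is
    the largest grid value maximizing ``effect - penalty * dispersion``.
    """

    quantile_grid: np.ndarray
    effect_size: np.ndarray
    dispersion: np.ndarray
    chosen_q: float

    def __post_init__(self) -> None:
        g = np.asarray(self.quantile_grid, dtype=float)
        if g.size == 0 or (np.diff(g) <= 0).any():
            raise ValidationError("quantile grid must be strictly increasing")
        if not (len(g) == len(self.effect_size) == len(self.dispersion)):
            raise ValidationError("curve arrays must have equal length")


def choose_uq_threshold(
    m: BetaMatrix,
    clock_cpgs: Sequence[str],
    at_risk_ids: Sequence[str],
    healthy_ids: Sequence[str],
    grid: Sequence[float] | None = None,
    n_boot: int = 200,
    seed: int | None = None,
    penalty: float = 1.0,
    mode: str = "linear",
) -> EffectSizeCurve:
    """Scan upper-quantile thresholds for group separation.

    For each q on the grid (default 0.75 to 0.99 in steps of 0.01), the
    effect size is the difference in mean per-sample UQ score between the
    at-risk and healthy groups, and the dispersion is a seeded bootstrap SE
    of that difference (resampling samples within each group). The chosen
    threshold is the largest grid q maximizing
    ``effect - penalty * dispersion`` — a documented heuristic for
    "maximize effect size without compromising sampling variability".
    """
    if grid is None:
        grid = np.round(np.arange(0.75, 0.995, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    if len(at_risk_ids) < 2 or len(healthy_ids) < 2:
        raise ValidationError("each group needs at least 2 samples")
    rng = np.random.default_rng(seed)
    sub_risk = m.subset_cpgs(list(clock_cpgs)).subset_samples(list(at_risk_ids))
    sub_heal = m.subset_cpgs(list(clock_cpgs)).subset_samples(list(healthy_ids))

    effects = np.empty(grid.size)
    disps = np.empty(grid.size)
    for i, q in enumerate(grid):
        clock = ClockDefinition(name="scan", cpg_ids=tuple(clock_cpgs),
                                method="upper_quantile", quantile_q=float(q))
        a = score_upper_quantile(sub_risk, clock, mode=mode)["score"].to_numpy()
        h = score_upper_quantile(sub_heal, clock, mode=mode)["score"].to_numpy()
        effects[i] = a.mean() - h.mean()
        boot_a = rng.choice(a, size=(n_boot, a.size), replace=True).mean(axis=1)
        boot_h = rng.choice(h, size=(n_boot, h.size), replace=True).mean(axis=1)
        disps[i] = float(np.std(boot_a - boot_h, ddof=1))

    objective = effects - penalty * disps
    best = objective.max()
    chosen_q = float(grid[np.nonzero(objective >= best - 1e-12)[0][-1]])
    return EffectSizeCurve(grid, effects, disps, chosen_q)
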