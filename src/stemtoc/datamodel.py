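"""Core containers for DNA-methylation mitotic-clock analysis.

A *beta value* is the fraction of methylated signal at a CpG, in [0, 1].
The containers here are thin, validated wrappers around pandas objects:

* :class:`BetaMatrix` — CpG x sample matrix of beta values with explicit
  missingness (NaN marks a missing cell; NaN can never collide with a legal
  beta, so observed 0.0 stays distinguishable from "absent").
* :class:`SampleSheet` — per-sample metadata: age, culture condition,
  population doublings, disease-stage/cohort group, cell-type fractions and
  arbitrary numeric covariates.
* :class:`CpGAnnotation` — genomic position and signed distance to the
  nearest transcription start site (negative = upstream).
* :class:`ClockDefinition` — a named CpG set plus its scoring rule.

Score tables are plain tidy DataFrames with columns
``("sample_id", "clock_name", "score")`` (see :data:`SCORE_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "SampleSheet",
    "CpGAnnotation",
    "ClockDefinition",
    "SCORE_COLUMNS",
    "CLOCK_METHODS",
]

#: Columns of a tidy score table.
SCORE_COLUMNS = ("sample_id", "clock_name", "score")

#: Supported clock scoring rules.
CLOCK_METHODS = ("upper_quantile", "mean", "one_minus_mean", "linear")


class ValidationError(ValueError):
    """An input violates a documented container invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of DNAm beta fractions with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by CpG id with sample ids as columns. Entries are
        floats in [0, 1]; NaN marks a missing measurement.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        _check_unique(self.values.index, "CpG ids")
        _check_unique(self.values.columns, "sample ids")
        try:
            arr = self.values.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric beta value: {exc}") from exc
        bad = (arr < 0.0) | (arr > 1.0)  # NaN compares False on both sides
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at CpG "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        self.values = pd.DataFrame(
            arr, index=self.values.index.astype(str), columns=self.values.columns.astype(str)
        )

    # -- basic accessors -------------------------------------------------
    @property
    def cpg_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing(self) -> pd.DataFrame:
        """Boolean mask, True where a cell is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float, copy=True)

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        missing = [c for c in cpg_ids if c not in self.values.index]
        if missing:
            raise KeyError(f"CpGs absent from matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[list(cpg_ids)].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return BetaMatrix(self.values[list(sample_ids)].copy())


@dataclass
class SampleSheet:
    """Per-sample metadata table indexed by sample id.

    Recognized (all optional) columns: ``age`` (years), ``condition``
    (e.g. baseline / mitomycin / serum_deprived), ``population_doublings``,
    ``days_in_culture``, ``group`` (disease stage or cohort), plus any number
    of numeric covariates. ``cell_fraction_cols`` names the columns holding
    cell-type fractions; each fraction must lie in [0, 1] and fractions must
    sum to within [0.95, 1.05] per sample.
    """

    data: pd.DataFrame
    cell_fraction_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        _check_unique(self.data.index, "sample ids")
        self.cell_fraction_cols = tuple(self.cell_fraction_cols)
        missing_cols = [c for c in self.cell_fraction_cols if c not in self.data.columns]
        if missing_cols:
            raise ValidationError(f"cell-fraction columns absent: {missing_cols}")
        if "age" in self.data.columns:
            age = pd.to_numeric(self.data["age"], errors="raise")
            if (age.dropna() < 0).any():
                raise ValidationError("negative age")
        if self.cell_fraction_cols:
            frac = self.data[list(self.cell_fraction_cols)].astype(float)
            arr = frac.to_numpy()
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError("cell fractions must lie in [0, 1]")
            sums = np.nansum(arr, axis=1)
            complete = ~np.isnan(arr).any(axis=1)
            bad = complete & ((sums < 0.95) | (sums > 1.05))
            if bad.any():
                sid = self.data.index[np.argwhere(bad)[0][0]]
                raise ValidationError(
                    f"cell fractions of sample {sid!r} sum to "
                    f"{sums[np.argwhere(bad)[0][0]]:.3f}, outside [0.95, 1.05]"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"sample sheet has no column {name!r}")
        return self.data[name]

    @property
    def cell_fractions(self) -> pd.DataFrame:
        return self.data[list(self.cell_fraction_cols)].astype(float)

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.data.loc[list(sample_ids)], self.cell_fraction_cols)


@dataclass
class CpGAnnotation:
    """CpG genomic annotation indexed by CpG id.

    Columns: ``chromosome``, ``position`` (1-based, fully closed), ``strand``,
    ``tss_distance`` (signed bp; negative = upstream of the TSS) and an
    optional ``gene`` symbol.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "cpg_id"
        _check_unique(self.data.index, "CpG ids")
        for col in ("chromosome", "position", "tss_distance"):
            if col not in self.data.columns:
                raise ValidationError(f"annotation lacks required column {col!r}")
        pos = pd.to_numeric(self.data["position"], errors="raise")
        if (pos < 1).any():
            raise ValidationError("positions must be >= 1 (1-based coordinates)")
        tss = pd.to_numeric(self.data["tss_distance"], errors="raise")
        if not np.isfinite(tss.to_numpy(dtype=float)).all():
            raise ValidationError("tss_distance must be finite for every annotated CpG")

    @property
    def cpg_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def tss_distance(self) -> pd.Series:
        return self.data["tss_distance"].astype(float)


@dataclass
class ClockDefinition:
    """A named CpG set plus its scoring rule.

    ``method`` is one of :data:`CLOCK_METHODS`. ``quantile_q`` is required for
    ``upper_quantile`` (0 < q <= 1); ``intercept``/``weights`` are required
    for ``linear`` and the weights must cover exactly ``cpg_ids``. Scores are
    always emitted with orientation +1 (higher score = more divisions).
    """

    name: str
    cpg_ids: tuple[str, ...]
    method: str = "upper_quantile"
    quantile_q: float | None = None
    intercept: float | None = None
    weights: Mapping[str, float] | None = None
    orientation: int = 1

    def __post_init__(self) -> None:
        self.cpg_ids = tuple(str(c) for c in self.cpg_ids)
        if not self.cpg_ids:
            raise ValidationError("clock must contain at least one CpG")
        _check_unique(pd.Index(self.cpg_ids), "clock CpG ids")
        if self.method not in CLOCK_METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {CLOCK_METHODS}"
            )
        if self.method == "upper_quantile":
            if self.quantile_q is None or not (0.0 < float(self.quantile_q) <= 1.0):
                raise ValidationError("upper_quantile clocks need 0 < quantile_q <= 1")
            self.quantile_q = float(self.quantile_q)
        if self.method == "linear":
            if self.weights is None or self.intercept is None:
                raise ValidationError("linear clocks need intercept and weights")
            self.weights = {str(k): float(v) for k, v in self.weights.items()}
            if set(self.weights) != set(self.cpg_ids):
                extra = sorted(set(self.weights) - set(self.cpg_ids))
                absent = sorted(set(self.cpg_ids) - set(self.weights))
                raise ValidationError(
                    f"weights must cover exactly the clock CpGs "
                    f"(missing {absent[:3]}, extra {extra[:3]})"
                )
            self.intercept = float(self.intercept)
        if self.orientation not in (1, -1):
            raise ValidationError("orientation must be +1 or -1")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)
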