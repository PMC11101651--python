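"""Readers and writers for the delimited-text formats the tool touches.

Conventions
-----------
* Beta matrices: delimited text (TSV by default, CSV for ``.csv`` paths),
  CpGs as rows, first column CpG ids, header row sample ids. A single
  configurable token (default ``"NA"``) marks missing cells.
* Sample sheets: TSV with a mandatory ``sample_id`` column.
* CpG annotation: either a manifest TSV (``cpg_id, chromosome, position,
  strand, tss_distance[, gene]``) or a BED-like TSV
  (``chrom, start, end, cpg_id, tss_distance, strand``; BED starts are
  0-based half-open and are converted to 1-based closed positions).
* Clock definitions: JSON with fields ``name / method / cpgs / quantile_q /
  intercept / weights``.
* Betas and scores are serialized with 6 decimal places.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    SCORE_COLUMNS,
    BetaMatrix,
    ClockDefinition,
    CpGAnnotation,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_clock",
    "write_clock",
    "read_score_table",
    "write_score_table",
    "read_tissue_rates",
    "write_tissue_rates",
]

FLOAT_FORMAT = "%.6f"
DEFAULT_MISSING_TOKEN = "NA"


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    sep: str | None = None,
) -> BetaMatrix:
    """Read a CpG x sample beta matrix from a delimited table.

    Values outside [0, 1] and non-numeric non-missing cells are rejected
    with an error naming the offending CpG and sample.
    """
    raw = pd.read_csv(
        path,
        sep=_sep_for(path, sep),
        index_col=0,
        dtype=str,
        na_values=[missing_token],
        keep_default_na=False,
    )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise ValidationError(
            f"non-numeric value {raw.iat[i, j]!r} at CpG {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    return BetaMatrix(numeric)


def write_beta_matrix(
    m: BetaMatrix,
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    sep: str | None = None,
) -> None:
    m.values.to_csv(
        path,
        sep=_sep_for(path, sep),
        index_label="cpg_id",
        na_rep=missing_token,
        float_format=FLOAT_FORMAT,
    )


def read_sample_sheet(
    path: str | Path,
    cell_fraction_cols: Sequence[str] | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    sep: str | None = None,
) -> SampleSheet:
    """Read a sample sheet; ``sample_id`` column is mandatory.

    If ``cell_fraction_cols`` is None, any columns prefixed ``frac_`` are
    treated as cell-type fractions.
    """
    df = pd.read_csv(
        path,
        sep=_sep_for(path, sep),
        na_values=[missing_token],
        keep_default_na=False,
    )
    if "sample_id" not in df.columns:
        raise ValidationError(f"sample sheet {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    for col in df.columns:
        if col not in ("condition", "group", "tissue"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass  # genuinely categorical extra column

    if cell_fraction_cols is None:
        cell_fraction_cols = [c for c in df.columns if c.startswith("frac_")]
    return SampleSheet(df, tuple(cell_fraction_cols))


def write_sample_sheet(
    sheet: SampleSheet,
    path: str | Path,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    sep: str | None = None,
) -> None:
    sheet.data.to_csv(
        path,
        sep=_sep_for(path, sep),
        index_label="sample_id",
        na_rep=missing_token,
        float_format=FLOAT_FORMAT,
    )


_MANIFEST_COLS = {"cpg_id", "chromosome", "position", "strand", "tss_distance"}


def read_annotation(path: str | Path, sep: str | None = None) -> CpGAnnotation:
    """Read CpG annotation from a manifest TSV or a BED-like TSV."""
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    cols = set(df.columns)
    if _MANIFEST_COLS <= cols:
        df = df.set_index("cpg_id")
        return CpGAnnotation(df)
    bed_cols = {"chrom", "start", "end", "cpg_id", "tss_distance", "strand"}
    if bed_cols <= cols:
        out = pd.DataFrame(
            {
                "chromosome": df["chrom"].to_numpy(),
                "position": df["start"].to_numpy(dtype=int) + 1,  # BED 0-based -> 1-based
                "strand": df["strand"].to_numpy(),
                "tss_distance": df["tss_distance"].to_numpy(),
            },
            index=df["cpg_id"].astype(str).to_numpy(),
        )
        return CpGAnnotation(out)
    raise ValidationError(
        f"annotation {path}: expected manifest columns {sorted(_MANIFEST_COLS)} "
        f"or BED-like columns {sorted(bed_cols)}; got {sorted(cols)}"
    )


def write_annotation(ann: CpGAnnotation, path: str | Path, sep: str | None = None) -> None:
    ann.data.to_csv(path, sep=_sep_for(path, sep), index_label="cpg_id")


def read_clock(path: str | Path) -> ClockDefinition:
    with open(path) as fh:
        obj = json.load(fh)
    return ClockDefinition(
        name=obj["name"],
        cpg_ids=tuple(obj["cpgs"]),
        method=obj.get("method", "upper_quantile"),
        quantile_q=obj.get("quantile_q"),
        intercept=obj.get("intercept"),
        weights=obj.get("weights"),
        orientation=obj.get("orientation", 1),
    )


def write_clock(clock: ClockDefinition, path: str | Path) -> None:
    obj: dict = {
        "name": clock.name,
        "method": clock.method,
        "cpgs": list(clock.cpg_ids),
        "orientation": clock.orientation,
    }
    if clock.quantile_q is not None:
        obj["quantile_q"] = clock.quantile_q
    if clock.method == "linear":
        obj["intercept"] = clock.intercept
        obj["weights"] = dict(clock.weights)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_score_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"score table {path} lacks columns {missing}")
    df["score"] = df["score"].astype(float)
    return df


def write_score_table(scores: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    scores.to_csv(path, sep=_sep_for(path, sep), index=False, float_format=FLOAT_FORMAT)


def read_tissue_rates(path: str | Path, sep: str | None = None) -> pd.Series:
    """Read a ``tissue, divisions_per_year`` table into a Series.

    Intrinsic rates are annual stem-cell divisions per tissue and must be
    nonnegative.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    for col in ("tissue", "divisions_per_year"):
        if col not in df.columns:
            raise ValidationError(f"rates table {path} lacks column {col!r}")
    rates = df.set_index("tissue")["divisions_per_year"].astype(float)
    if (rates < 0).any():
        raise ValidationError("intrinsic division rates must be nonnegative")
    return rates


def write_tissue_rates(rates: Mapping[str, float] | pd.Series, path: str | Path,
                       sep: str | None = None) -> None:
    ser = pd.Series(rates, name="divisions_per_year")
    ser.rename_axis("tissue").to_csv(path, sep=_sep_for(path, sep))
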