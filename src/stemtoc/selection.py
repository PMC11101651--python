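"""Mitotic-CpG selection pipeline.

The pipeline identifies CpGs that plausibly count stem-cell divisions, in
three shrinking stages:

1. **Fetal ground-state filter** — promoter-proximal CpGs (within a window
   upstream of the TSS) that are unmethylated (beta < 0.2) in *every* fetal /
   neonatal sample, so the candidates are not cell-type specific markers in
   the ground state.
2. **In-vitro mitotic filter** — CpGs gaining methylation with population
   doublings (FDR q < 0.05, positive slope) in every baseline cell line, but
   *not* gaining methylation (unadjusted P < 0.05) with days in culture under
   cell-cycle arrest (mitomycin-C) or serum deprivation. This decouples
   division count from mere passage of time.
3. **In-vivo meta-analysis** — CpGs whose methylation also rises with
   chronological age in several whole-blood cohorts after adjusting for
   immune cell-type fractions, combined by the directional Stouffer method
   (keep z > 0, P < 0.05).

Per-CpG regression results are DataFrames with columns
``cpg_id, slope, se, t, p, n`` (plus ``q`` after FDR adjustment); the meta
table has ``cpg_id, stouffer_z, p, n_cohorts``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import aliased_columns, mass_multiple_ols, mass_simple_ols
from .datamodel import BetaMatrix, ClockDefinition, CpGAnnotation, SampleSheet, ValidationError

__all__ = [
    "REGRESSION_COLUMNS",
    "META_COLUMNS",
    "select_fetal_unmethylated",
    "pd_association",
    "bh_fdr",
    "add_q_values",
    "select_vitro_mit",
    "age_association_cohort",
    "stouffer_meta",
    "select_vivo_mit",
    "build_clock",
    "SelectionResult",
    "run_selection_pipeline",
]

REGRESSION_COLUMNS = ("cpg_id", "slope", "se", "t", "p", "n")
META_COLUMNS = ("cpg_id", "stouffer_z", "p", "n_cohorts")

#: p-values of exactly 0 are clamped to this before the normal inverse.
P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# stage 1: fetal ground state
# ---------------------------------------------------------------------------

def select_fetal_unmethylated(
    m: BetaMatrix,
    ann: CpGAnnotation,
    max_beta: float = 0.2,
    tss_window: int = 200,
    symmetric_window: bool = False,
) -> list[str]:
    """CpGs unmethylated in every fetal sample and promoter-proximal.

    All samples of ``m`` are taken to be fetal/ground-state. A CpG is kept
    iff its ``tss_distance`` lies in ``[-tss_window, 0]`` (or
    ``[-tss_window, +tss_window]`` with ``symmetric_window``) and its beta is
    strictly below ``max_beta`` in every sample; a missing value disqualifies
    the CpG (constitutive unmethylation cannot be asserted).
    """
    common = m.values.index.intersection(ann.data.index)
    if len(common) == 0:
        raise ValidationError("no CpGs shared between beta matrix and annotation")
    tss = ann.tss_distance.loc[common]
    lo, hi = -abs(tss_window), (abs(tss_window) if symmetric_window else 0)
    in_window = (tss >= lo) & (tss <= hi)
    vals = m.values.loc[common]
    unmeth = (vals < max_beta).all(axis=1) & vals.notna().all(axis=1)
    keep = common[(in_window & unmeth).to_numpy()]
    # preserve matrix row order
    order = [c for c in m.cpg_ids if c in set(keep)]
    return order


# ---------------------------------------------------------------------------
# stage 2: in-vitro population-doubling associations
# ---------------------------------------------------------------------------

def pd_association(
    m: BetaMatrix,
    sheet: SampleSheet,
    predictor: str = "population_doublings",
) -> pd.DataFrame:
    """Per-CpG OLS of beta on a culture predictor (PDs or days in culture).

    Two-tailed p-values from the t distribution with n-2 df. Constant-beta
    CpGs report slope 0, p 1 rather than erroring mid-pipeline.
    """
    x = pd.to_numeric(sheet.data.loc[m.sample_ids, predictor], errors="raise").to_numpy(float)
    if np.isnan(x).any():
        raise ValidationError(f"predictor {predictor!r} missing for some samples")
    if len(x) < 3:
        raise ValidationError("need at least 3 samples for a PD regression")
    slope, se, t, p, n = mass_simple_ols(m.to_numpy(), x)
    return pd.DataFrame(
        {"cpg_id": m.cpg_ids, "slope": slope, "se": se, "t": t, "p": p, "n": n}
    )


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_q_values(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a regression table with a BH ``q`` column."""
    out = records.copy()
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def select_vitro_mit(
    baseline_runs: Mapping[str, pd.DataFrame],
    control_runs: Mapping[str, pd.DataFrame],
    q_thresh: float = 0.05,
    control_p: float = 0.05,
) -> list[str]:
    """In-vitro mitotic CpGs: PD-hypermethylated in every baseline line,
    not hypermethylated in any control (mitomycin / serum-deprived) run.

    ``baseline_runs`` maps cell-line name to its regression table (a ``q``
    column is added by BH over that line's p-values if absent).
    ``control_runs`` maps condition name to a regression table; exclusion
    uses the *unadjusted* p-value. A CpG absent from a control run is
    retained with a warning.
    """
    if not baseline_runs:
        raise ValidationError("baseline_runs must be nonempty")
    selected: list[str] | None = None
    for line, rec in baseline_runs.items():
        if "q" not in rec.columns:
            rec = add_q_values(rec)
        ok = set(rec.loc[(rec["slope"] > 0) & (rec["q"] < q_thresh), "cpg_id"])
        if selected is None:
            selected = [c for c in rec["cpg_id"] if c in ok]
        else:
            selected = [c for c in selected if c in ok]
    assert selected is not None
    for cond, rec in control_runs.items():
        known = set(rec["cpg_id"])
        absent = [c for c in selected if c not in known]
        if absent:
            warnings.warn(
                f"{len(absent)} CpGs absent from control run {cond!r}; retained",
                stacklevel=2,
            )
        drop = set(rec.loc[(rec["slope"] > 0) & (rec["p"] < control_p), "cpg_id"])
        selected = [c for c in selected if c not in drop]
    return selected


# ---------------------------------------------------------------------------
# stage 3: in-vivo age associations with cell-fraction adjustment
# ---------------------------------------------------------------------------

def age_association_cohort(
    m: BetaMatrix,
    sheet: SampleSheet,
    covariate_names: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-CpG multiple regression of beta on age plus covariates.

    The returned table reports the *age* coefficient, its SE, t and
    two-tailed p (df = n - p). If the named covariates are cell fractions
    summing to exactly 1 for all samples, the last one is dropped before
    fitting to avoid aliasing the intercept (a warning is emitted). Other
    rank deficiencies raise, naming the aliased columns.
    """
    meta = sheet.data.loc[m.sample_ids]
    age = pd.to_numeric(meta["age"], errors="raise").to_numpy(float)
    if np.isnan(age).any():
        raise ValidationError("age missing for some samples")
    covs = list(covariate_names)
    C = meta[covs].astype(float).to_numpy() if covs else np.empty((len(age), 0))
    if np.isnan(C).any():
        raise ValidationError("covariates contain missing values")
    if covs and np.allclose(C.sum(axis=1), 1.0, atol=1e-10):
        warnings.warn(
            f"covariates sum to 1 for all samples; dropping {covs[-1]!r}",
            stacklevel=2,
        )
        covs = covs[:-1]
        C = C[:, :-1]
    n = len(age)
    if n <= len(covs) + 2:
        raise ValidationError(f"need n > #covariates + 2; got n={n}, covariates={len(covs)}")
    X = np.column_stack([np.ones(n), age, C])
    names = ["intercept", "age", *covs]
    bad = aliased_columns(X, names)
    if bad:
        raise ValidationError(f"collinear design; aliased columns: {bad}")
    coef, se, t, p = mass_multiple_ols(m.to_numpy(), X, coef_index=1)
    return pd.DataFrame(
        {"cpg_id": m.cpg_ids, "slope": coef, "se": se, "t": t, "p": p, "n": n}
    )


def stouffer_meta(per_cohort: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Directional Stouffer combination of per-cohort regression tables.

    Per cohort, ``z_i = sign(slope_i) * Phi^-1(1 - p_i / 2)``; the combined
    statistic is ``sum(z_i) / sqrt(k)`` with two-tailed
    ``p = 2 (1 - Phi(|z|))``. CpGs are combined over the intersection of the
    cohorts' CpG sets, in the first cohort's order. Zero p-values are clamped
    at 1e-300 before the normal inverse.
    """
    if len(per_cohort) == 0:
        raise ValidationError("need at least one cohort")
    common: list[str] | None = None
    for rec in per_cohort:
        ids = set(rec["cpg_id"])
        common = [c for c in per_cohort[0]["cpg_id"] if c in ids] if common is None \
            else [c for c in common if c in ids]
    assert common is not None
    if not common:
        raise ValidationError("cohorts share no CpGs")
    k = len(per_cohort)
    z_sum = np.zeros(len(common))
    for rec in per_cohort:
        sub = rec.set_index("cpg_id").loc[common]
        p = np.clip(sub["p"].to_numpy(float), P_FLOOR, 1.0)
        z = np.sign(sub["slope"].to_numpy(float)) * stats.norm.isf(p / 2.0)
        z_sum += z
    z_comb = z_sum / np.sqrt(k)
    p_comb = 2.0 * stats.norm.sf(np.abs(z_comb))
    return pd.DataFrame(
        {"cpg_id": common, "stouffer_z": z_comb, "p": p_comb, "n_cohorts": k}
    )


def select_vivo_mit(
    meta: pd.DataFrame,
    z_min: float = 0.0,
    p_max: float = 0.05,
) -> list[str]:
    """CpGs with Stouffer z > ``z_min`` and meta p < ``p_max``, order kept."""
    if len(meta) == 0:
        raise ValidationError("empty meta table")
    mask = (meta["stouffer_z"] > z_min) & (meta["p"] < p_max)
    return meta.loc[mask, "cpg_id"].tolist()


def build_clock(
    cpgs: Sequence[str],
    method: str = "upper_quantile",
    quantile_q: float = 0.95,
    name: str = "mitotic-uq",
    intercept: float | None = None,
    weights: Mapping[str, float] | None = None,
) -> ClockDefinition:
    """Package a selected CpG set as a scoreable clock (default: 95% UQ)."""
    return ClockDefinition(
        name=name,
        cpg_ids=tuple(cpgs),
        method=method,
        quantile_q=quantile_q if method == "upper_quantile" else None,
        intercept=intercept,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the full fetal -> in-vitro -> in-vivo selection."""

    fetal_cpgs: list[str]
    vitro_cpgs: list[str]
    vivo_cpgs: list[str]
    clock: ClockDefinition
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_selection_pipeline(
    fetal: BetaMatrix,
    annotation: CpGAnnotation,
    baseline_data: Mapping[str, tuple[BetaMatrix, SampleSheet]],
    control_data: Mapping[str, tuple[BetaMatrix, SampleSheet]],
    cohort_data: Sequence[tuple[BetaMatrix, SampleSheet, Sequence[str]]],
    *,
    max_beta: float = 0.2,
    tss_window: int = 200,
    symmetric_window: bool = False,
    baseline_predictor: str = "population_doublings",
    control_predictor: str = "days_in_culture",
    q_thresh: float = 0.05,
    control_p: float = 0.05,
    z_min: float = 0.0,
    p_max: float = 0.05,
    quantile_q: float = 0.95,
    clock_name: str = "mitotic-uq",
) -> SelectionResult:
    """Run all three selection stages and package the final UQ clock.

    ``cohort_data`` entries are ``(beta, sheet, covariate_names)`` where the
    covariates are the cell-fraction columns to adjust for. Each filter
    stage only removes CpGs (monotone shrinking); counts per stage are kept
    in :attr:`SelectionResult.stage_counts`.
    """
    fetal_cpgs = select_fetal_unmethylated(
        fetal, annotation, max_beta=max_beta, tss_window=tss_window,
        symmetric_window=symmetric_window,
    )
    if not fetal_cpgs:
        raise ValidationError("fetal ground-state filter removed every CpG")

    baseline_runs = {}
    for line, (m, sheet) in baseline_data.items():
        sub = m.subset_cpgs([c for c in fetal_cpgs if c in set(m.cpg_ids)])
        baseline_runs[line] = add_q_values(pd_association(sub, sheet, baseline_predictor))
    control_runs = {}
    for cond, (m, sheet) in control_data.items():
        sub = m.subset_cpgs([c for c in fetal_cpgs if c in set(m.cpg_ids)])
        control_runs[cond] = pd_association(sub, sheet, control_predictor)
    vitro = select_vitro_mit(baseline_runs, control_runs, q_thresh, control_p)
    if not vitro:
        raise ValidationError("in-vitro filter removed every CpG")

    cohort_runs = []
    for m, sheet, covs in cohort_data:
        sub = m.subset_cpgs([c for c in vitro if c in set(m.cpg_ids)])
        cohort_runs.append(age_association_cohort(sub, sheet, covs))
    meta = stouffer_meta(cohort_runs)
    vivo = select_vivo_mit(meta, z_min=z_min, p_max=p_max)
    if not vivo:
        raise ValidationError("in-vivo meta-analysis removed every CpG")

    clock = build_clock(vivo, quantile_q=quantile_q, name=clock_name)
    counts = {
        "input": fetal.shape[0],
        "fetal_unmethylated": len(fetal_cpgs),
        "vitro_mitotic": len(vitro),
        "vivo_mitotic": len(vivo),
    }
    return SelectionResult(fetal_cpgs, vitro, vivo, clock, counts)
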