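"""Generative models for methylation drift and synthetic study designs.

Three generators make the selection pipeline and benchmarks testable from
scratch:

* :func:`simulate_stage_dataset` — the carcinogenesis toy model: every CpG
  starts from a low-methylation baseline Beta(10, 90); as samples progress
  through normal -> at-risk -> preneoplastic -> cancer stages, a per-sample
  random CpG subset (1-3, 5-10, 11-17 CpGs) has its value *replaced* by a
  draw from progressively more methylated Beta distributions
  (Beta(3,7), Beta(5,5), Beta(8,2)). Altered subsets are drawn independently
  per sample, so outlier CpGs overlap little between subjects — the
  stochastic subclonal-gain signature an upper-quantile score exploits.
* :func:`simulate_cellline_pd` — cultured cell lines whose planted mitotic
  CpGs gain methylation linearly with population doublings in the baseline
  condition only; mitomycin-arrested and serum-deprived series are driftless.
* :func:`simulate_cohort` — in-vivo cohorts with age-drifting planted CpGs,
  Dirichlet cell-type fractions, and optionally decoy CpGs confounded by an
  age-correlated cell fraction.

A single integer seed feeds a named-stream RNG (one independent stream per
generator), so every generator is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, CpGAnnotation, SampleSheet, ValidationError

__all__ = [
    "stream_rng",
    "sample_beta",
    "StageSpec",
    "SimStageConfig",
    "simulate_stage_dataset",
    "CellLineSim",
    "simulate_cellline_pd",
    "simulate_cohort",
    "simulate_fetal_matrix",
    "make_promoter_annotation",
]

_BETA_EPS = 1e-9
STAGE_ORDER = ("normal", "at_risk", "preneoplastic", "cancer")


def stream_rng(seed: int | None, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from (seed, name)."""
    tag = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, tag]))


def sample_beta(a: float, b: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws from Beta(a, b), constrained to the open interval (0, 1).

    Beta(a, b) has mean a/(a+b) and variance ab/((a+b+1)(a+b)^2).
    """
    if a <= 0 or b <= 0:
        raise ValidationError("Beta parameters must be positive")
    if n < 1:
        raise ValidationError("n must be >= 1")
    return np.clip(rng.beta(a, b, size=n), _BETA_EPS, 1.0 - _BETA_EPS)


# ---------------------------------------------------------------------------
# staged carcinogenesis model
# ---------------------------------------------------------------------------

@dataclass
class StageSpec:
    """One disease stage: how many CpGs are altered and from which Beta."""

    label: str
    n_samples: int = 10
    altered_count_range: tuple[int, int] = (0, 0)
    beta_params: tuple[float, float] | None = None


def _default_stages() -> list[StageSpec]:
    return [
        StageSpec("normal", 10, (0, 0), None),
        StageSpec("at_risk", 10, (1, 3), (3.0, 7.0)),
        StageSpec("preneoplastic", 10, (5, 10), (5.0, 5.0)),
        StageSpec("cancer", 10, (11, 17), (8.0, 2.0)),
    ]


@dataclass
class SimStageConfig:
    """Configuration of the staged carcinogenesis simulation.

    Defaults are the reduced study design: 20 CpGs, 10 samples per stage,
    baseline Beta(10, 90) (mean beta 0.1), and per-stage altered-CpG count
    ranges / Beta parameters as in :func:`_default_stages`.
    """

    n_cpgs: int = 20
    baseline_beta_params: tuple[float, float] = (10.0, 90.0)
    stages: list[StageSpec] = field(default_factory=_default_stages)
    seed: int | None = None

    def __post_init__(self) -> None:
        a0, b0 = self.baseline_beta_params
        if a0 <= 0 or b0 <= 0:
            raise ValidationError("baseline Beta parameters must be positive")
        labels = tuple(s.label for s in self.stages)
        if labels != STAGE_ORDER:
            raise ValidationError(f"stage order must be {STAGE_ORDER}; got {labels}")
        for s in self.stages:
            lo, hi = s.altered_count_range
            if not (0 <= lo <= hi <= self.n_cpgs):
                raise ValidationError(
                    f"stage {s.label!r}: altered range {s.altered_count_range} "
                    f"invalid for {self.n_cpgs} CpGs"
                )
            if s.beta_params is not None and (s.beta_params[0] <= 0 or s.beta_params[1] <= 0):
                raise ValidationError(f"stage {s.label!r}: Beta parameters must be positive")


def simulate_stage_dataset(
    cfg: SimStageConfig | None = None,
) -> tuple[BetaMatrix, SampleSheet, dict[str, list[str]]]:
    """Draw the staged dataset; returns (betas, sheet, altered-CpG ground truth).

    Every sample's CpGs are drawn from the baseline Beta; for non-normal
    stages an altered-CpG count is drawn uniformly on the stage's inclusive
    range, that many CpGs are chosen uniformly at random per sample, and
    their values are *replaced* by draws from the stage's Beta distribution.
    Deterministic under ``cfg.seed``.
    """
    cfg = cfg or SimStageConfig()
    rng = stream_rng(cfg.seed, "stage")
    cpg_ids = [f"cg{i:05d}" for i in range(cfg.n_cpgs)]
    a0, b0 = cfg.baseline_beta_params

    cols: dict[str, np.ndarray] = {}
    groups: list[str] = []
    truth: dict[str, list[str]] = {}
    for stage in cfg.stages:
        for r in range(stage.n_samples):
            sid = f"{stage.label}_{r:03d}"
            vals = sample_beta(a0, b0, cfg.n_cpgs, rng)
            altered: list[str] = []
            lo, hi = stage.altered_count_range
            if stage.beta_params is not None and hi > 0:
                count = int(rng.integers(lo, hi + 1))
                idx = rng.choice(cfg.n_cpgs, size=count, replace=False)
                vals[idx] = sample_beta(*stage.beta_params, count, rng)
                altered = [cpg_ids[i] for i in sorted(idx)]
            cols[sid] = vals
            groups.append(stage.label)
            truth[sid] = altered

    beta = BetaMatrix(pd.DataFrame(cols, index=cpg_ids))
    sheet = SampleSheet(pd.DataFrame({"group": groups}, index=list(cols)))
    return beta, sheet, truth


# ---------------------------------------------------------------------------
# cell-line population-doubling design
# ---------------------------------------------------------------------------

@dataclass
class CellLineSim:
    """Synthetic cell-line study: per-line baseline PD series plus pooled
    per-condition control series, and the planted mitotic CpG ids."""

    baseline: dict[str, tuple[BetaMatrix, SampleSheet]]
    controls: dict[str, tuple[BetaMatrix, SampleSheet]]
    planted: list[str]
    cpg_ids: list[str]


def simulate_cellline_pd(
    n_cpgs: int = 5000,
    n_mitotic: int = 100,
    n_lines: int = 6,
    pd_grid: Sequence[float] | None = None,
    slope_range: tuple[float, float] = (0.002, 0.004),
    noise_sd: float = 0.015,
    conditions: Sequence[str] = ("mitomycin", "serum_deprived"),
    seed: int | None = None,
) -> CellLineSim:
    """Simulate baseline PD series plus arrested/starved control series.

    Planted mitotic CpGs gain methylation linearly with population doublings
    (a per-line slope drawn from ``slope_range``) in the baseline condition
    only; all other CpGs, and all CpGs in control conditions (predictor:
    days in culture), fluctuate around a low per-CpG baseline drawn from
    U(0.05, 0.15). Control series pool all lines per condition.
    """
    if not (0 < n_mitotic <= n_cpgs):
        raise ValidationError("need 0 < n_mitotic <= n_cpgs")
    if slope_range[0] <= 0 or slope_range[1] < slope_range[0]:
        raise ValidationError("slopes must be positive with lo <= hi")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    if pd_grid is None:
        # 20 sampled passages per line, PD 3..60 — matching the order of
        # ~30 baseline arrays per cell line in serially passaged culture
        # studies of DNAm drift
        pd_grid = np.arange(3.0, 61.0, 3.0)
    pd_grid = np.asarray(pd_grid, dtype=float)
    rng = stream_rng(seed, "cellline")

    cpg_ids = [f"cg{i:05d}" for i in range(n_cpgs)]
    planted_idx = rng.choice(n_cpgs, size=n_mitotic, replace=False)
    planted = [cpg_ids[i] for i in sorted(planted_idx)]
    base_level = rng.uniform(0.05, 0.15, size=n_cpgs)

    def _series(line: str, cond: str, grid: np.ndarray, drift: bool):
        n = grid.size
        vals = base_level[:, None] + rng.normal(0.0, noise_sd, size=(n_cpgs, n))
        if drift:
            slopes = rng.uniform(*slope_range, size=n_mitotic)
            vals[planted_idx] += slopes[:, None] * grid[None, :]
        vals = np.clip(vals, 0.0, 1.0)
        sids = [f"{line}_{cond}_{j:02d}" for j in range(n)]
        beta = BetaMatrix(pd.DataFrame(vals, index=cpg_ids, columns=sids))
        meta = pd.DataFrame(
            {
                "condition": cond,
                "cell_line": line,
                "population_doublings": grid if drift else np.nan,
                "days_in_culture": grid,
            },
            index=sids,
        )
        return beta, SampleSheet(meta)

    baseline: dict[str, tuple[BetaMatrix, SampleSheet]] = {}
    for li in range(n_lines):
        line = f"line{li + 1}"
        baseline[line] = _series(line, "baseline", pd_grid, drift=True)

    controls: dict[str, tuple[BetaMatrix, SampleSheet]] = {}
    for cond in conditions:
        frames, metas = [], []
        for li in range(n_lines):
            line = f"line{li + 1}"
            b, s = _series(line, cond, pd_grid, drift=False)
            frames.append(b.values)
            metas.append(s.data)
        controls[cond] = (
            BetaMatrix(pd.concat(frames, axis=1)),
            SampleSheet(pd.concat(metas, axis=0)),
        )

    return CellLineSim(baseline, controls, planted, cpg_ids)


# ---------------------------------------------------------------------------
# in-vivo cohort design
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_samples: int = 300,
    age_range: tuple[float, float] = (20.0, 80.0),
    n_cpgs: int = 2000,
    planted_ids: Sequence[str] | None = None,
    n_planted: int = 100,
    drift_per_year: float = 0.002,
    n_cell_types: int = 12,
    fraction_concentration: float = 10.0,
    n_confounded: int = 0,
    confound_strength: float = 1.0,
    frac_age_coupling: float = 0.05,
    noise_sd: float = 0.02,
    seed: int | None = None,
    name: str = "cohort",
) -> tuple[BetaMatrix, SampleSheet, dict[str, list[str]]]:
    """Simulate an in-vivo cohort with cell-type fractions and age drift.

    Planted CpGs drift upward at ``drift_per_year`` from a low baseline.
    If ``n_confounded > 0``, the first cell type's fraction is coupled to age
    (magnitude ``frac_age_coupling`` across the age range) and that many
    decoy CpGs track the fraction with coefficient ``confound_strength`` —
    they look age-associated until fractions enter the regression as
    covariates. Fractions come from a symmetric Dirichlet and are recorded
    as ``frac_ct*`` columns in the sample sheet.

    Returns (betas, sheet, ground truth {"planted": ..., "confounded": ...}).
    """
    if noise_sd < 0 or drift_per_year < 0:
        raise ValidationError("noise_sd and drift_per_year must be nonnegative")
    rng = stream_rng(seed, f"cohort:{name}")
    cpg_ids = [f"cg{i:05d}" for i in range(n_cpgs)]
    id_set = set(cpg_ids)
    if planted_ids is None:
        if not (0 < n_planted <= n_cpgs):
            raise ValidationError("need 0 < n_planted <= n_cpgs")
        idx = rng.choice(n_cpgs, size=n_planted, replace=False)
        planted_ids = [cpg_ids[i] for i in sorted(idx)]
    else:
        missing = [c for c in planted_ids if c not in id_set]
        if missing:
            raise ValidationError(f"planted ids outside CpG set: {missing[:5]}")
    planted_pos = [cpg_ids.index(c) for c in planted_ids]

    free = [i for i in range(n_cpgs) if i not in set(planted_pos)]
    conf_pos = sorted(rng.choice(free, size=n_confounded, replace=False).tolist()) \
        if n_confounded else []

    age = rng.uniform(*age_range, size=n_samples)
    frac = rng.dirichlet(np.full(n_cell_types, fraction_concentration), size=n_samples)
    if n_confounded:
        lo, hi = age_range
        shift = frac_age_coupling * (age - (lo + hi) / 2.0) / (hi - lo)
        frac[:, 0] = np.clip(frac[:, 0] + shift, 0.0, 1.0)
        frac /= frac.sum(axis=1, keepdims=True)

    base = rng.uniform(0.05, 0.12, size=n_cpgs)
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(n_cpgs, n_samples))
    vals[planted_pos] += drift_per_year * (age[None, :] - age_range[0])
    if conf_pos:
        f0 = frac[:, 0]
        vals[conf_pos] += confound_strength * (f0 - f0.mean())[None, :]
    vals = np.clip(vals, 0.0, 1.0)

    sids = [f"{name}_{j:04d}" for j in range(n_samples)]
    frac_cols = [f"frac_ct{t + 1}" for t in range(n_cell_types)]
    meta = pd.DataFrame({"age": age}, index=sids)
    meta[frac_cols] = frac
    beta = BetaMatrix(pd.DataFrame(vals, index=cpg_ids, columns=sids))
    sheet = SampleSheet(meta, tuple(frac_cols))
    truth = {
        "planted": list(planted_ids),
        "confounded": [cpg_ids[i] for i in conf_pos],
    }
    return beta, sheet, truth


# ---------------------------------------------------------------------------
# fetal ground state + annotation helpers
# ---------------------------------------------------------------------------

def simulate_fetal_matrix(
    cpg_ids: Sequence[str],
    n_samples: int = 20,
    beta_params: tuple[float, float] = (10.0, 190.0),
    seed: int | None = None,
) -> BetaMatrix:
    """Fetal/ground-state samples for the selection pipeline.

    Emulates constitutively unmethylated promoter CpGs: every CpG draws from
    a tight low-methylation Beta (default mean 0.05, sd ~0.015), matching
    the array-background betas of truly unmethylated promoters, so the
    ground-state filter tests the window/threshold logic rather than the
    tail of the baseline distribution.
    """
    rng = stream_rng(seed, "fetal")
    vals = rng.beta(*beta_params, size=(len(cpg_ids), n_samples))
    vals = np.clip(vals, _BETA_EPS, 1.0 - _BETA_EPS)
    sids = [f"fetal_{j:03d}" for j in range(n_samples)]
    return BetaMatrix(pd.DataFrame(vals, index=list(cpg_ids), columns=sids))


def make_promoter_annotation(
    cpg_ids: Sequence[str],
    promoter_ids: Sequence[str] | None = None,
    tss_window: int = 200,
    seed: int | None = None,
) -> CpGAnnotation:
    """Synthetic annotation placing ``promoter_ids`` within the upstream TSS
    window and all other CpGs outside it."""
    rng = stream_rng(seed, "annotation")
    promoter = set(promoter_ids if promoter_ids is not None else cpg_ids)
    rows = []
    for i, c in enumerate(cpg_ids):
        if c in promoter:
            tss = -int(rng.integers(0, tss_window + 1))
        else:
            tss = int(rng.integers(tss_window + 1, 5000)) * int(rng.choice([-1, 1]))
        rows.append(
            {
                "chromosome": f"chr{(i % 22) + 1}",
                "position": 1000 + 37 * i,
                "strand": "+",
                "tss_distance": tss,
                "gene": f"GENE{i // 10}",
            }
        )
    return CpGAnnotation(pd.DataFrame(rows, index=list(cpg_ids)))
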