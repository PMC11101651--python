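import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from conftest import bh_oracle, ols_oracle
from stemtoc import (
    BetaMatrix,
    SampleSheet,
    ValidationError,
    age_association_cohort,
    bh_fdr,
    build_clock,
    pd_association,
    select_fetal_unmethylated,
    select_vitro_mit,
    select_vivo_mit,
    stouffer_meta,
)
from stemtoc.simulate import make_promoter_annotation


def _beta(vals, cpgs, samples):
    return BetaMatrix(pd.DataFrame(np.asarray(vals, float), index=cpgs, columns=samples))


class TestFetalFilter:
    def _ann(self, tss):
        rows = {
            c: {"chromosome": "chr1", "position": 100 + i, "strand": "+", "tss_distance": d}
            for i, (c, d) in enumerate(tss.items())
        }
        from stemtoc import CpGAnnotation

        return CpGAnnotation(pd.DataFrame.from_dict(rows, orient="index"))

    def test_window_and_threshold_rules(self):
        m = _beta(
            [[0.19, 0.15], [0.21, 0.05], [0.10, 0.10], [0.05, np.nan]],
            ["in_ok", "in_high", "out_window", "in_missing"],
            ["f1", "f2"],
        )
        ann = self._ann({"in_ok": -150, "in_high": -150, "out_window": -250, "in_missing": -10})
        assert select_fetal_unmethylated(m, ann) == ["in_ok"]

    def test_threshold_is_strict(self):
        m = _beta([[0.2, 0.1]], ["cgA"], ["f1", "f2"])
        ann = self._ann({"cgA": -100})
        assert select_fetal_unmethylated(m, ann) == []

    def test_symmetric_window_admits_downstream(self):
        m = _beta([[0.1], [0.1]], ["up", "down"], ["f1"])
        ann = self._ann({"up": -150, "down": 150})
        assert select_fetal_unmethylated(m, ann) == ["up"]
        both = select_fetal_unmethylated(m, ann, symmetric_window=True)
        assert both == ["up", "down"]

    def test_no_annotation_overlap_errors(self):
        m = _beta([[0.1]], ["cgA"], ["f1"])
        ann = self._ann({"cgZ": -10})
        with pytest.raises(ValidationError, match="shared"):
            select_fetal_unmethylated(m, ann)


class TestPdAssociation:
    def test_noiseless_fit_recovers_slope_with_zero_p(self, pd_sheet):
        pds = pd_sheet.column("population_doublings").to_numpy()
        m = _beta([0.1 + 0.001 * pds], ["cgA"], pd_sheet.sample_ids)
        rec = pd_association(m, pd_sheet)
        assert rec.loc[0, "slope"] == pytest.approx(0.001, abs=1e-12)
        assert rec.loc[0, "p"] < 1e-12

    def test_constant_beta_reports_zero_slope_p_one(self, pd_sheet):
        m = _beta([np.full(6, 0.3)], ["cgA"], pd_sheet.sample_ids)
        rec = pd_association(m, pd_sheet)
        assert rec.loc[0, "slope"] == 0.0
        assert rec.loc[0, "p"] == 1.0

    def test_matches_closed_form_ols_oracle(self, pd_sheet, rng):
        pds = pd_sheet.column("population_doublings").to_numpy()
        y = np.clip(0.1 + 0.002 * pds + rng.normal(0, 0.01, 6), 0, 1)
        rec = pd_association(_beta([y], ["cgA"], pd_sheet.sample_ids), pd_sheet)
        slope, se, t = ols_oracle(pds, y)
        assert rec.loc[0, "slope"] == pytest.approx(slope, abs=1e-10)
        assert rec.loc[0, "se"] == pytest.approx(se, abs=1e-10)
        assert rec.loc[0, "p"] == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-10)

    def test_slope_estimate_within_3_se_of_truth(self, rng):
        pds = np.linspace(0, 100, 30)
        sheet = SampleSheet(pd.DataFrame({"population_doublings": pds},
                                         index=[f"s{j}" for j in range(30)]))
        y = np.clip(0.1 + 0.002 * pds + rng.normal(0, 0.01, 30), 0, 1)
        rec = pd_association(_beta([y], ["cgA"], sheet.sample_ids), sheet)
        assert abs(rec.loc[0, "slope"] - 0.002) < 3 * rec.loc[0, "se"]

    def test_zero_predictor_variance_errors(self):
        sheet = SampleSheet(pd.DataFrame({"population_doublings": [5.0, 5.0, 5.0]},
                                         index=["a", "b", "c"]))
        m = _beta([[0.1, 0.2, 0.3]], ["cgA"], ["a", "b", "c"])
        with pytest.raises((ValidationError, ValueError), match="variance"):
            pd_association(m, sheet)


class TestBhFdr:
    def test_known_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            bh_fdr([])

    @settings(derandomize=True, max_examples=50)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=60))
    def test_matches_cumulative_min_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-10)

    @settings(derandomize=True, max_examples=30)
    @given(hst.lists(hst.floats(0, 1), min_size=2, max_size=30), hst.randoms())
    def test_min_q_ge_min_p_and_permutation_equivariant(self, p, rnd):
        q = bh_fdr(p)
        assert q.min() >= min(p) - 1e-12
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = bh_fdr([p[i] for i in perm])
        np.testing.assert_allclose(q_perm, [q[i] for i in perm], atol=1e-12)


def _run(cpgs, slope, p, q=None):
    df = pd.DataFrame({"cpg_id": cpgs, "slope": slope, "se": 0.1,
                       "t": 1.0, "p": p, "n": 10})
    if q is not None:
        df["q"] = q
    return df


class TestVitroSelection:
    def test_kept_when_significant_everywhere_and_controls_null(self):
        base = {f"l{i}": _run(["cgA"], [0.01], [0.001], [0.01]) for i in range(6)}
        ctrl = {"mitomycin": _run(["cgA"], [0.01], [0.2])}
        assert select_vitro_mit(base, ctrl) == ["cgA"]

    def test_dropped_when_hypermethylated_in_a_control(self):
        base = {f"l{i}": _run(["cgA"], [0.01], [0.001], [0.01]) for i in range(6)}
        ctrl = {"mitomycin": _run(["cgA"], [0.02], [0.01])}
        assert select_vitro_mit(base, ctrl) == []

    def test_dropped_when_one_baseline_misses_q_threshold(self):
        base = {f"l{i}": _run(["cgA"], [0.01], [0.001], [0.01]) for i in range(5)}
        base["l5"] = _run(["cgA"], [0.01], [0.03], [0.06])
        assert select_vitro_mit(base, {}) == []

    def test_negative_control_slope_does_not_drop(self):
        base = {"l0": _run(["cgA"], [0.01], [0.001], [0.01])}
        ctrl = {"serum_deprived": _run(["cgA"], [-0.02], [0.001])}
        assert select_vitro_mit(base, ctrl) == ["cgA"]

    def test_cpg_absent_from_control_retained_with_warning(self):
        base = {"l0": _run(["cgA"], [0.01], [0.001], [0.01])}
        ctrl = {"mitomycin": _run(["cgB"], [0.0], [0.9])}
        with pytest.warns(UserWarning, match="absent"):
            assert select_vitro_mit(base, ctrl) == ["cgA"]


class TestAgeAssociation:
    def _sheet(self, age, covs):
        df = pd.DataFrame({"age": age}, index=[f"s{j}" for j in range(len(age))])
        for name, vals in covs.items():
            df[name] = vals
        return SampleSheet(df)

    def test_exact_age_effect_with_noise_covariates(self, rng):
        age = np.linspace(20, 70, 40)
        covs = {f"c{i}": rng.normal(size=40) for i in range(3)}
        sheet = self._sheet(age, covs)
        m = _beta([0.1 + 0.002 * age], ["cgA"], sheet.sample_ids)
        rec = age_association_cohort(m, sheet, list(covs))
        assert rec.loc[0, "slope"] == pytest.approx(0.002, abs=1e-10)
        assert rec.loc[0, "p"] < 1e-10

    def test_adjustment_shrinks_fraction_driven_signal(self, rng):
        n = 120
        age = rng.uniform(20, 80, n)
        frac = 0.5 + 0.004 * (age - 50) + rng.normal(0, 0.05, n)
        y = np.clip(0.1 + 0.5 * (frac - 0.5) + rng.normal(0, 0.02, n), 0, 1)
        sheet = self._sheet(age, {"frac": frac})
        m = _beta([y], ["cgA"], sheet.sample_ids)
        unadj = age_association_cohort(m, sheet, [])
        adj = age_association_cohort(m, sheet, ["frac"])
        assert abs(adj.loc[0, "slope"]) < abs(unadj.loc[0, "slope"])

    def test_matches_normal_equations_oracle(self, rng):
        n, k = 50, 12
        age = rng.uniform(20, 80, n)
        C = rng.normal(size=(n, k))
        sheet = self._sheet(age, {f"c{i}": C[:, i] for i in range(k)})
        Y = rng.uniform(0.1, 0.9, size=(5, n))
        m = _beta(Y, [f"cg{i}" for i in range(5)], sheet.sample_ids)
        rec = age_association_cohort(m, sheet, [f"c{i}" for i in range(k)])
        X = np.column_stack([np.ones(n), age, C])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ Y.T)
        np.testing.assert_allclose(rec["slope"].to_numpy(), beta_hat[1], atol=1e-8)

    def test_fractions_summing_to_one_drop_last_with_warning(self, rng):
        n = 30
        age = np.linspace(20, 80, n)
        f1 = rng.uniform(0.2, 0.6, n)
        covs = {"f1": f1, "f2": 1.0 - f1}
        sheet = self._sheet(age, covs)
        m = _beta([np.full(n, 0.3)], ["cgA"], sheet.sample_ids)
        with pytest.warns(UserWarning, match="dropping"):
            rec = age_association_cohort(m, sheet, ["f1", "f2"])
        assert len(rec) == 1

    def test_collinear_design_errors_naming_columns(self, rng):
        n = 30
        age = np.linspace(20, 80, n)
        covs = {"c1": age * 2.0}
        sheet = self._sheet(age, covs)
        m = _beta([np.full(n, 0.3)], ["cgA"], sheet.sample_ids)
        with pytest.raises(ValidationError, match="aliased"):
            age_association_cohort(m, sheet, ["c1"])


class TestStoufferMeta:
    def test_single_cohort_identity(self):
        p1 = 2 * stats.norm.sf(2.0)
        meta = stouffer_meta([_run(["cgA"], [0.01], [p1])])
        assert meta.loc[0, "stouffer_z"] == pytest.approx(2.0, abs=1e-10)

    def test_three_equal_cohorts_arithmetic(self):
        p = 2 * stats.norm.sf(1.96)
        meta = stouffer_meta([_run(["cgA"], [0.01], [p])] * 3)
        assert meta.loc[0, "stouffer_z"] == pytest.approx(3 * 1.96 / np.sqrt(3), abs=1e-9)
        expect_p = 2 * stats.norm.sf(3 * 1.96 / np.sqrt(3))
        assert meta.loc[0, "p"] == pytest.approx(expect_p, abs=1e-12)

    def test_opposite_signs_cancel(self):
        p = 0.01
        meta = stouffer_meta([_run(["cgA"], [0.02], [p]), _run(["cgA"], [-0.02], [p])])
        assert meta.loc[0, "stouffer_z"] == pytest.approx(0.0, abs=1e-12)
        assert meta.loc[0, "p"] == pytest.approx(1.0)

    def test_zero_p_clamped_not_infinite(self):
        meta = stouffer_meta([_run(["cgA"], [0.01], [0.0])])
        assert np.isfinite(meta.loc[0, "stouffer_z"])

    def test_meta_p_consistent_with_z(self, rng):
        recs = [_run([f"cg{i}" for i in range(20)], rng.normal(size=20),
                     rng.uniform(0.001, 1, 20)) for _ in range(3)]
        meta = stouffer_meta(recs)
        expect = 2 * stats.norm.sf(np.abs(meta["stouffer_z"]))
        np.testing.assert_allclose(meta["p"], expect, atol=1e-12)


class TestVivoSelectionAndClock:
    def test_threshold_rules(self):
        meta = pd.DataFrame(
            {"cpg_id": ["a", "b", "c"], "stouffer_z": [3.0, -3.0, 1.0],
             "p": [0.002, 0.002, 0.32], "n_cohorts": 3}
        )
        assert select_vivo_mit(meta) == ["a"]

    def test_build_clock_defaults_to_95_quantile(self):
        clock = build_clock([f"cg{i}" for i in range(371)])
        assert clock.method == "upper_quantile"
        assert clock.quantile_q == 0.95
        assert clock.n_cpgs == 371

    def test_single_cpg_clock_scores_its_beta(self):
        from stemtoc import score_mean, score_upper_quantile

        m = _beta([[0.42]], ["cgA"], ["s1"])
        uq = build_clock(["cgA"], name="uq")
        mean = build_clock(["cgA"], method="mean", name="mean")
        assert score_upper_quantile(m, uq)["score"].iloc[0] == pytest.approx(0.42)
        assert score_mean(m, mean)["score"].iloc[0] == pytest.approx(0.42)
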