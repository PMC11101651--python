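import numpy as np
import pandas as pd
import pytest

from conftest import auc_oracle, ranksum_exact_oracle
from stemtoc import (
    SampleSheet,
    ValidationError,
    age_adjust,
    auc,
    compare_clocks,
    compute_rir,
    compute_tnsc,
    correlate,
    multivariate_assoc,
    wilcoxon_group_test,
)


class TestCorrelate:
    def test_perfect_linear_relationship(self, rng):
        x = rng.uniform(0, 10, 20)
        res = correlate(x, 2 * x + 1)
        assert res.pcc == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_negative_slope(self):
        x = np.arange(10.0)
        assert correlate(x, -x).pcc == pytest.approx(-1.0)

    def test_matches_covariance_and_rank_oracles(self, rng):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        res = correlate(x, y)
        pcc = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert res.pcc == pytest.approx(pcc, abs=1e-12)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        scc = np.cov(rx, ry, ddof=1)[0, 1] / (np.std(rx, ddof=1) * np.std(ry, ddof=1))
        assert res.scc == pytest.approx(scc, abs=1e-12)

    def test_affine_invariance_up_to_sign(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = correlate(x, y)
        shifted = correlate(3 * x + 7, y)
        flipped = correlate(-x, y)
        assert shifted.pcc == pytest.approx(base.pcc, abs=1e-12)
        assert flipped.pcc == pytest.approx(-base.pcc, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValidationError, match="variance"):
            correlate([1, 1, 1], [1, 2, 3])


class TestMultivariateAssoc:
    def test_pure_age_signal_with_noise_covariate(self, rng):
        age = np.linspace(20, 80, 60)
        design = pd.DataFrame({"age": age, "frac": rng.normal(size=60)})
        tab = multivariate_assoc(0.01 * age, design).set_index("term")
        assert tab.loc["age", "coef"] == pytest.approx(0.01, abs=1e-10)
        assert tab.loc["frac", "p"] > 0.05

    def test_fraction_driven_score_null_after_adjustment(self, rng):
        n = 200
        age = rng.uniform(20, 80, n)
        frac = 0.5 + 0.004 * (age - 50) + rng.normal(0, 0.05, n)
        y = 0.5 * frac + rng.normal(0, 0.01, n)
        adj = multivariate_assoc(y, pd.DataFrame({"age": age, "frac": frac}))
        unadj = multivariate_assoc(y, pd.DataFrame({"age": age}))
        adj_age = adj.set_index("term").loc["age"]
        unadj_age = unadj.set_index("term").loc["age"]
        assert unadj_age["p"] < 0.01
        assert abs(adj_age["coef"]) < abs(unadj_age["coef"])

    def test_matches_normal_equations_oracle(self, rng):
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["age", "a", "b"])
        y = rng.normal(size=n)
        tab = multivariate_assoc(y, X)
        M = np.column_stack([np.ones(n), X.to_numpy()])
        expect = np.linalg.solve(M.T @ M, M.T @ y)
        np.testing.assert_allclose(tab["coef"].to_numpy(), expect, atol=1e-8)

    def test_categorical_dummy_expansion(self, rng):
        n = 90
        smoking = np.array(["never", "ex", "current"] * (n // 3))
        age = rng.uniform(20, 80, n)
        y = 0.005 * age + 0.1 * (smoking == "current")
        tab = multivariate_assoc(y, pd.DataFrame({"age": age, "smoking": smoking}))
        terms = set(tab["term"])
        assert {"smoking_ex", "smoking_never"} <= terms or {
            "smoking_current", "smoking_never"} <= terms

    def test_rank_deficiency_names_aliased_column(self, rng):
        age = np.linspace(20, 80, 30)
        design = pd.DataFrame({"age": age, "twice_age": 2 * age})
        with pytest.raises(ValidationError, match="aliased"):
            multivariate_assoc(rng.normal(size=30), design)


class TestTnscRir:
    def _sheet(self):
        return SampleSheet(
            pd.DataFrame(
                {"age": [50.0, 20.0], "tissue": ["colon", "lung"]},
                index=["s1", "s2"],
            )
        )

    def test_tnsc_is_rate_times_age(self):
        rates = {"colon": 10.0, "lung": 0.5}
        tnsc = compute_tnsc(rates, self._sheet())
        assert tnsc.loc["s1"] == pytest.approx(500.0)
        assert tnsc.loc["s2"] == pytest.approx(10.0)

    def test_age_zero_gives_zero_and_log2_requires_positive(self):
        sheet = SampleSheet(pd.DataFrame({"age": [0.0], "tissue": ["colon"]}, index=["s1"]))
        assert compute_tnsc({"colon": 10.0}, sheet).loc["s1"] == 0.0
        with pytest.raises(ValidationError, match="log2"):
            compute_tnsc({"colon": 10.0}, sheet, log2=True)

    def test_missing_tissue_listed(self):
        with pytest.raises(ValidationError, match="lung"):
            compute_tnsc({"colon": 10.0}, self._sheet())

    def test_rir_median_ratio_times_ten(self):
        assert compute_rir([0.2, 0.4], [40.0, 80.0]) == pytest.approx(0.05)
        assert compute_rir([0.5], [50.0]) == pytest.approx(0.1)

    def test_rir_permutation_invariant_and_positive_ages_required(self, rng):
        s = rng.uniform(0, 1, 9)
        a = rng.uniform(20, 80, 9)
        perm = rng.permutation(9)
        assert compute_rir(s, a) == pytest.approx(compute_rir(s[perm], a[perm]))
        with pytest.raises(ValidationError, match="positive"):
            compute_rir([0.1], [0.0])

    def test_age_adjust_per_decade(self):
        np.testing.assert_allclose(age_adjust([0.5], [50.0]), [0.1])


class TestAuc:
    def test_perfect_separation_and_ties(self):
        assert auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
        assert auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_matches_pairwise_enumeration_oracle(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 10, size=30).astype(float)  # force ties
            labels = rng.integers(0, 2, size=30).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels) == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12
            )

    def test_complement_identity_without_ties(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_one_class_empty_errors(self):
        with pytest.raises(ValidationError):
            auc([1.0, 2.0], [1, 1])


class TestWilcoxonGroupTest:
    def test_exact_small_sample_value(self):
        # b fully above a: one-tailed p = 1/C(6,3) = 1/20
        assert wilcoxon_group_test([4, 5, 6], [1, 2, 3], "greater") == pytest.approx(0.05)

    def test_identical_groups_not_significant(self):
        p = wilcoxon_group_test([1, 2, 3, 4], [1, 2, 3, 4], "greater")
        assert p >= 0.5

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.permutation(12)[:5].astype(float)
            b = np.setdiff1d(np.arange(12), a)[:5].astype(float) + 0.5
            p = wilcoxon_group_test(a, b, "greater", method="exact")
            assert p == pytest.approx(ranksum_exact_oracle(a, b), abs=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            wilcoxon_group_test([], [1.0])


class TestCompareClocks:
    def _matrix(self, a, b, name_a="A", name_b="B"):
        return pd.DataFrame([a, b], index=[name_a, name_b],
                            columns=[f"d{i}" for i in range(len(a))])

    def test_uniform_dominance_over_nine_datasets(self):
        a = np.linspace(0.8, 0.9, 9)
        res = compare_clocks(self._matrix(a, a - 0.1))
        assert res.p_values.loc["A", "B"] == pytest.approx(1 / 512)
        assert np.isnan(res.p_values.loc["A", "A"])

    def test_identical_clocks_give_p_one(self):
        a = np.linspace(0.5, 0.9, 6)
        res = compare_clocks(self._matrix(a, a))
        assert res.p_values.loc["A", "B"] == 1.0

    def test_antisymmetry_on_dominating_data(self):
        a = np.linspace(0.8, 0.9, 9)
        res = compare_clocks(self._matrix(a, a - 0.1))
        assert res.p_values.loc["A", "B"] < 0.01
        assert res.p_values.loc["B", "A"] > 0.99

    def test_nans_dropped_pairwise_with_warning_when_too_few(self):
        m = self._matrix([0.8, np.nan, np.nan], [0.7, np.nan, np.nan])
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = compare_clocks(m)
        assert np.isnan(res.p_values.loc["A", "B"])

    def test_requires_two_clocks_and_datasets(self):
        with pytest.raises(ValidationError):
            compare_clocks(pd.DataFrame([[0.5, 0.6]], index=["A"], columns=["d0", "d1"]))
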