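"""Statistical battery: identities, closed forms, calibration at small scale,
and reductions of the stepwise procedure."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as hst

from femcurve import (
    compare_groups,
    ks_normality,
    make_cohort_table,
    pearson_matrix,
    sample_size_two_means,
    stepwise_regression,
    vif,
)
from femcurve.errors import InputError, ParameterError


class TestKsNormality:
    def test_constant_sequence_flags_degenerate(self):
        r = ks_normality(np.full(20, 3.0))
        assert r.degenerate and r.p_value == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(InputError):
            ks_normality(np.arange(5.0))

    def test_type_one_error_calibrated(self):
        """Rejection rate under the normal null is ~alpha (200 replicates;
        the full 2000-replicate check runs in the acceptance suite)."""
        rng = np.random.default_rng(1)
        rej = sum(
            ks_normality(rng.standard_normal(100), n_mc=4000, seed=0).p_value
            <= 0.05
            for _ in range(200)
        )
        assert 0.02 <= rej / 200 <= 0.09

    def test_power_against_exponential(self):
        rng = np.random.default_rng(2)
        rej = sum(
            ks_normality(rng.exponential(size=500), n_mc=4000, seed=0).p_value
            <= 0.05
            for _ in range(50)
        )
        assert rej == 50

    def test_asymptotic_p_is_anticonservative_relative_to_mc(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        r = ks_normality(x, seed=0)
        assert r.extra["p_asymptotic"] >= r.p_value


class TestCompareGroups:
    def test_identical_sequences_paired(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = compare_groups(x, x, "paired_t")
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_constant_shift_paired_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = compare_groups(x, x + 1.0, "paired_t")
        assert r.degenerate and r.p_value == 0.0 and r.statistic == -math.inf

    def test_pooled_t_matches_hand_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 40)
        r = compare_groups(x, y, "independent_t")
        sp = math.sqrt(
            ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
            / (len(x) + len(y) - 2)
        )
        t_hand = (x.mean() - y.mean()) / (sp * math.hypot(1 / math.sqrt(len(x)), 1 / math.sqrt(len(y))))
        assert r.statistic == pytest.approx(t_hand, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hst.integers(0, 10**6))
    def test_swap_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 15), rng.normal(0.3, 2, 18)
        for mode in ("independent_t", "mann_whitney"):
            a = compare_groups(x, y, mode)
            b = compare_groups(y, x, mode)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
            if mode == "independent_t":
                assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(InputError):
            compare_groups([1.0], [2.0, 3.0], "independent_t")
        with pytest.raises(InputError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0], "paired_t")
        with pytest.raises(ParameterError):
            compare_groups([1.0, 2.0], [1.0, 2.0], "anova")


class TestPearsonMatrix:
    def test_hand_value_five_points(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        cm = pearson_matrix(df, ["x", "y"])
        assert cm.r.loc["x", "y"] == pytest.approx(0.8)

    def test_perfect_correlation(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df.x
        cm = pearson_matrix(df, ["x", "y"])
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert cm.p.loc["x", "y"] < 1e-10

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        base = pearson_matrix(df, ["a", "b", "c"]).r.to_numpy()
        df2 = df * np.array([3.0, -2.0, 0.5]) + np.array([1.0, 7.0, -4.0])
        scaled = pearson_matrix(df2, ["a", "b", "c"]).r.to_numpy()
        signs = np.sign([3.0, -2.0, 0.5])
        assert np.allclose(scaled, base * np.outer(signs, signs), atol=1e-12)

    def test_combined_layout_r_above_p_below(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        cm = pearson_matrix(df, ["a", "b"])
        comb = cm.combined
        assert comb.loc["a", "b"] == cm.r.loc["a", "b"]
        assert comb.loc["b", "a"] == cm.p.loc["a", "b"]
        assert comb.loc["a", "a"] == 1.0

    def test_cohort_height_length_correlation(self):
        t = make_cohort_table(426, seed=8)
        cm = pearson_matrix(t, ["height_m", "length_mm"])
        assert cm.r.loc["height_m", "length_mm"] == pytest.approx(0.85, abs=0.04)


class TestStepwise:
    def test_pure_noise_candidate_rarely_enters(self):
        hits = 0
        for s in range(60):
            rng = np.random.default_rng(300 + s)
            df = pd.DataFrame(
                {"x": rng.normal(size=200), "y": rng.normal(size=200)}
            )
            m = stepwise_regression(df, "y", ["x"])
            hits += len(m.terms) == 0
        assert hits / 60 >= 0.90 - 0.07

    def test_recovers_printed_equation_structure(self):
        # residual sd 100: recovery-design noise (weakest term |t| ~ 4.5);
        # at the cohort-default sd the weakest term has ~60% selection power
        t = make_cohort_table(213, seed=77, noise_sd={"rfc_mm": 100.0})
        m = stepwise_regression(
            t, "rfc_mm",
            ["length_mm", "banking_deg", "gender", "laterality",
             "age_y", "height_m", "weight_kg"],
        )
        assert {"length_mm", "banking_deg", "gender"} <= set(m.terms)
        lo, hi = m.conf_int["length_mm"]
        assert lo <= 2.23 <= hi

    def test_reduces_to_full_ols_when_thresholds_open(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
        df["y"] = df.a - df.b + rng.normal(size=80)
        m = stepwise_regression(df, "y", ["a", "b", "c"],
                                p_enter=1.0, p_remove=1.000001)
        assert set(m.terms) == {"a", "b", "c"}
        full = sm.OLS(df.y, sm.add_constant(df[m.terms])).fit()
        for term in m.terms:
            assert m.coefficients[term] == pytest.approx(full.params[term])

    def test_reduces_to_intercept_only_when_closed(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "y"])
        m = stepwise_regression(df, "y", ["a"], p_enter=0.0)
        assert m.terms == [] and m.r_squared == 0.0
        assert m.coefficients["intercept"] == pytest.approx(df.y.mean())

    def test_agrees_with_exhaustive_subset_oracle(self):
        """On strong-signal candidates the greedy stepwise path reaches the
        global optimum of its own selection criterion: the best subset over
        all 2^4 candidate sets under RSS penalized by the F entry threshold
        (alpha = 0.05) per parameter."""
        import scipy.stats as st
        from itertools import combinations

        agree = 0
        n_rep = 30
        for s in range(n_rep):
            rng = np.random.default_rng(500 + s)
            X = pd.DataFrame(
                rng.normal(size=(300, 4)), columns=["a", "b", "c", "d"]
            )
            y = 1.0 * X.a - 0.8 * X.b + 0.6 * X.c + rng.normal(size=300)
            df = X.assign(y=y)
            m = stepwise_regression(df, "y", ["a", "b", "c", "d"])
            n = len(df)
            best, best_score = None, np.inf
            for k in range(5):
                for sub in combinations(["a", "b", "c", "d"], k):
                    exog = sm.add_constant(df[list(sub)], has_constant="add")
                    rss = float(sm.OLS(df.y, exog).fit().ssr)
                    fcrit = st.f.ppf(0.95, 1, n - k - 1)
                    score = n * math.log(rss / n) + fcrit * k
                    if score < best_score:
                        best, best_score = set(sub), score
            agree += set(m.terms) == best
        assert agree / n_rep >= 0.95 - 0.07

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": np.arange(5.0), "y": np.arange(5.0)})
        with pytest.raises(InputError):
            stepwise_regression(df, "y", ["a"])


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 400
        t = np.arange(n)
        df = pd.DataFrame(
            {
                "a": np.sin(2 * np.pi * t / n),
                "b": np.cos(2 * np.pi * t / n),
            }
        )
        v = vif(df, ["a", "b"])
        assert v["a"] == pytest.approx(1.0, abs=0.01)

    def test_duplicate_column_infinite(self):
        df = pd.DataFrame({"a": np.arange(20.0)})
        df["b"] = df.a
        v = vif(df, ["a", "b"])
        assert math.isinf(v["a"]) and math.isinf(v["b"])

    def test_closed_form_at_known_correlation(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=500)
        b = 0.9 * a + math.sqrt(1 - 0.81) * rng.normal(size=500)
        v = vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert v["a"] == pytest.approx(1.0 / (1.0 - 0.81), abs=0.5)


class TestSampleSize:
    def test_study_design_values(self):
        """sd 20, difference 10, alpha 5%, power 80%: 63 by the normal
        approximation, 64 after t refinement."""
        ss = sample_size_two_means(0.05, 0.80, 20.0, 10.0)
        assert ss.normal == 63
        assert ss.t_refined == 64
        # independent oracle
        from statsmodels.stats.power import TTestIndPower

        n_oracle = TTestIndPower().solve_power(
            effect_size=0.5, power=0.80, alpha=0.05
        )
        assert ss.t_refined == math.ceil(n_oracle)

    def test_floor_at_two_for_huge_effects(self):
        ss = sample_size_two_means(0.05, 0.80, 20.0, 200.0)
        assert ss.n == 2

    def test_domain_validation(self):
        with pytest.raises(ParameterError):
            sample_size_two_means(alpha=1.0)
        with pytest.raises(ParameterError):
            sample_size_two_means(power=0.0)
        with pytest.raises(ParameterError):
            sample_size_two_means(sd=-1.0)
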