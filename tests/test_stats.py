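import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from rsikit import (combined_model, compare_groups, delong_test,
                    generate_cohort_table, multivariate_lr, roc_analysis,
                    run_full_analysis, univariate_lr)
from rsikit.stats import _design


def frame(pos, neg, name="x"):
    return pd.DataFrame({name: np.concatenate([pos, neg]),
                         "lnm": [1] * len(pos) + [0] * len(neg)})


def mann_whitney_permutation_p(pos, neg):
    """Exhaustive two-sided permutation p for the U statistic."""
    pooled = np.concatenate([pos, neg])
    n1 = len(pos)

    def u_stat(a, b):
        return float(np.sum((a[:, None] > b[None, :])
                            + 0.5 * (a[:, None] == b[None, :])))

    observed = u_stat(np.asarray(pos, float), np.asarray(neg, float))
    center = n1 * len(neg) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        if abs(u - center) >= abs(observed - center) - 1e-12:
            count += 1
        total += 1
    return count / total


def logit_oracle(y, X):
    """Independent optimizer: minimize the logistic negative log-likelihood
    (with intercept) by BFGS with analytic gradient, run to high precision."""
    Xd = np.column_stack([np.ones(len(y)), X])

    def nll(beta):
        eta = Xd @ beta
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
        return Xd.T @ (p - y)

    res = minimize(nll, np.zeros(Xd.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x[1:]


class TestCompareGroups:
    def test_forced_mann_whitney_exact_small_sample(self):
        """{1,2} vs {3,4}: the exact two-sided p enumerates all C(4,2)=6
        labelings, two of which are as extreme -> p = 1/3."""
        df = frame([1.0, 2.0], [3.0, 4.0])
        r = compare_groups(df, "x", force="mann_whitney")
        assert r.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert r.test == "mann_whitney"

    def test_identical_categorical_groups(self):
        df = pd.DataFrame({"sex": ["male"] * 10 + ["female"] * 10
                           + ["male"] * 10 + ["female"] * 10,
                           "lnm": [1] * 20 + [0] * 20})
        r = compare_groups(df, "sex")
        assert r.test == "chi_square"
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_normality_gate_selects_test(self, rng):
        normal = frame(rng.normal(5, 1, 40), rng.normal(6, 1, 40))
        assert compare_groups(normal, "x").test == "t"
        skewed = frame(rng.lognormal(0, 1.2, 60), rng.lognormal(0.5, 1.2, 60))
        assert compare_groups(skewed, "x").test == "mann_whitney"

    def test_expected_count_guard_uses_fisher(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 1 + ["a"] * 1 + ["b"] * 3,
                           "lnm": [1] * 4 + [0] * 4})
        assert compare_groups(df, "g").test == "fisher"

    def test_constant_variable_rejected(self):
        df = frame(np.ones(10), np.ones(12))
        with pytest.raises(ValueError):
            compare_groups(df, "x")

    def test_tiny_groups_rejected_by_gate(self):
        df = frame([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            compare_groups(df, "x")

    @pytest.mark.parametrize("n1, n2", [(2, 2), (3, 3), (3, 4), (4, 4)])
    def test_mann_whitney_matches_exhaustive_permutation(self, n1, n2, rng):
        pos = rng.normal(0, 1, n1)
        neg = rng.normal(0.5, 1, n2)
        r = compare_groups(frame(pos, neg), "x", force="mann_whitney")
        assert r.p_value == pytest.approx(
            mann_whitney_permutation_p(pos, neg), abs=1e-9)


class TestLogisticRegression:
    @pytest.fixture(scope="class")
    def fixed_cohort(self):
        rng = np.random.default_rng(77)
        n = 20
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        eta = 0.3 + 1.2 * x1 - 0.8 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return pd.DataFrame({"x1": x1, "x2": x2, "lnm": y})

    def test_univariate_matches_independent_optimizer(self, fixed_cohort):
        res = univariate_lr(fixed_cohort, "x1")
        X = _design(fixed_cohort, ["x1"]).to_numpy()
        oracle = logit_oracle(fixed_cohort["lnm"].to_numpy(), X)
        assert res.table["coef"].iloc[0] == pytest.approx(oracle[0], abs=1e-6)

    def test_multivariate_matches_independent_optimizer(self, fixed_cohort):
        res = multivariate_lr(fixed_cohort, variables=["x1", "x2"])
        X = _design(fixed_cohort, ["x1", "x2"]).to_numpy()
        oracle = logit_oracle(fixed_cohort["lnm"].to_numpy(), X)
        assert res.table["coef"].to_numpy() == pytest.approx(oracle, abs=1e-6)

    def test_null_predictor_or_near_one(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 1, 500),
                           "lnm": rng.permutation([1] * 250 + [0] * 250)})
        res = univariate_lr(df, "x")
        assert 0.85 <= res.table["or_"].iloc[0] <= 1.18

    def test_antitone_predictor_gives_or_below_one(self):
        df = frame(np.array([1.0, 2.0, 3.0, 4.0, 2.5]),
                   np.array([3.5, 4.0, 5.0, 6.0, 4.5]))
        res = univariate_lr(df, "x")
        assert res.table["or_"].iloc[0] < 1.0

    def test_or_per_sd_invariant_to_rescaling(self, fixed_cohort):
        base = univariate_lr(fixed_cohort, "x1").table["or_"].iloc[0]
        rescaled = fixed_cohort.assign(x1=fixed_cohort["x1"] * 1e3 + 42.0)
        assert univariate_lr(rescaled, "x1").table["or_"].iloc[0] == \
            pytest.approx(base, rel=1e-8)

    def test_complete_separation_flagged(self):
        df = frame(np.arange(10.0, 20.0), np.arange(0.0, 10.0))
        res = univariate_lr(df, "x")
        assert res.separation and not res.converged and res.table.empty

    def test_ci_brackets_or(self, fixed_cohort):
        res = univariate_lr(fixed_cohort, "x1")
        row = res.table.iloc[0]
        assert row["ci_low"] <= row["or_"] <= row["ci_high"]
        assert row["or_"] > 0

    def test_single_selected_variable_equals_univariate(self, rng):
        df = pd.DataFrame({
            "strong": np.concatenate([rng.normal(1, 1, 40),
                                      rng.normal(0, 1, 40)]),
            "noise": rng.normal(0, 1, 80),
            "lnm": [1] * 40 + [0] * 40})
        multi = multivariate_lr(df, candidates=["strong", "noise"])
        uni = univariate_lr(df, "strong")
        assert multi.variables == ("strong",)
        assert multi.table["coef"].iloc[0] == pytest.approx(
            uni.table["coef"].iloc[0], abs=1e-10)

    def test_duplicated_predictors_flag_collinearity(self, fixed_cohort):
        df = fixed_cohort.assign(x1_copy=fixed_cohort["x1"])
        res = multivariate_lr(df, variables=["x1", "x1_copy"])
        assert res.collinear and not res.converged


class TestRoc:
    def test_pairwise_counting_example(self):
        df = frame([1.0, 2.0, 3.0], [0.0, 1.5, 2.5])
        r = roc_analysis(df, "x")
        assert r.auc == pytest.approx(6.0 / 9.0)

    def test_perfect_separation(self):
        df = frame([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        r = roc_analysis(df, "x")
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 3.0 < r.cutoff <= 5.0

    def test_sign_flip_symmetry(self, rng):
        df = frame(rng.normal(1, 1, 30), rng.normal(0, 1, 40))
        a = roc_analysis(df, "x").auc
        flipped = roc_analysis(df.assign(x=-df["x"]), "x").auc
        assert a + flipped == pytest.approx(1.0, abs=1e-12)

    def test_auc_equals_scaled_u_statistic(self, rng):
        """Exact identity with the Mann-Whitney U (ties included)."""
        for trial in range(5):
            pos = np.round(rng.normal(1, 1, 25), 1)   # rounding makes ties
            neg = np.round(rng.normal(0, 1, 35), 1)
            r = roc_analysis(frame(pos, neg), "x")
            u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert r.auc == pytest.approx(u / (len(pos) * len(neg)),
                                          abs=1e-12)

    def test_youden_ties_resolve_to_lowest_cutoff(self):
        # J is maximal (=1) at cutoffs 10 and 20; lowest wins
        df = frame([10.0, 20.0], [1.0, 2.0])
        r = roc_analysis(df, "x")
        assert r.cutoff == 10.0

    def test_auto_direction(self, rng):
        df = frame(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        r = roc_analysis(df, "x", direction="auto")
        assert r.direction == "<"
        assert r.auc >= 0.5

    def test_one_class_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "lnm": [1, 1]})
        with pytest.raises(ValueError):
            roc_analysis(df, "x")

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for i, n in enumerate((20, 80, 320)):
            df = generate_cohort_table(n, n, seed=100 + i)
            r = roc_analysis(df, "k_app")
            widths.append(r.ci_high - r.ci_low)
        assert widths[0] > widths[1] > widths[2]
        assert 2.0 < widths[0] / widths[2] < 8.0   # ~1/sqrt(n) scaling (4x)


class TestCombinedModel:
    def test_single_variable_equals_univariate_auc(self, rng):
        df = generate_cohort_table(30, 40, seed=3)
        single = roc_analysis(df, "k_app", direction="auto")
        comb = combined_model(df, ["k_app"])
        assert comb.auc == pytest.approx(single.auc, abs=1e-12)
        assert comb.cutoff_scale == "probability"

    def test_perfect_marker_with_noise_keeps_auc_one(self, rng):
        df = frame(np.arange(10.0, 20.0), np.arange(0.0, 10.0))
        df["junk"] = rng.normal(0, 1, 20)
        r = combined_model(df, ["x", "junk"])
        assert r.auc == 1.0

    def test_in_sample_dominance(self):
        for seed in (0, 1, 2):
            df = generate_cohort_table(31, 46, seed=seed)
            comb = combined_model(df, ["d_app", "k_app"])
            singles = [roc_analysis(df, v, direction="auto").auc
                       for v in ("d_app", "k_app")]
            assert comb.auc >= max(singles) - 0.02


class TestDeLong:
    def test_identical_markers(self):
        df = generate_cohort_table(20, 25, seed=5)
        r = delong_test(df, "k_app", "k_app")
        assert r.z == 0.0 and r.p_value == 1.0 and r.degenerate

    def test_antisymmetry(self):
        df = generate_cohort_table(25, 30, seed=6)
        ab = delong_test(df, "k_app", "f1")
        ba = delong_test(df, "f1", "k_app")
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_z_sign_matches_auc_difference(self):
        df = generate_cohort_table(30, 40, seed=7)
        r = delong_test(df, "k_app", "f2")
        assert np.sign(r.z) == np.sign(r.auc_difference)
        assert 0.0 <= r.p_value <= 1.0


class TestFullAnalysis:
    @pytest.fixture(scope="class")
    def report(self):
        return run_full_analysis(generate_cohort_table(31, 46, seed=8))

    def test_table3_has_six_parameters_and_three_composites(self, report):
        t3 = report["table3"]
        assert len(t3) == 9
        assert set(t3["marker"]) >= {"f1", "f2", "f3", "d_app", "k_app",
                                     "adc", "DWI", "RSI", "DKI"}

    def test_probabilities_and_aucs_in_range(self, report):
        for key in ("table1", "table2_univariate", "delong"):
            p = report[key]["p_value"].dropna()
            assert ((p >= 0) & (p <= 1)).all()
        auc = report["table3"]["auc"]
        assert ((auc >= 0.5) & (auc <= 1.0)).all()   # auto orientation

    def test_composite_cutoffs_marked_probability_scale(self, report):
        t3 = report["table3"].set_index("marker")
        assert t3.loc["RSI", "cutoff_scale"] == "probability"
        assert t3.loc["DKI", "cutoff_scale"] == "probability"
        assert t3.loc["adc", "cutoff_scale"] == "marker"

    def test_deterministic(self):
        df = generate_cohort_table(15, 20, seed=9)
        a, b = run_full_analysis(df), run_full_analysis(df)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_one_class_cohort_rejected(self):
        df = generate_cohort_table(10, 0, seed=10)
        with pytest.raises(ValueError):
            run_full_analysis(df)
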