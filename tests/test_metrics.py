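"""AUC/DeLong, balanced cut point, classification, odds ratios, logistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claimscreen.metrics import (
    ContingencyTable2x2,
    MetricsError,
    auc,
    balanced_cutpoint,
    classification_at,
    fit_multivariable_logistic,
    mean_prob_difference,
    odds_ratio,
    validation_report,
)


def brute_force_auc(x, y):
    """Pair-counting oracle: P(case > control) + 0.5 P(tie)."""
    x = np.asarray(x, float)[:, None]
    y = np.asarray(y, float)[None, :]
    return ((x > y).sum() + 0.5 * (x == y).sum()) / (x.size * y.size)


class TestAuc:
    def test_four_pair_example(self):
        a, _ = auc([0.9, 0.4], [0.3, 0.5])
        assert a == pytest.approx(0.75)

    def test_perfect_separation(self):
        a, ci = auc([0.8, 0.9], [0.1, 0.2])
        assert a == 1.0 and ci == (1.0, 1.0)

    def test_identical_multisets_give_half(self):
        a, _ = auc([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert a == pytest.approx(0.5)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(1.0, 1.0, size=40)
        assert auc(x, y)[0] + auc(y, x)[0] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(MetricsError):
            auc([], [0.5])

    def test_delong_ci_matches_r_proc_oracle(self):
        # frozen from R pROC ci.auc(..., method="delong") on this exact data
        rng = np.random.default_rng(42)
        cases = np.round(rng.normal(0.6, 0.2, 40), 4)
        controls = np.round(rng.normal(0.4, 0.2, 60), 4)
        a, (lo, hi) = auc(cases, controls)
        assert a == pytest.approx(0.8462500000, abs=1e-10)
        assert lo == pytest.approx(0.7682975584, abs=1e-9)
        assert hi == pytest.approx(0.9242024416, abs=1e-9)

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_equals_pair_counting_oracle(self, data):
        grid = st.integers(0, 20)  # coarse grid forces ties
        x = data.draw(st.lists(grid, min_size=1, max_size=40))
        y = data.draw(st.lists(grid, min_size=1, max_size=40))
        a, _ = auc(x, y)
        assert a == pytest.approx(brute_force_auc(x, y), abs=1e-12)


class TestBalancedCutpoint:
    def test_separated_groups_get_the_midpoint(self):
        t = balanced_cutpoint([0.9, 0.9], [0.1, 0.1])
        assert t == pytest.approx(0.5)

    def test_achieves_exhaustive_scan_minimum(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.choice(np.linspace(0, 1, 15), size=rng.integers(1, 12))
            y = rng.choice(np.linspace(0, 1, 15), size=rng.integers(1, 12))
            t = balanced_cutpoint(x, y)
            sens, spec = (x >= t).mean(), (y < t).mean()
            # exhaustive candidate scan oracle
            distinct = np.unique(np.concatenate([x, y]))
            cands = np.concatenate(
                [[distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2,
                 [distinct[-1] + 1]])
            best = min(abs((x >= c).mean() - (y < c).mean()) for c in cands)
            assert abs(sens - spec) <= best + 1e-12

    def test_symmetric_distributions_balance_near_half(self):
        x = np.array([0.2, 0.4, 0.6, 0.8, 0.9])
        y = 1.0 - x
        t = balanced_cutpoint(x, y)
        sens, spec = (x >= t).mean(), (y < t).mean()
        assert sens == pytest.approx(spec)


class TestClassificationAt:
    def test_threshold_below_everything(self):
        sens, spec, *_ = classification_at(-1.0, [0.5, 0.9], [0.1, 0.2])
        assert sens == 1.0 and spec == 0.0

    def test_threshold_above_everything(self):
        sens, spec, *_ = classification_at(2.0, [0.5, 0.9], [0.1, 0.2])
        assert sens == 0.0 and spec == 1.0

    def test_hand_counted_example(self):
        sens, spec, acc, sens_ci, spec_ci = classification_at(
            0.45, [0.9, 0.5, 0.2], [0.4, 0.1])
        assert sens == pytest.approx(2 / 3)
        assert spec == 1.0
        assert acc == pytest.approx(4 / 5)
        assert sens_ci[0] <= sens <= sens_ci[1]

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(MetricsError):
            classification_at(float("inf"), [0.5], [0.1])


def test_mean_prob_difference_arithmetic():
    assert mean_prob_difference([1, 1], [0, 0]) == 1.0
    assert mean_prob_difference([0.5], [0.5]) == 0.0
    assert mean_prob_difference([0.8, 0.6], [0.3, 0.1]) == pytest.approx(0.5)


class TestOddsRatio:
    def test_unit_table(self):
        point, _ = odds_ratio(ContingencyTable2x2(1, 1, 1, 1))
        assert point == pytest.approx(1.0)

    def test_swapping_exposure_inverts_the_or(self):
        t = ContingencyTable2x2(30, 20, 100, 200)
        swapped = ContingencyTable2x2(20, 30, 200, 100)
        assert odds_ratio(t)[0] == pytest.approx(1 / odds_ratio(swapped)[0])

    def test_zero_cell_flags_ci_undefined(self):
        point, (lo, hi) = odds_ratio(ContingencyTable2x2(0, 10, 5, 20))
        assert point == 0.0 and np.isnan(lo) and np.isnan(hi)

    def test_undefined_point_estimate_rejected(self):
        with pytest.raises(MetricsError):
            odds_ratio(ContingencyTable2x2(5, 0, 3, 10))


class TestLogistic:
    def test_single_binary_covariate_reproduces_crude_or(self):
        """Logistic OR for one exposure equals the closed-form 2x2 OR."""
        a, b, c, d = 552, 189, 31739, 16456
        x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        fit = fit_multivariable_logistic(pd.DataFrame({"exposed": x}), y)
        crude, _ = odds_ratio(ContingencyTable2x2(a, b, c, d))
        assert fit.loc["exposed", "or"] == pytest.approx(crude, rel=1e-6)
        assert round(fit.loc["exposed", "or"], 2) == 1.51

    def test_null_covariate_is_a_rank_error(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=100), "z": np.zeros(100)})
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(MetricsError, match="rank"):
            fit_multivariable_logistic(X, y)

    def test_recovers_generating_coefficients_within_3se(self):
        rng = np.random.default_rng(2024)
        n = 5000
        X = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": (rng.random(n) < 0.4).astype(float),
        })
        beta = {"const": -1.0, "x1": 0.7, "x2": -0.5}
        lp = beta["const"] + beta["x1"] * X["x1"] + beta["x2"] * X["x2"]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        fit = fit_multivariable_logistic(X, y)
        for term in ("const", "x1", "x2"):
            assert abs(fit.loc[term, "coef"] - beta[term]) <= 3 * fit.loc[term, "se"]


def test_validation_report_is_internally_consistent():
    rng = np.random.default_rng(3)
    cases = rng.beta(4, 2, 300)
    controls = rng.beta(2, 4, 700)
    rep = validation_report(cases, controls, label="demo")
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
    sens, spec, acc, *_ = classification_at(rep.cutpoint, cases, controls)
    assert rep.sensitivity == sens and rep.specificity == spec
    assert rep.accuracy == pytest.approx(
        (sens * 300 + spec * 700) / 1000, abs=1e-12)
    assert "AUC" in rep.summary()
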