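import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taplab.errors import InvalidArgumentError, UndefinedStatisticError
from taplab.stats import (auc_from_u, bh_adjust, compute_sbr,
                          confusion_accuracy, delong_variance,
                          group_compare_suite, log_sbr, logistic_fit,
                          mann_whitney, roc_analysis, spearman_bootstrap,
                          youden_cutoff)

from oracles import (bh_step_up, brute_force_auc, brute_force_youden,
                     spearman_by_hand)


class TestMannWhitney:
    def test_complete_separation_small_exact(self):
        U, p = mann_whitney([4, 5, 6], [1, 2, 3])
        assert U == 9
        assert p == pytest.approx(0.1)  # 2 of the 20 arrangements are as extreme

    def test_reverse_separation_gives_zero_u(self):
        U, _ = mann_whitney([1, 2], [3, 4])
        assert U == 0

    def test_all_ties_give_half_maximal_u(self):
        U, _ = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert U == 3.0  # n1·n2/2

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mann_whitney([], [1.0])


class TestAucFromU:
    @pytest.mark.parametrize("U,exact,auc2dp", [
        (297.5, 0.9296875, 0.93), (266.0, 0.83125, 0.83),
        (97.5, 0.3046875, 0.30), (114.0, 0.35625, 0.36),
    ])
    def test_identity_on_cohort_scale_u_statistics(self, U, exact, auc2dp):
        auc = auc_from_u(U, 32, 10)
        assert auc == pytest.approx(exact, abs=1e-12)
        assert round(auc, 2) == auc2dp

    def test_half_maximal_u_is_chance(self):
        assert auc_from_u(160, 32, 10) == 0.5

    def test_bounds_enforced(self):
        with pytest.raises(InvalidArgumentError):
            auc_from_u(321, 32, 10)


class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = np.r_[np.ones(6), np.zeros(4)]
        labels = np.r_[np.ones(6), np.zeros(4)].astype(bool)
        r = roc_analysis(scores, labels)
        assert r.auc == 1.0
        assert r.ci95[1] == 1.0
        assert r.sensitivity == r.specificity == 1.0

    def test_null_scores_give_chance_auc(self):
        rng = np.random.default_rng(0)
        aucs = [roc_analysis(rng.normal(size=60),
                             np.r_[np.ones(30), np.zeros(30)].astype(bool)).auc
                for _ in range(50)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_delong_auc_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 26, 2)
        pos = np.round(rng.normal(0.5, 1, n1), 1)  # rounding creates ties
        neg = np.round(rng.normal(0.0, 1, n2), 1)
        auc, _ = delong_variance(pos, neg)
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_u_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=40), 1)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False  # both classes present
        r = roc_analysis(scores, labels)
        U, _ = mann_whitney(scores[labels], scores[~labels])
        assert r.auc == pytest.approx(
            auc_from_u(U, labels.sum(), (~labels).sum()), abs=1e-12)

    def test_anti_discriminating_feature_not_flipped(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        assert roc_analysis(scores, labels).auc == 0.0

    def test_delong_se_ci_match_r_proc(self, tmp_path):
        """Independent cross-check of the DeLong SE and CI against pROC."""
        rng = np.random.default_rng(7)
        pos = np.round(rng.normal(1.0, 1.0, 14), 2)
        neg = np.round(rng.normal(0.0, 1.0, 9), 2)
        r = roc_analysis(np.r_[pos, neg],
                         np.r_[np.ones(14), np.zeros(9)].astype(bool))
        script = tmp_path / "delong.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"pos <- c({', '.join(map(str, pos))})\n"
            f"neg <- c({', '.join(map(str, neg))})\n"
            "roc <- roc(controls = neg, cases = pos, quiet = TRUE)\n"
            "ci <- ci.auc(roc, method = 'delong')\n"
            "cat(sprintf('%.10f %.10f %.10f %.10f', auc(roc),\n"
            "    sqrt(var(roc, method='delong')), ci[1], ci[3]))\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        auc_r, se_r, lo_r, hi_r = map(float, out.stdout.split())
        assert r.auc == pytest.approx(auc_r, abs=1e-9)
        assert r.se == pytest.approx(se_r, abs=1e-9)
        assert r.ci95[0] == pytest.approx(lo_r, abs=1e-6)
        assert r.ci95[1] == pytest.approx(min(hi_r, 1.0), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            roc_analysis([1.0, 2.0], [True, True])


class TestYouden:
    def test_separable_data(self):
        cutoff, sens, spec, acc = youden_cutoff([1, 2, 8, 9],
                                                [False, False, True, True])
        assert sens == spec == acc == 1.0
        assert 2 < cutoff < 8

    def test_spec_example_matches_exhaustive_scan(self):
        scores = [0.1, 0.3, 0.2, 0.4]
        labels = [False, False, True, True]
        got = youden_cutoff(scores, labels)
        exp = brute_force_youden(scores, labels)
        assert got[:3] == pytest.approx(exp)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.random(n) < 0.4
        labels[:2] = [True, False]
        got = youden_cutoff(scores, labels)
        exp = brute_force_youden(scores, labels)
        assert got[:3] == pytest.approx(exp)

    def test_accuracy_identity(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[:2] = [True, False]
        _, sens, spec, acc = youden_cutoff(scores, labels)
        n_pos, n_neg = labels.sum(), (~labels).sum()
        assert acc == pytest.approx((sens * n_pos + spec * n_neg) / 50)

    def test_confusion_accuracy_from_printed_rates(self):
        # 81.3% of 32 and 100% of 10 -> (26 + 10)/42
        assert confusion_accuracy(0.813, 1.0, 32, 10) == pytest.approx(36 / 42)


class TestLogisticFit:
    def test_null_model_has_no_explanatory_power(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 2))
        y = rng.random(200) < 0.5
        res = logistic_fit(X, y.astype(int))
        assert res.cox_snell_r2 < 0.05
        assert res.omnibus_p > 0.01

    def test_single_binary_predictor_recovers_log_odds_ratio(self):
        # 2x2 table: exposed 30 (20 cases), unexposed 40 (10 cases)
        x = np.r_[np.ones(30), np.zeros(40)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(30)]
        res = logistic_fit(x[:, None], y, feature_names=["exposed"])
        log_or = np.log((20 / 10) / (10 / 30))
        assert res.coefficients[1] == pytest.approx(log_or, abs=1e-6)
        assert res.odds_ratios[1] == pytest.approx(np.exp(log_or), rel=1e-6)

    def test_nagelkerke_dominates_cox_snell(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = (x + rng.normal(size=80) > 0).astype(int)
        res = logistic_fit(x[:, None], y)
        assert res.nagelkerke_r2 >= res.cox_snell_r2 > 0
        assert 0 < res.pct_correct <= 1

    def test_perfect_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(10), np.ones(10)] + np.linspace(0, 0.1, 20)
        y = np.r_[np.zeros(10), np.ones(10)]
        res = logistic_fit(x[:, None], y)
        assert not res.converged
        assert res.diagnostic != ""

    def test_too_few_observations_rejected(self):
        with pytest.raises(InvalidArgumentError):
            logistic_fit(np.ones((3, 2)) + np.arange(6).reshape(3, 2),
                         [0, 1, 0])


class TestSpearmanBootstrap:
    def test_monotone_transform_gives_unity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = spearman_bootstrap(x, np.exp(x), seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        res = spearman_bootstrap([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], seed=0)
        assert res.rho == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0]
        res = spearman_bootstrap(x, y, seed=0)
        assert res.rho == pytest.approx(spearman_by_hand(x, y), abs=1e-12)

    def test_ci_seeded_and_contains_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(size=30)
        r1 = spearman_bootstrap(x, y, seed=11)
        r2 = spearman_bootstrap(x, y, seed=11)
        assert r1.ci95 == r2.ci95
        assert r1.ci95[0] <= r1.rho <= r1.ci95[1]

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_bootstrap([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestBenjaminiHochberg:
    def test_four_element_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_matches_hand_rule_and_dominates_p(self):
        rng = np.random.default_rng(5)
        p = np.round(rng.random(12), 3)
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_step_up(list(p)), atol=1e-12)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bh_adjust([0.5, 1.2])


class TestGroupCompareSuite:
    @staticmethod
    def _cohort(rng, shift=0.0):
        n1, n2 = 25, 15
        return pd.DataFrame({
            "group": ["a"] * n1 + ["b"] * n2,
            "gauss": np.r_[rng.normal(0, 1, n1), rng.normal(shift, 1, n2)],
            "skewed": np.r_[rng.lognormal(0, 1, n1), rng.lognormal(shift, 1, n2)],
            "sex": rng.random(n1 + n2) < 0.5,
        })

    def test_test_selection_by_normality(self):
        rng = np.random.default_rng(6)
        out = group_compare_suite(self._cohort(rng), sex_col="sex")
        chosen = dict(zip(out["variable"], out["test"]))
        assert chosen["gauss"] == "welch_t"
        assert chosen["skewed"] == "mann_whitney"
        assert chosen["sex"] == "chi_square"
        assert np.all(out["q"].dropna() >= out["p"].dropna() - 1e-12)

    def test_chi_square_zero_on_proportional_table(self):
        df = pd.DataFrame({
            "group": ["a"] * 20 + ["b"] * 10,
            "x": np.tile(np.arange(10.0), 3),
            "sex": ["m"] * 10 + ["f"] * 10 + ["m"] * 5 + ["f"] * 5,
        })
        out = group_compare_suite(df, variables=["x"], sex_col="sex")
        chi = out.loc[out["variable"] == "sex", "statistic"].item()
        assert chi == pytest.approx(0.0, abs=1e-12)

    def test_welch_type_one_error_calibrated(self):
        """Null rejection rate of the Welch branch stays near nominal 5%
        under unequal variances (1000 replicates)."""
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, size=(1000, 12))
        b = rng.normal(0.0, 3.0, size=(1000, 30))
        p = ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = np.mean(p < 0.05)
        assert 0.035 < rate < 0.065

    def test_degenerate_variable_skipped(self):
        rng = np.random.default_rng(8)
        df = self._cohort(rng)
        df["flat"] = 1.0
        out = group_compare_suite(df, variables=["gauss", "flat"])
        assert out.loc[out["variable"] == "flat", "test"].item() == "skipped"


class TestSbr:
    @pytest.mark.parametrize("roi,bg,expected", [
        (2.0, 1.0, 1.0), (1.0, 1.0, 0.0), (1.8, 1.2, 0.5),
    ])
    def test_ratio(self, roi, bg, expected):
        assert compute_sbr(roi, bg) == pytest.approx(expected)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_sbr(1.0, 0.0)

    def test_log_requires_positive_sbr(self):
        assert log_sbr(1.0) == 0.0
        with pytest.raises(InvalidArgumentError):
            log_sbr(0.0)


def test_json_round_trip_of_roc_result():
    """ROC results serialize cleanly for run manifests."""
    r = roc_analysis(np.r_[np.ones(6), np.zeros(6)] + np.arange(12) * 0.01,
                     np.r_[np.ones(6), np.zeros(6)].astype(bool))
    payload = json.dumps({"auc": r.auc, "ci": r.ci95})
    assert json.loads(payload)["auc"] == r.auc
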