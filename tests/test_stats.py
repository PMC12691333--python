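"""Cohort splitting, comparison statistics, model fits, ROC/DeLong machinery,
calibration and decision curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sps

import habikit as hk
from conftest import auc_pairs_bruteforce, fisher_bruteforce


def _toy_table(n=195, prev=0.3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "BM": (rng.uniform(size=n) < prev).astype(int),
        "age": rng.normal(66, 9, size=n),
    })


class TestSplit:
    def test_ratio_rounding_and_sizes(self):
        table = hk.split_cohort(_toy_table(195), ratio=0.7, seed=1)
        n_train = (table["split"] == "training").sum()
        assert n_train in (136, 137, 138)
        assert n_train + (table["split"] == "validation").sum() == 195

    def test_prevalence_within_one_patient(self):
        table = hk.split_cohort(_toy_table(200, prev=0.35), ratio=0.7, seed=2)
        overall = table["BM"].mean()
        for split, grp in table.groupby("split"):
            assert abs(grp["BM"].sum() - overall * len(grp)) <= 1.0

    def test_same_seed_identical_split(self):
        t = _toy_table(100)
        s1 = hk.split_cohort(t, seed=9)["split"]
        s2 = hk.split_cohort(t, seed=9)["split"]
        assert s1.equals(s2)


class TestCohortCompare:
    def test_identical_groups_mannwhitney_p_one(self):
        vals = np.arange(30, dtype=float)
        table = pd.DataFrame({
            "x": np.concatenate([vals, vals]),
            "split": ["training"] * 30 + ["validation"] * 30,
        })
        out = hk.cohort_compare(table, variables=["x"])
        assert out.loc["x", "p"] > 0.95

    def test_fisher_2x2_matches_hypergeometric_enumeration(self):
        table = pd.DataFrame({
            "flag": [True] * 3 + [False] * 1 + [True] * 1 + [False] * 3,
            "split": ["training"] * 4 + ["validation"] * 4,
        })
        out = hk.cohort_compare(table, variables=["flag"])
        assert out.loc["flag", "test"] == "fisher"
        assert out.loc["flag", "p"] == pytest.approx(
            fisher_bruteforce([[3, 1], [1, 3]]), abs=1e-10)

    def test_chi2_matches_direct_formula(self):
        # large balanced 2x2 with all expected counts >= 5
        counts = {"training": (30, 20), "validation": (18, 32)}
        rows = []
        for split, (yes, no) in counts.items():
            rows += [{"flag": True, "split": split}] * yes
            rows += [{"flag": False, "split": split}] * no
        table = pd.DataFrame(rows)
        out = hk.cohort_compare(table, variables=["flag"])
        obs = np.array([[30, 18], [20, 32]], dtype=float)
        expected = obs.sum(1, keepdims=True) * obs.sum(0) / obs.sum()
        chi2_hand = ((obs - expected) ** 2 / expected).sum()
        assert out.loc["flag", "test"] == "chi2"
        assert out.loc["flag", "statistic"] == pytest.approx(chi2_hand)


class TestLogisticFits:
    def test_parameter_recovery_within_2se(self, rng):
        n = 2000
        x = rng.integers(0, 2, size=(n, 4)).astype(float)
        beta = np.array([0.8, -0.6, 0.4, 0.0])
        eta = -0.5 + x @ beta
        y = (rng.uniform(size=n) < special.expit(eta)).astype(int)
        table = pd.DataFrame(x, columns=["age_ge65", "N2_stage",
                                         "gene_mutation", "EGFR"])
        table["BM"] = y
        fit = hk.fit_clinical_model(table)
        for term, true in zip(fit.terms, beta):
            assert abs(fit.params[term] - true) < 2 * fit.bse[term] + 1e-9

    def test_separable_covariate_flagged(self):
        table = pd.DataFrame({
            "age_ge65": [0.0] * 20 + [1.0] * 20,
            "N2_stage": 0.0, "gene_mutation": 0.0, "EGFR": 0.0,
            "BM": [0] * 20 + [1] * 20,
        })
        fit = hk.fit_clinical_model(table)
        assert fit.separation_suspected

    def test_aic_penalty_for_null_covariates(self, rng):
        n = 1500
        y = (rng.uniform(size=n) < 0.4).astype(int)
        table = pd.DataFrame({
            "age_ge65": rng.integers(0, 2, n).astype(float),
            "N2_stage": rng.integers(0, 2, n).astype(float),
            "gene_mutation": rng.integers(0, 2, n).astype(float),
            "EGFR": rng.integers(0, 2, n).astype(float),
            "BM": y,
        })
        fit = hk.fit_clinical_model(table)
        import statsmodels.api as sm

        null_aic = sm.Logit(y, np.ones((n, 1))).fit(disp=0).aic
        # 4 null covariates add ~2 * 4 to AIC, minus the chi2_4-distributed
        # deviance gain; allow generous sampling slack
        assert abs(fit.aic - (null_aic + 8)) < 16

    def test_true_logodds_score_recovers_identity_link(self, rng):
        n = 4000
        score = rng.normal(0, 1.5, size=n)
        y = (rng.uniform(size=n) < special.expit(score)).astype(int)
        fit = hk.fit_score_model(score, y)
        assert fit.params.iloc[1] == pytest.approx(1.0, abs=0.1)
        assert fit.params.iloc[0] == pytest.approx(0.0, abs=0.1)


class TestAUC:
    def test_perfect_separation(self):
        ev = hk.evaluate_model(np.array([0.1, 0.2, 0.8, 0.9]),
                               np.array([0, 0, 1, 1]))
        assert ev.auc == 1.0
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0
        assert ev.accuracy == 1.0

    def test_four_point_example_matches_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        assert hk.auc_mann_whitney(scores, y) == pytest.approx(
            auc_pairs_bruteforce(scores, y))
        assert hk.auc_mann_whitney(scores, y) == pytest.approx(0.75)

    def test_label_flip_symmetry(self, rng):
        scores = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[0], y[1] = 0, 1
        assert hk.auc_mann_whitney(scores, y) == pytest.approx(
            1.0 - hk.auc_mann_whitney(scores, 1 - y))

    def test_delong_components_equal_pair_counting_with_ties(self, rng):
        scores = rng.integers(0, 5, size=80).astype(float)  # heavy ties
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        from habikit.stats import delong_components

        auc, v10, v01 = delong_components(scores, y)
        brute = auc_pairs_bruteforce(scores, y)
        assert auc == pytest.approx(brute, abs=1e-12)
        assert v10.mean() == pytest.approx(brute, abs=1e-12)
        assert v01.mean() == pytest.approx(brute, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        a = hk.evaluate_model(scores, y).auc
        b = hk.evaluate_model(np.exp(2 * scores), y).auc
        assert a == pytest.approx(b)

    def test_ci_contains_auc(self, rng):
        scores = rng.normal(size=120) + rng.integers(0, 2, size=120)
        y = (scores > 0.5).astype(int)
        y[:2] = [0, 1]
        ev = hk.evaluate_model(scores, y)
        assert ev.ci_low <= ev.auc <= ev.ci_high


class TestDeLongTest:
    def test_identical_scores_z_zero_p_one(self, rng):
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        cmp_ = hk.delong_test(scores, scores.copy(), y)
        assert cmp_.z == 0.0 and cmp_.p == 1.0

    def test_monotone_transform_gives_z_zero(self, rng):
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        cmp_ = hk.delong_test(scores, 3.0 * scores + 7.0, y)
        assert cmp_.z == 0.0 and cmp_.p == 1.0

    def test_sign_matches_auc_difference(self, rng):
        n = 300
        signal = rng.normal(size=n)
        y = (rng.uniform(size=n) < special.expit(2 * signal)).astype(int)
        y[:2] = [0, 1]
        good = signal + rng.normal(0, 0.3, size=n)
        bad = signal + rng.normal(0, 3.0, size=n)
        cmp_ = hk.delong_test(good, bad, y)
        assert cmp_.auc_difference > 0
        assert cmp_.z > 0


class TestCurves:
    def test_calibrated_probabilities_converge(self, rng):
        n = 60_000
        p = rng.uniform(0.05, 0.95, size=n)
        y = (rng.uniform(size=n) < p).astype(int)
        curve = hk.calibration_curve(p, y, n_bins=10)
        assert np.max(np.abs(curve["mean_predicted"]
                             - curve["observed_rate"])) < 0.02

    def test_constant_prediction_single_bin(self):
        p = np.full(40, 0.3)
        y = (np.arange(40) < 12).astype(int)
        curve = hk.calibration_curve(p, y)
        assert len(curve) == 1
        assert curve["mean_predicted"].iloc[0] == pytest.approx(0.3)
        assert curve["observed_rate"].iloc[0] == pytest.approx(0.3)

    def test_bins_partition_patients(self, rng):
        p = rng.uniform(size=500)
        y = rng.integers(0, 2, size=500)
        curve = hk.calibration_curve(p, y, n_bins=10)
        assert curve["count"].sum() == 500

    def test_treat_all_tends_to_prevalence(self, rng):
        y = rng.integers(0, 2, size=200)
        p = rng.uniform(size=200)
        dca = hk.decision_curve(p, y, thresholds=np.array([0.001, 0.01]))
        assert dca["treat_all"].iloc[0] == pytest.approx(y.mean(), abs=0.01)

    def test_perfect_model_net_benefit_is_prevalence(self):
        y = np.array([0] * 70 + [1] * 30)
        p = y.astype(float)
        dca = hk.decision_curve(p, y, thresholds=np.arange(0.05, 0.95, 0.1))
        np.testing.assert_allclose(dca["net_benefit"], 0.3)

    def test_random_model_bounded_by_best_trivial_policy(self, rng):
        n = 20_000
        y = (rng.uniform(size=n) < 0.3).astype(int)
        p = rng.uniform(size=n)  # outcome-independent
        dca = hk.decision_curve(p, y)
        bound = np.maximum(dca["treat_all"], 0.0)
        assert np.all(dca["net_benefit"] <= bound + 0.02)
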