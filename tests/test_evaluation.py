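"""Merged cross-validation, DeLong AUC, permutation nulls, calibration and
survival readouts against hand oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator

from dyam.evaluation import (
    auc_delong,
    binary_metrics,
    calibrate_youden,
    evaluate_model,
    fit_proportional_hazards,
    km_logrank,
    permutation_null,
    quartile_pfs_ratio,
    subsample_stability,
    tenfold_cv,
)


class OracleEstimator(BaseEstimator):
    """Scores with the first feature (tests wire it to the true label)."""

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        s = np.asarray(X)[:, 0]
        return np.column_stack([1 - s, s])


class ConstantEstimator(BaseEstimator):
    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        n = len(np.asarray(X))
        return np.full((n, 2), 0.5)


def brute_force_auc(scores, labels):
    """Concordant-pair counting with half credit for ties (test oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def product_limit_oracle(times, events):
    """Hand Kaplan-Meier: S(t) = prod over event times <= t of (1 - d/n)."""
    order = np.argsort(times)
    t_sorted, e_sorted = np.asarray(times, float)[order], np.asarray(events, int)[order]
    surv = {}
    s = 1.0
    at_risk = len(t_sorted)
    for t in np.unique(t_sorted):
        d = int(((t_sorted == t) & (e_sorted == 1)).sum())
        n_t = int((t_sorted >= t).sum())
        if d > 0:
            s *= 1.0 - d / n_t
        surv[t] = s
        at_risk -= int((t_sorted == t).sum())
    return surv


class TestTenfoldCV:
    def test_every_patient_scored_once(self, rng):
        X = rng.normal(size=(53, 3))
        y = rng.integers(0, 2, 53)
        scores = tenfold_cv(np.column_stack([y, X]), y, OracleEstimator(), seed=0)
        assert scores.shape == (53,)
        assert np.isfinite(scores).all()

    def test_fixed_seed_identical_assignment(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.integers(0, 2, 40)
        s1 = tenfold_cv(np.column_stack([y, X]), y, OracleEstimator(), seed=4)
        s2 = tenfold_cv(np.column_stack([y, X]), y, OracleEstimator(), seed=4)
        np.testing.assert_array_equal(s1, s2)

    def test_oracle_trainer_perfect_merged_auc(self, rng):
        y = rng.integers(0, 2, 60)
        X = np.column_stack([y.astype(float), rng.normal(size=60)])
        scores = tenfold_cv(X, y, OracleEstimator(), seed=1)
        assert auc_delong(scores, y)[0] == 1.0

    def test_rare_class_falls_back_to_stratification(self, rng):
        y = np.zeros(30, dtype=int)
        y[:3] = 1  # 3 positives over 10 folds: random folding can strand them
        X = np.column_stack([y.astype(float), rng.normal(size=30)])
        scores = tenfold_cv(X, y, OracleEstimator(), seed=0)
        assert np.isfinite(scores).all()


class TestDeLong:
    def test_four_point_example(self):
        # pairs: (0.1 vs 0.35)+, (0.1 vs 0.8)+, (0.4 vs 0.35)-, (0.4 vs 0.8)+
        auc, _, _ = auc_delong([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75

    def test_perfect_separation(self):
        auc, ci, _ = auc_delong([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert 0.0 <= ci[0] <= ci[1] <= 1.0

    def test_negation_symmetry(self, rng):
        scores = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        a1 = auc_delong(scores, y)[0]
        a2 = auc_delong(-scores, y)[0]
        assert a1 + a2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        assert auc_delong(scores, y)[0] == pytest.approx(brute_force_auc(scores, y), abs=1e-15)

    def test_ci_contains_auc(self, rng):
        scores = rng.normal(size=60) + rng.integers(0, 2, 60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        auc, (lo, hi), var = auc_delong(scores, y)
        assert lo <= auc <= hi and var >= 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([0.1, 0.2], [1, 1])


class TestPermutationNull:
    def test_oracle_null_centered_near_half(self, rng):
        y = rng.integers(0, 2, 80)
        X = np.column_stack([y.astype(float), rng.normal(size=80)])
        null = permutation_null(X, y, OracleEstimator(), n_iter=20, seed=0)
        assert abs(null.null_mean - 0.5) < 0.05
        assert null.n_sigma > 4 and null.stars == 4

    def test_constant_scores_no_signal(self):
        auc, _, _ = auc_delong(np.full(20, 0.3), [0, 1] * 10)
        assert auc == 0.5

    def test_null_trainer_within_two_sigma(self, rng):
        y = rng.integers(0, 2, 60)
        X = rng.normal(size=(60, 3))
        null = permutation_null(X, y, ConstantEstimator(), n_iter=5, seed=1)
        assert abs(null.n_sigma) <= 2


class TestSubsampling:
    def test_oracle_every_iteration_perfect(self, rng):
        y = rng.integers(0, 2, 100)
        X = np.column_stack([y.astype(float), rng.normal(size=100)])
        aucs = subsample_stability(X, y, OracleEstimator(), n_iter=20, seed=0)
        assert (aucs == 1.0).all()

    def test_fixed_seed_reproducible(self, rng):
        y = rng.integers(0, 2, 50)
        X = np.column_stack([y.astype(float), rng.normal(size=50)])
        a1 = subsample_stability(X, y, OracleEstimator(), n_iter=10, seed=2)
        a2 = subsample_stability(X, y, OracleEstimator(), n_iter=10, seed=2)
        np.testing.assert_array_equal(a1, a2)


class TestYouden:
    def test_toy_threshold_location(self):
        threshold, _ = calibrate_youden([0.2, 0.3, 0.6, 0.9], [0, 0, 1, 1])
        assert 0.3 < threshold <= 0.6

    def test_perfect_separation_unit_youden(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        threshold, _ = calibrate_youden(scores, y)
        pred = scores >= threshold
        sens = pred[y == 1].mean()
        spec = 1 - pred[y == 0].mean()
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_rescaled_unit_variance(self, rng):
        scores = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        _, rescaled = calibrate_youden(scores, y)
        assert rescaled.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_scores_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            calibrate_youden(np.full(10, 0.5), [0, 1] * 5)


class TestKaplanMeier:
    def test_no_events_flat_survival(self):
        curves, stat, _ = km_logrank([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        for df in curves.values():
            assert (df["survival"] == 1.0).all()
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_null_statistic(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 0, 1, 1, 0, 1]
        curves, stat, p = km_logrank(t + t, e + e, [0] * 6 + [1] * 6)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_staircase_matches_product_limit_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 0, 1]
        curves, _, _ = km_logrank(times, events, np.zeros(6, dtype=int))
        df = curves[0].set_index("time")["survival"]
        oracle = product_limit_oracle(times, events)
        for t, s in oracle.items():
            assert df.loc[t] == pytest.approx(s, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([], [], [])


class TestQuartileRatio:
    def test_counting_oracle_toy(self):
        # 8 patients; top risk quartile: both progress early; bottom: one does
        scores = np.array([0.9, 0.95, 0.5, 0.5, 0.5, 0.5, 0.05, 0.1])
        times = np.array([1, 2, 10, 10, 10, 10, 3, 10])
        events = np.array([1, 1, 0, 0, 0, 0, 1, 0])
        ratio, ci, e_top, e_bot = quartile_pfs_ratio(scores, times, events)
        assert (e_top, e_bot) == (2, 1)
        assert ratio == pytest.approx(2.0)
        assert ci[0] < ratio < ci[1]

    def test_flat_risk_large_cohort_ratio_near_one(self):
        rng = np.random.default_rng(0)
        n = 2000
        scores = rng.random(n)
        times = rng.exponential(3.0, n)
        events = np.ones(n, dtype=int)
        ratio, _, _, _ = quartile_pfs_ratio(scores, times, events)
        assert 0.8 < ratio < 1.25

    def test_zero_denominator_flagged(self):
        scores = np.linspace(0, 1, 8)
        times = np.full(8, 10.0)
        times[-2:] = 1.0
        events = np.zeros(8, dtype=int)
        events[-2:] = 1
        with pytest.raises(ValueError, match="bottom quartile"):
            quartile_pfs_ratio(scores, times, events)


class TestProportionalHazards:
    def test_null_covariate_hr_near_one(self, rng):
        x = rng.normal(size=500)
        times = rng.exponential(3.0, 500)
        events = np.ones(500, dtype=int)
        fit = fit_proportional_hazards(pd.DataFrame({"x": x}), times, events)
        assert 0.85 < fit["hazard_ratios"]["x"] < 1.15

    def test_duplicated_covariate_rejected(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            fit_proportional_hazards(pd.DataFrame({"a": x, "b": x}),
                                     np.ones(50), np.ones(50, dtype=int))

    def test_known_log_hazard_recovered(self):
        rng = np.random.default_rng(42)
        n, beta = 1000, 0.7
        x = rng.normal(size=n)
        lam = 0.25 * np.exp(beta * x)
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.uniform(0, 20, n)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        fit = fit_proportional_hazards(pd.DataFrame({"x": x}), times, events)
        assert abs(fit["coef"]["x"] - beta) < 2 * fit["coef_se"]["x"]
        assert fit["concordance"] > 0.6


def test_evaluate_model_end_to_end(rng):
    y = rng.integers(0, 2, 60)
    X = np.column_stack([y + 0.5 * rng.normal(size=60), rng.normal(size=60)])
    report = evaluate_model(X, y, OracleEstimator(), seed=0)
    assert report.ci95[0] <= report.auc <= report.ci95[1]
    assert set(report.metrics) == {"accuracy", "recall", "precision", "f1"}
    m = binary_metrics(report.merged_scores, y, report.threshold)
    assert m == report.metrics
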