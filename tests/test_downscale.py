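"""Logistic downscaling: SMOTE, fits, elimination, ranking, calibration, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from otevents import downscale as ds
from otevents.simulate import generate_logistic_training

TRUTH = {"MT": 2.0, "SH": -1.0, "SSRD": 0.8, "GH": -0.3}


class TestSmote:
    def test_exact_balance_with_originals_preserved(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(3, 1, (10, 3))])
        y = np.array([0] * 50 + [1] * 10)
        Xb, yb = ds.smote(X, y, seed=1)
        assert (yb == 0).sum() == (yb == 1).sum() == 50
        np.testing.assert_array_equal(Xb[:60], X)

    def test_synthetic_points_on_segment_for_two_minority(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[5.0, 5.0]] * 10)
        y = np.array([1, 1] + [0] * 10)
        Xb, yb = ds.smote(X, y, k_neighbors=1, seed=2)
        synth = Xb[len(X):]
        # every synthetic point lies on the segment between the two minority pts
        np.testing.assert_allclose(synth[:, 0], synth[:, 1], atol=1e-12)
        assert ((synth >= 0.0) & (synth <= 1.0)).all()

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        y = np.array([0, 1] * 10)
        Xb, yb = ds.smote(X, y, seed=4)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_tiny_minority_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([1] * 3 + [0] * 7)
        with pytest.raises(ValueError, match="minority"):
            ds.smote(X, y, k_neighbors=5)


class TestFitLogistic:
    def test_matches_likelihood_maximization_oracle(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        eta = -0.5 + 1.2 * X["a"] - 0.7 * X["b"]
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-eta))).astype(int)
        model = ds.fit_logistic(X, y)

        D = np.column_stack([np.ones(400), X.to_numpy()])

        def nll(beta):
            eta = D @ beta
            return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

        res = minimize(nll, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        np.testing.assert_allclose(
            [model.intercept, model.coefficients["a"], model.coefficients["b"]],
            res.x, atol=1e-4,
        )

    def test_null_simulation_pvalue_calibration(self):
        # each null predictor passes p > 0.05 w.p. 0.95, so "all of 2" holds
        # w.p. ~0.90; the 80% bar keeps the binomial false-failure rate tiny
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(2000, 2)), columns=["a", "b"])
            y = rng.integers(0, 2, size=2000)
            model = ds.fit_logistic(X, y)
            if all(p > 0.05 for p in model.p_values.values()):
                hits += 1
        assert hits >= 40

    def test_row_duplication_invariance(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        y = (rng.uniform(size=200) < 0.3).astype(int)
        m1 = ds.fit_logistic(X, y)
        m2 = ds.fit_logistic(pd.concat([X, X], ignore_index=True),
                             np.concatenate([y, y]))
        assert m2.coefficients["a"] == pytest.approx(m1.coefficients["a"], abs=1e-6)

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(7).normal(size=(50, 2)))
        with pytest.raises(ValueError, match="single class"):
            ds.fit_logistic(X, np.zeros(50))

    def test_coefficient_recovery(self):
        # standardized truth MT 2.0, SH -1.0, SSRD 0.8, GH -0.3 at n=2700
        errs = []
        for seed in range(10):
            X, y = generate_logistic_training(TRUTH, 2700, seed=seed)
            model = ds.fit_logistic(X, y)
            errs.append([model.coefficients[k] - v for k, v in TRUTH.items()])
        errs = np.array(errs)
        assert np.abs(errs).max() < 0.3
        assert np.sqrt((errs**2).mean()) < 0.2


class TestBackwardElimination:
    def test_informative_set_unchanged(self):
        X, y = generate_logistic_training(TRUTH, 2700, seed=0)
        model = ds.backward_eliminate(X, y)
        assert set(model.retained) == set(TRUTH)
        assert model.elimination_trace == []

    def test_noise_predictor_removed(self):
        removed = 0
        for seed in range(20):
            X, y = generate_logistic_training(TRUTH, 2700, seed=seed)
            X["NOISE"] = np.random.default_rng(seed + 999).normal(size=len(X))
            model = ds.backward_eliminate(X, y)
            if "NOISE" not in model.retained:
                removed += 1
        assert removed >= 18  # >= 90%

    def test_all_eliminated_gives_intercept_only(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        y = rng.integers(0, 2, size=500)
        model = ds.backward_eliminate(X, y, alpha=1e-6)
        assert model.degenerate and model.retained == []
        # intercept-only probability equals the event rate
        p = 1 / (1 + np.exp(-model.intercept))
        assert p == pytest.approx(y.mean(), abs=1e-9)

    def test_retained_all_significant(self):
        X, y = generate_logistic_training(TRUTH, 2000, seed=3)
        X["NOISE"] = np.random.default_rng(1234).normal(size=len(X))
        model = ds.backward_eliminate(X, y)
        assert all(p <= 0.05 for p in model.p_values.values())


class TestRankDrivers:
    def test_published_style_coefficients(self):
        # |MT| > |SH| > |SSRD| > WT > |GH| -> MID=MT, SMID=SH, TMID=SSRD
        model = ds.LogisticModel(
            intercept=0.0,
            coefficients={"GH": -0.44, "MT": 4.29, "SH": -1.66, "SSRD": 0.76,
                          "WT": 0.61},
            standard_errors={}, p_values={}, converged=True,
            separation_flag=False, log_likelihood=0.0,
        )
        r = ds.rank_drivers(model)
        assert (r.mid, r.smid, r.tmid) == ("MT", "SH", "SSRD")
        assert r.coefficients["SH"] == -1.66  # sign preserved

    def test_single_predictor(self):
        model = ds.LogisticModel(0.0, {"MT": 1.0}, {}, {}, True, False, 0.0)
        r = ds.rank_drivers(model)
        assert r.mid == "MT" and r.smid is None and r.tmid is None

    def test_tie_breaks_follow_column_order(self):
        model = ds.LogisticModel(
            0.0, {"SSRD": 1.0, "GH": -1.0, "MT": 1.0}, {}, {}, True, False, 0.0
        )
        r = ds.rank_drivers(model)
        assert (r.mid, r.smid, r.tmid) == ("GH", "MT", "SSRD")


class TestMcFadden:
    def test_null_model_is_zero(self):
        y = np.array([1, 0, 1, 0])
        p = y.mean()
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        model = ds.LogisticModel(0.0, {}, {}, {}, True, False, ll)
        assert ds.mcfadden_r2(model, y) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # y={1,0,1,0}, p_hat={0.8,0.2,0.8,0.2}: 1 - 4ln0.8 / 4ln0.5 ~ 0.678
        y = np.array([1, 0, 1, 0])
        ll = 4 * np.log(0.8)
        model = ds.LogisticModel(0.0, {}, {}, {}, True, False, float(ll))
        expected = 1 - np.log(0.8) / np.log(0.5)
        assert ds.mcfadden_r2(model, y) == pytest.approx(expected)

    def test_degenerate_outcome_rejected(self):
        model = ds.LogisticModel(0.0, {}, {}, {}, True, False, 0.0)
        with pytest.raises(ValueError):
            ds.mcfadden_r2(model, np.ones(5))


class TestClassificationMetrics:
    def test_confusion_arithmetic(self):
        y = np.array([1] * 10 + [0] * 10)
        prob = np.array([0.9] * 8 + [0.1] * 2 + [0.9] * 2 + [0.1] * 8)
        p, r, f1 = ds.classification_metrics(y, prob, 0.5)
        assert (p, r, f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_threshold_above_max_prob(self):
        y = np.array([1, 0, 1])
        p, r, f1 = ds.classification_metrics(y, np.array([0.3, 0.2, 0.4]), 0.9)
        assert r == 0.0 and f1 == 0.0

    def test_perfect_probabilities(self):
        y = np.array([1, 0, 1, 0])
        p, r, f1 = ds.classification_metrics(y, y.astype(float) * 0.98 + 0.01, 0.5)
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            ds.classification_metrics(np.zeros(3), np.zeros(4), 0.5)


class TestCalibrateThreshold:
    def test_returns_grid_minimum(self):
        X, y = generate_logistic_training(TRUTH, 1500, seed=10)
        thr = ds.calibrate_threshold(X, y, folds=5, seed=0)
        assert thr in ds.THRESHOLD_GRID

    def test_deterministic_given_seed(self):
        X, y = generate_logistic_training(TRUTH, 1200, seed=11)
        a = ds.calibrate_threshold(X, y, folds=5, seed=3)
        b = ds.calibrate_threshold(X, y, folds=5, seed=3)
        assert a == b


class TestEvaluate:
    def test_strong_signal_f1(self):
        X, y = generate_logistic_training(TRUTH, 2700, seed=12)
        report = ds.evaluate(X, y, folds=5, inner_folds=5, seed=0)
        assert report.f1 >= 0.65
        assert 0.0 <= report.mcfadden_r2 < 1.0
        assert len(report.per_fold) == 5

    def test_permuted_labels_collapse_to_baseline(self):
        X, y = generate_logistic_training(TRUTH, 2000, seed=13)
        rng = np.random.default_rng(14)
        y_perm = rng.permutation(y)
        report = ds.evaluate(X, y_perm, folds=5, inner_folds=5, seed=0)
        # a label-independent model cannot beat the event-rate baseline:
        # its precision is at most the event rate, so F1 collapses to or
        # below it (elimination typically leaves the intercept-only model,
        # giving F1 = 0)
        baseline = y_perm.mean()
        assert report.f1 <= baseline + 0.05
        assert report.mcfadden_r2 <= 0.05

    def test_same_seed_identical_report(self):
        X, y = generate_logistic_training(TRUTH, 1000, seed=15)
        r1 = ds.evaluate(X, y, folds=4, inner_folds=4, seed=5)
        r2 = ds.evaluate(X, y, folds=4, inner_folds=4, seed=5)
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)

    def test_validation_folds_never_contain_synthetic_samples(self):
        # leakage guard: every validation index maps to an original row
        from sklearn.model_selection import StratifiedKFold

        X, y = generate_logistic_training(TRUTH, 800, seed=16)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        n = len(X)
        for tr, va in skf.split(X, y):
            Xb, yb = ds.smote(X.iloc[tr].to_numpy(), y[tr], seed=0)
            # SMOTE output grows only past the training rows ...
            assert len(Xb) >= len(tr)
            np.testing.assert_array_equal(Xb[: len(tr)], X.iloc[tr].to_numpy())
            # ... and validation rows are untouched originals
            assert set(va).issubset(range(n))
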