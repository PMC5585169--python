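"""Marker–age regressions, sex ANCOVA, SVR training and evaluation."""

import numpy as np
import pandas as pd
import pytest

from msmelt.age_model import (
    SVR_C,
    SVR_EPSILON,
    AgePredictor,
    ancova_sex,
    evaluate,
    fit_marker_age,
    predict_age,
    train_predictor,
)
from msmelt.melt_simulator import (
    EDARADD,
    ELOVL2,
    TRAINING_STRATA,
    AgingModel,
    CohortSpec,
    simulate_cohort,
)


def _noiseless_cohort(seed=0):
    aging = {
        ELOVL2: AgingModel(ELOVL2, "log_linear", 5.0, 20.0, 0.0),
        EDARADD: AgingModel(EDARADD, "linear", 75.0, -0.45, 0.0),
    }
    samples, _ = simulate_cohort(
        CohortSpec(TRAINING_STRATA), aging=aging, seed=seed, include_curves=False
    )
    return samples.rename(columns={"m1_true": "m1", "m2_true": "m2"})


class TestMarkerAgeFit:
    def test_noiseless_exact_recovery(self):
        cohort = _noiseless_cohort()
        f1 = fit_marker_age(cohort, ELOVL2, "log_linear")
        assert f1.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert f1.intercept == pytest.approx(5.0, abs=1e-9)
        assert f1.slope == pytest.approx(20.0, abs=1e-9)
        f2 = fit_marker_age(cohort, EDARADD, "linear")
        assert f2.pearson_r == pytest.approx(-1.0, abs=1e-12)
        assert f2.slope == pytest.approx(-0.45, abs=1e-9)

    def test_default_cohort_r_in_band(self, small_cohort):
        f = fit_marker_age(small_cohort, ELOVL2, "log_linear")
        assert 0.82 <= f.pearson_r <= 0.92
        f2 = fit_marker_age(small_cohort, EDARADD, "linear")
        assert -0.62 <= f2.pearson_r <= -0.42

    def test_constant_scores_rejected(self):
        cohort = pd.DataFrame({"age": [20.0, 30.0, 40.0], "m1": [50.0, 50.0, 50.0]})
        with pytest.raises(ValueError, match="variance"):
            fit_marker_age(cohort, ELOVL2, "log_linear")

    def test_nonpositive_age_rejected_for_log_form(self):
        cohort = pd.DataFrame({"age": [0.0, 30.0, 40.0], "m1": [10.0, 60.0, 70.0]})
        with pytest.raises(ValueError, match="positive"):
            fit_marker_age(cohort, ELOVL2, "log_linear")


def _sex_cohort(rng, n_per_sex=30, offset=0.0, residual_sd=8.0):
    ages = rng.uniform(10, 70, size=2 * n_per_sex)
    sex = np.array(["M"] * n_per_sex + ["F"] * n_per_sex)
    scores = (
        5.0
        + 20.0 * np.log(ages)
        + offset * (sex == "F")
        + rng.normal(0, residual_sd, size=ages.size)
    )
    return pd.DataFrame({"age": ages, "sex": sex, "m1": scores})


class TestAncovaSex:
    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha = 0.05 over 1000 replicates."""
        rng = np.random.default_rng(2024)
        rejections = sum(
            ancova_sex(_sex_cohort(rng), ELOVL2, "log_linear")["p_sex"] < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_against_large_sex_offset(self):
        rng = np.random.default_rng(7)
        pvals = [
            ancova_sex(
                _sex_cohort(rng, n_per_sex=100, offset=20.0), ELOVL2, "log_linear"
            )["p_sex"]
            for _ in range(50)
        ]
        assert np.mean(np.asarray(pvals) < 0.001) >= 0.99

    def test_duplicated_data_gives_zero_sex_coefficient(self):
        rng = np.random.default_rng(3)
        half = _sex_cohort(rng, n_per_sex=20)[lambda d: d.sex == "M"]
        dup = pd.concat([half, half.assign(sex="F")], ignore_index=True)
        out = ancova_sex(dup, ELOVL2, "log_linear")
        assert out["sex_coefficient"] == pytest.approx(0.0, abs=1e-9)
        assert out["p_sex"] == pytest.approx(1.0, abs=1e-6)

    def test_single_sex_rejected(self):
        rng = np.random.default_rng(0)
        cohort = _sex_cohort(rng)[lambda d: d.sex == "M"]
        with pytest.raises(ValueError, match="both sexes"):
            ancova_sex(cohort, ELOVL2, "log_linear")


class TestPredictor:
    def test_training_is_deterministic(self, small_cohort):
        a = train_predictor(small_cohort)
        b = train_predictor(small_cohort)
        x = small_cohort["m1"].to_numpy()[:5], small_cohort["m2"].to_numpy()[:5]
        np.testing.assert_allclose(predict_age(a, *x), predict_age(b, *x), atol=1e-9)

    def test_prediction_matches_sklearn(self, small_cohort):
        """The numpy kernel expansion reproduces sklearn's own predict."""
        from sklearn.svm import SVR

        pred = train_predictor(small_cohort)
        x = small_cohort[["m1", "m2"]].to_numpy()
        y = small_cohort["age"].to_numpy()
        xs = (x - pred.x_mean) / pred.x_sd
        ys = (y - pred.y_mean) / pred.y_sd
        svr = SVR(kernel="rbf", C=1.1, gamma=0.1, epsilon=0.1).fit(xs, ys)
        ours = predict_age(pred, x[:, 0], x[:, 1])
        theirs = pred.y_mean + pred.y_sd * svr.predict(xs)
        np.testing.assert_allclose(ours, theirs, atol=1e-9)

    def test_json_round_trip_exact(self, small_cohort, tmp_path):
        pred = train_predictor(small_cohort)
        path = tmp_path / "predictor.json"
        pred.save(path)
        loaded = AgePredictor.load(path)
        m1 = small_cohort["m1"].to_numpy()
        m2 = small_cohort["m2"].to_numpy()
        np.testing.assert_allclose(
            predict_age(pred, m1, m2), predict_age(loaded, m1, m2), atol=1e-12
        )

    def test_two_markers_beat_best_single_marker_in_sample(self):
        for seed in (1, 2, 3):
            samples, _ = simulate_cohort(
                CohortSpec(TRAINING_STRATA), seed=seed, include_curves=False
            )
            cohort = samples.rename(columns={"m1_true": "m1", "m2_true": "m2"})
            both = train_predictor(cohort)
            mad_both = np.mean(
                np.abs(
                    predict_age(both, cohort["m1"], cohort["m2"]) - cohort["age"]
                )
            )
            singles = []
            for col in ("m1", "m2"):
                single = train_predictor(cohort, feature_cols=(col,))
                singles.append(
                    np.mean(
                        np.abs(
                            predict_age(single, cohort[col].to_numpy())
                            - cohort["age"]
                        )
                    )
                )
            assert mad_both < min(singles)

    def test_deterministic_age_function_learned(self):
        """Capacity check: age an exact smooth function of the scores."""
        rng = np.random.default_rng(11)
        m1 = rng.uniform(20, 90, size=200)
        m2 = rng.uniform(30, 80, size=200)
        age = 1.0 + np.exp((m1 - 5.0) / 20.0) * 0.5 + 0.1 * (75.0 - m2)
        cohort = pd.DataFrame({"age": age, "m1": m1, "m2": m2})
        pred = train_predictor(cohort)
        mad = np.mean(np.abs(predict_age(pred, m1, m2) - age))
        assert mad < 1.0

    def test_non_bound_points_sit_in_epsilon_tube(self, small_cohort):
        """KKT: any training point outside the epsilon tube (standardized)
        must be a support vector at the dual bound C."""
        pred = train_predictor(small_cohort)
        x = small_cohort[["m1", "m2"]].to_numpy()
        xs = (x - pred.x_mean) / pred.x_sd
        ys = (small_cohort["age"].to_numpy() - pred.y_mean) / pred.y_sd
        sq = ((xs[:, None, :] - pred.support_vectors[None, :, :]) ** 2).sum(-1)
        fitted = np.exp(-pred.gamma * sq) @ pred.dual_coef + pred.intercept
        # slack covers libsvm's default 1e-3 optimization tolerance
        outside = np.abs(fitted - ys) > SVR_EPSILON + 1e-2
        at_bound = np.isclose(np.abs(pred.dual_coef), SVR_C, atol=1e-6)
        assert outside.any()  # the cohort is noisy enough to have outliers
        for i in np.where(outside)[0]:
            dist = sq[i].min()
            assert dist < 1e-18 and at_bound[np.argmin(sq[i])]

    def test_mean_scores_predict_within_training_range(self, small_cohort):
        pred = train_predictor(small_cohort)
        out = predict_age(
            pred, [small_cohort["m1"].mean()], [small_cohort["m2"].mean()]
        )
        lo, hi = pred.train_age_range
        assert lo <= out[0] <= hi

    def test_zero_variance_feature_rejected(self):
        cohort = pd.DataFrame(
            {"age": np.arange(20.0, 40.0), "m1": 50.0, "m2": np.arange(20)}
        )
        with pytest.raises(ValueError, match="zero-variance"):
            train_predictor(cohort)

    def test_too_small_training_set_rejected(self):
        cohort = pd.DataFrame({"age": [20.0, 30.0], "m1": [1.0, 2.0], "m2": [3, 4]})
        with pytest.raises(ValueError, match=">= 10"):
            train_predictor(cohort)


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        rep = evaluate(truth, truth)
        assert rep.mad == 0.0
        assert rep.adjusted_r2 == pytest.approx(1.0)

    def test_constant_offset_mad(self):
        truth = np.array([12.0, 25.0, 47.0, 61.0])
        rep = evaluate(truth + 2.0, truth)
        assert rep.mad == pytest.approx(2.0)

    def test_hand_computed_mad(self):
        rep = evaluate([10.0, 20.0, 30.0, 15.0], [12.0, 18.0, 33.0, 15.0])
        assert rep.mad == pytest.approx((2 + 2 + 3 + 0) / 4)

    def test_per_bin_assignment(self):
        truth = np.array([5.0, 25.0, 45.0, 65.0])
        rep = evaluate(truth + 1.0, truth)
        assert rep.per_bin_n == {"under 20": 1, "20-39": 1, "40-59": 1, "over 60": 1}
        assert all(v == pytest.approx(1.0) for v in rep.per_bin_mad.values())

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(1, 70, 40)
        pred = truth + rng.normal(0, 5, 40)
        perm = rng.permutation(40)
        a = evaluate(pred, truth)
        b = evaluate(pred[perm], truth[perm])
        assert a.mad == pytest.approx(b.mad)
        assert a.adjusted_r2 == pytest.approx(b.adjusted_r2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0])

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
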