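import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odsensor.features import DESIGN_COLUMNS
from odsensor.model import (
    cross_validate,
    diagnose,
    fit_ols,
    ks_normality,
    predict_log,
    predict_od,
    r_squared,
    residual_autocorrelation,
    whiteness_bound,
)


def make_design(n_experiments=4, n_rows=12, beta=None, noise=0.0, seed=0):
    """Design rows generated exactly from known coefficients (plus noise)."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(
        beta if beta is not None else [0.4, 2.5, -1.8, 1.2, -0.9, 0.7, -0.5, 0.8, -0.3, 0.4]
    )
    rows = []
    for e in range(n_experiments):
        base = rng.normal(3.3, 0.2, size=3)
        for i in range(n_rows):
            x = np.concatenate([rng.normal(3.3, 0.4, size=3), base, rng.normal(4.0, 0.3, size=3)])
            y = beta[0] + x @ beta[1:] + rng.normal(0, noise)
            rows.append({
                "experiment_id": f"e{e}", "time_h": 0.5 * (i + 1),
                **dict(zip(DESIGN_COLUMNS, x)), "response": y,
            })
    return pd.DataFrame(rows), beta


class TestFitOls:
    def test_noiseless_recovery(self):
        design, beta = make_design(noise=0.0)
        fit = fit_ols(design)
        assert np.abs(fit.beta - beta).max() < 1e-8
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.full_rank

    def test_residuals_sum_to_zero(self):
        design, _ = make_design(noise=0.3, seed=3)
        fit = fit_ols(design)
        assert abs(fit.residuals.sum()) < 1e-8 * fit.n
        assert abs(fit.residuals.mean()) < 1e-10

    def test_single_experiment_rank_deficient(self):
        design, _ = make_design(n_experiments=1, n_rows=20, noise=0.1)
        with pytest.warns(UserWarning, match="rank deficient"):
            fit = fit_ols(design)
        assert not fit.full_rank

    def test_three_point_closed_form(self):
        # one active predictor; slope/intercept from the normal equations:
        # x = (0, 1, 2), y = (1, 2, 4) -> slope 1.5, intercept 5/6
        rows = []
        for x, y in [(0.0, 1.0), (1.0, 2.0), (2.0, 4.0)]:
            rec = {c: 0.0 for c in DESIGN_COLUMNS}
            rec.update({"experiment_id": "e0", "time_h": x, "x1": x, "response": y})
            rows.append(rec)
        with pytest.warns(UserWarning, match="rank deficient"):
            fit = fit_ols(pd.DataFrame(rows))
        assert fit.beta[1] == pytest.approx(1.5, abs=1e-10)
        assert fit.beta[0] == pytest.approx(5.0 / 6.0, abs=1e-10)

    def test_too_few_rows(self):
        design, _ = make_design()
        with pytest.raises(ValueError):
            fit_ols(design.iloc[:1])

    def test_json_round_trip(self, tmp_path):
        from odsensor.model import FitResult
        design, _ = make_design(noise=0.1)
        fit = fit_ols(design)
        fit.to_json(tmp_path / "m.json")
        back = FitResult.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.beta, fit.beta)
        assert back.n == fit.n


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction(self):
        obs = [1.0, 2.0, 3.0, 6.0]
        assert r_squared(obs, [3.0] * 4) == pytest.approx(0.0, abs=1e-12)

    def test_three_point_worked_example(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_can_be_negative(self):
        assert r_squared([1.0, 2.0, 3.0], [3.0, 3.0, -5.0]) < 0

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 3.0])

    @settings(max_examples=30, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=12)
        pred = obs + rng.normal(0, 0.5, size=12)
        r1 = r_squared(obs, pred)
        r2 = r_squared(scale * obs + shift, scale * pred + shift)
        assert r1 == pytest.approx(r2, abs=1e-8)


class TestPredictOd:
    def test_exp_zero_is_one(self):
        design, _ = make_design()
        fit = fit_ols(design)
        fit.beta[:] = 0.0
        assert predict_od(fit, design.iloc[:1]).item() == pytest.approx(1.0)

    def test_inverse_of_log_response(self):
        design, _ = make_design(noise=0.0)
        fit = fit_ols(design)
        row = design.iloc[[0]].copy()
        target = math.log(7.18)
        # shift the intercept so the linear predictor hits log(7.18)
        fit.beta[0] += target - predict_log(fit, row).item()
        assert predict_od(fit, row).item() == pytest.approx(7.18, rel=1e-10)

    def test_monotone_in_positive_coefficient(self):
        design, beta = make_design(noise=0.0)
        fit = fit_ols(design)
        assert fit.beta[1] > 0
        lo = design.iloc[[0]].copy()
        hi = lo.copy()
        hi["x1"] += 1.0
        assert predict_od(fit, hi).item() > predict_od(fit, lo).item()

    def test_strictly_positive(self):
        design, _ = make_design(noise=0.5, seed=7)
        fit = fit_ols(design)
        assert (predict_od(fit, design) > 0).all()


class TestAutocorrelation:
    def test_whiteness_bound_342(self):
        assert round(whiteness_bound(342), 3) == 0.108

    def test_alternating_sequence(self):
        n = 100
        e = np.tile([1.0, -1.0], n // 2)
        _, acf = residual_autocorrelation(e, max_lag=1)
        assert acf[0] == pytest.approx(-(n - 1) / n, abs=1e-12)

    def test_white_noise_within_bounds(self):
        rng = np.random.default_rng(123)
        e = rng.standard_normal(1000)
        lags, acf = residual_autocorrelation(e, max_lag=30)
        bound = whiteness_bound(1000)
        assert (np.abs(acf) <= bound).mean() >= 0.93

    def test_bounded_by_one(self):
        rng = np.random.default_rng(5)
        e = rng.standard_normal(200).cumsum()  # strongly correlated walk
        _, acf = residual_autocorrelation(e, max_lag=50)
        assert np.abs(acf).max() <= 1.0 + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError):
            residual_autocorrelation(np.ones(10), max_lag=3)
        with pytest.raises(ValueError):
            residual_autocorrelation(np.arange(5.0), max_lag=5)


class TestKsNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(11)
        _, p = ks_normality(rng.standard_normal(300))
        assert p > 0.05

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(11)
        _, p = ks_normality(rng.uniform(0, 1, size=300))
        assert p < 0.05

    def test_tiny_sample_flagged_low_power(self):
        report = diagnose([0.1, -0.2, 0.05])
        assert report.low_power

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))


class TestCrossValidate:
    def test_noiseless_loeo_perfect(self):
        design, _ = make_design(n_experiments=6, noise=0.0)
        cv = cross_validate(design, scheme="loeo")
        assert cv.r_squared == pytest.approx(1.0, abs=1e-9)
        assert len(cv.fold_betas) == 6

    def test_every_row_predicted_once(self):
        design, _ = make_design(noise=0.2, seed=2)
        for scheme, seed in [("loeo", None), ("loo", 3)]:
            cv = cross_validate(design, scheme=scheme, seed=seed)
            assert len(cv.predictions) == len(design)
            assert cv.predictions["prediction"].notna().all()

    def test_loeo_matches_brute_force_refit(self):
        design, _ = make_design(n_experiments=2, n_rows=3, noise=0.3, seed=4)
        import warnings
        cv = cross_validate(design, scheme="loeo")
        for eid in ("e0", "e1"):
            train = design[design.experiment_id != eid]
            test = design[design.experiment_id == eid]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_ols(train)
            expected = predict_log(fit, test)
            got = cv.predictions[cv.predictions.experiment_id == eid]["prediction"]
            np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-8)

    def test_loo_shuffle_deterministic(self):
        design, _ = make_design(noise=0.2)
        cv1 = cross_validate(design, scheme="loo", seed=9)
        cv2 = cross_validate(design, scheme="loo", seed=9)
        pd.testing.assert_frame_equal(cv1.predictions, cv2.predictions)
        cv3 = cross_validate(design, scheme="loo", seed=10)
        assert not cv1.predictions["time_h"].equals(cv3.predictions["time_h"])

    def test_training_r2_bounds_held_out_r2(self):
        design, _ = make_design(n_experiments=6, noise=0.4, seed=8)
        fit = fit_ols(design)
        cv = cross_validate(design, scheme="loeo")
        assert fit.r_squared >= cv.r_squared

    def test_parameter_recovery_improves_with_less_noise(self):
        errs = []
        for noise in (0.5, 0.05, 0.0):
            per_seed = []
            for seed in range(20):
                design, beta = make_design(n_experiments=5, noise=noise, seed=seed)
                per_seed.append(np.abs(fit_ols(design).beta - beta).mean())
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-8

    def test_scheme_validation(self):
        design, _ = make_design()
        with pytest.raises(ValueError):
            cross_validate(design, scheme="kfold")
        with pytest.raises(ValueError, match="seed"):
            cross_validate(design, scheme="loo")
        single = design[design.experiment_id == "e0"]
        with pytest.raises(ValueError, match="2 experiments"):
            cross_validate(single, scheme="loeo")


class TestDiagnose:
    def test_report_fields(self):
        rng = np.random.default_rng(2)
        e = rng.standard_normal(120)
        report = diagnose(e, fitted=rng.standard_normal(120), max_lag=15)
        assert report.lags == list(range(1, 16))
        assert report.whiteness_bound == pytest.approx(2 / math.sqrt(120))
        assert abs(report.residual_mean - e.mean()) < 1e-12
        assert not report.low_power

    def test_json_dump(self, tmp_path):
        rng = np.random.default_rng(2)
        report = diagnose(rng.standard_normal(50))
        report.to_json(tmp_path / "d.json")
        import json
        with open(tmp_path / "d.json") as fh:
            payload = json.load(fh)
        assert payload["whiteness_bound"] == pytest.approx(2 / math.sqrt(50))
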