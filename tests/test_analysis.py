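"""The analysis pipeline: normalization, summaries, fits, BIC comparison."""

import numpy as np
import pandas as pd
import pytest

from tooltouch.analysis import (
    TruncationParams,
    compare_bic,
    fit_accuracy_regression,
    fit_cohort,
    fit_trilateration,
    fit_truncation,
    normalize_image_task,
    normalize_space_task,
    normalize_trials,
    summarize_localization,
    truncated_sd,
)
from tooltouch.behavior import StudyDesign, TruncationGenParams, generate_cohort
from tooltouch.trilateration import TrilaterationParams, predicted_sd_curve

LOCS = np.array([100 / 6, 200 / 6, 50.0, 400 / 6, 500 / 6, 100.0])


def _profile_frame(sd, locs=LOCS):
    return pd.DataFrame({"location": locs, "variable_error": sd})


class TestNormalization:
    def test_image_task_proportionality(self):
        assert normalize_image_task(100.0, pixels_per_cm=10.0) == pytest.approx(50.0)
        assert normalize_image_task(200.0, pixels_per_cm=10.0) == pytest.approx(100.0)

    def test_image_task_clamps_off_drawing(self):
        with pytest.warns(UserWarning):
            assert normalize_image_task(210.0, pixels_per_cm=10.0) == 100.0

    def test_space_task_judged_tip_is_100pct(self):
        assert normalize_space_task(56.5, judged_tip_cm=56.5) == pytest.approx(100.0)
        assert normalize_space_task(28.25, judged_tip_cm=56.5) == pytest.approx(50.0)
        assert normalize_space_task(0.0, judged_tip_cm=56.5) == 0.0

    def test_nonpositive_judged_tip_rejected(self):
        with pytest.raises(ValueError):
            normalize_space_task(10.0, judged_tip_cm=0.0)

    def test_noiseless_cohort_round_trips(self, small_cohort):
        design, _, roster = small_cohort
        from dataclasses import replace

        from tooltouch.behavior import generate_trials

        p = replace(roster[0], trilateration=TrilaterationParams(0.0, 0.0, 0.0))
        recs = generate_trials(design, p, np.random.default_rng(0))
        df = pd.DataFrame([r.__dict__ for r in recs]).rename(
            columns={"true_location_cm": "location_cm"}
        )
        norm = normalize_trials(df, [p], design)
        np.testing.assert_allclose(norm["judgment"], norm["location"], atol=1e-9)


class TestSummaries:
    def test_two_point_cell(self):
        norm = pd.DataFrame(
            {"participant": 0, "task": "image", "location": 50.0, "judgment": [48.0, 52.0]}
        )
        s = summarize_localization(norm)
        assert s["mean_judgment"].iloc[0] == pytest.approx(50.0)
        assert s["variable_error"].iloc[0] == pytest.approx(np.sqrt(8.0), rel=1e-9)  # sample SD 2.83

    def test_task_offset_removed_by_demeaning(self):
        rng = np.random.default_rng(0)
        spread = rng.normal(0, 2.0, 10)
        norm = pd.DataFrame(
            {
                "participant": 0,
                "task": ["image"] * 10 + ["space"] * 10,
                "location": 50.0,
                "judgment": np.concatenate([50 + spread, 55 + spread]),
            }
        )
        pooled = summarize_localization(norm, demean_tasks=True)["variable_error"].iloc[0]
        single = np.sqrt(np.sum((spread - spread.mean()) ** 2) * 2 / 18)
        assert pooled == pytest.approx(single, rel=1e-9)
        inflated = summarize_localization(norm, demean_tasks=False)["variable_error"].iloc[0]
        assert inflated > pooled

    def test_singleton_cells_dropped_with_warning(self):
        norm = pd.DataFrame(
            {"participant": 0, "task": "image", "location": [10.0, 20.0, 20.0], "judgment": [9.0, 19.0, 21.0]}
        )
        with pytest.warns(UserWarning):
            s = summarize_localization(norm)
        assert list(s["location"]) == [20.0]


class TestRegression:
    def test_exact_linear_data_recovered(self):
        s = pd.DataFrame(
            {
                "participant": 0,
                "location": LOCS,
                "mean_judgment": 0.9 * LOCS + 5.0,
            }
        )
        res = fit_accuracy_regression(s)
        assert res.per_participant["slope"].iloc[0] == pytest.approx(0.9, abs=1e-9)
        assert res.per_participant["intercept"].iloc[0] == pytest.approx(5.0, abs=1e-9)

    def test_identity_data_slope_one(self):
        s = pd.DataFrame({"participant": 0, "location": LOCS, "mean_judgment": LOCS})
        res = fit_accuracy_regression(s)
        assert res.per_participant["slope"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert res.per_participant["intercept"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_group_ci_covers_generating_slope(self):
        rng = np.random.default_rng(5)
        rows = []
        for pid in range(20):
            rows.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "location": LOCS,
                        "mean_judgment": 0.93 * LOCS + rng.normal(0, 1.0, len(LOCS)),
                    }
                )
            )
        res = fit_accuracy_regression(pd.concat(rows))
        assert res.slope_ci[0] <= 0.93 <= res.slope_ci[1]


class TestTrilaterationFit:
    def test_exact_curve_recovered(self):
        true = TrilaterationParams(0.06, 1.0, 2.5)
        fit = fit_trilateration(_profile_frame(predicted_sd_curve(true, LOCS)))
        assert fit.rss < 1e-12
        assert fit.params["sigma_hat"] == pytest.approx(0.06, abs=1e-4)
        assert fit.params["eps1"] == pytest.approx(1.0, abs=1e-3)
        assert fit.params["eps2"] == pytest.approx(2.5, abs=1e-3)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_profile_degenerates_to_zero_slope(self):
        fit = fit_trilateration(_profile_frame(np.full(6, 2.0)))
        assert fit.at_bounds  # sigma_hat pinned at 0
        assert fit.params["sigma_hat"] < 1e-6

    def test_too_few_locations_rejected(self):
        with pytest.raises(ValueError):
            fit_trilateration(_profile_frame(np.ones(3), LOCS[:3]))

    def test_study_scale_parameter_recovery(self):
        """At the study's trial counts (6 locations x 20 trials), the three
        noise parameters are recovered with median relative error below 25%."""
        rng = np.random.default_rng(17)
        dof = 18  # pooled SD dof per location cell
        errs = []
        for i in range(38):
            true = TrilaterationParams(rng.uniform(0.02, 0.10), rng.uniform(0.5, 5), rng.uniform(0.5, 5))
            sd = predicted_sd_curve(true, LOCS)
            noisy = sd * np.sqrt(rng.chisquare(dof, len(LOCS)) / dof)
            fit = fit_trilateration(_profile_frame(noisy), seed=i)
            errs += [
                abs(fit.params["sigma_hat"] - true.sigma_hat) / true.sigma_hat,
                abs(fit.params["eps1"] - true.eps1) / true.eps1,
                abs(fit.params["eps2"] - true.eps2) / true.eps2,
            ]
        assert np.median(errs) < 0.25


class TestTruncationModel:
    def test_negligible_truncation_returns_base_sd(self):
        assert truncated_sd(TruncationParams(10.0, -30.0, 130.0), 50.0) == pytest.approx(10.0, rel=1e-4)

    def test_half_normal_closed_form(self):
        # touch exactly at a bound: SD of the half normal = sigma*sqrt(1-2/pi)
        assert truncated_sd(TruncationParams(10.0, 0.0, 100.0), 0.0) == pytest.approx(
            10.0 * np.sqrt(1.0 - 2.0 / np.pi), rel=1e-6
        )

    def test_monte_carlo_oracle(self, rng):
        # independent oracle: rejection-sample the truncated normal
        params = TruncationParams(8.0, 5.0, 95.0)
        for L in (10.0, 50.0, 90.0):
            x = rng.normal(L, params.sigma_t, 400000)
            x = x[(x >= params.gamma1) & (x <= params.gamma2)]
            assert truncated_sd(params, L) == pytest.approx(x.std(ddof=1), rel=0.01)

    def test_symmetry_about_bound_midpoint(self):
        p = TruncationParams(12.0, 10.0, 90.0)
        np.testing.assert_allclose(truncated_sd(p, [30.0, 40.0]), truncated_sd(p, [70.0, 60.0]), rtol=1e-9)

    def test_self_recovery_and_bound_flagging(self):
        true = TruncationParams(9.0, 5.0, 95.0)
        fit = fit_truncation(_profile_frame(truncated_sd(true, LOCS)))
        assert fit.rss < 1e-6
        flat = fit_truncation(_profile_frame(np.full(6, 45.0)))  # above sigma_t's upper bound
        assert flat.at_bounds


class TestModelComparison:
    def _fits(self, rss_tri, rss_trunc, n=6):
        sd = np.ones(n)
        f = lambda name, rss: type(
            "F", (), {"n_points": n, "rss": rss, "bic": lambda self, m=None, k=3: (m or n) * np.log(rss / (m or n)) + k * np.log(m or n)}
        )()
        from tooltouch.analysis import ModelFit

        def mk(name, rss):
            return ModelFit(
                model=name, params={}, locations=LOCS[:n], observed_sd=sd, predicted_sd=sd,
                rss=rss, r_squared=0.5, n_points=n, converged=True, at_bounds=False, n_starts=10,
            )

        return mk("trilateration", rss_tri), mk("truncation", rss_trunc)

    def test_equal_rss_is_weak_tie(self):
        cmp_ = compare_bic(*self._fits(1.0, 1.0))
        assert cmp_.delta_bic == 0.0 and cmp_.evidence == "weak" and cmp_.winner == "tie"

    def test_double_rss_is_moderate(self):
        cmp_ = compare_bic(*self._fits(1.0, 2.0))
        assert cmp_.delta_bic == pytest.approx(6 * np.log(2.0))
        assert cmp_.evidence == "moderate" and cmp_.winner == "trilateration"

    def test_e_fold_rss_ratio_gives_dbic_n(self):
        cmp_ = compare_bic(*self._fits(1.0, np.e))
        assert cmp_.delta_bic == pytest.approx(6.0)
        assert cmp_.evidence == "strong"

    def test_zero_rss_flagged_degenerate(self):
        cmp_ = compare_bic(*self._fits(0.0, 1.0))
        assert cmp_.degenerate

    def test_generating_model_detectable_at_large_n(self):
        """With many trials per cell the SD profiles are measured precisely and
        BIC identifies the generating law in both directions."""
        design = StudyDesign(n_participants=3, trials_per_location_per_task=400)
        for model, expected in (("trilateration", 1), ("truncation", -1)):
            df, roster = generate_cohort(design, seed=31, generative_model=model)
            norm = normalize_trials(df, roster, design)
            tab = fit_cohort(norm, seed=0)
            assert np.all(np.sign(tab["dBIC"]) == expected), model
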