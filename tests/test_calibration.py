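"""Fit-metric arithmetic and parameter recovery of the calibration stages."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import contrasim as cs
from contrasim import timegrid as tg
from contrasim.calibration import ReferenceTrajectory, expected_trajectory
from contrasim.methods import AGES, AGE_GROUPS, CONTRACEPTIVES, NOT_USING


def traj(years, values, variant="custom"):
    return ReferenceTrajectory(np.asarray(years), np.asarray(values), variant)


class TestRmsdFitPercentage:
    def test_model_equals_reference_is_zero(self):
        y = [2020, 2021]
        assert cs.rmsd_fit_percentage(traj(y, [5, 6]), traj(y, [5, 6]),
                                      traj(y, [9, 9])) == 0.0

    def test_model_equals_alternative_is_hundred(self):
        y = [2020, 2021]
        assert cs.rmsd_fit_percentage(traj(y, [9, 9]), traj(y, [5, 6]),
                                      traj(y, [9, 9])) == pytest.approx(100.0)

    def test_hand_example_fifty_percent(self):
        y = [2020, 2021]
        pct = cs.rmsd_fit_percentage(traj(y, [12, 10]), traj(y, [10, 10]),
                                     traj(y, [14, 10]))
        assert pct == pytest.approx(50.0)

    def test_degenerate_denominator_errors(self):
        y = [2020, 2021]
        with pytest.raises(ZeroDivisionError):
            cs.rmsd_fit_percentage(traj(y, [1, 2]), traj(y, [5, 6]),
                                   traj(y, [5, 6]))

    def test_mismatched_years_error(self):
        with pytest.raises(ValueError):
            cs.rmsd_fit_percentage(traj([2020], [1]), traj([2021], [1]),
                                   traj([2021], [1]))

    def test_scale_invariance_and_sign_symmetry(self):
        y = np.arange(2020, 2026)
        rng = np.random.default_rng(0)
        ref = rng.uniform(50, 100, 6)
        model = ref + rng.normal(0, 5, 6)
        alt = ref + rng.normal(0, 10, 6)
        a = cs.rmsd_fit_percentage(traj(y, model), traj(y, ref), traj(y, alt))
        b = cs.rmsd_fit_percentage(traj(y, 3 * model), traj(y, 3 * ref),
                                   traj(y, 3 * alt))
        assert a == pytest.approx(b)
        mirrored = 2 * ref - model  # deviations with flipped sign
        c = cs.rmsd_fit_percentage(traj(y, mirrored), traj(y, ref), traj(y, alt))
        assert a == pytest.approx(c)

    def test_trajectory_validation(self):
        with pytest.raises(ValueError):
            ReferenceTrajectory([2020, 2020], [1, 2])
        with pytest.raises(ValueError):
            ReferenceTrajectory([2020, 2021], [1, -2])


class TestScalingFactorFit:
    def test_fixed_point_when_already_matching(self, params):
        base = cs.fit_pregnancy_scaling_factors(params,
                                                params.age_specific_fertility_rates)
        achieved_asfr = pd.Series(base.achieved_vs_target["achieved"].values * 12,
                                  index=list(AGE_GROUPS))
        p = dataclasses.replace(
            params, scaling_factor_on_monthly_risk_of_pregnancy=base.fitted)
        res = cs.fit_pregnancy_scaling_factors(p, achieved_asfr)
        assert res.converged
        assert np.allclose(res.fitted.values, base.fitted.values, rtol=1e-6)

    def test_one_group_closed_form_without_contraception(self, params):
        """No contraception: factor = target / (base risk x live-birth prob)."""
        p = params.copy()
        mu = p.method_use_in_2010
        mu.iloc[:, :] = 0.0
        mu[NOT_USING] = 1.0
        p.pregnancy_not_using_in_2010[:] = 0.02
        p = dataclasses.replace(p, live_birth_probability=0.9)
        target = pd.Series(0.12, index=list(AGE_GROUPS))
        res = cs.fit_pregnancy_scaling_factors(p, target)
        closed_form = (0.12 / 12) / (0.02 * 0.9)
        assert np.allclose(res.fitted.values, closed_form, rtol=1e-9)

    def test_output_has_seven_group_format(self, params):
        res = cs.fit_pregnancy_scaling_factors(params,
                                               params.age_specific_fertility_rates)
        assert list(res.fitted.index) == list(AGE_GROUPS)
        assert len(res.fitted) == 7

    def test_unreachable_target_names_group(self, params):
        p = params.copy()
        mu = p.method_use_in_2010
        mu.iloc[:, :] = 0.0
        mu[NOT_USING] = 1.0
        p.pregnancy_not_using_in_2010[:] = 0.0
        with pytest.raises(RuntimeError, match="15-19"):
            cs.fit_pregnancy_scaling_factors(
                p, pd.Series(0.1, index=list(AGE_GROUPS)))

    def test_fit_reproduces_target_within_one_percent(self, params):
        res = cs.fit_pregnancy_scaling_factors(
            params, params.age_specific_fertility_rates, tol=0.01)
        assert res.converged
        rel = np.abs(res.achieved_vs_target["achieved"]
                     - res.achieved_vs_target["target_monthly"]) \
            / res.achieved_vs_target["target_monthly"]
        assert (rel < 0.01).all()


class TestTimeTrendFit:
    def horizon(self):
        return tg.month_index(2010), tg.month_index(2031)

    def test_fixed_point_at_no_trend(self, params):
        p = dataclasses.replace(params, time_age_trend_in_initiation=1.0,
                                time_age_trend_in_stopping=1.0)
        start, end = self.horizon()
        target = expected_trajectory(p, start, end)["births_by_year"]
        res = cs.fit_time_trends(p, ReferenceTrajectory(target.index.values,
                                                        target.values))
        assert abs(res.fitted["time_age_trend_in_initiation"] - 1.0) < 0.005
        assert abs(res.fitted["time_age_trend_in_stopping"] - 1.0) < 0.005

    def test_recovers_known_trends(self, params):
        truth = (1.02, 0.98)
        q = dataclasses.replace(params, time_age_trend_in_initiation=truth[0],
                                time_age_trend_in_stopping=truth[1])
        start, end = self.horizon()
        target = expected_trajectory(q, start, end)["births_by_year"]
        res = cs.fit_time_trends(params,
                                 ReferenceTrajectory(target.index.values,
                                                     target.values))
        assert res.converged
        assert res.fitted["time_age_trend_in_initiation"] == \
            pytest.approx(truth[0], abs=0.005)
        assert res.fitted["time_age_trend_in_stopping"] == \
            pytest.approx(truth[1], abs=0.005)

    def test_declining_births_need_rising_initiation(self, params):
        q = dataclasses.replace(params, time_age_trend_in_initiation=1.03,
                                time_age_trend_in_stopping=0.97)
        start, end = self.horizon()
        target = expected_trajectory(q, start, end)["births_by_year"]
        assert target.iloc[-1] < target.iloc[1]  # genuinely declining
        res = cs.fit_time_trends(params,
                                 ReferenceTrajectory(target.index.values,
                                                     target.values))
        assert res.fitted["time_age_trend_in_initiation"] > 1.0


class TestInterventionMultiplierFit:
    def config(self, iv):
        return cs.SimulationConfig(n_agents=1,
                                   start_month=tg.month_index(2010),
                                   end_month=tg.month_index(2031),
                                   intervention=iv)

    def test_fixed_point_at_no_intervention_projection(self, params):
        iv = cs.InterventionSpec(pop=pd.Series(dtype=float),
                                 ppfp=pd.Series(dtype=float),
                                 start_month=tg.month_index(2023))
        cfg = self.config(iv)
        shares = expected_trajectory(params, cfg.start_month, cfg.end_month,
                                     intervention=iv)["final_shares"]
        target = shares[["injection", "implant", "pill"]]
        res = cs.calibrate_intervention_multipliers(params, target, cfg)
        assert res.converged
        for m in target.index:
            assert res.fitted[f"pop:{m}"] == pytest.approx(1.0, abs=0.05)

    def test_higher_target_share_needs_larger_multiplier(self, params):
        iv = cs.InterventionSpec(pop=pd.Series(dtype=float),
                                 ppfp=pd.Series(dtype=float),
                                 start_month=tg.month_index(2023))
        cfg = self.config(iv)
        shares = expected_trajectory(params, cfg.start_month, cfg.end_month,
                                     intervention=iv)["final_shares"]
        target = pd.Series({"implant": min(2 * shares["implant"], 0.5)})
        res = cs.calibrate_intervention_multipliers(params, target, cfg)
        assert res.converged
        assert res.fitted["pop:implant"] > 1.0

    def test_self_consistency_at_horizon(self, params):
        iv = cs.default_intervention_spec(tg.month_index(2023))
        cfg = self.config(iv)
        target = pd.Series({"injection": 0.30, "implant": 0.12, "pill": 0.05})
        res = cs.calibrate_intervention_multipliers(params, target, cfg,
                                                    tol=0.01)
        assert res.converged
        fitted_iv = cs.InterventionSpec(
            pop=res.fitted.filter(like="pop:").rename(lambda s: s[4:]),
            ppfp=iv.ppfp, start_month=iv.start_month)
        achieved = expected_trajectory(params, cfg.start_month, cfg.end_month,
                                       intervention=fitted_iv)["final_shares"]
        for m in target.index:
            assert achieved[m] == pytest.approx(target[m], rel=0.011)

    def test_unreachable_and_invalid_targets_error(self, params):
        iv = cs.default_intervention_spec(tg.month_index(2023))
        cfg = self.config(iv)
        p = params.copy()
        p.initiation_by_method["IUD"] = 0.0
        with pytest.raises(ValueError, match="IUD"):
            cs.calibrate_intervention_multipliers(p, pd.Series({"IUD": 0.1}), cfg)
        with pytest.raises(ValueError):
            cs.calibrate_intervention_multipliers(
                params, pd.Series({"withdrawal": 0.1}), cfg)

    def test_postpartum_targets_fitted_directly(self, params):
        iv = cs.default_intervention_spec(tg.month_index(2023))
        cfg = self.config(iv)
        target_pp = pd.Series({"injection": 0.25})
        res = cs.calibrate_intervention_multipliers(
            params, pd.Series({"implant": 0.10}), cfg,
            target_postpartum=target_pp)
        expected = 0.25 / params.initiation_after_birth["injection"]
        assert res.fitted["ppfp:injection"] == pytest.approx(expected)
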