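"""Transition probabilities, sampling kernels, and full-run invariants."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import contrasim as cs
from contrasim import timegrid as tg
from contrasim.engine import (
    _MonthTables,
    sample_after_birth_outcomes,
    sample_not_using_outcomes,
    sample_using_outcomes,
)
from contrasim.methods import AGES, AGE_GROUPS, CONTRACEPTIVES, METHOD_INDEX, NOT_USING
from contrasim.population import FEMALE, Person


def flat_params(params, **series):
    """Parameter set with neutral age effects/trends and given method tables."""
    p = params.copy()
    over = dict(
        initiation_by_age=pd.Series(0.0, index=list(AGES)),
        discontinuation_by_age=pd.Series(0.0, index=list(AGES)),
        time_age_trend_in_initiation=1.0,
        time_age_trend_in_stopping=1.0,
        initiation_by_method_age=None,
        initiation_after_birth_age=None,
    )
    over.update(series)
    return dataclasses.replace(p, **over)


class TestRiskProducts:
    def test_not_using_risk_applies_scaling_factor(self, params):
        p = params.copy()
        p.pregnancy_not_using_in_2010[17] = 0.10
        # age 17 is in the 15-19 group with published scaling factor 1.227
        assert cs.monthly_pregnancy_risk_not_using(17, False, p) == \
            pytest.approx(0.1227)

    def test_not_using_risk_applies_hiv_multiplier(self, params):
        p = params.copy()
        p.pregnancy_not_using_in_2010[17] = 0.10
        assert cs.monthly_pregnancy_risk_not_using(17, True, p) == \
            pytest.approx(0.17178)  # 0.10 x 1.4 x 1.227

    def test_zero_base_is_zero(self, params):
        p = params.copy()
        p.pregnancy_not_using_in_2010[30] = 0.0
        assert cs.monthly_pregnancy_risk_not_using(30, True, p) == 0.0

    def test_age_out_of_range_errors(self, params):
        with pytest.raises(ValueError):
            cs.monthly_pregnancy_risk_not_using(14, False, params)

    def test_failure_risk_under_25(self, params):
        p = params.copy()
        p.failure_by_method["pill"] = 0.005
        # 0.005 x rr 2.2 x scaling 0.799 (20-24)
        assert cs.monthly_failure_risk("pill", 22, p) == pytest.approx(0.0087890)

    def test_failure_risk_over_25(self, params):
        p = params.copy()
        p.failure_by_method["pill"] = 0.005
        assert cs.monthly_failure_risk("pill", 30, p) == pytest.approx(0.004045)

    def test_failure_risk_not_using_errors(self, params):
        with pytest.raises(ValueError):
            cs.monthly_failure_risk(NOT_USING, 30, params)


class TestMultiplicativeContracts:
    def test_initiation_stack(self, params, month2010):
        """base 0.02 x (1 + 0.5) age effect x 2 intervention = 0.06."""
        p = flat_params(params)
        p.initiation_by_method["injection"] = 0.02
        p.initiation_by_age[30] = 0.5
        iv = cs.InterventionSpec(pop=pd.Series({"injection": 2.0}),
                                 ppfp=pd.Series(dtype=float),
                                 start_month=month2010)
        t = _MonthTables(p, month2010, iv)
        j = CONTRACEPTIVES.index("injection")
        assert t.init[30 - 15, j] == pytest.approx(0.06)

    def test_postpartum_multiplier(self, params, month2010):
        p = flat_params(params)
        p.initiation_after_birth["injection"] = 0.2
        iv = cs.InterventionSpec(pop=pd.Series(dtype=float),
                                 ppfp=pd.Series({"injection": 1.5}),
                                 start_month=month2010)
        t = _MonthTables(p, month2010, iv)
        j = CONTRACEPTIVES.index("injection")
        assert t.after_birth[0, j] == pytest.approx(0.3)

    def test_intervention_inactive_before_start(self, params, month2010):
        p = flat_params(params)
        p.initiation_by_method["injection"] = 0.02
        iv = cs.InterventionSpec(pop=pd.Series({"injection": 2.0}),
                                 ppfp=pd.Series(dtype=float),
                                 start_month=month2010 + 12)
        t = _MonthTables(p, month2010, iv)
        j = CONTRACEPTIVES.index("injection")
        assert t.init[0, j] == pytest.approx(p.initiation_by_method["injection"]
                                             * (1 + p.initiation_by_age.iloc[0]))

    def test_trend_compounds_per_year(self, params):
        p = flat_params(params, time_age_trend_in_initiation=1.02)
        p.initiation_by_method["pill"] = 0.01
        t = _MonthTables(p, tg.month_index(2015), None)
        j = CONTRACEPTIVES.index("pill")
        assert t.init[0, j] == pytest.approx(0.01 * 1.02 ** 5)


class TestSamplingKernels:
    def test_using_kernel_matches_enumeration(self):
        """(0.01, 0.1, 0.2) gives {0.01, 0.099, 0.1782, 0.7128} at 10^6 draws."""
        n = 1_000_000
        rng = np.random.default_rng(12345)
        sw = np.tile(np.cumsum(np.full(10, 0.1)), (n, 1))
        codes, _ = sample_using_outcomes(
            np.full(n, 0.01), np.full(n, 0.1), np.full(n, 0.2), sw,
            rng.random((n, 4)))
        expected = {1: 0.01, 2: 0.099, 3: 0.1782, 0: 0.7128}
        for code, prob in expected.items():
            freq = (codes == code).mean()
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(freq - prob) < 4 * se, (code, freq, prob)

    def test_not_using_kernel_matches_enumeration(self):
        n = 400_000
        rng = np.random.default_rng(7)
        init = np.zeros((n, 10))
        init[:, 2] = 0.03   # injection slot
        init[:, 0] = 0.01
        preg = np.full(n, 0.05)
        out, resc = sample_not_using_outcomes(init, preg, rng.random(n))
        assert resc == 0
        for code, prob in {3: 0.03, 1: 0.01, 11: 0.05, 0: 0.91}.items():
            freq = (out == code).mean()
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(freq - prob) < 4 * se

    def test_rescaling_when_probabilities_exceed_one(self):
        init = np.array([[0.8] + [0.0] * 9])
        preg = np.array([0.4])
        out, resc = sample_not_using_outcomes(init, preg, np.array([0.999]))
        assert resc == 1
        assert out[0] in (1, 11)  # stay has zero mass after rescaling

    def test_switch_destinations_follow_matrix_row(self):
        n = 200_000
        rng = np.random.default_rng(3)
        row = np.zeros(10)
        row[4] = 0.25
        row[5] = 0.75
        sw = np.tile(np.cumsum(row), (n, 1))
        codes, dest = sample_using_outcomes(
            np.zeros(n), np.zeros(n), np.ones(n), sw, rng.random((n, 4)))
        assert (codes == 3).all()
        share = (dest == 5).mean()
        assert abs(share - 0.75) < 4 * np.sqrt(0.75 * 0.25 / n)


class TestSinglePersonSteps:
    def woman(self, month, method=NOT_USING, age=30, pregnant=False,
              preg_month=None):
        return Person(person_id=0, sex="F", date_of_birth=month - age * 12,
                      co_contraception=method, is_pregnant=pregnant,
                      date_of_last_pregnancy=preg_month)

    def test_all_zero_probabilities_stay(self, zero_transition_params, month2010):
        rng = np.random.default_rng(0)
        out = cs.step_not_using(self.woman(month2010), zero_transition_params,
                                None, month2010, rng)
        assert out.kind == "stay"
        out = cs.step_using(self.woman(month2010, "pill"),
                            zero_transition_params, month2010, rng)
        assert out.kind == "stay"

    def test_sterilization_is_absorbing(self, params, month2010):
        p = params.copy()
        p.discontinuation_by_method["female_sterilization"] = 1.0
        p.prob_switch_from["female_sterilization"] = 1.0
        p.failure_by_method["female_sterilization"] = 0.0
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = cs.step_using(self.woman(month2010, "female_sterilization"),
                                p, month2010, rng)
            assert out.kind == "stay"

    def test_precondition_violations_error(self, params, month2010):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            cs.step_not_using(self.woman(month2010, "pill"), params, None,
                              month2010, rng)
        with pytest.raises(ValueError):
            cs.step_using(self.woman(month2010), params, month2010, rng)
        with pytest.raises(ValueError):
            cs.step_not_using(self.woman(month2010, age=52), params, None,
                              month2010, rng)

    def test_step_frequencies_match_kernel(self, params, month2010):
        """The record-level wrapper reproduces the kernel distribution."""
        p = flat_params(params)
        p.failure_by_method["pill"] = 0.01 / 0.809  # cancel the 30-34 scaling
        p.discontinuation_by_method["pill"] = 0.1
        p.prob_switch_from["pill"] = 0.2
        rng = np.random.default_rng(99)
        kinds = [cs.step_using(self.woman(month2010, "pill"), p, month2010, rng).kind
                 for _ in range(4000)]
        freq = pd.Series(kinds).value_counts(normalize=True)
        for kind, prob in {"failure_pregnancy": 0.01, "discontinue": 0.099,
                           "switch": 0.1782, "stay": 0.7128}.items():
            se = np.sqrt(prob * (1 - prob) / 4000)
            assert abs(freq.get(kind, 0.0) - prob) < 4 * se

    def test_resolve_pregnancy_schedule(self, params, month2010):
        w = self.woman(month2010, pregnant=True, preg_month=month2010 - 9)
        rng = np.random.default_rng(0)
        out = cs.resolve_pregnancy(w, params, None, month2010, rng)
        assert out.kind == "birth"  # live_birth_probability defaults to 1
        with pytest.raises(ValueError):
            cs.resolve_pregnancy(w, params, None, month2010 + 1, rng)


class TestRunSimulation:
    def run(self, p, n=3000, years=3, seed=5, iv=None, **kw):
        cfg = cs.SimulationConfig(
            n_agents=n, start_month=tg.month_index(2010),
            end_month=tg.month_index(2010 + years), seed=seed,
            intervention=iv, **kw)
        return cs.run_simulation(cfg, p)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cs.SimulationConfig(n_agents=0, start_month=0, end_month=1)
        with pytest.raises(ValueError):
            cs.SimulationConfig(n_agents=10, start_month=5, end_month=5)

    def test_frozen_world_changes_only_by_aging(self, zero_transition_params,
                                                zero_mortality):
        cfg = cs.SimulationConfig(n_agents=2000,
                                  start_month=tg.month_index(2010),
                                  end_month=tg.month_index(2013), seed=5)
        r = cs.run_simulation(cfg, zero_transition_params, sched=zero_mortality)
        assert r.monthly["births"].sum() == 0      # no initial ASFR either
        assert r.monthly["deaths"].sum() == 0
        assert r.monthly["new_pregnancies"].sum() == 0
        assert (r.monthly["population"] == r.monthly["population"].iloc[0]).all()

    def test_identical_seeds_identical_event_logs(self, restricted_params):
        a = self.run(restricted_params, seed=21)
        b = self.run(restricted_params, seed=21)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.monthly, b.monthly)

    def test_conservation_each_month(self, restricted_params):
        r = self.run(restricted_params)
        from contrasim.methods import METHODS
        state_sum = r.monthly[list(METHODS)].sum(axis=1)
        assert (state_sum == r.monthly["women_15_49"]).all()

    def test_newborns_equal_birth_events(self, restricted_params):
        r = self.run(restricted_params)
        n_birth_events = (r.events["kind"] == "birth").sum()
        assert n_birth_events == r.monthly["births"].sum()

    def test_no_transitions_for_dead_or_male(self, restricted_params):
        r = self.run(restricted_params)
        final = r.final_population.set_index("person_id")
        ev = r.events[r.events["kind"] != "death"]
        assert (final.loc[ev["person_id"].unique(), "sex"] == "F").all()
        # no event after a death event for the same person
        deaths = r.events[r.events["kind"] == "death"].set_index("person_id")["month"]
        merged = ev.join(deaths.rename("death_month"), on="person_id")
        assert not (merged["month"] > merged["death_month"]).any()

    def test_event_log_replay_reconstructs_method_state(self, restricted_params):
        r = self.run(restricted_params)
        final = r.final_population.set_index("person_id")
        changes = r.events[r.events["kind"].isin(
            ["initiate", "switch", "discontinue", "failure_pregnancy",
             "postpartum_initiate"])]
        last = changes.sort_values("month", kind="stable").groupby("person_id").tail(1)
        end_month = r.config.end_month
        for row in last.itertuples(index=False):
            f = final.loc[row.person_id]
            if not f.alive or f.is_pregnant:
                continue
            age = (end_month - f.date_of_birth) // 12
            if age > 49:
                continue  # forced to not_using on exit from the risk set
            expected = (NOT_USING if row.kind in ("discontinue",
                                                  "failure_pregnancy")
                        else row.to_method)
            if row.kind == "failure_pregnancy":
                # pregnancy may have resolved and postpartum happened later
                continue
            assert f.co_contraception == expected

    def test_intervention_raises_prevalence_every_month(self, restricted_params):
        iv = cs.default_intervention_spec(tg.month_index(2012))
        base = self.run(restricted_params, n=8000, years=8, seed=13)
        with_iv = self.run(restricted_params, n=8000, years=8, seed=13, iv=iv)
        using_b = 1 - base.monthly["not_using"] / base.monthly["women_15_49"]
        using_i = (1 - with_iv.monthly["not_using"]
                   / with_iv.monthly["women_15_49"])
        after = base.monthly.index >= iv.start_month
        assert (using_i[after] >= using_b[after]).all()
        assert (with_iv.monthly["new_pregnancies"][after].sum()
                <= base.monthly["new_pregnancies"][after].sum())
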