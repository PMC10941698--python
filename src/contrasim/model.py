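"""Model/Results facade over the simulator and calibration routines.

:class:`ContraceptionModel` bundles a parameter set with a run
configuration; :meth:`~ContraceptionModel.fit` runs the calibration stages
(baseline fertility scaling, secular trends, intervention multipliers) and
returns a results object carrying the fitted values, achieved-vs-target
diagnostics and a text summary; :meth:`~ContraceptionModel.simulate` runs
the stochastic engine.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from . import timegrid
from .calibration import (
    CalibrationResult,
    ReferenceTrajectory,
    calibrate_intervention_multipliers,
    fit_pregnancy_scaling_factors,
    fit_time_trends,
)
from .engine import SimulationConfig, SimulationResult, run_simulation
from .parameters import (
    InterventionSpec,
    ParameterSet,
    apply_sterilization_age_restriction,
    generate_default_parameters,
)


class ContraceptionModel:
    """A contraception-and-pregnancy microsimulation bound to one configuration."""

    def __init__(self, params: ParameterSet, config: SimulationConfig,
                 mortality: pd.DataFrame | None = None,
                 age_structure: pd.Series | None = None,
                 hiv_prevalence: pd.Series | None = None):
        self.params = params
        self.config = config
        self.mortality = mortality
        self.age_structure = age_structure
        self.hiv_prevalence = hiv_prevalence

    @classmethod
    def from_defaults(cls, seed: int = 0, n_agents: int = 20_000,
                      start_year: int = 2010, end_year: int = 2050,
                      intervention: InterventionSpec | None = None,
                      sterilization_age: int = 30,
                      **kwargs) -> "ContraceptionModel":
        """Synthetic default parameters with the sterilization age restriction."""
        p = apply_sterilization_age_restriction(
            generate_default_parameters(seed), eligible_age=sterilization_age)
        cfg = SimulationConfig(
            n_agents=n_agents,
            start_month=timegrid.month_index(start_year),
            end_month=timegrid.month_index(end_year),
            seed=seed, intervention=intervention, **kwargs)
        return cls(p, cfg)

    def simulate(self, params: ParameterSet | None = None) -> SimulationResult:
        return run_simulation(self.config, params or self.params,
                              sched=self.mortality,
                              age_structure=self.age_structure,
                              hiv_prevalence=self.hiv_prevalence)

    def fit(self,
            target_asfr: pd.Series | None = None,
            target_births: ReferenceTrajectory | None = None,
            target_mix: pd.Series | None = None,
            target_postpartum: pd.Series | None = None,
            tol: float = 0.01) -> "ContraceptionFit":
        """Run the applicable calibration stages and return the fitted results.

        Stage 1 fits the age-group pregnancy scaling factors to
        ``target_asfr``; stage 2 fits the two secular trend scalars to the
        ``target_births`` trajectory; stage 3 fits intervention multipliers
        to the ``target_mix`` method shares at the configured horizon.
        Stages whose target is not given are skipped.
        """
        p = self.params
        stages: dict[str, CalibrationResult] = {}
        if target_asfr is not None:
            res = fit_pregnancy_scaling_factors(p, target_asfr, self.config, tol=tol)
            p = dataclasses.replace(
                p, scaling_factor_on_monthly_risk_of_pregnancy=res.fitted)
            stages["scaling_factors"] = res
        if target_births is not None:
            res = fit_time_trends(p, target_births, self.config)
            p = dataclasses.replace(
                p,
                time_age_trend_in_initiation=float(
                    res.fitted["time_age_trend_in_initiation"]),
                time_age_trend_in_stopping=float(
                    res.fitted["time_age_trend_in_stopping"]))
            stages["time_trends"] = res
        intervention = self.config.intervention
        if target_mix is not None:
            if intervention is None:
                raise ValueError("config must carry an intervention to calibrate")
            res = calibrate_intervention_multipliers(
                p, target_mix, self.config, tol=tol,
                target_postpartum=target_postpartum)
            pop = res.fitted.filter(like="pop:").rename(lambda s: s[4:])
            ppfp = res.fitted.filter(like="ppfp:").rename(lambda s: s[5:])
            intervention = InterventionSpec(
                pop=pop, ppfp=ppfp, start_month=intervention.start_month)
            stages["intervention_multipliers"] = res
        return ContraceptionFit(self, p, intervention, stages)


@dataclasses.dataclass
class ContraceptionFit:
    """Calibrated parameters plus per-stage diagnostics."""

    model: ContraceptionModel
    params: ParameterSet
    intervention: InterventionSpec | None
    stages: dict[str, CalibrationResult]

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.stages.values())

    def simulate(self) -> SimulationResult:
        """Run the stochastic engine under the calibrated parameters."""
        cfg = dataclasses.replace(self.model.config, intervention=self.intervention)
        m = ContraceptionModel(self.params, cfg, self.model.mortality,
                               self.model.age_structure, self.model.hiv_prevalence)
        return m.simulate()

    def summary(self) -> str:
        lines = ["Contraception model calibration",
                 "=" * 34]
        for name, res in self.stages.items():
            lines.append(f"\n[{name}] converged={res.converged} "
                         f"iterations={res.iterations}")
            lines.append(res.achieved_vs_target.round(5).to_string())
        if not self.stages:
            lines.append("(no calibration stages requested)")
        return "\n".join(lines)
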