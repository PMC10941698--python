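"""Calibration of scaling factors, secular trends and intervention multipliers.

The fitting loops run on an *expectation-mode* companion of the stochastic
engine: instead of sampling individuals, it propagates expected state
fractions per single year of age through the identical monthly transition
structure (methods, pregnancy pipeline, postpartum initiation).  This makes
every objective evaluation deterministic and fast, so the fits are exact
fixed-point / least-squares problems.  Mortality and HIV status are not
modelled in expectation mode, and the inflow of women turning 15 is held at
its initial size (stationary inflow); the stochastic engine is the final
arbiter of any calibrated parameter set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from . import timegrid
from .methods import AGE_GROUPS, AGE_MIN, AGE_MAX, CONTRACEPTIVES, METHOD_INDEX, MODERN_METHODS
from .parameters import BASELINE_YEAR, InterventionSpec, ParameterSet
from .engine import PREGNANCY_MONTHS


@dataclasses.dataclass
class ReferenceTrajectory:
    """An annual reference series (births or population) to calibrate against."""

    years: np.ndarray
    values: np.ndarray
    variant: str = "custom"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.values = np.asarray(self.values, float)
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if (np.diff(self.years) <= 0).any():
            raise ValueError("years must be strictly increasing")
        if (self.values < 0).any():
            raise ValueError("values must be >= 0")

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years)


@dataclasses.dataclass
class CalibrationResult:
    """Fitted values plus the achieved-vs-target diagnostics."""

    fitted: pd.Series
    achieved_vs_target: pd.DataFrame
    converged: bool
    iterations: int
    rmsd: float | None = None

    def summary(self) -> str:
        lines = ["Calibration result",
                 f"  converged: {self.converged}  iterations: {self.iterations}"]
        if self.rmsd is not None:
            lines.append(f"  achieved RMSD: {self.rmsd:.6g}")
        lines.append(self.achieved_vs_target.to_string())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# expectation-mode propagation

_N_AGES = AGE_MAX - AGE_MIN + 1
# columns: 0 not_using, 1..10 methods, 11..19 pregnancy months 1..9, 20 postpartum
_N_STATES = 11 + PREGNANCY_MONTHS + 1
_STER = METHOD_INDEX["female_sterilization"] - 1


def _initial_state(p: ParameterSet, age_weights: np.ndarray) -> np.ndarray:
    C = np.zeros((_N_AGES, _N_STATES))
    C[:, :11] = p.method_use_in_2010.values * age_weights[:, None]
    return C


def expected_trajectory(
    p: ParameterSet,
    start_month: int,
    end_month: int,
    intervention: InterventionSpec | None = None,
    age_weights: np.ndarray | None = None,
) -> dict:
    """Deterministic expected births and method mix, monthly steps.

    Returns a dict with ``births_by_year`` (Series, live births per calendar
    year in units of the age-weight totals), ``final_shares`` (Series over
    the 11 states at the final month) and ``monthly_shares`` (DataFrame of
    state shares per month).
    """
    if age_weights is None:
        age_weights = np.ones(_N_AGES)
    C = _initial_state(p, np.asarray(age_weights, float))
    inflow = C[0].sum()

    # static per-age tables; only the trend factors and the intervention
    # switch vary by month
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    gi = (ages - AGE_MIN) // 5
    sf = p.scaling_factor_on_monthly_risk_of_pregnancy.values[gi]
    init_base = (p.initiation_matrix().values
                 * (1.0 + p.initiation_by_age.values)[:, None])
    preg_nu = np.minimum(p.pregnancy_not_using_in_2010.values * sf, 1.0)
    fail = np.clip(np.tile(p.failure_by_method.values, (_N_AGES, 1))
                   * np.where(ages < 25, p.rr_fail_under25, 1.0)[:, None]
                   * sf[:, None], 0.0, 1.0)
    disc_base = (np.tile(p.discontinuation_by_method.values, (_N_AGES, 1))
                 * (1.0 + p.discontinuation_by_age.values)[:, None])
    ab_base = p.after_birth_matrix().values
    pop_mult = intervention.pop.values if intervention is not None else None
    ppfp_mult = intervention.ppfp.values if intervention is not None else None
    base_m = timegrid.month_index(BASELINE_YEAR)

    births: dict[int, float] = {}
    share_rows = []
    sm = p.switch_matrix.values
    for month in range(start_month, end_month):
        active = intervention is not None and intervention.active(month)
        yrs = (month - base_m) / 12.0
        init_t = np.clip(init_base * p.time_age_trend_in_initiation ** yrs
                         * (pop_mult[None, :] if active else 1.0), 0.0, 1.0)
        disc_t = np.clip(disc_base * p.time_age_trend_in_stopping ** yrs, 0.0, 1.0)
        ab_t = np.clip(ab_base * (ppfp_mult[None, :] if active else 1.0), 0.0, 1.0)

        notu = C[:, 0]
        meth = C[:, 1:11]
        preg = C[:, 11:11 + PREGNANCY_MONTHS]
        pp = C[:, 11 + PREGNANCY_MONTHS]
        new = np.zeros_like(C)

        # postpartum initiation draw
        ab = ab_t
        ab_tot = ab.sum(axis=1)
        scale = np.where(ab_tot > 1, 1.0 / np.maximum(ab_tot, 1e-300), 1.0)
        new[:, 1:11] += pp[:, None] * ab * scale[:, None]
        new[:, 0] += pp * (1.0 - np.minimum(ab_tot, 1.0))

        # non-users
        q = preg_nu
        I = init_t
        tot = I.sum(axis=1) + q
        scale = np.where(tot > 1, 1.0 / np.maximum(tot, 1e-300), 1.0)
        new[:, 11] += notu * q * scale
        new[:, 1:11] += notu[:, None] * I * scale[:, None]
        new[:, 0] += notu * (1.0 - np.minimum(tot, 1.0))

        # users (sterilization is absorbing)
        pf = fail
        pdisc = disc_t.copy()
        pdisc[:, _STER] = 0.0
        psw = np.tile(p.prob_switch_from.values, (_N_AGES, 1))
        psw[:, _STER] = 0.0
        fail_flow = meth * pf
        disc_flow = meth * (1 - pf) * pdisc
        switch_out = meth * (1 - pf) * (1 - pdisc) * psw
        stay = meth * (1 - pf) * (1 - pdisc) * (1 - psw)
        new[:, 11] += fail_flow.sum(axis=1)
        new[:, 0] += disc_flow.sum(axis=1)
        new[:, 1:11] += stay + switch_out @ sm

        # pregnancy pipeline
        new[:, 12:11 + PREGNANCY_MONTHS] += preg[:, :-1]
        completing = preg[:, -1]
        new[:, 11 + PREGNANCY_MONTHS] += completing
        yr = timegrid.year_of(month)
        births[yr] = births.get(yr, 0.0) + completing.sum() * p.live_birth_probability

        C = new
        share_rows.append(C[:, :11].sum(axis=0) / C.sum())

        # aging at year end: everyone shifts one year of age in January
        if timegrid.month_of(month) == 12:
            C[1:] = C[:-1]
            C[0] = 0.0
            C[0, 0] = inflow

    monthly_shares = pd.DataFrame(
        share_rows, index=range(start_month, end_month),
        columns=["not_using"] + list(CONTRACEPTIVES))
    return {
        "births_by_year": pd.Series(births).sort_index(),
        "final_shares": monthly_shares.iloc[-1],
        "monthly_shares": monthly_shares,
    }


# ---------------------------------------------------------------------------
# stage 1: pregnancy scaling factors

def fit_pregnancy_scaling_factors(
    p: ParameterSet,
    target_asfr: pd.Series,
    sim=None,
    tol: float = 0.01,
    max_iter: int = 200,
    age_weights: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit the age-group scaling factors to baseline fertility.

    The factors are updated by iterative proportional fitting so that the
    expected age-specific monthly live-birth probability at the start of the
    simulation — given the baseline method mix — matches ``target_asfr/12``.
    The achieved probability is linear in the factor, so the loop converges
    immediately; the loop form retains robustness under the probability caps.
    """
    target_asfr = target_asfr.reindex(list(AGE_GROUPS)).astype(float)
    if age_weights is None:
        age_weights = np.ones(_N_AGES)
    w = np.asarray(age_weights, float)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    gi = (ages - AGE_MIN) // 5
    mu = p.method_use_in_2010.values
    rr = np.where(ages < 25, p.rr_fail_under25, 1.0)
    base_nu = p.pregnancy_not_using_in_2010.values
    fail = p.failure_by_method.values

    # per-age expected monthly pregnancy probability per unit scaling factor
    per_age = mu[:, 0] * base_nu + (mu[:, 1:] * fail[None, :] * rr[:, None]).sum(axis=1)
    per_age *= p.live_birth_probability

    factors = p.scaling_factor_on_monthly_risk_of_pregnancy.copy().astype(float)
    target_monthly = target_asfr.values / 12.0
    achieved = np.zeros(len(AGE_GROUPS))
    it = 0
    for it in range(1, max_iter + 1):
        for g in range(len(AGE_GROUPS)):
            sel = gi == g
            num = (w[sel] * np.minimum(per_age[sel] * factors.iloc[g], 1.0)).sum()
            den = w[sel].sum()
            achieved[g] = num / den if den > 0 else 0.0
        gaps = np.abs(achieved - target_monthly) / np.maximum(target_monthly, 1e-300)
        if (gaps < tol).all():
            break
        for g in range(len(AGE_GROUPS)):
            if target_monthly[g] > 0 and achieved[g] == 0:
                raise RuntimeError(
                    f"cannot reach positive fertility target in age group "
                    f"{AGE_GROUPS[g]}: achieved probability is zero")
            if achieved[g] > 0:
                factors.iloc[g] *= target_monthly[g] / achieved[g]
    converged = bool((gaps < tol).all())
    table = pd.DataFrame({"target_monthly": target_monthly, "achieved": achieved,
                          "factor": factors.values}, index=list(AGE_GROUPS))
    return CalibrationResult(fitted=factors, achieved_vs_target=table,
                             converged=converged, iterations=it)


# ---------------------------------------------------------------------------
# RMSD fit metric

def rmsd_fit_percentage(model: ReferenceTrajectory,
                        reference: ReferenceTrajectory,
                        alt_reference: ReferenceTrajectory) -> float:
    """Model fit as a percentage of the spread between projection variants.

    100 x RMSD(model, reference) / RMSD(alt_reference, reference); the
    denominator is the root-mean-square gap between the central reference
    and an alternative (e.g. high-variant) projection over the same years.
    """
    for other in (reference, alt_reference):
        if not np.array_equal(model.years, other.years):
            raise ValueError("all three series must share the same years")
    num = float(np.sqrt(np.mean((model.values - reference.values) ** 2)))
    den = float(np.sqrt(np.mean((alt_reference.values - reference.values) ** 2)))
    if den == 0:
        raise ZeroDivisionError(
            "reference and alternative variants coincide; fit metric undefined")
    return 100.0 * num / den


# ---------------------------------------------------------------------------
# stage 2: secular trends

def fit_time_trends(
    p: ParameterSet,
    target_births: ReferenceTrajectory,
    sim=None,
    tol: float = 1e-4,
    max_rounds: int = 4,
    bounds: tuple[float, float] = (0.90, 1.10),
    age_weights: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit the per-year initiation and discontinuation trends to a births path.

    Damped least squares on the vector of annual residuals (expectation-mode
    births minus target).  The two trends trade off along a narrow valley,
    so a Jacobian-based search is used rather than coordinate descent; the
    objective is deterministic, making the fit reproducible.
    """
    years = target_births.years
    start = timegrid.month_index(int(years[0]))
    end = timegrid.month_index(int(years[-1]) + 1)
    target = target_births.series()

    def run(ti: float, ts: float) -> pd.Series:
        q = dataclasses.replace(p, time_age_trend_in_initiation=float(ti),
                                time_age_trend_in_stopping=float(ts))
        traj = expected_trajectory(q, start, end, age_weights=age_weights)
        return traj["births_by_year"].reindex(years)

    def residuals(x: np.ndarray) -> np.ndarray:
        return run(x[0], x[1]).values - target.values

    sol = optimize.least_squares(
        residuals, x0=np.array([1.0, 1.0]),
        bounds=(np.array([bounds[0]] * 2), np.array([bounds[1]] * 2)),
        diff_step=1e-4, xtol=1e-10, ftol=1e-12, gtol=1e-12,
        max_nfev=60 * max_rounds)
    ti, ts = float(sol.x[0]), float(sol.x[1])
    model = run(ti, ts)
    best = float(np.sqrt(np.mean((model.values - target.values) ** 2)))
    table = pd.DataFrame({"target": target.values, "achieved": model.values},
                         index=years)
    fitted = pd.Series({"time_age_trend_in_initiation": ti,
                        "time_age_trend_in_stopping": ts})
    scale = float(np.mean(np.abs(target.values))) or 1.0
    converged = bool(sol.success) and best <= max(tol * scale, 1e-9)
    return CalibrationResult(fitted=fitted, achieved_vs_target=table,
                             converged=converged, iterations=int(sol.nfev),
                             rmsd=best)


# ---------------------------------------------------------------------------
# stage 3: intervention multipliers

def calibrate_intervention_multipliers(
    p: ParameterSet,
    target_mix: pd.Series,
    sim,
    tol: float = 0.01,
    max_iter: int = 200,
    target_postpartum: pd.Series | None = None,
    age_weights: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit per-method demand-creation multipliers to a target method mix.

    ``target_mix`` gives the desired share of women using each modern
    method at the horizon (``sim.end_month``) with the intervention active
    from ``sim.intervention.start_month``.  Multipliers are updated
    proportionally (multiplier <- multiplier x target/achieved) until every
    achieved share is within ``tol`` (relative) of its target.  Postpartum
    multipliers, if a postpartum-initiation target is given, are fitted the
    same way against the postpartum initiation probabilities.
    """
    target_mix = target_mix.dropna()
    bad = [m for m in target_mix.index if m not in MODERN_METHODS]
    if bad:
        raise ValueError(f"targets must be modern methods, got {bad}")
    if ((target_mix < 0) | (target_mix > 1)).any():
        raise ValueError("target shares must be in [0, 1]")
    iv0 = sim.intervention
    start_iv = iv0.start_month if iv0 is not None else sim.start_month
    mult = (iv0.pop.copy() if iv0 is not None
            else pd.Series(1.0, index=list(CONTRACEPTIVES)))
    ppfp = (iv0.ppfp.copy() if iv0 is not None
            else pd.Series(1.0, index=list(CONTRACEPTIVES)))

    base_init = p.initiation_by_method
    for m in target_mix.index:
        if base_init[m] == 0:
            raise ValueError(
                f"target share for {m!r} unreachable: baseline initiation is zero")

    achieved = pd.Series(index=target_mix.index, dtype=float)
    it = 0
    for it in range(1, max_iter + 1):
        iv = InterventionSpec(pop=mult.copy(), ppfp=ppfp.copy(),
                              start_month=start_iv)
        traj = expected_trajectory(p, sim.start_month, sim.end_month,
                                   intervention=iv, age_weights=age_weights)
        shares = traj["final_shares"]
        achieved = shares.reindex(target_mix.index).astype(float)
        gaps = (achieved - target_mix).abs() / np.maximum(target_mix, 1e-300)
        if (gaps < tol).all():
            break
        for m in target_mix.index:
            if achieved[m] > 0:
                mult[m] = mult[m] * float(target_mix[m] / achieved[m])

    if target_postpartum is not None:
        ab = p.initiation_after_birth
        for m in target_postpartum.index:
            if ab[m] == 0 and target_postpartum[m] > 0:
                raise ValueError(
                    f"postpartum target for {m!r} unreachable: baseline is zero")
            ppfp[m] = float(target_postpartum[m] / ab[m]) if ab[m] > 0 else 1.0

    converged = bool((gaps < tol).all())
    fitted = pd.concat([mult.rename(lambda m: f"pop:{m}"),
                        ppfp.rename(lambda m: f"ppfp:{m}")])
    table = pd.DataFrame({"target": target_mix, "achieved": achieved,
                          "multiplier": mult.reindex(target_mix.index)})
    return CalibrationResult(fitted=fitted, achieved_vs_target=table,
                             converged=converged, iterations=it)
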