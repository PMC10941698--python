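"""Monthly transition engine.

Each month, every alive woman aged 15-49 takes exactly one transition
outcome:

* not using: a single categorical draw over {initiate method m (for each
  of the 10 methods), become pregnant, stay};
* using a method: sequential competing draws — failure (pregnancy on the
  method), else discontinuation, else switching (destination drawn from the
  switch matrix row), else stay;
* pregnant: the pregnancy resolves nine months after conception; the
  following month the woman makes the postpartum initiation draw.

Female sterilization is absorbing: it never discontinues or switches.

Probabilities are modified multiplicatively by the age-effect deviations,
the per-year secular trends, the age-group pregnancy scaling factors, the
under-25 failure risk ratio, the HIV fertility effect, and — when an
intervention is active — the demand-creation (Pop) and postpartum (PPFP)
multipliers.  If a woman's non-stay probabilities sum above 1 after
multipliers they are rescaled proportionally and the event is counted.

Randomness is organised as one counter-based stream per (month, purpose),
with draws indexed by person id, so that two runs with the same seed but
different interventions share random numbers person-by-person (common
random numbers) and their difference isolates the intervention effect.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import timegrid
from .methods import (
    AGE_MAX,
    AGE_MIN,
    CONTRACEPTIVES,
    METHOD_INDEX,
    METHODS,
    NOT_USING,
    MAINTAINABLE_METHODS,
    age_group_index,
)
from .parameters import BASELINE_YEAR, InterventionSpec, ParameterSet, validate_parameters
from .population import (
    FEMALE,
    MALE,
    Person,
    Population,
    apply_mortality,
    advance_age,
    default_age_structure,
    default_mortality_schedule,
    initialize_population,
    schedule_initial_births,
)

PREGNANCY_MONTHS = 9

# rng stream purposes
_MORT, _SEX, _LIVE, _NU, _FAIL, _DISC, _SWITCH, _DEST, _PP = range(9)

EVENT_KINDS = (
    "initiate", "discontinue", "switch", "failure_pregnancy",
    "pregnancy_not_using", "birth", "postpartum_initiate", "death",
)


@dataclasses.dataclass
class TransitionOutcome:
    """One woman's outcome for one month."""

    kind: str
    person_id: int
    month: int
    from_method: str | None = None
    to_method: str | None = None


@dataclasses.dataclass
class SimulationConfig:
    n_agents: int
    start_month: int
    end_month: int           # exclusive
    seed: int = 0
    intervention: InterventionSpec | None = None
    scale_target_population: int | None = None
    record_events: bool = True

    def __post_init__(self) -> None:
        if self.n_agents <= 0:
            raise ValueError("n_agents must be > 0")
        if self.start_month >= self.end_month:
            raise ValueError("start_month must precede end_month")


@dataclasses.dataclass
class SimulationResult:
    """Monthly time series, event log and demographic snapshots."""

    monthly: pd.DataFrame        # indexed by month
    events: pd.DataFrame         # month, person_id, kind, from_method, to_method
    appointments: pd.DataFrame   # month, method, kind, count
    pyramids: pd.DataFrame       # year, sex, age, count (mid-year snapshots)
    config: SimulationConfig
    n_rescaled: int = 0          # woman-months with probability rescaling
    final_population: pd.DataFrame | None = None  # person-level end state

    @property
    def months(self) -> np.ndarray:
        return self.monthly.index.values

    def national_scale(self) -> float:
        """Multiplier taking simulated counts to the configured national scale."""
        if self.config.scale_target_population is None:
            return 1.0
        start_pop = float(self.monthly["population"].iloc[0])
        return self.config.scale_target_population / start_pop


def _stream(seed: int, month: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed) & 0x7FFFFFFF, int(month), purpose)))


def _trend_pow(rate: float, month: int) -> float:
    years = (month - timegrid.month_index(BASELINE_YEAR)) / 12.0
    return float(rate) ** years


# ---------------------------------------------------------------------------
# scalar risk functions

def monthly_pregnancy_risk_not_using(age: int, hiv_positive: bool,
                                     p: ParameterSet) -> float:
    """Monthly pregnancy probability for a non-user, with HIV and scaling effects."""
    gi = age_group_index(age)  # raises outside 15-49
    risk = float(p.pregnancy_not_using_in_2010.loc[age])
    if hiv_positive:
        risk *= float(p.pregnancy_not_using_hiv_effect.iloc[gi])
    risk *= float(p.scaling_factor_on_monthly_risk_of_pregnancy.iloc[gi])
    return min(risk, 1.0)


def monthly_failure_risk(method: str, age: int, p: ParameterSet) -> float:
    """Monthly pregnancy probability on a method (failure), with age effects."""
    if method == NOT_USING:
        raise ValueError("failure risk is undefined for non-users; "
                         "use monthly_pregnancy_risk_not_using")
    gi = age_group_index(age)
    risk = float(p.failure_by_method.loc[method])
    if age < 25:
        risk *= float(p.rr_fail_under25)
    risk *= float(p.scaling_factor_on_monthly_risk_of_pregnancy.iloc[gi])
    return min(risk, 1.0)


# ---------------------------------------------------------------------------
# per-month probability tables (ages 15-49 x 10 methods)

class _MonthTables:
    """Effective probabilities for one calendar month, vectorized over age."""

    def __init__(self, p: ParameterSet, month: int,
                 iv: InterventionSpec | None):
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        gi = (ages - AGE_MIN) // 5
        sf = p.scaling_factor_on_monthly_risk_of_pregnancy.values[gi]
        active = iv is not None and iv.active(month)

        init = p.initiation_matrix().values.copy()
        init *= (1.0 + p.initiation_by_age.values)[:, None]
        init *= _trend_pow(p.time_age_trend_in_initiation, month)
        if active:
            init *= iv.pop.values[None, :]
        self.init = np.clip(init, 0.0, 1.0)

        self.preg_nu = np.minimum(p.pregnancy_not_using_in_2010.values * sf, 1.0)
        self.hiv_mult = p.pregnancy_not_using_hiv_effect.values[gi]

        fail = np.tile(p.failure_by_method.values, (len(ages), 1))
        fail *= np.where(ages < 25, p.rr_fail_under25, 1.0)[:, None]
        fail *= sf[:, None]
        self.fail = np.clip(fail, 0.0, 1.0)

        disc = np.tile(p.discontinuation_by_method.values, (len(ages), 1))
        disc *= (1.0 + p.discontinuation_by_age.values)[:, None]
        disc *= _trend_pow(p.time_age_trend_in_stopping, month)
        self.disc = np.clip(disc, 0.0, 1.0)

        self.switch_from = p.prob_switch_from.values
        self.switch_cum = np.cumsum(p.switch_matrix.values, axis=1)

        ab = p.after_birth_matrix().values.copy()
        if active:
            ab *= iv.ppfp.values[None, :]
        self.after_birth = np.clip(ab, 0.0, 1.0)

        ster = METHOD_INDEX["female_sterilization"] - 1  # contraceptive index
        self._ster = ster


# ---------------------------------------------------------------------------
# vectorized sampling kernels

def sample_not_using_outcomes(init_probs: np.ndarray, preg_prob: np.ndarray,
                              u: np.ndarray) -> tuple[np.ndarray, int]:
    """Single categorical draw per woman over {initiate m, pregnancy, stay}.

    ``init_probs`` is (n, 10), ``preg_prob`` and ``u`` are (n,).  Returns
    outcome codes (0 = stay, 1..10 = initiate contraceptive index+1,
    11 = pregnancy) and the number of rescaled rows.  The initiation
    intervals precede the pregnancy interval on the unit line so that
    enlarging initiation probabilities (an intervention) converts pregnancy
    and stay outcomes into initiations under common random numbers.
    """
    total = init_probs.sum(axis=1) + preg_prob
    over = total > 1.0
    scale = np.where(over, 1.0 / np.maximum(total, 1e-300), 1.0)
    probs = init_probs * scale[:, None]
    preg = preg_prob * scale
    cum = np.cumsum(probs, axis=1)
    j = (u[:, None] >= cum).sum(axis=1)       # 0..10; 10 = no initiation
    out = np.where(j < 10, j + 1, 0).astype(np.int8)
    preg_mask = (j == 10) & (u < cum[:, -1] + preg)
    out[preg_mask] = 11
    return out, int(over.sum())


def sample_using_outcomes(p_fail: np.ndarray, p_disc: np.ndarray,
                          p_switch: np.ndarray, switch_cum_rows: np.ndarray,
                          u4: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sequential competing draws for method users.

    ``u4`` is (n, 4) uniforms for (failure, discontinuation, switching,
    destination).  Returns (codes, dest): codes 0 = stay, 1 = failure,
    2 = discontinue, 3 = switch; ``dest`` holds the contraceptive index of
    the switch destination where codes == 3.
    """
    fail = u4[:, 0] < p_fail
    disc = ~fail & (u4[:, 1] < p_disc)
    sw = ~fail & ~disc & (u4[:, 2] < p_switch)
    codes = np.zeros(len(p_fail), np.int8)
    codes[fail] = 1
    codes[disc] = 2
    codes[sw] = 3
    dest = np.full(len(p_fail), -1, np.int8)
    if sw.any():
        dest[sw] = (u4[sw, 3][:, None] >= switch_cum_rows[sw]).sum(axis=1)
    return codes, dest


def sample_after_birth_outcomes(ab_probs: np.ndarray,
                                u: np.ndarray) -> tuple[np.ndarray, int]:
    """Postpartum categorical draw: 0 = remain not using, 1..10 = initiate."""
    total = ab_probs.sum(axis=1)
    over = total > 1.0
    scale = np.where(over, 1.0 / np.maximum(total, 1e-300), 1.0)
    cum = np.cumsum(ab_probs * scale[:, None], axis=1)
    j = (u[:, None] >= cum).sum(axis=1)
    out = np.where(j < 10, j + 1, 0).astype(np.int8)
    return out, int(over.sum())


# ---------------------------------------------------------------------------
# single-person steps (record-level API over the same kernels)

def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def step_not_using(woman: Person, p: ParameterSet,
                   iv: InterventionSpec | None, month: int,
                   rng: np.random.Generator) -> TransitionOutcome:
    """One month for a non-using woman: pregnancy, initiation, or stay."""
    age = woman.age_years(month)
    _require(woman.alive and woman.sex == "F", "woman must be alive and female")
    _require(AGE_MIN <= age <= AGE_MAX, "woman must be aged 15-49")
    _require(not woman.is_pregnant and woman.co_contraception == NOT_USING,
             "woman must be a non-pregnant non-user")
    t = _MonthTables(p, month, iv)
    i = age - AGE_MIN
    q = t.preg_nu[i] * (t.hiv_mult[i] if woman.hiv_positive else 1.0)
    out, _ = sample_not_using_outcomes(
        t.init[i:i + 1], np.array([min(q, 1.0)]), rng.random(1))
    code = int(out[0])
    if code == 0:
        return TransitionOutcome("stay", woman.person_id, month, NOT_USING, NOT_USING)
    if code == 11:
        return TransitionOutcome("pregnancy_not_using", woman.person_id, month,
                                 NOT_USING, NOT_USING)
    return TransitionOutcome("initiate", woman.person_id, month, NOT_USING,
                             CONTRACEPTIVES[code - 1])


def step_using(woman: Person, p: ParameterSet, month: int,
               rng: np.random.Generator) -> TransitionOutcome:
    """One month for a method user: failure, discontinuation, switch, or stay."""
    age = woman.age_years(month)
    _require(woman.alive and woman.sex == "F", "woman must be alive and female")
    _require(AGE_MIN <= age <= AGE_MAX, "woman must be aged 15-49")
    _require(not woman.is_pregnant and woman.co_contraception != NOT_USING,
             "woman must be a non-pregnant method user")
    t = _MonthTables(p, month, None)
    i = age - AGE_MIN
    mi = METHOD_INDEX[woman.co_contraception] - 1
    absorbing = woman.co_contraception == "female_sterilization"
    pf = t.fail[i, mi]
    pdisc = 0.0 if absorbing else t.disc[i, mi]
    psw = 0.0 if absorbing else t.switch_from[mi]
    codes, dest = sample_using_outcomes(
        np.array([pf]), np.array([pdisc]), np.array([psw]),
        t.switch_cum[mi:mi + 1], rng.random((1, 4)))
    code = int(codes[0])
    m = woman.co_contraception
    if code == 1:
        return TransitionOutcome("failure_pregnancy", woman.person_id, month, m, NOT_USING)
    if code == 2:
        return TransitionOutcome("discontinue", woman.person_id, month, m, NOT_USING)
    if code == 3:
        return TransitionOutcome("switch", woman.person_id, month, m,
                                 CONTRACEPTIVES[int(dest[0])])
    return TransitionOutcome("stay", woman.person_id, month, m, m)


def resolve_pregnancy(woman: Person, p: ParameterSet,
                      iv: InterventionSpec | None, month: int,
                      rng: np.random.Generator) -> TransitionOutcome:
    """End-of-pregnancy event, nine months after conception.

    Decides live birth vs early termination; either way the pregnancy ends
    and the postpartum initiation draw happens the following month.
    """
    _require(woman.is_pregnant, "woman must be pregnant")
    _require(woman.date_of_last_pregnancy is not None
             and month == woman.date_of_last_pregnancy + PREGNANCY_MONTHS,
             "pregnancy resolves exactly nine months after conception")
    live = rng.random() < p.live_birth_probability
    kind = "birth" if live else "pregnancy_end"
    return TransitionOutcome(kind, woman.person_id, month, None, None)


# ---------------------------------------------------------------------------
# the simulation loop

def run_simulation(cfg: SimulationConfig, p: ParameterSet,
                   sched: pd.DataFrame | None = None,
                   age_structure: pd.Series | None = None,
                   hiv_prevalence: pd.Series | None = None) -> SimulationResult:
    """Run the monthly microsimulation and collect monthly series and events."""
    report = validate_parameters(p)
    if not report.ok:
        raise ValueError(f"invalid parameters: {report}")
    if sched is None:
        sched = default_mortality_schedule()
    if age_structure is None:
        age_structure = default_age_structure()
    iv = cfg.intervention

    pop = initialize_population(cfg.n_agents, age_structure, p,
                                hiv_prevalence=hiv_prevalence,
                                seed=cfg.seed, start_month=cfg.start_month)
    schedule_initial_births(pop, p, seed=cfg.seed + 1)

    appt_interval_months = {
        METHOD_INDEX[m]: p.days_between_appts_for_maintenance[m]
        for m in MAINTAINABLE_METHODS
    }
    maintainable = np.zeros(len(METHODS), bool)
    for m in MAINTAINABLE_METHODS:
        maintainable[METHOD_INDEX[m]] = True
    modern_idx = np.zeros(len(METHODS), bool)
    for m in ("pill", "IUD", "injection", "implant", "male_condom",
              "female_sterilization", "other_modern"):
        modern_idx[METHOD_INDEX[m]] = True

    ev_month, ev_pid, ev_kind, ev_from, ev_to = [], [], [], [], []
    appt_rows: list[tuple[int, str, str, int]] = []
    monthly_rows = []
    pyramid_rows = []
    n_rescaled = 0
    ordinals = {}

    def log(month, pids, kind, frm, to):
        if not cfg.record_events or len(pids) == 0:
            return
        ev_month.append(np.full(len(pids), month, np.int32))
        ev_pid.append(np.asarray(pids, np.int64))
        ev_kind.append(np.full(len(pids), EVENT_KINDS.index(kind), np.int8))
        ev_from.append(np.asarray(frm, np.int8))
        ev_to.append(np.asarray(to, np.int8))

    for month in range(cfg.start_month, cfg.end_month):
        pop.current_month = month
        ordinals[month] = timegrid.ordinal_of(month)
        advance_age(pop)

        # deaths
        before = pop.alive.copy()
        rng_m = _stream(cfg.seed, month, _MORT)
        u_mort = rng_m.random(pop._next_id)
        alive_idx = np.flatnonzero(pop.alive)
        ages_all = pop.ages(month)
        bands = np.clip(ages_all[alive_idx] // 5 * 5, sched.index.min(),
                        sched.index.max())
        qf = sched["F"].reindex(bands).values
        qm = sched["M"].reindex(bands).values
        annual = np.where(pop.sex[alive_idx] == FEMALE, qf, qm)
        monthly_q = 1.0 - (1.0 - annual) ** (1.0 / 12.0)
        dead = alive_idx[u_mort[pop.person_id[alive_idx]] < monthly_q]
        pop.alive[dead] = False
        deaths = len(dead)
        log(month, pop.person_id[dead], "death",
            pop.method[dead], pop.method[dead])

        # pregnancy resolutions due this month
        due = np.flatnonzero(pop.alive & pop.pregnant
                             & (pop.preg_start + PREGNANCY_MONTHS == month))
        births = 0
        if len(due):
            rng_live = _stream(cfg.seed, month, _LIVE)
            u_live = rng_live.random(pop._next_id)[pop.person_id[due]]
            live = u_live < p.live_birth_probability
            mothers = due[live]
            births = len(mothers)
            pop.pregnant[due] = False
            pop.postpartum[due] = True        # after-birth draw next month
            pop.method[due] = METHOD_INDEX[NOT_USING]
            log(month, pop.person_id[mothers], "birth",
                np.zeros(births), np.zeros(births))
            if births:
                rng_sex = _stream(cfg.seed, month, _SEX)
                sexes = np.where(rng_sex.random(births) < 0.5, FEMALE, MALE)
                pop.add(sexes.astype(np.int8),
                        np.full(births, month, np.int32))

        # transition steps (ages recomputed: newborns may have been added)
        tables = _MonthTables(p, month, iv)
        ages_all = pop.ages(month)
        eligible = pop.eligible_women(month) & ~pop.pregnant
        ages_rel = ages_all - AGE_MIN
        new_preg = 0
        # index sets fixed at the month's start so each woman takes exactly
        # one transition even though states mutate during the block
        method0 = pop.method.copy()

        # postpartum draw (takes priority the month after resolution)
        pp = np.flatnonzero(eligible & pop.postpartum)
        pop.postpartum[:] = False
        if len(pp):
            u = _stream(cfg.seed, month, _PP).random(pop._next_id)[pop.person_id[pp]]
            out, resc = sample_after_birth_outcomes(
                tables.after_birth[ages_rel[pp]], u)
            n_rescaled += resc
            started = pp[out > 0]
            pop.method[started] = out[out > 0]
            log(month, pop.person_id[started], "postpartum_initiate",
                np.zeros(len(started)), out[out > 0])

        # non-users
        nu = np.flatnonzero(eligible & (method0 == METHOD_INDEX[NOT_USING]))
        nu = np.setdiff1d(nu, pp, assume_unique=True)
        if len(nu):
            u = _stream(cfg.seed, month, _NU).random(pop._next_id)[pop.person_id[nu]]
            q = tables.preg_nu[ages_rel[nu]] * np.where(
                pop.hiv[nu], tables.hiv_mult[ages_rel[nu]], 1.0)
            out, resc = sample_not_using_outcomes(
                tables.init[ages_rel[nu]], np.minimum(q, 1.0), u)
            n_rescaled += resc
            init = nu[(out >= 1) & (out <= 10)]
            pop.method[init] = out[(out >= 1) & (out <= 10)]
            pop.last_appt_month[init[modern_idx[pop.method[init]]]] = month
            log(month, pop.person_id[init], "initiate",
                np.zeros(len(init)), pop.method[init])
            preg = nu[out == 11]
            pop.pregnant[preg] = True
            pop.preg_start[preg] = month
            new_preg += len(preg)
            log(month, pop.person_id[preg], "pregnancy_not_using",
                np.zeros(len(preg)), np.zeros(len(preg)))
            init_m = pop.method[init]
            for m_ix in np.unique(init_m[modern_idx[init_m]]):
                appt_rows.append((month, METHODS[m_ix], "initiation",
                                  int((init_m == m_ix).sum())))

        # users
        us = np.flatnonzero(eligible & (method0 != METHOD_INDEX[NOT_USING]))
        if len(us):
            u4 = np.column_stack([
                _stream(cfg.seed, month, s).random(pop._next_id)[pop.person_id[us]]
                for s in (_FAIL, _DISC, _SWITCH, _DEST)
            ])
            mi = method0[us].astype(int) - 1
            absorbing = mi == (METHOD_INDEX["female_sterilization"] - 1)
            pf = tables.fail[ages_rel[us], mi]
            pdisc = np.where(absorbing, 0.0, tables.disc[ages_rel[us], mi])
            psw = np.where(absorbing, 0.0, tables.switch_from[mi])
            codes, dest = sample_using_outcomes(pf, pdisc, psw,
                                                tables.switch_cum[mi], u4)
            failed = us[codes == 1]
            pop.pregnant[failed] = True
            pop.preg_start[failed] = month
            pop.unintended[failed] = True
            new_preg += len(failed)
            log(month, pop.person_id[failed], "failure_pregnancy",
                pop.method[failed], np.zeros(len(failed)))
            pop.method[failed] = METHOD_INDEX[NOT_USING]

            disc = us[codes == 2]
            log(month, pop.person_id[disc], "discontinue",
                pop.method[disc], np.zeros(len(disc)))
            pop.method[disc] = METHOD_INDEX[NOT_USING]

            sw = us[codes == 3]
            new_m = (dest[codes == 3] + 1).astype(np.int8)
            log(month, pop.person_id[sw], "switch", pop.method[sw], new_m)
            pop.method[sw] = new_m
            pop.last_appt_month[sw[modern_idx[new_m]]] = month
            for m_ix in np.unique(new_m[modern_idx[new_m]]):
                appt_rows.append((month, METHODS[m_ix], "initiation",
                                  int((new_m == m_ix).sum())))

        # postpartum initiations count as initiation appointments too
        if len(pp):
            started_m = pop.method[pp[pop.method[pp] != METHOD_INDEX[NOT_USING]]]
            started_m = started_m[modern_idx[started_m]]
            for m_ix in np.unique(started_m):
                appt_rows.append((month, METHODS[m_ix], "initiation",
                                  int((started_m == m_ix).sum())))
            pop.last_appt_month[pp[modern_idx[pop.method[pp]]]] = month

        # maintenance appointments: due when days since last visit exceed
        # the method interval; a user with no recorded visit is due now
        users = np.flatnonzero(pop.eligible_women(month) & ~pop.pregnant
                               & maintainable[pop.method])
        if len(users):
            last = pop.last_appt_month[users]
            never = last <= -(2**30)
            ord_now = ordinals[month]
            last_ord = np.array([ordinals.get(int(m), 0) for m in last])
            last_ord[never] = -(10**9)
            intervals = np.array([appt_interval_months[int(m)]
                                  for m in pop.method[users]])
            due_mask = (ord_now - last_ord) > intervals
            due_users = users[due_mask]
            kinds = np.where(never[due_mask], "initiation", "maintenance")
            pop.last_appt_month[due_users] = month
            for m_ix in np.unique(pop.method[due_users]):
                sel = pop.method[due_users] == m_ix
                for kind in ("initiation", "maintenance"):
                    c = int((sel & (kinds == kind)).sum())
                    if c:
                        appt_rows.append((month, METHODS[m_ix], kind, c))

        # monthly bookkeeping (pregnant women count in their method state,
        # which is not_using by construction)
        elig = pop.eligible_women(month)
        counts = np.bincount(pop.method[elig], minlength=len(METHODS))
        a = ages_all
        pop1549 = int((pop.alive & (a >= 15) & (a <= 49)).sum())
        row = {"month": month, "women_15_49": int(elig.sum()),
               "pregnant": int((elig & pop.pregnant).sum()),
               "new_pregnancies": new_preg, "births": births, "deaths": deaths,
               "population": int(pop.alive.sum()),
               "population_15_49": pop1549}
        for m_name, c in zip(METHODS, counts):
            row[m_name] = int(c)
        monthly_rows.append(row)

        if timegrid.month_of(month) == 6:  # mid-year snapshot
            yr = timegrid.year_of(month)
            for sex_code, sex_name in ((FEMALE, "F"), (MALE, "M")):
                sel = pop.alive & (pop.sex == sex_code)
                cnt = np.bincount(np.clip(a[sel], 0, 120))
                for age, c in enumerate(cnt):
                    if c:
                        pyramid_rows.append((yr, sex_name, age, int(c)))

    monthly = pd.DataFrame(monthly_rows).set_index("month")
    if ev_month:
        kinds = np.asarray(EVENT_KINDS)
        meths = np.asarray(METHODS)
        events = pd.DataFrame({
            "month": np.concatenate(ev_month),
            "person_id": np.concatenate(ev_pid),
            "kind": kinds[np.concatenate(ev_kind)],
            "from_method": meths[np.concatenate(ev_from)],
            "to_method": meths[np.concatenate(ev_to)],
        })
    else:
        events = pd.DataFrame(columns=["month", "person_id", "kind",
                                       "from_method", "to_method"])
    appointments = (pd.DataFrame(appt_rows,
                                 columns=["month", "method", "kind", "count"])
                    .groupby(["month", "method", "kind"], as_index=False)["count"]
                    .sum())
    pyramids = pd.DataFrame(pyramid_rows, columns=["year", "sex", "age", "count"])
    return SimulationResult(monthly=monthly, events=events,
                            appointments=appointments, pyramids=pyramids,
                            config=cfg, n_rescaled=n_rescaled,
                            final_population=pop.to_dataframe())
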