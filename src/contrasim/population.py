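"""Individual state, cohort initialization, aging, mortality, initial births.

The population is stored column-wise (one numpy array per property) for
speed; :class:`Person` is the record-level view used by the single-person
transition operations.  Dates are whole calendar months on the grid of
:mod:`contrasim.timegrid`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .methods import AGE_MAX, AGE_MIN, AGES, METHOD_INDEX, METHODS, NOT_USING
from .parameters import ParameterSet
from . import timegrid

FEMALE, MALE = 0, 1
_NULL_MONTH = np.int32(-(2**31) + 1)


@dataclasses.dataclass
class Person:
    """One simulated individual's demographic, contraception and pregnancy state."""

    person_id: int
    sex: str                       # "F" or "M"
    date_of_birth: int             # month index
    alive: bool = True
    hiv_positive: bool = False
    co_contraception: str = NOT_USING
    is_pregnant: bool = False
    date_of_last_pregnancy: int | None = None
    co_unintended_preg: bool = False
    co_date_of_last_fp_appt: int | None = None

    def age_years(self, month: int) -> int:
        return (month - self.date_of_birth) // 12


class Population:
    """Column-wise container of persons plus the current calendar month."""

    def __init__(self, current_month: int):
        self.current_month = int(current_month)
        z = np.zeros(0)
        self.person_id = z.astype(np.int64)
        self.sex = z.astype(np.int8)          # FEMALE / MALE
        self.dob_month = z.astype(np.int32)
        self.alive = z.astype(bool)
        self.hiv = z.astype(bool)
        self.method = z.astype(np.int8)       # index into METHODS
        self.pregnant = z.astype(bool)
        self.preg_start = np.full(0, _NULL_MONTH, np.int32)
        self.postpartum = z.astype(bool)      # due the after-birth draw this month
        self.unintended = z.astype(bool)
        self.last_appt_month = np.full(0, _NULL_MONTH, np.int32)
        self._next_id = 0

    # -- construction ------------------------------------------------------
    def add(self, sex: np.ndarray, dob_month: np.ndarray,
            hiv: np.ndarray | None = None,
            method: np.ndarray | None = None) -> np.ndarray:
        """Append persons; returns their ids."""
        n = len(sex)
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.person_id = np.concatenate([self.person_id, ids])
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.int8)])
        self.dob_month = np.concatenate([self.dob_month, np.asarray(dob_month, np.int32)])
        self.alive = np.concatenate([self.alive, np.ones(n, bool)])
        self.hiv = np.concatenate(
            [self.hiv, np.zeros(n, bool) if hiv is None else np.asarray(hiv, bool)])
        self.method = np.concatenate(
            [self.method,
             np.zeros(n, np.int8) if method is None else np.asarray(method, np.int8)])
        self.pregnant = np.concatenate([self.pregnant, np.zeros(n, bool)])
        self.preg_start = np.concatenate(
            [self.preg_start, np.full(n, _NULL_MONTH, np.int32)])
        self.postpartum = np.concatenate([self.postpartum, np.zeros(n, bool)])
        self.unintended = np.concatenate([self.unintended, np.zeros(n, bool)])
        self.last_appt_month = np.concatenate(
            [self.last_appt_month, np.full(n, _NULL_MONTH, np.int32)])
        return ids

    # -- views -------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.person_id)

    def ages(self, month: int | None = None) -> np.ndarray:
        """Completed age in years at the given (default: current) month."""
        m = self.current_month if month is None else month
        return (m - self.dob_month) // 12

    def eligible_women(self, month: int | None = None) -> np.ndarray:
        """Mask: alive women aged 15-49 (the contraception risk set)."""
        a = self.ages(month)
        return self.alive & (self.sex == FEMALE) & (a >= AGE_MIN) & (a <= AGE_MAX)

    def person(self, person_id: int) -> Person:
        i = int(np.searchsorted(self.person_id, person_id))
        if i >= len(self) or self.person_id[i] != person_id:
            raise KeyError(f"no person with id {person_id}")
        return Person(
            person_id=int(self.person_id[i]),
            sex="F" if self.sex[i] == FEMALE else "M",
            date_of_birth=int(self.dob_month[i]),
            alive=bool(self.alive[i]),
            hiv_positive=bool(self.hiv[i]),
            co_contraception=METHODS[self.method[i]],
            is_pregnant=bool(self.pregnant[i]),
            date_of_last_pregnancy=(int(self.preg_start[i])
                                    if self.preg_start[i] != _NULL_MONTH else None),
            co_unintended_preg=bool(self.unintended[i]),
            co_date_of_last_fp_appt=(int(self.last_appt_month[i])
                                     if self.last_appt_month[i] != _NULL_MONTH else None),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "person_id": self.person_id,
            "sex": np.where(self.sex == FEMALE, "F", "M"),
            "date_of_birth": self.dob_month,
            "alive": self.alive,
            "hiv_positive": self.hiv,
            "co_contraception": np.asarray(METHODS)[self.method],
            "is_pregnant": self.pregnant,
        })


# ---------------------------------------------------------------------------
# defaults emulating a young, high-fertility national population

def default_age_structure(max_age: int = 79) -> pd.Series:
    """Proportion of the population per (sex, age): a young expansive pyramid.

    An exponential decline of about 3.5 percent per year of age reproduces
    the broad-based shape of a high-fertility population; sexes are split
    evenly.  Proportions sum to 1.
    """
    ages = np.arange(0, max_age + 1)
    w = np.exp(-0.035 * ages)
    w = w / w.sum() / 2.0
    idx = pd.MultiIndex.from_product([["F", "M"], ages], names=["sex", "age"])
    return pd.Series(np.concatenate([w, w]), index=idx, name="proportion")


def default_hiv_prevalence() -> pd.Series:
    """HIV prevalence by age: zero in childhood, ~10 percent among adults."""
    ages = np.arange(0, 100)
    prev = np.where(ages < 15, 0.0, np.where(ages < 55, 0.10, 0.06))
    return pd.Series(prev, index=ages, name="prevalence")


def default_mortality_schedule() -> pd.DataFrame:
    """Annual death probability by (five-year band start, sex).

    A stylized schedule with the shape of a high-mortality life table:
    elevated under-5 mortality, low rates through the working ages, and a
    Gompertz-like rise at older ages.
    """
    bands = np.arange(0, 100, 5)
    q = np.where(bands == 0, 0.015,
                 np.where(bands < 15, 0.0018,
                          np.where(bands < 50, 0.0045, 0.006 * 1.6 ** ((bands - 50) / 5))))
    q = np.minimum(q, 0.7)
    return pd.DataFrame({"F": q, "M": q * 1.08}, index=bands).clip(upper=1.0)


# ---------------------------------------------------------------------------
# operations

def initialize_population(
    n: int,
    age_structure: pd.Series,
    p: ParameterSet,
    hiv_prevalence: pd.Series | None = None,
    seed: int = 0,
    start_month: int | None = None,
) -> Population:
    """Create a representative cohort at the simulation start.

    Counts per (sex, age) are the expected counts under ``age_structure``
    (largest-remainder rounding to total exactly ``n``).  Women aged 15-49
    draw a contraceptive state from the baseline method mix for their age;
    nobody starts pregnant.  Deterministic per seed.
    """
    if n < 0:
        raise ValueError("population size must be >= 0")
    if start_month is None:
        start_month = timegrid.month_index(2010)
    if abs(age_structure.sum() - 1.0) > 1e-6:
        raise ValueError("age_structure proportions must sum to 1")
    rng = np.random.default_rng(seed)
    pop = Population(start_month)
    if n == 0:
        return pop

    raw = age_structure.values * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1

    sexes, dobs = [], []
    for (sex, age), c in zip(age_structure.index, counts):
        if c == 0:
            continue
        offset = rng.integers(0, 12, c)
        dobs.append(start_month - 12 * int(age) - offset)
        sexes.append(np.full(c, FEMALE if sex == "F" else MALE, np.int8))
    sex_arr = np.concatenate(sexes)
    dob_arr = np.concatenate(dobs).astype(np.int32)

    age_arr = (start_month - dob_arr) // 12
    if hiv_prevalence is None:
        hiv_prevalence = default_hiv_prevalence()
    prev = hiv_prevalence.reindex(np.clip(age_arr, 0, hiv_prevalence.index.max())).values
    hiv_arr = rng.random(len(age_arr)) < prev

    method_arr = np.zeros(len(age_arr), np.int8)
    mu = p.method_use_in_2010
    women = (sex_arr == FEMALE) & (age_arr >= AGE_MIN) & (age_arr <= AGE_MAX)
    for age in AGES:
        mask = women & (age_arr == age)
        k = int(mask.sum())
        if k == 0:
            continue
        probs = mu.loc[age].values.astype(float)
        probs = probs / probs.sum()
        method_arr[mask] = rng.choice(len(METHODS), size=k, p=probs).astype(np.int8)

    pop.add(sex_arr, dob_arr, hiv=hiv_arr, method=method_arr)
    return pop


def schedule_initial_births(pop: Population, p: ParameterSet,
                            seed: int = 0) -> pd.DataFrame:
    """Seed the pregnancy pipeline at simulation start.

    No woman is pregnant at initialization, so for the first nine months
    births are scheduled directly from the age-specific fertility rates:
    each woman aged 15-49 is assigned a birth with probability
    ``ASFR(age group)/12`` per month over the nine months (ASFR * 9/12 in
    total), the due month drawn uniformly within months 1-9.  Assigned
    women are marked pregnant with conception backdated nine months before
    the due month.  Returns the event list (person_id, due_month).
    """
    rng = np.random.default_rng(seed)
    t0 = pop.current_month
    ages = pop.ages()
    mask = pop.eligible_women() & ~pop.pregnant
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return pd.DataFrame(columns=["person_id", "due_month"])
    asfr = p.age_specific_fertility_rates.values
    gi = np.clip((ages[idx] - AGE_MIN) // 5, 0, 6)
    p_assign = np.minimum(asfr[gi] * 9.0 / 12.0, 1.0)
    assigned = idx[rng.random(len(idx)) < p_assign]
    due = t0 + rng.integers(0, 9, len(assigned)).astype(np.int32)
    pop.pregnant[assigned] = True
    pop.preg_start[assigned] = due - 9
    pop.method[assigned] = METHOD_INDEX[NOT_USING]
    events = pd.DataFrame({"person_id": pop.person_id[assigned], "due_month": due})
    return events.sort_values("due_month", kind="stable").reset_index(drop=True)


def monthly_death_probability(annual_q: np.ndarray) -> np.ndarray:
    """Constant-hazard conversion of an annual to a monthly death probability."""
    return 1.0 - (1.0 - np.asarray(annual_q, float)) ** (1.0 / 12.0)


def apply_mortality(pop: Population, sched: pd.DataFrame, month: int,
                    rng: np.random.Generator) -> int:
    """Kill each alive person with the monthly hazard from the annual schedule.

    ``sched`` is indexed by five-year band start (0, 5, ... ) with columns
    "F"/"M" of annual death probabilities.  Returns the number of deaths.
    """
    alive_idx = np.flatnonzero(pop.alive)
    if len(alive_idx) == 0:
        return 0
    ages = pop.ages(month)[alive_idx]
    bands = np.clip(ages // 5 * 5, sched.index.min(), sched.index.max())
    qf = sched["F"].reindex(bands).values
    qm = sched["M"].reindex(bands).values
    if np.isnan(qf).any() or np.isnan(qm).any():
        bad = sorted(set(bands[np.isnan(qf) | np.isnan(qm)]))
        raise KeyError(f"mortality schedule missing strata (age bands {bad})")
    annual = np.where(pop.sex[alive_idx] == FEMALE, qf, qm)
    dead = rng.random(len(alive_idx)) < monthly_death_probability(annual)
    pop.alive[alive_idx[dead]] = False
    return int(dead.sum())


def advance_age(pop: Population) -> None:
    """Apply age-related state rules at the current month.

    Ages are derived from dates of birth, so this only enforces exit from
    the contraception risk set: women aged 50 or older are forced to
    non-use and take no further contraception transitions.
    """
    over = pop.alive & (pop.sex == FEMALE) & (pop.ages() > AGE_MAX) & ~pop.pregnant
    pop.method[over] = METHOD_INDEX[NOT_USING]
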