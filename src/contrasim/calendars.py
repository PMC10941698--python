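"""Synthetic contraceptive calendars and occurrence-exposure estimation.

Month-by-month retrospective calendars of contraceptive status (the format
popularized by the Demographic and Health Surveys) are simulated from known
monthly probabilities, and those probabilities are then recovered by
occurrence-exposure estimation.  This provides an end-to-end
parameter-recovery check of the transition conventions the engine uses:

* initiation: starts of method m / person-months not using;
* failure: pregnancies on m / person-months on m;
* discontinuation: stops of m, conditional on no failure that month;
* switching: conditional on neither failure nor discontinuation, with the
  destination distribution estimated from observed switch destinations.

Calendar generation applies the *method-level* baseline probabilities only
(no age effects, HIV adjustment, scaling factors or secular trends), which
is exactly the quantity the estimator targets.  After a failure the woman
is pregnant for nine months, a birth code is recorded, and she returns to
non-use.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .engine import PREGNANCY_MONTHS, sample_using_outcomes
from .methods import CONTRACEPTIVES, METHOD_INDEX, METHODS, NOT_USING
from .parameters import ParameterSet

#: Single-character state codes for the calendar strings (DHS-like):
#: 0 = not using, 1..9/T = the ten methods in canonical order, P = pregnant,
#: B = birth month.
STATE_CODES = "0123456789TPB"
_CODE_OF = {i: STATE_CODES[i] for i in range(11)}
PREGNANT_CODE, BIRTH_CODE = "P", "B"
_PREG = 11
_BIRTH = 12


@dataclasses.dataclass
class CalendarRecord:
    """One woman's calendar: ordered month codes plus discontinuation reasons."""

    woman_id: int
    age_at_start: int
    months: str                       # one STATE_CODES character per month
    reasons: dict[int, str] = dataclasses.field(default_factory=dict)

    def state_indices(self) -> np.ndarray:
        return np.array([STATE_CODES.index(c) for c in self.months], np.int8)


def code_legend() -> dict[str, str]:
    legend = {_CODE_OF[i]: METHODS[i] for i in range(11)}
    legend[PREGNANT_CODE] = "pregnant"
    legend[BIRTH_CODE] = "birth"
    return legend


def simulate_calendars(p: ParameterSet, n_women: int, n_months: int,
                       seed: int = 0) -> list[CalendarRecord]:
    """Generate calendars from the engine's step conventions.

    Women start in states drawn from the baseline method mix (marginal over
    age); each month non-users face the single categorical draw over
    initiation and pregnancy (baseline probabilities) and users face the
    sequential failure / discontinuation / switching draws.  Sterilization
    is absorbing.  Deterministic per seed.
    """
    if n_months < 1:
        raise ValueError("n_months must be >= 1")
    rng = np.random.default_rng(seed)
    if n_women == 0:
        return []

    mu = p.method_use_in_2010.mean(axis=0).values
    mu = mu / mu.sum()
    state = rng.choice(len(METHODS), size=n_women, p=mu).astype(np.int8)
    preg_left = np.zeros(n_women, np.int8)
    ages = rng.integers(15, 45, n_women)

    init = p.initiation_by_method.values
    preg_nu = float(p.pregnancy_not_using_in_2010.mean())
    fail = p.failure_by_method.values
    disc = p.discontinuation_by_method.values
    swfrom = p.prob_switch_from.values
    sw_cum = np.cumsum(p.switch_matrix.values, axis=1)
    ster = METHOD_INDEX["female_sterilization"] - 1
    init_cum = np.cumsum(np.append(init, preg_nu))

    codes = np.empty((n_women, n_months), np.int8)
    reasons: list[dict[int, str]] = [dict() for _ in range(n_women)]

    for t in range(n_months):
        # pregnancy pipeline
        pregnant = preg_left > 0
        preg_left[pregnant] -= 1
        delivering = pregnant & (preg_left == 0)
        codes[pregnant & ~delivering, t] = _PREG
        codes[delivering, t] = _BIRTH
        state[delivering] = METHOD_INDEX[NOT_USING]

        active = ~pregnant
        state0 = state.copy()   # one transition per woman per month
        nu = active & (state0 == 0)
        idx = np.flatnonzero(nu)
        if len(idx):
            u = rng.random(len(idx))
            j = (u[:, None] >= init_cum[None, :]).sum(axis=1)
            starts = j < 10
            state[idx[starts]] = (j[starts] + 1).astype(np.int8)
            new_preg = idx[j == 10]
            preg_left[new_preg] = PREGNANCY_MONTHS
            codes[idx, t] = state[idx]
            codes[new_preg, t] = _PREG
        us = np.flatnonzero(active & (state0 != 0))
        if len(us):
            mi = state[us].astype(int) - 1
            absorbing = mi == ster
            pf = fail[mi]
            pdisc = np.where(absorbing, 0.0, disc[mi])
            psw = np.where(absorbing, 0.0, swfrom[mi])
            out, dest = sample_using_outcomes(pf, pdisc, psw, sw_cum[mi],
                                              rng.random((len(us), 4)))
            failed = us[out == 1]
            preg_left[failed] = PREGNANCY_MONTHS
            for w in failed:
                reasons[w][t] = "failure"
            stopped = us[out == 2]
            for w in stopped:
                reasons[w][t] = "other"
            switched = us[out == 3]
            codes[us, t] = state[us]
            codes[failed, t] = _PREG
            state[failed] = 0
            codes[stopped, t] = 0
            state[stopped] = 0
            new_m = (dest[out == 3] + 1).astype(np.int8)
            codes[switched, t] = new_m
            state[switched] = new_m

    return [
        CalendarRecord(woman_id=w, age_at_start=int(ages[w]),
                       months="".join(STATE_CODES[c] for c in codes[w]),
                       reasons=reasons[w])
        for w in range(n_women)
    ]


# ---------------------------------------------------------------------------
# occurrence-exposure estimation

@dataclasses.dataclass
class RateEstimate:
    """events / exposure with a binomial standard error; NaN if no exposure."""

    events: int
    exposure: float

    @property
    def value(self) -> float:
        return self.events / self.exposure if self.exposure > 0 else float("nan")

    @property
    def se(self) -> float:
        if self.exposure <= 0:
            return float("nan")
        v = self.value
        return float(np.sqrt(max(v * (1 - v), 0.0) / self.exposure))


@dataclasses.dataclass
class EstimatedProbabilities:
    initiation_by_method: pd.DataFrame    # value, se, events, exposure per method
    failure_by_method: pd.DataFrame
    discontinuation_by_method: pd.DataFrame
    prob_switch_from: pd.DataFrame
    switch_matrix: pd.DataFrame           # estimated destination distribution
    pregnancy_not_using: RateEstimate


def _frame(est: dict[str, RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame({
        "value": {m: e.value for m, e in est.items()},
        "se": {m: e.se for m, e in est.items()},
        "events": {m: e.events for m, e in est.items()},
        "exposure": {m: e.exposure for m, e in est.items()},
    }).reindex(list(CONTRACEPTIVES))


def estimate_monthly_probabilities(
        calendars: list[CalendarRecord]) -> EstimatedProbabilities:
    """Occurrence-exposure estimates matched to the engine's conventions.

    Initiation and not-using pregnancy rates divide events by person-months
    of non-use; failure divides by person-months on the method.
    Discontinuation conditions on no failure in the month, and the
    switching probability conditions additionally on no discontinuation,
    mirroring the sequential draw order, so the estimates are directly
    comparable to the generating parameters.  Zero-exposure estimates are
    NaN (undefined), not zero.
    """
    if not calendars:
        raise ValueError("no calendars given")
    mat = np.stack([c.state_indices() for c in calendars])
    prev = mat[:, :-1]
    cur = mat[:, 1:]
    # reasons distinguish failure (pregnancy) from plain discontinuation;
    # both appear as method -> P only for failure
    nu_expo = float((prev == 0).sum())
    init_events = {m: int(((prev == 0) & (cur == METHOD_INDEX[m])).sum())
                   for m in CONTRACEPTIVES}
    preg_nu_events = int(((prev == 0) & (cur == _PREG)).sum())

    initiation, failure, discontinuation, switching = {}, {}, {}, {}
    sw_counts = pd.DataFrame(0, index=list(CONTRACEPTIVES),
                             columns=list(CONTRACEPTIVES), dtype=float)
    for m in CONTRACEPTIVES:
        k = METHOD_INDEX[m]
        on = prev == k
        expo = float(on.sum())
        n_fail = int((on & (cur == _PREG)).sum())
        n_disc = int((on & (cur == 0)).sum())
        to_other = on & (cur != k) & (cur != 0) & (cur != _PREG) & (cur != _BIRTH)
        n_switch = int(to_other.sum())
        initiation[m] = RateEstimate(init_events[m], nu_expo)
        failure[m] = RateEstimate(n_fail, expo)
        pf = n_fail / expo if expo else 0.0
        disc_expo = expo * (1 - pf)
        discontinuation[m] = RateEstimate(n_disc, disc_expo)
        pd_ = n_disc / disc_expo if disc_expo else 0.0
        sw_expo = disc_expo * (1 - pd_)
        switching[m] = RateEstimate(n_switch, sw_expo)
        if n_switch:
            dests = cur[to_other]
            for d in np.unique(dests):
                sw_counts.loc[m, METHODS[d]] = float((dests == d).sum())

    row_tot = sw_counts.sum(axis=1)
    sw_matrix = sw_counts.div(row_tot.where(row_tot > 0), axis=0)
    return EstimatedProbabilities(
        initiation_by_method=_frame(initiation),
        failure_by_method=_frame(failure),
        discontinuation_by_method=_frame(discontinuation),
        prob_switch_from=_frame(switching),
        switch_matrix=sw_matrix,
        pregnancy_not_using=RateEstimate(preg_nu_events, nu_expo),
    )


# ---------------------------------------------------------------------------
# file round-trip (one row per woman, months as a state-code string)

def save_calendars(calendars: list[CalendarRecord], path) -> None:
    rows = [{"woman_id": c.woman_id, "age_at_start": c.age_at_start,
             "months": c.months,
             "reasons": ";".join(f"{t}:{r}" for t, r in sorted(c.reasons.items()))}
            for c in calendars]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_calendars(path) -> list[CalendarRecord]:
    frame = pd.read_csv(path, dtype={"months": str}, keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        reasons = {}
        if row.reasons:
            for tok in str(row.reasons).split(";"):
                t, r = tok.split(":")
                reasons[int(t)] = r
        out.append(CalendarRecord(int(row.woman_id), int(row.age_at_start),
                                  str(row.months), reasons))
    return out
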