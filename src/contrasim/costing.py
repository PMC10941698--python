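"""Consumable packages, appointment costing, implementation costs, currency.

Each modern contraceptive method is delivered as a package of consumable
items dispensed at family-planning appointments: an initiation appointment
(which additionally uses a pregnancy slide test) when a woman starts or
switches to the method, and maintenance appointments at a method-specific
interval thereafter.  Costs are accounted internally in 2021 Malawi Kwacha
(MWK) as reals; USD conversion uses the 2021 rate of 790 MWK per dollar;
rounding happens only at display.

Intervention implementation costs (demand creation and postpartum
integration) are annual national amounts referenced to a base-year
population of 15-49-year-olds and scaled proportionally to the simulated
population each year.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import timegrid
from .methods import MAINTAINABLE_METHODS, MODERN_METHODS
from .parameters import ParameterSet
from .population import Person

MWK_PER_USD = 790.0


@dataclasses.dataclass
class ConsumableItem:
    name: str
    expected_units_per_case: float
    unit_cost_mwk_2021: float

    def __post_init__(self) -> None:
        if self.expected_units_per_case < 0 or self.unit_cost_mwk_2021 < 0:
            raise ValueError("units and unit cost must be >= 0")

    @property
    def cost(self) -> float:
        return self.expected_units_per_case * self.unit_cost_mwk_2021


@dataclasses.dataclass
class ConsumablePackage:
    method: str
    items: list[ConsumableItem]
    includes_initiation_test: bool = False

    @property
    def cost(self) -> float:
        return sum(item.cost for item in self.items)


@dataclasses.dataclass
class CostConfig:
    mwk_per_usd: float = MWK_PER_USD
    base_annual_cost_pop_mwk2021: float = 2_400e6
    base_annual_cost_ppfp_mwk2021: float = 264e6
    base_population_15_49: float | None = None   # defaults to simulated 2016
    total_health_expenditure_usd_per_capita: float = 34.4

    def __post_init__(self) -> None:
        for f in ("mwk_per_usd", "base_annual_cost_pop_mwk2021",
                  "base_annual_cost_ppfp_mwk2021",
                  "total_health_expenditure_usd_per_capita"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be positive")


def weighted_unit_cost(alternatives: list[tuple[float, float, float]]) -> float:
    """Weighted-average cost per case over product alternatives.

    ``alternatives`` is a list of (unit_cost_mwk, patient_share,
    units_per_case); shares must sum to 1.  Returns the exact MWK amount
    (sum of share x units x unit cost); round to the nearest MWK for table
    display.
    """
    shares = sum(s for _, s, _ in alternatives)
    if abs(shares - 1.0) > 1e-9:
        raise ValueError(f"alternative shares sum to {shares}, expected 1")
    return sum(cost * share * units for cost, share, units in alternatives)


# The per-cycle pill cost and per-case implant device cost are weighted
# averages over the products actually dispensed (80/20 split of two pill
# formulations; 50/50 split of a two-rod and a one-rod implant).
PILL_CYCLE_COST_MWK = weighted_unit_cost([(531.1, 0.8, 1), (340.4, 0.2, 1)])
IMPLANT_DEVICE_COST_MWK = weighted_unit_cost([(449.05, 0.5, 2), (622.12, 0.5, 1)])

#: Pregnancy slide test dispensed at every initiation appointment.
INITIATION_TEST = ConsumableItem("Pregnancy slide test kit (hCG), strip", 1, 32)


def implant_maintenance_interval_days(share_two_rod: float = 0.5,
                                      life_two_rod_years: float = 5.0,
                                      life_one_rod_years: float = 3.0) -> int:
    """Maintenance interval for implants from the device-mix lifetimes.

    The two-rod device lasts five years and the one-rod device three; with
    a 50/50 dispensing mix the expected time between appointments is four
    years, i.e. 1,461 days.
    """
    years = share_two_rod * life_two_rod_years + (1 - share_two_rod) * life_one_rod_years
    return round(years * 365.25)


def default_consumable_packages() -> dict[str, ConsumablePackage]:
    """The consumable package per modern method (2021 MWK unit costs)."""
    I = ConsumableItem
    packages = {
        "pill": [I("Combined/progestogen-only pill, cycle", 3.75,
                   round(PILL_CYCLE_COST_MWK))],
        "IUD": [I("Gloves, disposable latex, pair", 2, 37),
                I("IUD, Copper T-380A", 1, 26)],
        "injection": [I("Medroxyprogesterone acetate 150 mg/mL with syringe", 1, 481),
                      I("Gloves, disposable latex, pair", 1, 37),
                      I("Water for injection, 10 mL", 1, 32),
                      I("Povidone iodine 10%, 5 mL sachet", 1, 85),
                      I("Gauze swabs 8-ply 10x10 cm", 1, 16)],
        "implant": [I("Gauze swabs 8-ply 10x10 cm", 1, 16),
                    I("Implant device (two-rod/one-rod mix)", 1,
                      round(IMPLANT_DEVICE_COST_MWK)),
                    I("Trocar", 0.1, 312),
                    I("Syringe, needle + swab", 2, 200),
                    I("Needle, suture, round-bodied", 1, 179),
                    I("Lidocaine HCl 7.5%, 2 mL ampoule", 2, 310),
                    I("Gloves, disposable latex, pair", 3, 37),
                    I("Povidone iodine 10%, 5 mL sachet", 1, 85)],
        "male_condom": [I("Condom, male", 30, 21)],
        "female_sterilization": [
            I("Povidone iodine 10%, 5 mL sachet", 2, 85),
            I("Paracetamol 500 mg, tablet", 8, 4),
            I("Gloves, surgeon's, size 7, sterile, pair", 2, 302),
            I("Tape, adhesive, zinc oxide, 5 m roll", 0.25, 1558),
            I("Catgut chromic suture, sterile", 3, 307),
            I("Gauze swabs 8-ply 10x10 cm", 2, 16),
            I("Syringe, autodestruct 5 mL + alcohol swabs", 3, 154),
            I("Diazepam 5 mg/mL, 2 mL", 1, 130),
            I("Atropine sulphate 600 ug/mL, 1 mL", 0.5, 121),
            I("Lidocaine HCl 7.5%, 2 mL ampoule", 1, 310),
            I("Cotton wool, 500 g", 0.2, 2690),
            I("Polyamide monofilament suture, sterile", 3, 179),
        ],
        "other_modern": [I("Condom, female", 30, 22)],
    }
    return {m: ConsumablePackage(m, items, includes_initiation_test=True)
            for m, items in packages.items()}


def package_cost(method: str, packages: dict[str, ConsumablePackage]) -> float:
    """MWK cost of one appointment's consumables for a method."""
    if method not in packages:
        raise KeyError(f"no consumable package for method {method!r}")
    return packages[method].cost


def convert_currency(amount_mwk: float, mwk_per_usd: float = MWK_PER_USD) -> float:
    """2021 MWK to 2021 USD; round to 2 decimals only for display."""
    return amount_mwk / mwk_per_usd


def maintenance_due(woman: Person, method: str, date, p: ParameterSet) -> bool:
    """Whether a maintenance appointment is due at ``date``.

    True iff the days elapsed since the last family-planning appointment
    strictly exceed the method's maintenance interval.  A woman with no
    recorded appointment is due (her next appointment is the initiation
    appointment).  ``date`` and the stored appointment date may be given as
    calendar dates or month indexes (resolved to the first of the month).
    """
    if method not in MAINTAINABLE_METHODS:
        raise ValueError(f"{method!r} has no maintenance schedule")
    last = woman.co_date_of_last_fp_appt
    if last is None:
        return True
    to_ord = lambda d: timegrid.ordinal_of(d) if isinstance(d, int) else d.toordinal()
    elapsed = to_ord(date) - to_ord(last)
    return elapsed > p.days_between_appts_for_maintenance[method]


def implementation_cost(year: int, population_15_49: float, cc: CostConfig,
                        which: str) -> float:
    """Annual intervention implementation cost, scaled to the year's population."""
    if population_15_49 <= 0:
        raise ValueError("population must be positive")
    if cc.base_population_15_49 is None or cc.base_population_15_49 <= 0:
        raise ValueError("CostConfig.base_population_15_49 must be set")
    base = {"Pop": cc.base_annual_cost_pop_mwk2021,
            "PPFP": cc.base_annual_cost_ppfp_mwk2021}[which]
    return base * population_15_49 / cc.base_population_15_49


class CostLedger:
    """Accumulated costs by (period, category), MWK internally."""

    POP = "Pop implementation"
    PPFP = "PPFP implementation"

    def __init__(self, mwk_per_usd: float = MWK_PER_USD):
        self.mwk_per_usd = mwk_per_usd
        self._mwk: dict[tuple[str, str], float] = {}

    def add(self, period: str, category: str, amount_mwk: float) -> None:
        key = (period, category)
        self._mwk[key] = self._mwk.get(key, 0.0) + amount_mwk

    def mwk(self, period: str, category: str) -> float:
        return self._mwk.get((period, category), 0.0)

    def usd(self, period: str, category: str) -> float:
        return self.mwk(period, category) / self.mwk_per_usd

    def total_mwk(self, period: str) -> float:
        return sum(v for (pd_, _), v in self._mwk.items() if pd_ == period)

    def category_total_mwk(self, category: str) -> float:
        return sum(v for (_, c), v in self._mwk.items() if c == category)

    def to_frame(self) -> pd.DataFrame:
        rows = [(pd_, c, v, v / self.mwk_per_usd)
                for (pd_, c), v in sorted(self._mwk.items())]
        return pd.DataFrame(rows, columns=["period", "category", "mwk", "usd"])


def per_capita_summary(additional_cost_usd: float, mean_population: float,
                       years: float, cc: CostConfig) -> tuple[float, float]:
    """(USD per capita per year, percent of total health expenditure).

    Display convention: report the per-capita cost to the cent and the
    percentage to one decimal place.
    """
    if mean_population <= 0 or years <= 0:
        raise ValueError("mean_population and years must be positive")
    per_capita = additional_cost_usd / (mean_population * years)
    pct = per_capita / cc.total_health_expenditure_usd_per_capita * 100.0
    return per_capita, pct


# ---------------------------------------------------------------------------
# simulation cost summaries

def _period_bounds(period: str) -> tuple[int, int]:
    a, b = period.split("-")
    return timegrid.month_index(int(a)), timegrid.month_index(int(b) + 1)


def summarize_costs(result, periods: list[str], cc: CostConfig,
                    packages: dict[str, ConsumablePackage] | None = None,
                    ) -> tuple[CostLedger, pd.DataFrame]:
    """Usage shares and accumulated costs per period from a simulation.

    For each period (e.g. "2023-2030") and modern method: the mean
    percentage of women 15-49 using the method (display: nearest 0.1
    percent), the mean number of users after national scaling (display:
    nearest 1,000, reported in thousands), and the consumable cost of the
    method's appointments.  Implementation costs accrue per simulated year
    in which the intervention is active, scaled to the national population
    aged 15-49.  Returns the ledger and the usage table.
    """
    if packages is None:
        packages = default_consumable_packages()
    monthly = result.monthly
    scale = result.national_scale()
    iv = result.config.intervention

    if cc.base_population_15_49 is None:
        yr2016 = monthly[[timegrid.year_of(m) == 2016 for m in monthly.index]]
        ref = yr2016 if len(yr2016) else monthly.iloc[:12]
        cc = dataclasses.replace(
            cc, base_population_15_49=float(ref["population_15_49"].mean()) * scale)

    appts = result.appointments
    ledger = CostLedger(cc.mwk_per_usd)
    usage_rows = []
    for period in periods:
        lo, hi = _period_bounds(period)
        sel = (monthly.index >= lo) & (monthly.index < hi)
        if not sel.any():
            raise ValueError(f"period {period} outside the simulated horizon")
        span = monthly[sel]
        for m in MODERN_METHODS:
            pct = float((span[m] / span["women_15_49"]).mean()) * 100.0
            users = float(span[m].mean()) * scale
            usage_rows.append((period, m, pct, users))
            asel = appts[(appts["method"] == m) & (appts["month"] >= lo)
                         & (appts["month"] < hi)]
            n_init = int(asel.loc[asel["kind"] == "initiation", "count"].sum())
            n_maint = int(asel.loc[asel["kind"] == "maintenance", "count"].sum())
            cost = (n_init + n_maint) * package_cost(m, packages)
            cost += n_init * INITIATION_TEST.cost
            ledger.add(period, m, cost * scale)
        if iv is not None:
            for year in range(timegrid.year_of(lo), timegrid.year_of(hi - 1) + 1):
                months = [mm for mm in span.index
                          if timegrid.year_of(mm) == year and mm >= iv.start_month]
                if not months:
                    continue
                frac = len(months) / 12.0
                nat_pop = float(span.loc[months, "population_15_49"].mean()) * scale
                ledger.add(period, CostLedger.POP,
                           implementation_cost(year, nat_pop, cc, "Pop") * frac)
                ledger.add(period, CostLedger.PPFP,
                           implementation_cost(year, nat_pop, cc, "PPFP") * frac)

    usage = pd.DataFrame(usage_rows,
                         columns=["period", "method", "pct_using", "users"])
    usage["pct_using_display"] = usage["pct_using"].round(1)
    usage["users_thousands_display"] = (usage["users"] / 1000.0).round(0)
    return ledger, usage


# ---------------------------------------------------------------------------
# published scenario summary (reference inputs for cost arithmetic)
#
# Per-method consumable costs (millions of 2021 MWK) and implementation
# costs by decade for the Malawi contraception scale-up scenario, and the
# 2023-2050 scenario aggregates.  These are published reference figures
# used as *inputs* to ledger arithmetic (column totals, cost ratios,
# per-capita summaries); they are never produced as simulation output.

PUBLISHED_METHOD_COSTS_MWK_M: dict[tuple[str, str], dict[str, float]] = {
    ("2023-2030", "without"): {
        "pill": 6089, "IUD": 4, "injection": 26815, "implant": 2111,
        "male_condom": 3082, "female_sterilization": 587, "other_modern": 235},
    ("2023-2030", "with"): {
        "pill": 9294, "IUD": 17, "injection": 31509, "implant": 3563,
        "male_condom": 5189, "female_sterilization": 784, "other_modern": 507},
    ("2031-2040", "without"): {
        "pill": 10458, "IUD": 6, "injection": 47091, "implant": 4268,
        "male_condom": 5292, "female_sterilization": 1003, "other_modern": 451},
    ("2031-2040", "with"): {
        "pill": 16272, "IUD": 25, "injection": 53149, "implant": 8083,
        "male_condom": 8800, "female_sterilization": 1157, "other_modern": 1113},
}

PUBLISHED_IMPLEMENTATION_MWK_M: dict[tuple[str, str], float] = {
    ("2023-2030", "without"): 0.0, ("2023-2030", "with"): 29859.0,
    ("2031-2040", "without"): 0.0, ("2031-2040", "with"): 47784.0,
}

#: 2023-2050 scenario aggregates (billions MWK / millions USD as published).
PUBLISHED_2023_2050 = {
    "pop_implementation_usd_m": 152.8,
    "ppfp_implementation_usd_m": 17.2,
    "consumables_with_usd_m": 314.5,
    "consumables_without_usd_m": 253.3,
    "pop_implementation_mwk_b": 120.7,
    "ppfp_implementation_mwk_b": 13.6,
    "consumables_with_mwk_b": 248.5,
    "consumables_without_mwk_b": 200.1,
    "mean_population": 26_948_785,
    "years": 28,
}


def published_ledger(period: str, scenario: str) -> CostLedger:
    """Build a ledger from the published per-method entries for one column."""
    ledger = CostLedger()
    for m, v in PUBLISHED_METHOD_COSTS_MWK_M[(period, scenario)].items():
        ledger.add(period, m, v)
    impl = PUBLISHED_IMPLEMENTATION_MWK_M[(period, scenario)]
    if impl:
        ledger.add(period, CostLedger.POP + " + " + CostLedger.PPFP, impl)
    return ledger


def published_modern_total_mwk_m(period: str, scenario: str) -> float:
    """Column sum over the seven modern methods (millions MWK)."""
    return sum(PUBLISHED_METHOD_COSTS_MWK_M[(period, scenario)].values())


def published_grand_total_mwk_m(period: str, scenario: str) -> float:
    """Modern-method consumables plus implementation (millions MWK)."""
    return (published_modern_total_mwk_m(period, scenario)
            + PUBLISHED_IMPLEMENTATION_MWK_M[(period, scenario)])


def published_additional_cost_usd_m() -> float:
    """Extra cost of the scale-up scenario over 2023-2050, millions USD.

    Implementation costs plus the consumable increment over the
    no-intervention scenario.
    """
    a = PUBLISHED_2023_2050
    return (a["pop_implementation_usd_m"] + a["ppfp_implementation_usd_m"]
            + a["consumables_with_usd_m"] - a["consumables_without_usd_m"])


def published_intervention_cost_ratios() -> tuple[float, float]:
    """(implementation as % of scenario consumables, PPFP as % of Pop cost)."""
    a = PUBLISHED_2023_2050
    impl = a["pop_implementation_mwk_b"] + a["ppfp_implementation_mwk_b"]
    share_of_consumables = impl / a["consumables_with_mwk_b"] * 100.0
    ppfp_vs_pop = (a["ppfp_implementation_mwk_b"]
                   / a["pop_implementation_mwk_b"] * 100.0)
    return share_of_consumables, ppfp_vs_pop
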