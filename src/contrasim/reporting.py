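"""Output surfaces: method mix, pregnancies, pyramids, dependency ratio, scaling.

All series are tidy tables derived from a :class:`~contrasim.engine.SimulationResult`.
Display conventions: method-mix percentages to the nearest 0.1 percent and
nationally scaled user counts to the nearest 1,000 (simulation noise at the
reference agent count is below these resolutions); raw values are returned
unrounded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import timegrid
from .engine import SimulationResult
from .methods import METHODS


def method_mix_series(r: SimulationResult) -> pd.DataFrame:
    """Proportion of women 15-49 in each contraception state per month.

    Pregnant women are counted in the not_using state (their method ended
    or was absent at conception), so each month's shares sum to 1.
    """
    counts = r.monthly[list(METHODS)]
    shares = counts.div(r.monthly["women_15_49"], axis=0)
    return shares


def pregnancy_proportion_series(r: SimulationResult) -> pd.Series:
    """Women with a pregnancy begun in a year / mean women 15-49 that year."""
    years = np.array([timegrid.year_of(m) for m in r.monthly.index])
    g = r.monthly.groupby(years)
    return g["new_pregnancies"].sum() / g["women_15_49"].mean()


def dependency_ratio(pop_by_age: pd.Series) -> float:
    """Dependents (0-14 and 65+) per adult aged 15-64.

    ``pop_by_age`` maps age in years to a count (summed over sexes).
    """
    ages = np.asarray(pop_by_age.index, int)
    counts = np.asarray(pop_by_age.values, float)
    adults = counts[(ages >= 15) & (ages <= 64)].sum()
    if adults == 0:
        raise ZeroDivisionError("no adults aged 15-64: dependency ratio undefined")
    dependents = counts[(ages < 15) | (ages >= 65)].sum()
    return float(dependents / adults)


def dependency_ratio_series(r: SimulationResult) -> pd.Series:
    """Dependency ratio per mid-year snapshot."""
    out = {}
    for year, grp in r.pyramids.groupby("year"):
        by_age = grp.groupby("age")["count"].sum()
        out[year] = dependency_ratio(by_age)
    return pd.Series(out).sort_index()


def population_pyramid(r: SimulationResult, year: int) -> pd.DataFrame:
    """Mid-year population counts per (sex, five-year age group).

    Scaled to the national total if the run was configured with one.
    """
    grp = r.pyramids[r.pyramids["year"] == year]
    if grp.empty:
        raise ValueError(f"year {year} outside the simulated horizon")
    scale = r.national_scale()
    bands = grp["age"] // 5 * 5
    out = (grp.assign(band=bands)
           .groupby(["sex", "band"])["count"].sum() * scale)
    frame = out.rename("count").reset_index()
    frame["age_group"] = frame["band"].map(lambda b: f"{b}-{b + 4}")
    return frame[["sex", "age_group", "count"]]


def scale_to_national(sim_count: float, sim_population: float,
                      national_population: float) -> float:
    """Scale a simulated count to the national population (display: nearest 1,000)."""
    if sim_population <= 0:
        raise ValueError("simulated population must be positive")
    return sim_count * national_population / sim_population


def write_report(r: SimulationResult, out_dir) -> dict[str, str]:
    """Write the figure-facing tidy CSVs; returns {name: path}."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    mix = method_mix_series(r).reset_index().melt(
        id_vars="month", var_name="method", value_name="proportion")
    files["methodmix"] = str(out / "methodmix.csv")
    mix.to_csv(files["methodmix"], index=False)

    preg = pregnancy_proportion_series(r).rename("proportion_pregnant")
    files["pregnancy"] = str(out / "pregnancy.csv")
    preg.to_csv(files["pregnancy"], index_label="year")

    years = np.array([timegrid.year_of(m) for m in r.monthly.index])
    births = r.monthly.groupby(years)["births"].sum().rename("births")
    files["births"] = str(out / "births.csv")
    births.to_csv(files["births"], index_label="year")

    dep = dependency_ratio_series(r).rename("dependency_ratio")
    files["dependency"] = str(out / "dependency.csv")
    dep.to_csv(files["dependency"], index_label="year")

    for year in sorted(r.pyramids["year"].unique())[:: max(1, len(r.pyramids["year"].unique()) // 8)]:
        path = out / f"pyramid_{year}.csv"
        population_pyramid(r, int(year)).to_csv(path, index=False)
        files[f"pyramid_{year}"] = str(path)
    return files
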