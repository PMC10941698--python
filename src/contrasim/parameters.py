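"""Parameter set of the contraception-and-pregnancy model.

All transition probabilities are *monthly* probabilities.  Method-level
tables are indexed by the 11 DHS calendar categories; age-level tables by
single year of age 15-49; age-group tables by the seven five-year groups
15-19 ... 45-49.

Age effects on initiation and discontinuation are stored as proportional
deviations: the multiplier applied to the method-level probability is
``1 + deviation``.  Secular trends are per-year multiplicative factors
applied as ``trend ** years_since_baseline`` (baseline 2010).

The sterilization age restriction (no female sterilization below an
eligibility age, with the lost initiation mass shifted onto older women and
the within-age total preserved by rescaling the other methods) is a
transform producing age-expanded initiation matrices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .methods import (
    AGE_GROUPS,
    AGES,
    CONTRACEPTIVES,
    MAINTAINABLE_METHODS,
    METHODS,
    MODERN_METHODS,
    NOT_USING,
    TRADITIONAL_METHODS,
    age_group_of,
)

# Published scalar vectors (five-year age groups 15-19 ... 45-49).
HIV_FERTILITY_EFFECT = (1.4, 0.9, 0.8, 0.7, 0.5, 0.4, 0.3)
AGE_SPECIFIC_FERTILITY_RATES = (0.144, 0.239, 0.213, 0.174, 0.123, 0.061, 0.022)
PREGNANCY_SCALING_FACTORS = (1.227, 0.799, 0.829, 0.809, 0.749, 0.645, 0.941)
RR_FAIL_UNDER25 = 2.2
DAYS_BETWEEN_APPTS = {
    "IUD": 4383,
    "implant": 1461,
    "injection": 91,
    "male_condom": 91,
    "other_modern": 91,
    "pill": 91,
}
BASELINE_YEAR = 2010

_SUM_TOL = 1e-9


@dataclasses.dataclass
class ValidationReport:
    """Outcome of parameter validation: all rule violations, not just the first."""

    violations: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, rule: str, location: str, message: str) -> None:
        self.violations.append((rule, location, message))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "ValidationReport(ok)"
        lines = "\n  ".join(f"[{r}] {loc}: {msg}" for r, loc, msg in self.violations)
        return f"ValidationReport({len(self.violations)} violations)\n  {lines}"


@dataclasses.dataclass
class InterventionSpec:
    """Family-planning scale-up interventions.

    ``pop`` multiplies the monthly initiation probability of each modern
    method (population-scope demand-creation campaign); ``ppfp`` multiplies
    the postpartum initiation probability (postpartum family-planning
    integration).  Traditional methods always carry multiplier 1.
    """

    pop: pd.Series
    ppfp: pd.Series
    start_month: int  # absolute month index (see timegrid)

    def __post_init__(self) -> None:
        self.pop = self.pop.reindex(CONTRACEPTIVES).fillna(1.0).astype(float)
        self.ppfp = self.ppfp.reindex(CONTRACEPTIVES).fillna(1.0).astype(float)
        for name, s in (("pop", self.pop), ("ppfp", self.ppfp)):
            if (s < 0).any():
                raise ValueError(f"{name} multipliers must be >= 0")
            bad = [m for m in TRADITIONAL_METHODS if s[m] != 1.0]
            if bad:
                raise ValueError(
                    f"{name} multipliers for traditional methods must be 1: {bad}"
                )

    def active(self, month: int) -> bool:
        return month >= self.start_month


@dataclasses.dataclass
class ParameterSet:
    """Complete parameter bundle for the monthly transition model."""

    # age 15-49 indexed (single years)
    method_use_in_2010: pd.DataFrame          # ages x 11 states, rows sum to 1
    pregnancy_not_using_in_2010: pd.Series    # monthly pregnancy probability
    initiation_by_age: pd.Series              # proportional deviation
    discontinuation_by_age: pd.Series         # proportional deviation
    # five-year age-group indexed
    pregnancy_not_using_hiv_effect: pd.Series
    age_specific_fertility_rates: pd.Series   # annual live births per woman
    scaling_factor_on_monthly_risk_of_pregnancy: pd.Series
    # method indexed (10 contraceptives)
    initiation_by_method: pd.Series
    initiation_after_birth: pd.Series
    prob_switch_from: pd.Series
    switch_matrix: pd.DataFrame               # from x to, rows sum to 1, diag 0
    failure_by_method: pd.Series
    discontinuation_by_method: pd.Series
    # scalars
    rr_fail_under25: float = RR_FAIL_UNDER25
    time_age_trend_in_initiation: float = 1.0
    time_age_trend_in_stopping: float = 1.0
    live_birth_probability: float = 1.0
    days_between_appts_for_maintenance: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(DAYS_BETWEEN_APPTS)
    )
    # age-expanded initiation matrices set by the sterilization restriction;
    # when absent the method-level vectors are broadcast over ages.
    initiation_by_method_age: pd.DataFrame | None = None
    initiation_after_birth_age: pd.DataFrame | None = None

    # -- derived accessors -------------------------------------------------
    def initiation_matrix(self) -> pd.DataFrame:
        """Base monthly initiation probabilities, ages x contraceptives."""
        if self.initiation_by_method_age is not None:
            return self.initiation_by_method_age
        return pd.DataFrame(
            np.tile(self.initiation_by_method.values, (len(AGES), 1)),
            index=list(AGES), columns=list(CONTRACEPTIVES),
        )

    def after_birth_matrix(self) -> pd.DataFrame:
        """Postpartum initiation probabilities, ages x contraceptives."""
        if self.initiation_after_birth_age is not None:
            return self.initiation_after_birth_age
        return pd.DataFrame(
            np.tile(self.initiation_after_birth.values, (len(AGES), 1)),
            index=list(AGES), columns=list(CONTRACEPTIVES),
        )

    def copy(self) -> "ParameterSet":
        return dataclasses.replace(
            self,
            **{
                f.name: (
                    getattr(self, f.name).copy()
                    if isinstance(getattr(self, f.name), (pd.Series, pd.DataFrame, dict))
                    else getattr(self, f.name)
                )
                for f in dataclasses.fields(self)
            },
        )


# ---------------------------------------------------------------------------
# validation

def _check_prob(report, rule, location, values) -> None:
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        report.add(rule, location, "contains NaN")
    elif (arr < 0).any() or (arr > 1).any():
        report.add(rule, location, "probability out of range [0, 1]")


def validate_parameters(p: ParameterSet) -> ValidationReport:
    """Check every structural invariant; violations are data, not exceptions."""
    r = ValidationReport()

    mu = p.method_use_in_2010
    if list(mu.index) != list(AGES):
        r.add("method_use.ages", "method_use_in_2010", "rows must be ages 15..49")
    if list(mu.columns) != list(METHODS):
        r.add("method_use.columns", "method_use_in_2010",
              f"columns must be the 11 states {METHODS}")
    _check_prob(r, "prob_range", "method_use_in_2010", mu.values)
    rowsum = mu.sum(axis=1)
    bad = rowsum[(rowsum - 1.0).abs() > _SUM_TOL]
    for age, s in bad.items():
        r.add("method_use.rowsum", f"method_use_in_2010[age={age}]",
              f"states sum to {s:.12f}, expected 1")

    _check_prob(r, "prob_range", "pregnancy_not_using_in_2010",
                p.pregnancy_not_using_in_2010)
    for name in ("initiation_by_method", "initiation_after_birth",
                 "prob_switch_from", "failure_by_method",
                 "discontinuation_by_method"):
        s = getattr(p, name)
        if list(s.index) != list(CONTRACEPTIVES):
            r.add("method_index", name, "index must be the 10 contraceptive methods")
        _check_prob(r, "prob_range", name, s)

    sm = p.switch_matrix
    if list(sm.index) != list(CONTRACEPTIVES) or list(sm.columns) != list(CONTRACEPTIVES):
        r.add("switch_matrix.shape", "switch_matrix",
              "rows/columns must be the 10 contraceptive methods")
    else:
        _check_prob(r, "prob_range", "switch_matrix", sm.values)
        if (np.diag(sm.values) != 0).any():
            r.add("switch_matrix.diag", "switch_matrix",
                  "self-switching probability must be 0")
        rs = sm.sum(axis=1)
        for m, s in rs[(rs - 1.0).abs() > _SUM_TOL].items():
            r.add("switch_matrix.rowsum", f"switch_matrix[{m}]",
                  f"row sums to {s:.12f}, expected 1")

    for name in ("pregnancy_not_using_hiv_effect", "age_specific_fertility_rates",
                 "scaling_factor_on_monthly_risk_of_pregnancy"):
        s = getattr(p, name)
        if list(s.index) != list(AGE_GROUPS):
            r.add("agegroup_index", name, "index must be the 7 five-year age groups")
        if (np.asarray(s, float) < 0).any():
            r.add("nonneg", name, "values must be >= 0")

    for name in ("initiation_by_age", "discontinuation_by_age"):
        s = getattr(p, name)
        if list(s.index) != list(AGES):
            r.add("age_index", name, "index must be ages 15..49")
        if (1.0 + np.asarray(s, float) < 0).any():
            r.add("age_effect", name, "1 + deviation must be >= 0")

    if not p.rr_fail_under25 > 0:
        r.add("rr_fail", "rr_fail_under25", "must be > 0")
    if not 0 <= p.live_birth_probability <= 1:
        r.add("prob_range", "live_birth_probability", "probability out of range [0, 1]")
    for t in ("time_age_trend_in_initiation", "time_age_trend_in_stopping"):
        if not getattr(p, t) > 0:
            r.add("trend", t, "per-year trend factor must be > 0")
    for m in MAINTAINABLE_METHODS:
        d = p.days_between_appts_for_maintenance.get(m)
        if not (isinstance(d, (int, np.integer)) and d > 0):
            r.add("appt_days", f"days_between_appts_for_maintenance[{m}]",
                  "must be a positive integer number of days")

    for mat, name in ((p.initiation_by_method_age, "initiation_by_method_age"),
                      (p.initiation_after_birth_age, "initiation_after_birth_age")):
        if mat is not None:
            _check_prob(r, "prob_range", name, mat.values)

    return r


# ---------------------------------------------------------------------------
# sterilization age restriction

def apply_sterilization_age_restriction(
    p: ParameterSet,
    eligible_age: int = 30,
    age_weights: pd.Series | None = None,
) -> ParameterSet:
    """Zero sterilization initiation below ``eligible_age``, preserving totals.

    The initiation probability of female sterilization is set to 0 for ages
    below the eligibility cut and scaled up for older ages by
    ``sum(weights) / sum(weights at eligible ages)`` so that the
    population-expected number of sterilization initiations (under the given
    age weights) is unchanged.  Within each age, the other methods are then
    rescaled multiplicatively so the total initiation probability at that
    age is also unchanged.  Both the from-non-use and the postpartum
    initiation tables are transformed.
    """
    if age_weights is None:
        age_weights = pd.Series(1.0, index=list(AGES))
    w = age_weights.reindex(list(AGES)).fillna(0.0).astype(float)
    if (w < 0).any():
        raise ValueError("age_weights must be nonnegative")
    ages = np.array(AGES)
    w_tot = w.values.sum()
    w_old = w.values[ages >= eligible_age].sum()
    if w_tot == 0 or w_old == 0:
        raise ValueError("age_weights must have mass at ages >= eligible_age")
    scale = w_tot / w_old

    out = p.copy()
    for attr, getter in (("initiation_by_method_age", p.initiation_matrix),
                         ("initiation_after_birth_age", p.after_birth_matrix)):
        mat = getter().copy()
        ster = mat["female_sterilization"].values.copy()
        new_ster = np.where(ages < eligible_age, 0.0, ster * scale)
        if (new_ster > 1).any():
            raise ValueError(
                "scaled sterilization probability exceeds 1; raise eligible_age "
                "or cap the input probability"
            )
        others = [m for m in CONTRACEPTIVES if m != "female_sterilization"]
        other_tot = mat[others].sum(axis=1).values
        target_other = mat.sum(axis=1).values - new_ster
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(other_tot > 0, target_other / other_tot, 1.0)
        if ((other_tot <= 0) & (target_other > 1e-15)).any():
            raise ValueError(
                "cannot redistribute initiation mass at an age with no other methods"
            )
        mat[others] = mat[others].values * factor[:, None]
        mat["female_sterilization"] = new_ster
        setattr(out, attr, mat)
    return out


# ---------------------------------------------------------------------------
# synthetic defaults

def _smooth_noise(rng: np.random.Generator, n: int, sd: float = 0.02) -> np.ndarray:
    """Small smooth multiplicative perturbation (moving-average of white noise)."""
    z = rng.normal(0.0, sd, n + 4)
    k = np.ones(5) / 5.0
    return 1.0 + np.convolve(z, k, mode="valid")


def generate_default_parameters(seed: int = 0) -> ParameterSet:
    """Synthesize a complete, validated parameter set.

    The published scalar vectors (HIV fertility multipliers, age-specific
    fertility rates, pregnancy scaling factors, the under-25 failure risk
    ratio and the maintenance-appointment intervals) are embedded verbatim.
    The method-level tables, for which only survey-derived estimates exist,
    are synthesized to a realistic Malawi-2010 pattern: injection is the
    dominant modern method, sterilization is rare and concentrated at older
    ages, traditional methods are minor.  ``seed`` controls only a small
    smooth perturbation of the age curves, so any seed yields a valid set
    and equal seeds yield identical sets.
    """
    rng = np.random.default_rng(seed)
    ages = np.array(AGES, dtype=float)

    # -- method-level tables ------------------------------------------------
    initiation = pd.Series({
        "pill": 0.0030, "IUD": 0.0002, "injection": 0.0090, "implant": 0.0018,
        "male_condom": 0.0030, "female_sterilization": 0.0006,
        "other_modern": 0.0002, "periodic_abstinence": 0.0015,
        "withdrawal": 0.0012, "other_traditional": 0.0005,
    }).reindex(CONTRACEPTIVES)
    after_birth = pd.Series({
        "pill": 0.020, "IUD": 0.002, "injection": 0.100, "implant": 0.030,
        "male_condom": 0.010, "female_sterilization": 0.004,
        "other_modern": 0.002, "periodic_abstinence": 0.008,
        "withdrawal": 0.005, "other_traditional": 0.003,
    }).reindex(CONTRACEPTIVES)
    failure = pd.Series({
        "pill": 0.0040, "IUD": 0.0006, "injection": 0.0015, "implant": 0.0003,
        "male_condom": 0.0090, "female_sterilization": 0.00004,
        "other_modern": 0.0060, "periodic_abstinence": 0.0180,
        "withdrawal": 0.0150, "other_traditional": 0.0120,
    }).reindex(CONTRACEPTIVES)
    discontinuation = pd.Series({
        "pill": 0.035, "IUD": 0.012, "injection": 0.025, "implant": 0.014,
        "male_condom": 0.045, "female_sterilization": 0.0,
        "other_modern": 0.040, "periodic_abstinence": 0.050,
        "withdrawal": 0.055, "other_traditional": 0.050,
    }).reindex(CONTRACEPTIVES)
    switch_from = pd.Series({
        "pill": 0.015, "IUD": 0.008, "injection": 0.010, "implant": 0.008,
        "male_condom": 0.018, "female_sterilization": 0.0,
        "other_modern": 0.015, "periodic_abstinence": 0.020,
        "withdrawal": 0.020, "other_traditional": 0.018,
    }).reindex(CONTRACEPTIVES)

    # switch destinations proportional to the initiation profile of the
    # destination method (a woman switching tends to pick a popular method)
    sm = np.zeros((len(CONTRACEPTIVES), len(CONTRACEPTIVES)))
    init_w = initiation.values
    for i in range(len(CONTRACEPTIVES)):
        w = init_w.copy()
        w[i] = 0.0
        sm[i] = w / w.sum()
    switch_matrix = pd.DataFrame(sm, index=list(CONTRACEPTIVES),
                                 columns=list(CONTRACEPTIVES))

    # -- baseline method mix by age ----------------------------------------
    # overall use rises from the mid-teens, peaks in the thirties, eases off
    use_total = 0.12 + 0.33 * np.exp(-((ages - 35.0) / 12.0) ** 2)
    use_total *= _smooth_noise(rng, len(ages))
    shares = pd.DataFrame(0.0, index=list(AGES), columns=list(CONTRACEPTIVES))
    base_share = {
        "pill": 0.085, "IUD": 0.012, "injection": 0.60, "implant": 0.07,
        "male_condom": 0.055, "other_modern": 0.008,
        "periodic_abstinence": 0.07, "withdrawal": 0.05,
        "other_traditional": 0.025,
    }
    ster_ramp = np.clip((ages - 25.0) / 24.0, 0.0, 1.0) ** 2 * 0.25
    for m, s in base_share.items():
        shares[m] = s
    shares["female_sterilization"] = ster_ramp
    shares = shares.div(shares.sum(axis=1), axis=0)
    mu = shares.mul(use_total, axis=0)
    mu.insert(0, NOT_USING, 1.0 - mu.sum(axis=1))
    method_use = mu[list(METHODS)]

    # -- pregnancy risk while not using, monthly, by age --------------------
    group_p = np.array([0.020, 0.028, 0.025, 0.021, 0.015, 0.008, 0.003])
    group_mid = np.array([17, 22, 27, 32, 37, 42, 47], dtype=float)
    preg_nu = np.interp(ages, group_mid, group_p)
    preg_nu *= _smooth_noise(rng, len(ages), sd=0.01)

    # -- age effects (proportional deviations) ------------------------------
    init_dev = 0.3 - 0.9 * ((ages - 25.0) / 24.0) ** 2
    init_dev *= _smooth_noise(rng, len(ages), sd=0.01)
    disc_dev = 0.4 - 0.8 * (ages - 15.0) / 34.0
    disc_dev *= _smooth_noise(rng, len(ages), sd=0.01)

    p = ParameterSet(
        method_use_in_2010=method_use,
        pregnancy_not_using_in_2010=pd.Series(preg_nu, index=list(AGES)),
        initiation_by_age=pd.Series(init_dev, index=list(AGES)),
        discontinuation_by_age=pd.Series(disc_dev, index=list(AGES)),
        pregnancy_not_using_hiv_effect=pd.Series(HIV_FERTILITY_EFFECT,
                                                 index=list(AGE_GROUPS)),
        age_specific_fertility_rates=pd.Series(AGE_SPECIFIC_FERTILITY_RATES,
                                               index=list(AGE_GROUPS)),
        scaling_factor_on_monthly_risk_of_pregnancy=pd.Series(
            PREGNANCY_SCALING_FACTORS, index=list(AGE_GROUPS)),
        initiation_by_method=initiation,
        initiation_after_birth=after_birth,
        prob_switch_from=switch_from,
        switch_matrix=switch_matrix,
        failure_by_method=failure,
        discontinuation_by_method=discontinuation,
        rr_fail_under25=RR_FAIL_UNDER25,
        time_age_trend_in_initiation=1.02,
        time_age_trend_in_stopping=0.98,
    )
    report = validate_parameters(p)
    assert report.ok, report
    return p


def default_intervention_spec(start_month: int) -> InterventionSpec:
    """Scale-up multipliers emulating an ambitious national plan.

    Long-acting methods are pushed hardest (implant, IUD), consistent with
    costed-implementation-plan targets that shift the mix toward
    long-acting reversible contraception.
    """
    pop = pd.Series({
        "pill": 1.8, "IUD": 3.0, "injection": 1.6, "implant": 3.5,
        "male_condom": 2.0, "female_sterilization": 1.4, "other_modern": 2.5,
    })
    ppfp = pd.Series({
        "pill": 1.8, "IUD": 3.0, "injection": 1.5, "implant": 3.0,
        "male_condom": 1.8, "female_sterilization": 1.4, "other_modern": 2.2,
    })
    return InterventionSpec(pop=pop, ppfp=ppfp, start_month=start_month)


# ---------------------------------------------------------------------------
# serialization: one CSV per table family plus a YAML manifest

_TABLE_FIELDS = (
    "method_use_in_2010", "pregnancy_not_using_in_2010", "initiation_by_age",
    "discontinuation_by_age", "pregnancy_not_using_hiv_effect",
    "age_specific_fertility_rates", "scaling_factor_on_monthly_risk_of_pregnancy",
    "initiation_by_method", "initiation_after_birth", "prob_switch_from",
    "switch_matrix", "failure_by_method", "discontinuation_by_method",
)
_OPTIONAL_TABLE_FIELDS = ("initiation_by_method_age", "initiation_after_birth_age")
_SCALAR_FIELDS = (
    "rr_fail_under25", "time_age_trend_in_initiation", "time_age_trend_in_stopping",
    "live_birth_probability",
)

#: Defaults used when an optional table/scalar is absent from a bundle.
_OPTIONAL_DEFAULTS = {
    "initiation_by_age": lambda: pd.Series(0.0, index=list(AGES)),
    "discontinuation_by_age": lambda: pd.Series(0.0, index=list(AGES)),
    "pregnancy_not_using_hiv_effect": lambda: pd.Series(
        HIV_FERTILITY_EFFECT, index=list(AGE_GROUPS)),
    "age_specific_fertility_rates": lambda: pd.Series(
        AGE_SPECIFIC_FERTILITY_RATES, index=list(AGE_GROUPS)),
    "scaling_factor_on_monthly_risk_of_pregnancy": lambda: pd.Series(
        PREGNANCY_SCALING_FACTORS, index=list(AGE_GROUPS)),
}


def save_parameters(p: ParameterSet, directory: str | Path) -> Path:
    """Write a parameter bundle (CSV per table + manifest.yaml); returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tables": {}, "scalars": {}}
    for name in _TABLE_FIELDS + _OPTIONAL_TABLE_FIELDS:
        obj = getattr(p, name)
        if obj is None:
            continue
        fn = f"{name}.csv"
        frame = obj.to_frame("value") if isinstance(obj, pd.Series) else obj
        frame.to_csv(directory / fn, index_label="index")
        manifest["tables"][name] = fn
    for name in _SCALAR_FIELDS:
        manifest["scalars"][name] = float(getattr(p, name))
    manifest["scalars"]["days_between_appts_for_maintenance"] = {
        k: int(v) for k, v in p.days_between_appts_for_maintenance.items()
    }
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


class ParameterSchemaError(ValueError):
    """A parameter table is missing or malformed."""


def _read_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise ParameterSchemaError(f"missing parameter table '{name}' ({path})")
    try:
        frame = pd.read_csv(path, index_col="index")
    except Exception as exc:  # noqa: BLE001 - report file and table name
        raise ParameterSchemaError(f"malformed table '{name}' ({path}): {exc}") from exc
    return frame


def load_parameters(source: str | Path) -> ParameterSet:
    """Load a parameter bundle from a manifest file or bundle directory.

    Optional tables absent from the bundle are filled from the documented
    defaults (zero age effects; the published HIV-effect, fertility-rate and
    scaling-factor vectors).  The loaded set must pass validation.
    """
    source = Path(source)
    manifest_path = source / "manifest.yaml" if source.is_dir() else source
    if not manifest_path.exists():
        raise ParameterSchemaError(f"no parameter manifest at {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    directory = manifest_path.parent
    tables: dict[str, str] = manifest.get("tables", {})
    scalars: dict = manifest.get("scalars", {})

    kwargs: dict = {}
    for name in _TABLE_FIELDS:
        if name in tables:
            frame = _read_table(directory / tables[name], name)
        elif name in _OPTIONAL_DEFAULTS:
            kwargs[name] = _OPTIONAL_DEFAULTS[name]()
            continue
        else:
            raise ParameterSchemaError(f"missing required parameter table '{name}'")
        if name in ("method_use_in_2010", "switch_matrix"):
            kwargs[name] = frame
        else:
            if "value" not in frame.columns:
                raise ParameterSchemaError(
                    f"table '{name}' must have a single 'value' column")
            kwargs[name] = frame["value"]
    for name in _OPTIONAL_TABLE_FIELDS:
        if name in tables:
            kwargs[name] = _read_table(directory / tables[name], name)

    # normalize indexes: method tables use string labels, age tables ints
    for name, obj in list(kwargs.items()):
        if isinstance(obj, (pd.Series, pd.DataFrame)):
            try:
                obj.index = obj.index.astype(int)
            except (TypeError, ValueError):
                obj.index = obj.index.astype(str)
            obj.index.name = None
            if isinstance(obj, pd.Series):
                obj.name = None

    for name in _SCALAR_FIELDS:
        if name in scalars:
            kwargs[name] = float(scalars[name])
    if "days_between_appts_for_maintenance" in scalars:
        kwargs["days_between_appts_for_maintenance"] = {
            k: int(v) for k, v in scalars["days_between_appts_for_maintenance"].items()
        }

    p = ParameterSet(**kwargs)
    report = validate_parameters(p)
    if not report.ok:
        raise ParameterSchemaError(f"loaded parameters invalid: {report}")
    return p
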