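import dataclasses

import numpy as np
import pandas as pd
import pytest

import contrasim as cs
from contrasim import timegrid as tg
from contrasim.methods import AGES, AGE_GROUPS, CONTRACEPTIVES, METHODS


@pytest.fixture(scope="session")
def params():
    return cs.generate_default_parameters(1)


@pytest.fixture(scope="session")
def restricted_params(params):
    return cs.apply_sterilization_age_restriction(params)


@pytest.fixture(scope="session")
def packages():
    return cs.default_consumable_packages()


def make_params(base, **overrides):
    """Copy of a parameter set with field overrides (tables may be mutated)."""
    return dataclasses.replace(base.copy(), **overrides)


@pytest.fixture
def zero_transition_params(params):
    """All transition, failure and pregnancy probabilities zero."""
    p = params.copy()
    zero_m = pd.Series(0.0, index=list(CONTRACEPTIVES))
    return dataclasses.replace(
        p,
        pregnancy_not_using_in_2010=pd.Series(0.0, index=list(AGES)),
        initiation_by_method=zero_m.copy(),
        initiation_after_birth=zero_m.copy(),
        prob_switch_from=zero_m.copy(),
        failure_by_method=zero_m.copy(),
        discontinuation_by_method=zero_m.copy(),
        age_specific_fertility_rates=pd.Series(0.0, index=list(AGE_GROUPS)),
        time_age_trend_in_initiation=1.0,
        time_age_trend_in_stopping=1.0,
        initiation_by_method_age=None,
        initiation_after_birth_age=None,
    )


@pytest.fixture
def zero_mortality():
    sched = cs.default_mortality_schedule()
    return sched * 0.0


def women_only_structure(age: int) -> pd.Series:
    """Age structure concentrated on women of a single age."""
    idx = pd.MultiIndex.from_tuples([("F", age)], names=["sex", "age"])
    return pd.Series([1.0], index=idx)


@pytest.fixture
def month2010():
    return tg.month_index(2010)
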