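"""Contraceptive method categories.

The state space is the 11-category classification used in DHS contraceptive
calendars: "not_using" plus 10 methods.  Modern methods are the seven
categories targeted by family-planning programmes; the remaining three are
traditional methods.
"""

from __future__ import annotations

NOT_USING = "not_using"

#: All 11 states, in canonical order (index 0 is non-use).
METHODS: tuple[str, ...] = (
    "not_using",
    "pill",
    "IUD",
    "injection",
    "implant",
    "male_condom",
    "female_sterilization",
    "other_modern",
    "periodic_abstinence",
    "withdrawal",
    "other_traditional",
)

#: The 10 actual methods (everything except non-use).
CONTRACEPTIVES: tuple[str, ...] = METHODS[1:]

MODERN_METHODS: tuple[str, ...] = (
    "pill",
    "IUD",
    "injection",
    "implant",
    "male_condom",
    "female_sterilization",
    "other_modern",
)

TRADITIONAL_METHODS: tuple[str, ...] = (
    "periodic_abstinence",
    "withdrawal",
    "other_traditional",
)

#: Methods whose continued use requires a recurring family-planning
#: appointment at which a consumable package is dispensed.
MAINTAINABLE_METHODS: tuple[str, ...] = (
    "IUD",
    "implant",
    "injection",
    "male_condom",
    "other_modern",
    "pill",
)

METHOD_INDEX: dict[str, int] = {m: i for i, m in enumerate(METHODS)}

#: Five-year age-group labels covering the reproductive ages 15-49.
AGE_GROUPS: tuple[str, ...] = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
)

AGE_MIN = 15
AGE_MAX = 49
AGES = tuple(range(AGE_MIN, AGE_MAX + 1))


def is_modern(method: str) -> bool:
    return method in MODERN_METHODS


def age_group_of(age: int) -> str:
    """Five-year age-group label for an age in years (15-49)."""
    if age < AGE_MIN or age > AGE_MAX:
        raise ValueError(f"age {age} outside the reproductive range 15-49")
    lo = AGE_MIN + 5 * ((age - AGE_MIN) // 5)
    return f"{lo}-{lo + 4}"


def age_group_index(age: int) -> int:
    if age < AGE_MIN or age > AGE_MAX:
        raise ValueError(f"age {age} outside the reproductive range 15-49")
    return (age - AGE_MIN) // 5
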