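"""Attribute schema: the catalogue of variables describing zones, households and
individuals in the synthetic population.

The schema drives discretization, conditional-table estimation, Gibbs sampling and
validation.  Every categorical variable carries an ordered category list; age is stored
both as an integer (years) and as a 4-class band used by all conditionals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "AGE_CLASSES",
    "AGE_BOUNDS",
    "Variable",
    "AttributeSchema",
    "SchemaError",
    "default_schema",
    "age_to_class",
    "age_class_interval",
]


class SchemaError(ValueError):
    """A variable or category is absent from, or inconsistent with, the schema."""


# Age bands: lower bound inclusive, upper bound exclusive, except the last band whose
# upper bound (120) is inclusive.
AGE_CLASSES: tuple[str, ...] = ("0-15", "15-35", "35-65", "65-120")
AGE_BOUNDS: tuple[tuple[int, int], ...] = ((0, 15), (15, 35), (35, 65), (65, 121))

HOUSEHOLD_TYPES: tuple[str, ...] = ("Single", "single parent", "couple", "family")
HOUSEHOLD_SIZES: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
GENDERS: tuple[str, ...] = ("Male", "Female")
SPC_CATEGORIES: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
SPC_RETIRED = 7
SPC_INACTIVE = 8
EDUCATION_LEVELS: tuple[str, ...] = ("none", "primary", "secondary", "university/college")
ROLES: tuple[str, ...] = ("head", "spouse", "child")
ACTIVITIES: tuple[str, ...] = (
    "Employed",
    "unemployed",
    "retired",
    "student",
    "other unemployed",
)
OVERWEIGHT_LEVELS: tuple[int, ...] = (0, 1, 2)  # normal / overweight / obese
CAR_OWNERSHIP: tuple[int, ...] = (0, 1)
INCOME_CLASSES: tuple[str, ...] = ("low", "intermediate", "high")

#: activities counted as non-working for the adult income floor
NON_WORKING_ACTIVITIES: frozenset[str] = frozenset(
    {"unemployed", "retired", "other unemployed"}
)


@dataclass(frozen=True)
class Variable:
    """One schema variable.

    Parameters
    ----------
    name:
        Column name in microdata tables.
    level:
        ``"zonal"``, ``"household"`` or ``"individual"``.
    vtype:
        ``"categorical"``, ``"integer"`` or ``"continuous"``.
    categories:
        Ordered category tuple for categorical/integer-coded variables; empty for
        continuous variables.
    other_category:
        Optional designated sink category into which rare categories are merged
        during estimation.
    """

    name: str
    level: str
    vtype: str
    categories: tuple = ()
    other_category: object | None = None

    def __post_init__(self) -> None:
        if self.level not in ("zonal", "household", "individual"):
            raise SchemaError(f"unknown level {self.level!r} for variable {self.name!r}")
        if self.vtype not in ("categorical", "integer", "continuous"):
            raise SchemaError(f"unknown type {self.vtype!r} for variable {self.name!r}")
        if self.other_category is not None and self.other_category not in self.categories:
            raise SchemaError(
                f"other_category {self.other_category!r} not a category of {self.name!r}"
            )

    @property
    def cardinality(self) -> int:
        return len(self.categories)

    def code_of(self, value) -> int:
        try:
            return self.categories.index(value)
        except ValueError:
            raise SchemaError(f"{value!r} is not a category of {self.name!r}") from None


@dataclass
class AttributeSchema:
    """Ordered mapping of :class:`Variable` by name."""

    variables: dict[str, Variable] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def __getitem__(self, name: str) -> Variable:
        try:
            return self.variables[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def add(self, var: Variable) -> None:
        self.variables[var.name] = var

    def names(self, level: str | None = None) -> list[str]:
        return [
            v.name
            for v in self.variables.values()
            if level is None or v.level == level
        ]

    def categorical_names(self) -> list[str]:
        return [v.name for v in self.variables.values() if v.categories]

    def validate_presence(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise SchemaError(f"schema is missing variables: {missing}")

    def categories(self, name: str) -> tuple:
        return self[name].categories


def default_schema() -> AttributeSchema:
    """The default variable catalogue for the generator."""
    schema = AttributeSchema()
    for var in (
        Variable("population", "zonal", "integer"),
        Variable("household_type", "household", "categorical", HOUSEHOLD_TYPES),
        Variable("household_size", "household", "integer", HOUSEHOLD_SIZES),
        Variable("income", "household", "continuous"),
        Variable("income_class", "household", "categorical", INCOME_CLASSES),
        Variable("car_ownership", "household", "integer", CAR_OWNERSHIP),
        Variable("age", "individual", "integer"),
        Variable("age_class", "individual", "categorical", AGE_CLASSES),
        Variable("gender", "individual", "categorical", GENDERS),
        Variable("spc", "individual", "integer", SPC_CATEGORIES, other_category=SPC_INACTIVE),
        Variable("education", "individual", "categorical", EDUCATION_LEVELS),
        Variable("role", "individual", "categorical", ROLES),
        Variable(
            "main_activity",
            "individual",
            "categorical",
            ACTIVITIES,
            other_category="other unemployed",
        ),
        Variable("overweight", "individual", "integer", OVERWEIGHT_LEVELS),
    ):
        schema.add(var)
    return schema


def age_to_class(age: float) -> str:
    """Map an integer age in years to its band (lower-inclusive, upper-exclusive,
    final band upper-inclusive)."""
    if age < 0:
        raise ValueError(f"negative age {age}")
    if age > 120:
        raise ValueError(f"age {age} above the supported maximum of 120")
    for label, (lo, hi) in zip(AGE_CLASSES, AGE_BOUNDS):
        if lo <= age < hi:
            return label
    raise AssertionError("unreachable")


def age_class_interval(age_class: str) -> tuple[int, int]:
    """Inclusive integer interval ``(lo, hi)`` of ages covered by a band."""
    try:
        i = AGE_CLASSES.index(age_class)
    except ValueError:
        raise SchemaError(f"unknown age class {age_class!r}") from None
    lo, hi = AGE_BOUNDS[i]
    return lo, hi - 1


def compatible_household_types(size: int) -> tuple[str, ...]:
    """Household types structurally compatible with a household size."""
    if size == 1:
        return ("Single",)
    if size == 2:
        return ("single parent", "couple")
    return ("single parent", "family")


def roles_for(household_type: str, size: int) -> tuple[str, ...]:
    """Member roles by position: head first, spouse second in couple/family,
    everyone after the parents a child."""
    if household_type == "Single":
        if size != 1:
            raise ValueError("Single household must have size 1")
        return ("head",)
    if household_type == "single parent":
        return ("head",) + ("child",) * (size - 1)
    if household_type in ("couple", "family"):
        if size < 2:
            raise ValueError(f"{household_type} household needs at least 2 members")
        return ("head", "spouse") + ("child",) * (size - 2)
    raise SchemaError(f"unknown household type {household_type!r}")
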