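"""Income and overweight/obesity enrichment of generated individuals.

Income follows a weighted-median scheme: an individual's income is the commune's
median annual income scaled by alpha(SPC) = median income of the SPC / median income
of the whole population, with a multiplicative lognormal dispersion to restore
within-cell spread, then floored at the 2010 French minimum wage (12,672 EUR/year)
for the employed and at the Active Solidarity Income (5,520 EUR/year) for non-working
adults aged 25 or over.  Schoolchildren and students receive no income.

Overweight status (0 normal / 1 overweight / 2 obese) is drawn independently per
agent from a national contingency table stratified by gender x age class x SPC, with
fallback to gender x age class and then to the overall marginal when a stratum is
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .schema import NON_WORKING_ACTIVITIES

__all__ = [
    "EMPLOYED_FLOOR",
    "NON_WORKING_FLOOR",
    "IncomeModel",
    "OverweightModel",
    "assign_income",
    "assign_income_frame",
    "aggregate_household_income",
    "aggregate_household_income_frame",
    "assign_overweight",
    "assign_overweight_frame",
]

#: 2010 annual minimum wage, EUR/year
EMPLOYED_FLOOR = 12672.0
#: 2010 annual Active Solidarity Income, EUR/year
NON_WORKING_FLOOR = 5520.0


@dataclass
class IncomeModel:
    """Commune and SPC income medians with the derived alpha weights.

    ``alpha(spc) > 1`` exactly when that SPC's median exceeds the population
    median, in which case its members earn above the commune median.
    """

    commune_medians: dict[str, float]
    spc_medians: dict[int, float]
    population_median: float
    employed_floor: float = EMPLOYED_FLOOR
    non_working_floor: float = NON_WORKING_FLOOR
    dispersion_sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.population_median <= 0:
            raise ValueError("population median income must be positive")
        if self.employed_floor <= 0 or self.non_working_floor <= 0:
            raise ValueError("income floors must be positive")

    def alpha(self, spc: int) -> float:
        try:
            return self.spc_medians[int(spc)] / self.population_median
        except KeyError:
            raise ValueError(f"no median income known for SPC {spc!r}") from None

    @classmethod
    def from_tables(
        cls,
        commune_table: pd.DataFrame,
        spc_table: pd.DataFrame,
        population_median: float,
        **kwargs,
    ) -> "IncomeModel":
        """Build from delimited tables (zone_id, median_income) and (spc, median_income)."""
        return cls(
            commune_medians=dict(
                zip(commune_table["zone_id"].astype(str), commune_table["median_income"])
            ),
            spc_medians=dict(
                zip(spc_table["spc"].astype(int), spc_table["median_income"])
            ),
            population_median=float(population_median),
            **kwargs,
        )


def assign_income(
    age: int,
    spc: int,
    main_activity: str,
    commune: str,
    model: IncomeModel,
    rng: np.random.Generator | None = None,
) -> float:
    """Annual income (EUR/year) for one individual.

    With ``model.dispersion_sigma == 0`` (dispersion off) the result is exactly
    ``alpha(SPC) x commune median``, before flooring.
    """
    if main_activity == "student" or age < 18:
        return 0.0
    try:
        median = model.commune_medians[commune]
    except KeyError:
        raise ValueError(f"no median income known for commune {commune!r}") from None
    base = model.alpha(spc) * median
    if model.dispersion_sigma > 0:
        if rng is None:
            raise ValueError("dispersion requires a random generator")
        base *= rng.lognormal(0.0, model.dispersion_sigma)
    if main_activity == "Employed":
        return max(base, model.employed_floor)
    if main_activity in NON_WORKING_ACTIVITIES and age >= 25:
        return max(base, model.non_working_floor)
    return base


def assign_income_frame(
    individuals: pd.DataFrame,
    commune_of_zone: dict[str, str],
    model: IncomeModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized :func:`assign_income` over an individuals table."""
    n = len(individuals)
    communes = individuals["zone_id"].map(commune_of_zone)
    if communes.isna().any():
        missing = individuals.loc[communes.isna(), "zone_id"].iloc[0]
        raise ValueError(f"zone {missing!r} has no commune mapping")
    medians = communes.map(model.commune_medians)
    if medians.isna().any():
        raise ValueError(f"commune {communes[medians.isna()].iloc[0]!r} has no median income")
    alphas = individuals["spc"].astype(int).map(
        {s: model.alpha(s) for s in model.spc_medians}
    )
    if alphas.isna().any():
        raise ValueError(
            f"no median income known for SPC "
            f"{individuals.loc[alphas.isna(), 'spc'].iloc[0]!r}"
        )
    base = alphas.to_numpy() * medians.to_numpy()
    if model.dispersion_sigma > 0:
        base = base * rng.lognormal(0.0, model.dispersion_sigma, n)

    age = individuals["age"].to_numpy()
    activity = individuals["main_activity"]
    income = base.copy()
    employed = (activity == "Employed").to_numpy()
    income[employed] = np.maximum(income[employed], model.employed_floor)
    floor_nw = (activity.isin(NON_WORKING_ACTIVITIES)).to_numpy() & (age >= 25)
    income[floor_nw] = np.maximum(income[floor_nw], model.non_working_floor)
    income[(activity == "student").to_numpy() | (age < 18)] = 0.0
    return income


def aggregate_household_income(household) -> float:
    """Household income = sum of member incomes (order-invariant)."""
    total = 0.0
    for member in household.members:
        if member.income is None:
            raise ValueError(
                f"member {member.individual_id} of {household.household_id} "
                f"has no income yet"
            )
        total += member.income
    return total


def aggregate_household_income_frame(individuals: pd.DataFrame) -> pd.Series:
    """Per-household income totals from an individuals table."""
    if individuals["income"].isna().any():
        bad = individuals.loc[individuals["income"].isna(), "individual_id"].iloc[0]
        raise ValueError(f"individual {bad!r} has no income yet")
    return individuals.groupby("household_id")["income"].sum()


@dataclass
class OverweightModel:
    """Contingency P(overweight level | gender, age class, SPC) with fallback."""

    contingency: dict[tuple, np.ndarray]
    _by_gender_age: dict[tuple, np.ndarray] = field(init=False, repr=False)
    _marginal: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.contingency:
            raise ValueError("empty overweight contingency")
        clean = {}
        for key, probs in self.contingency.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError(f"cell {key!r} is not a probability vector over 3 levels")
            clean[tuple(key)] = p
        self.contingency = clean
        by_ga: dict[tuple, list[np.ndarray]] = {}
        for (g, a, _s), p in clean.items():
            by_ga.setdefault((g, a), []).append(p)
        self._by_gender_age = {k: np.mean(v, axis=0) for k, v in by_ga.items()}
        self._marginal = np.mean(list(clean.values()), axis=0)

    def probs(self, gender: str, age_class: str, spc: int) -> np.ndarray:
        cell = self.contingency.get((gender, age_class, int(spc)))
        if cell is not None:
            return cell
        cell = self._by_gender_age.get((gender, age_class))
        if cell is not None:
            return cell
        return self._marginal

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "OverweightModel":
        """From delimited text with columns gender, age_class, spc, p0, p1, p2."""
        return cls(
            {
                (r.gender, r.age_class, int(r.spc)): np.array([r.p0, r.p1, r.p2])
                for r in table.itertuples(index=False)
            }
        )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gender": g, "age_class": a, "spc": s, "p0": p[0], "p1": p[1], "p2": p[2]}
                for (g, a, s), p in self.contingency.items()
            ]
        )


def assign_overweight(
    gender: str, age_class: str, spc: int, model: OverweightModel, rng: np.random.Generator
) -> int:
    """Independent draw of the overweight level for one agent's subgroup."""
    return int(rng.choice(3, p=model.probs(gender, age_class, spc)))


def assign_overweight_frame(
    individuals: pd.DataFrame, model: OverweightModel, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized overweight assignment (one independent draw per individual)."""
    keys = list(
        zip(individuals["gender"], individuals["age_class"], individuals["spc"].astype(int))
    )
    probs = np.stack([model.probs(*k) for k in keys])
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(individuals))
    return np.minimum((cum < u[:, None]).sum(axis=1), 2).astype(int)
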