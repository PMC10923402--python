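"""Stage 1 — microdata preparation and estimation of the conditional tree.

Covers cleaning (whole-household removal of invalid records), age discretization,
rare-category merging, and estimation of conditional probability tables with a
hierarchical spatial fallback: every conditioning cell is estimated at the finest zone
level whose pooled support reaches ``min_count``, climbing IRIS → commune → department
→ region when data is sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditionals import Cell, ConditionalTable
from .schema import AttributeSchema, SchemaError, age_to_class
from .zones import HierarchyError, ZoneHierarchy

__all__ = [
    "CleaningReport",
    "EstimationError",
    "build_zone_hierarchy",
    "clean_microdata",
    "discretize",
    "merge_rare_categories",
    "estimate_conditional",
    "household_size_distribution",
]

#: default minimum pooled observations per conditioning cell
DEFAULT_MIN_COUNT = 10
#: default relative-frequency floor below which target categories merge into the
#: variable's designated sink category
DEFAULT_MERGE_FLOOR = 0.005


class EstimationError(ValueError):
    """A conditioning cell has insufficient support at every spatial level."""


def build_zone_hierarchy(zone_table: pd.DataFrame) -> ZoneHierarchy:
    """Validate a zone table (zone_id, level, parent_id, population) into a tree."""
    return ZoneHierarchy.from_frame(zone_table)


# ---------------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------------

@dataclass
class CleaningReport:
    """Counts of removed rows per rule.

    ``household_collateral`` counts valid rows dropped because another member of
    their household was invalid: a partial household is not a usable record.
    """

    removed: dict[str, int] = field(default_factory=dict)
    household_collateral: int = 0
    n_input_rows: int = 0
    n_output_rows: int = 0

    def increment(self, rule: str, n: int = 1) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + n

    @property
    def empty(self) -> bool:
        return not self.removed and self.household_collateral == 0


def clean_microdata(
    raw: pd.DataFrame, schema: AttributeSchema
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove rows with missing, unparseable or out-of-schema values.

    Households losing any member are dropped whole.  Returns the cleaned table and a
    report of removals per rule.
    """
    if "household_id" not in raw.columns:
        raise ValueError("microdata table has no household_id column")
    if "zone_id" not in raw.columns:
        raise ValueError("microdata table has no zone_id column")

    report = CleaningReport(n_input_rows=len(raw))
    bad = pd.Series(False, index=raw.index)

    def flag(mask: pd.Series, rule: str) -> None:
        fresh = mask & ~bad
        if fresh.any():
            report.increment(rule, int(fresh.sum()))
            bad[fresh] = True

    flag(raw["household_id"].isna() | raw["zone_id"].isna(), "missing id")

    if "age" in raw.columns:
        age = pd.to_numeric(raw["age"], errors="coerce")
        flag(raw["age"].notna() & age.isna(), "unparseable age")
        flag(age.notna() & ((age < 0) | (age > 120)), "age out of range")

    if "household_size" in raw.columns:
        size = pd.to_numeric(raw["household_size"], errors="coerce")
        flag(raw["household_size"].notna() & size.isna(), "unparseable household size")
        flag(size.notna() & ~size.isin(schema.categories("household_size")), "household size out of range")

    for name in schema.categorical_names():
        if name in ("age_class", "household_size") or name not in raw.columns:
            continue
        col = raw[name]
        flag(col.isna(), f"missing {name}")
        cats = set(schema.categories(name))
        flag(col.notna() & ~col.isin(cats), f"out-of-schema {name}")

    bad_households = set(raw.loc[bad, "household_id"])
    in_bad_hh = raw["household_id"].isin(bad_households)
    report.household_collateral = int((in_bad_hh & ~bad).sum())
    cleaned = raw.loc[~in_bad_hh].copy()
    report.n_output_rows = len(cleaned)
    return cleaned, report


def discretize(table: pd.DataFrame, schema: AttributeSchema) -> pd.DataFrame:
    """Map numeric age to its band and verify every categorical column.

    Band convention: lower bound inclusive, upper bound exclusive, final band
    (65–120) upper-inclusive.  Ages above 120 raise.
    """
    out = table.copy()
    if "age" in out.columns:
        ages = pd.to_numeric(out["age"])
        if (ages < 0).any() or (ages > 120).any():
            offending = ages[(ages < 0) | (ages > 120)].iloc[0]
            raise ValueError(f"age {offending} outside [0, 120]")
        out["age_class"] = [age_to_class(a) for a in ages]
    for name in schema.categorical_names():
        if name == "age_class" or name not in out.columns:
            continue
        cats = set(schema.categories(name))
        invalid = ~out[name].isin(cats)
        if invalid.any():
            raise SchemaError(
                f"column {name!r} contains out-of-schema value "
                f"{out.loc[invalid, name].iloc[0]!r}"
            )
    return out


def merge_rare_categories(
    table: pd.DataFrame,
    schema: AttributeSchema,
    floor: float = DEFAULT_MERGE_FLOOR,
) -> pd.DataFrame:
    """Merge categories with region-level relative frequency below ``floor`` into the
    variable's designated sink category (variables without a sink are left alone)."""
    out = table.copy()
    for name in schema.categorical_names():
        var = schema[name]
        if var.other_category is None or name not in out.columns:
            continue
        freqs = out[name].value_counts(normalize=True)
        rare = [c for c, f in freqs.items() if f < floor and c != var.other_category]
        if rare:
            out[name] = out[name].replace(dict.fromkeys(rare, var.other_category))
    return out


# ---------------------------------------------------------------------------------
# conditional estimation with hierarchical fallback
# ---------------------------------------------------------------------------------

def _empirical_probs(values: pd.Series, categories: tuple) -> tuple[np.ndarray, int]:
    counts = values.value_counts()
    vec = np.array([counts.get(c, 0) for c in categories], dtype=float)
    n = int(vec.sum())
    return vec / n, n


def estimate_conditional(
    table: pd.DataFrame,
    target: str,
    given: tuple[str, ...] | list[str],
    hierarchy: ZoneHierarchy | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    schema: AttributeSchema | None = None,
    merge_floor: float | None = None,
    conditioning_backoff: bool = False,
) -> ConditionalTable:
    """Empirical P(target | given), with spatial fallback where ``given`` contains
    ``zone_id``.

    For each observed conditioning cell, the distribution is estimated at the finest
    zone level whose pooled support reaches ``min_count``; cells record the level
    used.  Non-spatial tables are pooled region-wide (level ``"region"``).  A cell
    that stays below ``min_count`` even at the region raises :class:`EstimationError`
    naming the cell — unless ``conditioning_backoff`` is set, in which case the cell
    borrows the distribution of the coarser table dropping the last conditioning
    variable (recursively), recording level ``"backoff"``.  Rare attribute
    crossings always exist in survey data, and aggregating over the weakest
    conditioner is the non-spatial analogue of climbing the zone tree.
    """
    given = tuple(given)
    if schema is not None:
        schema.validate_presence([target] + [g for g in given if g != "zone_id"])
        if merge_floor is not None:
            table = merge_rare_categories(table, schema, merge_floor)
        categories = tuple(schema.categories(target))
    else:
        categories = tuple(sorted(table[target].dropna().unique().tolist()))
    if min_count < 1:
        raise ValueError("min_count must be at least 1")
    for col in (target, *given):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")

    spatial = "zone_id" in given
    other = tuple(g for g in given if g != "zone_id")
    cells: dict[tuple, Cell] = {}

    if not spatial:
        coarser: ConditionalTable | None = None
        grouped = table.groupby(list(given), observed=True, sort=True) if given else [((), table)]
        for key, grp in grouped:
            key = key if isinstance(key, tuple) else (key,)
            probs, n = _empirical_probs(grp[target], categories)
            if n < min_count:
                if not conditioning_backoff or not given:
                    raise EstimationError(
                        f"cell {dict(zip(given, key))} of P({target}|{','.join(given) or '-'}) "
                        f"has only {n} observations (< {min_count}) with no spatial fallback"
                    )
                if coarser is None:
                    coarser = estimate_conditional(
                        table, target, given[:-1], min_count=min_count,
                        schema=schema, conditioning_backoff=True,
                    )
                parent = coarser.cell(key[:-1])
                cells[key] = Cell(parent.probs, parent.support, "backoff")
                continue
            cells[key] = Cell(probs, n, "region")
        return ConditionalTable(target, given, categories, cells)

    if hierarchy is None:
        raise ValueError("spatial conditioning requires a zone hierarchy")

    zone_pos = given.index("zone_id")
    # pre-index rows by the non-spatial part of the conditioning, then by zone
    for zone in sorted(table["zone_id"].astype(str).unique()):
        if zone not in hierarchy:
            raise HierarchyError(f"microdata references unknown zone {zone!r}")

    ancestor_of = {
        z: {hierarchy.level(a): a for a in hierarchy.ancestors(z)}
        for z in table["zone_id"].astype(str).unique()
    }
    work = table.copy()
    work["zone_id"] = work["zone_id"].astype(str)

    obs_zones = sorted(work["zone_id"].unique())
    other_groups = (
        work.groupby(list(other), observed=True, sort=True) if other else [((), work)]
    )
    for okey, grp in other_groups:
        okey = okey if isinstance(okey, tuple) else (okey,)
        zone_col = grp["zone_id"]
        for zone in obs_zones:
            # climb fine -> coarse until support suffices
            chosen = None
            for anc in hierarchy.ancestors(zone):
                pool = grp.loc[zone_col.isin(hierarchy.subtree(anc)), target]
                if len(pool) >= min_count:
                    probs, n = _empirical_probs(pool, categories)
                    chosen = Cell(probs, n, hierarchy.level(anc))
                    break
            if chosen is None:
                full_key = okey[:zone_pos] + (zone,) + okey[zone_pos:]
                raise EstimationError(
                    f"cell {dict(zip(given, full_key))} of P({target}|{','.join(given)}) "
                    f"has insufficient support at every level up to the region"
                )
            full_key = okey[:zone_pos] + (zone,) + okey[zone_pos:]
            cells[full_key] = chosen
    return ConditionalTable(target, given, categories, cells)


def household_size_distribution(
    table: pd.DataFrame,
    zone: str,
    hierarchy: ZoneHierarchy,
    min_count: int = DEFAULT_MIN_COUNT,
) -> np.ndarray:
    """Probability vector over household sizes 1..6 for one zone, with the same
    hierarchical fallback as :func:`estimate_conditional`."""
    if zone not in hierarchy:
        raise HierarchyError(f"unknown zone {zone!r}")
    households = table.drop_duplicates("household_id")[["zone_id", "household_size"]]
    households = households.assign(zone_id=households["zone_id"].astype(str))
    sizes = (1, 2, 3, 4, 5, 6)
    for anc in hierarchy.ancestors(zone):
        members = hierarchy.subtree(anc)
        pool = households.loc[households["zone_id"].isin(members), "household_size"]
        if len(pool) >= min_count:
            probs, _ = _empirical_probs(pool.astype(int), sizes)
            return probs
    raise EstimationError(
        f"household size distribution for zone {zone!r} has insufficient support "
        f"at every level up to the region"
    )
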