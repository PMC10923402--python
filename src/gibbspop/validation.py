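"""Endogenous validation: train/test splitting and marginal / multi-attribute joint
comparison via SRMSE, R², RMSE and MAE, at regional and per-zone scales.

SRMSE between an observed cell-probability vector p and a simulated vector p-hat over
m cells is

    SRMSE = sqrt( sum_i (p-hat_i - p_i)^2 / m ) / ( sum_i p_i / m )

so 0 means a perfect match and the statistic grows with the divergence.  Joint
distributions are taken over the full Cartesian category grid of the chosen
attributes (absent combinations are zero cells, which penalize spurious synthetic
mass), with individual-level weighting: household attributes count once per member.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import AttributeSchema, SchemaError, default_schema

__all__ = [
    "split_train_test",
    "srmse",
    "FitMetrics",
    "fit_metrics",
    "JointDistribution",
    "joint_distribution",
    "srmse_between",
    "per_zone_comparison",
    "MetricsReport",
]


def split_train_test(
    microdata: pd.DataFrame,
    frac_train: float,
    seed: int,
    stratify_by: str = "zone_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Household-level split: a household's members never straddle the two sides.

    Stratified by ``stratify_by`` (zone by default) so every zone contributes to
    both sides; disjoint and exhaustive by construction.
    """
    if not 0 < frac_train < 1:
        raise ValueError(f"frac_train {frac_train} outside (0, 1)")
    if "household_id" not in microdata.columns:
        raise ValueError("microdata table has no household_id column")
    train_ids: list = []
    strata = (
        microdata.groupby(stratify_by, sort=True)
        if stratify_by in microdata.columns
        else [("", microdata)]
    )
    for name, grp in strata:
        hh = grp["household_id"].unique()
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(str(name).encode())])
        )
        hh = hh[rng.permutation(len(hh))]
        n_train = int(round(frac_train * len(hh)))
        train_ids.extend(hh[:n_train])
    mask = microdata["household_id"].isin(set(train_ids))
    return microdata[mask].copy(), microdata[~mask].copy()


def srmse(observed: np.ndarray, simulated: np.ndarray) -> float:
    """Standardized root mean square error between two cell-probability vectors."""
    p = np.asarray(observed, dtype=float)
    q = np.asarray(simulated, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"cell sets differ: {p.shape} vs {q.shape}")
    if p.sum() <= 0:
        raise ValueError("observed distribution is all zero; SRMSE undefined")
    m = p.size
    return float(np.sqrt(np.sum((q - p) ** 2) / m) / (p.sum() / m))


@dataclass
class FitMetrics:
    r2: float | None
    rmse: float
    mae: float
    note: str = ""


def fit_metrics(observed, simulated) -> FitMetrics:
    """R² (squared Pearson correlation), RMSE and MAE over paired vectors.

    Zero variance on either side leaves R² undefined (reported as such, not as an
    exception: the other two metrics remain informative).
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(simulated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if x.size < 2:
        raise ValueError("at least two pairs required")
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    mae = float(np.mean(np.abs(y - x)))
    if np.std(x) == 0 or np.std(y) == 0:
        return FitMetrics(None, rmse, mae, note="R2 undefined: zero variance")
    r, _ = stats.pearsonr(x, y)
    return FitMetrics(float(r**2), rmse, mae)


@dataclass
class JointDistribution:
    """Probability vector over the full cross-classification of some attributes."""

    attributes: tuple[str, ...]
    categories: tuple[tuple, ...]
    probs: np.ndarray  # dense, length prod(len(c) for c in categories)

    @property
    def m(self) -> int:
        return int(self.probs.size)


def joint_distribution(
    population: pd.DataFrame,
    attributes: list[str] | tuple[str, ...],
    schema: AttributeSchema | None = None,
) -> JointDistribution:
    """Normalized cell frequencies over the full Cartesian grid, zero-filled.

    ``population`` must carry one row per individual with household attributes
    broadcast (see ``Population.merged``).  Up to 9 attributes are supported; the
    grid stays dense but modest (< 3e5 cells for the default schema).
    """
    schema = schema or default_schema()
    attributes = tuple(attributes)
    if not 1 <= len(attributes) <= 9:
        raise ValueError("between 1 and 9 attributes required")
    cats = []
    for a in attributes:
        if a not in schema or not schema[a].categories:
            raise SchemaError(f"attribute {a!r} is not a categorical schema variable")
        if a not in population.columns:
            raise SchemaError(f"population table has no column {a!r}")
        cats.append(tuple(schema.categories(a)))
    codes = []
    for a, c in zip(attributes, cats):
        col = pd.Categorical(population[a], categories=list(c))
        if (col.codes < 0).any():
            bad = population[a][col.codes < 0].iloc[0]
            raise SchemaError(f"value {bad!r} of {a!r} outside the schema categories")
        codes.append(col.codes.astype(np.int64))
    dims = tuple(len(c) for c in cats)
    flat = np.ravel_multi_index(codes, dims)
    m = int(np.prod(dims))
    counts = np.bincount(flat, minlength=m).astype(float)
    return JointDistribution(attributes, tuple(cats), counts / counts.sum())


def srmse_between(
    observed_pop: pd.DataFrame,
    simulated_pop: pd.DataFrame,
    attributes: list[str] | tuple[str, ...],
    schema: AttributeSchema | None = None,
) -> float:
    """SRMSE between the joint distributions of two populations."""
    obs = joint_distribution(observed_pop, attributes, schema)
    sim = joint_distribution(simulated_pop, attributes, schema)
    return srmse(obs.probs, sim.probs)


@dataclass
class PerZoneComparison:
    table: pd.DataFrame  # zone_id, category, observed_pct, simulated_pct
    pooled: FitMetrics
    per_category: dict
    excluded_zones: list[str]
    low_variance_categories: list


def per_zone_comparison(
    test_data: pd.DataFrame,
    synthetic_pop: pd.DataFrame,
    attribute: str,
    schema: AttributeSchema | None = None,
    zone_col: str = "zone_id",
    low_variance_pct: float = 1.0,
) -> PerZoneComparison:
    """Paired per-zone occurrence percentages of each category of one attribute.

    Zones present in only one dataset are excluded (and reported).  Categories
    whose observed percentages vary by less than ``low_variance_pct`` (standard
    deviation, percentage points) across zones are flagged: fit metrics are not
    informative on a near-constant rate.
    """
    schema = schema or default_schema()
    cats = schema.categories(attribute)
    zones_obs = set(test_data[zone_col])
    zones_sim = set(synthetic_pop[zone_col])
    common = sorted(zones_obs & zones_sim)
    excluded = sorted((zones_obs | zones_sim) - set(common))

    def pct(df: pd.DataFrame) -> pd.DataFrame:
        tab = (
            df.groupby([zone_col, attribute], observed=False)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(cats), fill_value=0)
            .reindex(index=common, fill_value=0)
        )
        return tab.div(tab.sum(axis=1), axis=0) * 100.0

    obs = pct(test_data)
    sim = pct(synthetic_pop)
    records = []
    for z in common:
        for c in cats:
            records.append(
                {
                    "zone_id": z,
                    "category": c,
                    "observed_pct": obs.loc[z, c],
                    "simulated_pct": sim.loc[z, c],
                }
            )
    table = pd.DataFrame(records)
    pooled = fit_metrics(table["observed_pct"], table["simulated_pct"])
    per_category = {
        c: fit_metrics(obs[c].to_numpy(), sim[c].to_numpy()) for c in cats
    }
    low_var = [c for c in cats if float(np.std(obs[c])) < low_variance_pct]
    return PerZoneComparison(table, pooled, per_category, excluded, low_var)


@dataclass
class MetricsReport:
    """Rows of (variables, scale) -> SRMSE / R² / RMSE / MAE."""

    rows: list[dict] = field(default_factory=list)

    def add(
        self,
        variables,
        scale: str,
        srmse_value: float | None = None,
        fit: FitMetrics | None = None,
        cells: int | None = None,
        support: int | None = None,
    ) -> None:
        self.rows.append(
            {
                "variables": "+".join(variables) if not isinstance(variables, str) else variables,
                "scale": scale,
                "srmse": srmse_value,
                "r2": fit.r2 if fit else None,
                "rmse": fit.rmse if fit else None,
                "mae": fit.mae if fit else None,
                "cells": cells,
                "support": support,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.rows, indent=1, default=float))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)
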