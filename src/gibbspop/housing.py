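"""Stage 4.1 — housing stock: classify buildings, derive dwelling counts from
geometry, and price-class each building.

Dwelling counts for blocks come from the ratio of total floor surface (footprint x
floors, one floor per 3 m of height) to the average dwelling size of the building's
urban ring: 59 m² in the center, 69 m² in the inner ring, 89 m² in the outer ring.
Price classes are per-commune tertiles of price per m² (department tertiles when a
commune has fewer than three priced buildings).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .zones import ZoneHierarchy

__all__ = [
    "AVG_DWELLING_SIZES",
    "STOREY_HEIGHT",
    "classify_building",
    "classify_buildings",
    "count_dwellings",
    "count_dwellings_frame",
    "assign_price_class",
    "build_dwellings",
    "write_buildings_geojson",
]

#: average dwelling size (m²) per urban ring
AVG_DWELLING_SIZES = {"center": 59.0, "inner": 69.0, "outer": 89.0}
#: storey height (m) for the floors-from-height conversion
STOREY_HEIGHT = 3.0
#: house / block classification thresholds
HOUSE_MAX_FLOORS = 2
HOUSE_MAX_FOOTPRINT = 250.0

PRICE_CLASSES = ("low", "intermediate", "high")


def _floors(height: float, storey_height: float = STOREY_HEIGHT) -> int:
    return max(1, int(math.floor(height / storey_height)))


def classify_building(
    footprint_area: float,
    height: float,
    land_use: str,
    storey_height: float = STOREY_HEIGHT,
) -> str | None:
    """``"house"`` | ``"block"`` for residential buildings, ``None`` (excluded)
    otherwise.  A house is residential with at most 2 floors and under 250 m² of
    footprint."""
    if footprint_area <= 0 or height <= 0:
        raise ValueError("footprint area and height must be positive")
    if land_use != "residential":
        return None
    if _floors(height, storey_height) <= HOUSE_MAX_FLOORS and footprint_area < HOUSE_MAX_FOOTPRINT:
        return "house"
    return "block"


def classify_buildings(
    buildings: pd.DataFrame, storey_height: float = STOREY_HEIGHT
) -> tuple[pd.DataFrame, int]:
    """Residential subset with ``kind`` and ``floors`` columns, plus the number of
    non-residential buildings excluded from the housing stock."""
    if (buildings["footprint_area"] <= 0).any() or (buildings["height"] <= 0).any():
        raise ValueError("buildings with nonpositive footprint or height")
    res = buildings[buildings["land_use"] == "residential"].copy()
    excluded = len(buildings) - len(res)
    res["floors"] = np.maximum(1, np.floor(res["height"] / storey_height)).astype(int)
    res["kind"] = np.where(
        (res["floors"] <= HOUSE_MAX_FLOORS) & (res["footprint_area"] < HOUSE_MAX_FOOTPRINT),
        "house",
        "block",
    )
    return res, excluded


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def count_dwellings(
    footprint_area: float,
    height: float,
    kind: str,
    zone_class: str,
    recorded: float | None = None,
    avg_sizes: dict[str, float] | None = None,
    storey_height: float = STOREY_HEIGHT,
) -> int:
    """Dwelling count of one building: recorded count if present, 1 for houses,
    else total floor surface over the ring's average dwelling size."""
    if recorded is not None and not (isinstance(recorded, float) and math.isnan(recorded)):
        return int(recorded)
    if kind == "house":
        return 1
    if footprint_area <= 0 or height <= 0:
        raise ValueError("footprint area and height must be positive")
    avg = (avg_sizes or AVG_DWELLING_SIZES)[zone_class]
    total_surface = footprint_area * _floors(height, storey_height)
    return max(1, _round_half_up(total_surface / avg))


def count_dwellings_frame(
    residential: pd.DataFrame,
    avg_sizes: dict[str, float] | None = None,
    storey_height: float = STOREY_HEIGHT,
) -> pd.DataFrame:
    """Vectorized dwelling counting; keeps recorded counts, houses get one."""
    avg_sizes = avg_sizes or AVG_DWELLING_SIZES
    out = residential.copy()
    floors = np.maximum(1, np.floor(out["height"] / storey_height))
    avg = out["zone_class"].map(avg_sizes)
    derived = np.maximum(
        1, np.floor(out["footprint_area"] * floors / avg + 0.5)
    ).astype(int)
    derived = np.where(out["kind"] == "house", 1, derived)
    recorded = out["n_dwellings"] if "n_dwellings" in out else pd.Series(np.nan, index=out.index)
    out["n_dwellings"] = np.where(recorded.notna(), recorded, derived).astype(int)
    return out


def _tertile_classes(prices: np.ndarray) -> np.ndarray:
    """low/intermediate/high by tertile; boundary values go to the lower class;
    all-equal prices collapse to intermediate."""
    if prices.min() == prices.max():
        return np.full(len(prices), "intermediate", dtype=object)
    q1, q2 = np.quantile(prices, [1 / 3, 2 / 3])
    return np.where(prices <= q1, "low", np.where(prices <= q2, "intermediate", "high"))


def assign_price_class(
    buildings: pd.DataFrame,
    hierarchy: ZoneHierarchy,
    price_col: str = "price_per_m2",
) -> pd.DataFrame:
    """Per-commune price tertiles over ``price_col``; communes with fewer than three
    priced buildings fall back to department tertiles."""
    out = buildings.copy()
    if price_col not in out.columns:
        raise ValueError(f"buildings table has no {price_col!r} column")
    if out[price_col].isna().any():
        raise ValueError("buildings with missing price per m2")

    def commune_of(zone: str) -> str:
        level = hierarchy.level(zone)
        if level == "commune":
            return zone
        return hierarchy.commune_of(zone)

    communes = out["zone_id"].map(commune_of)
    out["price_class"] = ""
    for commune in communes.unique():
        mask = (communes == commune).to_numpy()
        if mask.sum() >= 3:
            out.loc[mask, "price_class"] = _tertile_classes(
                out.loc[mask, price_col].to_numpy()
            )
        else:
            dept = next(
                z for z in hierarchy.ancestors(commune) if hierarchy.level(z) == "department"
            )
            dept_communes = set(hierarchy.descendants_at(dept, "commune"))
            dmask = communes.isin(dept_communes).to_numpy()
            classes = _tertile_classes(out.loc[dmask, price_col].to_numpy())
            out.loc[mask, "price_class"] = classes[mask[dmask]]
    return out


def build_dwellings(buildings: pd.DataFrame) -> pd.DataFrame:
    """Expand priced, counted buildings into one row per dwelling."""
    for col in ("n_dwellings", "price_class"):
        if col not in buildings.columns:
            raise ValueError(f"buildings table lacks {col!r}; run counting/pricing first")
    counts = buildings["n_dwellings"].astype(int).to_numpy()
    idx = np.repeat(np.arange(len(buildings)), counts)
    rank = np.concatenate([np.arange(c) for c in counts]) if len(counts) else np.array([], int)
    base = buildings.iloc[idx]
    return pd.DataFrame(
        {
            "dwelling_id": [
                f"{b}-D{r:03d}" for b, r in zip(base["building_id"], rank)
            ],
            "building_id": base["building_id"].to_numpy(),
            "zone_id": base["zone_id"].to_numpy(),
            "price_class": base["price_class"].to_numpy(),
        }
    )


def write_buildings_geojson(
    buildings: pd.DataFrame, path: str | Path, spacing: float = 100.0
) -> None:
    """Plain GeoJSON export: each building a square of its footprint area laid out
    on a synthetic grid (the fixtures carry no real coordinates)."""
    features = []
    side_grid = max(1, int(math.ceil(math.sqrt(len(buildings)))))
    for i, row in enumerate(buildings.itertuples(index=False)):
        side = math.sqrt(row.footprint_area)
        x0 = (i % side_grid) * spacing
        y0 = (i // side_grid) * spacing
        ring = [
            [x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side], [x0, y0]
        ]
        props = {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in row._asdict().items()
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
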