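"""Stage 4.2 — allocate households to dwellings within their zone.

Households are stratified into per-zone income tertiles (low / intermediate / high)
and matched to dwelling price classes: the high stratum is placed first, then
intermediate, then low; each household draws uniformly at random among the free
dwellings of its matching class, spilling to the nearest class when the stock is
exhausted.  In the balanced case (per-class supply equals per-stratum demand) every
household lands in its own class, whatever the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .generation import zone_rng

__all__ = ["CapacityError", "stratify_household_income", "allocate_households"]

STRATA = ("low", "intermediate", "high")
#: class preference order on saturation
NEAREST = {
    "high": ("high", "intermediate", "low"),
    "intermediate": ("intermediate", "high", "low"),
    "low": ("low", "intermediate", "high"),
}


class CapacityError(ValueError):
    """A zone has more households than dwellings."""


def stratify_household_income(households: pd.DataFrame) -> pd.Series:
    """Per-zone income tertile of each household (boundaries to the lower stratum;
    all-equal incomes collapse to intermediate)."""
    if households["income"].isna().any():
        raise ValueError("households with unset income cannot be stratified")
    out = pd.Series("", index=households.index, dtype=object, name="stratum")
    for _zone, grp in households.groupby("zone_id"):
        incomes = grp["income"].to_numpy(dtype=float)
        if incomes.min() == incomes.max():
            out.loc[grp.index] = "intermediate"
            continue
        q1, q2 = np.quantile(incomes, [1 / 3, 2 / 3])
        out.loc[grp.index] = np.where(
            incomes <= q1, "low", np.where(incomes <= q2, "intermediate", "high")
        )
    return out


def allocate_households(
    households: pd.DataFrame,
    dwellings: pd.DataFrame,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Assignment table (household_id, dwelling_id, building_id, zone_id).

    Requires a ``stratum`` column on households (see
    :func:`stratify_household_income`).  Processing order within a stratum is
    shuffled by the zone substream, so results are reproducible from the master
    seed and independent of zone processing order.
    """
    if "stratum" not in households.columns:
        raise ValueError("households need a stratum column; stratify first")
    short = []
    for zone, grp in households.groupby("zone_id"):
        n_dw = int((dwellings["zone_id"] == zone).sum())
        if n_dw < len(grp):
            short.append(f"{zone} ({len(grp)} households, {n_dw} dwellings)")
    if short:
        raise CapacityError("insufficient dwellings in: " + "; ".join(short))

    rows = []
    for zone, grp in households.groupby("zone_id"):
        rng = zone_rng(master_seed, f"alloc:{zone}")
        dz = dwellings[dwellings["zone_id"] == zone]
        free: dict[str, list[int]] = {
            c: list(np.flatnonzero((dz["price_class"] == c).to_numpy())) for c in STRATA
        }
        dz_ids = dz["dwelling_id"].to_numpy()
        dz_buildings = dz["building_id"].to_numpy()
        for stratum in ("high", "intermediate", "low"):
            sub = grp[grp["stratum"] == stratum]
            order = sub.index.to_numpy()[rng.permutation(len(sub))]
            for hh_idx in order:
                pick = None
                for cls in NEAREST[stratum]:
                    if free[cls]:
                        pool = free[cls]
                        j = int(rng.integers(len(pool)))
                        pool[j], pool[-1] = pool[-1], pool[j]
                        pick = pool.pop()
                        break
                assert pick is not None  # guarded by the capacity check
                rows.append(
                    {
                        "household_id": households.loc[hh_idx, "household_id"],
                        "dwelling_id": dz_ids[pick],
                        "building_id": dz_buildings[pick],
                        "zone_id": zone,
                        "stratum": stratum,
                        "price_class": dz["price_class"].to_numpy()[pick],
                    }
                )
    return pd.DataFrame(rows)
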