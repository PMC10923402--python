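"""Synthetic input fixtures with known ground-truth probabilistic structure.

Real applications of this generator ingest census microdata, a zone hierarchy, a
building database, income medians and a health contingency table.  None of those can
ship with the package, so this module emulates all five inputs from an explicit
:class:`GroundTruthModel`: a fully specified conditional tree whose cells are random
but valid distributions.  Because the census emulator draws households *exactly* from
that tree (ancestral sampling, honoring the structural rules), every downstream stage
can be tested for parameter recovery against known truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .attributes import IncomeModel, OverweightModel, assign_income_frame, assign_overweight_frame
from .conditionals import Cell, ConditionalTable
from .generation import GenerationConfig, CompiledModel, _generate_households, zone_rng
from .schema import (
    ACTIVITIES,
    AGE_CLASSES,
    AttributeSchema,
    EDUCATION_LEVELS,
    GENDERS,
    HOUSEHOLD_TYPES,
    INCOME_CLASSES,
    SPC_CATEGORIES,
    SPC_INACTIVE,
    SPC_RETIRED,
    SchemaError,
    default_schema,
)
from .zones import ZoneHierarchy, ZoneNode

__all__ = [
    "GroundTruthModel",
    "generate_ground_truth_model",
    "simulate_census_sample",
    "simulate_buildings",
    "default_zone_hierarchy",
    "DEFAULT_COMMUNE_CLASSES",
]

#: commune -> urban ring used for dwelling sizing and building prices
DEFAULT_COMMUNE_CLASSES = {"C1": "center", "C2": "inner", "C3": "outer", "C4": "outer"}

#: per-SPC median annual income (EUR/year) of the fixture region
DEFAULT_SPC_MEDIANS = {
    1: 18000.0, 2: 24000.0, 3: 42000.0, 4: 27600.0,
    5: 19800.0, 6: 17400.0, 7: 19200.0, 8: 10800.0,
}
#: per-commune median annual income (EUR/year)
DEFAULT_COMMUNE_MEDIANS = {"C1": 26000.0, "C2": 22000.0, "C3": 19500.0, "C4": 18000.0}
#: regional population median annual income (EUR/year)
DEFAULT_POPULATION_MEDIAN = 21000.0


def default_zone_hierarchy(total_population: int = 30000) -> ZoneHierarchy:
    """4-level fixture tree: 1 region, 2 departments, 4 communes, 8 IRIS.

    IRIS population counts split the regional total with fixed unequal weights so
    zonal heterogeneity is exercised.
    """
    weights = [0.06, 0.08, 0.10, 0.12, 0.13, 0.14, 0.17, 0.20]
    iris_pops = [int(round(total_population * w)) for w in weights]
    iris_pops[-1] += total_population - sum(iris_pops)
    nodes: dict[str, ZoneNode] = {}
    nodes["R"] = ZoneNode("R", "region", None, total_population)
    for d, communes in (("D1", ("C1", "C2")), ("D2", ("C3", "C4"))):
        nodes[d] = ZoneNode(d, "department", "R", 0)
        for c in communes:
            nodes[c] = ZoneNode(c, "commune", d, 0)
    iris_ids = [f"I{i}" for i in range(1, 9)]
    for i, iris in enumerate(iris_ids):
        commune = ("C1", "C1", "C2", "C2", "C3", "C3", "C4", "C4")[i]
        nodes[iris] = ZoneNode(iris, "iris", commune, iris_pops[i])
    # roll populations up
    for level in ("commune", "department"):
        for z, n in list(nodes.items()):
            if n.level == level:
                pop = sum(
                    m.population for m in nodes.values() if m.parent_id == z
                )
                nodes[z] = ZoneNode(z, level, n.parent_id, pop)
    return ZoneHierarchy(nodes)


@dataclass
class GroundTruthModel:
    """Fully specified generative model of the fixture population."""

    schema: AttributeSchema
    cpts: dict[tuple[str, tuple[str, ...]], ConditionalTable]
    size_dist_by_zone: dict[str, np.ndarray]
    spc_income_medians: dict[int, float]
    zone_medians: dict[str, float]
    population_median_income: float
    seed: int

    def income_model(self, dispersion_sigma: float = 0.25) -> IncomeModel:
        return IncomeModel(
            commune_medians=dict(self.zone_medians),
            spc_medians=dict(self.spc_income_medians),
            population_median=self.population_median_income,
            dispersion_sigma=dispersion_sigma,
        )

    def overweight_model(self) -> OverweightModel:
        table = self.cpts[("overweight", ("gender", "age_class", "spc"))]
        return OverweightModel(
            {key: cell.probs for key, cell in table.cells.items()}
        )

    def compiled(self) -> CompiledModel:
        # overweight is assigned downstream, not Gibbs-sampled
        tree = {k: t for k, t in self.cpts.items() if k[0] != "overweight"}
        return CompiledModel(tree, self.schema)

    # -- serialization (oracle tests) --------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "seed": self.seed,
                "population_median_income": self.population_median_income,
                "spc_income_medians": {str(k): v for k, v in self.spc_income_medians.items()},
                "zone_medians": self.zone_medians,
                "size_dist_by_zone": {
                    z: [float(x) for x in p] for z, p in self.size_dist_by_zone.items()
                },
                "cpts": [t.to_dict() for t in self.cpts.values()],
            },
            indent=1,
        ))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthModel":
        d = json.loads(Path(path).read_text())
        cpts = {}
        for td in d["cpts"]:
            t = ConditionalTable.from_dict(td)
            # JSON round-trips tuple-typed category values as lists
            cpts[t.key] = t
        return cls(
            schema=default_schema(),
            cpts=cpts,
            size_dist_by_zone={z: np.array(p) for z, p in d["size_dist_by_zone"].items()},
            spc_income_medians={int(k): v for k, v in d["spc_income_medians"].items()},
            zone_medians=d["zone_medians"],
            population_median_income=d["population_median_income"],
            seed=d["seed"],
        )


def _mixed_dirichlet(rng: np.random.Generator, k: int, floor: float = 0.2) -> np.ndarray:
    """Dirichlet draw mixed with uniform so no cell is vanishingly small: keeps every
    generated combination estimable from moderate samples."""
    p = rng.dirichlet(np.full(k, 1.5))
    return (1 - floor) * p + floor / k


def _sub_probs(rng, categories: tuple, support: tuple, floor: float = 0.2) -> np.ndarray:
    """Random distribution over ``categories`` whose mass lives on ``support``."""
    p = np.zeros(len(categories))
    idx = [categories.index(c) for c in support]
    p[idx] = _mixed_dirichlet(rng, len(idx), floor)
    return p


def generate_ground_truth_model(
    seed: int, schema: AttributeSchema | None = None
) -> GroundTruthModel:
    """Random but structurally valid conditional tree, deterministic given the seed.

    Structural zeros are baked in so that the tree and the hard rules agree: heads
    and spouses of multi-person households live in the 35+ bands (so the mother-child
    gap never truncates a whole age class), under-15s are schoolchildren with
    inactive SPC, retirees carry the retired SPC.
    """
    schema = schema or default_schema()
    for name in (
        "household_type", "household_size", "age_class", "gender", "spc",
        "education", "role", "main_activity", "overweight", "income_class",
        "car_ownership",
    ):
        if name not in schema:
            raise SchemaError(f"schema is missing required variable {name!r}")

    def stream(tag: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
        )

    cpts: dict[tuple[str, tuple[str, ...]], ConditionalTable] = {}

    def add(target: str, given: tuple[str, ...], cells: dict) -> None:
        table = ConditionalTable(
            target, given, tuple(schema.categories(target)),
            {k: Cell(v) for k, v in cells.items()},
        )
        cpts[table.key] = table

    rng = stream("household_type")
    add("household_type", ("household_size",), {
        (1,): _sub_probs(rng, HOUSEHOLD_TYPES, ("Single",)),
        (2,): _sub_probs(rng, HOUSEHOLD_TYPES, ("single parent", "couple")),
        **{
            (s,): _sub_probs(rng, HOUSEHOLD_TYPES, ("single parent", "family"))
            for s in (3, 4, 5, 6)
        },
    })

    rng = stream("income_class")
    add("income_class", ("household_type",), {
        (t,): _mixed_dirichlet(rng, len(INCOME_CLASSES)) for t in HOUSEHOLD_TYPES
    })

    rng = stream("car_ownership")
    add("car_ownership", ("household_type", "income_class"), {
        (t, ic): _mixed_dirichlet(rng, 2)
        for t in HOUSEHOLD_TYPES
        for ic in INCOME_CLASSES
    })

    rng = stream("gender")
    gender_cells = {}
    for t in HOUSEHOLD_TYPES:
        head = _mixed_dirichlet(rng, 2)
        gender_cells[("head", t)] = head
        gender_cells[("spouse", t)] = head[::-1].copy()  # structural complement
        gender_cells[("child", t)] = _mixed_dirichlet(rng, 2)
    add("gender", ("role", "household_type"), gender_cells)

    rng = stream("age_class")
    age_cells = {}
    adult, senior_adult, young = ("35-65", "65-120"), ("35-65", "65-120"), ("0-15", "15-35")
    for t in HOUSEHOLD_TYPES:
        if t == "Single":
            age_cells[(t, "head")] = _sub_probs(rng, AGE_CLASSES, ("15-35", "35-65", "65-120"))
        else:
            age_cells[(t, "head")] = _sub_probs(rng, AGE_CLASSES, adult)
        age_cells[(t, "spouse")] = _sub_probs(rng, AGE_CLASSES, senior_adult)
        age_cells[(t, "child")] = _sub_probs(rng, AGE_CLASSES, young)
    add("age_class", ("household_type", "role"), age_cells)

    rng = stream("main_activity")
    act_cells = {
        ("0-15",): _sub_probs(rng, ACTIVITIES, ("student",)),
        ("15-35",): _sub_probs(
            rng, ACTIVITIES, ("Employed", "unemployed", "student", "other unemployed")
        ),
        ("35-65",): _sub_probs(rng, ACTIVITIES, ("Employed", "unemployed", "other unemployed")),
    }
    # retirement dominates after 65 but is not exclusive
    p = np.zeros(len(ACTIVITIES))
    mix = _mixed_dirichlet(rng, 3, floor=0.25)
    p[ACTIVITIES.index("retired")] = 0.70 + 0.10 * mix[0]
    p[ACTIVITIES.index("Employed")] = (1 - p[ACTIVITIES.index("retired")]) * mix[1] / (mix[1] + mix[2])
    p[ACTIVITIES.index("other unemployed")] = 1 - p.sum() + p[ACTIVITIES.index("other unemployed")]
    act_cells[("65-120",)] = p / p.sum()
    add("main_activity", ("age_class",), act_cells)

    rng = stream("spc")
    working_spc = tuple(s for s in SPC_CATEGORIES if s not in (SPC_RETIRED, SPC_INACTIVE))
    spc_cells = {}
    for a in AGE_CLASSES:
        for act in ACTIVITIES:
            if act == "retired":
                spc_cells[(a, act)] = _sub_probs(rng, SPC_CATEGORIES, (SPC_RETIRED,))
            elif act in ("student", "other unemployed"):
                spc_cells[(a, act)] = _sub_probs(rng, SPC_CATEGORIES, (SPC_INACTIVE,))
            else:
                spc_cells[(a, act)] = _sub_probs(rng, SPC_CATEGORIES, working_spc)
    add("spc", ("age_class", "main_activity"), spc_cells)

    rng = stream("education")
    edu_cells = {}
    for a in AGE_CLASSES:
        for s in SPC_CATEGORIES:
            if a == "0-15":
                edu_cells[(a, s)] = _sub_probs(rng, EDUCATION_LEVELS, ("none", "primary"))
            else:
                edu_cells[(a, s)] = _mixed_dirichlet(rng, len(EDUCATION_LEVELS))
    add("education", ("age_class", "spc"), edu_cells)

    rng = stream("overweight")
    ow_cells = {}
    for g in GENDERS:
        for a in AGE_CLASSES:
            for s in SPC_CATEGORIES:
                prior = (8.0, 1.5, 0.5) if a == "0-15" else (5.0, 3.0, 1.0)
                p = rng.dirichlet(prior)
                ow_cells[(g, a, s)] = 0.9 * p + 0.1 / 3
    add("overweight", ("gender", "age_class", "spc"), ow_cells)

    rng = stream("household_size")
    size_dist_by_zone = {
        f"I{i}": _mixed_dirichlet(rng, 6, floor=0.18) for i in range(1, 9)
    }

    return GroundTruthModel(
        schema=schema,
        cpts=cpts,
        size_dist_by_zone=size_dist_by_zone,
        spc_income_medians=dict(DEFAULT_SPC_MEDIANS),
        zone_medians=dict(DEFAULT_COMMUNE_MEDIANS),
        population_median_income=DEFAULT_POPULATION_MEDIAN,
        seed=int(seed),
    )


def simulate_census_sample(
    model: GroundTruthModel,
    n_households: int,
    zones: list[str],
    seed: int,
    hierarchy: ZoneHierarchy | None = None,
    config: GenerationConfig | None = None,
    dispersion_sigma: float = 0.25,
) -> pd.DataFrame:
    """Individual-level census-like microdata drawn exactly from the model.

    Households are split across zones (largest-remainder proportional to zone
    population when a hierarchy is given, equal shares otherwise), sizes drawn iid
    from each zone's size distribution, members drawn ancestrally from the tree
    under the structural rules, and income / overweight attached from the model's
    income medians and health contingency.  Household attributes are broadcast onto
    member rows.
    """
    if n_households < 1:
        raise ValueError("n_households must be at least 1")
    if not zones:
        raise ValueError("zone list is empty")
    config = config or GenerationConfig()
    compiled = model.compiled()

    if hierarchy is not None:
        weights = np.array([hierarchy.population(z) for z in zones], dtype=float)
        weights = weights / weights.sum()
    else:
        weights = np.full(len(zones), 1.0 / len(zones))
    share = np.floor(weights * n_households).astype(int)
    remainder = n_households - share.sum()
    order = np.argsort(-(weights * n_households - share))
    share[order[:remainder]] += 1

    parts = []
    for zone, n_z in zip(zones, share):
        if n_z == 0:
            continue
        rng = zone_rng(seed, f"census:{zone}")
        size_probs = model.size_dist_by_zone.get(zone)
        if size_probs is None:
            raise KeyError(f"model has no household size distribution for zone {zone!r}")
        sizes = rng.choice(np.arange(1, 7), size=n_z, p=size_probs)
        pop = _generate_households(zone, sizes, compiled, config, rng, ancestral=True)
        parts.append(pop)

    from .generation import Population

    pop = Population.concat(parts)
    income_model = model.income_model(dispersion_sigma)
    commune_of = (
        {z: hierarchy.commune_of(z) for z in zones}
        if hierarchy is not None
        else {z: z for z in zones}
    )
    if hierarchy is None:
        # without a hierarchy, zones index the commune medians directly or fall back
        # to the regional median
        commune_of = {z: z if z in model.zone_medians else "__region__" for z in zones}
        income_model.commune_medians["__region__"] = model.population_median_income
    rng = zone_rng(seed, "census:attributes")
    pop.individuals["income"] = assign_income_frame(
        pop.individuals, commune_of, income_model, rng
    )
    pop.individuals["overweight"] = assign_overweight_frame(
        pop.individuals, model.overweight_model(), rng
    )
    hh_income = pop.individuals.groupby("household_id")["income"].sum()
    pop.households["income"] = hh_income.loc[pop.households["household_id"]].to_numpy()

    merged = pop.individuals.drop(columns=["income"]).merge(
        pop.households[
            ["household_id", "household_size", "household_type", "income_class",
             "car_ownership", "income"]
        ],
        on="household_id",
    )
    return merged


def simulate_buildings(
    zones: list[str],
    n_buildings: int,
    seed: int,
    zone_classes: dict[str, str] | None = None,
    residential_fraction: float = 0.85,
    recorded_fraction: float = 0.15,
) -> pd.DataFrame:
    """Synthetic building stock: positive footprints (log-uniform 50-2000 m²),
    heights (uniform 3-30 m), land-use tags, and a price per m² by urban ring.

    A ``recorded_fraction`` of residential buildings carry an observed dwelling
    count (the rest must be derived from geometry downstream).
    """
    if n_buildings < 1:
        raise ValueError("n_buildings must be at least 1")
    if not zones:
        raise ValueError("zone list is empty")
    if zone_classes is None:
        rings = ("center", "inner", "outer")
        zone_classes = {z: rings[i % 3] for i, z in enumerate(sorted(zones))}
    price_base = {"center": 8000.0, "inner": 5500.0, "outer": 3500.0}

    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(b"buildings")])
    )
    zone_idx = np.arange(n_buildings) % len(zones)
    zone_col = [zones[i] for i in zone_idx]
    ring = [zone_classes[z] for z in zone_col]
    area = np.exp(rng.uniform(np.log(50.0), np.log(2000.0), n_buildings))
    height = rng.uniform(3.0, 30.0, n_buildings)
    land_use = rng.choice(
        ["residential", "commercial", "industrial"],
        size=n_buildings,
        p=[residential_fraction, (1 - residential_fraction) * 0.7,
           (1 - residential_fraction) * 0.3],
    )
    price = np.array([price_base[r] for r in ring]) * rng.lognormal(0.0, 0.3, n_buildings)

    recorded = np.full(n_buildings, np.nan)
    mask = (land_use == "residential") & (rng.random(n_buildings) < recorded_fraction)
    floors = np.maximum(1, np.floor(height / 3.0)).astype(int)
    approx = np.maximum(1, np.round(area * floors / 70.0)).astype(float)
    recorded[mask] = approx[mask]

    return pd.DataFrame(
        {
            "building_id": [f"B{i:06d}" for i in range(n_buildings)],
            "zone_id": zone_col,
            "footprint_area": area,
            "height": height,
            "land_use": land_use,
            "zone_class": ring,
            "n_dwellings": recorded,
            "price_per_m2": price,
        }
    )
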