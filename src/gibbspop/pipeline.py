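"""End-to-end orchestration of the four stages plus validation.

Artifacts are written as delimited text under one output directory, with a manifest
recording the config hash, master seed and row counts of every table.  All
randomness flows from the single master seed via per-zone substreams, so a rerun of
the same config reproduces every table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allocation, attributes, fixtures, housing, preprocess, validation
from .conditionals import cpts_from_json, cpts_to_json
from .generation import (
    CompiledModel,
    GenerationConfig,
    Population,
    generate_zone_population,
    zone_rng,
)
from .schema import default_schema
from .zones import ZoneHierarchy

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

SEP = "\t"

#: attribute sets used for the multi-attribute joint validation
MV_SETS = {
    "MV2": ("age_class", "gender"),
    "MV4": ("age_class", "gender", "spc", "main_activity"),
    "MV6": ("age_class", "gender", "spc", "main_activity", "education", "household_type"),
    "MV9": (
        "age_class", "gender", "spc", "main_activity", "education",
        "role", "overweight", "household_type", "household_size",
    ),
}
MARGINALS = (
    "age_class", "gender", "spc", "main_activity", "education",
    "household_type", "household_size", "car_ownership",
)


@dataclass
class PipelineConfig:
    """All knobs of a full run; ``seed`` is mandatory and governs every draw."""

    seed: int
    n_households: int = 10000
    frac_train: float = 0.66
    min_count: int = 10
    merge_floor: float = 0.005
    burn_in: int = 20
    head_min_age_multi: int = 21
    head_min_age_single: int = 18
    mother_child_gap: int = 15
    dispersion_sigma: float = 0.25
    n_buildings: int | None = None
    avg_dwelling_sizes: dict = field(
        default_factory=lambda: dict(housing.AVG_DWELLING_SIZES)
    )
    storey_height: float = housing.STOREY_HEIGHT

    def generation_config(self) -> GenerationConfig:
        return GenerationConfig(
            burn_in=self.burn_in,
            head_min_age_multi=self.head_min_age_multi,
            head_min_age_single=self.head_min_age_single,
            mother_child_gap=self.mother_child_gap,
            master_seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config is missing the mandatory 'seed' key")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = outdir / "manifest.json"
        self.data = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": {},
            "outputs": {},
        }

    def record(self, stage: str, seconds: float, outputs: dict[str, int]) -> None:
        self.data["stages"][stage] = {"seconds": round(seconds, 3)}
        self.data["outputs"].update(outputs)
        self.path.write_text(json.dumps(self.data, indent=1))


def _write(df: pd.DataFrame, path: Path) -> tuple[str, int]:
    df.to_csv(path, sep=SEP, index=False)
    return path.name, len(df)


# ---------------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------------

def stage_fixtures(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    model = fixtures.generate_ground_truth_model(cfg.seed)
    hierarchy = fixtures.default_zone_hierarchy(
        total_population=int(round(cfg.n_households * 3.2))
    )
    iris = hierarchy.iris_ids()
    census = fixtures.simulate_census_sample(
        model, cfg.n_households, iris, cfg.seed, hierarchy,
        config=cfg.generation_config(), dispersion_sigma=cfg.dispersion_sigma,
    )
    n_buildings = cfg.n_buildings or max(
        30 * len(iris), int(np.ceil(cfg.n_households / 12))
    )
    ring_of_iris = {
        z: fixtures.DEFAULT_COMMUNE_CLASSES[hierarchy.commune_of(z)] for z in iris
    }
    buildings = fixtures.simulate_buildings(
        iris, n_buildings, cfg.seed, zone_classes=ring_of_iris
    )
    commune_medians = pd.DataFrame(
        {"zone_id": list(model.zone_medians), "median_income": list(model.zone_medians.values())}
    )
    spc_medians = pd.DataFrame(
        {
            "spc": list(model.spc_income_medians),
            "median_income": list(model.spc_income_medians.values()),
        }
    )
    outputs = dict(
        [
            _write(census, outdir / "census.tsv"),
            _write(buildings, outdir / "buildings.tsv"),
            _write(commune_medians, outdir / "commune_medians.tsv"),
            _write(spc_medians, outdir / "spc_medians.tsv"),
            _write(model.overweight_model().to_table(), outdir / "overweight.tsv"),
        ]
    )
    hierarchy.write(outdir / "zones.tsv")
    outputs["zones.tsv"] = len(hierarchy.nodes)
    model.to_json(outdir / "ground_truth_model.json")
    outputs["ground_truth_model.json"] = len(model.cpts)
    return outputs


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    schema = default_schema()
    hierarchy = ZoneHierarchy.read(outdir / "zones.tsv")
    census = pd.read_csv(outdir / "census.tsv", sep=SEP, dtype={"zone_id": str})
    cleaned, report = preprocess.clean_microdata(census, schema)
    cleaned = preprocess.discretize(cleaned, schema)
    cleaned = preprocess.merge_rare_categories(cleaned, schema, cfg.merge_floor)
    train, test = validation.split_train_test(
        cleaned, cfg.frac_train, cfg.seed, stratify_by="zone_id"
    )
    hh_train = train.drop_duplicates("household_id")
    cpts = {}
    from .generation import REQUIRED_CPTS

    household_targets = {"household_type", "income_class", "car_ownership"}
    for target, given in REQUIRED_CPTS:
        base = hh_train if target in household_targets else train
        table = preprocess.estimate_conditional(
            base, target, given, min_count=cfg.min_count, schema=schema,
            conditioning_backoff=True,
        )
        cpts[table.key] = table
    cpts_to_json(cpts, outdir / "cpts.json")
    size_dists = {
        z: [float(x) for x in preprocess.household_size_distribution(
            train, z, hierarchy, cfg.min_count
        )]
        for z in hierarchy.iris_ids()
    }
    (outdir / "size_dists.json").write_text(json.dumps(size_dists, indent=1))
    (outdir / "cleaning_report.json").write_text(
        json.dumps(
            {
                "removed": report.removed,
                "household_collateral": report.household_collateral,
                "rows_in": report.n_input_rows,
                "rows_out": report.n_output_rows,
            },
            indent=1,
        )
    )
    outputs = dict([_write(train, outdir / "train.tsv"), _write(test, outdir / "test.tsv")])
    outputs["cpts.json"] = len(cpts)
    return outputs


def stage_generate(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    hierarchy = ZoneHierarchy.read(outdir / "zones.tsv")
    census = pd.read_csv(outdir / "census.tsv", sep=SEP, dtype={"zone_id": str})
    cpts = cpts_from_json(outdir / "cpts.json")
    size_dists = json.loads((outdir / "size_dists.json").read_text())
    model = CompiledModel(cpts)
    gen_cfg = cfg.generation_config()
    zone_pops = census.groupby("zone_id").size()
    parts = []
    for zone in hierarchy.iris_ids():
        n = int(zone_pops.get(zone, 0))
        if n == 0:
            continue
        parts.append(
            generate_zone_population(
                zone, model, np.array(size_dists[zone]), gen_cfg,
                population=n,
            )
        )
    pop = Population.concat(parts)

    commune_medians = pd.read_csv(outdir / "commune_medians.tsv", sep=SEP, dtype={"zone_id": str})
    spc_medians = pd.read_csv(outdir / "spc_medians.tsv", sep=SEP)
    income_model = attributes.IncomeModel.from_tables(
        commune_medians, spc_medians,
        population_median=fixtures.DEFAULT_POPULATION_MEDIAN,
        dispersion_sigma=cfg.dispersion_sigma,
    )
    commune_of = {z: hierarchy.commune_of(z) for z in hierarchy.iris_ids()}
    rng = zone_rng(cfg.seed, "synthetic:attributes")
    pop.individuals["income"] = attributes.assign_income_frame(
        pop.individuals, commune_of, income_model, rng
    )
    ow_model = attributes.OverweightModel.from_table(
        pd.read_csv(outdir / "overweight.tsv", sep=SEP)
    )
    pop.individuals["overweight"] = attributes.assign_overweight_frame(
        pop.individuals, ow_model, rng
    )
    totals = attributes.aggregate_household_income_frame(pop.individuals)
    pop.households["income"] = totals.loc[pop.households["household_id"]].to_numpy()
    return dict(
        [
            _write(pop.households, outdir / "synthetic_households.tsv"),
            _write(pop.individuals, outdir / "synthetic_individuals.tsv"),
        ]
    )


def stage_housing(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    hierarchy = ZoneHierarchy.read(outdir / "zones.tsv")
    buildings = pd.read_csv(outdir / "buildings.tsv", sep=SEP, dtype={"zone_id": str})
    households = pd.read_csv(
        outdir / "synthetic_households.tsv", sep=SEP, dtype={"zone_id": str}
    )
    residential, excluded = housing.classify_buildings(buildings, cfg.storey_height)
    residential = housing.count_dwellings_frame(
        residential, cfg.avg_dwelling_sizes, cfg.storey_height
    )
    # top up zones whose stock cannot hold their households with single houses
    demand = households.groupby("zone_id").size()
    supply = residential.groupby("zone_id")["n_dwellings"].sum()
    extra_rows = []
    for zone, need in demand.items():
        have = int(supply.get(zone, 0))
        if have < need:
            ring = residential.loc[residential["zone_id"] == zone, "zone_class"]
            ring = ring.iloc[0] if len(ring) else "outer"
            mean_price = buildings.loc[buildings["zone_id"] == zone, "price_per_m2"].mean()
            for i in range(need - have):
                extra_rows.append(
                    {
                        "building_id": f"X{zone}-{i:05d}",
                        "zone_id": zone,
                        "footprint_area": 100.0,
                        "height": 6.0,
                        "land_use": "residential",
                        "zone_class": ring,
                        "floors": 2,
                        "kind": "house",
                        "n_dwellings": 1,
                        "price_per_m2": float(mean_price),
                    }
                )
    if extra_rows:
        residential = pd.concat(
            [residential, pd.DataFrame(extra_rows)], ignore_index=True
        )
    residential = housing.assign_price_class(residential, hierarchy)
    dwellings = housing.build_dwellings(residential)
    housing.write_buildings_geojson(residential, outdir / "buildings.geojson")
    outputs = dict(
        [
            _write(residential, outdir / "residential_buildings.tsv"),
            _write(dwellings, outdir / "dwellings.tsv"),
        ]
    )
    outputs["excluded_non_residential"] = excluded
    return outputs


def stage_allocate(cfg: PipelineConfig, outdir: Path) -> dict[str, int]:
    households = pd.read_csv(
        outdir / "synthetic_households.tsv", sep=SEP, dtype={"zone_id": str}
    )
    dwellings = pd.read_csv(outdir / "dwellings.tsv", sep=SEP, dtype={"zone_id": str})
    households["stratum"] = allocation.stratify_household_income(households)
    assignment = allocation.allocate_households(households, dwellings, cfg.seed)
    occupancy = (
        assignment.groupby("building_id").size().rename("n_households").reset_index()
    )
    residential = pd.read_csv(
        outdir / "residential_buildings.tsv", sep=SEP, dtype={"zone_id": str}
    ).merge(occupancy, on="building_id", how="left")
    residential["n_households"] = residential["n_households"].fillna(0).astype(int)
    housing.write_buildings_geojson(residential, outdir / "occupancy.geojson")
    return dict([_write(assignment, outdir / "assignment.tsv")])


def stage_validate(
    cfg: PipelineConfig, outdir: Path, attrs: tuple[str, ...] | None = None
) -> dict[str, int]:
    schema = default_schema()
    test = pd.read_csv(outdir / "test.tsv", sep=SEP, dtype={"zone_id": str})
    individuals = pd.read_csv(
        outdir / "synthetic_individuals.tsv", sep=SEP, dtype={"zone_id": str}
    )
    households = pd.read_csv(
        outdir / "synthetic_households.tsv", sep=SEP, dtype={"zone_id": str}
    )
    synthetic = Population(households, individuals).merged()

    report = validation.MetricsReport()
    for var in MARGINALS:
        s = validation.srmse_between(test, synthetic, (var,), schema)
        report.add((var,), "region", srmse_value=s, cells=len(schema.categories(var)),
                   support=len(test))
    for name, combo in MV_SETS.items():
        s = validation.srmse_between(test, synthetic, combo, schema)
        m = int(np.prod([len(schema.categories(v)) for v in combo]))
        report.add(f"{name}:{'+'.join(combo)}", "region", srmse_value=s, cells=m,
                   support=len(test))
    for var in attrs or ("household_size", "age_class", "spc"):
        cmp = validation.per_zone_comparison(test, synthetic, var, schema)
        report.add((var,), "iris", fit=cmp.pooled, cells=len(cmp.table),
                   support=len(test))
        cmp.table.to_csv(outdir / f"per_zone_{var}.tsv", sep=SEP, index=False)
    report.to_json(outdir / "metrics.json")
    report.write(outdir / "metrics.tsv")
    return {"metrics.json": len(report.rows)}


STAGES = {
    "fixtures": stage_fixtures,
    "preprocess": stage_preprocess,
    "generate": stage_generate,
    "housing": stage_housing,
    "allocate": stage_allocate,
    "validate": stage_validate,
}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all stages in order, writing artifacts and a manifest; on failure a
    FAILED marker naming the stage is left next to the partial outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    for name, stage in STAGES.items():
        t0 = time.perf_counter()
        try:
            outputs = stage(config, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise
        manifest.record(name, time.perf_counter() - t0, outputs)
    return outdir
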