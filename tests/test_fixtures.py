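import json

import numpy as np
import pytest

from gibbspop import fixtures as F
from gibbspop.fixtures import GroundTruthModel
from gibbspop.schema import AttributeSchema, SchemaError, default_schema


class TestGroundTruthModel:
    def test_household_types_match_the_catalogue(self, model):
        t = model.cpts[("household_type", ("household_size",))]
        assert t.categories == ("Single", "single parent", "couple", "family")

    def test_every_vector_is_a_distribution(self, model):
        for table in model.cpts.values():
            for cell in table.cells.values():
                assert cell.probs.sum() == pytest.approx(1.0, abs=1e-9)
                assert (cell.probs >= 0).all()
        for probs in model.size_dist_by_zone.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        F.generate_ground_truth_model(1).to_json(a)
        F.generate_ground_truth_model(1).to_json(b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        F.generate_ground_truth_model(1).to_json(a)
        F.generate_ground_truth_model(2).to_json(b)
        assert a.read_bytes() != b.read_bytes()

    def test_json_roundtrip(self, model, tmp_path):
        path = tmp_path / "m.json"
        model.to_json(path)
        again = GroundTruthModel.from_json(path)
        assert set(again.cpts) == set(model.cpts)
        np.testing.assert_allclose(
            again.size_dist_by_zone["I5"], model.size_dist_by_zone["I5"]
        )

    def test_invalid_schema_rejected(self):
        broken = AttributeSchema(
            {k: v for k, v in default_schema().variables.items() if k != "spc"}
        )
        with pytest.raises(SchemaError, match="spc"):
            F.generate_ground_truth_model(1, broken)

    def test_structural_zeros_encode_the_hard_rules(self, model):
        # under-15s are schoolchildren with inactive SPC; retirees carry SPC 7
        act = model.cpts[("main_activity", ("age_class",))]
        assert act.cells[("0-15",)].probs[list(act.categories).index("student")] == 1.0
        spc = model.cpts[("spc", ("age_class", "main_activity"))]
        for band in ("15-35", "35-65", "65-120"):
            assert spc.cells[(band, "retired")].probs[6] == 1.0
            assert spc.cells[(band, "student")].probs[7] == 1.0


class TestCensusSample:
    def test_sizes_sum_to_row_count(self, census_small):
        per_hh = census_small.groupby("household_id")["household_size"].first()
        assert per_hh.sum() == len(census_small)
        members = census_small.groupby("household_id").size()
        assert (members == per_hh.loc[members.index]).all()

    def test_point_mass_size_one_means_all_singles(self, model, hierarchy):
        clone = GroundTruthModel(
            schema=model.schema,
            cpts=model.cpts,
            size_dist_by_zone={
                z: np.array([1.0, 0, 0, 0, 0, 0]) for z in hierarchy.iris_ids()
            },
            spc_income_medians=model.spc_income_medians,
            zone_medians=model.zone_medians,
            population_median_income=model.population_median_income,
            seed=model.seed,
        )
        census = F.simulate_census_sample(clone, 300, hierarchy.iris_ids(), 5, hierarchy)
        assert (census["household_type"] == "Single").all()
        assert (census["household_size"] == 1).all()

    def test_type_given_size_within_monte_carlo_error(self, model, census_small):
        truth = model.cpts[("household_type", ("household_size",))]
        hh = census_small.drop_duplicates("household_id")
        for size in (2, 3):
            sub = hh[hh["household_size"] == size]
            n = len(sub)
            assert n > 100
            for cat, p in zip(truth.categories, truth.cells[(size,)].probs):
                phat = (sub["household_type"] == cat).mean()
                se = np.sqrt(max(p * (1 - p), 1e-9) / n)
                assert abs(phat - p) < 3.5 * se + 1e-9

    def test_empty_zone_list_rejected(self, model):
        with pytest.raises(ValueError, match="zone"):
            F.simulate_census_sample(model, 10, [], 1)


class TestBuildings:
    def test_row_count_and_positive_geometry(self, hierarchy):
        b = F.simulate_buildings(hierarchy.iris_ids(), 10, 1)
        assert len(b) == 10
        assert (b["footprint_area"] > 0).all()
        assert (b["height"] > 0).all()

    def test_fixed_seed_reproduces_the_table(self, hierarchy):
        a = F.simulate_buildings(hierarchy.iris_ids(), 50, 6)
        b = F.simulate_buildings(hierarchy.iris_ids(), 50, 6)
        assert a.equals(b)

    def test_all_center_zones_tag_all_rows_center(self):
        b = F.simulate_buildings(["Z1", "Z2"], 20, 2, zone_classes={"Z1": "center", "Z2": "center"})
        assert (b["zone_class"] == "center").all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            F.simulate_buildings(["Z"], 0, 1)
        with pytest.raises(ValueError):
            F.simulate_buildings([], 5, 1)


def test_default_hierarchy_shape():
    h = F.default_zone_hierarchy(30000)
    assert len(h.zones_at("region")) == 1
    assert len(h.zones_at("department")) == 2
    assert len(h.zones_at("commune")) == 4
    assert len(h.iris_ids()) == 8
    assert sum(h.population(z) for z in h.iris_ids()) == 30000
    assert h.population("R") == 30000
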