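import numpy as np
import pandas as pd
import pytest

from gibbspop import preprocess as P
from gibbspop.preprocess import EstimationError


def micro(rows):
    cols = ["household_id", "zone_id", "age", "gender", "household_size"]
    return pd.DataFrame(rows, columns=cols)


class TestCleaning:
    def test_valid_table_passes_untouched(self, schema):
        raw = micro([("h1", "I1", 30, "Male", 2), ("h1", "I1", 28, "Female", 2)])
        cleaned, report = P.clean_microdata(raw, schema)
        assert cleaned.equals(raw)
        assert report.empty

    def test_negative_age_removed_and_counted(self, schema):
        raw = micro([("h1", "I1", -3, "Male", 1)])
        cleaned, report = P.clean_microdata(raw, schema)
        assert len(cleaned) == 0
        assert report.removed == {"age out of range": 1}

    def test_whole_household_dropped_with_one_bad_member(self, schema):
        raw = micro(
            [
                ("h1", "I1", 40, "Male", 3),
                ("h1", "I1", 38, "Robot", 3),  # out-of-schema gender
                ("h1", "I1", 10, "Female", 3),
                ("h2", "I1", 50, "Male", 1),
            ]
        )
        cleaned, report = P.clean_microdata(raw, schema)
        assert list(cleaned["household_id"]) == ["h2"]
        assert report.removed == {"out-of-schema gender": 1}
        assert report.household_collateral == 2

    def test_unparseable_age_counted_separately(self, schema):
        raw = micro([("h1", "I1", "forty", "Male", 1)])
        _, report = P.clean_microdata(raw, schema)
        assert report.removed == {"unparseable age": 1}

    def test_missing_household_id_column_rejected(self, schema):
        with pytest.raises(ValueError, match="household_id"):
            P.clean_microdata(pd.DataFrame({"zone_id": ["I1"]}), schema)


class TestDiscretize:
    def test_age_bands_assigned(self, schema):
        table = micro([("h1", "I1", 15, "Male", 1), ("h2", "I1", 120, "Female", 1)])
        out = P.discretize(table, schema)
        assert list(out["age_class"]) == ["15-35", "65-120"]

    def test_age_above_120_rejected(self, schema):
        with pytest.raises(ValueError):
            P.discretize(micro([("h1", "I1", 130, "Male", 1)]), schema)

    def test_out_of_schema_category_rejected(self, schema):
        table = micro([("h1", "I1", 30, "Other", 1)])
        with pytest.raises(Exception, match="gender"):
            P.discretize(table, schema)


def test_rare_categories_merge_into_designated_sink(schema):
    acts = ["Employed"] * 995 + ["retired"] * 4 + ["unemployed"] * 1
    table = pd.DataFrame({"main_activity": acts})
    out = P.merge_rare_categories(table, schema, floor=0.005)
    # retired (0.4%) and unemployed (0.1%) both fall under the floor
    assert set(out["main_activity"]) == {"Employed", "other unemployed"}
    assert (out["main_activity"] == "other unemployed").sum() == 5


class TestEstimateConditional:
    def make_table(self, n_iris, n_rest, hierarchy):
        """n_iris rows in I1, n_rest rows spread over the rest of the commune."""
        rows = [("h%d" % i, "I1", "a" if i % 2 else "b") for i in range(n_iris)]
        rows += [
            ("g%d" % i, "I2", "a" if i % 4 else "b") for i in range(n_rest)
        ]
        return pd.DataFrame(rows, columns=["household_id", "zone_id", "x"])

    def test_cell_with_enough_support_stays_at_iris(self, hierarchy):
        table = self.make_table(500, 200, hierarchy)
        t = P.estimate_conditional(table, "x", ("zone_id",), hierarchy, min_count=10)
        assert t.cells[("I1",)].level == "iris"
        assert t.cells[("I1",)].support == 500

    def test_sparse_iris_falls_back_to_commune(self, hierarchy):
        table = self.make_table(3, 200, hierarchy)
        t = P.estimate_conditional(table, "x", ("zone_id",), hierarchy, min_count=10)
        assert t.cells[("I1",)].level == "commune"
        # pooled over I1+I2 (both under C1)
        assert t.cells[("I1",)].support == 203

    def test_error_names_cell_when_region_is_still_sparse(self, hierarchy):
        table = self.make_table(3, 2, hierarchy)
        with pytest.raises(EstimationError, match="I1"):
            P.estimate_conditional(table, "x", ("zone_id",), hierarchy, min_count=10)

    def test_decreasing_min_count_never_coarsens(self, hierarchy):
        table = self.make_table(30, 500, hierarchy)
        order = {"iris": 0, "commune": 1, "department": 2, "region": 3}
        prev = None
        for mc in (200, 50, 10):
            t = P.estimate_conditional(table, "x", ("zone_id",), hierarchy, min_count=mc)
            level = order[t.cells[("I1",)].level]
            if prev is not None:
                assert level <= prev
            prev = level

    def test_uniform_data_estimates_within_3_se(self, hierarchy):
        rng = np.random.default_rng(42)
        n = 4000
        table = pd.DataFrame(
            {
                "household_id": [f"h{i}" for i in range(n)],
                "zone_id": "I1",
                "x": rng.choice(["a", "b", "c", "d"], n),
            }
        )
        t = P.estimate_conditional(table, "x", (), min_count=10)
        se = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(t.cells[()].probs - 0.25) < 3 * se)

    def test_conditioning_backoff_borrows_from_coarser_table(self):
        table = pd.DataFrame(
            {
                "g1": ["u"] * 100 + ["v"] * 5,
                "x": ["a", "b"] * 50 + ["a"] * 5,
            }
        )
        with pytest.raises(EstimationError):
            P.estimate_conditional(table, "x", ("g1",), min_count=10)
        t = P.estimate_conditional(
            table, "x", ("g1",), min_count=10, conditioning_backoff=True
        )
        assert t.cells[("v",)].level == "backoff"
        np.testing.assert_allclose(
            t.cells[("v",)].probs,
            P.estimate_conditional(table, "x", (), min_count=10).cells[()].probs,
        )


class TestHouseholdSizeDistribution:
    def test_point_mass_zone(self, hierarchy):
        table = pd.DataFrame(
            {
                "household_id": [f"h{i}" for i in range(20)],
                "zone_id": "I1",
                "household_size": 2,
            }
        )
        probs = P.household_size_distribution(table, "I1", hierarchy, min_count=10)
        np.testing.assert_allclose(probs, [0, 1, 0, 0, 0, 0])

    def test_empty_iris_uses_commune_distribution(self, hierarchy):
        table = pd.DataFrame(
            {
                "household_id": [f"h{i}" for i in range(30)],
                "zone_id": "I2",  # sibling of I1 under C1
                "household_size": 3,
            }
        )
        probs = P.household_size_distribution(table, "I1", hierarchy, min_count=10)
        np.testing.assert_allclose(probs, [0, 0, 1, 0, 0, 0])

    def test_all_fixture_zones_sum_to_one(self, census_small, hierarchy):
        for zone in hierarchy.iris_ids():
            probs = P.household_size_distribution(census_small, zone, hierarchy)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)


def test_recovered_conditionals_match_ground_truth_on_fixture(
    model, census_small, schema
):
    """Estimates from a moderate exact sample track the generating tree closely
    (the tight 3-SE audit at 50k households lives in the acceptance suite)."""
    t = P.estimate_conditional(
        census_small, "main_activity", ("age_class",), min_count=10, schema=schema
    )
    truth = model.cpts[("main_activity", ("age_class",))]
    for cond, cell in t.cells.items():
        if cell.support < 200:
            continue
        np.testing.assert_allclose(
            cell.probs, truth.cells[cond].probs, atol=4 * np.sqrt(0.25 / cell.support)
        )
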