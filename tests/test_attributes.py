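import numpy as np
import pandas as pd
import pytest

from gibbspop.attributes import (
    EMPLOYED_FLOOR,
    NON_WORKING_FLOOR,
    IncomeModel,
    OverweightModel,
    aggregate_household_income,
    assign_income,
    assign_overweight,
    assign_overweight_frame,
)
from gibbspop.generation import Household, Individual


def make_model(**kw):
    kw.setdefault("commune_medians", {"C1": 20000.0})
    kw.setdefault("spc_medians", {3: 30000.0, 5: 20000.0, 6: 8000.0, 8: 4000.0})
    kw.setdefault("population_median", 20000.0)
    kw.setdefault("dispersion_sigma", 0.0)
    return IncomeModel(**kw)


class TestAssignIncome:
    def test_unit_alpha_reproduces_the_commune_median(self):
        model = make_model()
        assert assign_income(40, 5, "Employed", "C1", model) == 20000.0

    def test_alpha_scales_the_median(self):
        # r_SPC = 30000, r = 20000 -> alpha = 1.5 -> income 30000
        model = make_model()
        assert model.alpha(3) == pytest.approx(1.5)
        assert assign_income(40, 3, "Employed", "C1", model) == pytest.approx(30000.0)

    def test_employed_floor_at_minimum_wage(self):
        # alpha 0.4 x 20000 = 8000, floored to the 2010 minimum wage
        model = make_model()
        assert assign_income(40, 6, "Employed", "C1", model) == EMPLOYED_FLOOR

    def test_non_working_floor_applies_from_25(self):
        # alpha 0.2 x 20000 = 4000, below the Active Solidarity Income
        model = make_model()
        assert assign_income(30, 8, "unemployed", "C1", model) == NON_WORKING_FLOOR
        # 18-24 year-old non-working: no floor
        assert assign_income(22, 8, "unemployed", "C1", model) == 4000.0

    def test_students_and_minors_get_zero(self):
        model = make_model()
        assert assign_income(30, 3, "student", "C1", model) == 0.0
        assert assign_income(16, 6, "Employed", "C1", model) == 0.0

    def test_unknown_spc_rejected(self):
        with pytest.raises(ValueError, match="SPC"):
            assign_income(40, 99, "Employed", "C1", make_model())

    def test_dispersion_spreads_but_respects_floors(self):
        model = make_model(dispersion_sigma=0.5)
        rng = np.random.default_rng(0)
        draws = [assign_income(40, 6, "Employed", "C1", model, rng) for _ in range(500)]
        assert len(set(draws)) > 50  # lognormal spread above the floor
        assert min(draws) == EMPLOYED_FLOOR  # floor engaged below it


class TestAggregateIncome:
    def make_household(self, incomes):
        members = [
            Individual(f"p{i}", "h1", "head", 40, "35-65", "Male", 3, "none",
                       "Employed", income=v)
            for i, v in enumerate(incomes)
        ]
        return Household("h1", "I1", len(members), "family", "low", 0, members)

    def test_sum(self):
        assert aggregate_household_income(self.make_household([20000, 15000, 0])) == 35000

    def test_single(self):
        assert aggregate_household_income(self.make_household([5520.0])) == 5520.0

    def test_permutation_invariant(self):
        a = aggregate_household_income(self.make_household([1.0, 2.0, 3.0]))
        b = aggregate_household_income(self.make_household([3.0, 1.0, 2.0]))
        assert a == b

    def test_unset_income_rejected(self):
        hh = self.make_household([1000.0])
        hh.members[0].income = None
        with pytest.raises(ValueError, match="no income"):
            aggregate_household_income(hh)


class TestOverweight:
    def test_point_mass_cell(self):
        model = OverweightModel({("Male", "35-65", 3): np.array([0.0, 0.0, 1.0])})
        rng = np.random.default_rng(0)
        assert all(
            assign_overweight("Male", "35-65", 3, model, rng) == 2 for _ in range(50)
        )

    def test_empirical_rates_within_3_se(self):
        p = np.array([0.6, 0.3, 0.1])
        model = OverweightModel({("Female", "15-35", 5): p})
        df = pd.DataFrame(
            {"gender": "Female", "age_class": "15-35", "spc": 5}, index=range(10000)
        )
        draws = assign_overweight_frame(df, model, np.random.default_rng(1))
        for level in (0, 1, 2):
            phat = (draws == level).mean()
            se = np.sqrt(p[level] * (1 - p[level]) / len(df))
            assert abs(phat - p[level]) < 3 * se

    def test_fallback_to_gender_age_then_marginal(self):
        model = OverweightModel(
            {
                ("Male", "35-65", 3): np.array([1.0, 0.0, 0.0]),
                ("Male", "35-65", 4): np.array([0.0, 1.0, 0.0]),
            }
        )
        # missing SPC stratum -> average of the gender x age cells
        np.testing.assert_allclose(model.probs("Male", "35-65", 7), [0.5, 0.5, 0.0])
        # missing gender x age entirely -> overall marginal
        np.testing.assert_allclose(model.probs("Female", "0-15", 8), [0.5, 0.5, 0.0])

    def test_table_roundtrip(self, model):
        ow = model.overweight_model()
        again = OverweightModel.from_table(ow.to_table())
        for key, p in ow.contingency.items():
            np.testing.assert_allclose(again.contingency[key], p)


def test_generated_population_respects_income_floors(synthetic10k):
    ind = synthetic10k.individuals
    employed = ind[ind["main_activity"] == "Employed"]
    assert employed["income"].min() >= EMPLOYED_FLOOR
    non_working = ind[
        ind["main_activity"].isin(["unemployed", "retired", "other unemployed"])
        & (ind["age"] >= 25)
    ]
    assert non_working["income"].min() >= NON_WORKING_FLOOR
    minors = ind[ind["age"] < 18]
    assert (minors["income"] == 0).all()
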