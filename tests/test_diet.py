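"""Nutrient profiles, DASH scoring, Schofield BMR and Goldberg cut-offs."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from upfmed.diet import (
    DashComponentSpec,
    GoldbergParams,
    compute_bmr,
    compute_dash_score,
    compute_nutrient_profile,
    goldberg_classify,
    goldberg_cutoffs,
)
from upfmed.errors import MissingDataError
from upfmed.nova import FoodCode


def _single_nutrient_catalogue(nutrient: str, grams_per_100g: float, factor: float):
    code = FoodCode(
        f"{nutrient}_food",
        "test food",
        energy_per_100g=grams_per_100g * factor,
        nutrients_per_100g={nutrient: grams_per_100g},
    )
    return {code.code_id: code}


class TestNutrientProfile:
    def test_fibre_density_is_grams_per_1000_kcal(self):
        # 2000 kcal/day with 18 g/day fibre -> 9 g per 1000 kcal
        code = FoodCode("f", "bread", energy_per_100g=200.0,
                        nutrients_per_100g={"fibre": 1.8})
        entries = [{"code_id": "f", "grams": 1000.0, "day": d} for d in range(1, 8)]
        prof = compute_nutrient_profile(entries, {"f": code})
        assert prof.mean_daily_energy == pytest.approx(2000.0)
        assert prof.fibre_density == pytest.approx(9.0)

    def test_fat_energy_percentage_uses_factor_9(self):
        # 100 g/day fat in a 2000 kcal/day diet: 9*100/2000 = 45%
        code = FoodCode("f", "meal", energy_per_100g=200.0,
                        nutrients_per_100g={"fat": 10.0})
        entries = [{"code_id": "f", "grams": 1000.0, "day": 1}]
        assert compute_nutrient_profile(entries, {"f": code}).pct_energy_fat == pytest.approx(45.0)

    @pytest.mark.parametrize(
        "nutrient,factor",
        [("fat", 9.0), ("protein", 4.0), ("carbohydrate", 3.75), ("nmes", 3.75)],
    )
    def test_single_macronutrient_diary_closes_to_100pct(self, nutrient, factor):
        cat = _single_nutrient_catalogue(nutrient, 20.0, factor)
        entries = [{"code_id": f"{nutrient}_food", "grams": 500.0, "day": 1}]
        prof = compute_nutrient_profile(entries, cat)
        pct = getattr(prof, f"pct_energy_{nutrient}")
        assert pct == pytest.approx(100.0)

    def test_energy_density_excludes_beverages(self):
        solid = FoodCode("s", "rice white boiled", energy_per_100g=120.0)
        drink = FoodCode("d", "cola soft drink", brand_name="X",
                         energy_per_100g=40.0, is_beverage=True)
        entries = [{"code_id": "s", "grams": 200.0, "day": 1},
                   {"code_id": "d", "grams": 500.0, "day": 1}]
        prof = compute_nutrient_profile(entries, {"s": solid, "d": drink})
        assert prof.energy_density == pytest.approx(1.2)  # 240 kcal / 200 g solids

    def test_empty_diary_raises(self):
        with pytest.raises(MissingDataError):
            compute_nutrient_profile([], {})


class TestDashScore:
    ADEQ = DashComponentSpec("fruit", 200.0, "adequacy")
    MODER = DashComponentSpec("sodium", 2300.0, "moderation")

    def test_meeting_adequacy_target_awards_full_points(self):
        score = compute_dash_score({"fruit": 200.0}, [self.ADEQ])
        assert score.total == pytest.approx(10.0)

    def test_half_target_awards_half_points(self):
        score = compute_dash_score({"fruit": 100.0}, [self.ADEQ])
        assert score.total == pytest.approx(5.0)

    def test_zero_adequacy_intake_scores_zero(self):
        assert compute_dash_score({"fruit": 0.0}, [self.ADEQ]).total == 0.0

    def test_moderation_full_points_at_or_below_target(self):
        assert compute_dash_score({"sodium": 2300.0}, [self.MODER]).total == 10.0
        assert compute_dash_score({"sodium": 1000.0}, [self.MODER]).total == 10.0

    def test_moderation_decays_above_target(self):
        assert compute_dash_score({"sodium": 4600.0}, [self.MODER]).total == pytest.approx(5.0)

    def test_negative_intake_rejected(self):
        with pytest.raises(ValueError):
            compute_dash_score({"fruit": -1.0}, [self.ADEQ])

    def test_normalised_total_is_on_ten_point_scale(self):
        score = compute_dash_score({"fruit": 200.0, "sodium": 2300.0},
                                   [self.ADEQ, self.MODER])
        assert score.total == pytest.approx(20.0)
        assert score.normalised == pytest.approx(10.0)

    @given(lo=st.floats(0.0, 600.0), delta=st.floats(0.0, 600.0))
    def test_adequacy_monotone_nondecreasing(self, lo, delta):
        s1 = compute_dash_score({"fruit": lo}, [self.ADEQ]).total
        s2 = compute_dash_score({"fruit": lo + delta}, [self.ADEQ]).total
        assert s2 >= s1 - 1e-12

    @given(lo=st.floats(2300.0, 9000.0), delta=st.floats(0.0, 5000.0))
    def test_moderation_monotone_nonincreasing_above_target(self, lo, delta):
        s1 = compute_dash_score({"sodium": lo}, [self.MODER]).total
        s2 = compute_dash_score({"sodium": lo + delta}, [self.MODER]).total
        assert s2 <= s1 + 1e-12


class TestBmr:
    def test_schofield_worked_value_30y_male(self):
        # 30-59 male band: 11.472*W + 873.1; at 75 kg -> 1733.5 kcal/day
        assert compute_bmr(30, "male", 75.0) == pytest.approx(1733.5, abs=1.0)

    def test_monotone_in_weight_within_band(self):
        assert compute_bmr(45, "female", 80.0) > compute_bmr(45, "female", 40.0)

    def test_deterministic(self):
        assert compute_bmr(25, "male", 70.0) == compute_bmr(25, "male", 70.0)

    def test_missing_weight_raises(self):
        with pytest.raises(MissingDataError):
            compute_bmr(30, "male", float("nan"))


class TestGoldberg:
    def test_cutoffs_match_independent_formula_evaluation(self):
        # S = sqrt(23^2/7 + 8.5^2 + 15.1^2) = 19.3864;
        # 1.55*exp(-/+ 1.96*S/100) = 1.0600 / 2.2665
        lo, hi = goldberg_cutoffs()
        assert lo == pytest.approx(1.0600, abs=5e-5)
        assert hi == pytest.approx(2.2665, abs=5e-5)

    def test_ratio_at_pal_is_acceptable(self):
        assert goldberg_classify(1.55 * 1700.0, 1700.0) == "acceptable"

    def test_below_lower_cutoff_is_under(self):
        lo, _ = goldberg_cutoffs()
        assert goldberg_classify(0.9 * lo * 1700.0, 1700.0) == "under"

    def test_above_upper_cutoff_is_over(self):
        _, hi = goldberg_cutoffs()
        assert goldberg_classify(1.1 * hi * 1700.0, 1700.0) == "over"

    @given(
        pal=st.floats(1.2, 2.2),
        cv_ei=st.floats(5.0, 40.0),
        days=st.integers(1, 14),
        cv_bmr=st.floats(2.0, 15.0),
        cv_pal=st.floats(5.0, 25.0),
    )
    def test_interval_always_brackets_pal(self, pal, cv_ei, days, cv_bmr, cv_pal):
        params = GoldbergParams(pal=pal, cv_within_ei=cv_ei, diary_days=days,
                                cv_bmr=cv_bmr, cv_pal=cv_pal)
        lo, hi = goldberg_cutoffs(params)
        assert lo < pal < hi
        assert math.isclose(lo * hi, pal**2, rel_tol=1e-12)  # geometric symmetry
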