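"""qNRF scoring, substitution factors and nutritional functional units."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entolca.core import ImpactVector
from entolca.nutrition import (
    DEFAULT_REFERENCE_INTAKES,
    QUALIFYING_NUTRIENTS,
    NutrientProfile,
    ReferenceIntakes,
    meal_score,
    nutritional_fu_convert,
    qnrf_score,
    substitution_factor,
)

REFS = ReferenceIntakes(
    protein=50.0,
    qualifying={n: 30.0 if n == "fiber" else 100.0 for n in QUALIFYING_NUTRIENTS},
    saturated_fat=20.0,
    sodium=2400.0,
)


class TestQnrfScore:
    def test_all_zero_profile_scores_zero(self):
        assert qnrf_score(NutrientProfile(protein=0.0), REFS).value == 0.0

    def test_hand_computed_example(self):
        profile = NutrientProfile(
            protein=25.0, diaas=0.8, qualifying={"fiber": 7.5}, saturated_fat=5.0
        )
        score = qnrf_score(profile, REFS)
        # 100*(25*0.8/50) + 100*(7.5/30) - 100*(5/20) = 40 + 25 - 25 = 40
        assert score.value == pytest.approx(40.0)
        assert score.components["protein"] == pytest.approx(40.0)
        assert score.components["saturated_fat"] == pytest.approx(-25.0)

    def test_profile_meeting_every_dri_scores_1100_under_cap(self):
        profile = NutrientProfile(
            protein=REFS.protein, diaas=1.0,
            qualifying={n: REFS.qualifying[n] for n in QUALIFYING_NUTRIENTS},
        )
        assert qnrf_score(profile, REFS, cap=100.0).value == pytest.approx(1100.0)

    def test_cap_binds_encouraged_terms_only(self):
        profile = NutrientProfile(
            protein=500.0, diaas=1.0, saturated_fat=100.0
        )
        score = qnrf_score(profile, REFS, cap=100.0)
        assert score.components["protein"] == 100.0
        assert score.components["saturated_fat"] == pytest.approx(-500.0)
        uncapped = qnrf_score(profile, REFS, cap=None)
        assert uncapped.components["protein"] == pytest.approx(1000.0)

    def test_missing_diaas_uses_unity_and_flags(self):
        score = qnrf_score(NutrientProfile(protein=25.0, diaas=None), REFS)
        assert score.missing_diaas
        assert score.components["protein"] == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        nutrient=st.sampled_from(QUALIFYING_NUTRIENTS),
        base=st.floats(0, 50, allow_nan=False),
        bump=st.floats(0, 50, allow_nan=False),
    )
    def test_more_encouraged_nutrient_never_lowers_score(self, nutrient, base, bump):
        p1 = NutrientProfile(protein=10.0, diaas=0.9, qualifying={nutrient: base})
        p2 = NutrientProfile(protein=10.0, diaas=0.9, qualifying={nutrient: base + bump})
        assert qnrf_score(p2, REFS).value >= qnrf_score(p1, REFS).value

    @settings(derandomize=True, max_examples=60)
    @given(sfa=st.floats(0, 50, allow_nan=False), extra=st.floats(0, 50, allow_nan=False))
    def test_more_saturated_fat_never_raises_score(self, sfa, extra):
        p1 = NutrientProfile(protein=10.0, saturated_fat=sfa)
        p2 = NutrientProfile(protein=10.0, saturated_fat=sfa + extra)
        assert qnrf_score(p2, REFS).value <= qnrf_score(p1, REFS).value


class TestSubstitution:
    def test_beef_to_mealworm_multiplier(self):
        assert substitution_factor(146.0, 117.0) == pytest.approx(1.25, abs=5e-3)

    def test_equal_scores_give_unity(self):
        assert substitution_factor(88.0, 88.0) == 1.0

    def test_beef_to_quinoa_multiplier(self):
        assert substitution_factor(146.0, 204.0) == pytest.approx(0.7157, abs=1e-4)

    def test_reciprocal_pair_multiplies_to_one(self):
        assert substitution_factor(146.0, 117.0) * substitution_factor(117.0, 146.0) == (
            pytest.approx(1.0)
        )

    def test_non_positive_alternative_is_an_error(self):
        with pytest.raises(ValueError):
            substitution_factor(100.0, 0.0)


class TestNutritionalFU:
    def test_mealworm_carbon_footprint_per_1000_score(self):
        per_kg = ImpactVector.from_dict({"GWP": 1.45})
        out = nutritional_fu_convert(per_kg, 117.0)
        assert out["GWP"] == pytest.approx(1.24, abs=5e-3)

    def test_score_100_is_identity(self):
        per_kg = ImpactVector.from_dict({"GWP": 2.0, "LU": 7.0})
        assert nutritional_fu_convert(per_kg, 100.0).isclose(per_kg)

    def test_category_ratios_are_preserved(self):
        per_kg = ImpactVector.from_dict({"GWP": 2.0, "ADPfossil": 8.0})
        out = nutritional_fu_convert(per_kg, 57.0)
        assert out["ADPfossil"] / out["GWP"] == pytest.approx(4.0)

    def test_non_positive_score_is_an_error(self):
        with pytest.raises(ValueError):
            nutritional_fu_convert(ImpactVector.zero(), -3.0)


class TestMealScore:
    def test_single_ingredient_meal_scores_like_the_ingredient(self):
        p = NutrientProfile(protein=20.0, diaas=0.9, qualifying={"fiber": 5.0})
        assert meal_score([(p, 2.5)], REFS).value == pytest.approx(qnrf_score(p, REFS).value)

    def test_fifty_fifty_blend_scores_the_averaged_profile(self):
        a = NutrientProfile(protein=10.0, diaas=1.0, qualifying={"fiber": 4.0})
        b = NutrientProfile(protein=30.0, diaas=1.0, saturated_fat=6.0)
        blend = NutrientProfile(
            protein=20.0, diaas=1.0, qualifying={"fiber": 2.0}, saturated_fat=3.0
        )
        assert meal_score([(a, 1.0), (b, 1.0)], REFS).value == pytest.approx(
            qnrf_score(blend, REFS).value
        )

    def test_capping_makes_mixing_nonlinear(self):
        # min(cap, .) is concave, so a blend scores at least the
        # mass-weighted average of the capped scores (Jensen) while
        # staying strictly below the uncapped mixture
        rich = NutrientProfile(protein=0.0, qualifying={"fiber": 300.0})
        empty = NutrientProfile(protein=0.0)
        blended = meal_score([(rich, 1.0), (empty, 1.0)], REFS).value
        weighted = 0.5 * (qnrf_score(rich, REFS).value + qnrf_score(empty, REFS).value)
        uncapped_blend = meal_score([(rich, 1.0), (empty, 1.0)], REFS, cap=None).value
        assert blended >= weighted
        assert blended < uncapped_blend

    def test_order_of_ingredients_is_irrelevant(self):
        a = NutrientProfile(protein=12.0, diaas=0.8, qualifying={"iron": 3.0})
        b = NutrientProfile(protein=5.0, diaas=1.1, saturated_fat=2.0)
        assert meal_score([(a, 1.0), (b, 2.0)], REFS).value == pytest.approx(
            meal_score([(b, 2.0), (a, 1.0)], REFS).value
        )
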