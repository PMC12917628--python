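"""Synthetic background generation, calibration, nutrient-profile synthesis."""

import numpy as np
import pytest

from entolca.core import CATEGORIES, SCENARIOS
from entolca.engine import compute_impacts, contribution_by_stage
from entolca.nutrition import DEFAULT_REFERENCE_INTAKES, qnrf_score
from entolca.synthetic import (
    TEMPLATE_PROFILES,
    calibrate_to_targets,
    farm_stage_targets,
    generate_background,
    nutrient_profiles,
    profile_with_target_score,
)
from entolca.tables import DEFAULT_CFS


class TestGenerateBackground:
    def test_same_seed_gives_identical_tables(self):
        a, am = generate_background(["x", "y"], seed=42)
        b, bm = generate_background(["x", "y"], seed=42)
        assert a.equals(b) and am.equals(bm)

    def test_different_seeds_differ(self):
        a, _ = generate_background(["x", "y"], seed=1)
        b, _ = generate_background(["x", "y"], seed=2)
        assert not a.equals(b)

    def test_unit_perturbation_makes_marginal_equal_average(self):
        avg, marg = generate_background(["x"], seed=0, perturbation=1.0)
        assert avg.equals(marg)

    def test_intensities_respect_category_ranges(self):
        avg, _ = generate_background(["x", "y", "z"], seed=3, ranges={"GWP": (1.0, 2.0)})
        col = avg.frame["GWP"]
        assert ((col >= 1.0) & (col <= 2.0)).all()

    def test_tables_are_strictly_positive_and_finite(self):
        avg, marg = generate_background(["a", "b", "c"], seed=8)
        for t in (avg, marg):
            arr = t.frame.to_numpy()
            assert np.isfinite(arr).all() and (arr > 0).all()

    def test_empty_product_list_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            generate_background([], seed=0)


class TestCalibration:
    def test_current_outputs_are_a_fixed_point(self, farm):
        products = sorted({n for p in farm.processes for n, _ in p.background_inputs})
        base, _ = generate_background(products, seed=4)
        report = contribution_by_stage(farm, 1.0, base, DEFAULT_CFS)
        targets = {
            stage: dict(zip(CATEGORIES, report.absolute.loc[stage]))
            for stage in report.absolute.index
        }
        calibrated, notes = calibrate_to_targets(farm, targets, base, DEFAULT_CFS)
        assert calibrated.equals(base, rtol=1e-12)
        assert notes == []

    def test_unreachable_target_without_inputs_is_an_error(self, farm):
        products = sorted({n for p in farm.processes for n, _ in p.background_inputs})
        base, _ = generate_background(products, seed=4)
        stripped = farm
        stripped.process_map()["farm_drying"].background_inputs = []
        targets = {"drying": {"GWP": 1.0}}
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_to_targets(stripped, targets, base, DEFAULT_CFS)

    def test_round_trip_hits_the_scenario_totals(self, fixtures_bundle):
        from entolca.allocation import allocate
        from entolca.calibration_targets import FARM_TOTALS

        fx = fixtures_bundle
        gross = compute_impacts(fx.farm, 1.0, fx.average, fx.cfs)
        for cat, target in FARM_TOTALS["TM_AW"].items():
            assert gross[cat] == pytest.approx(target, rel=5e-3)
        ae = allocate(fx.farm, SCENARIOS["TM_AE"], fx.average, fx.cfs).main
        for cat, target in FARM_TOTALS["TM_AE"].items():
            assert ae[cat] == pytest.approx(target, rel=5e-3)

    def test_round_trip_hits_the_stage_shares(self, fixtures_bundle):
        fx = fixtures_bundle
        report = contribution_by_stage(fx.farm, 1.0, fx.average, fx.cfs)
        assert report.shares.loc["feed_production", "LU"] == pytest.approx(0.999, abs=5e-4)
        assert report.shares.loc["feed_production", "MEP"] == pytest.approx(0.99, abs=5e-3)
        assert report.shares.loc["feed_production", "ADPfossil"] == pytest.approx(0.672, abs=2e-3)

    def test_farm_stage_targets_are_nonnegative_and_sum_to_gross(self, farm):
        targets, notes = farm_stage_targets(farm)
        from entolca.calibration_targets import FARM_TOTALS

        for cat in CATEGORIES:
            vals = [targets[s][cat] for s in targets]
            assert all(v >= 0 for v in vals)
            assert sum(vals) == pytest.approx(FARM_TOTALS["TM_AW"][cat], rel=1e-9)


class TestProfileSynthesis:
    def test_target_117_is_hit_within_tolerance(self):
        profile = profile_with_target_score(117.0)
        assert qnrf_score(profile).value == pytest.approx(117.0, abs=0.1)

    def test_zero_target_with_zero_template(self):
        zero = TEMPLATE_PROFILES["mealworm"].scaled(0.0)
        result = profile_with_target_score(0.0, template=zero)
        assert qnrf_score(result).value == pytest.approx(0.0, abs=0.1)

    def test_boundary_target_1100_under_cap(self):
        from entolca.nutrition import NutrientProfile, QUALIFYING_NUTRIENTS

        template = NutrientProfile(
            protein=10.0, diaas=1.0, qualifying={n: 1.0 for n in QUALIFYING_NUTRIENTS}
        )
        result = profile_with_target_score(1100.0, template=template)
        assert qnrf_score(result).value == pytest.approx(1100.0, abs=0.1)

    def test_unreachable_target_is_an_error(self):
        from entolca.nutrition import NutrientProfile

        template = NutrientProfile(protein=10.0, diaas=1.0)  # max 100 under cap
        with pytest.raises(ValueError, match="unreachable"):
            profile_with_target_score(500.0, template=template)

    def test_all_published_scores_are_reproduced(self):
        from entolca.calibration_targets import QNRF_SCORES

        profiles = nutrient_profiles(seed=0)
        for name, target in QNRF_SCORES.items():
            assert qnrf_score(profiles[name]).value == pytest.approx(target, abs=0.1)

    def test_profile_synthesis_is_seed_reproducible(self):
        a = profile_with_target_score(150.0, seed=5)
        b = profile_with_target_score(150.0, seed=5)
        assert a == b
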