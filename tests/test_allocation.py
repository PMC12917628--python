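"""Multifunctionality allocation: fractions, shared/specific split, scenarios."""

import numpy as np
import pytest

from entolca.allocation import (
    allocate,
    allocation_fractions,
    split_shared_specific,
    wheat_bran_upstream_allocation,
)
from entolca.core import CATEGORIES, SCENARIOS, ForegroundProcess, Product, ProductSystem
from entolca.tables import BackgroundIntensityTable, CharacterizationTable

FARM_COPRODUCTS = [
    ("yellow mealworm larvae", 1.0, 221.0),
    ("mealworm frass", 2.50, 24.4),
    ("dried mealworm residue", 0.0318, 24.4),
]


class TestFractions:
    def test_economic_fractions_of_the_farm(self):
        f = allocation_fractions(FARM_COPRODUCTS, "economic")
        assert f["yellow mealworm larvae"] == pytest.approx(0.7815, abs=1e-4)
        assert f["mealworm frass"] == pytest.approx(0.2158, abs=1e-4)
        assert f["dried mealworm residue"] == pytest.approx(0.0027, abs=1e-4)

    def test_mass_fractions_of_the_farm(self):
        f = allocation_fractions(FARM_COPRODUCTS, "mass")
        assert f["yellow mealworm larvae"] == pytest.approx(0.2832, abs=1e-4)
        assert f["mealworm frass"] == pytest.approx(0.7078, abs=1e-4)
        assert f["dried mealworm residue"] == pytest.approx(0.0090, abs=1e-4)

    def test_equal_prices_reduce_economic_to_mass(self):
        items = [("a", 2.0, 5.0), ("b", 3.0, 5.0)]
        econ = allocation_fractions(items, "economic")
        mass = allocation_fractions(items, "mass")
        assert econ == pytest.approx(mass)

    def test_fractions_sum_to_one(self):
        for basis in ("economic", "mass", "none"):
            f = allocation_fractions(FARM_COPRODUCTS, basis)
            assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_price_under_economic_basis(self):
        with pytest.raises(ValueError, match="prices"):
            allocation_fractions([("a", 1.0, None), ("b", 1.0, 2.0)], "economic")

    def test_zero_total_weight(self):
        with pytest.raises(ValueError, match="zero"):
            allocation_fractions([("a", 0.0, 0.0)], "mass")


class TestWheatBranUpstream:
    def test_flour_bran_split_matches_market_prices(self):
        f = wheat_bran_upstream_allocation(0.64, 0.18, 2.3646, 1.0)
        assert f["flour"] == pytest.approx(0.8937, abs=1e-4)
        assert f["bran"] == pytest.approx(0.1063, abs=1e-4)

    def test_equal_value_shares(self):
        f = wheat_bran_upstream_allocation(1.0, 1.0, 1.0, 1.0)
        assert f == pytest.approx({"flour": 0.5, "bran": 0.5})

    def test_worthless_bran_carries_nothing(self):
        f = wheat_bran_upstream_allocation(1.0, 0.0, 1.0, 1.0)
        assert f == pytest.approx({"flour": 1.0, "bran": 0.0})


class TestSharedSpecific:
    def test_all_stages_shared_means_zero_specific(self, farm, fixtures_bundle):
        from entolca.core import Scenario

        fx = fixtures_bundle
        everything = frozenset(
            {"feed_production", "rearing", "cleaning", "facilities_maintenance",
             "waste_management", "killing_blanching", "drying"}
        )
        scen = Scenario("TM_AE", "economic", everything)
        shared, specific = split_shared_specific(farm, scen, fx.average, fx.cfs)
        for vec in specific.values():
            assert np.allclose(vec.as_array(), 0.0)

    def test_shared_plus_specific_equals_gross(self, fixtures_bundle):
        from entolca.engine import compute_impacts

        fx = fixtures_bundle
        shared, specific = split_shared_specific(
            fx.farm, SCENARIOS["TM_AE"], fx.average, fx.cfs
        )
        total = shared
        for vec in specific.values():
            total = total + vec
        gross = compute_impacts(fx.farm, 1.0, fx.average, fx.cfs)
        assert total.isclose(gross, rtol=1e-9)

    def test_calibrated_shared_pool_matches_back_solved_value(self, fixtures_bundle):
        # economically allocated 1.45 out of gross 1.80 with larvae fraction
        # 0.7815 implies shared ~1.585 and larvae-specific ~0.21 (the drying
        # remainder is small), solved from f*S + K = 1.45, S + K + D = 1.80
        fx = fixtures_bundle
        shared, specific = split_shared_specific(
            fx.farm, SCENARIOS["TM_AE"], fx.average, fx.cfs
        )
        assert shared["GWP"] == pytest.approx(1.585, abs=0.01)
        assert specific["yellow mealworm larvae"]["GWP"] == pytest.approx(0.211, abs=0.005)


class TestAllocate:
    def test_economic_larvae_footprints(self, fixtures_bundle):
        fx = fixtures_bundle
        res = allocate(fx.farm, SCENARIOS["TM_AE"], fx.average, fx.cfs)
        assert res.main["GWP"] == pytest.approx(1.45, rel=5e-3)
        assert res.main["ADPfossil"] == pytest.approx(18.42, rel=5e-3)

    def test_mass_basis_larvae_footprint(self, fixtures_bundle):
        fx = fixtures_bundle
        res = allocate(fx.farm, SCENARIOS["TM_AM"], fx.average, fx.cfs)
        assert 0.65 <= res.main["GWP"] <= 0.67

    def test_conservation_across_bases(self, fixtures_bundle):
        fx = fixtures_bundle
        for name in ("TM_AE", "TM_AM", "TM_AW"):
            res = allocate(fx.farm, SCENARIOS[name], fx.average, fx.cfs)
            total = np.zeros(len(CATEGORIES))
            for vec in res.per_product.values():
                total += vec.as_array()
            assert np.allclose(total, res.gross.as_array(), rtol=1e-9)

    def test_basis_ordering_for_larvae(self, fixtures_bundle):
        fx = fixtures_bundle
        aw = allocate(fx.farm, SCENARIOS["TM_AW"], fx.average, fx.cfs).main
        ae = allocate(fx.farm, SCENARIOS["TM_AE"], fx.average, fx.cfs).main
        am = allocate(fx.farm, SCENARIOS["TM_AM"], fx.average, fx.cfs).main
        for cat in CATEGORIES:
            assert aw[cat] >= ae[cat] >= am[cat]

    def test_single_output_system_allocation_is_a_noop(self):
        proc = ForegroundProcess(
            id="p", stage_label="killing_blanching",
            outputs=[(Product("x", "kg", price=1.0), 1.0)],
            background_inputs=[("bg", 2.0)],
        )
        system = ProductSystem([proc], Product("x", "kg", price=1.0))
        bg = BackgroundIntensityTable.from_dict({"bg": {"GWP": 3.0}})
        cfs = CharacterizationTable.zeros(["N2O"])
        for name in ("TM_AE", "TM_AM", "TM_AW"):
            res = allocate(system, SCENARIOS[name], bg, cfs)
            assert res.main["GWP"] == pytest.approx(6.0)

    def test_main_allocated_share_monotone_in_fraction(self, fixtures_bundle):
        # larger larvae fraction (economic > mass) never decreases the
        # allocated larvae burden while the shared pool is fixed
        fx = fixtures_bundle
        ae = allocate(fx.farm, SCENARIOS["TM_AE"], fx.average, fx.cfs)
        am = allocate(fx.farm, SCENARIOS["TM_AM"], fx.average, fx.cfs)
        f_ae = ae.fractions["yellow mealworm larvae"]
        f_am = am.fractions["yellow mealworm larvae"]
        assert f_ae > f_am
        for cat in CATEGORIES:
            assert ae.main[cat] >= am.main[cat]

    def test_expansion_scenario_is_rejected(self, fixtures_bundle):
        fx = fixtures_bundle
        with pytest.raises(ValueError, match="expansion"):
            allocate(fx.farm, SCENARIOS["TM_C"], fx.average, fx.cfs)
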