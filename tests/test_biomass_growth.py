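"""Growth curves, allocation, pool assignment, and the non-arbour pathway."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbmcn.biomass_growth import (
    AllocationModel,
    DegenerateAllocationError,
    GrowthCurve,
    NonArbourSeries,
    RootModel,
    aboveground_components,
    age_group,
    assign_biomass_pools,
    belowground_components,
    biomass_to_carbon,
    live_carbon,
    net_growth_increment,
    nonarbour_biomass,
    stand_volume,
)
from cbmcn.model_core import LIVE_POOLS, PoolVector, StandRecord


class TestGrowthCurves:
    @pytest.mark.parametrize(
        "family,coefs",
        [
            ("richards", (300.0, 0.05, 2.0)),
            ("logistic", (250.0, 20.0, 0.1)),
            ("korf", (350.0, 8.0, 1.2)),
            ("tabulated", (10.0, 50.0, 40.0, 200.0, 120.0, 320.0)),
        ],
    )
    def test_zero_at_age_zero_and_nonnegative(self, family, coefs):
        c = GrowthCurve("k", family, coefs, max_age=200)
        assert c.volume(0) == 0.0
        ages = np.arange(0, 201)
        vols = [c.volume(a) for a in ages]
        assert min(vols) >= 0.0

    def test_richards_closed_form(self):
        c = GrowthCurve("k", "richards", (300.0, 0.05, 2.0), max_age=200)
        expected = 300.0 * (1.0 - math.exp(-0.05 * 20)) ** 2  # direct evaluation
        assert stand_volume(c, 20) == pytest.approx(expected, rel=1e-12)

    def test_clamped_beyond_max_age(self):
        c = GrowthCurve("k", "richards", (300.0, 0.05, 2.0), max_age=200)
        assert stand_volume(c, 500) == stand_volume(c, 200)

    def test_tabulated_linear_interpolation(self):
        c = GrowthCurve("k", "tabulated", (10.0, 100.0, 20.0, 300.0), max_age=50)
        assert c.volume(15) == pytest.approx(200.0)
        assert c.volume(5) == pytest.approx(50.0)  # implied (0, 0) anchor


class TestAllocation:
    def test_zero_volume_gives_all_zero_components(self):
        m = AllocationModel("x", 0.4, 1.0, {k: (0.0, 0.0) for k in ("stemwood", "bark", "branches", "foliage")})
        assert aboveground_components(m, 0.0) == {"stemwood": 0.0, "bark": 0.0, "branches": 0.0, "foliage": 0.0}

    def test_zero_logits_give_equal_quarters(self):
        m = AllocationModel("x", 0.4, 1.0, {k: (0.0, 0.0) for k in ("stemwood", "bark", "branches", "foliage")})
        comps = aboveground_components(m, 50.0)
        b_stem = 0.4 * 50.0
        assert comps["stemwood"] == pytest.approx(b_stem)
        assert sum(comps.values()) == pytest.approx(4.0 * b_stem)

    def test_manual_softmax_oracle(self):
        # independent evaluation: a=0.1, b=0.9, V=100, z = (1, 0, -1, -2)
        m = AllocationModel(
            "x", 0.1, 0.9,
            {"stemwood": (1.0, 0.0), "bark": (0.0, 0.0), "branches": (-1.0, 0.0), "foliage": (-2.0, 0.0)},
        )
        e = [math.exp(z) for z in (1.0, 0.0, -1.0, -2.0)]
        p = [x / sum(e) for x in e]
        b_stem = 0.1 * 100.0**0.9
        agb = b_stem / p[0]
        comps = aboveground_components(m, 100.0)
        for name, pk in zip(("stemwood", "bark", "branches", "foliage"), p):
            assert comps[name] == pytest.approx(pk * agb, rel=1e-12)

    @given(volume=st.floats(0.01, 2000.0))
    @settings(deadline=None, max_examples=50)
    def test_proportions_sum_to_one_for_any_volume(self, volume):
        m = AllocationModel(
            "x", 0.4, 0.95,
            {"stemwood": (0.0, 0.0), "bark": (-2.2, 0.0), "branches": (-1.5, -0.02), "foliage": (-1.3, -0.2)},
        )
        p = m.proportions(volume)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 < v < 1.0 for v in p.values())

    def test_degenerate_stem_proportion_raises(self):
        m = AllocationModel(
            "x", 0.4, 1.0,
            {"stemwood": (-30.0, 0.0), "bark": (0.0, 0.0), "branches": (0.0, 0.0), "foliage": (0.0, 0.0)},
        )
        with pytest.raises(DegenerateAllocationError):
            aboveground_components(m, 100.0)


class TestRoots:
    def test_softwood_default_oracle(self):
        rm = RootModel("softwood", "linear", 0.222, 1.0)
        coarse, fine = belowground_components(rm, 100.0)
        total = 0.222 * 100.0
        f = 0.072 + 0.354 * math.exp(-0.06 * total)
        assert coarse + fine == pytest.approx(total, rel=1e-12)
        assert fine == pytest.approx(total * f, rel=1e-12)

    def test_hardwood_power_form(self):
        rm = RootModel("hardwood", "power", 1.576, 0.615)
        coarse, fine = belowground_components(rm, 100.0)
        assert coarse + fine == pytest.approx(1.576 * 100.0**0.615, rel=1e-12)

    def test_zero_agb_gives_zero_roots(self):
        rm = RootModel("softwood", "linear", 0.222, 1.0)
        assert belowground_components(rm, 0.0) == (0.0, 0.0)

    def test_fine_fraction_decreases_with_root_mass(self):
        rm = RootModel("softwood", "linear", 0.222, 1.0)
        grid = np.linspace(0.1, 200.0, 100)
        fracs = [rm.fine_fraction(r) for r in grid]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestAgeGroups:
    SCHEDULE = {"sp": (10, 20, 30, 40)}

    @pytest.mark.parametrize("age,expected", [(0, "YF"), (9, "YF"), (10, "MAF"), (30, "MF"), (100, "PMF")])
    def test_examples(self, age, expected):
        assert age_group(self.SCHEDULE, "sp", age) == expected

    def test_boundary_belongs_to_older_group_exhaustively(self):
        # independent scan: count of thresholds reached defines the group
        for age in range(0, 51):
            expected = ["YF", "MAF", "NMF", "MF", "PMF"][sum(age >= t for t in (10, 20, 30, 40))]
            assert age_group(self.SCHEDULE, "sp", age) == expected

    def test_unknown_species_raises(self):
        with pytest.raises(KeyError):
            age_group(self.SCHEDULE, "nope", 5)


class TestPoolAssignment:
    COMPONENTS = {"stemwood": 8.0, "bark": 2.0, "branches": 2.0, "foliage": 1.5}
    ROOTS = (2.0, 0.5)

    def test_young_stand_has_no_merchantable_pool(self):
        pv = assign_biomass_pools(self.COMPONENTS, self.ROOTS, "YF", 0.9)
        assert pv["merchantable_stemwood"] == 0.0
        assert pv["other_wood"] == pytest.approx(12.0)

    def test_mature_stand_splits_by_merch_proportion(self):
        pv = assign_biomass_pools(self.COMPONENTS, self.ROOTS, "MF", 0.9)
        assert pv["merchantable_stemwood"] == pytest.approx(9.0)
        assert pv["other_wood"] == pytest.approx(1.0 + 2.0)

    @pytest.mark.parametrize("group", ["YF", "MAF", "NMF", "MF", "PMF"])
    def test_total_mass_conserved_exactly(self, group):
        pv = assign_biomass_pools(self.COMPONENTS, self.ROOTS, group, 0.8)
        total_in = sum(self.COMPONENTS.values()) + sum(self.ROOTS)
        assert pv.total_live() == pytest.approx(total_in, rel=1e-15)

    def test_nmf_to_mf_boundary_moves_stem_mass_without_changing_total(self):
        nmf = assign_biomass_pools(self.COMPONENTS, self.ROOTS, "NMF", 0.85)
        mf = assign_biomass_pools(self.COMPONENTS, self.ROOTS, "MF", 0.85)
        assert nmf.total_live() == pytest.approx(mf.total_live(), rel=1e-15)
        assert mf["merchantable_stemwood"] > 0.0 == nmf["merchantable_stemwood"]


class TestNonArbour:
    def _series(self, species="shrub_mixed", maturity=6):
        return NonArbourSeries(
            species=species,
            maturity_age=maturity,
            ages=np.array([2.0, 6.0]),
            agb_pua=np.array([8.0, 24.0]),
            bgb_pua=np.array([2.0, 6.0]),
            alloc=np.tile([0.5, 0.15, 0.15, 0.15, 0.05], (2, 1)),
        )

    def test_linear_interpolation_between_tabulated_ages(self):
        s = self._series()
        agb, bgb = s.biomass_pua(4)
        assert agb + bgb == pytest.approx(20.0)  # midpoint of 10 and 30 total

    def test_constant_at_and_after_maturity(self):
        s = self._series()
        ref = nonarbour_biomass(s, 6, 2.0).data
        for age in (6, 7, 20, 100):
            np.testing.assert_array_equal(nonarbour_biomass(s, age, 2.0).data, ref)

    def test_zero_below_first_tabulated_age(self):
        s = self._series()
        assert nonarbour_biomass(s, 0, 1.0).total_live() == 0.0
        assert nonarbour_biomass(s, 1, 1.0).total_live() == 0.0

    def test_bamboo_stem_is_merchantable_only_at_maturity(self):
        s = self._series(species="moso_bamboo")
        young = nonarbour_biomass(s, 3, 1.0, forest_type="bamboo")
        mature = nonarbour_biomass(s, 6, 1.0, forest_type="bamboo")
        assert young["merchantable_stemwood"] == 0.0
        assert mature["merchantable_stemwood"] > 0.0

    def test_scaled_by_area_and_nondecreasing_before_maturity(self):
        s = self._series()
        one = nonarbour_biomass(s, 4, 1.0).total_live()
        five = nonarbour_biomass(s, 4, 5.0).total_live()
        assert five == pytest.approx(5.0 * one, rel=1e-12)
        totals = [nonarbour_biomass(s, a, 1.0).total_live() for a in range(0, 7)]
        assert all(b >= a for a, b in zip(totals, totals[1:]))


class TestCarbonConversion:
    def test_half_content_halves_every_pool(self):
        pv = PoolVector.zeros()
        pv["other_wood"] = 10.0
        pv["foliage"] = 4.0
        table = {("sp", comp): 0.5 for comp in LIVE_POOLS}
        out = biomass_to_carbon(pv, table, "sp")
        assert out["other_wood"] == 5.0 and out["foliage"] == 2.0

    def test_component_specific_contents_multiply_elementwise(self):
        pv = PoolVector.zeros()
        pv["merchantable_stemwood"] = 10.0
        pv["foliage"] = 10.0
        table = {("sp", comp): 0.47 for comp in LIVE_POOLS}
        table[("sp", "foliage")] = 0.52
        out = biomass_to_carbon(pv, table, "sp")
        assert out["merchantable_stemwood"] == pytest.approx(4.7)
        assert out["foliage"] == pytest.approx(5.2)

    def test_zero_biomass_gives_zero_carbon(self):
        table = {("sp", comp): 0.5 for comp in LIVE_POOLS}
        assert biomass_to_carbon(PoolVector.zeros(), table, "sp").total_live() == 0.0


class TestNetGrowthIncrement:
    def _stand(self, params, age):
        key = next(iter(params.growth_curves))
        species, zone, sq, origin, rocky = key.split("|")
        return StandRecord(
            stand_id="G1", spu_id="1", species=species,
            genus_class="softwood" if species in ("chinese_fir", "masson_pine", "cypress") else "hardwood",
            forest_type="arbour", origin=origin, land_use="forest", age=age, area=3.0,
            climatic_zone=zone, site_quality=sq, rocky_desertification=rocky,
        )

    def test_matches_independent_two_point_evaluation(self, params):
        stand = self._stand(params, 10)
        delta = net_growth_increment(stand, params)
        oracle = np.maximum(live_carbon(stand, params, 11) - live_carbon(stand, params, 10), 0.0)
        np.testing.assert_allclose(delta.data[:5], oracle, rtol=1e-12)

    def test_flat_curve_region_gives_zero_delta(self, params):
        stand = self._stand(params, 500)
        assert net_growth_increment(stand, params).total_live() == 0.0

    def test_deltas_are_never_negative(self, params):
        for age in (1, 5, 17, 24, 25, 40, 80):
            delta = net_growth_increment(self._stand(params, age), params)
            assert (delta.data[:5] >= 0.0).all()

    def test_arbour_pathway_zero_volume_gives_zero_pools(self, params):
        stand = self._stand(params, 0)
        assert live_carbon(stand, params, 0).sum() == 0.0
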