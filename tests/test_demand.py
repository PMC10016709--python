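"""Reef demand geometry and sweep clustering."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coralplan as cp
from coralplan.demand import DemandParams, Reef


def reef(id="r", lat=-18.0, lon=147.0, area=1.0) -> Reef:
    return Reef(id=id, lat=lat, lon=lon, area=area)


class TestRadius:
    def test_inverse_of_disc_area(self):
        area_km2 = math.pi * 200**2 * 1e-6
        assert cp.reef_radius(area_km2) == pytest.approx(200.0)

    def test_one_square_metre(self):
        assert cp.reef_radius(1e-6) == pytest.approx(math.sqrt(1 / math.pi), abs=1e-4)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            cp.reef_radius(0.0)
        with pytest.raises(ValueError):
            reef(area=-1.0)


class TestDemand:
    def test_annulus_branch(self):
        # radius 200 m, 20 m band centred on the perimeter
        r = reef(area=math.pi * 200**2 * 1e-6)
        expected = math.pi * (210**2 - 190**2)
        assert cp.reef_demand(r) == pytest.approx(expected)
        assert cp.reef_demand(r) == pytest.approx(25132.74, rel=1e-6)

    def test_disc_branch_for_small_reefs(self):
        r = reef(area=math.pi * 50**2 * 1e-6)
        assert cp.reef_demand(r) == pytest.approx(math.pi * 60**2)

    def test_zero_density_zero_demand(self):
        assert cp.reef_demand(reef(), DemandParams(d_c=0.0)) == 0.0

    def test_density_scales_linearly(self):
        r = reef(area=2.0)
        assert cp.reef_demand(r, DemandParams(d_c=3.0)) == pytest.approx(
            3.0 * cp.reef_demand(r)
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        a1=st.floats(0.05, 50.0),
        da=st.floats(0.01, 50.0),
    )
    def test_annulus_demand_monotone_in_area(self, a1, da):
        d1 = cp.reef_demand(reef(area=a1))
        d2 = cp.reef_demand(reef(area=a1 + da))
        assert d1 <= d2 + 1e-9


def _reefs_with_demands(demands_north_to_south):
    """Reefs on a meridian, latitudes descending, with forced demands."""
    return (
        [
            reef(id=f"r{k}", lat=-10.0 - k, lon=147.0)
            for k in range(len(demands_north_to_south))
        ],
        list(demands_north_to_south),
    )


class TestSweep:
    def test_greedy_accumulation_trace(self):
        reefs, demands = _reefs_with_demands([100e3, 200e3, 400e3])
        clusters = cp.sweep_cluster(reefs, s_c=432e3, demands=demands)
        assert [c.member_reef_ids for c in clusters] == [("r0", "r1"), ("r2",)]
        assert clusters[0].annual_demand == pytest.approx(300e3)

    def test_oversize_reef_forms_singleton(self):
        reefs, demands = _reefs_with_demands([900e3])
        clusters = cp.sweep_cluster(reefs, s_c=432e3, demands=demands)
        assert len(clusters) == 1
        assert clusters[0].member_reef_ids == ("r0",)
        assert clusters[0].annual_demand > 432e3

    def test_zero_demand_reefs_form_one_cluster(self):
        reefs, demands = _reefs_with_demands([0.0, 0.0, 0.0, 0.0])
        clusters = cp.sweep_cluster(reefs, s_c=432e3, demands=demands)
        assert len(clusters) == 1
        assert len(clusters[0].member_reef_ids) == 4

    def test_empty_input_empty_output(self):
        assert cp.sweep_cluster([], s_c=432e3) == []

    def test_demand_conserved_and_capacity_respected(self, synthetic_field):
        reefs = cp.select_reef_subset(synthetic_field, 50, seed=3)
        s_c = 432e3
        clusters = cp.sweep_cluster(reefs, s_c=s_c)
        total_reef = sum(cp.reef_demand(r) for r in reefs)
        total_cluster = sum(c.annual_demand for c in clusters)
        assert total_cluster == pytest.approx(total_reef, rel=1e-12)
        for c in clusters:
            if len(c.member_reef_ids) > 1:
                assert c.annual_demand <= s_c * (1 + 1e-12)

    def test_members_latitude_contiguous_in_sweep_order(self, synthetic_field):
        reefs = cp.select_reef_subset(synthetic_field, 40, seed=5)
        clusters = cp.sweep_cluster(reefs, s_c=432e3)
        lat_of = {r.id: r.lat for r in reefs}
        seen = [lat_of[rid] for c in clusters for rid in c.member_reef_ids]
        assert seen == sorted(seen, reverse=True)

    def test_centroid_is_member_mean(self):
        reefs, demands = _reefs_with_demands([1.0, 1.0])
        clusters = cp.sweep_cluster(reefs, s_c=10.0, demands=demands)
        assert clusters[0].centroid_lat == pytest.approx(-10.5)
        assert clusters[0].centroid_lon == pytest.approx(147.0)


class TestAllowance:
    def test_singleton_allowance_zero(self):
        reefs, demands = _reefs_with_demands([1.0])
        (c,) = cp.sweep_cluster(reefs, s_c=10.0, demands=demands)
        assert c.intra_allowance_km == pytest.approx(0.0, abs=1e-9)
        assert cp.intra_cluster_allowance(c, reefs) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_pair_allowance_equals_round_trip(self):
        # two reefs on the equator; centroid midway on the same great circle
        r1 = reef(id="a", lat=0.0, lon=147.0)
        r2 = reef(id="b", lat=0.0, lon=147.2)
        clusters = cp.sweep_cluster([r1, r2], s_c=10.0, demands=[1.0, 1.0])
        sep = cp.haversine_km(r1.lat, r1.lon, r2.lat, r2.lon)
        assert clusters[0].intra_allowance_km == pytest.approx(2 * sep, rel=1e-9)

    def test_three_collinear_reefs(self):
        rs = [reef(id=f"r{k}", lat=0.0, lon=147.0 + 0.1 * k) for k in range(3)]
        clusters = cp.sweep_cluster(rs, s_c=10.0, demands=[1.0] * 3)
        span = cp.haversine_km(0.0, 147.0, 0.0, 147.2)
        # star tour: 2 * (half-span + 0 + half-span)
        assert clusters[0].intra_allowance_km == pytest.approx(2 * span, rel=1e-9)

    def test_unknown_member_rejected(self):
        reefs, demands = _reefs_with_demands([1.0])
        (c,) = cp.sweep_cluster(reefs, s_c=10.0, demands=demands)
        with pytest.raises(ValueError):
            cp.intra_cluster_allowance(c, [])


class TestSubset:
    def test_full_sample_is_identity_as_set(self, synthetic_field):
        sub = cp.select_reef_subset(synthetic_field, len(synthetic_field), seed=0)
        assert {r.id for r in sub} == {r.id for r in synthetic_field}

    def test_same_seed_same_subset(self, synthetic_field):
        a = cp.select_reef_subset(synthetic_field, 50, seed=11)
        b = cp.select_reef_subset(synthetic_field, 50, seed=11)
        assert [r.id for r in a] == [r.id for r in b]

    def test_fifty_distinct_ids(self, synthetic_field):
        sub = cp.select_reef_subset(synthetic_field, 50, seed=2)
        assert len({r.id for r in sub}) == 50

    def test_oversample_rejected(self, synthetic_field):
        with pytest.raises(ValueError):
            cp.select_reef_subset(synthetic_field[:10], 11, seed=0)
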