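import math

import numpy as np
import pytest

from healthaccess.access_metrics import (
    apc,
    binary_access_mask,
    build_report,
    classify_heatmap,
    red_zone_population,
    travel_time_summary,
    weighted_quantile,
)
from healthaccess.raster_core import AlignmentError, GridSpec, Raster


def tt_raster(values, spec=None, cell=1000.0):
    values = np.asarray(values, dtype=float)
    spec = spec or GridSpec(*values.shape, cell, y_origin=values.shape[0] * cell)
    return Raster(spec, values, "travel_time")


def pop_raster(values, spec):
    return Raster(spec, np.asarray(values, dtype=float), "population")


@pytest.fixture(scope="module")
def seeded_surfaces():
    """48x48 random travel-time + population pair used by the oracle checks."""
    rng = np.random.default_rng(21)
    spec = GridSpec(48, 48, 1000.0, y_origin=48_000.0)
    tt_vals = rng.exponential(scale=60.0, size=(48, 48))
    tt_vals[rng.random((48, 48)) < 0.02] = np.inf  # a few unreachable cells
    pop_vals = rng.lognormal(mean=3.0, sigma=1.5, size=(48, 48))
    pop_vals[rng.random((48, 48)) < 0.05] = 0.0
    return tt_raster(tt_vals, spec), pop_raster(pop_vals, spec)


class TestBinaryAccessMask:
    def test_all_zero_tt(self):
        tt = tt_raster(np.zeros((2, 2)))
        mask = binary_access_mask(tt, 30.0)
        assert (mask.values == 1).all()

    def test_threshold_inclusive(self):
        tt = tt_raster([[30.0, 30.0 + 1e-9]])
        mask = binary_access_mask(tt, 30.0)
        assert mask.values[0, 0] == 1
        assert mask.values[0, 1] == 0

    def test_matches_elementwise_oracle(self, seeded_surfaces):
        tt, _ = seeded_surfaces
        mask = binary_access_mask(tt, 45.0)
        expected = (tt.values <= 45.0).astype(int)
        np.testing.assert_array_equal(mask.values, expected)

    def test_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            binary_access_mask(tt_raster(np.zeros((1, 1))), 0.0)


class TestApc:
    def test_everything_covered(self):
        spec = GridSpec(2, 2, 1000.0, y_origin=2000.0)
        tt = tt_raster(np.full((2, 2), 10.0), spec)
        pop = pop_raster(np.full((2, 2), 5.0), spec)
        assert apc(tt, pop, 30.0) == 100.0

    def test_hand_arithmetic(self):
        spec = GridSpec(1, 2, 1000.0, y_origin=1000.0)
        tt = tt_raster([[10.0, 90.0]], spec)
        pop = pop_raster([[30.0, 70.0]], spec)
        assert apc(tt, pop, 30.0) == 30.0

    def test_matches_flat_loop_oracle(self, seeded_surfaces):
        tt, pop = seeded_surfaces
        for thr in (30.0, 60.0, 120.0):
            num = den = 0.0
            for r in range(48):
                for c in range(48):
                    den += pop.values[r, c]
                    if tt.values[r, c] <= thr:
                        num += pop.values[r, c]
            expected = 100.0 * num / den
            got = apc(tt, pop, thr, rounded=False)
            assert math.isclose(got, expected, rel_tol=1e-12)

    def test_zero_population_flagged(self):
        spec = GridSpec(1, 1, 1000.0, y_origin=1000.0)
        tt = tt_raster([[5.0]], spec)
        pop = pop_raster([[0.0]], spec)
        with pytest.raises(ValueError, match="zero"):
            apc(tt, pop, 30.0)

    def test_misaligned(self):
        tt = tt_raster(np.zeros((2, 2)))
        pop = pop_raster(np.ones((2, 2)), GridSpec(2, 2, 1000.0, x_origin=5.0, y_origin=2000.0))
        with pytest.raises(AlignmentError):
            apc(tt, pop, 30.0)


def sort_scan_quantile(values, weights, q):
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for v, w in pairs:
        cum += w
        if cum >= q * total:
            return v
    return pairs[-1][0]


class TestTravelTimeSummary:
    def test_constant_surface(self):
        spec = GridSpec(3, 3, 1000.0, y_origin=3000.0)
        tt = tt_raster(np.full((3, 3), 42.0), spec)
        pop = pop_raster(np.ones((3, 3)), spec)
        s = travel_time_summary(tt, pop)
        assert s["median"] == 42.0 and s["q1"] == 42.0 and s["q3"] == 42.0
        assert s["sd"] == 0.0 and s["mean"] == 42.0

    def test_three_cells_median(self):
        spec = GridSpec(1, 3, 1000.0, y_origin=1000.0)
        tt = tt_raster([[10.0, 20.0, 90.0]], spec)
        pop = pop_raster([[1.0, 1.0, 1.0]], spec)
        assert travel_time_summary(tt, pop)["median"] == 20.0

    def test_weighted_median_matches_sort_scan_oracle(self, seeded_surfaces):
        tt, pop = seeded_surfaces
        s = travel_time_summary(tt, pop)
        sel = pop.values > 0
        vals = tt.values[sel].tolist()
        w = pop.values[sel].tolist()
        for key, q in (("q1", 0.25), ("median", 0.5), ("q3", 0.75)):
            assert s[key] == sort_scan_quantile(vals, w, q)

    def test_pixel_weighting(self, seeded_surfaces):
        tt, pop = seeded_surfaces
        s = travel_time_summary(tt, weighting="pixel")
        flat = np.sort(tt.values.ravel())
        assert s["median"] == sort_scan_quantile(flat.tolist(), [1.0] * flat.size, 0.5)

    def test_quartile_ordering(self, seeded_surfaces):
        tt, pop = seeded_surfaces
        s = travel_time_summary(tt, pop)
        assert s["q1"] <= s["median"] <= s["q3"]

    def test_inf_cells_push_mean_not_median(self):
        spec = GridSpec(1, 5, 1000.0, y_origin=1000.0)
        tt = tt_raster([[1.0, 2.0, 3.0, 4.0, np.inf]], spec)
        pop = pop_raster([[1.0] * 5], spec)
        s = travel_time_summary(tt, pop)
        assert math.isinf(s["mean"])
        assert s["median"] == 3.0

    def test_empty_stratum(self):
        spec = GridSpec(1, 1, 1000.0, y_origin=1000.0)
        tt = tt_raster([[5.0]], spec)
        pop = pop_raster([[0.0]], spec)
        with pytest.raises(ValueError, match="empty"):
            travel_time_summary(tt, pop)


class TestWeightedQuantile:
    def test_left_continuous_step_inverse(self):
        # smallest v with cumulative weight >= q * W
        assert weighted_quantile([1.0, 2.0, 3.0], [1.0, 1.0, 2.0], 0.5) == 2.0
        assert weighted_quantile([1.0, 2.0, 3.0], [1.0, 1.0, 2.0], 0.51) == 3.0

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            weighted_quantile([1.0], [1.0], 1.5)


class TestRedZone:
    def test_all_within_60(self):
        spec = GridSpec(2, 2, 1000.0, y_origin=2000.0)
        tt = tt_raster(np.full((2, 2), 59.0), spec)
        pop = pop_raster(np.full((2, 2), 7.0), spec)
        assert red_zone_population(tt, pop) == 0.0

    def test_complement_identity(self, seeded_surfaces):
        tt, pop = seeded_surfaces
        total = pop.values.sum()
        within = pop.values[tt.values <= 60.0].sum()
        red = red_zone_population(tt, pop)
        assert math.isclose(red + within, total, rel_tol=1e-12)

    def test_matches_naive_loop(self, seeded_surfaces):
        tt, pop = seeded_surfaces
        expected = 0.0
        for r in range(48):
            for c in range(48):
                if tt.values[r, c] > 60.0:
                    expected += pop.values[r, c]
        assert math.isclose(red_zone_population(tt, pop), expected, rel_tol=1e-12)


class TestClassifyHeatmap:
    @pytest.mark.parametrize(
        "value,expected",
        [(10.0, 1), (15.0, 1), (15.0001, 2), (30.0, 2), (45.0, 3),
         (60.0, 3), (60.0001, 4), (np.inf, 4)],
    )
    def test_band_boundaries(self, value, expected):
        heat = classify_heatmap(tt_raster([[value]]))
        assert heat.values[0, 0] == expected

    def test_class_counts_match_histogram_oracle(self, seeded_surfaces):
        tt, _ = seeded_surfaces
        heat = classify_heatmap(tt)
        v = tt.values
        expected = [
            (v <= 15).sum(),
            ((v > 15) & (v <= 30)).sum(),
            ((v > 30) & (v <= 60)).sum(),
            (v > 60).sum(),
        ]
        for cls, n in zip((1, 2, 3, 4), expected):
            assert (heat.values == cls).sum() == n

    def test_classes_partition_cells(self, seeded_surfaces):
        tt, _ = seeded_surfaces
        heat = classify_heatmap(tt)
        assert np.isin(heat.values, (1, 2, 3, 4)).all()

    def test_class4_population_equals_red_zone(self, seeded_surfaces):
        tt, pop = seeded_surfaces
        heat = classify_heatmap(tt)
        class4_pop = pop.values[heat.values == 4].sum()
        assert math.isclose(class4_pop, red_zone_population(tt, pop), rel_tol=1e-12)


@pytest.fixture(scope="module")
def world():
    rng = np.random.default_rng(33)
    spec = GridSpec(24, 24, 1000.0, y_origin=24_000.0)
    tt = tt_raster(rng.exponential(60.0, (24, 24)), spec)
    pop = pop_raster(rng.lognormal(3, 1, (24, 24)), spec)
    zones = Raster(spec, (np.arange(24 * 24).reshape(24, 24) // 192), "zone")
    urban = Raster(spec, (rng.random((24, 24)) < 0.3).astype(int), "mask")
    return tt, pop, zones, urban


class TestBuildReport:
    def test_single_zone_all_covered(self):
        spec = GridSpec(2, 2, 1000.0, y_origin=2000.0)
        tt = tt_raster(np.full((2, 2), 5.0), spec)
        pop = pop_raster(np.ones((2, 2)), spec)
        zones = Raster(spec, np.zeros((2, 2), dtype=int), "zone")
        rep = build_report(tt, pop, zones)
        row = rep[(rep.zone == 0) & (rep.settlement == "total")].iloc[0]
        assert row["apc_30"] == row["apc_60"] == row["apc_120"] == 100.0

    def test_row_count(self, world):
        tt, pop, zones, urban = world
        rep = build_report(tt, pop, zones, urban)
        n_zones = len(np.unique(zones.values))
        assert len(rep) == (n_zones + 1) * 3

    def test_national_apc_is_weighted_combination_of_zones(self, world):
        tt, pop, zones, urban = world
        num = den = 0.0
        for code in np.unique(zones.values):
            sel = zones.values == code
            den += pop.values[sel].sum()
            num += pop.values[sel & (tt.values <= 60.0)].sum()
        expected = 100.0 * num / den
        got = apc(tt, pop, 60.0, rounded=False)
        assert math.isclose(got, expected, rel_tol=1e-12)

    def test_report_matches_individual_operations(self, world):
        tt, pop, zones, urban = world
        rep = build_report(tt, pop, zones, urban).set_index(["zone", "settlement"])
        urban_sel = urban.values == 1
        for code in np.unique(zones.values):
            sel = (zones.values == code) & urban_sel
            mask = Raster(tt.spec, sel.astype(int), "mask")
            row = rep.loc[(code, "urban")]
            if row["flag"] == "zero_population":
                continue
            assert row["apc_30"] == apc(tt, pop, 30.0, mask)
            s = travel_time_summary(tt, pop, mask)
            assert row["median_tt"] == s["median"]
            assert row["q1_tt"] == s["q1"]

    def test_zero_population_zone_flagged_not_dropped(self):
        spec = GridSpec(1, 2, 1000.0, y_origin=1000.0)
        tt = tt_raster([[5.0, 10.0]], spec)
        pop = pop_raster([[0.0, 9.0]], spec)
        zones = Raster(spec, np.array([[0, 1]]), "zone")
        rep = build_report(tt, pop, zones)
        row = rep[(rep.zone == 0) & (rep.settlement == "total")].iloc[0]
        assert row["flag"] == "zero_population"
        assert math.isnan(row["apc_30"])

    def test_bad_thresholds(self, world):
        tt, pop, zones, urban = world
        with pytest.raises(ValueError):
            build_report(tt, pop, thresholds=(60.0, 30.0))

    def test_apc_monotone_in_threshold_every_stratum(self, world):
        tt, pop, zones, urban = world
        rep = build_report(tt, pop, zones, urban)
        ok = rep[rep.flag == ""]
        assert (ok["apc_30"] <= ok["apc_60"]).all()
        assert (ok["apc_60"] <= ok["apc_120"]).all()

    def test_rural_urban_numerators_sum_to_total(self, world):
        tt, pop, zones, urban = world
        urban_sel = urban.values == 1
        for code in np.unique(zones.values):
            zsel = zones.values == code
            for thr in (30.0, 60.0, 120.0):
                cov = tt.values <= thr
                total_num = pop.values[zsel & cov].sum()
                rural_num = pop.values[zsel & ~urban_sel & cov].sum()
                urban_num = pop.values[zsel & urban_sel & cov].sum()
                assert math.isclose(rural_num + urban_num, total_num, rel_tol=1e-12)
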