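"""Area accounting, trend correlations and transition matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lulcpipe.change import (
    class_area_series, percent_point_change, transition_matrix,
    trend_correlation,
)
from lulcpipe.scheme import (
    FOREST, GRASSLAND, PIXEL_AREA_KM2, SECONDARY, WATER, WOODY,
)
from lulcpipe.splitting import RefinedMaps, refine_truth


def _refined_uniform(cls, years=(2002, 2003, 2004), shape=(100, 100)):
    maps = {y: np.full(shape, cls, dtype=np.int8) for y in years}
    return RefinedMaps(maps=maps, woody_history=np.zeros(shape, np.uint32),
                       input_years=(years[0] - 1,) + tuple(years))


class TestAreaSeries:
    def test_uniform_forest_region(self):
        series = class_area_series(_refined_uniform(FOREST))
        forest = series[(series["class"] == "forest")
                        & (series["year"] == 2002)]
        assert forest["area_km2"].iloc[0] == pytest.approx(
            10_000 * PIXEL_AREA_KM2)
        others = series[(series["class"] != "forest")
                        & (series["year"] == 2002)]
        assert (others["area_km2"] == 0).all()

    def test_totals_conserved_across_years(self, small_truth):
        refined = refine_truth(small_truth)
        series = class_area_series(refined)
        totals = series.groupby("year")["area_km2"].sum()
        expected = small_truth.shape[0] * small_truth.shape[1] \
            * PIXEL_AREA_KM2
        np.testing.assert_allclose(totals.to_numpy(), expected)

    def test_matches_bruteforce_pixel_counting(self, small_truth):
        refined = refine_truth(small_truth)
        series = class_area_series(refined)
        y = refined.years[0]
        for code in (FOREST, SECONDARY, GRASSLAND, WATER):
            n = int((refined.maps[y] == code).sum())
            row = series[(series["year"] == y) & (series["code"] == code)]
            assert row["n_pixels"].iloc[0] == n

    def test_empty_region_rejected(self):
        refined = _refined_uniform(FOREST, shape=(5, 5))
        with pytest.raises(ValueError, match="empty region"):
            class_area_series(refined, region_mask=np.zeros((5, 5), bool))


def _series_from_values(values, years, cls="forest"):
    return pd.DataFrame({
        "region": "all", "year": years, "class": cls,
        "code": FOREST, "n_pixels": 0, "area_km2": values})


class TestTrendCorrelation:
    def test_strictly_increasing_r_is_one(self):
        years = list(range(2002, 2011))
        s = _series_from_values(np.arange(9) * 3.0 + 1, years)
        tr = trend_correlation(s, (2002, 2010), "forest", seed=1)
        assert tr.r == pytest.approx(1.0)
        assert tr.p_permutation < 0.01

    def test_symmetric_tent_r_is_zero(self):
        s = _series_from_values([1, 2, 3, 2, 1], list(range(2002, 2007)))
        tr = trend_correlation(s, (2002, 2006), "forest", seed=2)
        assert tr.r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_reported_as_no_trend(self):
        s = _series_from_values([5.0] * 6, list(range(2002, 2008)))
        tr = trend_correlation(s, (2002, 2007), "forest", seed=3)
        assert np.isnan(tr.r)
        assert tr.direction == "none"

    def test_deforestation_scene_sign_recovery(self):
        # prescribed woody->grassland conversion only: grassland rises,
        # forest falls over the simulated period
        from lulcpipe.synthetic import SceneConfig, generate_truth
        cfg = SceneConfig(grid_rows=40, grid_cols=40, year_end=2010,
                          class_proportions={WOODY: 0.7, GRASSLAND: 0.3},
                          transition_rates={(WOODY, GRASSLAND): 0.04},
                          seed=31)
        truth = generate_truth(cfg)
        refined = refine_truth(truth)
        series = class_area_series(refined)
        period = (refined.years[0], refined.years[-1])
        up = trend_correlation(series, period, "grassland", seed=4)
        down = trend_correlation(series, period, "forest", seed=5)
        assert up.r > 0 and up.direction == "increase"
        assert down.r < 0 and down.direction == "decrease"


class TestTransitionMatrix:
    def test_identical_maps_are_diagonal(self, small_truth):
        refined = refine_truth(small_truth)
        y = refined.years[0]
        acct = transition_matrix(refined.maps[y], refined.maps[y])
        m = acct.matrix.to_numpy()
        assert np.all(m == np.diag(np.diag(m)))
        assert acct.net_deforestation_km2 == 0
        assert acct.net_reforestation_km2 == 0

    def test_four_pixel_toy_by_hand(self):
        base = np.array([[FOREST, FOREST], [GRASSLAND, WATER]], np.int8)
        end = np.array([[GRASSLAND, FOREST], [SECONDARY, WATER]], np.int8)
        acct = transition_matrix(base, end)
        drivers = acct.driver_summary().set_index("driver")
        assert drivers.loc["grassland", "percent"] == pytest.approx(100.0)
        refo = acct.reforestation_summary().set_index("source")
        assert refo.loc["grassland", "percent"] == pytest.approx(100.0)
        assert acct.net_deforestation_km2 == pytest.approx(PIXEL_AREA_KM2)
        assert acct.net_reforestation_km2 == pytest.approx(PIXEL_AREA_KM2)

    def test_entries_equal_bruteforce_pair_tally(self, small_truth):
        refined = refine_truth(small_truth)
        y0, y1 = refined.years[0], refined.years[-1]
        acct = transition_matrix(refined.maps[y0], refined.maps[y1])
        a = refined.maps[y0].ravel()
        b = refined.maps[y1].ravel()
        # matrix rows/cols follow code order, so position == class code
        for i in range(len(acct.matrix)):
            for j in range(len(acct.matrix)):
                n = int(np.sum((a == i) & (b == j)))
                assert acct.matrix.iloc[i, j] == pytest.approx(
                    n * PIXEL_AREA_KM2)

    def test_grand_total_equals_region_area(self, small_truth):
        refined = refine_truth(small_truth)
        y0, y1 = refined.years[0], refined.years[-1]
        acct = transition_matrix(refined.maps[y0], refined.maps[y1])
        area = small_truth.shape[0] * small_truth.shape[1] * PIXEL_AREA_KM2
        assert acct.total_area == pytest.approx(area)

    def test_antisymmetry_transpose_tally(self, small_truth):
        refined = refine_truth(small_truth)
        y0, y1 = refined.years[0], refined.years[-1]
        fwd = transition_matrix(refined.maps[y0], refined.maps[y1])
        rev = transition_matrix(refined.maps[y1], refined.maps[y0])
        np.testing.assert_allclose(fwd.matrix.to_numpy(),
                                   rev.matrix.to_numpy().T)

    def test_extent_mismatch_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            transition_matrix(np.zeros((3, 3), np.int8),
                              np.zeros((4, 4), np.int8))

    def test_prescribed_rate_recovery(self):
        # annual woody->grassland rate r over k steps: deforested fraction
        # of initial woody cells = 1 - (1-r)^k within 3-sigma binomial
        from lulcpipe.synthetic import SceneConfig, generate_truth
        r_rate, k = 0.03, 9
        cfg = SceneConfig(grid_rows=80, grid_cols=80,
                          year_start=2001, year_end=2001 + k,
                          class_proportions={WOODY: 0.7, GRASSLAND: 0.3},
                          transition_rates={(WOODY, GRASSLAND): r_rate},
                          seed=37)
        truth = generate_truth(cfg)
        base, end = truth.fine_truth[0], truth.fine_truth[-1]
        acct = transition_matrix(base, end)
        woody_base = (base == WOODY).sum()
        lost = int(((base == WOODY) & (end == GRASSLAND)).sum())
        p = 1 - (1 - r_rate) ** k
        sd = np.sqrt(woody_base * p * (1 - p))
        assert abs(lost - woody_base * p) <= 3 * sd
        # and the matrix agrees with the raw tally
        assert acct.matrix.loc["woody", "grassland"] == pytest.approx(
            lost * PIXEL_AREA_KM2)


class TestPercentPointChange:
    @pytest.mark.parametrize("start,end,expected", [
        (63.9, 68.5, 4.6), (68.5, 65.5, -3.0)])
    def test_published_woody_cover_changes(self, start, end, expected):
        assert percent_point_change(start, end) == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_no_change_is_zero(self, x):
        assert percent_point_change(x, x) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            percent_point_change(-1.0, 50.0)
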