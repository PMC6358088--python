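"""Generator behaviour: truth schedules, stacks, ancillary, interpretation."""

import numpy as np
import pandas as pd
import pytest

from lulcpipe.accuracy import interpretation_agreement
from lulcpipe.scheme import (
    COMPOSITES_PER_YEAR, GRASSLAND, VARIABLES, WETLAND, WOODY,
)
from lulcpipe.synthetic import (
    NOT_WOODY, SceneConfig, default_signature, generate_ancillary,
    generate_truth, interpret_labels, slope_from_elevation, synthesize_stack,
)


def _woody_since_brute(truth):
    """Independent per-pixel backward scan of the pixel_truth history."""
    years = truth.years
    out = np.full(truth.shape, NOT_WOODY, dtype=np.int64)
    r, c = truth.shape
    for i in range(r):
        for j in range(c):
            if truth.pixel_truth[-1, i, j] != WOODY:
                continue
            k = len(years) - 1
            while k >= 0 and truth.pixel_truth[k, i, j] == WOODY:
                k -= 1
            out[i, j] = years[k + 1]
    return out


class TestGenerateTruth:
    def test_zero_rates_freeze_the_landscape(self):
        cfg = SceneConfig(grid_rows=12, grid_cols=12, year_end=2005,
                          transition_rates={}, seed=5)
        truth = generate_truth(cfg)
        for t in range(1, len(truth.years)):
            np.testing.assert_array_equal(truth.fine_truth[t],
                                          truth.fine_truth[0])
        assert truth.change_log.empty

    def test_transition_count_within_binomial_band(self):
        # enough woody cells for a tight binomial band on one annual step
        rate = 0.05
        cfg = SceneConfig(grid_rows=40, grid_cols=40, year_start=2001,
                          year_end=2002, subgrid_factor=3,
                          class_proportions={WOODY: 0.8, GRASSLAND: 0.2},
                          transition_rates={(WOODY, GRASSLAND): rate},
                          seed=17)
        truth = generate_truth(cfg)
        n_woody = int((truth.fine_truth[0] == WOODY).sum())
        changed = int(((truth.fine_truth[0] == WOODY)
                       & (truth.fine_truth[1] == GRASSLAND)).sum())
        mean = n_woody * rate
        sd = np.sqrt(n_woody * rate * (1 - rate))
        assert abs(changed - mean) <= 3 * sd

    def test_woody_since_matches_backward_scan(self, small_truth):
        np.testing.assert_array_equal(small_truth.woody_since,
                                      _woody_since_brute(small_truth))

    def test_change_log_matches_raster_diff(self, small_truth):
        """Summed per-pair logged counts equal a brute-force diff of
        consecutive fine rasters."""
        total_logged = int(small_truth.change_log["n_cells"].sum())
        total_diff = sum(
            int((small_truth.fine_truth[t] != small_truth.fine_truth[t - 1])
                .sum())
            for t in range(1, len(small_truth.years)))
        assert total_logged == total_diff

    def test_year0_is_spatially_coherent(self, small_truth):
        # patches, not i.i.d. noise: most cells share class with a neighbour
        f = small_truth.fine_truth[0]
        same_right = (f[:, :-1] == f[:, 1:]).mean()
        assert same_right > 0.9

    def test_row_sum_over_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SceneConfig(transition_rates={(WOODY, GRASSLAND): 0.7,
                                          (WOODY, WETLAND): 0.5})

    def test_seeded_determinism(self):
        cfg = dict(grid_rows=10, grid_cols=10, year_end=2003, seed=99)
        a, b = generate_truth(SceneConfig(**cfg)), \
            generate_truth(SceneConfig(**cfg))
        np.testing.assert_array_equal(a.fine_truth, b.fine_truth)
        np.testing.assert_array_equal(a.woody_since, b.woody_since)


class TestSynthesizeStack:
    def test_noise_free_series_is_the_seasonal_curve(self, clean_config,
                                                     clean_truth,
                                                     clean_stack):
        sig = default_signature(0.03)
        periods = np.arange(1, COMPOSITES_PER_YEAR + 1, dtype=float)
        r, c = 3, 11
        cls = clean_truth.pixel_truth[0, r, c]
        expected = sig.curve(int(cls), "ndvi", periods)
        got = clean_stack.values["ndvi"][:COMPOSITES_PER_YEAR, r, c]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_fifteen_year_stack_has_345_layers(self):
        cfg = SceneConfig(grid_rows=5, grid_cols=5, year_start=2001,
                          year_end=2015, seed=3)
        truth = generate_truth(cfg)
        stack = synthesize_stack(truth, default_signature(), cfg)
        assert stack.n_layers == 345
        for var in VARIABLES:
            assert stack.values[var].shape[0] == 345

    def test_contaminated_fraction_within_binomial_band(self):
        p = 0.2
        cfg = SceneConfig(grid_rows=30, grid_cols=30, year_start=2001,
                          year_end=2005, cloud_prob=p, seed=8)
        truth = generate_truth(cfg)
        stack = synthesize_stack(truth, default_signature(), cfg)
        n = stack.contamination.size
        assert n >= 1e5
        frac = stack.contamination.mean()
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_determinism(self, clean_config, clean_truth):
        sig = default_signature()
        a = synthesize_stack(clean_truth, sig, clean_config)
        b = synthesize_stack(clean_truth, sig, clean_config)
        for var in VARIABLES:
            np.testing.assert_array_equal(a.values[var], b.values[var])


class TestAncillary:
    def test_flat_field_has_zero_slope(self):
        assert slope_from_elevation(np.full((8, 8), 55.0), 231.3).max() == 0

    def test_plane_slope_closed_form(self):
        # elevation = g * x: slope is arctan(g) everywhere
        g = 0.1
        x = np.arange(12) * 231.3
        elev = np.tile(g * x, (9, 1))
        expected = np.degrees(np.arctan(g))
        np.testing.assert_allclose(slope_from_elevation(elev, 231.3),
                                   expected, atol=1e-9)

    def test_wetland_lower_than_woody(self):
        # scene large enough that both classes are guaranteed patches
        cfg = SceneConfig(grid_rows=60, grid_cols=60, year_start=2001,
                          year_end=2001, seed=1)
        truth = generate_truth(cfg)
        elev, _ = generate_ancillary(truth, cfg)
        cls = truth.pixel_truth[0]
        assert (cls == WETLAND).sum() > 0 and (cls == WOODY).sum() > 0
        assert elev[cls == WETLAND].mean() < elev[cls == WOODY].mean()


class TestInterpretLabels:
    def _sites(self, truth, n, seed=0):
        rng = np.random.default_rng(seed)
        r = rng.integers(0, truth.shape[0], n)
        c = rng.integers(0, truth.shape[1], n)
        return pd.DataFrame({"row": r, "col": c,
                             "x": c * truth.pixel_size,
                             "y": r * truth.pixel_size,
                             "year": truth.years[0]})

    def test_zero_error_reproduces_truth(self, small_truth):
        sites = self._sites(small_truth, 200)
        out = interpret_labels(small_truth, sites, 0.0, seed=1)
        expected = small_truth.pixel_truth[0][sites["row"], sites["col"]]
        np.testing.assert_array_equal(out["label"].to_numpy(), expected)

    def test_five_percent_error_matches_agreement_regime(self, small_truth):
        # at n = 375 the interpreter-vs-truth kappa sits in the high-
        # agreement regime (kappa ~0.93 for a 5% error rate)
        sites = self._sites(small_truth, 375, seed=2)
        out = interpret_labels(small_truth, sites, 0.05, seed=3)
        truth_lbl = small_truth.pixel_truth[0][sites["row"], sites["col"]]
        res = interpretation_agreement(truth_lbl, out["label"].to_numpy())
        assert res["kappa"] >= 0.85
        assert abs(res["accuracy"] - 0.95) <= 0.03

    def test_full_flip_gives_zero_agreement(self, small_truth):
        sites = self._sites(small_truth, 300, seed=4)
        out = interpret_labels(small_truth, sites, 1.0, seed=5)
        truth_lbl = small_truth.pixel_truth[0][sites["row"], sites["col"]]
        assert (out["label"].to_numpy() == truth_lbl).sum() == 0

    def test_site_outside_extent_rejected(self, small_truth):
        sites = pd.DataFrame({"row": [999], "col": [0], "year": [2001]})
        with pytest.raises(IndexError):
            interpret_labels(small_truth, sites, 0.0)
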