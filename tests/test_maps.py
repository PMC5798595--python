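"""Median aggregation, hotspot localization and power-comparison arithmetic."""

import numpy as np
import pandas as pd
import pytest

from whiskmap import (
    AngleTrace,
    MotorMap,
    RegionSpec,
    StimGrid,
    Trial,
    average_across_mice,
    bilateral_maps,
    compute_metrics,
    grand_peak_stats,
    locate_region_peak,
    masked_extremum,
    per_mouse_map,
    percent_amplitude_reduction,
    percent_latency_increase,
)

from conftest import N_FRAMES, ONSET


GRID = StimGrid()


def metrics_frame(site_values, metric="mean_change_right", mouse="m1", power="high"):
    """Minimal metrics table: {(row, col): [trial values]}."""
    rows = []
    for (r, c), vals in site_values.items():
        ml, ap = GRID.site_coord(r, c)
        for i, v in enumerate(vals):
            rows.append({
                "mouse": mouse, "session": "s1", "rep": i, "row": r, "col": c,
                "ml_mm": ml, "ap_mm": ap, "power": power, metric: v,
            })
    return pd.DataFrame(rows)


def map_from(values, mouse="m1", metric="mean_change", whisker="right"):
    vals = np.asarray(values, dtype=float)
    return MotorMap(metric, whisker, mouse, "high", vals,
                    np.isfinite(vals).astype(int), GRID)


class TestPerMouseMap:
    def test_median_robust_to_outlier(self):
        df = metrics_frame({(2, 3): [-5.0, -6.0, 40.0]})
        m = per_mouse_map(df, "mean_change", "right", mouse_id="m1")
        assert m.values[2, 3] == -5.0
        assert m.n_trials[2, 3] == 3

    def test_even_count_midpoint(self):
        df = metrics_frame({(0, 0): [2.0, 4.0]})
        m = per_mouse_map(df, "mean_change", "right", mouse_id="m1")
        assert m.values[0, 0] == 3.0

    def test_censored_latencies_dropped(self):
        df = metrics_frame({(1, 1): [30.0, np.nan, 50.0]}, metric="latency_ms_right")
        m = per_mouse_map(df, "latency_ms", "right", mouse_id="m1")
        assert m.values[1, 1] == 40.0
        assert m.n_trials[1, 1] == 2

    def test_empty_site_missing(self):
        df = metrics_frame({(1, 1): [1.0]})
        m = per_mouse_map(df, "mean_change", "right", mouse_id="m1")
        assert m.missing[0, 0]
        assert not m.missing[1, 1]

    def test_trial_order_permutation_invariance(self):
        rng = np.random.default_rng(14)
        df = metrics_frame(
            {(r, c): list(rng.normal(0, 5, 7)) for r in range(8) for c in range(6)}
        )
        a = per_mouse_map(df, "mean_change", "right", mouse_id="m1")
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        b = per_mouse_map(shuffled, "mean_change", "right", mouse_id="m1")
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.n_trials, b.n_trials)


class TestAverageAcrossMice:
    def test_identical_maps_average_to_themselves(self):
        vals = np.arange(48, dtype=float).reshape(8, 6)
        maps = [map_from(vals, mouse=f"m{i}") for i in range(4)]
        avg = average_across_mice(maps)
        assert np.array_equal(avg.values, vals)
        assert (avg.mouse_count == 4).all()

    def test_missing_values_lower_the_count(self):
        base = np.zeros((8, 6))
        grids = []
        for i, v in enumerate([1.0, 2.0, 3.0, np.nan]):
            g = base.copy()
            g[4, 2] = v
            grids.append(map_from(g, mouse=f"m{i}"))
        avg = average_across_mice(grids)
        assert avg.values[4, 2] == 2.0
        assert avg.mouse_count[4, 2] == 3

    def test_inconsistent_maps_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            average_across_mice([
                map_from(np.zeros((8, 6))),
                map_from(np.zeros((8, 6)), metric="band_amp"),
            ])


class TestMaskedExtremum:
    def test_brute_force_oracle_on_random_maps(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            vals = rng.normal(0, 5, (8, 6))
            vals[rng.random((8, 6)) < 0.2] = np.nan
            mask = rng.random((8, 6)) < 0.7
            if not (mask & np.isfinite(vals)).any():
                continue
            for polarity in ("min", "max"):
                row, col, value = masked_extremum(vals, mask, polarity)
                best = None
                for r in range(8):
                    for c in range(6):
                        if not mask[r, c] or not np.isfinite(vals[r, c]):
                            continue
                        v = vals[r, c]
                        better = best is None or (
                            v < best[2] if polarity == "min" else v > best[2]
                        )
                        if better:
                            best = (r, c, v)
                assert (row, col, value) == best

    def test_tie_breaks_row_then_column(self):
        vals = np.zeros((8, 6))
        vals[2, 4] = vals[2, 1] = vals[5, 0] = 9.0
        assert masked_extremum(vals, np.ones((8, 6), bool), "max")[:2] == (2, 1)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            masked_extremum(np.full((8, 6), np.nan), np.ones((8, 6), bool), "min")


class TestRegionPeaks:
    def test_single_mouse_peak_without_sd(self):
        vals = np.zeros((8, 6))
        vals[5, 4] = -12.0
        peak = locate_region_peak([map_from(vals)], RegionSpec("wS1", "whole", "min"))
        assert peak.sites[0].row == 5 and peak.sites[0].col == 4
        assert peak.ml_sd is None and peak.value_sd is None
        assert peak.direction == "retraction" and peak.magnitude_mean == 12.0

    def test_masks_restrict_the_search(self):
        vals = np.zeros((8, 6))
        vals[1, 2] = 5.0   # anterior (ap > 0)
        vals[6, 1] = 8.0   # posterior
        maps = [map_from(vals)]
        ant = locate_region_peak(maps, RegionSpec("wM1_wM2", "anterior", "max"))
        post = locate_region_peak(maps, RegionSpec("PtA", "posterior", "max"))
        assert (ant.sites[0].row, ant.sites[0].col) == (1, 2)
        assert (post.sites[0].row, post.sites[0].col) == (6, 1)

    def test_companion_values_read_at_same_sites(self):
        vals = np.zeros((8, 6))
        vals[5, 4] = -12.0
        other = np.full((8, 6), 17.0)
        peak = locate_region_peak(
            [map_from(vals)], RegionSpec("wS1", "whole", "min"),
            companion_maps=[map_from(other, whisker="left")],
        )
        assert peak.sites[0].companion_value == 17.0

    def test_grand_peak_on_identical_maps_has_zero_sd(self):
        vals = np.zeros((8, 6))
        vals[5, 4] = -12.0
        maps = [map_from(vals, mouse=f"m{i}") for i in range(4)]
        avg = average_across_mice(maps)
        grand = grand_peak_stats(avg, maps, RegionSpec("wS1", "whole", "min"))
        assert grand.fixed_site == (5, 4)
        assert grand.value_mean == -12.0 and grand.value_sd == 0.0


class TestPowerComparison:
    def test_printed_example(self):
        assert percent_amplitude_reduction(-14.3, -6.6352) == pytest.approx(53.6, abs=0.01)

    def test_equal_powers_no_change(self):
        assert percent_amplitude_reduction(-10.0, -10.0) == 0.0
        assert percent_latency_increase(40.0, 40.0) == 0.0

    def test_zero_low_is_full_reduction(self):
        assert percent_amplitude_reduction(-10.0, 0.0) == 100.0

    def test_zero_high_undefined(self):
        assert np.isnan(percent_amplitude_reduction(0.0, 1.0))

    def test_latency_increase(self):
        assert percent_latency_increase(33.8, 88.15) == pytest.approx(160.8, abs=0.1)


class TestBilateralMaps:
    def test_identical_whiskers(self):
        rng = np.random.default_rng(30)
        trials = []
        for rep in range(3):
            for r, c in ((0, 0), (4, 3)):
                x = rng.normal(0, 1, N_FRAMES)
                x[ONSET:] += 5.0
                trials.append(Trial(
                    "m1", "s1", rep, (r, c), GRID.site_coord(r, c), "high",
                    AngleTrace(x), AngleTrace(x.copy()),
                ))
        df = compute_metrics(trials)
        diff, corr = bilateral_maps(df, mouse_id="m1")
        present = ~diff.missing
        assert np.allclose(diff.values[present], 0.0)
        assert np.allclose(corr.values[~corr.missing], 1.0, atol=1e-9)
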