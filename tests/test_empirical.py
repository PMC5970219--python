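"""In-vivo-style FRA/DSI analysis procedures."""

import numpy as np
import pandas as pd
import pytest

from onoffrf.empirical import (
    SpikeFRA,
    SweepSpikes,
    UnitProperties,
    bandwidth_30db,
    best_frequency,
    cf_shift_octaves,
    characteristic_frequency,
    default_freq_axis,
    default_level_axis,
    dsi,
    fit_dsi_regression,
    fra_boundary,
    fra_overlap_percent,
    is_direction_selective,
    lfp_on_amplitude,
    normalized_change,
    smooth_fra,
)

FREQS = default_freq_axis()
LEVELS = default_level_axis()


class TestGrid:
    def test_freq_axis_spacing(self):
        assert FREQS.size == 25
        assert FREQS[0] == pytest.approx(7.0)
        assert FREQS[-1] == pytest.approx(56.0)
        assert np.allclose(np.diff(np.log2(FREQS)), 0.125)

    def test_level_axis(self):
        assert LEVELS.size == 8
        assert LEVELS[0] == 10.0 and LEVELS[-1] == 80.0


class TestSmoothing:
    def test_constant_surface_unchanged(self):
        s = np.full((25, 8), 3.7)
        assert np.allclose(smooth_fra(s), 3.7)

    def test_interior_impulse_centre_weight(self):
        s = np.zeros((25, 8))
        s[10, 4] = 1.0
        sm = smooth_fra(s)
        assert sm[10, 4] == pytest.approx(0.25)  # centre tap 4/16

    def test_corner_renormalisation(self):
        s = np.zeros((25, 8))
        s[0, 0] = 1.0
        sm = smooth_fra(s)
        # corner sees taps 4,2,2,1 -> renormalised centre weight 4/9
        assert sm[0, 0] == pytest.approx(4.0 / 9.0)

    def test_interior_mass_conserved(self, rng):
        s = np.zeros((25, 8))
        s[5:20, 2:6] = rng.uniform(size=(15, 4))
        assert smooth_fra(s).sum() == pytest.approx(s.sum())

    def test_wrong_shape(self):
        with pytest.raises(ValueError):
            smooth_fra(np.zeros(25))


class TestBoundary:
    def test_below_threshold_empty(self):
        assert not fra_boundary(np.full((25, 8), 1.0), baseline=10.0).any()

    def test_inclusive_at_threshold(self):
        s = np.full((25, 8), 1.0)
        s[3, 3] = 13.0
        mask = fra_boundary(s, baseline=10.0)
        assert mask[3, 3] and mask.sum() == 1

    def test_zero_baseline_falls_back_to_surface_max(self):
        s = np.zeros((25, 8))
        s[5, 5] = 10.0
        s[6, 5] = 2.0
        mask = fra_boundary(s, baseline=0.0)
        assert mask[5, 5] and not mask[6, 5]


class TestCFAndBF:
    def test_single_cell_cf(self):
        mask = np.zeros((25, 8), dtype=bool)
        mask[8, 1] = True  # 14 kHz at 20 dB
        cf = characteristic_frequency(mask, FREQS, LEVELS)
        assert cf == pytest.approx(FREQS[8])

    def test_two_equal_cells_geometric_midpoint(self):
        mask = np.zeros((25, 8), dtype=bool)
        mask[8, 0] = mask[9, 0] = True
        cf = characteristic_frequency(mask, FREQS, LEVELS)
        assert cf == pytest.approx(np.sqrt(FREQS[8] * FREQS[9]))

    def test_lowest_level_wins(self):
        mask = np.zeros((25, 8), dtype=bool)
        mask[4, 2] = True
        mask[20, 5] = True
        assert characteristic_frequency(mask, FREQS, LEVELS) == pytest.approx(FREQS[4])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            characteristic_frequency(np.zeros((25, 8), bool), FREQS, LEVELS)

    def test_best_frequency_tie_breaks(self):
        s = np.zeros((25, 8))
        s[4, 2] = s[4, 5] = 7.0     # tie across levels -> lower level
        assert best_frequency(s, FREQS, LEVELS) == (FREQS[4], LEVELS[2])
        s2 = np.full((25, 8), 1.0)  # full tie -> lowest freq, lowest level
        assert best_frequency(s2, FREQS, LEVELS) == (FREQS[0], LEVELS[0])


class TestBandwidth:
    def test_single_point_zero_octaves(self):
        mask = np.zeros((25, 8), dtype=bool)
        mask[5, 0] = True       # threshold 10 dB
        mask[5, 3] = True       # 40 dB = threshold + 30
        assert bandwidth_30db(mask, FREQS, LEVELS) == 0.0

    def test_nine_cells_one_octave(self):
        mask = np.zeros((25, 8), dtype=bool)
        mask[5, 0] = True
        mask[5:14, 3] = True    # 9 contiguous cells at 0.125 oct spacing
        assert bandwidth_30db(mask, FREQS, LEVELS) == pytest.approx(1.0)

    def test_out_of_grid_flagged_undefined(self):
        mask = np.zeros((25, 8), dtype=bool)
        mask[5, 5] = True       # threshold 60 dB -> target 90 dB > 80
        assert bandwidth_30db(mask, FREQS, LEVELS) is None


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = np.zeros((25, 8), dtype=bool)
        a[3:8, 2:5] = True
        assert fra_overlap_percent(a, a) == pytest.approx(100.0)
        b = np.zeros_like(a)
        b[15:20, 2:5] = True
        assert fra_overlap_percent(a, b) == 0.0

    def test_intersection_over_mean(self):
        a = np.zeros((25, 8), dtype=bool)
        a.flat[:10] = True
        b = np.zeros_like(a)
        b.flat[:20] = True
        assert fra_overlap_percent(a, b) == pytest.approx(100 * 10 / 15)

    def test_both_empty_undefined(self):
        z = np.zeros((25, 8), dtype=bool)
        with pytest.raises(ValueError):
            fra_overlap_percent(z, z)


def make_sweeps(dsis, base=10.0, repeats=1):
    counts = {}
    for speed, d in dsis.items():
        counts[(speed, "UP")] = np.full(repeats, base * (1 + d))
        counts[(speed, "DOWN")] = np.full(repeats, base * (1 - d))
    return SweepSpikes(counts, tuple(sorted(dsis)))


class TestDSI:
    def test_examples(self):
        sw = make_sweeps({2.2: 0.0})
        assert dsi(sw, 2.2) == 0.0
        sw2 = SweepSpikes({(2.2, "UP"): [15], (2.2, "DOWN"): [5]})
        assert dsi(sw2, 2.2) == pytest.approx(0.5)

    def test_antisymmetry_and_bounds(self, rng):
        for _ in range(20):
            up, down = rng.uniform(0, 20, 2)
            sw = SweepSpikes({(2.2, "UP"): [up], (2.2, "DOWN"): [down]})
            flipped = SweepSpikes({(2.2, "UP"): [down], (2.2, "DOWN"): [up]})
            assert -1 <= dsi(sw, 2.2) <= 1
            assert dsi(flipped, 2.2) == pytest.approx(-dsi(sw, 2.2))

    def test_zero_spikes_flagged_zero(self):
        sw = SweepSpikes({(2.2, "UP"): [0], (2.2, "DOWN"): [0]})
        assert dsi(sw, 2.2) == 0.0

    @pytest.mark.parametrize("d1,d2,expected", [
        (0.2, 0.2, True),
        (0.06, -0.06, False),   # mean is zero: mean-then-abs ordering
        (0.05, 0.05, False),    # strictly above the criterion required
    ])
    def test_direction_selective_criterion(self, d1, d2, expected):
        sw = make_sweeps({2.2: d1, 4.4: d2})
        assert is_direction_selective(sw) is expected

    def test_missing_low_speed_raises(self):
        sw = make_sweeps({2.2: 0.3})
        with pytest.raises(ValueError):
            is_direction_selective(sw)


def synthetic_units(n, rng, slope=-0.5, noise=0.02):
    units = []
    for _ in range(n):
        cfd = rng.uniform(-0.5, 0.5)
        units.append(UnitProperties(
            on_rate_increase=rng.uniform(5, 15),
            off_rate_increase=rng.uniform(5, 15),
            fano_on=rng.uniform(0.8, 1.2),
            fano_off=rng.uniform(0.8, 1.2),
            spont_rate=rng.uniform(1, 4),
            fano_spont=rng.uniform(0.8, 1.2),
            bw_on=rng.uniform(0.8, 1.6),
            bw_off=rng.uniform(0.8, 1.6),
            overlap_pct=rng.uniform(30, 90),
            cf_diff_oct=cfd,
            dsi_low=slope * cfd + noise * rng.normal(),
        ))
    return units


class TestDSIRegression:
    def test_planted_slope_recovered_as_top_predictor(self, rng):
        res = fit_dsi_regression(synthetic_units(40, rng))
        coefs = res["coefficients"]
        top = max(coefs, key=lambda k: abs(coefs[k]))
        assert top == "cf_diff_oct"
        assert res["pre"]["cf_diff_oct"] == max(res["pre"].values())
        assert res["adjusted_r2"] > 0.8

    def test_near_zero_coefficient_gives_near_zero_pre(self, rng):
        res = fit_dsi_regression(synthetic_units(60, rng))
        # predictors unrelated to DSI contribute almost nothing
        for name in ("fano_on", "fano_off", "bw_on"):
            assert res["pre"][name] < 0.1

    def test_pre_formula_against_direct_computation(self, rng):
        units = synthetic_units(30, rng)
        res = fit_dsi_regression(units)
        df = pd.DataFrame([u.as_row() for u in units])
        X = df[list(UnitProperties.PREDICTORS)].to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        y = df["dsi_low"].to_numpy()
        coef = np.array([res["coefficients"][k] for k in UnitProperties.PREDICTORS])
        yhat = res["intercept"] + Z @ coef
        sse_full = ((y - yhat) ** 2).sum()
        assert sse_full == pytest.approx(res["sse_full"], rel=1e-8)
        j = list(UnitProperties.PREDICTORS).index("cf_diff_oct")
        yhat_trunc = yhat - coef[j] * Z[:, j]
        pre = (((y - yhat_trunc) ** 2).sum() - sse_full) / sse_full
        assert pre == pytest.approx(res["pre"]["cf_diff_oct"], rel=1e-8)

    def test_too_few_units(self, rng):
        with pytest.raises(ValueError):
            fit_dsi_regression(synthetic_units(8, rng))

    def test_collinear_predictors_named(self, rng):
        units = [u.as_row() for u in synthetic_units(30, rng)]
        for u in units:
            u["bw_off"] = 2.0 * u["bw_on"]   # exact collinearity
        with pytest.raises(ValueError, match="bw_o"):
            fit_dsi_regression(units)


class TestChangeMetrics:
    def test_normalized_change_examples(self):
        r = np.array([2.0, 4.0, 8.0])
        assert normalized_change(r, r) == 1.0
        assert normalized_change(r, 2 * r) == 2.0

    def test_floor_exclusion(self):
        r1 = np.array([0.0, 2.0])
        r2 = np.array([5.0, 4.0])
        assert normalized_change(r1, r2) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            normalized_change(np.zeros(3), np.ones(3))

    def test_lfp_amplitude_window(self):
        fs = 1000.0
        trace = np.zeros(500)
        assert lfp_on_amplitude(trace, fs) == 0.0
        trace[50] = -40.0
        assert lfp_on_amplitude(trace, fs) == -40.0
        late = np.zeros(500)
        late[350] = -40.0    # outside the 0-300 ms window
        assert lfp_on_amplitude(late, fs) == 0.0
        with pytest.raises(ValueError):
            lfp_on_amplitude(np.zeros(10), fs, window_ms=(0, 300))

    def test_cf_shift_examples(self):
        assert cf_shift_octaves(16.0, 16.0) == 0.0
        assert cf_shift_octaves(8.0, 16.0) == 1.0
        assert cf_shift_octaves(16.0, 13.45) == pytest.approx(-0.25, abs=0.01)
        with pytest.raises(ValueError):
            cf_shift_octaves(0.0, 5.0)
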