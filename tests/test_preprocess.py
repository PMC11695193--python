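"""Preparation chain: smoothing, compositing, aggregation, zonal means,
normalization, drought classification, sample assembly."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheatcast.containers import CountyMap, CountySeries, GridStack
from wheatcast.preprocess import (
    DroughtClass,
    EmptyCountyError,
    aggregate_climate,
    build_samples,
    classify_spei,
    denormalize_minmax,
    mask_and_average,
    mvc_composite,
    normalize_minmax,
    resample_bilinear,
    sg_smooth,
)

import pandas as pd


class TestSavitzkyGolay:
    def test_constant_series_unchanged(self):
        x = np.full(20, 3.7)
        assert np.allclose(sg_smooth(x), x)

    def test_quadratic_reproduced_exactly(self):
        t = np.arange(30, dtype=float)
        x = 0.3 * t**2 - 2.0 * t + 5.0
        assert np.allclose(sg_smooth(x, window=9, order=2), x, atol=1e-9)

    def test_interior_point_matches_normal_equations(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(25)
        # brute-force least-squares quadratic over points 8..16, evaluated at 12
        idx = np.arange(8, 17)
        A = np.vander(idx - 12.0, 3, increasing=True)
        coef, *_ = np.linalg.lstsq(A, x[idx], rcond=None)
        assert sg_smooth(x)[12] == pytest.approx(coef[0], abs=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 40))
        lhs = sg_smooth(2.5 * x - 1.5 * y)
        rhs = 2.5 * sg_smooth(x) - 1.5 * sg_smooth(y)
        assert np.allclose(lhs, rhs, atol=1e-9)

    @pytest.mark.parametrize("series_len,window", [(5, 9), (20, 8)])
    def test_invalid_inputs_rejected(self, series_len, window):
        with pytest.raises(ValueError):
            sg_smooth(np.zeros(series_len), window=window)


class TestMVC:
    def _stack(self, values, dates):
        return GridStack("SIF", values, dates)

    def test_dominant_second_frame_wins(self):
        a = np.zeros((1, 3, 3))
        b = np.ones((1, 3, 3))
        st = self._stack(np.concatenate([a, b]), [0, 4])
        out = mvc_composite(st, 8)
        assert np.allclose(out.values[0], 1.0)

    def test_one_frame_per_window_is_identity(self):
        rng = np.random.default_rng(1)
        vals = rng.random((4, 2, 2))
        st = self._stack(vals, [0, 8, 16, 24])
        out = mvc_composite(st, 8)
        assert np.allclose(out.values, vals)

    def test_matches_exhaustive_max_scan(self):
        rng = np.random.default_rng(2)
        dates = np.arange(0, 64, 4)
        vals = rng.random((len(dates), 5, 4))
        out = mvc_composite(self._stack(vals, dates), 8)
        for w, s in enumerate(out.start_dates):
            for r in range(5):
                for c in range(4):
                    contrib = [vals[i, r, c] for i, d in enumerate(dates) if s <= d < s + 8]
                    assert out.values[w, r, c] == pytest.approx(max(contrib))

    def test_nodata_ignored_unless_all_nodata(self):
        vals = np.array([[[np.nan, 0.2]], [[0.5, np.nan]]])
        out = mvc_composite(self._stack(vals, [0, 4]), 8)
        assert out.values[0, 0, 0] == pytest.approx(0.5)
        assert out.values[0, 0, 1] == pytest.approx(0.2)
        allnan = np.full((2, 1, 1), np.nan)
        out2 = mvc_composite(self._stack(allnan, [0, 4]), 8)
        assert np.isnan(out2.values[0, 0, 0])

    def test_empty_window_is_an_error(self):
        st = self._stack(np.zeros((2, 1, 1)), [0, 20])
        with pytest.raises(ValueError, match=r"\[8, 16\)"):
            mvc_composite(st, 8)

    def test_mvc_dominates_mean_composite(self):
        rng = np.random.default_rng(3)
        dates = np.arange(0, 32, 4)
        vals = rng.random((len(dates), 3, 3))
        st = self._stack(vals, dates)
        mx = mvc_composite(st, 8)
        mean = aggregate_climate(GridStack("x", vals, dates), 8,
                                 composite_starts=mx.start_dates)
        assert np.all(mx.values >= mean.values - 1e-12)


class TestAggregate:
    def test_constant_series(self):
        st = GridStack("T2m", np.full((16, 2, 2), 4.2), np.arange(16))
        out = aggregate_climate(st, 8)
        assert np.allclose(out.values, 4.2)

    def test_days_one_to_eight_mean(self):
        vals = np.arange(1, 9, dtype=float)[:, None, None]
        out = aggregate_climate(GridStack("x", vals, np.arange(8)), 8)
        assert out.values[0, 0, 0] == pytest.approx(4.5)

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((248, 2, 2))
        st = GridStack("T2m", vals, np.arange(248))
        out = aggregate_climate(st, 8)
        for w, s in enumerate(out.start_dates):
            assert np.allclose(out.values[w], vals[s : s + 8].mean(axis=0))


class TestBilinear:
    def test_identity_dims(self):
        rng = np.random.default_rng(5)
        g = rng.random((6, 7))
        assert np.allclose(resample_bilinear(g, 6, 7), g, atol=1e-12)

    def test_two_by_two_center(self):
        g = np.array([[0.0, 1.0], [1.0, 2.0]])
        out = resample_bilinear(g, 3, 3)
        assert out[1, 1] == pytest.approx(1.0)

    def test_matches_per_pixel_formula(self):
        rng = np.random.default_rng(6)
        g = rng.random((5, 5))
        out = resample_bilinear(g, 9, 9)
        for i in range(9):
            for j in range(9):
                r = min(max((i + 0.5) * 5 / 9 - 0.5, 0), 4)
                c = min(max((j + 0.5) * 5 / 9 - 0.5, 0), 4)
                r0, c0 = int(np.floor(r)), int(np.floor(c))
                r1, c1 = min(r0 + 1, 4), min(c0 + 1, 4)
                fr, fc = r - r0, c - c0
                exp = (
                    g[r0, c0] * (1 - fr) * (1 - fc) + g[r0, c1] * (1 - fr) * fc
                    + g[r1, c0] * fr * (1 - fc) + g[r1, c1] * fr * fc
                )
                assert out[i, j] == pytest.approx(exp)

    def test_bad_target_dims(self):
        with pytest.raises(ValueError):
            resample_bilinear(np.zeros((3, 3)), 0, 4)


class TestZonalMeans:
    def test_uniform_grid(self):
        cm = CountyMap(np.array([[0, 0], [1, 1]]), np.ones((2, 2), bool))
        st = GridStack("EVI", np.full((3, 2, 2), 7.0), [0, 8, 16])
        out = mask_and_average(st, cm)
        assert np.allclose(out, 7.0)

    def test_hand_example(self):
        cm = CountyMap(np.array([[0, 0], [1, 1]]), np.ones((2, 2), bool))
        vals = np.array([[[2.0, 4.0], [10.0, 20.0]]])
        out = mask_and_average(GridStack("x", vals, [0]), cm)
        assert out[0, 0] == pytest.approx(3.0)
        assert out[1, 0] == pytest.approx(15.0)

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 4, size=(6, 6))
        labels.flat[:4] = [0, 1, 2, 3]  # every county non-empty
        mask = rng.random((6, 6)) < 0.7
        for c in range(4):
            mask[np.nonzero(labels == c)[0][0], np.nonzero(labels == c)[1][0]] = True
        cm = CountyMap(labels, mask)
        vals = rng.random((3, 6, 6))
        out = mask_and_average(GridStack("x", vals, [0, 8, 16]), cm)
        for c in range(4):
            sel = (labels == c) & mask
            for t in range(3):
                assert out[c, t] == pytest.approx(vals[t][sel].mean())

    def test_weighted_recombination_recovers_global_mean(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 3, size=(8, 8))
        labels.flat[:3] = [0, 1, 2]
        cm = CountyMap(labels, np.ones((8, 8), bool))
        vals = rng.random((2, 8, 8))
        out = mask_and_average(GridStack("x", vals, [0, 8]), cm)
        counts = np.bincount(labels.ravel(), minlength=3)
        recombined = (out * counts[:, None]).sum(axis=0) / counts.sum()
        assert np.allclose(recombined, vals.reshape(2, -1).mean(axis=1), atol=1e-9)

    def test_empty_county_is_named(self):
        cm = CountyMap(np.array([[0, 1]]), np.array([[True, False]]))
        st = GridStack("x", np.zeros((1, 1, 2)), [0])
        with pytest.raises(EmptyCountyError) as err:
            mask_and_average(st, cm)
        assert err.value.county_ids == [1]


class TestNormalization:
    def test_span_maps_to_unit_interval(self):
        X = np.linspace(-3.0, 5.0, 11)[None, :, None]
        Xn, params = normalize_minmax(X)
        assert Xn.min() == 0.0 and Xn.max() == 1.0

    def test_round_trip(self):
        rng = np.random.default_rng(9)
        X = rng.random((4, 6, 3)) * 10 - 5
        Xn, params = normalize_minmax(X)
        assert np.allclose(denormalize_minmax(Xn, params), X, atol=1e-12)

    def test_out_of_range_test_values_clip(self):
        Xtr = np.array([[[0.0], [1.0]]])
        _, params = normalize_minmax(Xtr)
        Xte, _ = normalize_minmax(np.array([[[2.0], [-1.0]]]), params=params)
        assert Xte[0, 0, 0] == 1.0
        assert Xte[0, 1, 0] == 0.0

    def test_degenerate_feature_maps_to_zero_with_warning(self, caplog):
        X = np.full((2, 3, 1), 4.0)
        with caplog.at_level(logging.WARNING, logger="wheatcast.preprocess"):
            Xn, _ = normalize_minmax(X)
        assert np.all(Xn == 0.0)
        assert any("constant feature" in r.message for r in caplog.records)

    def test_param_feature_count_mismatch(self):
        _, params = normalize_minmax(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            normalize_minmax(np.zeros((1, 2, 3)), params=params)


class TestSPEIClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.3, "ND"),
            (-0.5, "MD1"),
            (-0.9, "MD1"),
            (-1.0, "MD2"),
            (-1.2, "MD2"),
            (-1.5, "SD"),
            (-2.0, "ED"),
            (-3.0, "ED"),
        ],
    )
    def test_band_boundaries(self, value, expected):
        assert classify_spei(value).name == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_spei(float("nan"))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        a=st.floats(-10, 10, allow_nan=False),
        b=st.floats(-10, 10, allow_nan=False),
    )
    def test_monotone_step_function(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert classify_spei(lo).severity >= classify_spei(hi).severity


class TestBuildSamples:
    def _series(self, county, year, T=5, F=("EVI", "SIF")):
        rng = np.random.default_rng(county * 10 + year)
        return CountySeries(county, year, rng.random((T, len(F))), F, np.arange(T) * 8)

    def _yields(self, pairs):
        return pd.DataFrame(
            [{"county_id": c, "year": y, "yield_kg_ha": 5000.0 + c} for c, y in pairs]
        )

    def test_shapes(self):
        series = [self._series(c, y) for c in range(3) for y in range(2)]
        pairs = [(c, y) for c in range(3) for y in range(2)]
        s = build_samples(series, self._yields(pairs), ("EVI", "SIF"))
        assert s.X.shape == (6, 5, 2)

    def test_channel_order_carries_values_verbatim(self):
        series = [self._series(c, y) for c in range(3) for y in range(2)]
        pairs = [(c, y) for c in range(3) for y in range(2)]
        s = build_samples(series, self._yields(pairs), ("EVI", "SIF"))
        assert np.array_equal(s.X[0, :, 0], series[0].values[:, 0])
        # reversed order swaps channels
        s2 = build_samples(series, self._yields(pairs), ("SIF", "EVI"))
        assert np.array_equal(s2.X[0, :, 0], series[0].values[:, 1])

    def test_missing_yield_excluded_with_log(self, caplog):
        series = [self._series(c, y) for c in range(3) for y in range(2)]
        pairs = [(c, y) for c in range(3) for y in range(2)][:-1]
        with caplog.at_level(logging.INFO, logger="wheatcast.preprocess"):
            s = build_samples(series, self._yields(pairs), ("EVI",))
        assert len(s) == 5
        assert any("no yield record" in r.message for r in caplog.records)

    def test_unknown_feature_rejected(self):
        series = [self._series(0, 0)]
        with pytest.raises(KeyError):
            build_samples(series, self._yields([(0, 0)]), ("NDVI",))
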