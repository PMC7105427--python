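"""Shear metrics: cycle averages, maxima, oscillatory index, region statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftmetrics import (
    CycleWindow,
    FieldSeries,
    MetricMap,
    RegionMask,
    SurfaceMesh,
    ThresholdSpec,
    area_fraction,
    compute_osi,
    compute_tawss,
    compute_wss_max,
    region_median,
    robust_max,
)

from conftest import sin_x_series, vector_series


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestTawss:
    def test_constant_vector(self, unit_window):
        s = vector_series(np.tile([3.0, 0.0, 0.0], (1000, 1)), unit_window)
        assert compute_tawss(s, unit_window).values[0] == pytest.approx(3.0)

    def test_abs_sine_closed_form(self, unit_window):
        # mean of |sin| over one period is 2/pi
        s = sin_x_series(unit_window)
        assert compute_tawss(s, unit_window).values[0] == pytest.approx(
            2 / np.pi, abs=1e-4
        )

    def test_zero_field(self, unit_window):
        s = vector_series(np.zeros((1000, 3)), unit_window)
        assert compute_tawss(s, unit_window).values[0] == 0.0

    def test_second_order_time_convergence(self):
        # |sin| has integrand kinks at the sample points: composite trapezoid
        # over the smooth pieces converges at exactly second order
        errors = []
        for n in (17, 33, 65, 129):
            w = CycleWindow.uniform(1.0, n)
            tawss = compute_tawss(sin_x_series(w), w).values[0]
            errors.append(abs(tawss - 2 / np.pi))
        rates = [np.log2(errors[i] / errors[i + 1]) for i in range(len(errors) - 1)]
        assert min(rates) > 1.8  # second order


class TestWssMax:
    def test_sine_through_peak(self):
        w = CycleWindow.uniform(1.0, 5)  # includes t = 0.25 where sin peaks
        s = sin_x_series(w)
        assert compute_wss_max(s, w).values[0] == pytest.approx(1.0)

    def test_constant(self, unit_window):
        s = vector_series(np.tile([0.0, 2.0, 0.0], (1000, 1)), unit_window)
        assert compute_wss_max(s, unit_window).values[0] == pytest.approx(2.0)

    def test_dominates_tawss_on_random_fields(self, unit_window):
        rng = np.random.default_rng(42)
        vals = rng.standard_normal((unit_window.n_samples, 30, 3))
        s = FieldSeries(
            kind="vector3", attachment="element", values=vals, units="Pa", window=unit_window
        )
        tawss = compute_tawss(s, unit_window).values
        wmax = compute_wss_max(s, unit_window).values
        assert np.all(wmax >= tawss - 1e-12)


class TestOsi:
    def test_steady_unidirectional_is_zero(self, unit_window):
        s = vector_series(np.tile([2.0, 0.0, 0.0], (1000, 1)), unit_window)
        assert compute_osi(s, unit_window).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_pure_reversal_is_half(self, unit_window):
        s = sin_x_series(unit_window)
        assert compute_osi(s, unit_window).values[0] == pytest.approx(0.5, abs=1e-6)

    def test_three_quarter_forward_oracle(self):
        # forward 3T/4, reverse T/4 at equal magnitude: brute-force quadrature
        n = 4001  # sample falls exactly on the break
        w = CycleWindow.uniform(1.0, n)
        sig = np.zeros((n, 3))
        sig[:, 0] = np.where(w.sample_times < 0.75, 1.0, -1.0)
        s = vector_series(sig, w)
        osi = compute_osi(s, w).values[0]
        # independent brute-force evaluation of the definition
        wts = w.trapezoid_weights()
        num = abs(np.sum(wts * sig[:, 0]))
        den = np.sum(wts * np.abs(sig[:, 0]))
        assert osi == pytest.approx(0.5 * (1 - num / den), abs=1e-12)
        assert osi == pytest.approx(0.25, abs=1e-3)

    def test_degenerate_zero_field_flagged(self, unit_window):
        s = vector_series(np.zeros((1000, 3)), unit_window)
        m = compute_osi(s, unit_window)
        assert m.values[0] == 0.0
        assert m.flagged[0]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds_hold_for_arbitrary_series(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        w = CycleWindow.uniform(1.0, int(n))
        vals = rng.standard_normal((int(n), 5, 3)) * rng.lognormal(0, 2)
        s = FieldSeries(
            kind="vector3", attachment="element", values=vals, units="Pa", window=w
        )
        osi = compute_osi(s, w).values
        assert np.all(osi >= 0.0) and np.all(osi <= 0.5)

    def test_rotation_invariance_of_all_metrics(self, unit_window):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((unit_window.n_samples, 10, 3))
        s = FieldSeries(
            kind="vector3", attachment="element", values=vals, units="Pa", window=unit_window
        )
        R = random_rotation(rng)
        s_rot = FieldSeries(
            kind="vector3",
            attachment="element",
            values=vals @ R.T,
            units="Pa",
            window=unit_window,
        )
        for fn in (compute_tawss, compute_wss_max, compute_osi):
            np.testing.assert_allclose(
                fn(s, unit_window).values, fn(s_rot, unit_window).values, rtol=1e-9
            )


class TestAreaFraction:
    def _map(self, vals):
        return MetricMap(values=np.asarray(vals, dtype=float), units="Pa", metric_name="WSS_max")

    def test_equal_areas(self, flat_patch):
        vals = np.zeros(10)
        vals[:3] = 50.0
        region = flat_patch.all_elements_mask()
        th = ThresholdSpec("WSS_max", 40.0, "above")
        assert area_fraction(self._map(vals), th, region) == pytest.approx(30.0)

    def test_area_weighting(self):
        # two elements with areas 1 and 3; only the larger exceeds
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 2, 0], [10, 0, 0], [13, 0, 0], [10, 2, 0]],
            dtype=float,
        )
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = SurfaceMesh(points=pts, triangles=tris)
        th = ThresholdSpec("WSS_max", 7.0, "above")
        frac = area_fraction(self._map([1.0, 10.0]), th, mesh.all_elements_mask())
        assert frac == pytest.approx(75.0)

    def test_all_below_is_zero(self, flat_patch):
        th = ThresholdSpec("WSS_max", 40.0, "above")
        frac = area_fraction(self._map(np.ones(10)), th, flat_patch.all_elements_mask())
        assert frac == 0.0

    def test_strict_inequality_at_bound(self, flat_patch):
        th = ThresholdSpec("WSS_max", 7.0, "above")
        frac = area_fraction(self._map(np.full(10, 7.0)), th, flat_patch.all_elements_mask())
        assert frac == 0.0

    def test_below_direction(self, flat_patch):
        th = ThresholdSpec("TAWSS", 0.1, "below")
        vals = np.full(10, 0.05)
        vals[5:] = 1.0
        frac = area_fraction(self._map(vals), th, flat_patch.all_elements_mask())
        assert frac == pytest.approx(50.0)

    def test_empty_region_rejected(self, flat_patch):
        region = RegionMask(element_ids=np.array([], dtype=int), label="custom", mesh=flat_patch)
        with pytest.raises(ValueError, match="empty"):
            area_fraction(self._map(np.ones(10)), ThresholdSpec("x", 1, "above"), region)

    def test_nested_thresholds_monotone(self, flat_patch):
        rng = np.random.default_rng(3)
        region = flat_patch.all_elements_mask()
        for _ in range(50):
            m = self._map(rng.lognormal(2, 1.5, size=10))
            f40 = area_fraction(m, ThresholdSpec("WSS_max", 40.0, "above"), region)
            f7 = area_fraction(m, ThresholdSpec("WSS_max", 7.0, "above"), region)
            assert f40 <= f7


def brute_force_robust_max(values, areas, omit_fraction):
    """Independent loop implementation of the top-area-omission rule."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    total = sum(areas)
    removed_area = 0.0
    removed = set()
    for i in order:
        if removed_area >= omit_fraction * total - 1e-15 * total:
            break
        removed.add(i)
        removed_area += areas[i]
    kept = [values[i] for i in range(len(values)) if i not in removed]
    return max(kept) if kept else min(values)


class TestRobustMax:
    def test_hundred_equal_elements(self):
        # 100 equal-area elements valued 1..100; omitting the top 1% of area
        # discards exactly the highest element
        pts, tris = [], []
        for i in range(100):
            base = len(pts)
            pts += [(i, 0, 0), (i + 1, 0, 0), (i, 1, 0)]
            tris.append((base, base + 1, base + 2))
        mesh = SurfaceMesh(points=np.array(pts, dtype=float), triangles=np.array(tris))
        m = MetricMap(values=np.arange(1.0, 101.0), units="Pa", metric_name="x")
        region = mesh.all_elements_mask()
        assert robust_max(m, region, 0.01) == pytest.approx(99.0)
        assert robust_max(m, region, 0.0) == pytest.approx(100.0)

    def test_top_element_holding_double_area(self):
        # top-valued element holds 2% of area; omitting 1% must remove it
        pts = [(0, 0, 0), (2, 0, 0), (0, 2, 0)]  # area 2
        tris = [(0, 1, 2)]
        for i in range(98):
            base = len(pts)
            x = 3 + i
            pts += [(x, 0, 0), (x + 1, 0, 0), (x, 2, 0)]  # area 1 each
            tris.append((base, base + 1, base + 2))
        mesh = SurfaceMesh(points=np.array(pts, dtype=float), triangles=np.array(tris))
        vals = np.concatenate([[1000.0], np.arange(98.0)])
        m = MetricMap(values=vals, units="Pa", metric_name="x")
        assert robust_max(m, mesh.all_elements_mask(), 0.01) == pytest.approx(97.0)

    def test_matches_brute_force_on_random_instances(self, flat_patch):
        rng = np.random.default_rng(11)
        region = flat_patch.all_elements_mask()
        areas = flat_patch.element_area
        for _ in range(100):
            vals = rng.standard_normal(10) * 10
            omit = float(rng.uniform(0, 0.5))
            m = MetricMap(values=vals, units="Pa", metric_name="x")
            expected = brute_force_robust_max(list(vals), list(areas), omit)
            assert robust_max(m, region, omit) == pytest.approx(expected)

    def test_monotone_in_omit_fraction(self, flat_patch):
        rng = np.random.default_rng(5)
        m = MetricMap(values=rng.standard_normal(10), units="Pa", metric_name="x")
        region = flat_patch.all_elements_mask()
        prev = np.inf
        for omit in (0.0, 0.1, 0.2, 0.4, 0.8):
            cur = robust_max(m, region, omit)
            assert cur <= prev + 1e-12
            assert cur <= robust_max(m, region, 0.0)
            prev = cur

    def test_omit_fraction_one_rejected(self, flat_patch):
        m = MetricMap(values=np.ones(10), units="Pa", metric_name="x")
        with pytest.raises(ValueError):
            robust_max(m, flat_patch.all_elements_mask(), 1.0)


class TestRegionMedian:
    def test_equal_area_elements(self, flat_patch):
        vals = np.zeros(10)
        vals[:3] = [1.0, 2.0, 3.0]
        m = MetricMap(values=np.array([1, 2, 3], dtype=float), units="Pa", metric_name="x")
        region = RegionMask(element_ids=np.array([0, 1, 2]), label="custom", mesh=flat_patch)
        full = MetricMap(values=vals, units="Pa", metric_name="x")
        assert region_median(full, region) == pytest.approx(2.0)

    def test_area_weighted_median_oracle(self):
        # values {1, 10} with areas {3, 1}: half the area is reached inside
        # the low-valued element
        pts = np.array(
            [[0, 0, 0], [3, 0, 0], [0, 2, 0], [10, 0, 0], [11, 0, 0], [10, 2, 0]],
            dtype=float,
        )
        mesh = SurfaceMesh(points=pts, triangles=np.array([[0, 1, 2], [3, 4, 5]]))
        m = MetricMap(values=np.array([1.0, 10.0]), units="Pa", metric_name="x")
        assert region_median(m, mesh.all_elements_mask()) == pytest.approx(1.0)
        # count-based alternative sits between the two values
        assert region_median(m, mesh.all_elements_mask(), area_weighted=False) == pytest.approx(5.5)

    def test_constant_map(self, flat_patch):
        m = MetricMap(values=np.full(10, 3.3), units="Pa", metric_name="x")
        assert region_median(m, flat_patch.all_elements_mask()) == pytest.approx(3.3)
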