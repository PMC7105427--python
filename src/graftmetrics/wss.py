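"""Wall-shear-stress metrics over one cardiac cycle.

Implements the three standard haemodynamic wall parameters used to assess
arteriovenous graft anastomoses:

* TAWSS, the time-averaged WSS magnitude ``(1/T) integral ||tau(t)|| dt``;
* WSS_max, the time-maximum WSS magnitude (sampled maximum, no
  inter-sample interpolation);
* OSI, the oscillatory shear index
  ``0.5 * (1 - ||integral tau dt|| / integral ||tau|| dt)``,
  ranging from 0 (unidirectional shear) to 0.5 (perfectly oscillatory,
  zero net shear).

plus the region statistics those maps feed: threshold-exceedance area
fractions, area-weighted medians, and an artefact-robust maximum that
discards the highest-valued elements holding the top 1% of region area.

All time integrals use the trapezoidal rule on the window's actual sample
times, so non-uniform solver output is handled without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import CycleWindow, FieldSeries, MetricMap, RegionMask

#: Exceedance thresholds commonly applied to anastomotic WSS maps:
#: TAWSS below the physiological floor of 0.1 Pa, time-maximum WSS above the
#: physiological ceiling of 7 Pa, above the 40 Pa endothelial-damage level,
#: and OSI above 0.25 for highly oscillatory shear.
DEFAULT_THRESHOLDS: tuple["ThresholdSpec", ...] = ()  # populated below


@dataclass(frozen=True)
class ThresholdSpec:
    """A one-sided bound on a metric map, e.g. ``WSS_max > 40 Pa``."""

    metric_name: str
    bound: float
    direction: Literal["above", "below"]
    units: str = "Pa"

    def __post_init__(self):
        if not np.isfinite(self.bound):
            raise ValueError("threshold bound must be finite")
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")

    @property
    def label(self) -> str:
        op = ">" if self.direction == "above" else "<"
        unit = f" {self.units}" if self.units else ""
        return f"{self.metric_name}{op}{self.bound:g}{unit}"


DEFAULT_THRESHOLDS = (
    ThresholdSpec("OSI", 0.25, "above", units=""),
    ThresholdSpec("TAWSS", 0.1, "below"),
    ThresholdSpec("WSS_max", 7.0, "above"),
    ThresholdSpec("WSS_max", 40.0, "above"),
)


def _check_vector_series(wss: FieldSeries, window: CycleWindow) -> None:
    if wss.kind != "vector3":
        raise ValueError(f"WSS series must be vector3, got {wss.kind}")
    if wss.window is not window and not np.array_equal(
        wss.window.sample_times, window.sample_times
    ):
        raise ValueError("series sample times do not match the analysis window")


def compute_tawss(wss: FieldSeries, window: CycleWindow) -> MetricMap:
    """Time-averaged WSS magnitude per element, in Pa."""
    _check_vector_series(wss, window)
    w = window.trapezoid_weights()
    mag = wss.magnitude()  # (n_t, n_e)
    vals = (w @ mag) / window.period_T
    return MetricMap(values=vals, units="Pa", metric_name="TAWSS", window=window)


def compute_wss_max(wss: FieldSeries, window: CycleWindow) -> MetricMap:
    """Sampled time-maximum WSS magnitude per element, in Pa."""
    _check_vector_series(wss, window)
    vals = wss.magnitude().max(axis=0)
    return MetricMap(values=vals, units="Pa", metric_name="WSS_max", window=window)


def compute_osi(
    wss: FieldSeries, window: CycleWindow, zero_tolerance: float = 1e-12
) -> MetricMap:
    """Oscillatory shear index per element, dimensionless in [0, 0.5].

    Elements whose cycle-integrated WSS magnitude falls below
    ``zero_tolerance * T`` are degenerate (the index is 0/0 there); they are
    reported as 0 — no oscillation — and flagged in the returned map.
    """
    _check_vector_series(wss, window)
    w = window.trapezoid_weights()
    int_vec = np.einsum("t,tec->ec", w, wss.values)  # integral of tau
    int_mag = w @ wss.magnitude()  # integral of ||tau||
    degenerate = int_mag < zero_tolerance * window.period_T
    safe = np.where(degenerate, 1.0, int_mag)
    osi = 0.5 * (1.0 - np.linalg.norm(int_vec, axis=1) / safe)
    osi = np.clip(osi, 0.0, 0.5)  # guard float round-off at the bounds
    osi[degenerate] = 0.0
    return MetricMap(
        values=osi, units="", metric_name="OSI", window=window, flagged=degenerate
    )


def area_fraction(
    metric_map: MetricMap, threshold: ThresholdSpec, region: RegionMask
) -> float:
    """Percent of region area where the map satisfies the threshold strictly."""
    if region.is_empty:
        raise ValueError(f"region {region.label!r} is empty")
    vals = metric_map.values[region.element_ids]
    areas = region.mesh.element_area[region.element_ids]
    if threshold.direction == "above":
        hit = vals > threshold.bound
    else:
        hit = vals < threshold.bound
    return float(100.0 * areas[hit].sum() / region.total_area)


def robust_max(
    metric_map: MetricMap, region: RegionMask, omit_area_fraction: float = 0.01
) -> float:
    """Maximum after discarding the highest-valued top-area sliver.

    Member elements are sorted by value descending (ties broken by element id
    ascending) and removed from the top until the removed area reaches
    ``omit_area_fraction`` of the region area; the result is the maximum of
    what remains.  With ``omit_area_fraction=0`` this is the plain maximum.
    The omission guards reported maxima against localised mesh artefacts.
    """
    if region.is_empty:
        raise ValueError(f"region {region.label!r} is empty")
    if omit_area_fraction >= 1.0:
        raise ValueError("omit_area_fraction must be < 1")
    if omit_area_fraction < 0.0:
        raise ValueError("omit_area_fraction must be >= 0")
    ids = region.element_ids
    vals = metric_map.values[ids]
    areas = region.mesh.element_area[ids]
    # descending value, ties by ascending element id
    order = np.lexsort((ids, -vals))
    cum_before = np.concatenate([[0.0], np.cumsum(areas[order])[:-1]])
    keep = cum_before >= omit_area_fraction * region.total_area - 1e-15 * region.total_area
    kept = vals[order][keep]
    if kept.size == 0:  # everything removed; fall back to the smallest value
        return float(vals[order][-1])
    return float(kept.max())


def region_median(
    metric_map: MetricMap, region: RegionMask, area_weighted: bool = True
) -> float:
    """Median of a metric map over a region.

    By default the median is area-weighted — the value at which cumulative
    member area (elements sorted by value ascending) first reaches half the
    region area — so the statistic does not depend on local mesh density.
    ``area_weighted=False`` gives the plain element-count median.
    """
    if region.is_empty:
        raise ValueError(f"region {region.label!r} is empty")
    vals = metric_map.values[region.element_ids]
    if not area_weighted:
        return float(np.median(vals))
    areas = region.mesh.element_area[region.element_ids]
    order = np.argsort(vals, kind="stable")
    cum = np.cumsum(areas[order])
    half = 0.5 * region.total_area
    idx = int(np.searchsorted(cum, half * (1 - 1e-12)))
    idx = min(idx, len(vals) - 1)
    return float(vals[order][idx])
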